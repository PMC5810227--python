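"""Simulate a structured cohort and inspect the focal variant.

Generates 2,000 samples from two mildly diverged subpopulations with a
PPARG-like missense variant at MAF 0.131 plus background markers, then
checks that the realized genotype counts and Hardy-Weinberg behavior look
like a real exome-array cohort.
"""

import numpy as np

from gbrecall import (
    CohortSpec,
    MarkerSpec,
    compute_genotype_counts,
    hwe_exact_pvalue,
    simulate_covariates,
    simulate_genotypes,
)

markers = (MarkerSpec(maf=0.131, rsid="rs1801282", consequence="missense"),) + tuple(
    MarkerSpec(maf=m) for m in np.linspace(0.05, 0.5, 30)
)
spec = CohortSpec(
    n_samples=2000,
    markers=markers,
    n_subpops=2,
    fst_like_divergence=0.01,
    related_pairs=5,
    seed=42,
)

genotypes = simulate_genotypes(spec)
covariates = simulate_covariates(spec)

counts = compute_genotype_counts(genotypes, "rs1801282")
print(f"samples x markers: {genotypes.n_samples} x {genotypes.n_markers}")
print(f"focal genotype counts (minor-hom / het / major-hom): "
      f"{counts.n_minor_hom} / {counts.n_het} / {counts.n_major_hom}")
print(f"realized MAF: {counts.maf:.4f}  (target 0.131)")
p = hwe_exact_pvalue(counts)
print(f"exact HWE p = {p:.3f} -> {'consistent with' if p > 1e-4 else 'deviates from'} "
      "Hardy-Weinberg, as expected for a clean simulated marker")
print(f"age range: {covariates['age'].min():.1f}-{covariates['age'].max():.1f} y, "
      f"{covariates['sex'].mean():.0%} female")
# A realized MAF near 0.131 with a comfortably non-significant HWE p means the
# generator is drawing genotypes from the intended population model.
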