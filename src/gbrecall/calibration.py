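"""Monte-Carlo calibration experiments for the association pipeline.

Replicated end-to-end runs of the synthetic generator plus the association
scan, used to verify that the pipeline recovers a simulated additive effect
without bias and holds its nominal type-I error. These are the package's
own operating-characteristic checks, exercised by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .screen import PhenotypeSpec, association_scan, prepare_phenotype
from .simulate import CohortSpec, EffectSpec, MarkerSpec, simulate_genotypes, simulate_phenotypes

__all__ = ["beta_recovery", "type_one_error"]


def _fixed_covariates(n: int, sample_ids, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    return pd.DataFrame(
        {"age": rng.uniform(45, 75, n), "sex": rng.integers(0, 2, n)},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _one_replicate(n: int, maf: float, beta: float, seed: int,
                   cov: pd.DataFrame | None = None):
    spec = CohortSpec(n_samples=n, markers=(MarkerSpec(maf=maf, rsid="rsSIM"),),
                      seed=seed)
    gm = simulate_genotypes(spec)
    if cov is None:
        cov = _fixed_covariates(n, gm.sample_ids, seed)
    eff = EffectSpec("rsSIM", beta_per_allele=beta, noise_sd=1.0)
    pheno = simulate_phenotypes(gm, eff, cov, seed=seed)["phenotype"]
    z, _ = prepare_phenotype(pheno, PhenotypeSpec("phenotype"))
    res = association_scan(gm, ["rsSIM"], z, cov)
    return float(res.at["rsSIM", "beta"]), float(res.at["rsSIM", "p"])


def beta_recovery(n: int, maf: float, beta: float, reps: int, seed: int) -> dict:
    """Mean estimated effect over ``reps`` fresh cohorts with a true effect.

    Each replicate simulates a cohort at the given size and MAF, injects an
    additive effect of ``beta`` phenotype-SD per minor allele on a unit-SD
    noise background, z-scores the phenotype and runs the covariate-
    adjusted scan. Returns mean/SD of the estimates and the bias.
    """
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(reps)]
    cov = None
    betas = np.empty(reps)
    for r, s in enumerate(sub_seeds):
        betas[r], _ = _one_replicate(n, maf, beta, s, cov)
    return {
        "mean_beta_hat": float(betas.mean()),
        "sd_beta_hat": float(betas.std(ddof=1)),
        "bias": float(betas.mean() - beta),
        "reps": reps,
        "n": n,
    }


def type_one_error(n: int, maf: float, reps: int, seed: int,
                   alpha: float = 0.05) -> dict:
    """Null rejection rate of the scan at level ``alpha`` over fresh cohorts."""
    ss = np.random.SeedSequence([seed, 51])
    sub_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(reps)]
    rejections = 0
    for s in sub_seeds:
        _, p = _one_replicate(n, maf, 0.0, s)
        rejections += p < alpha
    rate = rejections / reps
    return {
        "rejection_rate": float(rate),
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / reps)),
        "reps": reps,
        "n": n,
        "alpha": alpha,
    }
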