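"""Analyze a deep-phenotyped recall sample: group table and regressions.

Builds a 40-person recall sample (12 / 15 / 13 across genotype groups,
with an injected genotype effect on insulin resistance), then produces a
publication-style group summary and the covariate-adjusted additive-model
regression behind each p-value.
"""

import numpy as np
import pandas as pd

from gbrecall import (
    RecallAnalysisSpec,
    baseline_tests,
    group_summary,
    recall_regression,
)

rng = np.random.default_rng(19)
sizes = (12, 15, 13)
idx = pd.Index([f"R{i:03d}" for i in range(sum(sizes))], name="sample_id")
groups = pd.Series(np.repeat(["hom_major", "het", "hom_minor"], sizes), index=idx)
dosage = groups.map({"hom_major": 0, "het": 1, "hom_minor": 2})
cov = pd.DataFrame({"age": rng.uniform(50, 70, len(idx)),
                    "sex": rng.integers(0, 2, len(idx))}, index=idx)

# HOMA-IR falls ~25% per minor allele; BMI carries no genotype effect
panel = pd.DataFrame({
    "homa_ir": np.exp(0.6 - 0.30 * dosage + rng.normal(0, 0.35, len(idx))),
    "bmi": rng.normal(26.5, 3.0, len(idx)),
}, index=idx)

base = baseline_tests(groups, cov["age"], cov["sex"])
print(f"baseline comparability: age ANOVA p = {base['p_age']:.2f}, "
      f"sex Fisher p = {base['p_sex']:.2f}")

spec = RecallAnalysisSpec(covariates=("age", "sex"))
print("\ngroup summary (mean (sd) on the original scale; p from the "
      "log-scale additive model):")
print(group_summary(panel, groups, dosage, cov, spec).to_string())

res = recall_regression(panel, dosage, cov, spec)
print("\nper-allele regression estimates:")
print(res.round(4).to_string())
# The injected -0.30 log-HOMA-IR effect per allele is recovered with a small
# p-value even at n=40, while the null BMI column stays non-significant —
# the contrast a genotype-based recall study is designed to expose.
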