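"""Recall-phase statistics.

Additive-model linear regressions of metabolic phenotypes on minor-allele
dosage adjusted for age, sex and ancestry components; baseline group
comparability tests (one-way ANOVA for age, Fisher's exact test on the
sex-by-genotype table); and publication-style group summary tables with
means and SDs on the original scale alongside p-values computed on the
transformed scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import check_collinearity, fisher_exact_rxc, ols_fit
from .containers import GENOTYPE_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "RecallAnalysisSpec",
    "recall_regression",
    "baseline_tests",
    "group_summary",
]

#: phenotypes natural-log transformed before regression by default
DEFAULT_LOG_TRANSFORM = (
    "fasting_glucose",
    "fasting_insulin",
    "homa_ir",
    "auc_glucose_0_180",
    "auc_insulin_0_180",
    "triglycerides",
    "auc_nefa_0_120",
    "auc_glycerol_0_120",
    "nefa_baseline",
    "glycerol_baseline",
)


@dataclass(frozen=True)
class RecallAnalysisSpec:
    """Transform list and covariate set for the recall-phase regressions."""

    log_transform: tuple[str, ...] = DEFAULT_LOG_TRANSFORM
    covariates: tuple[str, ...] = ("age", "sex", "mds1", "mds2", "mds3")


def recall_regression(
    panel: pd.DataFrame,
    dosage: pd.Series,
    covariates: pd.DataFrame,
    spec: RecallAnalysisSpec = RecallAnalysisSpec(),
    phenotypes=None,
) -> pd.DataFrame:
    """Per-phenotype additive-model OLS on the recall sample.

    Each phenotype column of ``panel`` is log-transformed if listed in the
    spec, then regressed on minor-allele dosage plus the spec's covariate
    columns, complete-case per phenotype. Returns beta, se, p (two-sided t
    on the dosage coefficient) and n per phenotype.
    """
    cols = list(phenotypes) if phenotypes is not None else list(panel.columns)
    cov_cols = [c for c in spec.covariates if c in covariates.columns]
    dropped = set(spec.covariates) - set(cov_cols)
    if dropped:
        logger.info("covariates absent and skipped: %s", sorted(dropped))
    idx = panel.index
    dos = dosage.reindex(idx).to_numpy(dtype=float)
    cov = covariates.reindex(idx)[cov_cols].to_numpy(dtype=float)
    n_par = 2 + len(cov_cols)
    rows = []
    for pheno in cols:
        y = panel[pheno].to_numpy(dtype=float)
        if pheno in spec.log_transform:
            with np.errstate(invalid="ignore", divide="ignore"):
                y = np.where(y > 0, np.log(y), np.nan)
        use = ~np.isnan(y) & ~np.isnan(dos) & ~np.isnan(cov).any(axis=1)
        n = int(use.sum())
        if n < n_par + 2:
            raise ValueError(
                f"{pheno}: {n} complete cases; need at least {n_par + 2} "
                f"for {n_par} parameters"
            )
        X = np.column_stack([np.ones(n), dos[use], cov[use]])
        try:
            fit = ols_fit(X, y[use])
        except np.linalg.LinAlgError:
            check_collinearity(X, ["intercept", "dosage", *cov_cols])
            raise
        rows.append((pheno, fit.beta[1], fit.se[1], fit.p[1], n))
    return pd.DataFrame(rows, columns=["phenotype", "beta", "se", "p", "n"]).set_index("phenotype")


def baseline_tests(groups: pd.Series, age: pd.Series, sex: pd.Series) -> dict:
    """Group comparability at baseline: ANOVA for age, Fisher exact for sex.

    ``groups`` maps sample to genotype group; returns ``{"p_age": ...,
    "p_sex": ...}`` with None (and a logged notice) for a test whose
    prerequisites fail (e.g. an empty group).
    """
    present = [g for g in GENOTYPE_GROUPS if (groups == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two non-empty genotype groups")
    if len(present) < len(GENOTYPE_GROUPS):
        logger.warning("empty genotype group(s); tests run on %s", present)
    out: dict[str, float | None] = {}
    age_groups = [age[groups == g].dropna().to_numpy() for g in present]
    if all(len(a) >= 2 for a in age_groups):
        f, p = stats.f_oneway(*age_groups)
        out["p_age"] = 1.0 if np.isnan(p) else float(p)
    else:
        logger.warning("a group has <2 ages; ANOVA skipped")
        out["p_age"] = None
    table = np.array([
        [int(((groups == g) & (sex == s)).sum()) for g in present]
        for s in sorted(sex.dropna().unique())
    ])
    if table.shape[0] >= 2 and (table.sum(axis=1) > 0).all():
        out["p_sex"] = fisher_exact_rxc(table)
    else:
        logger.warning("sex table degenerate; Fisher test skipped")
        out["p_sex"] = None
    return out


def group_summary(
    panel: pd.DataFrame,
    groups: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame,
    spec: RecallAnalysisSpec = RecallAnalysisSpec(),
) -> pd.DataFrame:
    """Publication-style per-group summary with additive-model p-values.

    Means and SDs are reported on the original measurement scale; the
    p-value per phenotype comes from :func:`recall_regression` on the
    transformed scale. The first row gives group sizes. Phenotypes absent
    from the panel are skipped with a notice.
    """
    present_groups = [g for g in GENOTYPE_GROUPS if (groups == g).any()]
    rows = []
    header = {"phenotype": "n"}
    for g in present_groups:
        header[g] = float((groups == g).sum())
    header["p"] = np.nan
    rows.append(header)
    reg = recall_regression(panel, dosage, covariates, spec)
    for pheno in panel.columns:
        rec = {"phenotype": pheno}
        for g in present_groups:
            vals = panel.loc[groups[groups == g].index.intersection(panel.index), pheno].dropna()
            rec[g] = f"{vals.mean():.3g} ({vals.std(ddof=1) if len(vals) > 1 else 0.0:.3g})" \
                if len(vals) else "—"
        rec["p"] = reg.at[pheno, "p"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("phenotype")
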