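"""Recall-variant eligibility screening and the association scan.

Eligibility follows the homozygote-anchored recall logic: a variant is only
worth recalling on if the cohort contains enough minor-allele homozygotes to
fill the deep-phenotyping group. The association scan is ordinary least
squares of a prepared (transformed, z-scored) phenotype on minor-allele
dosage under an additive model, adjusted for age, sex and ancestry
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import check_collinearity, ols_fit
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EligibilityRule",
    "PhenotypeSpec",
    "eligible_variants",
    "prepare_phenotype",
    "association_scan",
    "rank_candidates",
]


@dataclass(frozen=True)
class EligibilityRule:
    """Minimum minor-homozygote count and consequence classes for recall."""

    min_minor_hom: int = 10
    allowed_consequences: tuple[str, ...] = ("LOF", "missense")
    directly_genotyped_only: bool = True

    def __post_init__(self) -> None:
        if self.min_minor_hom < 1:
            raise ValueError("min_minor_hom must be >= 1")


@dataclass(frozen=True)
class PhenotypeSpec:
    """How a quantitative trait is prepared for the additive-model scan."""

    name: str
    transform: str = "none"  # "none" or "natural_log"
    z_score: bool = True
    fasting_required_hours: float | None = None
    exclude_diabetic: bool = False

    def __post_init__(self) -> None:
        if self.transform not in ("none", "natural_log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.fasting_required_hours is not None and self.fasting_required_hours < 0:
            raise ValueError("fasting_required_hours must be >= 0")


def eligible_variants(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    rule: EligibilityRule = EligibilityRule(),
) -> pd.DataFrame:
    """Variants eligible for genotype-based recall.

    ``counts`` must carry ``n_minor_hom`` (indexed by rsID, computed on the
    unrelated analysis set); ``annotation`` must carry ``consequence`` and
    optionally ``directly_genotyped``. Markers without annotation are
    skipped with a warning. Result sorted by descending homozygote count.
    """
    if counts.empty:
        return counts.assign(consequence=pd.Series(dtype=object))
    unannotated = counts.index.difference(annotation.index)
    if len(unannotated):
        logger.warning("skipping %d markers without annotation: %s",
                       len(unannotated), list(unannotated[:5]))
    annot_cols = [c for c in ("consequence", "locus", "directly_genotyped")
                  if c in annotation.columns]
    merged = counts.drop(columns=annot_cols, errors="ignore").join(
        annotation[annot_cols], how="inner",
    )
    keep = merged["consequence"].isin(rule.allowed_consequences)
    keep &= merged["n_minor_hom"] >= rule.min_minor_hom
    if rule.directly_genotyped_only and "directly_genotyped" in merged.columns:
        keep &= merged["directly_genotyped"].astype(bool)
    out = merged.loc[keep].sort_values("n_minor_hom", ascending=False, kind="stable")
    return out


def prepare_phenotype(
    values: pd.Series,
    spec: PhenotypeSpec,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Transform and z-score a phenotype on its inclusion set.

    The inclusion mask drops missing values, diabetic samples and samples
    fasting under the required hours (per spec), and — under a log
    transform — non-positive values (logged count). The returned vector has
    mean 0, SD 1 over the included samples; excluded entries are NaN.
    """
    values = values.astype(float)
    mask = values.notna()
    if spec.exclude_diabetic:
        if covariates is None or "diabetes_flag" not in covariates:
            raise ValueError("exclude_diabetic requires a diabetes_flag covariate column")
        mask &= ~covariates.loc[values.index, "diabetes_flag"].astype(bool)
    if spec.fasting_required_hours is not None:
        if covariates is None or "fasting_hours" not in covariates:
            raise ValueError("fasting requirement needs a fasting_hours covariate column")
        mask &= covariates.loc[values.index, "fasting_hours"] >= spec.fasting_required_hours
    x = values.copy()
    if spec.transform == "natural_log":
        nonpos = mask & (x <= 0)
        if nonpos.any():
            logger.warning("%s: %d non-positive values masked before log transform",
                           spec.name, int(nonpos.sum()))
            mask &= ~nonpos
        x[mask] = np.log(x[mask])
    if spec.z_score:
        inc = x[mask]
        sd = inc.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"degenerate phenotype {spec.name!r}: zero variance on included set")
        x[mask] = (inc - inc.mean()) / sd
    out = x.where(mask)
    return out, mask


def association_scan(
    matrix: GenotypeMatrix,
    variant_ids,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Additive-model OLS of phenotype on minor-allele dosage per variant.

    ``covariates`` columns (typically age, sex and the leading MDS ancestry
    components) enter every model; samples with a missing genotype are
    dropped for that variant only (complete-case). Returns one row per
    variant: beta, se, p (two-sided t), n_used.
    """
    sample_order = list(matrix.sample_ids)
    y_all = phenotype.reindex(sample_order).to_numpy(dtype=float)
    cov = covariates.reindex(sample_order)
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"covariates incomplete on scan samples: {bad}")
    cov_mat = cov.to_numpy(dtype=float)
    base_names = ["intercept", "dosage", *cov.columns]
    rows = []
    for rsid in variant_ids:
        dosage = matrix.dosage(rsid)
        use = ~np.isnan(dosage) & ~np.isnan(y_all)
        X = np.column_stack([
            np.ones(int(use.sum())), dosage[use], cov_mat[use]
        ])
        try:
            fit = ols_fit(X, y_all[use])
        except np.linalg.LinAlgError:
            check_collinearity(X, base_names)
            raise
        rows.append((rsid, fit.beta[1], fit.se[1], fit.p[1], fit.n))
    return pd.DataFrame(rows, columns=["rsID", "beta", "se", "p", "n_used"]).set_index("rsID")


def rank_candidates(
    results: pd.DataFrame,
    counts: pd.DataFrame,
    target_group_size: int = 15,
    assumed_response_rate: float = 0.5,
) -> pd.DataFrame:
    """Rank screened variants by recruitment feasibility then evidence.

    A candidate is feasible when the expected number of recruitable
    minor-allele homozygotes (count x assumed response rate) reaches the
    target deep-phenotyping group size. Sorted feasible-first, then by best
    association p-value.
    """
    if results.empty:
        raise ValueError("no association results to rank")
    best_p = results.groupby(level=0)["p"].min() if results.index.has_duplicates \
        else results["p"]
    tab = counts[["n_minor_hom"]].join(best_p.rename("best_p"), how="inner")
    if "maf" in counts.columns:
        tab["maf"] = counts["maf"]
    tab["expected_recruitable"] = tab["n_minor_hom"] * assumed_response_rate
    tab["feasible"] = tab["expected_recruitable"] >= target_group_size
    return tab.sort_values(["feasible", "best_p"], ascending=[False, True], kind="stable")
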