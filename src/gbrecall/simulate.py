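"""Synthetic cohort generator.

Emulates the sampling frame the recall pipeline assumes: a population cohort
of genotyped adults (default ages 45-75) with Hardy-Weinberg genotypes at
specified minor-allele frequencies, optional mild population structure
(Balding-Nichols perturbation of allele frequencies across subpopulations),
a few related pairs produced by gene-dropping, additive genetic effects on
quantitative traits, gamma-pulse OGTT response curves, and genotype-group-
specific participation behavior.

All randomness flows from integer seeds through ``numpy.random.Generator``;
every operation is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GENOTYPE_GROUPS, MISSING, GenotypeMatrix, RecallPlan

__all__ = [
    "MarkerSpec",
    "CohortSpec",
    "EffectSpec",
    "OgttCurveParams",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_ogtt",
    "simulate_response",
    "OGTT_TIMEPOINTS",
]

OGTT_TIMEPOINTS = (0, 15, 30, 60, 90, 120, 180)


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {field_name}: {msg}")


@dataclass(frozen=True)
class MarkerSpec:
    """One simulated biallelic marker."""

    maf: float
    consequence: str = "other"
    missing_rate: float = 0.0
    rsid: str | None = None

    def __post_init__(self) -> None:
        _require(0.0 < self.maf <= 0.5, "maf", f"{self.maf} not in (0, 0.5]")
        _require(self.consequence in ("LOF", "missense", "other"),
                 "consequence", repr(self.consequence))
        _require(0.0 <= self.missing_rate <= 1.0, "missing_rate",
                 f"{self.missing_rate} not in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Study-frame parameters of a simulated cohort."""

    n_samples: int
    markers: tuple[MarkerSpec, ...]
    n_subpops: int = 1
    fst_like_divergence: float = 0.0
    related_pairs: int = 0
    related_kinship: str = "full_sib"  # or "parent_offspring"
    age_range: tuple[float, float] = (45.0, 75.0)
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        _require(self.n_samples >= 1, "n_samples", "must be positive")
        _require(len(self.markers) >= 1, "markers", "at least one marker required")
        _require(self.n_subpops >= 1, "n_subpops", "must be positive")
        _require(self.fst_like_divergence >= 0.0, "fst_like_divergence", "must be >= 0")
        _require(self.related_pairs >= 0, "related_pairs", "must be >= 0")
        _require(self.n_samples >= 2 * self.related_pairs, "related_pairs",
                 "n_samples must be at least 2 x related_pairs")
        _require(self.related_kinship in ("full_sib", "parent_offspring"),
                 "related_kinship", repr(self.related_kinship))
        _require(0.0 <= self.sex_ratio <= 1.0, "sex_ratio", "must be in [0, 1]")
        _require(self.age_range[0] < self.age_range[1], "age_range", "must be increasing")


@dataclass(frozen=True)
class EffectSpec:
    """Additive genetic effect and participation behavior of the focal variant."""

    variant_id: str
    beta_per_allele: float = 0.0
    age_coef: float = 0.0
    sex_coef: float = 0.0
    noise_sd: float = 1.0
    participation_probs: tuple[float, float, float] = (0.31, 0.44, 0.40)

    def __post_init__(self) -> None:
        _require(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        for p in self.participation_probs:
            _require(0.0 <= p <= 1.0, "participation_probs", f"{p} not in [0, 1]")


@dataclass(frozen=True)
class OgttCurveParams:
    """Shape of a simulated oral glucose tolerance test response.

    The excursion is a gamma-shaped pulse f(t) = (t/tp)^k exp(k (1 - t/tp))
    with tp = ``peak_time`` and k = peak_time / decay_time; f peaks at 1 at
    tp and decays toward 0, guaranteeing positivity and a single peak.
    """

    basal_glucose: float = 5.5        # mmol/L
    glucose_excursion_peak: float = 4.0
    basal_insulin: float = 7.0        # mU/L
    insulin_response_scale: float = 8.0
    basal_nefa: float = 400.0         # umol/L
    nefa_suppression_fraction: float = 0.7
    basal_glycerol: float = 80.0      # umol/L
    peak_time: float = 40.0           # minutes
    decay_time: float = 60.0
    noise_cv: float = 0.05            # lognormal measurement noise, CV scale

    def __post_init__(self) -> None:
        for name in ("basal_glucose", "basal_insulin", "basal_nefa",
                     "basal_glycerol", "peak_time", "decay_time"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(self.glucose_excursion_peak >= 0, "glucose_excursion_peak", "must be >= 0")
        _require(self.insulin_response_scale >= 0, "insulin_response_scale", "must be >= 0")
        _require(0.0 <= self.nefa_suppression_fraction <= 1.0,
                 "nefa_suppression_fraction", "must be in [0, 1]")
        _require(self.noise_cv >= 0.0, "noise_cv", "must be >= 0")


def _subpop_frequencies(maf: float, n_subpops: int, fst: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw of subpopulation allele frequencies."""
    if n_subpops == 1 or fst <= 0:
        return np.full(n_subpops, maf)
    a = maf * (1.0 - fst) / fst
    b = (1.0 - maf) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b, size=n_subpops), 1e-6, 1.0 - 1e-6)


def simulate_genotypes(spec: CohortSpec) -> GenotypeMatrix:
    """HWE genotypes with optional structure, relatedness and missingness.

    Within each subpopulation, genotypes are binomial(2, p_s) draws at the
    subpopulation allele frequency — i.e. exact Hardy-Weinberg proportions.
    The last ``2 * related_pairs`` samples form related pairs generated by
    gene-dropping from shared parental haplotypes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, m = spec.n_samples, len(spec.markers)
    subpop = rng.integers(spec.n_subpops, size=n)
    calls = np.zeros((n, m), dtype=np.int8)
    pair_base = n - 2 * spec.related_pairs
    for j, mk in enumerate(spec.markers):
        freqs = _subpop_frequencies(mk.maf, spec.n_subpops,
                                    spec.fst_like_divergence, rng)
        p = freqs[subpop]
        calls[:, j] = rng.binomial(2, p)
        # related pairs: overwrite by gene-dropping from shared parents
        for r in range(spec.related_pairs):
            i1, i2 = pair_base + 2 * r, pair_base + 2 * r + 1
            pp = p[i1]
            if spec.related_kinship == "full_sib":
                pat = rng.binomial(1, pp, size=2)  # father's two alleles
                mat = rng.binomial(1, pp, size=2)
                calls[i1, j] = pat[rng.integers(2)] + mat[rng.integers(2)]
                calls[i2, j] = pat[rng.integers(2)] + mat[rng.integers(2)]
            else:  # parent_offspring
                parent = rng.binomial(1, pp, size=2)
                calls[i1, j] = parent.sum()
                calls[i2, j] = parent[rng.integers(2)] + rng.binomial(1, pp)
        if mk.missing_rate > 0:
            miss = rng.random(n) < mk.missing_rate
            calls[miss, j] = MISSING
    sample_ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    markers = pd.DataFrame(
        {
            "chromosome": [(j % 22) + 1 for j in range(m)],
            "position": [1000 * (j + 1) for j in range(m)],
            "minor_allele": "A",
            "major_allele": "G",
            "consequence": [mk.consequence for mk in spec.markers],
            "maf_true": [mk.maf for mk in spec.markers],
        },
        index=pd.Index(
            [mk.rsid or f"sim{j}" for j, mk in enumerate(spec.markers)], name="rsID"
        ),
    )
    gm = GenotypeMatrix(calls, sample_ids, markers)
    # stash subpop labels for structure-aware tests
    gm.subpop_labels = pd.Series(subpop, index=sample_ids)  # type: ignore[attr-defined]
    return gm


def simulate_covariates(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Sample table: age, sex, fasting hours, medication/diabetes flags.

    Ages are uniform over ``age_range``; sex is Bernoulli(sex_ratio) coded
    1 = female. Fasting hours cluster around 11 h with a small fraction
    under 6 h; exclusion flags (diabetes, anticoagulant, lipid-lowering)
    carry realistic population prevalences for this age band.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed if seed is None else seed).spawn(1)[0]
    )
    n = spec.n_samples
    lo, hi = spec.age_range
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "age": rng.uniform(lo, hi, size=n),
            "sex": rng.binomial(1, spec.sex_ratio, size=n),
            "fasting_hours": np.clip(rng.normal(11.0, 2.5, size=n), 0.0, None),
            "diabetes_flag": rng.random(n) < 0.08,
            "anticoagulant_flag": rng.random(n) < 0.05,
            "lipid_lowering_flag": rng.random(n) < 0.15,
        }
    ).set_index("sample_id")
    return df


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: EffectSpec,
    covariates: pd.DataFrame,
    seed: int = 0,
    phenotype_name: str = "phenotype",
) -> pd.DataFrame:
    """Quantitative trait under an additive genetic model.

    phenotype = beta_per_allele x dosage + age and sex terms + N(0, noise_sd).
    Missing genotypes are imputed to the sample-mean dosage for generation
    only (the analysis stages never see this imputation).
    """
    if effects.variant_id not in genotypes.marker_ids:
        raise KeyError(f"variant {effects.variant_id!r} not in genotype matrix")
    missing_cov = set(genotypes.sample_ids) - set(covariates.index)
    if missing_cov:
        raise ValueError(f"covariates missing for samples: {sorted(missing_cov)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    dosage = genotypes.dosage(effects.variant_id)
    dosage = np.where(np.isnan(dosage), np.nanmean(dosage), dosage)
    cov = covariates.loc[list(genotypes.sample_ids)]
    y = (
        effects.beta_per_allele * dosage
        + effects.age_coef * cov["age"].to_numpy()
        + effects.sex_coef * cov["sex"].to_numpy()
        + (rng.normal(0.0, effects.noise_sd, size=len(dosage))
           if effects.noise_sd > 0 else 0.0)
    )
    return pd.DataFrame({phenotype_name: y},
                        index=pd.Index(genotypes.sample_ids, name="sample_id"))


def _gamma_pulse(t: np.ndarray, peak_time: float, decay_time: float) -> np.ndarray:
    k = peak_time / decay_time
    x = np.asarray(t, dtype=float) / peak_time
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.power(x[pos], k) * np.exp(k * (1.0 - x[pos]))
    return out


def simulate_ogtt(
    params: OgttCurveParams,
    insulin_sensitivity_multiplier: float = 1.0,
    seed: int = 0,
    timepoints: tuple[int, ...] = OGTT_TIMEPOINTS,
) -> pd.DataFrame:
    """Timed glucose/insulin/NEFA/glycerol series for one OGTT.

    Glucose rises to a single peak near ``peak_time`` and decays toward
    basal; insulin tracks the glucose pulse scaled inversely by the
    sensitivity multiplier; NEFA and glycerol decline linearly to their
    suppressed level by 120 min. Multiplicative log-normal noise; all
    values strictly positive. Returns a long frame (analyte, minutes,
    value, unit).
    """
    if insulin_sensitivity_multiplier <= 0:
        raise ValueError("insulin_sensitivity_multiplier must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    t = np.asarray(timepoints, dtype=float)
    pulse = _gamma_pulse(t, params.peak_time, params.decay_time)
    glucose = params.basal_glucose + params.glucose_excursion_peak * pulse
    insulin = params.basal_insulin * (
        1.0 + params.insulin_response_scale * pulse / insulin_sensitivity_multiplier
    )
    supp = min(params.nefa_suppression_fraction, 0.99) * np.minimum(t / 120.0, 1.0)
    nefa = params.basal_nefa * (1.0 - supp)
    glycerol = params.basal_glycerol * (1.0 - supp)
    rows = []
    units = {"glucose": "mmol/L", "insulin": "mU/L", "nefa": "umol/L",
             "glycerol": "umol/L"}
    for analyte, series in (("glucose", glucose), ("insulin", insulin),
                            ("nefa", nefa), ("glycerol", glycerol)):
        noisy = series
        if params.noise_cv > 0:
            sigma = np.sqrt(np.log1p(params.noise_cv ** 2))
            noisy = series * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=len(t)))
        for minutes, value in zip(timepoints, noisy):
            rows.append((analyte, int(minutes), float(value), units[analyte]))
    return pd.DataFrame(rows, columns=["analyte", "minutes", "value", "unit"])


def simulate_response(
    plan: RecallPlan,
    participation_probs,
    seed: int = 0,
) -> RecallPlan:
    """Bernoulli invitation outcomes at genotype-group response probabilities.

    ``participation_probs`` maps group name to probability, or is a
    3-sequence ordered (hom_major, het, hom_minor). Returns a new plan with
    ``responded`` and ``included`` filled for invited rows.
    """
    if not isinstance(participation_probs, dict):
        participation_probs = dict(zip(GENOTYPE_GROUPS, participation_probs))
    for g, p in participation_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"participation probability for {g} outside [0, 1]: {p}")
    df = plan.invitees.copy()
    unknown = set(df["group"]) - set(participation_probs)
    if unknown:
        raise ValueError(f"no participation probability for groups: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    probs = df["group"].map(participation_probs).to_numpy(dtype=float)
    responded = (rng.random(len(df)) < probs) & df["invited"].to_numpy()
    df["responded"] = responded
    df["included"] = responded
    return RecallPlan(plan.focal_variant, df, unmatched=plan.unmatched,
                      log=plan.log + ["simulated Bernoulli responses"])
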