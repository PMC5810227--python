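"""Homozygote-anchored matched invitation design for genotype-based recall.

Every minor-allele homozygote in the eligible pool becomes an anchor; for
each anchor one heterozygote and one major-allele homozygote of the same sex
and within a configurable age window are drawn uniformly at random without
replacement. Invitations go out in batches (anchor triads stay together),
responses are tallied per genotype group, and recall-phase confirmatory
genotypes are checked for concordance with the cohort calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GENOTYPE_GROUPS, RecallPlan

logger = logging.getLogger(__name__)

__all__ = [
    "MatchRule",
    "apply_exclusions",
    "build_matched_invitations",
    "assign_batches",
    "tally_participation",
    "genotype_concordance",
    "clinic_export",
]

EXCLUSION_FLAGS = ("anticoagulant_flag", "lipid_lowering_flag", "diabetes_flag")

_GROUP_OF_DOSAGE = {0: "hom_major", 1: "het", 2: "hom_minor"}


@dataclass(frozen=True)
class MatchRule:
    """Age/sex matching rule for recall invitations.

    ``age_window_years`` is the TOTAL window width centered on the anchor's
    age (the default 2.0 means a match may differ by at most 1 year).
    ``extra_invites`` optionally over-invites non-anchored carriers per
    group, e.g. ``{"hom_major": 9, "het": 4}``.
    """

    age_window_years: float = 2.0
    match_sex: bool = True
    candidates_per_anchor: int = 1
    extra_invites: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.age_window_years <= 0:
            raise ValueError("age_window_years must be positive")
        if self.candidates_per_anchor < 1:
            raise ValueError("candidates_per_anchor must be >= 1")


def apply_exclusions(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples on anticoagulants, lipid-lowering agents, or with diabetes.

    Returns the eligible pool and an exclusion log (sample id, reason).
    Requires all three flag columns.
    """
    missing = [c for c in EXCLUSION_FLAGS if c not in samples.columns]
    if missing:
        raise ValueError(f"missing exclusion flag columns: {missing}")
    reasons = []
    for col in EXCLUSION_FLAGS:
        flagged = samples.index[samples[col].astype(bool)]
        reasons.extend((sid, col.removesuffix("_flag")) for sid in flagged)
    log = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    keep = ~samples[list(EXCLUSION_FLAGS)].astype(bool).any(axis=1)
    pool = samples.loc[keep]
    if pool.empty:
        logger.warning("exclusion filters removed every sample; pool is empty")
    return pool, log


def build_matched_invitations(
    pool: pd.DataFrame,
    dosage: pd.Series,
    focal_variant: str,
    rule: MatchRule = MatchRule(),
    seed: int = 0,
) -> RecallPlan:
    """Anchor on minor-allele homozygotes and match carriers of the major allele.

    ``pool`` needs ``age`` and ``sex`` columns; ``dosage`` gives the focal
    minor-allele dosage per pool sample. Anchors with no available same-sex
    candidate inside the age window in a group are recorded as unmatched
    for that group but still invited. Matching is uniform without
    replacement, deterministic given ``seed`` (candidate order is sorted by
    sample id before shuffling so pool row order is irrelevant).
    """
    dos = dosage.reindex(pool.index)
    if dos.isna().all():
        raise ValueError(f"focal variant {focal_variant!r} has no genotypes in the pool")
    half = rule.age_window_years / 2.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    typed = pool.loc[dos.notna()].copy()
    typed["dosage"] = dos[dos.notna()].astype(int)
    anchors = sorted(typed.index[typed["dosage"] == 2])
    available = {
        "het": set(typed.index[typed["dosage"] == 1]),
        "hom_major": set(typed.index[typed["dosage"] == 0]),
    }
    rows = []
    unmatched = []
    for anchor in anchors:
        rows.append((anchor, "hom_minor", None))
        a_age = typed.at[anchor, "age"]
        a_sex = typed.at[anchor, "sex"]
        for group in ("het", "hom_major"):
            cands = sorted(
                s for s in available[group]
                if abs(typed.at[s, "age"] - a_age) <= half
                and (not rule.match_sex or typed.at[s, "sex"] == a_sex)
            )
            picks = list(rng.choice(cands, size=min(rule.candidates_per_anchor, len(cands)),
                                    replace=False)) if cands else []
            if len(picks) < rule.candidates_per_anchor:
                unmatched.append((anchor, group,
                                  rule.candidates_per_anchor - len(picks)))
            for s in picks:
                available[group].discard(s)
                rows.append((s, group, anchor))
    # optional over-invitation of non-anchored carriers
    for group, extra in rule.extra_invites:
        if group not in available:
            raise ValueError(f"extra_invites group must be het or hom_major, got {group!r}")
        cands = sorted(available[group])
        picks = list(rng.choice(cands, size=min(extra, len(cands)), replace=False))
        for s in picks:
            available[group].discard(s)
            rows.append((s, group, None))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "anchor_id"])
    df["batch"] = 1
    df["invited"] = True
    df["responded"] = False
    df["included"] = False
    um = pd.DataFrame(unmatched, columns=["anchor_id", "group", "n_short"])
    log = [f"{len(anchors)} anchors; {len(df)} invitations; {len(um)} unmatched anchor-group slots"]
    return RecallPlan(focal_variant, df, unmatched=um, log=log)


def assign_batches(plan: RecallPlan, batch_fractions=(0.5, 0.5), seed: int = 0) -> RecallPlan:
    """Randomly split anchor triads (kept together) into invitation batches."""
    fr = np.asarray(batch_fractions, dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("batch fractions must lie in [0, 1]")
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError(f"batch fractions must sum to 1, got {fr.sum()}")
    df = plan.invitees.copy()
    # a unit = an anchor with its matched partners; unanchored extras are their own unit
    unit = df["anchor_id"].fillna(df["sample_id"])
    units = sorted(unit.unique())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(len(units))
    sizes = np.floor(fr * len(units)).astype(int)
    while sizes.sum() < len(units):  # distribute remainder to largest fractions
        sizes[int(np.argmax(fr * len(units) - sizes))] += 1
    labels = {}
    start = 0
    for b, size in enumerate(sizes, start=1):
        for t in order[start:start + size]:
            labels[units[t]] = b
        start += size
    df["batch"] = unit.map(labels).astype(int)
    return RecallPlan(plan.focal_variant, df, unmatched=plan.unmatched,
                      log=plan.log + [f"batches assigned with fractions {tuple(fr)}"])


def tally_participation(plan: RecallPlan | pd.DataFrame) -> pd.DataFrame:
    """Per-group invited / included counts and integer participation rates.

    ``rate_percent`` is round(100 x included / invited) to the nearest
    integer; groups with zero invited report NaN rather than 0.
    """
    df = plan.invitees if isinstance(plan, RecallPlan) else plan
    rows = []
    for group in GENOTYPE_GROUPS:
        sub = df[df["group"] == group]
        invited = int(sub["invited"].sum())
        included = int(sub["included"].sum())
        if included > invited:
            raise ValueError(f"group {group}: included ({included}) exceeds invited ({invited})")
        rate = float(round(100.0 * included / invited)) if invited else float("nan")
        rows.append((group, invited, included, rate))
    return pd.DataFrame(rows, columns=["group", "invited", "included",
                                       "rate_percent"]).set_index("group")


def genotype_concordance(
    cohort_calls: pd.Series, recall_calls: pd.Series
) -> tuple[float, list[str]]:
    """Concordance of recall-phase confirmatory genotypes with cohort calls.

    Both series map sample id to genotype call at the focal variant.
    Returns the concordant fraction and the discordant sample ids.
    """
    missing = set(recall_calls.index) ^ set(cohort_calls.index)
    common = cohort_calls.index.intersection(recall_calls.index)
    if len(common) == 0:
        raise ValueError("no overlapping sample ids between call sets")
    if missing:
        raise ValueError(f"sample id mismatch between call sets: {sorted(missing)[:10]}")
    same = cohort_calls.loc[common].to_numpy() == recall_calls.loc[common].to_numpy()
    discordant = [str(s) for s in common[~same]]
    return float(same.mean()), discordant


def clinic_export(plan: RecallPlan, samples: pd.DataFrame) -> pd.DataFrame:
    """Blinded export for clinic use: invitees with covariates, NO genotype.

    Blinding is structural — the genotype group and anchor columns are
    omitted; genotype is re-joined only at analysis time by sample id.
    """
    inv = plan.invitees.loc[plan.invitees["invited"], ["sample_id", "batch"]]
    return inv.merge(samples, left_on="sample_id", right_index=True, how="left")
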