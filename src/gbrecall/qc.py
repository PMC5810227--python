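"""Cohort genotype quality control.

Implements the standard exome-array QC cascade: per-sample filters (ancestry
outliers by multidimensional scaling of identity-by-state distance,
heterozygosity outliers per MAF stratum, sample call rate), two marker-filter
passes (call rate and Hardy-Weinberg exact test, with optional array
cluster-quality score filters), and relatedness pruning with a
method-of-moments estimator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeCounts,
    GenotypeMatrix,
    QcRemoval,
    QcReport,
    QcThresholds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_genotype_counts",
    "genotype_count_table",
    "hwe_exact_pvalue",
    "heterozygosity_outliers",
    "ancestry_components",
    "relatedness_matrix",
    "relatedness_prune",
    "apply_qc_cascade",
]


def compute_genotype_counts(
    matrix: GenotypeMatrix, marker: str, sample_subset=None
) -> GenotypeCounts:
    """Genotype counts for one marker over a sample subset.

    Counts are normalized to minor-allele orientation: if the allele stored
    as "minor" has observed frequency above 0.5, hom/het labels are flipped
    so the reported MAF is <= 0.5 (ties keep the input's minor label).
    """
    if sample_subset is not None and len(sample_subset) == 0:
        raise ValueError("sample_subset must be non-empty")
    sub = matrix if sample_subset is None else matrix.subset(sample_ids=sample_subset)
    col = sub.calls[:, sub.marker_index(marker)]
    n2 = int((col == 2).sum())
    n1 = int((col == 1).sum())
    n0 = int((col == 0).sum())
    nm = int((col == MISSING).sum())
    called = n0 + n1 + n2
    if called and (2 * n2 + n1) / (2.0 * called) > 0.5:
        n0, n2 = n2, n0
    return GenotypeCounts(n_minor_hom=n2, n_het=n1, n_major_hom=n0, n_missing=nm)


def genotype_count_table(matrix: GenotypeMatrix, sample_subset=None) -> pd.DataFrame:
    """Vectorized per-marker counts; columns mirror :class:`GenotypeCounts`."""
    calls = matrix.calls if sample_subset is None else \
        matrix.subset(sample_ids=sample_subset).calls
    n2 = (calls == 2).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n0 = (calls == 0).sum(axis=0)
    nm = (calls == MISSING).sum(axis=0)
    called = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called > 0, (2 * n2 + n1) / (2.0 * np.maximum(called, 1)), np.nan)
    flip = freq > 0.5
    n0f = np.where(flip, n2, n0)
    n2f = np.where(flip, n0, n2)
    maf = np.where(flip, 1.0 - freq, freq)
    total = called + nm
    return pd.DataFrame(
        {
            "n_minor_hom": n2f,
            "n_het": n1,
            "n_major_hom": n0f,
            "n_missing": nm,
            "maf": maf,
            "call_rate": np.where(total > 0, called / np.maximum(total, 1), 0.0),
        },
        index=matrix.marker_ids,
    )


def hwe_exact_pvalue(counts) -> float:
    """Exact Hardy-Weinberg test p-value conditional on allele counts.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the probabilities of configurations no more probable than the
    observed one (the conventional mid-tail exact HWE test for array QC).
    Accepts a :class:`GenotypeCounts` or an ``(n_minor_hom, n_het,
    n_major_hom)`` triple. Invariant to swapping the minor/major labels.
    """
    if isinstance(counts, GenotypeCounts):
        n_aa, n_ab, n_bb = counts.n_minor_hom, counts.n_het, counts.n_major_hom
    else:
        n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one called genotype required")
    rare = 2 * n_aa + n_ab
    rare = min(rare, 2 * n - rare)
    if rare == 0:
        return 1.0

    # P(het | allele counts) satisfies a two-term recurrence; build the full
    # distribution from its mode outward in one sweep.
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(hets))
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if (mid - rare) % 2 != 0:
        mid += 1
    mid_idx = int(np.searchsorted(hets, mid))
    probs[mid_idx] = 1.0
    # downward: P(h-2) = P(h) * h(h-1) / ((rare-h+2)(2n-rare-h+2))
    for i in range(mid_idx, 0, -1):
        h = hets[i]
        probs[i - 1] = probs[i] * h * (h - 1) / (
            (rare - h + 2.0) * (2 * n - rare - h + 2.0)
        )
    # upward: P(h+2) = P(h) * (rare-h)(2n-rare-h) / ((h+2)(h+1))
    for i in range(mid_idx, len(hets) - 1):
        h = hets[i]
        probs[i + 1] = probs[i] * (rare - h) * (2 * n - rare - h) / (
            (h + 2.0) * (h + 1.0)
        )
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(hets, n_ab))]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def hwe_pvalues(count_table: pd.DataFrame) -> pd.Series:
    """Exact HWE p per marker of a :func:`genotype_count_table` frame."""
    out = np.ones(len(count_table))
    cols = count_table[["n_minor_hom", "n_het", "n_major_hom"]].to_numpy()
    for i, (aa, ab, bb) in enumerate(cols):
        if aa + ab + bb >= 1:
            out[i] = hwe_exact_pvalue((aa, ab, bb))
    return pd.Series(out, index=count_table.index, name="hwe_p")


def heterozygosity_outliers(
    matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> list[str]:
    """Samples with outlying heterozygosity in either MAF stratum.

    The heterozygous-call fraction is computed separately over markers with
    MAF below and at/above ``maf_stratum_cut``; a sample is flagged when
    either statistic sits more than ``het_sd_max`` SDs from the stratum
    mean. Zero-variance strata produce no flags.
    """
    if matrix.n_samples < 2:
        raise ValueError("heterozygosity outlier detection needs at least 2 samples")
    maf = genotype_count_table(matrix)["maf"].to_numpy()
    flagged: set[str] = set()
    for lo_stratum in (True, False):
        sel = (maf < thresholds.maf_stratum_cut) if lo_stratum else (maf >= thresholds.maf_stratum_cut)
        sel &= ~np.isnan(maf)
        if not sel.any():
            logger.warning("heterozygosity stratum %s empty; skipped",
                           "MAF<cut" if lo_stratum else "MAF>=cut")
            continue
        calls = matrix.calls[:, sel]
        called = (calls != MISSING).sum(axis=1)
        het = (calls == 1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rate = np.where(called > 0, het / np.maximum(called, 1), np.nan)
        ok = ~np.isnan(rate)
        if ok.sum() < 2:
            continue
        mu, sd = rate[ok].mean(), rate[ok].std(ddof=0)
        if sd == 0:
            continue
        out = ok & (np.abs(rate - mu) > thresholds.het_sd_max * sd)
        flagged.update(matrix.sample_ids[out])
    return sorted(flagged)


def _ibs_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise 1 - IBS-proportion over mutually non-missing markers.

    Uses one-hot genotype indicators so everything reduces to matrix
    products (fast for cohort-scale n with a few thousand markers).
    """
    h = [(calls == g).astype(np.float32) for g in (0, 1, 2)]
    valid = (calls != MISSING).astype(np.float32)
    n_valid = valid @ valid.T
    n_same = sum(hi @ hi.T for hi in h)
    # |dosage difference| == 2 only for opposite homozygotes
    n_opp = h[0] @ h[2].T + h[2] @ h[0].T
    n_d1 = n_valid - n_same - n_opp
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(n_valid > 0, (0.5 * n_d1 + n_opp) / np.maximum(n_valid, 1), 0.0)
    np.fill_diagonal(dist, 0.0)
    return dist.astype(float)


def ancestry_components(
    matrix: GenotypeMatrix,
    k: int = 3,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, list[str]]:
    """Classical MDS of allele-sharing distance plus ancestry-outlier flags.

    Returns the first ``k`` coordinates per sample (columns ``mds1..mdsk``;
    sign is arbitrary per component) and the samples deviating more than
    ``ancestry_sd_max`` SDs from the mean on component 1 or 2.
    """
    n = matrix.n_samples
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    d = _ibs_distance(matrix.calls)
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    frame = pd.DataFrame(
        coords, index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=[f"mds{i + 1}" for i in range(k)],
    )
    flagged: set[str] = set()
    for comp in frame.columns[: min(2, k)]:
        x = frame[comp].to_numpy()
        sd = x.std(ddof=0)
        if sd == 0:
            continue
        out = np.abs(x - x.mean()) > thresholds.ancestry_sd_max * sd
        flagged.update(frame.index[out])
    return frame, sorted(flagged)


def relatedness_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments pairwise relatedness on the pi-hat scale.

    Allele-frequency-standardized dosage products averaged over markers
    (the off-diagonal of a genomic relationship matrix): about 1 for
    duplicates/MZ twins, 0.5 for first-degree, 0.25 for second-degree
    relatives, 0 for unrelated pairs. Missing calls are mean-imputed.
    """
    calls = matrix.calls.astype(float)
    calls[calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    calls = calls[:, usable]
    p = p[usable]
    z = (np.where(np.isnan(calls), 2 * p, calls) - 2 * p) / np.sqrt(2 * p * (1 - p))
    grm = (z @ z.T) / z.shape[1]
    return pd.DataFrame(grm, index=matrix.sample_ids, columns=matrix.sample_ids)


def relatedness_prune(
    matrix: GenotypeMatrix, kinship_threshold: float = 0.1875
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Remove one member of each pair with relatedness above threshold.

    The default 0.1875 sits midway between the expected sharing of second-
    and third-degree relatives, so first- and second-degree pairs are
    pruned. The member with the lower call rate is dropped (ties broken by
    keeping the lexicographically smaller sample id). Returns the retained
    ids (input order) and the flagged pairs with their estimates.
    """
    if matrix.n_samples < 2:
        raise ValueError("relatedness pruning needs at least 2 samples")
    rel = relatedness_matrix(matrix).to_numpy()
    ids = matrix.sample_ids
    call_rate = matrix.call_rates_per_sample()
    iu, ju = np.triu_indices(len(ids), k=1)
    above = rel[iu, ju] > kinship_threshold
    pairs = sorted(
        ((iu[t], ju[t], rel[iu[t], ju[t]]) for t in np.flatnonzero(above)),
        key=lambda x: -x[2],
    )
    removed: set[int] = set()
    flagged: list[tuple[str, str, float]] = []
    for i, j, r in pairs:
        flagged.append((str(ids[i]), str(ids[j]), float(r)))
        if i in removed or j in removed:
            continue
        if call_rate[i] < call_rate[j]:
            removed.add(i)
        elif call_rate[j] < call_rate[i]:
            removed.add(j)
        else:
            removed.add(i if str(ids[i]) > str(ids[j]) else j)
    retained = [str(s) for t, s in enumerate(ids) if t not in removed]
    return retained, flagged


def apply_qc_cascade(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    marker_scores: pd.DataFrame | None = None,
    sex_discordant: pd.Series | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full ordered QC cascade; returns the filtered matrix and an audit report.

    Order: (1) sample filters — reported-sex discordance (precomputed
    boolean, if given), ancestry outliers, heterozygosity outliers, sample
    call rate; (2) marker stage A — call rate < precall minimum, HWE, and
    cluster-separation / GenTrain score filters when ``marker_scores``
    provides ``cluster_sep`` / ``gentrain`` columns; (3) marker stage B —
    call rate < postcall minimum and HWE recomputed on surviving samples;
    (4) relatedness pruning.
    """
    report = QcReport()
    report.record_step("input", matrix.n_samples, matrix.n_markers)

    # --- stage 1: sample filters -------------------------------------------------
    drop_samples: dict[str, str] = {}
    if sex_discordant is not None:
        for sid in matrix.sample_ids:
            if bool(sex_discordant.get(sid, False)):
                drop_samples.setdefault(str(sid), "sex_discordance")
    else:
        report.notices.append("sex-discordance flags not provided; filter skipped")
    _, anc_out = ancestry_components(matrix, k=2, thresholds=thresholds)
    for sid in anc_out:
        drop_samples.setdefault(str(sid), "ancestry_outlier")
    for sid in heterozygosity_outliers(matrix, thresholds):
        drop_samples.setdefault(str(sid), "heterozygosity_outlier")
    cr = matrix.call_rates_per_sample()
    for sid in matrix.sample_ids[cr < thresholds.sample_call_rate_min]:
        drop_samples.setdefault(str(sid), "sample_call_rate")
    for sid, reason in drop_samples.items():
        report.removals.append(QcRemoval("sample", sid, reason, "samples"))
    keep_samples = [str(s) for s in matrix.sample_ids if str(s) not in drop_samples]
    cur = matrix.subset(sample_ids=keep_samples)
    report.record_step("sample_filters", cur.n_samples, cur.n_markers)

    # --- stage 2: marker filters, first pass -------------------------------------
    def _marker_pass(m: GenotypeMatrix, cr_min: float, step: str) -> GenotypeMatrix:
        tab = genotype_count_table(m)
        hwe = hwe_pvalues(tab)
        drop: dict[str, str] = {}
        for rsid in tab.index[tab["call_rate"] < cr_min]:
            drop.setdefault(str(rsid), "marker_call_rate")
        for rsid in hwe.index[hwe < thresholds.hwe_p_min]:
            drop.setdefault(str(rsid), "hwe")
        if step == "markers_stage_a":
            for col, cut, reason in (
                ("cluster_sep", thresholds.cluster_sep_min, "cluster_separation"),
                ("gentrain", thresholds.gentrain_min, "gentrain"),
            ):
                if marker_scores is not None and col in marker_scores.columns:
                    bad = marker_scores.index[marker_scores[col] < cut]
                    for rsid in bad:
                        if rsid in tab.index:
                            drop.setdefault(str(rsid), reason)
                else:
                    msg = f"marker score column {col!r} not provided; filter skipped"
                    report.notices.append(msg)
                    logger.info(msg)
        for rsid, reason in drop.items():
            report.removals.append(QcRemoval("marker", rsid, reason, step))
        keep = [str(r) for r in m.marker_ids if str(r) not in drop]
        out = m.subset(marker_ids=keep)
        report.record_step(step, out.n_samples, out.n_markers)
        return out

    cur = _marker_pass(cur, thresholds.marker_call_rate_min_precall, "markers_stage_a")
    # --- stage 3: marker filters, second pass (stricter call rate, HWE redone) ---
    cur = _marker_pass(cur, thresholds.marker_call_rate_min_postcall, "markers_stage_b")

    # --- stage 4: relatedness ----------------------------------------------------
    retained, flagged_pairs = relatedness_prune(cur, thresholds.relatedness_max)
    removed = set(str(s) for s in cur.sample_ids) - set(retained)
    for sid in sorted(removed):
        report.removals.append(QcRemoval("sample", sid, "relatedness", "relatedness"))
    cur = cur.subset(sample_ids=retained)
    report.record_step("relatedness", cur.n_samples, cur.n_markers)
    return cur, report
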