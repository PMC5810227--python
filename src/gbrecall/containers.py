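"""Core in-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, a dense samples x markers
matrix of minor-allele dosages (0/1/2, with -1 for missing calls) plus the
marker metadata needed by QC, screening and recall design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

GENOTYPE_GROUPS = ("hom_major", "het", "hom_minor")


@dataclass
class GenotypeMatrix:
    """Dense biallelic genotype calls with sample and marker metadata.

    Parameters
    ----------
    calls
        ``(n_samples, n_markers)`` integer array of minor-allele dosages in
        ``{0, 1, 2}``; missing calls are stored as ``-1``.
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    markers
        DataFrame indexed by rsID with at least ``chromosome``, ``position``
        (GRCh37, 1-based), ``minor_allele`` and ``major_allele`` columns.
        Optional columns (``consequence``, ``locus``) ride along untouched.
    """

    calls: np.ndarray
    sample_ids: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x markers array")
        if self.calls.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"calls has {self.calls.shape[0]} rows but {len(self.sample_ids)} sample_ids"
            )
        if self.calls.shape[1] != len(self.markers):
            raise ValueError(
                f"calls has {self.calls.shape[1]} columns but {len(self.markers)} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.markers.index.has_duplicates:
            raise ValueError("marker rsIDs must be unique")
        required = {"chromosome", "position", "minor_allele", "major_allele"}
        missing_cols = required - set(self.markers.columns)
        if missing_cols:
            raise ValueError(f"markers missing required columns: {sorted(missing_cols)}")
        if (np.asarray(self.markers["position"]) <= 0).any():
            raise ValueError("marker positions must be positive 1-based integers")
        same = self.markers["minor_allele"].astype(str) == self.markers["major_allele"].astype(str)
        if same.any():
            bad = self.markers.index[same].tolist()
            raise ValueError(f"minor and major allele identical for markers: {bad}")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("calls must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    def marker_index(self, rsid: str) -> int:
        try:
            return int(self.markers.index.get_loc(rsid))
        except KeyError:
            raise KeyError(f"marker {rsid!r} not found in matrix") from None

    def dosage(self, rsid: str) -> np.ndarray:
        """Minor-allele dosage for one marker as float, NaN where missing."""
        col = self.calls[:, self.marker_index(rsid)].astype(float)
        col[col == MISSING] = np.nan
        return col

    def subset(self, sample_ids=None, marker_ids=None) -> "GenotypeMatrix":
        """Row/column subset preserving metadata; order follows the request."""
        rows = slice(None)
        new_samples = self.sample_ids
        if sample_ids is not None:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            try:
                rows = np.array([pos[s] for s in sample_ids], dtype=int)
            except KeyError as exc:
                raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
            new_samples = np.asarray(list(sample_ids), dtype=object)
        new_markers = self.markers
        cols = slice(None)
        if marker_ids is not None:
            cols = np.array([self.marker_index(m) for m in marker_ids], dtype=int)
            new_markers = self.markers.loc[list(marker_ids)]
        return GenotypeMatrix(self.calls[rows][:, cols], new_samples, new_markers)

    def call_rates_per_sample(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def call_rates_per_marker(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one marker over a sample set.

    ``maf`` is NaN (and ``maf_defined`` False) when every call is missing.
    Orientation is normalized so that maf <= 0.5.
    """

    n_minor_hom: int
    n_het: int
    n_major_hom: int
    n_missing: int = 0

    @property
    def n_called(self) -> int:
        return self.n_minor_hom + self.n_het + self.n_major_hom

    @property
    def n_total(self) -> int:
        return self.n_called + self.n_missing

    @property
    def call_rate(self) -> float:
        return self.n_called / self.n_total if self.n_total else 0.0

    @property
    def maf_defined(self) -> bool:
        return self.n_called > 0

    @property
    def maf(self) -> float:
        if not self.maf_defined:
            return float("nan")
        return (2 * self.n_minor_hom + self.n_het) / (2.0 * self.n_called)


@dataclass(frozen=True)
class QcThresholds:
    """Cohort QC thresholds.

    Defaults reproduce a standard exome-array QC cascade: sample call rate
    >= 98%, marker call rate >= 97% before / >= 99% after the rare-variant
    calling pass, HWE exact p >= 1e-4, heterozygosity within 5 SD per MAF
    stratum, ancestry within 3 SD on the first two MDS components, and
    optional array cluster-quality scores.
    """

    sample_call_rate_min: float = 0.98
    marker_call_rate_min_precall: float = 0.97
    marker_call_rate_min_postcall: float = 0.99
    hwe_p_min: float = 1e-4
    het_sd_max: float = 5.0
    ancestry_sd_max: float = 3.0
    maf_stratum_cut: float = 0.01
    cluster_sep_min: float = 0.4
    gentrain_min: float = 0.6
    relatedness_max: float = 0.1875

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "marker_call_rate_min_precall",
                     "marker_call_rate_min_postcall", "hwe_p_min", "maf_stratum_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("het_sd_max", "ancestry_sd_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QcRemoval:
    kind: str        # "sample" or "marker"
    item_id: str
    reason: str
    step: str


@dataclass
class QcReport:
    """Audit trail of a QC cascade run."""

    removals: list[QcRemoval] = field(default_factory=list)
    step_counts: list[dict] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)

    def removed_ids(self, reason: str | None = None) -> list[str]:
        return [r.item_id for r in self.removals if reason is None or r.reason == reason]

    def record_step(self, step: str, n_samples: int, n_markers: int) -> None:
        self.step_counts.append({"step": step, "n_samples": n_samples, "n_markers": n_markers})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.kind, r.item_id, r.reason, r.step) for r in self.removals],
            columns=["kind", "id", "reason", "step"],
        )


@dataclass
class RecallPlan:
    """Invitation plan for a genotype-based recall substudy.

    ``invitees`` has one row per person with columns: ``sample_id``, ``group``
    (hom_major / het / hom_minor), ``anchor_id`` (the minor-allele homozygote
    a matched invitee references; NaN for anchors and over-invitees),
    ``batch``, ``invited``, ``responded``, ``included``.
    """

    focal_variant: str
    invitees: pd.DataFrame
    unmatched: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.invitees
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"samples appear more than once in plan: {dups}")
        bad = ~df["group"].isin(GENOTYPE_GROUPS)
        if bad.any():
            raise ValueError(f"unknown genotype groups: {sorted(df.loc[bad, 'group'].unique())}")
        if (df["included"] & ~df["responded"]).any() or (df["responded"] & ~df["invited"]).any():
            raise ValueError("plan violates included => responded => invited")
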