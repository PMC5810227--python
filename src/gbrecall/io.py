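"""File interchange: PLINK bed/bim/fam, VCF, TSV tables and YAML configs.

The PLINK codec covers the variant-major 2-bit bed layout (magic bytes
0x6c 0x1b 0x03). Calls are re-oriented to minor-allele dosage at load when
the bim allele-1 frequency exceeds 0.5, with a logged record per flipped
marker.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix
from .simulate import CohortSpec, EffectSpec, MarkerSpec

logger = logging.getLogger(__name__)

__all__ = [
    "write_plink",
    "read_plink",
    "write_vcf",
    "read_phenotype_tsv",
    "write_ogtt_tsv",
    "read_ogtt_tsv",
    "cohort_spec_from_yaml",
    "effect_spec_from_yaml",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # third byte 0x01 = variant-major

# bed 2-bit code -> dosage of allele 1 (bim column 5): 00=2, 01=missing, 10=1, 11=0
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam files; allele 1 in the bim is the minor allele."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mk = matrix.markers
    bim = pd.DataFrame({
        "chrom": mk["chromosome"].to_numpy(),
        "rsid": mk.index.to_numpy(),
        "cm": 0,
        "pos": mk["position"].to_numpy(),
        "a1": mk["minor_allele"].to_numpy(),
        "a2": mk["major_allele"].to_numpy(),
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": matrix.sample_ids, "iid": matrix.sample_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    n = matrix.n_samples
    stride = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(stride, dtype=np.uint8)
        for j in range(matrix.n_markers):
            buf[:] = 0
            col = matrix.calls[:, j]
            for i in range(n):
                code = _DOSAGE_TO_CODE[int(col[i])]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read bed/bim/fam into a minor-allele-oriented :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "rsid", "cm", "pos", "a1", "a2"],
                      dtype={"a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC[:2] or raw[2] != 0x01:
        raise ValueError("not a variant-major PLINK bed file")
    n, m = len(fam), len(bim)
    stride = (n + 3) // 4
    body = raw[3:].reshape(m, stride)
    # unpack 2-bit codes, sample-within-byte little-endian
    codes = np.zeros((m, stride * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    calls = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()  # samples x markers
    # orient to minor allele
    minor = bim["a1"].to_numpy(dtype=object)
    major = bim["a2"].to_numpy(dtype=object)
    for j in range(m):
        col = calls[:, j]
        called = col != MISSING
        if called.any() and col[called].mean() / 2.0 > 0.5:
            col[called] = 2 - col[called]
            minor[j], major[j] = major[j], minor[j]
            logger.info("re-oriented %s to minor-allele dosage", bim["rsid"].iloc[j])
    markers = pd.DataFrame({
        "chromosome": bim["chrom"].to_numpy(),
        "position": bim["pos"].to_numpy(),
        "minor_allele": minor,
        "major_allele": major,
    }, index=pd.Index(bim["rsid"], name="rsID"))
    return GenotypeMatrix(calls, fam["iid"].astype(str).to_numpy(dtype=object), markers)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal uncompressed VCF v4.2 (GT only).

    REF is the major allele, ALT the minor allele, so the ALT dosage equals
    the stored minor-allele dosage.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, matrix.sample_ids)) + "\n")
        mk = matrix.markers
        for j, rsid in enumerate(mk.index):
            row = mk.iloc[j]
            gts = "\t".join(gt_of[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{row['chromosome']}\t{row['position']}\t{rsid}\t"
                     f"{row['major_allele']}\t{row['minor_allele']}\t.\t.\t.\tGT\t{gts}\n")


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    """Phenotype/covariate table keyed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype TSV must have a sample_id column")
    return df.set_index("sample_id")


def write_ogtt_tsv(ogtt: pd.DataFrame, path: str | Path) -> None:
    """Long-format OGTT table (sample_id, analyte, minutes, value, unit)."""
    required = {"sample_id", "analyte", "minutes", "value", "unit"}
    missing = required - set(ogtt.columns)
    if missing:
        raise ValueError(f"OGTT frame missing columns: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ogtt.to_csv(path, sep="\t", index=False)


_EXPECTED_UNITS = {"glucose": "mmol/L", "insulin": "mU/L",
                   "nefa": "umol/L", "glycerol": "umol/L"}


def read_ogtt_tsv(path: str | Path) -> pd.DataFrame:
    """Read and unit-validate a long-format OGTT table."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "analyte", "minutes", "value", "unit"} - set(df.columns)
    if missing:
        raise ValueError(f"OGTT TSV missing columns: {sorted(missing)}")
    for analyte, unit in _EXPECTED_UNITS.items():
        bad = df[(df["analyte"] == analyte) & (df["unit"] != unit)]
        if len(bad):
            raise ValueError(f"{analyte} rows carry unit {bad['unit'].unique()!r}; "
                             f"expected {unit!r}")
    return df


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML config mirroring its fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    markers = tuple(MarkerSpec(**mk) for mk in cfg.pop("markers"))
    if "age_range" in cfg:
        cfg["age_range"] = tuple(cfg["age_range"])
    return CohortSpec(markers=markers, **cfg)


def effect_spec_from_yaml(path: str | Path) -> EffectSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "participation_probs" in cfg:
        cfg["participation_probs"] = tuple(cfg["participation_probs"])
    return EffectSpec(**cfg)
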