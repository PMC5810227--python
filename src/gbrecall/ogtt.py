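"""Oral glucose tolerance test metrics and anthropometry.

Implements the recall-phase metabolic phenotyping panel: trapezoidal areas
under the curve, HOMA-IR, the Matsuda whole-body insulin sensitivity index,
the revised QUICKI (with non-esterified fatty acids in the denominator),
2-hour glucose, BMI and waist-hip ratio.

Unit conventions (chosen so that index magnitudes land on the scales the
clinical literature reports — HOMA-IR of order 1-3, Matsuda 2-12, revised
QUICKI about 0.2):

* glucose enters HOMA-IR in mmol/L but is converted to mg/dL (x 18.016) in
  the Matsuda and revised QUICKI denominators;
* insulin is mU/L throughout;
* NEFA is umol/L and the log in revised QUICKI is base 10.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "auc_trapezoid",
    "homa_ir",
    "matsuda_index",
    "revised_quicki",
    "anthropometry",
    "index_panel",
    "MGDL_PER_MMOL_GLUCOSE",
]

MGDL_PER_MMOL_GLUCOSE = 18.016

# Matsuda mean window: fasting through 120 min (the index's defining sampling
# scheme); the 180-min point never enters the means.
MATSUDA_WINDOW_MIN = 120

EXPECTED_TIMEPOINTS = (0, 15, 30, 60, 90, 120, 180)


def _as_series(times, values):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    order = np.argsort(t)
    t, v = t[order], v[order]
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate timepoints in series")
    return t, v


def auc_trapezoid(times, values, window_end: float) -> float:
    """Trapezoidal area under the curve from 0 to ``window_end`` minutes.

    Integrates over the observed timepoints up to and including
    ``window_end`` (units: minutes x concentration). Missing interior
    points simply widen a trapezoid; a completeness notice is logged when
    the standard sampling grid is not fully observed.
    """
    t, v = _as_series(times, values)
    if window_end > t[-1]:
        raise ValueError(f"window_end {window_end} beyond last observed timepoint {t[-1]}")
    sel = t <= window_end
    expected = [tp for tp in EXPECTED_TIMEPOINTS if tp <= window_end]
    if len(t[sel]) < len(expected):
        logger.info("series incomplete over [0, %g]: %d of %d standard timepoints",
                    window_end, int(sel.sum()), len(expected))
    return float(np.trapezoid(v[sel], t[sel]))


def homa_ir(fasting_glucose: float, fasting_insulin: float) -> float:
    """HOMA-IR = fasting glucose [mmol/L] x fasting insulin [mU/L] / 22.5."""
    if fasting_glucose <= 0 or fasting_insulin <= 0:
        raise ValueError("fasting glucose and insulin must be positive")
    return fasting_glucose * fasting_insulin / 22.5


def matsuda_index(glucose_times, glucose_mmol, insulin_times, insulin_mu) -> float:
    """Matsuda index from paired OGTT glucose and insulin series.

    10000 / sqrt(Gf x If x Gbar x Ibar) with glucose in mg/dL (converted
    from mmol/L), insulin in mU/L, and the means taken over the 0-120 min
    timepoints. Requires the fasting (0 min) sample in both series.
    """
    gt, gv = _as_series(glucose_times, glucose_mmol)
    it, iv = _as_series(insulin_times, insulin_mu)
    for t, label in ((gt, "glucose"), (it, "insulin")):
        if t[0] != 0:
            raise ValueError(f"{label} series lacks the fasting (0 min) sample")
    if (gv <= 0).any() or (iv <= 0).any():
        raise ValueError("glucose and insulin concentrations must be positive")
    g_mgdl = gv * MGDL_PER_MMOL_GLUCOSE
    gf, if_ = g_mgdl[0], iv[0]
    g_mean = g_mgdl[gt <= MATSUDA_WINDOW_MIN].mean()
    i_mean = iv[it <= MATSUDA_WINDOW_MIN].mean()
    return 10000.0 / math.sqrt(gf * if_ * g_mean * i_mean)


def revised_quicki(fasting_glucose: float, fasting_insulin: float,
                   fasting_nefa: float) -> float:
    """Revised QUICKI = 1 / (log G + log I + log NEFA), logs base 10.

    Units: glucose in mmol/L (converted to mg/dL internally), insulin in
    mU/L, NEFA in umol/L. NEFA values below 10 are rejected as a probable
    unit error (fasting NEFA in mmol/L, ~0.2-0.8, would roughly halve the
    index's denominator and inflate it to ~0.45).
    """
    if min(fasting_glucose, fasting_insulin, fasting_nefa) <= 0:
        raise ValueError("all fasting concentrations must be positive")
    if fasting_nefa < 10:
        raise ValueError(
            f"fasting NEFA {fasting_nefa} looks like mmol/L; umol/L required"
        )
    denom = (math.log10(fasting_glucose * MGDL_PER_MMOL_GLUCOSE)
             + math.log10(fasting_insulin) + math.log10(fasting_nefa))
    if denom <= 0:
        raise ValueError("index undefined: log-sum denominator <= 0")
    return 1.0 / denom


def anthropometry(weight_kg: float, height_cm: float, waist_cm: float,
                  hip_cm: float) -> tuple[float, float]:
    """BMI (kg/m^2) and waist-hip ratio."""
    if min(weight_kg, height_cm, waist_cm, hip_cm) <= 0:
        raise ValueError("anthropometric measures must be positive")
    if not 100 <= height_cm <= 250:
        raise ValueError(f"implausible height {height_cm} cm (expected 100-250)")
    h = height_cm / 100.0
    return weight_kg / (h * h), waist_cm / hip_cm


def index_panel(ogtt: pd.DataFrame, anthro: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample metabolic index panel from long-format OGTT data.

    ``ogtt`` columns: sample_id, analyte (glucose/insulin/nefa/glycerol),
    minutes, value (units per the module convention). ``anthro`` (optional)
    is indexed by sample id with weight_kg, height_cm, waist_cm, hip_cm
    columns. Returns one row per sample: homa_ir, matsuda, revised_quicki,
    AUCs (glucose/insulin 0-180, NEFA/glycerol 0-120), glucose_2h, and —
    when anthro is given — bmi and waist_hip_ratio.
    """
    required = {"sample_id", "analyte", "minutes", "value"}
    if not required <= set(ogtt.columns):
        raise ValueError(f"ogtt frame missing columns: {sorted(required - set(ogtt.columns))}")
    rows = {}
    for sid, g in ogtt.groupby("sample_id"):
        series = {a: _as_series(sub["minutes"], sub["value"])
                  for a, sub in g.groupby("analyte")}
        rec: dict[str, float] = {}
        glu = series.get("glucose")
        ins = series.get("insulin")
        nefa = series.get("nefa")
        gly = series.get("glycerol")
        if glu is not None and glu[0][0] == 0 and ins is not None and ins[0][0] == 0:
            rec["homa_ir"] = homa_ir(glu[1][0], ins[1][0])
            rec["matsuda"] = matsuda_index(glu[0], glu[1], ins[0], ins[1])
            if nefa is not None and nefa[0][0] == 0:
                rec["revised_quicki"] = revised_quicki(glu[1][0], ins[1][0], nefa[1][0])
                rec["nefa_baseline"] = nefa[1][0]
            rec["fasting_glucose"] = glu[1][0]
            rec["fasting_insulin"] = ins[1][0]
        if glu is not None:
            rec["auc_glucose_0_180"] = auc_trapezoid(*glu, 180)
            at_2h = glu[1][glu[0] == 120]
            if at_2h.size:
                rec["glucose_2h"] = float(at_2h[0])
        if ins is not None:
            rec["auc_insulin_0_180"] = auc_trapezoid(*ins, 180)
        if nefa is not None:
            rec["auc_nefa_0_120"] = auc_trapezoid(*nefa, 120)
        if gly is not None:
            rec["auc_glycerol_0_120"] = auc_trapezoid(*gly, 120)
            if gly[0][0] == 0:
                rec["glycerol_baseline"] = gly[1][0]
        rows[sid] = rec
    panel = pd.DataFrame.from_dict(rows, orient="index")
    panel.index.name = "sample_id"
    if anthro is not None:
        bmi, whr = [], []
        for sid in panel.index:
            if sid in anthro.index:
                b, w = anthropometry(anthro.at[sid, "weight_kg"], anthro.at[sid, "height_cm"],
                                     anthro.at[sid, "waist_cm"], anthro.at[sid, "hip_cm"])
            else:
                b = w = float("nan")
            bmi.append(b)
            whr.append(w)
        panel["bmi"] = bmi
        panel["waist_hip_ratio"] = whr
    return panel
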