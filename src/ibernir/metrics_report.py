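"""Classification and regression performance metrics plus TSV report tables.

Sensitivity and specificity are computed one-vs-rest per class,

    SE = TP / (TP + FN),    SP = TN / (TN + FP),

expressed as percentages; the regression side carries 1-VR, RMSECV,
SECV, R²v, RMSEV and the practical-utility indices RPD = SD/RMSE and
RER = (Ymax - Ymin)/RMSE.  Rendered tables use 2 decimals for
percentages, 3 for regression statistics, and the literal string "NA"
for undefined cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """Per-class (sensitivity %, specificity %); NaN when undefined."""
    if cm.tp + cm.fn > 0:
        se = 100.0 * cm.tp / (cm.tp + cm.fn)
    else:
        warnings.warn("no positive samples: SE undefined", stacklevel=2)
        se = math.nan
    if cm.tn + cm.fp > 0:
        sp = 100.0 * cm.tn / (cm.tn + cm.fp)
    else:
        warnings.warn("no negative samples: SP undefined", stacklevel=2)
        sp = math.nan
    return se, sp


def build_confusion(
    truth: Sequence[str], predicted: Sequence[str | None], cls: str
) -> ConfusionMatrix:
    """One-vs-rest confusion counts for ``cls``.

    ``predicted`` entries may be None (a class-modelling "none"
    assignment), which counts as a negative prediction for every class.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predictions differ in length")
    tp = fn = tn = fp = 0
    for t, p in zip(truth, predicted):
        if t == cls:
            if p == cls:
                tp += 1
            else:
                fn += 1
        else:
            if p == cls:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fn, tn, fp)


def rpd_rer(sd: float, y_min: float, y_max: float, rmse: float) -> tuple[float, float]:
    """Residual prediction deviation SD/RMSE and range error ratio
    (Ymax - Ymin)/RMSE; NaN when RMSE is zero."""
    if y_max < y_min:
        raise ValueError("y_max < y_min")
    if rmse <= 0:
        warnings.warn("RMSE is zero: RPD/RER undefined", stacklevel=2)
        return math.nan, math.nan
    return sd / rmse, (y_max - y_min) / rmse


def r_squared(y: np.ndarray, y_hat: np.ndarray, kind: str = "corr") -> float:
    """Coefficient of determination of external validation.

    ``kind='corr'`` (default) is the squared Pearson correlation — the
    common NIRS-community reading, robust to slope/bias mismatch;
    ``kind='ss'`` is 1 - SSE/SST.  Returns NaN when either vector is
    constant (printed as "NA" in reports).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if kind == "ss":
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            return math.nan
        return 1.0 - float(np.sum((y - y_hat) ** 2) / ss_tot)
    if np.std(y) == 0 or np.std(y_hat) == 0:
        return math.nan
    return float(np.corrcoef(y, y_hat)[0, 1] ** 2)


# ----------------------------------------------------------------------
# Table rendering
# ----------------------------------------------------------------------

def _fmt(value, decimals: int) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{value:.{decimals}f}"


_CLASSIF_PCT = {"SE_cal", "SP_cal", "SE_val", "SP_val"}


def render_classification_table(rows: list[dict]) -> pd.DataFrame:
    """Rows -> formatted table matching the discriminant report layout:
    category, pre-treatment, components, per-set n, SE, SP."""
    cols = [
        "category", "pretreatment", "components",
        "n_cal", "SE_cal", "SP_cal", "n_val", "SE_val", "SP_val",
    ]
    out = []
    for row in rows:
        rec = {}
        for c in cols:
            v = row.get(c)
            if c in _CLASSIF_PCT:
                rec[c] = _fmt(v, 2)
            elif c.startswith("n_") or c == "components":
                rec[c] = _fmt(v, 0)
            else:
                rec[c] = "NA" if v is None else str(v)
        out.append(rec)
    return pd.DataFrame(out, columns=cols)


def render_quantitative_table(rows: list[dict]) -> pd.DataFrame:
    """Rows -> formatted per-trait PLSR table: pre-treatment, LVs, n,
    calibration 1-VR/RMSECV and validation R²v/RMSEV/RPDv/RERv."""
    cols = [
        "trait", "pretreatment", "LVs", "n",
        "one_minus_VR", "RMSECV", "R2v", "RMSEV", "RPDv", "RERv",
    ]
    out = []
    for row in rows:
        rec = {}
        for c in cols:
            v = row.get(c)
            if c in ("LVs", "n"):
                rec[c] = _fmt(v, 0)
            elif c in ("trait", "pretreatment"):
                rec[c] = "NA" if v is None else str(v)
            else:
                rec[c] = _fmt(v, 3)
        out.append(rec)
    return pd.DataFrame(out, columns=cols)


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
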