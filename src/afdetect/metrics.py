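"""Beat-level confusion counts and the six performance measures.

AF is the positive class.  Se, Sp, PPV, NPV and CA are the usual
confusion-matrix ratios expressed as percentages; the F-Score is the
harmonic mean of Se and PPV,

    FS = 2 * Se * PPV / (Se + PPV).

Monte Carlo cross-validation repeats are summarised per measure as the
sample mean +/- sample SD.  A measure whose denominator is zero is
reported as NaN (explicitly undefined), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MEASURE_NAMES = ("se", "sp", "ppv", "npv", "ca", "fs")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN beat counts with AF as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Confusion counts between predicted and reference +1/-1 labels."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"pred shape {pred.shape} != ref shape {ref.shape}")
    p = pred > 0
    r = ref > 0
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        tn=int(np.sum(~p & ~r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
    )


@dataclass(frozen=True)
class PerformanceMeasures:
    """Se, Sp, PPV, NPV, CA and FS as percentages (NaN = undefined)."""

    se: float
    sp: float
    ppv: float
    npv: float
    ca: float
    fs: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASURE_NAMES}

    def round(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding (tables use two decimals); internals stay exact."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def f_score(se: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and positive predictive value (%)."""
    if math.isnan(se) or math.isnan(ppv) or se + ppv == 0:
        return math.nan
    return 2.0 * se * ppv / (se + ppv)


def measures(c: ConfusionCounts) -> PerformanceMeasures:
    """The six performance measures from one set of confusion counts."""
    se = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    ca = _ratio(c.tp + c.tn, c.n)
    return PerformanceMeasures(se, sp, ppv, npv, ca, f_score(se, ppv))


def evaluate(pred: np.ndarray, ref: np.ndarray) -> PerformanceMeasures:
    """Convenience: confusion + measures in one call."""
    return measures(confusion(pred, ref))


def mc_summary(repeats: list[PerformanceMeasures]) -> pd.DataFrame:
    """Mean and sample SD per measure over Monte Carlo CV repeats.

    Returns a two-row frame (index ``mean``, ``sd``) with one column per
    measure — the shape of a published results-table row.
    """
    if not repeats:
        raise ValueError("mc_summary requires at least one repeat")
    data = np.array([[getattr(r, k) for k in MEASURE_NAMES] for r in repeats])
    mean = np.nanmean(data, axis=0)
    sd = np.nanstd(data, axis=0, ddof=1) if len(repeats) > 1 else np.zeros(len(MEASURE_NAMES))
    return pd.DataFrame([mean, sd], index=["mean", "sd"], columns=list(MEASURE_NAMES))
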