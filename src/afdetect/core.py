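"""Core containers for beat-to-beat interval series.

Everything downstream of beat detection works on the sequence of RR
intervals (the times between consecutive heartbeats, in milliseconds)
and its reciprocal, the instantaneous heart rate in beats per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AF = "AF"
NON_AF = "nonAF"

#: Beats at each record edge that lack a complete symmetric feature window
#: (half-width of the default 21-beat window) and are excluded from analysis.
BOUNDARY_EXCLUSION = 10


class InvalidInputError(ValueError):
    """Raised when input data violate a precondition (e.g. RR <= 0)."""


@dataclass
class RRSeries:
    """One signal's ordered RR intervals with optional per-beat labels.

    Parameters
    ----------
    signal_id
        Identifier of the source record.
    rr_ms
        Ordered RR intervals in milliseconds; all strictly positive.
    label
        Optional per-beat rhythm labels, each ``"AF"`` or ``"nonAF"``,
        aligned with ``rr_ms``.
    """

    signal_id: str
    rr_ms: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.rr_ms.ndim != 1:
            raise InvalidInputError("rr_ms must be one-dimensional")
        bad = ~(self.rr_ms > 0) | ~np.isfinite(self.rr_ms)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise InvalidInputError(
                f"RR interval at beat {idx} is non-positive or non-finite "
                f"({self.rr_ms[idx]!r}); RR intervals must be > 0 ms"
            )
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=object)
            if len(self.label) != len(self.rr_ms):
                raise InvalidInputError(
                    f"label length {len(self.label)} != rr length {len(self.rr_ms)}"
                )
            unknown = set(self.label) - {AF, NON_AF}
            if unknown:
                raise InvalidInputError(f"unknown labels: {sorted(map(str, unknown))}")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def y(self) -> np.ndarray | None:
        """Labels coded +1 for AF, -1 for non-AF (None when unlabeled)."""
        if self.label is None:
            return None
        return np.where(self.label == AF, 1, -1).astype(int)


@dataclass
class HRSeries:
    """Instantaneous heart rate (bpm), index-aligned with its RRSeries."""

    signal_id: str
    hr_bpm: np.ndarray

    def __len__(self) -> int:
        return len(self.hr_bpm)


def hr_from_rr(rr: RRSeries | np.ndarray) -> HRSeries | np.ndarray:
    """Convert RR intervals (ms) to instantaneous heart rate (bpm).

    HR_i = 60000 / RR_i, element-wise.  Accepts either an :class:`RRSeries`
    (returns an :class:`HRSeries`) or a bare array (returns an array).
    """
    if isinstance(rr, RRSeries):
        return HRSeries(rr.signal_id, 60000.0 / rr.rr_ms)
    arr = np.asarray(rr, dtype=float)
    bad = ~(arr > 0) | ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise InvalidInputError(
            f"RR interval at beat {idx} is non-positive or non-finite ({arr[idx]!r})"
        )
    return 60000.0 / arr


@dataclass(frozen=True)
class WindowConfig:
    """Symmetric moving-window configuration for feature extraction.

    ``N`` is the total window width in beats (odd), ``k = (N-1)/2`` its
    half-width.  ``quantile_order`` parameterises the robust quantile
    feature; ``prp_low``/``prp_high`` bound the heart-rate band whose
    occupancy fraction is the PRP feature; ``nn_threshold`` is the
    successive-difference cutoff (ms) for pNN50.
    """

    N: int = 21
    quantile_order: float = 0.7
    prp_low: float = 120.0
    prp_high: float = 160.0
    nn_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.N < 3 or self.N % 2 == 0:
            raise ValueError(f"window width N must be odd and >= 3, got {self.N}")
        if not 0.0 < self.quantile_order < 1.0:
            raise ValueError("quantile_order must lie in (0, 1)")
        if not self.prp_low < self.prp_high:
            raise ValueError("prp_low must be < prp_high")

    @property
    def k(self) -> int:
        """Half-width (N-1)/2."""
        return (self.N - 1) // 2
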