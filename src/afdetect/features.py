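"""Windowed heart-rate irregularity features.

Sixteen features are computed for every beat that has a complete
symmetric window of ``N`` beats (default 21) around it:

* robust statistics of the HR window — median (MED), median absolute
  deviation (MAD), order-0.7 quantile (QNT), and the fraction of HR
  values inside the 120–160 bpm band (PRP);
* classical time-domain HRV — mean HR, SD of HR, RMSSD, pNN50;
* non-linear HRV — Poincaré SD1/SD2 and the turning-point ratio (TPR);
* four short-term variability indices from fetal heart-rate monitoring —
  the Yeh, Zugaib, Huey and de Haan indices — all highly sensitive to
  beat-to-beat changes;
* plus the instantaneous HR of the centre beat itself.

AF produces chaotic RR sequences, so the dispersion-type features
(RMSSD, SD1, the beat-to-beat indices) separate AF windows from sinus
rhythm.  Quantiles use linear interpolation between order statistics
(the "type 7" convention) everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RRSeries, WindowConfig, hr_from_rr

FEATURE_NAMES = (
    "hr",
    "med",
    "mad",
    "qnt",
    "prp",
    "mean_hr",
    "std_hr",
    "rmssd",
    "pnn50",
    "sd1",
    "sd2",
    "tpr",
    "di_yeh",
    "stv_zug",
    "stv_huey",
    "sti_haan",
)


def _check_window(win: np.ndarray, n: int, name: str) -> np.ndarray:
    win = np.asarray(win, dtype=float)
    if win.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {win.shape}")
    return win


def expected_turning_points(n: int) -> float:
    """Expected number of turning points, (2N-4)/3, in a random sequence."""
    return (2 * n - 4) / 3


def robust_features(
    window_hr: np.ndarray, cfg: WindowConfig = WindowConfig()
) -> tuple[float, float, float, float]:
    """Median, MAD, quantile and band-occupancy of one HR window.

    Returns ``(med, mad, qnt, prp)`` where ``prp`` is the fraction of HR
    values inside the inclusive band ``[cfg.prp_low, cfg.prp_high]``.
    """
    hr = _check_window(window_hr, cfg.N, "window_hr")
    med = float(np.median(hr))
    mad = float(np.median(np.abs(hr - med)))
    qnt = float(np.quantile(hr, cfg.quantile_order))
    prp = float(np.mean((hr >= cfg.prp_low) & (hr <= cfg.prp_high)))
    return med, mad, qnt, prp


def time_domain_features(
    window_hr: np.ndarray,
    window_rr: np.ndarray,
    cfg: WindowConfig = WindowConfig(),
) -> tuple[float, float, float, float]:
    """Mean HR, sample SD of HR, RMSSD and pNN50 of one window.

    RMSSD (ms) is the root mean square of the N-1 successive RR
    differences; pNN50 (%) the percentage of those differences whose
    magnitude strictly exceeds ``cfg.nn_threshold``.
    """
    hr = _check_window(window_hr, cfg.N, "window_hr")
    rr = _check_window(window_rr, cfg.N, "window_rr")
    mean_hr = float(np.mean(hr))
    std_hr = float(np.std(hr, ddof=1))
    drr = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(drr**2)))
    pnn50 = float(np.mean(np.abs(drr) > cfg.nn_threshold) * 100.0)
    return mean_hr, std_hr, rmssd, pnn50


def nonlinear_features(
    window_rr: np.ndarray, cfg: WindowConfig = WindowConfig()
) -> tuple[float, float, float]:
    """Poincaré SD1/SD2 and the turning-point ratio of one RR window.

    SD1/SD2 come from the variance identities of the Poincaré cloud
    (RR_j, RR_{j+1}): SD1^2 = Var(diff)/2 and SD2^2 = 2 Var(RR) - SD1^2
    with population variances; they measure dispersion perpendicular to
    and along the identity line.  A turning point is a strict local
    extremum; TPR normalises the observed count by the (2N-4)/3
    expectation for a random sequence.
    """
    rr = _check_window(window_rr, cfg.N, "window_rr")
    drr = np.diff(rr)
    sd1_sq = np.var(drr) / 2.0
    sd1 = float(np.sqrt(sd1_sq))
    sd2 = float(np.sqrt(max(2.0 * np.var(rr) - sd1_sq, 0.0)))
    tp = int(np.sum(drr[:-1] * drr[1:] < 0))
    tpr = tp / expected_turning_points(cfg.N)
    return sd1, sd2, float(tpr)


def fhr_features(
    window_rr: np.ndarray,
    window_hr: np.ndarray,
    cfg: WindowConfig = WindowConfig(),
) -> tuple[float, float, float, float]:
    """The four fetal-heart-rate short-term variability indices.

    * Yeh: SD (with 1/(N-2) normalisation over the N-1 terms, i.e. the
      sample SD) of d_i = (RR_i - RR_{i+1}) / (RR_i + RR_{i+1}).
    * Zugaib: mean absolute deviation of D_i = |RR_{i+1} - RR_i| /
      (RR_{i+1} + RR_i) from their median.
    * Huey: sum of |HR_{i+1} - HR_i| over positions where the successive
      HR difference strictly changes sign.
    * de Haan: interquartile range of the angles (degrees) of the points
      (RR_{i-1}, RR_i) in polar coordinates.
    """
    rr = _check_window(window_rr, cfg.N, "window_rr")
    hr = _check_window(window_hr, cfg.N, "window_hr")
    d = (rr[:-1] - rr[1:]) / (rr[:-1] + rr[1:])
    di_yeh = float(np.std(d, ddof=1))
    big_d = np.abs(d)
    stv_zug = float(np.mean(np.abs(big_d - np.median(big_d))))
    dhr = np.diff(hr)
    sign_change = dhr[:-1] * dhr[1:] < 0
    stv_huey = float(np.sum(np.abs(dhr[1:])[sign_change]))
    phi = np.degrees(np.arctan2(rr[1:], rr[:-1]))
    sti_haan = float(np.quantile(phi, 0.75) - np.quantile(phi, 0.25))
    return di_yeh, stv_zug, stv_huey, sti_haan


def feature_vector(
    window_rr: np.ndarray, cfg: WindowConfig = WindowConfig()
) -> np.ndarray:
    """All 16 features of one window, ordered as :data:`FEATURE_NAMES`."""
    rr = _check_window(window_rr, cfg.N, "window_rr")
    hr = hr_from_rr(rr)
    med, mad, qnt, prp = robust_features(hr, cfg)
    mean_hr, std_hr, rmssd, pnn50 = time_domain_features(hr, rr, cfg)
    sd1, sd2, tpr = nonlinear_features(rr, cfg)
    di_yeh, stv_zug, stv_huey, sti_haan = fhr_features(rr, hr, cfg)
    centre_hr = hr[cfg.k]
    return np.array(
        [centre_hr, med, mad, qnt, prp, mean_hr, std_hr, rmssd, pnn50,
         sd1, sd2, tpr, di_yeh, stv_zug, stv_huey, sti_haan]
    )


@dataclass
class FeatureMatrix:
    """Per-beat 16-feature vectors with a validity mask.

    ``X`` holds one row per *valid* beat (a beat with k predecessors and
    k successors); ``beat_index`` maps rows back to beat positions in
    the source series; ``valid_mask`` flags validity over all beats.
    """

    signal_id: str
    X: np.ndarray
    beat_index: np.ndarray
    valid_mask: np.ndarray
    label: np.ndarray | None = None

    @property
    def n_valid(self) -> int:
        return len(self.beat_index)

    @property
    def y(self) -> np.ndarray | None:
        """Valid-beat labels coded +1 (AF) / -1 (non-AF)."""
        if self.label is None:
            return None
        return np.where(self.label == "AF", 1, -1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        """Full-length table: beat_index, valid flag, 16 feature columns."""
        n = len(self.valid_mask)
        full = np.full((n, len(FEATURE_NAMES)), np.nan)
        full[self.beat_index] = self.X
        df = pd.DataFrame(full, columns=list(FEATURE_NAMES))
        df.insert(0, "beat_index", np.arange(n))
        df.insert(1, "valid", self.valid_mask)
        return df


def _windowed(x: np.ndarray, n: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, n)


def extract_features(
    rr: RRSeries, cfg: WindowConfig = WindowConfig()
) -> FeatureMatrix:
    """Compute the 16 features for every beat with a complete window.

    The first and last ``k`` beats of the series have no complete
    symmetric window and are masked invalid, so a series of length L
    yields ``L - 2k`` valid beats.  Computation is vectorised over all
    windows; per-window semantics are identical to the scalar functions.
    """
    n_beats = len(rr)
    k = cfg.k
    valid_mask = np.zeros(n_beats, dtype=bool)
    if n_beats < cfg.N:
        warnings.warn(
            f"series {rr.signal_id!r} has {n_beats} beats < window width "
            f"{cfg.N}; no valid beats",
            stacklevel=2,
        )
        return FeatureMatrix(
            rr.signal_id,
            np.empty((0, len(FEATURE_NAMES))),
            np.empty(0, dtype=int),
            valid_mask,
            np.empty(0, dtype=object) if rr.label is not None else None,
        )
    valid_mask[k : n_beats - k] = True
    beat_index = np.flatnonzero(valid_mask)

    w_rr = _windowed(rr.rr_ms, cfg.N)  # (M, N) windows
    w_hr = 60000.0 / w_rr
    m = w_rr.shape[0]

    med = np.median(w_hr, axis=1)
    mad = np.median(np.abs(w_hr - med[:, None]), axis=1)
    qnt = np.quantile(w_hr, cfg.quantile_order, axis=1)
    prp = np.mean((w_hr >= cfg.prp_low) & (w_hr <= cfg.prp_high), axis=1)

    mean_hr = np.mean(w_hr, axis=1)
    std_hr = np.std(w_hr, axis=1, ddof=1)
    drr = np.diff(w_rr, axis=1)
    rmssd = np.sqrt(np.mean(drr**2, axis=1))
    pnn50 = np.mean(np.abs(drr) > cfg.nn_threshold, axis=1) * 100.0

    sd1_sq = np.var(drr, axis=1) / 2.0
    sd1 = np.sqrt(sd1_sq)
    sd2 = np.sqrt(np.clip(2.0 * np.var(w_rr, axis=1) - sd1_sq, 0.0, None))
    tp = np.sum(drr[:, :-1] * drr[:, 1:] < 0, axis=1)
    tpr = tp / expected_turning_points(cfg.N)

    d = (w_rr[:, :-1] - w_rr[:, 1:]) / (w_rr[:, :-1] + w_rr[:, 1:])
    di_yeh = np.std(d, axis=1, ddof=1)
    big_d = np.abs(d)
    stv_zug = np.mean(np.abs(big_d - np.median(big_d, axis=1)[:, None]), axis=1)
    dhr = np.diff(w_hr, axis=1)
    stv_huey = np.sum(np.abs(dhr[:, 1:]) * (dhr[:, :-1] * dhr[:, 1:] < 0), axis=1)
    phi = np.degrees(np.arctan2(w_rr[:, 1:], w_rr[:, :-1]))
    sti_haan = np.quantile(phi, 0.75, axis=1) - np.quantile(phi, 0.25, axis=1)

    centre_hr = w_hr[:, k]
    X = np.column_stack(
        [centre_hr, med, mad, qnt, prp, mean_hr, std_hr, rmssd, pnn50,
         sd1, sd2, tpr, di_yeh, stv_zug, stv_huey, sti_haan]
    )
    assert X.shape == (m, len(FEATURE_NAMES))
    label = rr.label[beat_index] if rr.label is not None else None
    return FeatureMatrix(rr.signal_id, X, beat_index, valid_mask, label)
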