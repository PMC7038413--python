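"""Synthetic two-state rhythm records for end-to-end testing.

Real long-term recordings alternate between sinus rhythm — slow,
smoothly varying RR intervals — and AF episodes with fast, erratically
varying intervals.  The generator emulates exactly that contrast:

* the rhythm state follows a two-state Markov chain with per-beat
  entry/exit probabilities, so episode durations are geometric;
* sinus RR intervals follow a stationary AR(1) process around
  ``sinus_mean_rr`` with marginal SD ``sinus_sd`` (respiratory-like
  serial correlation);
* AF RR intervals are independent draws around ``af_mean_rr`` whose
  successive differences have SD ``af_succ_sd`` — a deliberate
  caricature of fibrillatory irregularity, not a physiological model.

All intervals are floored at 250 ms (HR <= 240 bpm) so every feature
stays finite.  Per-beat labels record the generating state, which makes
the whole pipeline testable without any external database.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import AF, NON_AF, RRSeries
from .dataset import SignalSet

RR_FLOOR_MS = 250.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults give sinus/AF separation typical
    of annotated long-term records (AF fraction ~0.4, episodes lasting
    hundreds of beats, i.e. minutes)."""

    n_beats: int = 2000
    sinus_mean_rr: float = 800.0
    sinus_sd: float = 20.0
    sinus_ar1: float = 0.8
    af_mean_rr: float = 600.0
    af_succ_sd: float = 120.0
    p_enter_af: float = 0.002
    p_exit_af: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        for name in ("sinus_mean_rr", "sinus_sd", "af_mean_rr", "af_succ_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.sinus_ar1 < 1.0:
            raise ValueError("sinus_ar1 must lie in [0, 1)")
        for name in ("p_enter_af", "p_exit_af"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def gen_record(
    cfg: SyntheticConfig,
    signal_id: str = "synthetic",
    rng: np.random.Generator | None = None,
    initial_state: str | None = None,
) -> RRSeries:
    """Generate one labeled RR record from the two-state rhythm model.

    The initial state is drawn from the chain's stationary distribution
    unless ``initial_state`` is given ("AF" or "nonAF").
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pe, px = cfg.p_enter_af, cfg.p_exit_af
    if initial_state is None:
        p_af = pe / (pe + px) if pe + px > 0 else 0.0
        state_af = bool(rng.random() < p_af)
    else:
        state_af = initial_state == AF

    # AF intervals are iid; successive-difference SD s*sqrt(2) = af_succ_sd
    af_sd = cfg.af_succ_sd / np.sqrt(2.0)
    # AR(1) innovations chosen so the stationary marginal SD is sinus_sd
    innov_sd = cfg.sinus_sd * np.sqrt(1.0 - cfg.sinus_ar1**2)

    rr = np.empty(cfg.n_beats)
    labels = np.empty(cfg.n_beats, dtype=object)
    dev = 0.0  # sinus AR(1) deviation from its mean, persists across AF
    u = rng.random(cfg.n_beats)
    for i in range(cfg.n_beats):
        if state_af:
            rr[i] = cfg.af_mean_rr + af_sd * rng.standard_normal()
            labels[i] = AF
            state_af = u[i] >= px
        else:
            dev = cfg.sinus_ar1 * dev + innov_sd * rng.standard_normal()
            rr[i] = cfg.sinus_mean_rr + dev
            labels[i] = NON_AF
            state_af = u[i] < pe
    np.clip(rr, RR_FLOOR_MS, None, out=rr)
    return RRSeries(signal_id, rr, labels)


def gen_database(
    n_signals: int = 25,
    cfg: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    af_prevalence: list[float | None] | None = None,
) -> SignalSet:
    """Generate a set of independent records (default 25).

    ``af_prevalence`` optionally overrides the stationary AF fraction of
    individual signals (values in [0, 1]; 0 and 1 give pure-class
    records, mimicking the extreme imbalance seen in real databases).
    Each signal gets an independent child seed, so a fixed ``seed``
    reproduces the set bit-identically.
    """
    if n_signals < 1:
        raise ValueError("n_signals must be >= 1")
    if af_prevalence is not None and len(af_prevalence) != n_signals:
        raise ValueError("af_prevalence must have one entry per signal")
    children = np.random.SeedSequence(seed).spawn(n_signals)
    signals = []
    switch_rate = cfg.p_enter_af + cfg.p_exit_af
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        c = cfg
        init = None
        if af_prevalence is not None and af_prevalence[i] is not None:
            prev = af_prevalence[i]
            if prev <= 0.0:
                c = replace(cfg, p_enter_af=0.0)
                init = NON_AF
            elif prev >= 1.0:
                c = replace(cfg, p_exit_af=0.0)
                init = AF
            else:
                c = replace(
                    cfg,
                    p_enter_af=switch_rate * prev,
                    p_exit_af=switch_rate * (1.0 - prev),
                )
        signals.append(gen_record(c, signal_id=f"syn{i:02d}", rng=rng, initial_state=init))
    return SignalSet(signals)
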