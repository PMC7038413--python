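"""Reading labeled RR records and constructing balanced train/test splits.

The canonical on-disk record is a delimited text table with columns
``beat_index``, ``rr_ms`` and optionally ``label`` (``AF``/``nonAF``).
A second reader derives RR series and rhythm labels from rdann-style
*text* beat/rhythm annotation listings (the export format of PhysioNet
annotation files).

Training sets are built the way a severely class-imbalanced beat
database demands: per signal, half of the minority class is drawn
without replacement and matched by an equal draw from the majority
class, giving an exactly balanced training set; every remaining beat
goes to testing.  Monte Carlo cross-validation repeats this with
independent child seeds spawned from one master seed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AF, NON_AF, BOUNDARY_EXCLUSION, InvalidInputError, RRSeries


class BalancedDrawError(ValueError):
    """Raised when a signal lacks one of the two classes."""


@dataclass
class SignalSet:
    """A collection of labeled RR series with per-signal class counts."""

    signals: list[RRSeries]
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.signals)

    def __iter__(self):
        return iter(self.signals)

    def __getitem__(self, signal_id: str) -> RRSeries:
        for s in self.signals:
            if s.signal_id == signal_id:
                return s
        raise KeyError(signal_id)

    def counts(self) -> pd.DataFrame:
        """Per-signal N_AF, N_nAF and N_SIG (plus the AF percentage)."""
        rows = []
        for s in self.signals:
            if s.label is None:
                raise ValueError(f"signal {s.signal_id!r} is unlabeled")
            n_af = int(np.sum(s.label == AF))
            n_sig = len(s)
            rows.append(
                {
                    "signal_id": s.signal_id,
                    "n_af": n_af,
                    "n_naf": n_sig - n_af,
                    "n_sig": n_sig,
                    "af_pct": 100.0 * n_af / n_sig if n_sig else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    @property
    def n_beats(self) -> int:
        return sum(len(s) for s in self.signals)


@dataclass
class SplitSpec:
    """One train/test division: per-signal training beat indices.

    Indices refer to beat positions within each signal; every beat not
    listed is a testing beat.  Training draws are class-balanced.
    """

    repeat_index: int
    seed: int
    train_indices: dict[str, np.ndarray] = field(default_factory=dict)

    def n_train(self) -> int:
        return sum(len(v) for v in self.train_indices.values())

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "repeat_index": self.repeat_index,
                "seed": self.seed,
                "train_indices": {k: v.tolist() for k, v in self.train_indices.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        import json

        blob = json.loads(text)
        return cls(
            repeat_index=blob["repeat_index"],
            seed=blob["seed"],
            train_indices={
                k: np.asarray(v, dtype=int) for k, v in blob["train_indices"].items()
            },
        )


# --------------------------------------------------------------------------
# readers


def read_rr_table(path: str | Path, signal_id: str | None = None) -> RRSeries:
    """Read a delimited beat table (beat_index, rr_ms[, label]).

    Accepts comma or whitespace/tab separated files, with or without a
    header row.  Malformed rows raise with their line number.
    """
    path = Path(path)
    text = path.read_text()
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    first = text.splitlines()[0].replace(",", " ").split()
    header = 0 if any(not _is_number(tok) and tok not in (AF, NON_AF) for tok in first) else None
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, header=header)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InvalidInputError(f"{path}: cannot parse: {exc}") from exc
    if header is None:
        names = ["beat_index", "rr_ms", "label"][: df.shape[1]]
        df.columns = names
    if "rr_ms" not in df.columns:
        raise InvalidInputError(f"{path}: missing rr_ms column")
    rr = pd.to_numeric(df["rr_ms"], errors="coerce")
    bad = rr.isna() | (rr <= 0)
    if bad.any():
        line = int(bad.idxmax()) + (2 if header == 0 else 1)
        raise InvalidInputError(
            f"{path}, line {line}: RR value {df['rr_ms'][bad.idxmax()]!r} "
            "is missing, non-numeric or non-positive"
        )
    label = None
    if "label" in df.columns and df["label"].notna().all():
        label = df["label"].astype(str).to_numpy()
    return RRSeries(signal_id or path.stem, rr.to_numpy(float), label)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_rr_table(series: RRSeries, path: str | Path) -> None:
    """Write a series in the canonical CSV format."""
    df = pd.DataFrame({"beat_index": np.arange(len(series)), "rr_ms": series.rr_ms})
    if series.label is not None:
        df["label"] = series.label
    df.to_csv(path, index=False)


def read_wfdb_rhythm(record_path: str | Path, signal_id: str | None = None) -> RRSeries:
    """Derive an RR series from an rdann-style text annotation listing.

    Each line holds a beat or rhythm annotation: ``<time_s> <symbol>
    [aux]``.  Lines whose symbol is ``+`` are rhythm changes whose aux
    field (e.g. ``(AFIB``, ``(N``) opens a rhythm interval lasting until
    the next change (half-open).  All other symbols are beats.

    RR_i is the difference of consecutive beat times (ms); each interval
    carries the rhythm state at its *starting* beat, AF iff that beat
    lies inside an ``(AFIB``-opened interval.  Records with no rhythm
    annotation are all non-AF.
    """
    path = Path(record_path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    beat_times: list[float] = []
    rhythm_changes: list[tuple[float, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise InvalidInputError(f"{path}, line {lineno}: expected '<time> <symbol> [aux]'")
        try:
            t = float(parts[0])
        except ValueError as exc:
            raise InvalidInputError(f"{path}, line {lineno}: bad time {parts[0]!r}") from exc
        symbol = parts[1]
        if symbol == "+":
            aux = parts[2] if len(parts) > 2 else ""
            rhythm_changes.append((t, aux))
        else:
            beat_times.append(t)
    if len(beat_times) < 2:
        raise InvalidInputError(f"{path}: fewer than two beats; no RR intervals")
    times = np.asarray(beat_times)
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError(f"{path}: beat times must be strictly increasing")
    rr_ms = np.diff(times) * 1000.0

    change_times = np.array([t for t, _ in rhythm_changes])
    is_af_state = np.array([aux.startswith("(AFIB") for _, aux in rhythm_changes])
    start_beats = times[:-1]
    if len(change_times) == 0:
        label = np.full(len(rr_ms), NON_AF, dtype=object)
    else:
        # state at each starting beat: last change with time <= beat time
        idx = np.searchsorted(change_times, start_beats, side="right") - 1
        af = np.where(idx >= 0, is_af_state[np.clip(idx, 0, None)], False)
        label = np.where(af, AF, NON_AF).astype(object)
    return RRSeries(signal_id or path.stem, rr_ms, label)


# --------------------------------------------------------------------------
# exclusion and balanced sampling


def exclude_boundary(signal_set: SignalSet, k: int = BOUNDARY_EXCLUSION) -> SignalSet:
    """Remove the first and last ``k`` beats of every signal.

    Those beats have no complete symmetric feature window.  Signals too
    short to retain any beat (length <= 2k) are dropped with a warning.
    Returns a new set whose ``n_excluded`` counts the removed beats.
    """
    kept: list[RRSeries] = []
    excluded = 0
    for s in signal_set:
        if len(s) <= 2 * k:
            warnings.warn(
                f"signal {s.signal_id!r} has only {len(s)} beats "
                f"(<= 2k = {2 * k}); dropped",
                stacklevel=2,
            )
            continue
        excluded += 2 * k
        kept.append(
            RRSeries(
                s.signal_id,
                s.rr_ms[k : len(s) - k],
                None if s.label is None else s.label[k : len(s) - k],
            )
        )
    return SignalSet(kept, n_excluded=signal_set.n_excluded + excluded)


def balanced_draw(
    signal: RRSeries,
    seed: int | np.random.Generator,
    minority_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced training draw from one labeled signal.

    Draws ``floor(minority_fraction * N_minority)`` beats of the
    minority class without replacement, then an equal number from the
    majority class, also without replacement.  Returns sorted
    ``(train_indices, test_indices)``; testing is everything else.

    Raises :class:`BalancedDrawError` on a single-class signal — such
    records cannot contribute balanced training data.
    """
    if signal.label is None:
        raise ValueError(f"signal {signal.signal_id!r} is unlabeled")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    af_idx = np.flatnonzero(signal.label == AF)
    naf_idx = np.flatnonzero(signal.label == NON_AF)
    if len(af_idx) == 0 or len(naf_idx) == 0:
        raise BalancedDrawError(
            f"signal {signal.signal_id!r} contains a single class only "
            f"(N_AF={len(af_idx)}, N_nAF={len(naf_idx)}); cannot draw balanced "
            "training data"
        )
    minority, majority = (af_idx, naf_idx) if len(af_idx) <= len(naf_idx) else (naf_idx, af_idx)
    n_draw = int(np.floor(minority_fraction * len(minority)))
    train = np.concatenate(
        [
            rng.choice(minority, size=n_draw, replace=False),
            rng.choice(majority, size=n_draw, replace=False),
        ]
    )
    train.sort()
    mask = np.ones(len(signal), dtype=bool)
    mask[train] = False
    return train, np.flatnonzero(mask)


def build_training_design(
    signal_set: SignalSet,
    signal_ids: list[str] | None,
    size: int,
    seed: int | np.random.Generator,
    repeat_index: int = 0,
) -> SplitSpec:
    """Draw a class-balanced training set of ``size`` beats from a signal group.

    ``signal_ids`` names the pool (None = all signals, the all-signals
    mixed design); ``size/2`` beats per class are drawn without
    replacement from the pooled class populations.  Signals with a
    single class still contribute their beats to the pool (they only
    cannot be the *sole* source of a balanced draw).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = [s.signal_id for s in signal_set] if signal_ids is None else list(signal_ids)
    per_class = size // 2
    pools: dict[str, list[tuple[str, int]]] = {AF: [], NON_AF: []}
    for sid in ids:
        s = signal_set[sid]
        if s.label is None:
            raise ValueError(f"signal {sid!r} is unlabeled")
        for cls in (AF, NON_AF):
            for i in np.flatnonzero(s.label == cls):
                pools[cls].append((sid, int(i)))
    for cls in (AF, NON_AF):
        if len(pools[cls]) < per_class:
            raise ValueError(
                f"requested {per_class} {cls} training beats but the pool holds "
                f"only {len(pools[cls])} (short by {per_class - len(pools[cls])})"
            )
    split = SplitSpec(repeat_index=repeat_index, seed=int(rng.integers(0, 2**31)))
    chosen: dict[str, list[int]] = {}
    for cls in (AF, NON_AF):
        pool = pools[cls]
        pick = rng.choice(len(pool), size=per_class, replace=False)
        for j in pick:
            sid, i = pool[j]
            chosen.setdefault(sid, []).append(i)
    split.train_indices = {
        sid: np.asarray(sorted(ix), dtype=int) for sid, ix in sorted(chosen.items())
    }
    return split


def mc_splits(
    signal_set: SignalSet,
    signal_ids: list[str] | None,
    size: int,
    n_repeats: int,
    master_seed: int,
) -> list[SplitSpec]:
    """Monte Carlo CV: independent balanced draws from spawned child seeds."""
    children = np.random.SeedSequence(master_seed).spawn(n_repeats)
    return [
        build_training_design(
            signal_set, signal_ids, size, np.random.default_rng(child), repeat_index=r
        )
        for r, child in enumerate(children)
    ]
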