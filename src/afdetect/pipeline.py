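"""End-to-end orchestration: features -> LSVM -> aggregation -> measures.

The stage order mirrors how the method is applied to a beat database:

1. extract windowed irregularity features per signal (boundary beats,
   which lack a complete window, drop out);
2. draw a class-balanced training set, train the LSVM, classify every
   valid beat;
3. smooth the per-beat decisions with the aggregation window, choosing
   (w, p) by F-Score grid search — smoothing is applied per signal, a
   window never spans two records;
4. report the six performance measures on held-out beats and on the
   whole database, before and after aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import GRID_P, GRID_W, AggregationParams, smooth_labels
from .core import WindowConfig
from .dataset import SignalSet, SplitSpec, build_training_design, exclude_boundary
from .features import FeatureMatrix, extract_features
from .lsvm import LSVMConfig, LSVMModel, lsvm_train
from .metrics import PerformanceMeasures, evaluate, mc_summary


def extract_all(
    signal_set: SignalSet, cfg: WindowConfig = WindowConfig()
) -> dict[str, FeatureMatrix]:
    """Feature matrices for every signal in the set."""
    return {s.signal_id: extract_features(s, cfg) for s in signal_set}


def valid_beat_pool(
    signal_set: SignalSet, cfg: WindowConfig = WindowConfig()
) -> SignalSet:
    """The analyzable pool: every signal trimmed of its k boundary beats.

    Beat j of a trimmed signal corresponds exactly to row j of that
    signal's :class:`FeatureMatrix`, so split indices drawn from this
    pool index feature rows directly.
    """
    return exclude_boundary(signal_set, k=cfg.k)


def assemble_training(
    features: dict[str, FeatureMatrix], split: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the training rows named by a split into (X, y)."""
    xs, ys = [], []
    for sid, idx in split.train_indices.items():
        fm = features[sid]
        xs.append(fm.X[idx])
        ys.append(fm.y[idx])
    return np.vstack(xs), np.concatenate(ys)


@dataclass
class PipelineResult:
    """Everything one full run produces."""

    model: LSVMModel
    split: SplitSpec
    pred: dict[str, np.ndarray]
    ref: dict[str, np.ndarray]
    agg_params: AggregationParams | None
    surface: pd.DataFrame | None
    measures_test: PerformanceMeasures
    measures_all: PerformanceMeasures
    measures_test_agg: PerformanceMeasures | None
    measures_all_agg: PerformanceMeasures | None

    def table(self) -> pd.DataFrame:
        """Results table: one row per reporting mode, two-decimal display."""
        rows = {"test": self.measures_test.round(), "all": self.measures_all.round()}
        if self.measures_test_agg is not None:
            rows["test+aggregation"] = self.measures_test_agg.round()
            rows["all+aggregation"] = self.measures_all_agg.round()
        return pd.DataFrame(rows).T


def _held_out_masks(
    features: dict[str, FeatureMatrix], split: SplitSpec
) -> dict[str, np.ndarray]:
    masks = {}
    for sid, fm in features.items():
        m = np.ones(fm.n_valid, dtype=bool)
        if sid in split.train_indices:
            m[split.train_indices[sid]] = False
        masks[sid] = m
    return masks


def _pooled(
    labels: dict[str, np.ndarray], masks: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    parts = [
        v if masks is None else v[masks[k]] for k, v in sorted(labels.items())
    ]
    return np.concatenate(parts)


def grid_optimize_multi(
    pred: dict[str, np.ndarray],
    ref: dict[str, np.ndarray],
    grid_w: tuple[int, ...] = GRID_W,
    grid_p: tuple[float, ...] = GRID_P,
) -> tuple[AggregationParams, pd.DataFrame]:
    """F-Score grid search with per-signal smoothing and pooled counts.

    Same contract as :func:`afdetect.aggregation.grid_optimize` but the
    smoothing window is applied within each signal separately.
    """
    ref_pool = _pooled(ref)
    rows = []
    best = None
    for w in grid_w:
        for p in grid_p:
            params = AggregationParams(w, p)
            sm = {sid: smooth_labels(v, params) for sid, v in pred.items()}
            m = evaluate(_pooled(sm), ref_pool)
            rows.append((w, p, m.se, m.ppv, m.fs))
            key = (-(m.fs if m.fs == m.fs else -np.inf), w, p)
            if best is None or key < best:
                best = key
    return AggregationParams(best[1], best[2]), pd.DataFrame(
        rows, columns=["w", "p", "se", "ppv", "fs"]
    )


def full_run(
    signal_set: SignalSet,
    window_cfg: WindowConfig = WindowConfig(),
    lsvm_cfg: LSVMConfig = LSVMConfig(),
    train_size: int = 2000,
    seed: int = 0,
    optimize_aggregation: bool = True,
    grid_w: tuple[int, ...] = GRID_W,
    grid_p: tuple[float, ...] = GRID_P,
) -> PipelineResult:
    """One complete pass over a labeled signal set.

    Draws a balanced training set of ``train_size`` beats from the
    pooled valid beats of all signals, trains the LSVM, classifies every
    valid beat, optionally grid-optimises the aggregation stage on the
    held-out beats, and reports measures for testing-only and whole-pool
    beats, before and after aggregation.
    """
    features = extract_all(signal_set, window_cfg)
    pool = valid_beat_pool(signal_set, window_cfg)
    split = build_training_design(pool, None, train_size, seed)
    X_train, y_train = assemble_training(features, split)
    model = lsvm_train(X_train, y_train, lsvm_cfg)

    pred = {sid: model.predict(fm.X) for sid, fm in features.items()}
    ref = {sid: fm.y for sid, fm in features.items()}
    masks = _held_out_masks(features, split)

    measures_test = evaluate(_pooled(pred, masks), _pooled(ref, masks))
    measures_all = evaluate(_pooled(pred), _pooled(ref))

    agg_params = surface = m_test_agg = m_all_agg = None
    if optimize_aggregation:
        agg_params, surface = grid_optimize_multi(pred, ref, grid_w, grid_p)
        sm = {sid: smooth_labels(v, agg_params) for sid, v in pred.items()}
        m_test_agg = evaluate(_pooled(sm, masks), _pooled(ref, masks))
        m_all_agg = evaluate(_pooled(sm), _pooled(ref))

    return PipelineResult(
        model=model,
        split=split,
        pred=pred,
        ref=ref,
        agg_params=agg_params,
        surface=surface,
        measures_test=measures_test,
        measures_all=measures_all,
        measures_test_agg=m_test_agg,
        measures_all_agg=m_all_agg,
    )


def monte_carlo_cv(
    signal_set: SignalSet,
    window_cfg: WindowConfig = WindowConfig(),
    lsvm_cfg: LSVMConfig = LSVMConfig(),
    train_size: int = 2000,
    n_repeats: int = 50,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Repeated random train/test division; mean +/- SD per measure.

    Feature extraction is done once; each repeat redraws the balanced
    training set from an independently spawned child seed, retrains and
    re-evaluates on its own held-out beats (no aggregation stage — this
    assesses the raw classifier, the aggregation optimum is found once
    afterwards).
    """
    features = extract_all(signal_set, window_cfg)
    pool = valid_beat_pool(signal_set, window_cfg)
    children = np.random.SeedSequence(master_seed).spawn(n_repeats)
    results = []
    for r, child in enumerate(children):
        split = build_training_design(
            pool, None, train_size, np.random.default_rng(child), repeat_index=r
        )
        X_train, y_train = assemble_training(features, split)
        model = lsvm_train(X_train, y_train, lsvm_cfg)
        pred = {sid: model.predict(fm.X) for sid, fm in features.items()}
        ref = {sid: fm.y for sid, fm in features.items()}
        masks = _held_out_masks(features, split)
        results.append(evaluate(_pooled(pred, masks), _pooled(ref, masks)))
    return mc_summary(results)
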