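"""Compound-screen preprocessing, activity binarization, diversity
splitting, and binary classification statistics.

The evaluation statistics are the seven standard confusion-matrix
measures: overall accuracy, sensitivity (true-positive rate), specificity
(true-negative rate), precision, recall, F-measure, and Matthews
correlation coefficient (MCC). The classifier itself is deliberately an
interchangeable component: any estimator with ``fit``/``predict`` can be
scored through :func:`score_classifier`; reference hyperparameters for a
C4.5-style decision tree and a small multilayer perceptron are recorded in
:data:`REFERENCE_LEARNER_CONFIG`.

Activity labeling uses a dual IC50 cut-off: compounds at or below the
active threshold (default 10 uM) are labeled active (1), compounds above
the least-active threshold (default 18 uM) are labeled least-active (0),
and the window in between is excluded from classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "binarize",
    "preprocess_compounds",
    "SplitResult",
    "diverse_split",
    "ConfusionMatrix",
    "MetricsReport",
    "evaluate",
    "score_classifier",
    "REFERENCE_LEARNER_CONFIG",
]

#: Label marker for compounds inside the (active_max, least_active_min] window.
EXCLUDED = None

#: Hyperparameters of the reference learners for anyone wiring a standard
#: classifier (the learner is pluggable; nothing in this module trains one
#: by default).
REFERENCE_LEARNER_CONFIG = {
    "decision_tree": {
        "algorithm": "C4.5 (J48)",
        "min_instances_per_leaf": 1,
        "confidence_factor": "lowest (aggressive pruning)",
        "cross_validation_folds": 10,
    },
    "mlp": {
        "layers": (10, 4, 2),
        "learning_rate": 0.3,
        "momentum": 0.2,
        "epochs": 500,
        "cross_validation_folds": 10,
    },
}


def binarize(
    ic50: float, active_max: float = 10.0, least_active_min: float = 18.0
) -> Optional[int]:
    """Dual cut-off activity label: 1 active, 0 least-active, EXCLUDED gap.

    ``ic50 <= active_max`` -> 1; ``ic50 > least_active_min`` -> 0; values in
    the window ``(active_max, least_active_min]`` return :data:`EXCLUDED`.
    Raises on non-positive potencies.
    """
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    if ic50 <= active_max:
        return 1
    if ic50 > least_active_min:
        return 0
    return EXCLUDED


def preprocess_compounds(
    records: pd.DataFrame,
    mw_min: float = 200.0,
    dedup: bool = True,
    consistency_ratio: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard screen cleanup: fragments, duplicates, inconsistent assays.

    ``records`` needs columns ``id``, ``mw`` and ``ic50_um``; a compound
    may appear in several rows (repeat measurements). Rows with molecular
    weight below ``mw_min`` are dropped as small fragments. When ``dedup``
    is set, repeat measurements of one compound are collapsed to their
    geometric mean, unless their max/min IC50 ratio exceeds
    ``consistency_ratio``, in which case the compound is dropped entirely
    as inconsistent. Returns ``(clean, removal_log)`` where the log has one
    row per removal with a reason.
    """
    required = {"id", "mw", "ic50_um"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns {sorted(missing)}")
    log_rows: list[dict] = []
    df = records.copy()
    bad = df[sorted(required)].isna().any(axis=1)
    for rid in df.loc[bad, "id"]:
        log_rows.append({"id": rid, "reason": "missing required field"})
    df = df[~bad]

    frag = df["mw"] < mw_min
    for rid in df.loc[frag, "id"]:
        log_rows.append({"id": rid, "reason": f"small fragment (MW < {mw_min:g})"})
    df = df[~frag]

    if dedup:
        keep_parts = []
        for rid, grp in df.groupby("id", sort=False):
            if len(grp) == 1:
                keep_parts.append(grp)
                continue
            ratio = grp["ic50_um"].max() / grp["ic50_um"].min()
            if ratio > consistency_ratio:
                log_rows.append(
                    {
                        "id": rid,
                        "reason": (
                            f"inconsistent IC50 measurements "
                            f"(ratio {ratio:.3g} > {consistency_ratio:g})"
                        ),
                    }
                )
                continue
            rep = grp.iloc[[0]].copy()
            rep["ic50_um"] = float(np.exp(np.log(grp["ic50_um"]).mean()))
            keep_parts.append(rep)
            log_rows.append(
                {"id": rid, "reason": f"collapsed {len(grp)} duplicate measurements"}
            )
        df = (
            pd.concat(keep_parts, ignore_index=True)
            if keep_parts
            else df.iloc[0:0].reset_index(drop=True)
        )
    else:
        df = df.reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["id", "reason"])
    return df, log


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple
    test_ids: tuple
    method: str


def diverse_split(
    records: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    descriptor_cols: Optional[Sequence[str]] = None,
) -> SplitResult:
    """Diversity-based train/test split on descriptor distance.

    The test side receives the most mutually distant compounds: descriptors
    are z-scored, the compound farthest from the centroid seeds the test
    set, and compounds maximizing the minimum Euclidean distance to the
    already-selected test set are added greedily (maximin) until the test
    fraction is reached. Exact ties are broken reproducibly with ``seed``.
    """
    if descriptor_cols is None:
        descriptor_cols = [c for c in records.columns if c.startswith("d")]
    if not descriptor_cols:
        raise ValueError("no descriptor columns to split on")
    if records[list(descriptor_cols)].isna().any().any():
        raise ValueError("descriptor columns contain missing values")
    ids = list(records["id"])
    if len(ids) < 2:
        raise ValueError("need at least two records to split")
    x = records[list(descriptor_cols)].to_numpy(dtype=float)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    z = (x - x.mean(axis=0)) / std
    n_test = max(1, int(round(test_fraction * len(ids))))
    rng = np.random.default_rng(seed)

    def argmax_tiebreak(values: np.ndarray) -> int:
        best = np.flatnonzero(values >= values.max() - 1e-12)
        return int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])

    centroid_dist = np.linalg.norm(z - z.mean(axis=0), axis=1)
    chosen = [argmax_tiebreak(centroid_dist)]
    min_dist = np.linalg.norm(z - z[chosen[0]], axis=1)
    while len(chosen) < n_test:
        min_dist[chosen] = -np.inf
        nxt = argmax_tiebreak(min_dist)
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(z - z[nxt], axis=1))
    test = sorted(chosen)
    train = [i for i in range(len(ids)) if i not in set(test)]
    return SplitResult(
        tuple(ids[i] for i in train),
        tuple(ids[i] for i in test),
        method=f"maximin diverse subset (test_fraction={test_fraction}, seed={seed})",
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: Optional[float]
    recall: float
    f_measure: Optional[float]
    mcc: Optional[float]  # None when a marginal vanishes (undefined)


def _metrics(cm: ConfusionMatrix) -> MetricsReport:
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    accuracy = (tp + tn) / cm.total
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else None
    recall = sensitivity
    if precision is None:
        f_measure = None
    elif precision + recall == 0:
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return MetricsReport(
        accuracy, sensitivity, specificity, precision, recall, f_measure, mcc
    )


def evaluate(
    predicted: Sequence[int], true: Sequence[int]
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and the seven statistics, with class 1 positive.

    MCC is reported as ``None`` (undefined) rather than coerced to zero
    when any marginal of the matrix vanishes.
    """
    predicted = list(predicted)
    true = list(true)
    if len(predicted) != len(true):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, {len(true)} labels"
        )
    if any(v not in (0, 1) for v in predicted + true):
        raise ValueError("labels must be binary (0/1)")
    tp = sum(1 for p, t in zip(predicted, true) if p == 1 and t == 1)
    fp = sum(1 for p, t in zip(predicted, true) if p == 1 and t == 0)
    tn = sum(1 for p, t in zip(predicted, true) if p == 0 and t == 0)
    fn = sum(1 for p, t in zip(predicted, true) if p == 0 and t == 1)
    cm = ConfusionMatrix(tp, fp, tn, fn)
    return cm, _metrics(cm)


def score_classifier(
    learner,
    train: pd.DataFrame,
    test: pd.DataFrame,
    descriptor_cols: Optional[Sequence[str]] = None,
    label_col: str = "label",
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Fit any sklearn-style ``learner`` on ``train`` and score on ``test``."""
    if descriptor_cols is None:
        descriptor_cols = [c for c in train.columns if c.startswith("d")]
    cols = list(descriptor_cols)
    learner.fit(train[cols].to_numpy(), train[label_col].astype(int).to_numpy())
    pred = learner.predict(test[cols].to_numpy())
    return evaluate(list(pred), list(test[label_col].astype(int)))
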