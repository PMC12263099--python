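"""Frame-level detection metrics, data splits, and the experiment harness.

Detection quality is scored per frame: every frame is either inside a
transient's rising phase (positive class) or not.  Precision, recall and F1
are computed for each class orientation, and the macro F1 — the arithmetic
mean of the two class F1 scores — is the headline number: with ~97% negative
frames, accuracy alone would be blind to transient-class performance.

The two class orientations are dual: designating the non-transient class as
positive swaps TP with TN and FP with FN, so the macro F1 is invariant to
the choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trace_model import FrameLabels

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "precision_recall_f1",
    "macro_f1",
    "macro_f1_from_masks",
    "metrics_report",
    "split_cells",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    #: True when any metric had an empty denominator and was defined as 0.
    degenerate: bool


@dataclass(frozen=True)
class MetricsReport:
    """Per-class frame metrics plus their macro average."""

    transient: ClassMetrics
    non_transient: ClassMetrics
    macro_f1: float

    def to_dict(self) -> Dict:
        return {
            "transient": vars(self.transient.counts)
            | {
                "precision": self.transient.precision,
                "recall": self.transient.recall,
                "f1": self.transient.f1,
            },
            "non_transient": vars(self.non_transient.counts)
            | {
                "precision": self.non_transient.precision,
                "recall": self.non_transient.recall,
                "f1": self.non_transient.f1,
            },
            "macro_f1": self.macro_f1,
        }


def _as_mask(x) -> np.ndarray:
    if isinstance(x, FrameLabels):
        return x.mask
    return np.asarray(x)


def confusion(pred, truth, positive_class: int = 1) -> ConfusionCounts:
    """Frame-wise confusion counts under the chosen positive class.

    ``positive_class=1`` scores the transient class; ``0`` scores the
    non-transient class (which permutes the counts per the duality).
    """
    p = _as_mask(pred)
    t = _as_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p = p == positive_class
    t = t == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def precision_recall_f1(counts: ConfusionCounts) -> Tuple[float, float, float, bool]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean.

    Empty denominators define the metric as 0; the returned flag marks that
    the convention was used.
    """
    degenerate = False
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, degenerate = 0.0, True
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return precision, recall, f1, degenerate


def macro_f1(report: "MetricsReport") -> float:
    """Arithmetic mean of the transient and non-transient F1 scores."""
    return (report.transient.f1 + report.non_transient.f1) / 2.0


def metrics_report(pred, truth) -> MetricsReport:
    """Full two-class report for predicted vs ground-truth masks."""
    classes = {}
    for name, pos in (("transient", 1), ("non_transient", 0)):
        counts = confusion(pred, truth, positive_class=pos)
        precision, recall, f1, degenerate = precision_recall_f1(counts)
        classes[name] = ClassMetrics(counts, precision, recall, f1, degenerate)
    return MetricsReport(
        transient=classes["transient"],
        non_transient=classes["non_transient"],
        macro_f1=(classes["transient"].f1 + classes["non_transient"].f1) / 2.0,
    )


def macro_f1_from_masks(pred, truth) -> float:
    return metrics_report(pred, truth).macro_f1


def split_cells(
    cell_ids: Sequence,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[List, List, List]:
    """Seeded random split into train/validation/test cell sets.

    Validation and test sizes are floored; the remainder goes to training —
    282 cells at 80/10/10 therefore split 226/28/28.  The three sets are
    disjoint and exhaustive.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    ids = list(cell_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_val = int(len(ids) * fractions[1])
    n_test = int(len(ids) * fractions[2])
    n_train = len(ids) - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def run_experiment(
    datasets: Dict[str, Dict],
    n_train_cells: Sequence[int],
    conditions: Optional[Sequence[Tuple[str, str]]] = None,
    n_repeats: int = 3,
    cfg=None,
    seed: int = 0,
    n_val_cells: int = 1,
    redraw_train: bool = True,
) -> pd.DataFrame:
    """Training-set-size × test-source sweep of a sequence-labeling detector.

    Parameters
    ----------
    datasets : dict
        tag -> ``{"traceset": CalciumTraceSet, "labels": FrameLabels}``.
        Tags name data sources (e.g., session stages, days, animals,
        regions); cross-source conditions train on one tag and test on
        another.
    n_train_cells : sequence of int
        Grid of training-set sizes.
    conditions : sequence of (train_tag, test_tag)
        Defaults to same-source conditions, one per dataset tag.
    n_repeats : int
        Repeats per grid point; with ``redraw_train`` both training and
        test cells are redrawn each repeat, otherwise only test cells.
    cfg : TrainConfig
        Detector configuration (default: GRU reference settings).

    Returns a long-format table: one row per repeat × condition × metric.
    Grid points with too few cells are skipped with a reason row.
    """
    from .ml_detection import TrainConfig, build_model, classify, make_windows
    from .ml_detection import predict_frames, train

    if cfg is None:
        cfg = TrainConfig()
    if conditions is None:
        conditions = [(tag, tag) for tag in datasets]
    rows: List[Dict] = []
    rng = np.random.default_rng(seed)
    for train_tag, test_tag in conditions:
        cond = f"{train_tag}->{test_tag}"
        src, dst = datasets[train_tag], datasets[test_tag]
        src_ts, src_labels = src["traceset"], src["labels"]
        dst_ts, dst_labels = dst["traceset"], dst["labels"]
        for n_cells in n_train_cells:
            base_draw = None
            for rep in range(n_repeats):
                same_source = train_tag == test_tag
                need = n_cells + n_val_cells + (1 if same_source else 0)
                if need > src_ts.n_cells:
                    rows.append(
                        {
                            "condition": cond,
                            "n_train_cells": n_cells,
                            "repeat": rep,
                            "metric": "skipped",
                            "value": np.nan,
                            "reason": f"needs {need} cells, "
                            f"dataset has {src_ts.n_cells}",
                        }
                    )
                    continue
                if redraw_train or base_draw is None:
                    draw = rng.permutation(src_ts.n_cells)
                    base_draw = draw
                else:
                    draw = base_draw
                train_ids = [src_ts.cell_ids[i] for i in draw[:n_cells]]
                val_ids = [
                    src_ts.cell_ids[i] for i in draw[n_cells : n_cells + n_val_cells]
                ]
                if same_source:
                    pool = [
                        src_ts.cell_ids[i] for i in draw[n_cells + n_val_cells :]
                    ]
                    test_ids = list(rng.choice(pool, size=1, replace=False))
                else:
                    test_ids = [
                        dst_ts.cell_ids[i]
                        for i in rng.permutation(dst_ts.n_cells)[:1]
                    ]
                rep_cfg = TrainConfig(
                    **{
                        **vars(cfg),
                        "seed": int(rng.integers(0, 2**31 - 1)),
                    }
                )
                model = build_model(rep_cfg)
                tw = make_windows(src_ts, src_labels, rep_cfg, cell_ids=train_ids)
                vw = make_windows(src_ts, src_labels, rep_cfg, cell_ids=val_ids)
                model, _ = train(model, tw, vw)
                probs = predict_frames(model, dst_ts, cell_ids=test_ids)
                pred, _ = classify(probs, rep_cfg.threshold, rep_cfg.min_run)
                idx = [dst_ts.cell_index(c) for c in test_ids]
                rep_report = metrics_report(pred.mask, dst_labels.mask[idx])
                flat = {
                    "macro_f1": rep_report.macro_f1,
                    "precision_transient": rep_report.transient.precision,
                    "recall_transient": rep_report.transient.recall,
                    "f1_transient": rep_report.transient.f1,
                    "precision_non_transient": rep_report.non_transient.precision,
                    "recall_non_transient": rep_report.non_transient.recall,
                    "f1_non_transient": rep_report.non_transient.f1,
                }
                for metric, value in flat.items():
                    rows.append(
                        {
                            "condition": cond,
                            "n_train_cells": n_cells,
                            "repeat": rep,
                            "metric": metric,
                            "value": value,
                            "reason": "",
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["condition", "n_train_cells", "repeat", "metric", "value", "reason"],
    )
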