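"""The A-B/B-A twin-subset validation protocol and its metrics.

Two independent runs — train on subset A / test on B ("a-b"), then the
reverse ("b-a") — are averaged into a pooled row, guarding against a
single favourable split.  "Overall accuracy" throughout this package is the
arithmetic mean of sensitivity and specificity, i.e. balanced accuracy:
this is the only definition that reproduces the published arithmetic
((67.86 + 83.72)/2 = 75.79 etc.), whereas raw accuracy does not.  AUC uses
the Mann–Whitney formulation, P(score⁺ > score⁻) + ½·P(tie); the pooled AUC
is the mean of the two directions' AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable
from .mlp import MLPConfig, train_mlp, predict_scores
from .preprocessing import minmax_scale

__all__ = ["ConfusionMatrix", "DirectionMetrics", "ValidationReport",
           "confusion_metrics", "auc_score", "ab_ba_protocol", "round2"]


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as used for reported percentages."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        )


@dataclass(frozen=True)
class DirectionMetrics:
    """One report row: test-set composition and percent metrics.

    ``overall_accuracy`` is always (sensitivity + specificity)/2, recomputed,
    never stored independently.  Percentages are kept at full precision;
    rounding happens only at display/serialisation time.
    """

    direction: str
    n_test: int
    n_pos: int
    n_neg: int
    sensitivity: float
    specificity: float
    auc: float

    @property
    def overall_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def rounded(self) -> dict:
        return {
            "direction": self.direction,
            "n_test": self.n_test,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "sensitivity": round2(self.sensitivity),
            "specificity": round2(self.specificity),
            "overall_accuracy": round2(self.overall_accuracy),
            "auc": round(self.auc, 3),
        }


class UndefinedMetricError(ValueError):
    pass


def confusion_metrics(cm: ConfusionMatrix, direction: str = "",
                      auc: float = float("nan")) -> DirectionMetrics:
    """Sensitivity, specificity and their mean (overall accuracy), in percent."""
    if cm.positives == 0 or cm.negatives == 0:
        raise UndefinedMetricError(
            "sensitivity/specificity undefined: test set must contain both classes"
        )
    sens = 100.0 * cm.TP / cm.positives
    spec = 100.0 * cm.TN / cm.negatives
    return DirectionMetrics(direction=direction, n_test=cm.positives + cm.negatives,
                            n_pos=cm.positives, n_neg=cm.negatives,
                            sensitivity=sens, specificity=spec, auc=auc)


def auc_score(scores, truth) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) + ½ P(score⁺ = score⁻)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as ½ wins
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ValidationReport:
    """Three-row report: a-b, b-a, and their pooled mean (counts summed)."""

    row_ab: DirectionMetrics
    row_ba: DirectionMetrics

    @property
    def row_mean(self) -> DirectionMetrics:
        a, b = self.row_ab, self.row_ba
        return DirectionMetrics(
            direction="mean",
            n_test=a.n_test + b.n_test,
            n_pos=a.n_pos + b.n_pos,
            n_neg=a.n_neg + b.n_neg,
            sensitivity=(a.sensitivity + b.sensitivity) / 2.0,
            specificity=(a.specificity + b.specificity) / 2.0,
            auc=(a.auc + b.auc) / 2.0,
        )

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = [self.row_ab, self.row_ba, self.row_mean]
        if rounded:
            return pd.DataFrame([r.rounded() for r in rows])
        return pd.DataFrame([{**asdict(r), "overall_accuracy": r.overall_accuracy}
                             for r in rows])

    def to_dict(self) -> dict:
        return {"ab": self.row_ab.rounded(), "ba": self.row_ba.rounded(),
                "mean": self.row_mean.rounded()}


def _evaluate_direction(train_tbl: CohortTable, test_tbl: CohortTable,
                        features: list[str], config: MLPConfig,
                        direction: str) -> DirectionMetrics:
    train_scaled = minmax_scale(train_tbl.X[features])
    # apply the training ranges to the test set (clipped) to avoid leakage
    test_scaled = minmax_scale(test_tbl.X[features], ranges=train_scaled.ranges,
                               clip=True)
    model = train_mlp(train_scaled.values, train_tbl.y, config)
    scores = predict_scores(model, test_scaled.values)
    preds = (scores >= 0.5).astype(int)
    cm = ConfusionMatrix.from_predictions(test_tbl.y, preds)
    return confusion_metrics(cm, direction=direction,
                             auc=auc_score(scores, test_tbl.y))


def ab_ba_protocol(table: CohortTable, selected_features, split,
                   mlp_config: MLPConfig = MLPConfig()) -> ValidationReport:
    """Run both protocol directions with fresh seeded inits per direction.

    ``split`` is a boolean/0-1 array over records: True/1 assigns subset A.
    Each direction trains an independent model (seeds derived from
    ``mlp_config.seed``) and evaluates on the held-out subset.
    """
    split = np.asarray(split, dtype=bool)
    if split.shape[0] != table.n:
        raise ValueError("split length must equal record count")
    if split.all() or (~split).all():
        raise ValueError("split must assign records to both subsets")
    features = list(selected_features)
    if not features:
        raise ValueError("selected_features must be non-empty")

    tbl_a = CohortTable.from_frame(table.frame[split], table.variable_names)
    tbl_b = CohortTable.from_frame(table.frame[~split], table.variable_names)
    for name, t in (("A", tbl_a), ("B", tbl_b)):
        if len(np.unique(t.y)) < 2:
            raise ValueError(f"subset {name} contains a single outcome class")

    cfg_ab = MLPConfig(**{**asdict(mlp_config), "seed": mlp_config.seed * 2 + 1})
    cfg_ba = MLPConfig(**{**asdict(mlp_config), "seed": mlp_config.seed * 2 + 2})
    try:
        row_ab = _evaluate_direction(tbl_a, tbl_b, features, cfg_ab, "a-b")
    except Exception as e:
        raise RuntimeError(f"direction a-b failed: {e}") from e
    try:
        row_ba = _evaluate_direction(tbl_b, tbl_a, features, cfg_ba, "b-a")
    except Exception as e:
        raise RuntimeError(f"direction b-a failed: {e}") from e
    return ValidationReport(row_ab=row_ab, row_ba=row_ba)
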