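"""TWIST: joint input selection and twin-subset construction.

A single genome encodes both decisions: 13 feature bits (which variables the
classifier may use) and one bit per record (subset A vs subset B).  The
fitness of a genome is the mean balanced accuracy of a small fixed-budget
MLP trained A→tested on B and trained B→tested on A on the masked, scaled
features — so the evolutionary search simultaneously looks for the most
informative variables and for a bipartition whose two halves support each
other's generalisation (i.e. share a similar probability density).

Constraint violations are repaired, not rejected: an empty feature mask gets
the best univariately-ranked feature; a subset missing a class, or whose
class proportion drifts more than 5 points from the cohort's, is fixed by
deterministic record moves/swaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .gend import GenDParams, gend_evolve
from .mlp import MLPConfig, train_mlp, predict_scores
from .preprocessing import minmax_scale

__all__ = ["TwistResult", "twist_select", "DEFAULT_INNER_MLP"]

#: Small fixed training budget for the inner fitness classifier; a cheap
#: deterministic network keeps the evolutionary search tractable.
DEFAULT_INNER_MLP = MLPConfig(hidden_units=4, learning_rate=1.0, epochs=80,
                              init_scale=0.5, seed=17)

MAX_CLASS_IMBALANCE = 0.05  # subset class proportion within 5 points of global


@dataclass
class TwistResult:
    selected_features: list[str]
    subset_a_ids: list[int]
    subset_b_ids: list[int]
    class_counts: dict  # {"A": {"pos": ..., "neg": ...}, "B": {...}}
    fitness_history: np.ndarray
    best_fitness: float
    split_mask: np.ndarray = field(repr=False)     # True -> subset A
    feature_mask: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "subset_a_ids": self.subset_a_ids,
            "subset_b_ids": self.subset_b_ids,
            "class_counts": self.class_counts,
            "fitness_history": self.fitness_history.tolist(),
            "best_fitness": self.best_fitness,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    sens = (y_pred[pos] == 1).mean()
    spec = (y_pred[~pos] == 0).mean()
    return (sens + spec) / 2.0


def _univariate_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Features ordered by decreasing |point-biserial r| with the outcome."""
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / denom, 0.0)
    return np.argsort(-np.abs(r), kind="stable")


def _repair(genome: np.ndarray, n_features: int, y: np.ndarray,
            feature_rank: np.ndarray) -> np.ndarray:
    g = genome.copy()
    fmask = g[:n_features]
    split = g[n_features:]
    n = split.shape[0]

    if not fmask.any():
        fmask[feature_rank[0]] = True

    p_global = y.mean()
    # both subsets non-trivially sized
    min_size = max(2, int(0.25 * n))
    for _ in range(n):
        size_a = int(split.sum())
        if size_a < min_size:
            split[np.flatnonzero(~split)[0]] = True
        elif n - size_a < min_size:
            split[np.flatnonzero(split)[0]] = False
        else:
            break
    # class proportions within MAX_CLASS_IMBALANCE of global: swap a record
    # of the over-represented class in A with one of the other class in B
    for _ in range(n):
        in_a = split
        p_a = y[in_a].mean()
        p_b = y[~in_a].mean()
        if (abs(p_a - p_global) <= MAX_CLASS_IMBALANCE
                and abs(p_b - p_global) <= MAX_CLASS_IMBALANCE):
            break
        if p_a > p_global:  # A has too many positives -> B too few
            i = np.flatnonzero(in_a & (y == 1))[0]
            j = np.flatnonzero(~in_a & (y == 0))[0]
        else:
            i = np.flatnonzero(in_a & (y == 0))[0]
            j = np.flatnonzero(~in_a & (y == 1))[0]
        split[i], split[j] = False, True

    return np.concatenate([fmask, split])


def twist_select(table: CohortTable, params: GenDParams = GenDParams(),
                 inner_mlp: MLPConfig = DEFAULT_INNER_MLP) -> TwistResult:
    """Run the joint feature-selection / twin-subset search.

    The cohort is min-max scaled once over all records before the search
    (the masked columns feed the inner classifier directly).  Requires at
    least 20 records with both outcome classes present.
    """
    if table.n < 20:
        raise ValueError("TWIST requires at least 20 records")
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("TWIST requires both outcome classes in the cohort")

    scaled = minmax_scale(table)
    X = scaled.values.to_numpy()
    names = list(scaled.values.columns)
    n_features = X.shape[1]
    feature_rank = _univariate_rank(X, y)

    def repair(genome: np.ndarray) -> np.ndarray:
        return _repair(genome, n_features, y, feature_rank)

    def fitness(genome: np.ndarray) -> float:
        fmask = genome[:n_features]
        split = genome[n_features:]
        cols = np.flatnonzero(fmask)
        accs = []
        for train_sel in (split, ~split):
            model = train_mlp(X[np.ix_(train_sel, cols)], y[train_sel], inner_mlp)
            pred = (predict_scores(model, X[np.ix_(~train_sel, cols)]) >= 0.5)
            accs.append(_balanced_accuracy(y[~train_sel], pred.astype(int)))
        return float(np.mean(accs))

    res = gend_evolve(fitness, genome_length=n_features + table.n,
                      params=params, repair_fn=repair)

    fmask = res.best_genome[:n_features]
    split = res.best_genome[n_features:]
    ids_a = np.flatnonzero(split)
    ids_b = np.flatnonzero(~split)
    counts = {
        "A": {"pos": int(y[ids_a].sum()), "neg": int((1 - y[ids_a]).sum())},
        "B": {"pos": int(y[ids_b].sum()), "neg": int((1 - y[ids_b]).sum())},
    }
    return TwistResult(
        selected_features=[names[i] for i in np.flatnonzero(fmask)],
        subset_a_ids=ids_a.tolist(),
        subset_b_ids=ids_b.tolist(),
        class_counts=counts,
        fitness_history=res.fitness_history,
        best_fitness=res.best_fitness,
        split_mask=split,
        feature_mask=fmask,
    )
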