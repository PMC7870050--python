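"""Statsmodels-style modelling facade.

Two model classes wrap the library's stages:

* :class:`FractureRiskModel` — evolutionary input selection and twin-subset
  construction followed by the A-B/B-A MLP validation protocol; ``fit()``
  returns a :class:`FractureRiskResults` whose ``summary()`` prints the
  selected variables and the three-row sensitivity/specificity/overall-
  accuracy/AUC table.
* :class:`SemanticMap` — the Auto-CM (or prior-probability) similarity
  matrix with its MST/maximally-regular-graph connectivity map; ``fit()``
  returns a :class:`SemanticMapResults` with the graph and an outcome-node
  adjacency report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autocm import ConnectivityGraph, SimilarityMatrix, build_map, map_report
from .cohort import CohortTable, VARIABLE_NAMES, OUTCOME_COLUMN
from .gend import GenDParams
from .mlp import MLPConfig
from .preprocessing import complement_augment, minmax_scale
from .twist import DEFAULT_INNER_MLP, TwistResult, twist_select
from .validation import ValidationReport, ab_ba_protocol

__all__ = ["FractureRiskModel", "FractureRiskResults",
           "SemanticMap", "SemanticMapResults"]


def _as_cohort(data) -> CohortTable:
    if isinstance(data, CohortTable):
        return data
    return CohortTable.from_frame(data)


class FractureRiskModel:
    """Joint variable selection + twin-subset split + MLP validation.

    Parameters
    ----------
    data : CohortTable or DataFrame with the 13 variables + outcome column.
    gend_params : evolutionary-search budget and rates.
    mlp_config : architecture/budget of the final classifier (the inner
        fitness classifier uses a smaller fixed budget).
    """

    def __init__(self, data, gend_params: GenDParams | None = None,
                 mlp_config: MLPConfig | None = None,
                 inner_mlp: MLPConfig = DEFAULT_INNER_MLP):
        self.data = _as_cohort(data)
        self.gend_params = gend_params or GenDParams()
        self.mlp_config = mlp_config or MLPConfig(hidden_units=4, epochs=400,
                                                  learning_rate=0.5)
        self.inner_mlp = inner_mlp

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "FractureRiskModel":
        return cls(CohortTable.from_frame(frame), **kwargs)

    def fit(self, seed: int | None = None) -> "FractureRiskResults":
        params = self.gend_params
        if seed is not None:
            params = GenDParams(**{**params.__dict__, "seed": seed})
            mlp_cfg = MLPConfig(**{**self.mlp_config.__dict__, "seed": seed})
        else:
            mlp_cfg = self.mlp_config
        twist = twist_select(self.data, params, self.inner_mlp)
        split = np.zeros(self.data.n, dtype=bool)
        split[twist.subset_a_ids] = True
        report = ab_ba_protocol(self.data, twist.selected_features, split, mlp_cfg)
        return FractureRiskResults(model=self, twist=twist, report=report)


@dataclass
class FractureRiskResults:
    model: FractureRiskModel
    twist: TwistResult
    report: ValidationReport

    @property
    def selected_features(self) -> list[str]:
        return self.twist.selected_features

    @property
    def overall_accuracy(self) -> float:
        return self.report.row_mean.overall_accuracy

    @property
    def auc(self) -> float:
        return self.report.row_mean.auc

    def summary(self) -> str:
        r = self.report
        lines = [
            "Fracture-risk model (TWIST selection + MLP, A-B/B-A validation)",
            "=" * 64,
            f"Records: {self.model.data.n}   "
            f"subset A: {len(self.twist.subset_a_ids)} "
            f"({self.twist.class_counts['A']['pos']} fracture / "
            f"{self.twist.class_counts['A']['neg']} no fracture)   "
            f"subset B: {len(self.twist.subset_b_ids)} "
            f"({self.twist.class_counts['B']['pos']} / "
            f"{self.twist.class_counts['B']['neg']})",
            f"Selected variables ({len(self.selected_features)}): "
            + ", ".join(self.selected_features),
            f"Search fitness (balanced accuracy): {self.twist.best_fitness:.3f}",
            "",
            r.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)


class SemanticMap:
    """Auto-CM semantic connectivity map of the high/low variable nodes.

    ``similarity`` selects the matrix source: trained Auto-CM lateral
    weights (default) or the prior-probability concordance index.
    """

    def __init__(self, data, similarity: str = "autocm", C: float | None = None,
                 epochs: int = 50, max_extra: int = 6):
        self.data = _as_cohort(data)
        self.similarity = similarity
        self.C = C
        self.epochs = epochs
        self.max_extra = max_extra

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "SemanticMap":
        return cls(CohortTable.from_frame(frame), **kwargs)

    def fit(self) -> "SemanticMapResults":
        scaled = minmax_scale(self.data)
        augmented = complement_augment(scaled, self.data.y)
        sim, graph = build_map(augmented, similarity=self.similarity, C=self.C,
                               epochs=self.epochs, max_extra=self.max_extra)
        return SemanticMapResults(model=self, similarity=sim, graph=graph)


@dataclass
class SemanticMapResults:
    model: SemanticMap
    similarity: SimilarityMatrix
    graph: ConnectivityGraph

    def outcome_report(self) -> dict:
        return map_report(self.graph)

    def summary(self) -> str:
        rep = self.outcome_report()
        lines = [
            f"Semantic connectivity map ({self.similarity.source} similarity)",
            "=" * 64,
            f"Nodes: {self.graph.graph.number_of_nodes()}   "
            f"tree edges: {len(self.graph.tree_edges)}   "
            f"loop edges: {len(self.graph.extra_edges)}",
        ]
        for outcome, nbrs in rep.items():
            lines.append(f"\nDirect neighbours of '{outcome}':")
            for n in nbrs:
                lines.append(f"  {n['node']:<22s} weight {n['weight']:.4f} ({n['kind']})")
        return "\n".join(lines)
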