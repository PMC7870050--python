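"""Min-max scaling and the high/low complement expansion.

Two downstream consumers, two contracts:

* the classifier path consumes a :class:`ScaledMatrix` — each variable
  rescaled to [0, 1] by its observed (or supplied) range;
* the semantic-map path consumes an :class:`AugmentedMatrix` — every scaled
  variable split into a "high" node (the scaled value) and a "low" node (its
  complement, 1 − value), plus two binary outcome indicator columns
  ("further fracture", "no further fracture").  The 13 variables thus become
  26 map inputs, so connections can be read for both tails of a variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["ScaledMatrix", "AugmentedMatrix", "minmax_scale", "complement_augment",
           "DegenerateColumnError"]

logger = logging.getLogger(__name__)

OUTCOME_HIGH = "further fracture"
OUTCOME_LOW = "no further fracture"


class DegenerateColumnError(ValueError):
    """A column with zero observed range cannot be min-max scaled."""


@dataclass
class ScaledMatrix:
    """[0, 1]-scaled variables with the ranges needed to invert the transform."""

    values: pd.DataFrame
    ranges: dict[str, tuple[float, float]]

    def inverse(self) -> pd.DataFrame:
        """Undo the scaling using the stored per-column ranges."""
        out = {}
        for col in self.values.columns:
            lo, hi = self.ranges[col]
            out[col] = self.values[col] * (hi - lo) + lo
        return pd.DataFrame(out)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AugmentedMatrix:
    """Records × (2k + 2) matrix of high/low node activations plus outcomes."""

    values: pd.DataFrame

    @property
    def node_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def variable_columns(self) -> list[str]:
        return [c for c in self.values.columns if c not in (OUTCOME_HIGH, OUTCOME_LOW)]


def minmax_scale(data: CohortTable | pd.DataFrame,
                 ranges: dict[str, tuple[float, float]] | None = None,
                 clip: bool = False) -> ScaledMatrix:
    """Scale each column to [0, 1] by x' = (x − min) / (max − min).

    Ranges default to the observed per-column min/max of ``data``.  Passing
    ``ranges`` (e.g. a training set's stored ranges) applies a fixed
    transform instead; with ``clip=True`` out-of-range values are clipped to
    [0, 1] and a warning is logged — without it they pass through unclipped.

    Raises
    ------
    DegenerateColumnError
        If any column's range is zero (the transform is undefined there).
    """
    frame = data.X if isinstance(data, CohortTable) else data
    frame = frame.astype(float)
    used_ranges: dict[str, tuple[float, float]] = {}
    out = {}
    for col in frame.columns:
        x = frame[col].to_numpy()
        if ranges is None:
            lo, hi = float(np.min(x)), float(np.max(x))
        else:
            lo, hi = ranges[col]
        if hi <= lo:
            raise DegenerateColumnError(
                f"column {col!r} has zero range [{lo}, {hi}]; cannot scale"
            )
        scaled = (x - lo) / (hi - lo)
        if clip and ((scaled < 0).any() or (scaled > 1).any()):
            n_out = int(((scaled < 0) | (scaled > 1)).sum())
            logger.warning("column %r: clipped %d out-of-range value(s) to [0, 1]",
                           col, n_out)
            scaled = np.clip(scaled, 0.0, 1.0)
        out[col] = scaled
        used_ranges[col] = (lo, hi)
    return ScaledMatrix(values=pd.DataFrame(out, index=frame.index), ranges=used_ranges)


def complement_augment(scaled: ScaledMatrix, outcome: np.ndarray) -> AugmentedMatrix:
    """Expand k scaled variables into 2k high/low columns plus outcome nodes.

    Column order is (high₁, low₁, high₂, low₂, …) followed by the
    "further fracture" indicator (the outcome) and "no further fracture"
    (its complement).  For every record, high + low = 1 exactly.
    """
    outcome = np.asarray(outcome)
    if len(outcome) != len(scaled.values):
        raise ValueError(
            f"outcome length {len(outcome)} != record count {len(scaled.values)}"
        )
    if not set(np.unique(outcome)) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    out = {}
    for col in scaled.values.columns:
        x = scaled.values[col].to_numpy()
        out[f"{col} high"] = x
        out[f"{col} low"] = 1.0 - x
    out[OUTCOME_HIGH] = outcome.astype(float)
    out[OUTCOME_LOW] = 1.0 - outcome.astype(float)
    return AugmentedMatrix(values=pd.DataFrame(out, index=scaled.values.index))
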