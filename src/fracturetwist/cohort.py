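"""Synthetic DXA cohort generation.

The clinical dataset behind the published fracture-prediction analysis was
never deposited, so every downstream stage of this package is exercised on
synthetic cohorts that reproduce its published summary statistics: a cohort
of 172 post-menopausal women with a prevalent vertebral fracture, of whom 93
developed a further vertebral fracture during follow-up and 79 did not.
Each of the 13 densitometric / clinical variables is drawn from a
class-conditional Gaussian with the published per-group mean and SD,
truncated at the published whole-cohort minimum and maximum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableSpec",
    "GeneratorSpec",
    "CohortTable",
    "VARIABLE_NAMES",
    "OUTCOME_COLUMN",
    "default_generator_spec",
    "plausible_correlation",
    "generate_cohort",
    "planted_signal_spec",
    "null_spec",
    "truncated_normal_mean",
    "truncated_normal_sd",
]

#: Canonical variable order; also the required CSV header order.
VARIABLE_NAMES: tuple[str, ...] = (
    "Menopause age",
    "SDI",
    "Age",
    "BMI",
    "LBMC",
    "LBMD",
    "LBSI",
    "Neck BMC",
    "Neck BMD",
    "Neck BSI",
    "FTot BMC",
    "FTot BMD",
    "FTot BSI",
)

OUTCOME_COLUMN = "further_fracture"


class CohortValidationError(ValueError):
    """Raised when a generator spec or cohort table violates its contract."""


@dataclass(frozen=True)
class VariableSpec:
    """Per-variable class-conditional truncated-Gaussian parameters.

    Units follow the source population table: years (ages), kg/m² (BMI),
    g (BMC), g/cm² (BMD); SDI and BSI are dimensionless.
    """

    name: str
    mean_frac: float
    sd_frac: float
    mean_nofrac: float
    sd_nofrac: float
    min: float
    max: float

    def validate(self) -> None:
        if self.sd_frac <= 0 or self.sd_nofrac <= 0:
            raise CohortValidationError(
                f"variable {self.name!r}: standard deviations must be > 0"
            )
        if self.min >= self.max:
            raise CohortValidationError(
                f"variable {self.name!r}: min ({self.min}) must be < max ({self.max})"
            )
        for m in (self.mean_frac, self.mean_nofrac):
            if not (self.min <= m <= self.max):
                raise CohortValidationError(
                    f"variable {self.name!r}: mean {m} outside [{self.min}, {self.max}]"
                )


@dataclass(frozen=True)
class GeneratorSpec:
    """Full class-conditional cohort model: 13 variables plus group sizes.

    ``correlation``, when given, is a 13×13 within-group correlation matrix
    applied through a Gaussian copula; ``None`` means independent draws.
    """

    variables: tuple[VariableSpec, ...]
    n_frac: int = 93
    n_nofrac: int = 79
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.variables) != 13:
            raise CohortValidationError(
                f"expected 13 variables, got {len(self.variables)}"
            )
        for v in self.variables:
            v.validate()
        if self.n_frac < 1 or self.n_nofrac < 1:
            raise CohortValidationError("both outcome groups must be non-empty")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (13, 13):
                raise CohortValidationError("correlation must be 13×13")
            if not np.allclose(c, c.T, atol=1e-10):
                raise CohortValidationError("correlation must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise CohortValidationError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise CohortValidationError("correlation must be positive semi-definite")

    @property
    def n_total(self) -> int:
        return self.n_frac + self.n_nofrac

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass
class CohortTable:
    """Subjects × 13 named variables plus a binary further-fracture outcome."""

    frame: pd.DataFrame
    variable_names: tuple[str, ...] = field(default=VARIABLE_NAMES)

    def __post_init__(self) -> None:
        missing = [c for c in (*self.variable_names, OUTCOME_COLUMN) if c not in self.frame.columns]
        if missing:
            raise CohortValidationError(f"cohort table missing columns: {missing}")
        if self.frame.isna().any().any():
            raise CohortValidationError("cohort table contains missing values")
        outcome = self.frame[OUTCOME_COLUMN]
        if not set(np.unique(outcome)) <= {0, 1}:
            raise CohortValidationError("outcome values must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.variable_names)]

    @property
    def y(self) -> np.ndarray:
        return self.frame[OUTCOME_COLUMN].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variable_names=VARIABLE_NAMES) -> "CohortTable":
        return cls(frame=frame.reset_index(drop=True), variable_names=tuple(variable_names))


# Published per-group parameters: (mean_nofrac, sd_nofrac, mean_frac, sd_frac,
# min, max) per variable, groups being "no further fracture" (n=79) and
# "further fracture" (n=93); the min/max bounds are whole-cohort.
_TABLE_PARAMS: tuple[tuple[str, float, float, float, float, float, float], ...] = (
    ("Menopause age", 48.63, 3.90, 48.30, 5.61, 33.00, 58.00),
    ("SDI", 3.89, 3.73, 3.58, 3.04, 1.00, 20.00),
    ("Age", 68.38, 7.51, 70.35, 8.95, 44.00, 87.00),
    ("BMI", 23.66, 4.43, 24.91, 4.35, 14.67, 42.46),
    ("LBMC", 35.04, 9.86, 36.11, 9.39, 12.55, 60.50),
    ("LBMD", 0.75, 0.11, 0.74, 0.11, 0.40, 1.20),
    ("LBSI", 2.23, 0.56, 2.43, 0.67, 1.11, 4.59),
    ("Neck BMC", 2.88, 0.39, 2.93, 0.43, 1.72, 3.90),
    ("Neck BMD", 0.58, 0.08, 0.58, 0.08, 0.32, 0.81),
    ("Neck BSI", 2.01, 0.42, 1.95, 0.49, 1.13, 3.42),
    ("FTot BMC", 23.14, 3.43, 24.14, 4.51, 13.48, 35.94),
    ("FTot BMD", 0.68, 0.09, 0.70, 0.11, 0.40, 0.98),
    ("FTot BSI", 1.75, 0.31, 1.71, 0.37, 1.04, 2.96),
)


def default_generator_spec(correlation: np.ndarray | None = None) -> GeneratorSpec:
    """Generator spec hard-coded to the published cohort summary statistics.

    Group sizes default to 93 re-fractured / 79 not re-fractured (172 total);
    variables are independent within group unless ``correlation`` is given
    (see :func:`plausible_correlation`).
    """
    variables = tuple(
        VariableSpec(
            name=name,
            mean_nofrac=m0, sd_nofrac=s0,
            mean_frac=m1, sd_frac=s1,
            min=lo, max=hi,
        )
        for name, m0, s0, m1, s1, lo, hi in _TABLE_PARAMS
    )
    return GeneratorSpec(variables=variables, n_frac=93, n_nofrac=79,
                         correlation=correlation)


def plausible_correlation(r: float = 0.6) -> np.ndarray:
    """Block correlation tying BMC/BMD/BSI within each skeletal site.

    Within each site (lumbar, femoral neck, total femur) the mineral content
    and density are positively correlated (+r) and both are negatively
    correlated with the strain index (−r), since a higher strain index means
    mechanically weaker bone.  Sites are mutually independent here, which is
    a deliberate simplification for map-structure testing.
    """
    c = np.eye(13)
    blocks = [(4, 5, 6), (7, 8, 9), (10, 11, 12)]  # (BMC, BMD, BSI) per site
    for bmc, bmd, bsi in blocks:
        c[bmc, bmd] = c[bmd, bmc] = r
        c[bmc, bsi] = c[bsi, bmc] = -r
        c[bmd, bsi] = c[bsi, bmd] = -r
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise CohortValidationError(f"site-block correlation with r={r} is not PSD")
    return c


def _sample_truncated_independent(rng: np.random.Generator, mean: float, sd: float,
                                  lo: float, hi: float, n: int) -> np.ndarray:
    """Rejection-sample a truncated Gaussian; bounds sit ≥2 SD out almost
    everywhere so acceptance is high and the loop terminates quickly."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _sample_group(rng: np.random.Generator, spec: GeneratorSpec, n: int,
                  fractured: bool) -> np.ndarray:
    cols = []
    if spec.correlation is None:
        for v in spec.variables:
            mean = v.mean_frac if fractured else v.mean_nofrac
            sd = v.sd_frac if fractured else v.sd_nofrac
            cols.append(_sample_truncated_independent(rng, mean, sd, v.min, v.max, n))
        return np.column_stack(cols)
    # Gaussian copula: correlated standard normals -> uniforms -> per-variable
    # truncated-normal quantiles, preserving both marginals and rank structure.
    chol = np.linalg.cholesky(spec.correlation + 1e-12 * np.eye(13))
    z = rng.standard_normal((n, 13)) @ chol.T
    u = stats.norm.cdf(z)
    for j, v in enumerate(spec.variables):
        mean = v.mean_frac if fractured else v.mean_nofrac
        sd = v.sd_frac if fractured else v.sd_nofrac
        a, b = (v.min - mean) / sd, (v.max - mean) / sd
        cols.append(stats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd))
    return np.column_stack(cols)


def generate_cohort(spec: GeneratorSpec | None = None, n_total: int = 172,
                    seed: int = 0) -> CohortTable:
    """Draw a seeded synthetic cohort from a class-conditional model.

    Group sizes are exactly stratified: ``round(n_total * n_frac / n)``
    subjects are assigned the further-fracture outcome before any variable is
    drawn, mirroring the class-conditional structure of the published
    per-group table.  Identical ``seed`` gives an identical table.
    """
    if spec is None:
        spec = default_generator_spec()
    if n_total < 2:
        raise CohortValidationError("n_total must be ≥ 2")
    n_frac = int(round(n_total * spec.n_frac / spec.n_total))
    n_frac = min(max(n_frac, 1), n_total - 1)
    n_nofrac = n_total - n_frac

    rng = np.random.default_rng(seed)
    x_frac = _sample_group(rng, spec, n_frac, fractured=True)
    x_nofrac = _sample_group(rng, spec, n_nofrac, fractured=False)

    frame = pd.DataFrame(np.vstack([x_frac, x_nofrac]), columns=list(spec.variable_names))
    frame[OUTCOME_COLUMN] = np.concatenate([np.ones(n_frac, int), np.zeros(n_nofrac, int)])
    # interleave groups deterministically so record order carries no signal
    order = rng.permutation(n_total)
    frame = frame.iloc[order].reset_index(drop=True)
    return CohortTable.from_frame(frame, spec.variable_names)


def planted_signal_spec(shift: float = 1.5, shift_idx: tuple[int, ...] = (2, 12),
                        n_frac: int = 93, n_nofrac: int = 79) -> GeneratorSpec:
    """Benchmark spec: unit-variance variables, a known subset carrying signal.

    All 13 variables are N(10, 1) truncated to [0, 20] in both groups except
    those at ``shift_idx``, whose further-fracture-group mean is shifted by
    ``shift`` standard deviations.  Used for planted-signal recovery studies
    of the feature selection and of the semantic map.
    """
    variables = tuple(
        VariableSpec(
            name=f"V{i}",
            mean_frac=10.0 + (shift if i in shift_idx else 0.0), sd_frac=1.0,
            mean_nofrac=10.0, sd_nofrac=1.0,
            min=0.0, max=20.0,
        )
        for i in range(13)
    )
    return GeneratorSpec(variables=variables, n_frac=n_frac, n_nofrac=n_nofrac)


def null_spec() -> GeneratorSpec:
    """Benchmark spec with no class signal at all (permutation-style null)."""
    return planted_signal_spec(shift=0.0, shift_idx=())


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Exact mean of a Gaussian truncated to [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def truncated_normal_sd(mean: float, sd: float, lo: float, hi: float) -> float:
    """Exact SD of a Gaussian truncated to [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.std(a, b, loc=mean, scale=sd))
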