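"""Generate clustered longitudinal datasets with a known dependency structure.

The generator produces balanced long-format data for *i* clusters
(individuals) observed at *t* equally spaced time points.  Dependency within
a cluster is induced by a cluster-specific random intercept
``RI_i ~ N(0, sigma_g2)``; observation-level noise is
``e_it ~ N(0, sigma_e2)``.  The split of the total variance between the two
components is controlled by the intraclass correlation coefficient,
``ICC = sigma_g2 / (sigma_g2 + sigma_e2)``.

Five response surfaces are supported.  With full time-varying effects
(designs ``primary`` and ``crse_correct``):

    linear       Y = b0 + b1*X + b2*T     + b3*X*T    + RI + e
    exponential  Y = b0 + exp(b1*X + b2*T + b3*X*T)   + RI + e
    parabolic    Y = b0 + b1*X + b2*T**2  + b3*X*T**2 + RI + e

and without the X-by-Time interaction (design ``no_interaction``):

    linear       Y = b0 + b1*X + b2*T      + RI + e
    exponential  Y = b0 + b1*X + exp(b2*T) + RI + e

The predictor X is either a Bernoulli(0.5) "exposure" indicator or a
standard normal score, and is either time-invariant (one draw per cluster,
repeated across time — e.g. a genotype or polygenic score) or time-variant
(one independent draw per observation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Design",
    "Linearity",
    "PredictorDist",
    "TimeVariance",
    "SimulationParams",
    "VarianceComponents",
    "LongitudinalDataset",
    "SimulationOverflowError",
    "partition_variance",
    "generate_predictor",
    "generate_response",
    "simulate",
]

#: Largest exponent argument accepted before a replicate is declared failed.
#: numpy overflows to inf just above exp(709); anything near that bound
#: signals a parameter combination outside the intended simulation regime.
EXP_OVERFLOW_BOUND = 700.0


class Design(str, enum.Enum):
    """Which parameter-grid family a scenario belongs to."""

    PRIMARY = "primary"
    NO_INTERACTION = "no_interaction"
    CRSE_CORRECT = "crse_correct"


class Linearity(str, enum.Enum):
    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    PARABOLIC = "parabolic"


class PredictorDist(str, enum.Enum):
    BINOMIAL_HALF = "binomial_half"  # Bernoulli(0.5) exposure indicator
    STANDARD_NORMAL = "standard_normal"


class TimeVariance(str, enum.Enum):
    INVARIANT = "invariant"  # one draw per cluster, constant over time
    VARIANT = "variant"  # independent draw per observation


@dataclass(frozen=True)
class SimulationParams:
    """Complete description of one simulation scenario.

    Parameters
    ----------
    design
        Grid family: ``primary`` (full time-varying effects),
        ``no_interaction`` (response generated without X*Time) or
        ``crse_correct`` (time-varying effects, cluster-robust SEs later
        applied to the full model).
    beta0
        Intercept of the response surface (default 1).
    beta
        Shared effect size used for every non-intercept coefficient in the
        generating equation (b1 = b2 = b3 = beta).
    icc
        Target intraclass correlation in [0, 1].
    total_variance
        sigma_g2 + sigma_e2 (default 10).
    n_clusters, n_timepoints
        Number of individuals and measurements per individual.
    time_start, time_increment
        Time values are ``time_start + k * time_increment`` for
        k = 0..n_timepoints-1.  The default coding is visit numbers
        1, 2, 3, 4; set ``time_start=0`` for zero-based coding.
    linearity
        Response surface shape.
    predictor_dist, predictor_time_variance
        Distribution of X and whether it changes over time.
    include_interaction
        Whether the generating model contains the b3 * X * Time term.
        Derived from the design for grid scenarios; exposed for custom runs.
    seed
        Seed for this scenario-replicate; any value accepted by
        :func:`numpy.random.default_rng` (int or SeedSequence).
    """

    design: Design = Design.PRIMARY
    beta0: float = 1.0
    beta: float = 0.3
    icc: float = 0.5
    total_variance: float = 10.0
    n_clusters: int = 100
    n_timepoints: int = 4
    time_start: float = 1.0
    time_increment: float = 1.0
    linearity: Linearity = Linearity.LINEAR
    predictor_dist: PredictorDist = PredictorDist.STANDARD_NORMAL
    predictor_time_variance: TimeVariance = TimeVariance.INVARIANT
    include_interaction: bool = True
    seed: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", Design(self.design))
        object.__setattr__(self, "linearity", Linearity(self.linearity))
        object.__setattr__(self, "predictor_dist", PredictorDist(self.predictor_dist))
        object.__setattr__(
            self, "predictor_time_variance", TimeVariance(self.predictor_time_variance)
        )
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError(f"icc must be in [0, 1], got {self.icc}")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.design is Design.NO_INTERACTION:
            if self.include_interaction:
                raise ValueError("no_interaction design generates no X*Time term")
            if self.linearity is Linearity.PARABOLIC:
                raise ValueError("no_interaction design is linear or exponential only")
        if (
            self.design is Design.CRSE_CORRECT
            and self.predictor_dist is not PredictorDist.STANDARD_NORMAL
        ):
            raise ValueError("crse_correct design uses a standard normal predictor")

    @property
    def time_values(self) -> np.ndarray:
        return self.time_start + self.time_increment * np.arange(self.n_timepoints)

    def with_seed(self, seed: object) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class VarianceComponents:
    """Between-cluster and residual variance splitting the total."""

    sigma_g2: float
    sigma_e2: float

    @property
    def total(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    @property
    def icc(self) -> float:
        return self.sigma_g2 / self.total if self.total > 0 else 0.0


@dataclass
class LongitudinalDataset:
    """Balanced long-format dataset plus the latent truths used to build it.

    ``data`` has columns ``cluster_id`` (0..i-1), ``time``, ``x``, ``y``,
    sorted by cluster then time.  ``true_random_intercepts`` maps each
    cluster id to the RI_i draw so tests can verify the variance partition.
    """

    data: pd.DataFrame
    true_random_intercepts: Mapping[int, float]
    params: SimulationParams
    residuals: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @staticmethod
    def read_long_table(
        path,
        cluster_col: str = "cluster_id",
        time_col: str = "time",
        x_col: str = "x",
        y_col: str = "y",
        sep: str = ",",
    ) -> pd.DataFrame:
        """Read a user-supplied long-format delimited table into the
        canonical column layout accepted by the fitters."""
        df = pd.read_csv(path, sep=sep)
        out = df[[cluster_col, time_col, x_col, y_col]].copy()
        out.columns = ["cluster_id", "time", "x", "y"]
        return out


class SimulationOverflowError(FloatingPointError):
    """An exponential response surface left the numerically safe range."""


def partition_variance(icc: float, total_variance: float = 10.0) -> VarianceComponents:
    """Split a total variance into between-cluster and residual parts.

    ``sigma_g2 = icc * total`` and ``sigma_e2 = (1 - icc) * total``, so the
    implied intraclass correlation sigma_g2 / (sigma_g2 + sigma_e2) equals
    ``icc`` exactly.

    >>> partition_variance(0.1, 10)
    VarianceComponents(sigma_g2=1.0, sigma_e2=9.0)
    """
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"icc must be in [0, 1], got {icc}")
    if total_variance <= 0:
        raise ValueError("total_variance must be positive")
    return VarianceComponents(icc * total_variance, (1.0 - icc) * total_variance)


def generate_predictor(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Draw the predictor matrix X, shaped (n_clusters, n_timepoints).

    Time-invariant predictors are drawn once per cluster and broadcast
    across time; time-variant predictors are drawn independently for every
    (cluster, time) cell.  ``binomial_half`` is a single Bernoulli(0.5)
    trial per draw (a 0/1 exposure indicator).
    """
    i, t = params.n_clusters, params.n_timepoints
    shape = (i, 1) if params.predictor_time_variance is TimeVariance.INVARIANT else (i, t)
    if params.predictor_dist is PredictorDist.BINOMIAL_HALF:
        x = rng.binomial(1, 0.5, size=shape).astype(float)
    else:
        x = rng.standard_normal(size=shape)
    return np.broadcast_to(x, (i, t)).copy() if x.shape != (i, t) else x


def _linear_predictor(params: SimulationParams, x: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Fixed-effects part of the response surface (everything except b0,
    RI and e), per the scenario's generating equation."""
    b = params.beta
    if params.include_interaction:
        if params.linearity is Linearity.LINEAR:
            return b * x + b * time + b * x * time
        if params.linearity is Linearity.EXPONENTIAL:
            arg = b * x + b * time + b * x * time
            _check_exp(arg)
            return np.exp(arg)
        # parabolic: Time enters squared in both main effect and interaction
        return b * x + b * time**2 + b * x * time**2
    if params.linearity is Linearity.LINEAR:
        return b * x + b * time
    arg = b * time
    _check_exp(arg)
    return b * x + np.exp(arg)


def _check_exp(arg: np.ndarray) -> None:
    m = float(np.max(arg)) if arg.size else 0.0
    if m > EXP_OVERFLOW_BOUND:
        raise SimulationOverflowError(
            f"exponent {m:.1f} exceeds safe bound {EXP_OVERFLOW_BOUND}"
        )


def generate_response(
    params: SimulationParams,
    x_matrix: np.ndarray,
    time_values: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    *,
    suppress_noise: bool = False,
) -> LongitudinalDataset:
    """Assemble Y from the scenario's generating equation.

    RI_i is drawn once per cluster from N(0, sigma_g2) and e_it per record
    from N(0, sigma_e2); both come from ``rng``.  ``suppress_noise`` forces
    RI = e = 0 and exists for deterministic unit tests only.

    Raises
    ------
    SimulationOverflowError
        If an exponential surface would overflow; the replicate should be
        counted as failed, never emitted with infinities.
    """
    i, t = params.n_clusters, params.n_timepoints
    x_matrix = np.asarray(x_matrix, dtype=float)
    if x_matrix.shape != (i, t):
        raise ValueError(f"x_matrix must be shaped ({i}, {t}), got {x_matrix.shape}")
    if time_values is None:
        time_values = params.time_values
    time_values = np.asarray(time_values, dtype=float)
    if time_values.shape != (t,):
        raise ValueError(f"time_values must have length {t}")

    vc = partition_variance(params.icc, params.total_variance)
    if suppress_noise:
        ri = np.zeros(i)
        e = np.zeros((i, t))
    else:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        ri = rng.normal(0.0, np.sqrt(vc.sigma_g2), size=i)
        e = rng.normal(0.0, np.sqrt(vc.sigma_e2), size=(i, t))

    time_grid = np.broadcast_to(time_values, (i, t))
    y = params.beta0 + _linear_predictor(params, x_matrix, time_grid) + ri[:, None] + e

    df = pd.DataFrame(
        {
            "cluster_id": np.repeat(np.arange(i), t),
            "time": np.tile(time_values, i),
            "x": x_matrix.ravel(),
            "y": y.ravel(),
        }
    )
    return LongitudinalDataset(
        data=df,
        true_random_intercepts={c: float(ri[c]) for c in range(i)},
        params=params,
        residuals=e.ravel(),
    )


def simulate(params: SimulationParams, rng: np.random.Generator | None = None) -> LongitudinalDataset:
    """Draw one complete dataset: predictor, random effects, response."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = generate_predictor(params, rng)
    return generate_response(params, x, params.time_values, rng)
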