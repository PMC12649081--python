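"""Population PK model: log-normal between-subject variability and cohort simulation.

The population distribution places independent log-normal between-subject
variability on each one-compartment parameter: individual i has

    p_i = tv_p * exp(eta_i),   eta_i ~ Normal(0, omega2_p)

with omega2 the VARIANCE of the log-scale random effect (the convention
of NLME software "omega-squared" output).  Residual error, when enabled,
is multiplicative: C_obs = C * (1 + eps), eps ~ Normal(0, stdev0^2),
truncated below at -1 so concentrations stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk_model import DoseEvent, PKParams, predict_concentration

__all__ = ["PopulationModel", "SimCohort", "sample_individuals", "simulate_cohort", "TABLE_POP"]


@dataclass(frozen=True)
class PopulationModel:
    """Typical values plus diagonal log-scale between-subject variances.

    Attributes
    ----------
    tv : PKParams
        Typical (population median) parameter values.
    omega2_ka, omega2_v, omega2_cl : float
        Between-subject variances of ln(ka), ln(v_f), ln(cl_f).
        Correlations are fixed at zero (no off-diagonal omega).
    stdev0 : float
        Proportional residual SD (multiplicative error magnitude).
    """

    tv: PKParams
    omega2_ka: float = 0.0
    omega2_v: float = 0.0
    omega2_cl: float = 0.0
    stdev0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega2_ka", "omega2_v", "omega2_cl", "stdev0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: published population estimates: tvKa 8.34/h, tvV/F 27.9 L/kg,
#: tvCl/F 10.1 mL/min/kg; omega^2 0.5969/0.1233/0.0492; stdev0 0.187
TABLE_POP = PopulationModel(
    tv=PKParams(ka=8.34, cl_f=10.1, v_f=27.9),
    omega2_ka=0.5969,
    omega2_v=0.1233,
    omega2_cl=0.0492,
    stdev0=0.187,
)


@dataclass
class SimCohort:
    """A simulated cohort: concentration matrix over a shared time grid."""

    grid: np.ndarray  # times, h
    conc_matrix: np.ndarray  # n_individuals x n_times, ng/mL
    params_per_individual: list[PKParams] = field(repr=False, default_factory=list)
    seed: int | None = None
    residual_applied: bool = False


def sample_individuals(pop: PopulationModel, n: int, seed: int | None = None) -> list[PKParams]:
    """Draw n individual parameter sets from the population distribution.

    Deterministic under a fixed seed; independent etas per parameter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n, 3))
    ka = pop.tv.ka * np.exp(eta[:, 0] * np.sqrt(pop.omega2_ka))
    v = pop.tv.v_f * np.exp(eta[:, 1] * np.sqrt(pop.omega2_v))
    cl = pop.tv.cl_f * np.exp(eta[:, 2] * np.sqrt(pop.omega2_cl))
    return [PKParams(ka=float(k), cl_f=float(c), v_f=float(w)) for k, c, w in zip(ka, cl, v)]


def simulate_cohort(
    pop: PopulationModel,
    dose: DoseEvent,
    grid: np.ndarray | list[float],
    n: int,
    seed: int | None = None,
    with_residual: bool = False,
) -> SimCohort:
    """Simulate an n-individual concentration matrix on a time grid.

    Row i is the closed-form profile of individual i; with
    ``with_residual`` each value is perturbed multiplicatively by
    (1 + eps), eps ~ Normal(0, stdev0^2) truncated at -1.  Residual
    error is off by default: for detection-time work the regulatory
    quantity is the individual's true concentration, not a re-assayed
    one.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("simulation grid must not be empty")
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n, 3))
    ka = pop.tv.ka * np.exp(eta[:, 0] * np.sqrt(pop.omega2_ka))
    v = pop.tv.v_f * np.exp(eta[:, 1] * np.sqrt(pop.omega2_v))
    cl = pop.tv.cl_f * np.exp(eta[:, 2] * np.sqrt(pop.omega2_cl))
    params = [PKParams(ka=float(k), cl_f=float(c), v_f=float(w)) for k, c, w in zip(ka, cl, v)]
    matrix = np.empty((n, grid.size))
    for i, p in enumerate(params):
        matrix[i] = predict_concentration(p, dose, grid)
    if with_residual and pop.stdev0 > 0:
        eps = np.maximum(rng.normal(0.0, pop.stdev0, size=matrix.shape), -1.0)
        matrix = matrix * (1.0 + eps)
    return SimCohort(
        grid=grid,
        conc_matrix=matrix,
        params_per_individual=params,
        seed=seed,
        residual_applied=with_residual,
    )
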