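"""Virtual species with known environmental drivers.

A species is defined by three randomly chosen driver covariates and
coefficients beta drawn from Normal(mean, 0.5). Its occurrence probability
per cell is

    P = exp(-(beta1*x1 + beta2*x2 + beta3*x3)^2)

a ridge-shaped niche that is maximal (P = 1) where the linear combination
of drivers is zero and decays with distance from that surface. The binary
"true distribution" is a cellwise Bernoulli(P) realization, from which
presence-only samples are drawn at cell centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, Landscape

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesScenario:
    """Strength scenario for the driver coefficients.

    ``weak`` draws coefficients from Normal(1, 0.5) — a broad niche loosely
    tied to the drivers; ``strong`` from Normal(5, 0.5) — a narrow niche
    tightly constrained by them.
    """

    name: str
    coefficient_mean: float
    coefficient_sd: float = 0.5
    n_true_vars: int = 3
    n_presence_points: int = 50

    def __post_init__(self) -> None:
        if self.coefficient_sd < 0:
            raise ValueError("coefficient_sd must be >= 0")
        if self.n_true_vars < 1:
            raise ValueError("n_true_vars must be >= 1")


WEAK = SpeciesScenario("weak", coefficient_mean=1.0)
STRONG = SpeciesScenario("strong", coefficient_mean=5.0)
SCENARIOS = {"weak": WEAK, "strong": STRONG}


@dataclass
class VirtualSpecies:
    """A simulated species with known drivers and realized distribution."""

    true_vars: list[str]
    betas: np.ndarray
    probability: np.ndarray
    realized: np.ndarray
    presences: np.ndarray  # (n, 2) centroid coordinates
    scenario: SpeciesScenario
    seeds: dict = field(default_factory=dict)


def select_true_variables(
    landscape: Landscape, k: int, seed: int | np.random.SeedSequence
) -> list[str]:
    """Draw k distinct covariate names uniformly without replacement."""
    names = landscape.names
    if k > len(names):
        raise ValueError(f"cannot draw {k} variables from {len(names)} covariates")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(names), size=k, replace=False)
    return [names[i] for i in idx]


def draw_coefficients(
    scenario: SpeciesScenario, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Draw the driver coefficients ~ Normal(mean, sd), iid."""
    rng = np.random.default_rng(seed)
    return rng.normal(scenario.coefficient_mean, scenario.coefficient_sd, scenario.n_true_vars)


def occurrence_probability(
    landscape: Landscape, true_vars: list[str], betas: np.ndarray
) -> np.ndarray:
    """Cellwise occurrence probability P = exp(-(sum_i beta_i x_i)^2)."""
    betas = np.asarray(betas, dtype=float)
    if len(true_vars) != len(betas):
        raise ValueError("true_vars and betas must have equal length")
    missing = [v for v in true_vars if v not in landscape]
    if missing:
        raise KeyError(f"covariates not in landscape: {missing}")
    lin = np.zeros(landscape.grid.shape)
    for name, b in zip(true_vars, betas):
        lin += b * landscape[name]
    return np.exp(-(lin**2))


def realize_distribution(
    probability: np.ndarray, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Cellwise independent Bernoulli(P) realization (dtype int8, 0/1)."""
    probability = np.asarray(probability, dtype=float)
    if np.any((probability < 0) | (probability > 1)) or np.any(np.isnan(probability)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(probability.shape) < probability).astype(np.int8)


def sample_presences(
    realized: np.ndarray,
    grid: GridSpec,
    n: int,
    seed: int | np.random.SeedSequence,
    replace: bool = False,
) -> np.ndarray:
    """Sample n presence cells (without replacement by default), returning centroids.

    Raises ValueError naming the shortfall when fewer than n presence cells
    exist and ``replace`` is False.
    """
    rows, cols = np.nonzero(realized)
    n_avail = len(rows)
    if not replace and n_avail < n:
        raise ValueError(
            f"requested {n} presence points but the realization has only "
            f"{n_avail} presence cells (short by {n - n_avail})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_avail, size=n, replace=replace)
    x, y = grid.centroid(rows[idx], cols[idx])
    return np.column_stack([x, y])


def simulate_species(
    landscape: Landscape,
    scenario: SpeciesScenario,
    seed: int | np.random.SeedSequence,
    max_attempts: int = 20,
) -> VirtualSpecies:
    """Simulate one virtual species end to end.

    Draws drivers, coefficients, probability surface, Bernoulli realization
    and presence sample. A realization with fewer presence cells than the
    scenario's ``n_presence_points`` is rejected and re-simulated with the
    next derived seed (logged); per-stage child seeds are recorded in
    ``seeds`` for reproducibility.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for attempt in range(max_attempts):
        var_ss, beta_ss, real_ss, samp_ss = master.spawn(4)
        true_vars = select_true_variables(landscape, scenario.n_true_vars, var_ss)
        betas = draw_coefficients(scenario, beta_ss)
        probability = occurrence_probability(landscape, true_vars, betas)
        realized = realize_distribution(probability, real_ss)
        n_presence_cells = int(realized.sum())
        if n_presence_cells >= scenario.n_presence_points:
            presences = sample_presences(
                realized, landscape.grid, scenario.n_presence_points, samp_ss
            )
            return VirtualSpecies(
                true_vars=true_vars,
                betas=betas,
                probability=probability,
                realized=realized,
                presences=presences,
                scenario=scenario,
                seeds={"master": str(master.entropy), "attempt": attempt},
            )
        log.info(
            "rejecting species realization with %d presence cells (< %d), attempt %d",
            n_presence_cells,
            scenario.n_presence_points,
            attempt,
        )
        master = master.spawn(1)[0]
    raise RuntimeError(
        f"no realization with >= {scenario.n_presence_points} presence cells "
        f"after {max_attempts} attempts"
    )
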