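"""Multimodal memetic optimization: species-based niching with SASS local search.

The optimizer maintains a population of *species*: each one couples a
feasible point (its center), the cached objective value there, and an
attraction radius.  A species is an exploration window — a hypersphere in
the normalized search space.  Search proceeds over ``l`` levels:

1. one full-diameter species is created at a random point and locally
   optimized;
2. at each later level the level radius shrinks geometrically (from the
   search-space diameter down to the user minimum ``r_min`` — "radius
   cooling"), new species are seeded wherever a midpoint between two
   sampled points scores worse than both endpoints (evidence of separate
   basins), overlapping species are fused, the population is trimmed to at
   most ``M`` members by dropping the shortest radii, and every survivor is
   locally optimized.

The local search is SASS (Solis–Wets stochastic hill climbing): Gaussian
perturbations whose standard deviation doubles after five consecutive
successes and halves after three consecutive failures, clamped to
``[1e-5, 1]``; it stops after 32 consecutive failed or discarded moves.

All geometry (distances, radii, steps) lives in the normalized unit box
``[0, 1]^d``; physical parameter vectors are mapped in and out through
:func:`normalize` / :func:`denormalize`.  Without normalization a
wide-ranged parameter (the slope factor spans three decades of mV) would
dominate the Euclidean metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .adex import AdExParameters, ParameterBounds, SimulationConfig, StimulusProtocol
from .features import FeatureConfig, extract_feature_set
from .fitness import PENALTY_SCORE, FeatureWeights, ReferenceFeatures, total_score

__all__ = [
    "UEGOConfig",
    "Species",
    "LevelSchedule",
    "EvaluationLedger",
    "BudgetExhausted",
    "normalize",
    "denormalize",
    "unit_diameter",
    "level_schedule",
    "init_population",
    "create_species",
    "fuse_population",
    "shorten_population",
    "sass_search",
    "SASSResult",
    "run_uego",
    "make_neuron_objective",
]

# SASS constants (recommended Solis-Wets configuration)
SASS_SIGMA_MAX = 1.0
SASS_SIGMA_MIN = 1e-5
SASS_DOUBLE_AFTER = 5
SASS_HALVE_AFTER = 3
SASS_MAX_CONSECUTIVE_FAILURES = 32


class BudgetExhausted(RuntimeError):
    """Internal signal: the global evaluation budget ``N`` is spent."""


@dataclass
class UEGOConfig:
    """Optimizer parameters.

    ``max_species`` (M), ``max_evaluations`` (N), ``min_radius`` (r, in the
    normalized space) and ``levels`` (l) default to the full-scale study
    configuration M=100, N=10,000,000, r=0.7, l=50.
    """

    max_species: int = 100
    max_evaluations: int = 10_000_000
    min_radius: float = 0.7
    levels: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_species < 1:
            raise ValueError("max_species must be >= 1")
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be >= 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not self.min_radius > 0:
            raise ValueError("min_radius must be > 0")


@dataclass
class Species:
    """A candidate solution plus its attraction radius.

    ``center`` lives in the normalized unit box; ``fitness`` is the cached
    objective value at the center; ``radius`` is a Euclidean length in the
    normalized space.
    """

    center: np.ndarray
    fitness: float
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if np.any(self.center < -1e-12) or np.any(self.center > 1 + 1e-12):
            raise ValueError("species center must lie in the unit box")
        if not self.radius > 0:
            raise ValueError("species radius must be > 0")


@dataclass(frozen=True)
class LevelSchedule:
    """Per-level radii and evaluation budgets.

    ``radii`` decreases geometrically from the search-space diameter to
    ``min_radius``.  ``creation`` is 3*M evaluations per level from level 2
    on.  ``optimization`` ramps linearly with the level index, spending more
    effort on later (finer) levels; the ramp is scaled so all budgets
    together stay within the global cap.
    """

    radii: np.ndarray
    creation: np.ndarray
    optimization: np.ndarray

    @property
    def levels(self) -> int:
        return len(self.radii)


@dataclass
class EvaluationLedger:
    """Bookkeeping of objective-function consumption."""

    total: int = 0
    per_level: list = field(default_factory=list)
    best_per_level: list = field(default_factory=list)
    best: float = math.inf


def unit_diameter(dim: int) -> float:
    """Diameter of the normalized search space: ``sqrt(dim)``."""
    return math.sqrt(dim)


def normalize(params: AdExParameters, bounds: ParameterBounds) -> np.ndarray:
    """Map physical parameters into the unit box (affine, per coordinate)."""
    arr = params.to_array()
    if np.any(arr < bounds.lower - 1e-9) or np.any(arr > bounds.upper + 1e-9):
        raise ValueError("parameters outside the bounds box")
    x = (arr - bounds.lower) / (bounds.upper - bounds.lower)
    return np.clip(x, 0.0, 1.0)


def denormalize(point: np.ndarray, bounds: ParameterBounds) -> AdExParameters:
    """Map a unit-box point back to physical parameters."""
    point = np.asarray(point, dtype=float)
    if np.any(point < -1e-9) or np.any(point > 1 + 1e-9):
        raise ValueError("point outside the unit box")
    arr = bounds.lower + np.clip(point, 0.0, 1.0) * (bounds.upper - bounds.lower)
    return AdExParameters.from_array(arr)


def level_schedule(config: UEGOConfig, diameter: float) -> LevelSchedule:
    """Radii and budgets for every level.

    Radii: ``radius_i = diameter * (r_min/diameter)^((i-1)/(l-1))`` — a
    geometric progression with endpoints (diameter, r_min).  Creation gets
    3*M evaluations per level from level 2 on; the remaining budget ``B``
    (after creation and the single initialization evaluation) funds local
    search with ``optimization_i = floor(B * i / sum(1..l))``.
    """
    l = config.levels
    if config.min_radius > diameter:
        raise ValueError(
            f"min_radius {config.min_radius} exceeds the search-space "
            f"diameter {diameter:.4f}"
        )
    if l == 1:
        return LevelSchedule(
            radii=np.array([diameter]),
            creation=np.array([0]),
            optimization=np.array([max(0, config.max_evaluations - 1)]),
        )
    i = np.arange(1, l + 1, dtype=float)
    radii = diameter * (config.min_radius / diameter) ** ((i - 1) / (l - 1))
    creation = np.full(l, 3 * config.max_species, dtype=np.int64)
    creation[0] = 0
    B = max(0, config.max_evaluations - int(creation.sum()) - 1)
    ramp_total = l * (l + 1) // 2
    optimization = np.floor(B * i / ramp_total).astype(np.int64)
    return LevelSchedule(radii=radii, creation=creation, optimization=optimization)


class _CountingObjective:
    """Wraps the raw objective: counts evaluations, enforces the global cap,
    maps exceptions/non-finite values to the penalty score, tracks the best."""

    def __init__(self, fn: Callable, cap: int):
        self.fn = fn
        self.cap = int(cap)
        self.total = 0
        self.best = math.inf

    @property
    def remaining(self) -> int:
        return self.cap - self.total

    def __call__(self, x: np.ndarray) -> float:
        if self.total >= self.cap:
            raise BudgetExhausted
        try:
            value = float(self.fn(x))
        except Exception:
            value = PENALTY_SCORE
        if not math.isfinite(value):
            value = PENALTY_SCORE
        self.total += 1
        if value < self.best:
            self.best = value
        return value


def init_population(
    objective: Callable, dim: int, diameter: float, rng: np.random.Generator
) -> list:
    """One species at a uniform-random point, radius = diameter (1 evaluation).

    The initial species covers the whole search space, so no point is ever
    unreachable; fusion keeps the larger radius and shortening removes the
    shortest radii first, so a full-diameter species survives to the end.
    """
    center = rng.random(dim)
    return [Species(center=center, fitness=objective(center), radius=diameter)]


def _sample_in_ball(
    center: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw from the ball around ``center``, clipped to the unit box."""
    d = center.size
    g = rng.standard_normal(d)
    norm = float(np.linalg.norm(g))
    if norm == 0.0:  # pragma: no cover - probability zero
        g = np.ones(d)
        norm = math.sqrt(d)
    r = radius * rng.random() ** (1.0 / d)
    return np.clip(center + (r / norm) * g, 0.0, 1.0)


def create_species(
    population: list,
    level_radius: float,
    creation_budget: int,
    objective: Callable,
    rng: np.random.Generator,
) -> int:
    """Seed new species inside the regions of the existing ones (in place).

    The creation budget is split evenly across species.  Within each
    species' ball, ``n`` random points are drawn and evaluated — ``n`` the
    largest integer with ``n + C(n, 2) <= allotment`` so that the midpoint
    evaluations of all pairs also fit the budget.  For every pair whose
    midpoint scores strictly worse than both endpoints (the two points
    straddle a barrier, so they sit in different basins), both endpoints
    become new species with the current level radius.  Any evaluated point
    (sample or midpoint) that strictly beats the parent's center replaces
    it.  Species with an allotment below 3 evaluations are starved and
    create nothing.  Returns the number of evaluations used.
    """
    if not population or creation_budget <= 0:
        return 0
    allotment = creation_budget // len(population)
    # n + n(n-1)/2 = n(n+1)/2 evaluations per species
    n = int((math.isqrt(8 * allotment + 1) - 1) // 2)
    evals = 0
    offspring = []
    for sp in list(population):
        if n < 2:
            continue  # starved: not enough budget for a pair plus its midpoint
        points = [_sample_in_ball(sp.center, sp.radius, rng) for _ in range(n)]
        fits = [objective(p) for p in points]
        evals += n
        best_point, best_fit = None, sp.fitness
        promoted: set = set()
        for i in range(n):
            if fits[i] < best_fit:
                best_point, best_fit = points[i], fits[i]
            for j in range(i + 1, n):
                mid = 0.5 * (points[i] + points[j])
                f_mid = objective(mid)
                evals += 1
                if f_mid < best_fit:
                    best_point, best_fit = mid, f_mid
                if f_mid > fits[i] and f_mid > fits[j]:
                    for k in (i, j):
                        if k not in promoted:
                            promoted.add(k)
                            offspring.append(
                                Species(
                                    center=points[k].copy(),
                                    fitness=fits[k],
                                    radius=level_radius,
                                )
                            )
        if best_point is not None:
            sp.center = best_point.copy()
            sp.fitness = best_fit
    population.extend(offspring)
    return evals


def fuse_population(population: list, level_radius: float) -> list:
    """Merge species whose centers are closer than ``level_radius`` (in place).

    The fused species keeps the center (and fitness) of the better member —
    on ties, the earlier-created one — and the larger of the two radii, so
    the explored region never shrinks through fusion.  Repeats until all
    pairwise center distances are >= ``level_radius``.
    """
    merged = True
    while merged:
        merged = False
        for i in range(len(population)):
            for j in range(i + 1, len(population)):
                a, b = population[i], population[j]
                if np.linalg.norm(a.center - b.center) < level_radius:
                    winner = b if b.fitness < a.fitness else a
                    population[i] = Species(
                        center=winner.center.copy(),
                        fitness=winner.fitness,
                        radius=max(a.radius, b.radius),
                    )
                    del population[j]
                    merged = True
                    break
            if merged:
                break
    return population


def shorten_population(population: list, max_species: int) -> list:
    """Trim to ``max_species`` members by dropping the shortest radii (in place).

    Ties on radius are broken by removing the worse fitness first.  Keeping
    the long radii preserves the ability to escape low-performing regions —
    in particular the full-diameter species always survives.
    """
    excess = len(population) - max_species
    if excess <= 0:
        return population
    order = sorted(
        range(len(population)),
        key=lambda k: (population[k].radius, -population[k].fitness),
    )
    drop = set(order[:excess])
    population[:] = [sp for k, sp in enumerate(population) if k not in drop]
    return population


@dataclass
class SASSResult:
    """Outcome of one SASS run: the (moved) species, evaluations used, and
    the final step standard deviation."""

    species: Species
    evaluations: int
    sigma: float


def sass_search(
    species: Species,
    step_bound: float,
    budget: int,
    objective: Callable,
    rng: np.random.Generator,
    sigma_init: float = SASS_SIGMA_MAX,
) -> SASSResult:
    """Solis–Wets stochastic hill climbing within the species region.

    Each move proposes ``center + step_bound * sigma * g`` with ``g`` a
    standard Gaussian vector; the displacement norm is capped at
    ``step_bound`` and the candidate is clipped to the unit box.  Strict
    improvements move the center (success); otherwise the move fails.
    ``sigma`` starts at ``sigma_init`` (default: the upper clamp 1),
    doubles after 5 consecutive successes, halves after 3 consecutive
    failures, and stays within [1e-5, 1].  Proposals whose clipped
    displacement is zero are *discarded*: they count toward termination but
    consume no evaluation.  The search stops when the budget is spent or
    after 32 consecutive failed or discarded moves.
    """
    sigma = min(max(float(sigma_init), SASS_SIGMA_MIN), SASS_SIGMA_MAX)
    evals = 0
    consecutive_bad = 0
    success_streak = 0
    failure_streak = 0
    d = species.center.size
    while evals < budget and consecutive_bad < SASS_MAX_CONSECUTIVE_FAILURES:
        step = step_bound * sigma * rng.standard_normal(d)
        norm = float(np.linalg.norm(step))
        if norm > step_bound:
            step *= step_bound / norm
        candidate = np.clip(species.center + step, 0.0, 1.0)
        if not np.any(candidate != species.center):
            consecutive_bad += 1  # discarded: fully clipped away, no evaluation
            continue
        value = objective(candidate)
        evals += 1
        if value < species.fitness:
            species.center = candidate
            species.fitness = value
            consecutive_bad = 0
            failure_streak = 0
            success_streak += 1
            if success_streak >= SASS_DOUBLE_AFTER:
                sigma = min(sigma * 2.0, SASS_SIGMA_MAX)
                success_streak = 0
        else:
            consecutive_bad += 1
            success_streak = 0
            failure_streak += 1
            if failure_streak >= SASS_HALVE_AFTER:
                sigma = max(sigma / 2.0, SASS_SIGMA_MIN)
                failure_streak = 0
    return SASSResult(species=species, evaluations=evals, sigma=sigma)


def run_uego(
    objective: Callable,
    dim: int,
    config: UEGOConfig,
    observer: Optional[Callable] = None,
) -> tuple:
    """Execute the full multi-level optimization.

    ``objective`` maps a unit-box point to a float (lower is better);
    raised exceptions and non-finite values are treated as the penalty
    score.  ``observer(event, level, population)`` — if given — is called
    after every phase (``"init"``, ``"optimize"``, ``"create"``, ``"fuse"``,
    ``"shorten"``, ``"fuse2"``), which is how the invariant test suite
    watches the run.  Returns ``(population, ledger)``; the run is fully
    reproducible from ``config.seed`` and never exceeds
    ``config.max_evaluations`` objective calls.
    """
    rng = np.random.default_rng(config.seed)
    diameter = unit_diameter(dim)
    schedule = level_schedule(config, diameter)
    counting = _CountingObjective(objective, config.max_evaluations)
    ledger = EvaluationLedger()

    def notify(event: str, level: int, population: list) -> None:
        if observer is not None:
            observer(event, level, population)

    def close_level(used_before: int) -> None:
        ledger.per_level.append(counting.total - used_before)
        ledger.best_per_level.append(counting.best)
        ledger.total = counting.total
        ledger.best = counting.best

    population: list = []
    try:
        used_before = counting.total
        population = init_population(counting, dim, diameter, rng)
        notify("init", 1, population)
        budget = min(int(schedule.optimization[0]), counting.remaining)
        sass_search(population[0], population[0].radius, budget, counting, rng)
        notify("optimize", 1, population)
        close_level(used_before)

        for level in range(2, schedule.levels + 1):
            used_before = counting.total
            level_radius = float(schedule.radii[level - 1])
            budget = min(int(schedule.creation[level - 1]), counting.remaining)
            create_species(population, level_radius, budget, counting, rng)
            notify("create", level, population)
            fuse_population(population, level_radius)
            notify("fuse", level, population)
            shorten_population(population, config.max_species)
            notify("shorten", level, population)
            budget = min(int(schedule.optimization[level - 1]), counting.remaining)
            per_species = budget // len(population)
            for sp in population:
                sass_search(sp, sp.radius, per_species, counting, rng)
            notify("optimize", level, population)
            fuse_population(population, level_radius)
            notify("fuse2", level, population)
            close_level(used_before)
    except BudgetExhausted:  # pragma: no cover - budgets are pre-clipped
        ledger.total = counting.total
        ledger.best = counting.best
    return population, ledger


def make_neuron_objective(
    bounds: ParameterBounds,
    protocols: Sequence[StimulusProtocol],
    reference: ReferenceFeatures,
    weights: FeatureWeights = FeatureWeights(),
    sim_config: SimulationConfig = SimulationConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> Callable:
    """Compose denormalization, simulation, feature extraction and scoring
    into a unit-box objective for :func:`run_uego`."""

    def objective(point: np.ndarray) -> float:
        params = denormalize(point, bounds)
        feature_set = extract_feature_set(params, protocols, sim_config, feature_config)
        return total_score(feature_set, reference, weights).total

    return objective
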