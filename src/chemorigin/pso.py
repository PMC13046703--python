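"""Particle swarm optimization of model hyperparameters.

A swarm of candidate parameter vectors flies through a box-bounded search
space; each particle's velocity combines inertia (weight decayed linearly
from 0.9 to 0.4 over the run), attraction to its personal best (cognitive
acceleration 1.5) and attraction to the swarm's global best (social
acceleration 1.5), with fresh uniform random factors r1, r2 ∈ [0, 1] per
dimension per step.  Fitness is the mean stratified 5-fold cross-validation
accuracy of the model built from the particle's parameters; fitness is
maximized.

Special handling:

* integer dimensions are rounded after every move;
* the hybrid-kernel mixture weights (m, n, q) form a simplex group — after
  every move they are divided by their sum so that m + n + q = 1 exactly
  (re-seeded uniformly if the sum collapses below 1e-6);
* velocities are clamped to half the box width per dimension;
* positions are clamped to the box after every move.

Named search-space presets cover the seven tuned model variants
(svm-linear … svm-hybrid, bpnn, rf) with the published tuning ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .classifiers import ForestOriginClassifier, KernelSVC, MLPOriginClassifier
from .kernels import KernelSpec
from .metrics import stratified_kfold
from .synthesis import ChemTable

__all__ = [
    "PSOConfig",
    "Dim",
    "SearchSpace",
    "SwarmState",
    "PSOResult",
    "SEARCH_SPACES",
    "inertia_at",
    "initialize",
    "step",
    "optimize",
    "cv_fitness",
    "build_model",
]

_SIMPLEX_COLLAPSE = 1e-6


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    max_iters: int = 50
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    accel_cognitive: float = 1.5
    accel_social: float = 1.5
    fitness_tolerance: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 1 or self.max_iters < 1:
            raise ValueError("swarm_size and max_iters must be positive")
        if self.inertia_start < self.inertia_end:
            raise ValueError("inertia must not increase over iterations")
        if self.accel_cognitive <= 0 or self.accel_social <= 0:
            raise ValueError("accelerations must be positive")


@dataclass(frozen=True)
class Dim:
    name: str
    lower: float
    upper: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"dimension {self.name!r}: lower must be < upper")


@dataclass(frozen=True)
class SearchSpace:
    dims: tuple[Dim, ...]
    simplex_group: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        if self.simplex_group is not None:
            for name in self.simplex_group:
                d = self.dim(name)
                if d.lower < 0.0 or d.upper > 1.0:
                    raise ValueError("simplex dimensions must have bounds within [0, 1]")

    def dim(self, name: str) -> Dim:
        for d in self.dims:
            if d.name == name:
                return d
        raise KeyError(f"no dimension named {name!r}")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dims], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dims], dtype=float)

    @property
    def simplex_idx(self) -> list[int]:
        if self.simplex_group is None:
            return []
        return [self.names.index(n) for n in self.simplex_group]

    def to_params(self, x: np.ndarray) -> dict[str, float]:
        return {d.name: (int(round(v)) if d.integer else float(v))
                for d, v in zip(self.dims, x)}


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    rng: np.random.Generator | None = field(default=None, repr=False)


def inertia_at(t: int, config: PSOConfig) -> float:
    """Linearly decayed inertia weight w(t) over t = 0 … max_iters − 1."""
    if not 0 <= t < config.max_iters:
        raise ValueError(f"iteration {t} outside [0, {config.max_iters})")
    if config.max_iters == 1:
        return config.inertia_start
    frac = t / (config.max_iters - 1)
    return config.inertia_start - (config.inertia_start - config.inertia_end) * frac


def _project(X: np.ndarray, space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    if X.shape[1] == 0:
        return X
    X = np.clip(X, space.lower, space.upper)
    sidx = space.simplex_idx
    if sidx:
        block = X[:, sidx]
        sums = block.sum(axis=1)
        collapsed = sums < _SIMPLEX_COLLAPSE
        if collapsed.any():
            block[collapsed] = rng.uniform(size=(int(collapsed.sum()), len(sidx)))
            sums = block.sum(axis=1)
        X[:, sidx] = block / sums[:, None]
    for j, d in enumerate(space.dims):
        if d.integer:
            X[:, j] = np.round(X[:, j])
    return X


def _evaluate(fitness_fn, X: np.ndarray, space: SearchSpace) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        params = space.to_params(x)
        try:
            out[i] = fitness_fn(params)
        except Exception as exc:
            raise RuntimeError(f"fitness evaluation failed for particle {i} "
                               f"at {params}") from exc
    return out


def initialize(fitness_fn, space: SearchSpace, config: PSOConfig,
               rng: np.random.Generator) -> SwarmState:
    S, D = config.swarm_size, len(space.dims)
    if D:
        width = space.upper - space.lower
        X = space.lower + rng.uniform(size=(S, D)) * width
        V = rng.uniform(-0.5, 0.5, size=(S, D)) * width
    else:
        X = np.zeros((S, 0))
        V = np.zeros((S, 0))
    X = _project(X, space, rng)
    fit = _evaluate(fitness_fn, X, space)
    g = int(np.argmax(fit))
    return SwarmState(X, V, X.copy(), fit.copy(), X[g].copy(), float(fit[g]),
                      rng=rng)


def step(state: SwarmState, fitness_fn, config: PSOConfig,
         space: SearchSpace) -> SwarmState:
    """One synchronous swarm update; gbest fitness never decreases."""
    rng = state.rng if state.rng is not None else np.random.default_rng(config.seed)
    w = inertia_at(min(state.iteration, config.max_iters - 1), config)
    S, D = state.positions.shape
    if D:
        r1 = rng.uniform(size=(S, D))
        r2 = rng.uniform(size=(S, D))
        V = (w * state.velocities
             + config.accel_cognitive * r1 * (state.pbest_positions - state.positions)
             + config.accel_social * r2 * (state.gbest_position - state.positions))
        vmax = 0.5 * (space.upper - space.lower)
        V = np.clip(V, -vmax, vmax)
        X = _project(state.positions + V, space, rng)
    else:
        V = state.velocities
        X = state.positions
    fit = _evaluate(fitness_fn, X, space)

    improved = fit > state.pbest_fitness
    pbest_pos = state.pbest_positions.copy()
    pbest_fit = state.pbest_fitness.copy()
    pbest_pos[improved] = X[improved]
    pbest_fit[improved] = fit[improved]
    g = int(np.argmax(pbest_fit))
    if pbest_fit[g] > state.gbest_fitness:
        gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])
    else:
        gbest_pos, gbest_fit = state.gbest_position, state.gbest_fitness

    return SwarmState(X, V, pbest_pos, pbest_fit, gbest_pos, gbest_fit,
                      state.iteration + 1, rng=rng)


@dataclass(frozen=True)
class PSOResult:
    best_params: dict[str, float]
    best_fitness: float
    trace: tuple[tuple[int, float, dict[str, float]], ...] = field(repr=False)


def optimize(fitness_fn, space: SearchSpace, config: PSOConfig) -> PSOResult:
    """Run the swarm to ``max_iters`` (or until ``fitness_tolerance`` is hit).

    Returns the global best parameters, their fitness and the per-iteration
    gbest trace (iteration 0 is the initial swarm).  Reproducible under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize(fitness_fn, space, config, rng)
    trace = [(0, state.gbest_fitness, space.to_params(state.gbest_position))]
    tol = config.fitness_tolerance
    for t in range(config.max_iters):
        if tol is not None and state.gbest_fitness >= tol:
            break
        state = step(state, fitness_fn, config, space)
        trace.append((state.iteration, state.gbest_fitness,
                      space.to_params(state.gbest_position)))
    return PSOResult(space.to_params(state.gbest_position),
                     state.gbest_fitness, tuple(trace))


# -- model presets ------------------------------------------------------------

SEARCH_SPACES: dict[str, SearchSpace] = {
    "svm-linear": SearchSpace(()),
    "svm-poly": SearchSpace((
        Dim("c1", 1 / 80, 1 / 40), Dim("c2", 0.1, 3.0), Dim("c3", 2.0, 4.0))),
    "svm-gaussian": SearchSpace((Dim("sigma2", 10.0, 50.0),)),
    "svm-sigmoid": SearchSpace((Dim("a", 1 / 100, 1.0), Dim("c", -5.0, 5.0))),
    "svm-hybrid": SearchSpace(
        (Dim("c1", 1 / 80, 1 / 40), Dim("c2", 0.1, 3.0), Dim("c3", 2.0, 4.0),
         Dim("sigma2", 10.0, 50.0),
         Dim("m", 0.0, 1.0), Dim("n", 0.0, 1.0), Dim("q", 0.0, 1.0)),
        simplex_group=("m", "n", "q")),
    "bpnn": SearchSpace((
        Dim("hidden_layers", 1, 5, integer=True),
        Dim("neurons_per_layer", 2, 40, integer=True),
        Dim("learning_rate", 0.001, 0.1))),
    "rf": SearchSpace((
        Dim("n_trees", 50, 200, integer=True),
        Dim("min_samples_leaf", 2, 10, integer=True))),
}

_SVM_FAMILY = {"svm-linear": "linear", "svm-poly": "polynomial",
               "svm-gaussian": "gaussian", "svm-sigmoid": "sigmoid",
               "svm-hybrid": "hybrid"}


def build_model(preset: str, params: Mapping[str, float], *, C: float = 1.0,
                seed: int = 0):
    """Instantiate the estimator a preset's parameter vector describes."""
    if preset in _SVM_FAMILY:
        spec = KernelSpec(family=_SVM_FAMILY[preset],
                          **{k: v for k, v in params.items()
                             if k in ("c1", "c2", "c3", "sigma2", "a", "c", "m", "n", "q")})
        return KernelSVC(kernel_spec=spec, C=C)
    if preset == "bpnn":
        return MLPOriginClassifier(hidden_layers=int(params["hidden_layers"]),
                                   neurons_per_layer=int(params["neurons_per_layer"]),
                                   learning_rate=float(params["learning_rate"]),
                                   seed=seed)
    if preset == "rf":
        return ForestOriginClassifier(n_trees=int(params["n_trees"]),
                                      min_samples_leaf=int(params["min_samples_leaf"]),
                                      seed=seed)
    raise ValueError(f"unknown model preset {preset!r}")


def cv_fitness(preset: str, table: ChemTable, *, k: int = 5, seed: int = 0,
               group_by: str = "region", C: float = 1.0,
               model_seed: int = 0) -> Callable[[Mapping[str, float]], float]:
    """Mean stratified k-fold CV accuracy as a function of a parameter mapping.

    Folds are drawn once (from ``seed``) and reused for every candidate, so
    fitness values are comparable across the whole run.
    """
    y = table.labels(group_by).astype(str)
    folds = stratified_kfold(table, k=k, seed=seed, group_by=group_by)

    def fitness(params: Mapping[str, float]) -> float:
        accs = []
        for test_idx in folds:
            mask = np.ones(table.n_samples, dtype=bool)
            mask[test_idx] = False
            model = build_model(preset, params, C=C, seed=model_seed)
            model.fit(table.values[mask], y[mask])
            pred = model.predict(table.values[test_idx])
            accs.append(float(np.mean(pred == y[test_idx])))
        return float(np.mean(accs))

    return fitness
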