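"""Binary Black Hole Optimization (BHO) over feature masks.

A population of "stars" — binary masks over the feature columns — is scored
by the hold-out accuracy of a classifier trained on the masked features
(wrapper feature selection). The best star is the "black hole"; ties are
broken toward fewer selected features, then lower star index. Every other
star is pulled toward the black hole: each coordinate takes a 0.7-step from
its current bit toward the black hole's bit, and the moved position x is
re-binarized through the transfer rule

    bit = 1  if |tanh(x)| > u,  u ~ Uniform[0, 1) drawn per bit,
    bit = 0  otherwise.

Stars whose mask duplicates the black hole (and, optionally, stars inside a
Hamming event horizon) are absorbed and replaced by fresh random stars. An
alternative update mode inherits each bit from the black hole independently
with probability 1/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .errors import ValidationError
from .kerf import KerfParams, fit_kerf_matrix
from .preprocessing import FeatureTable

__all__ = [
    "Star",
    "Population",
    "FitnessSpec",
    "BhoConfig",
    "BhoResult",
    "populate_stars",
    "evaluate_fitness",
    "select_black_hole",
    "update_positions",
    "inheritance_update",
    "handle_duplicates_and_horizon",
    "run_bho",
]

STEP = 0.7  # attraction step toward the black hole, fixed by the update rule


@dataclass
class Star:
    """One candidate feature subset: binary mask plus transient position."""

    mask: np.ndarray
    position: np.ndarray
    fitness: Optional[float] = None
    born: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.int8)
        self.position = np.asarray(self.position, dtype=float)
        if self.mask.shape != self.position.shape:
            raise ValidationError("mask and position must have equal length")
        if self.mask.size and not np.isin(self.mask, (0, 1)).all():
            raise ValidationError("mask entries must be binary")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


Population = list


@dataclass
class FitnessSpec:
    """Inner wrapper classifier used to score a mask.

    ``classifier`` is ``"random_forest"`` (default, 50 trees) or ``"kerf"``
    (this package's kernel forest thresholded at 0.5). The data is split
    stratified 80/20 with ``seed``; fitness is hold-out accuracy, so it is
    deterministic given (mask, data, seed).
    """

    classifier: str = "random_forest"
    n_estimators: int = 50
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("random_forest", "kerf"):
            raise ValidationError("classifier must be 'random_forest' or 'kerf'")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError("test_fraction must be in (0, 1)")


@dataclass
class BhoConfig:
    num_stars: int = 30
    max_iter: int = 100
    step: float = STEP
    seed: int = 0
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    duplicate_policy: str = "replace"
    event_horizon: bool = False
    mode: str = "tanh"

    def __post_init__(self) -> None:
        if self.num_stars < 1:
            raise ValidationError("num_stars must be >= 1")
        if self.max_iter < 0:
            raise ValidationError("max_iter must be >= 0")
        if not (0.0 < self.step <= 1.0):
            raise ValidationError("step must be in (0, 1]")
        if self.duplicate_policy not in ("replace", "keep"):
            raise ValidationError("duplicate_policy must be 'replace' or 'keep'")
        if self.mode not in ("tanh", "inheritance"):
            raise ValidationError("mode must be 'tanh' or 'inheritance'")


@dataclass
class BhoResult:
    """Outcome of one optimization run."""

    best_mask: np.ndarray
    best_fitness: float
    trajectory: list[float]
    n_evaluations: int
    seed: int

    def to_json(self, config: Optional[BhoConfig] = None) -> str:
        payload = {
            "best_mask": np.asarray(self.best_mask, dtype=int).tolist(),
            "best_fitness": self.best_fitness,
            "trajectory": list(self.trajectory),
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }
        if config is not None:
            cfg = asdict(config)
            payload["config"] = cfg
        return json.dumps(payload)


def _random_nonzero_mask(n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(0.5) mask, redrawn until at least one bit is set."""
    while True:
        mask = rng.integers(0, 2, size=n_features).astype(np.int8)
        if mask.any():
            return mask


def populate_stars(
    num_stars: int, n_features: int, rng: np.random.Generator
) -> Population:
    """Initialize stars with i.i.d. Bernoulli(0.5) bits; all-zero masks redrawn."""
    if num_stars < 1:
        raise ValidationError("num_stars must be >= 1")
    if n_features < 1:
        raise ValidationError("n_features must be >= 1")
    stars = []
    for _ in range(num_stars):
        mask = _random_nonzero_mask(n_features, rng)
        stars.append(Star(mask.copy(), mask.astype(float)))
    return stars


def evaluate_fitness(
    star: Star,
    data: FeatureTable,
    fitness_spec: Optional[FitnessSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Hold-out accuracy of the inner classifier on the masked feature subset.

    An empty mask scores 0 by convention. Deterministic given
    (mask, data, fitness_spec.seed); the result is cached on the star.
    """
    spec = fitness_spec or FitnessSpec()
    if star.mask.sum() == 0:
        star.fitness = 0.0
        return 0.0
    if data.target is None:
        raise ValidationError("fitness evaluation requires a table with a target")
    y = data.target
    if data.n_samples < 10:
        raise ValidationError("fitness evaluation requires >= 10 samples")
    if len(np.unique(y)) < 2:
        raise ValidationError("fitness evaluation requires both classes present")
    X = data.values[:, star.mask.astype(bool)]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=spec.test_fraction, stratify=y, random_state=spec.seed
    )
    if spec.classifier == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=spec.n_estimators, random_state=spec.seed, n_jobs=1
        )
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
    else:
        forest = fit_kerf_matrix(
            X_tr, y_tr, KerfParams(n_trees=spec.n_estimators, seed=spec.seed)
        )
        pred = (forest.predict(X_te) >= 0.5).astype(int)
    fitness = float((pred == y_te).mean())
    star.fitness = fitness
    return fitness


def select_black_hole(population: Population) -> int:
    """Index of the best star: max fitness, then fewer features, then index."""
    for i, star in enumerate(population):
        if star.fitness is None:
            raise ValidationError(f"star {i} has no evaluated fitness")
    return min(
        range(len(population)),
        key=lambda i: (-population[i].fitness, population[i].n_selected, i),
    )


def update_positions(
    population: Population,
    black_hole: Star,
    rng: np.random.Generator,
    step: float = STEP,
) -> Population:
    """Pull every other star toward the black hole and re-binarize.

    position <- mask + step * (black_hole.mask - mask), then each bit is set
    to 1 when |tanh(position)| exceeds a fresh uniform draw. Positions are
    re-binarized to the new mask; the black hole itself is unchanged.
    """
    for star in population:
        if star is black_hole:
            continue
        position = star.position + step * (black_hole.mask - star.mask)
        w = np.abs(np.tanh(position))
        new_mask = (w > rng.random(star.mask.size)).astype(np.int8)
        star.mask = new_mask
        star.position = new_mask.astype(float)
        star.fitness = None
    return population


def inheritance_update(
    population: Population, black_hole: Star, rng: np.random.Generator
) -> Population:
    """Alternative update: inherit each bit from the black hole w.p. 1/2."""
    for star in population:
        if star is black_hole:
            continue
        inherit = rng.random(star.mask.size) < 0.5
        star.mask = np.where(inherit, black_hole.mask, star.mask).astype(np.int8)
        star.position = star.mask.astype(float)
        star.fitness = None
    return population


def handle_duplicates_and_horizon(
    population: Population,
    black_hole: Star,
    rng: np.random.Generator,
    event_horizon: bool = False,
    iteration: int = 0,
) -> Population:
    """Absorb stars that duplicate (or crowd) the black hole.

    Any non-black-hole star whose mask equals the black hole's is replaced by
    a fresh random star. With ``event_horizon`` on, stars within Hamming
    radius R = ceil(f_bh * d / sum_fitness) of the black hole are likewise
    replaced. Replacements are unevaluated.
    """
    d = black_hole.mask.size
    radius = 0
    if event_horizon:
        fitnesses = [s.fitness for s in population if s.fitness is not None]
        total = sum(fitnesses)
        if black_hole.fitness is not None and total > 0:
            radius = math.ceil(black_hole.fitness * d / total)
    for star in population:
        if star is black_hole:
            continue
        hamming = int(np.sum(star.mask != black_hole.mask))
        if hamming == 0 or (event_horizon and hamming < radius):
            mask = _random_nonzero_mask(d, rng)
            for _ in range(1000):  # replacement must not duplicate again
                if not np.array_equal(mask, black_hole.mask):
                    break
                mask = _random_nonzero_mask(d, rng)
            star.mask = mask
            star.position = mask.astype(float)
            star.fitness = None
            star.born = iteration
    return population


def run_bho(data: FeatureTable, config: BhoConfig) -> BhoResult:
    """Full optimization loop; returns the best mask ever evaluated.

    Fitness values are cached by mask bits, so re-evaluating an unchanged
    mask costs nothing and the best-so-far trajectory is non-decreasing by
    elitism (the black hole is never moved or absorbed).
    """
    if data.target is None or len(np.unique(data.target)) < 2:
        raise ValidationError("run_bho requires a table with both classes")
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}
    n_evaluations = 0

    def evaluate(star: Star) -> None:
        nonlocal n_evaluations
        if star.fitness is not None:
            return
        key = star.mask.tobytes()
        if key in cache:
            star.fitness = cache[key]
            return
        evaluate_fitness(star, data, config.fitness)
        cache[key] = star.fitness
        n_evaluations += 1

    population = populate_stars(config.num_stars, data.n_features, rng)
    for star in population:
        evaluate(star)
    bh_idx = select_black_hole(population)
    best_mask = population[bh_idx].mask.copy()
    best_fitness = population[bh_idx].fitness
    trajectory = [best_fitness]

    for iteration in range(1, config.max_iter + 1):
        black_hole = population[bh_idx]
        if config.duplicate_policy == "replace" or config.event_horizon:
            handle_duplicates_and_horizon(
                population, black_hole, rng, config.event_horizon, iteration
            )
        if config.mode == "tanh":
            update_positions(population, black_hole, rng, config.step)
        else:
            inheritance_update(population, black_hole, rng)
        for star in population:
            evaluate(star)
        bh_idx = select_black_hole(population)
        incumbent = population[bh_idx]
        if incumbent.fitness > best_fitness or (
            incumbent.fitness == best_fitness
            and incumbent.n_selected < int(best_mask.sum())
        ):
            best_mask = incumbent.mask.copy()
            best_fitness = incumbent.fitness
        trajectory.append(best_fitness)

    return BhoResult(best_mask, best_fitness, trajectory, n_evaluations, config.seed)
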