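"""Binary differential-evolution wrapper feature selection.

A candidate solution is a binary mask x ∈ {0,1}^d over feature columns.  The
optimizer iterates the classic rand/1/bin scheme — mutation by a scaled
donor difference, binomial crossover with a forced ``jrand`` coordinate,
greedy one-to-one selection — with candidates binarized by a strict 0.5
threshold.  Fitness is wrapper-style: the holdout misclassification of an
inner classifier restricted to the selected columns, plus a sparsity penalty
proportional to the selected fraction:

    fitness(x) = error(X[:, x], y) + alpha * k / d,      k = |x|

with Pop = 10, Gmax = 200, F = 0.5, Cr = 0.7, alpha = 0.005 as defaults.
An alternative convex blend ``alpha*error + (1-alpha)*k/d`` is available via
``DEConfig.fitness_form = "convex"``.

Also provided: an exhaustive-search oracle for small d (test/benchmark use),
per-feature selection-frequency analytics, and the dimensionality-reduction
percentage helper.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestCentroid

from .errors import InvalidConfigError, InvalidDatasetError
from .io import FeatureMatrix

__all__ = [
    "BinaryMask",
    "DEConfig",
    "DEState",
    "FitnessEvaluatorSpec",
    "FitnessFunction",
    "init_population",
    "fitness",
    "mutate",
    "crossover",
    "select",
    "run_de",
    "exhaustive_oracle",
    "selection_frequency",
    "reduction_percentage",
]


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryMask:
    """Length-d 0/1 vector encoding a feature subset."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise InvalidConfigError("mask entries must be 0 or 1")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BinaryMask":
        return cls(tuple(int(b) for b in np.asarray(arr).ravel()))

    @classmethod
    def from_indices(cls, d: int, indices: Iterable[int]) -> "BinaryMask":
        bits = np.zeros(d, dtype=np.uint8)
        idx = list(indices)
        if idx:
            bits[np.asarray(idx)] = 1
        return cls.from_array(bits)

    @property
    def d(self) -> int:
        return len(self.bits)

    @property
    def k(self) -> int:
        return int(sum(self.bits))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.uint8)

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.as_array())

    def to_dict(self) -> dict:
        return {"bits": list(self.bits), "k": self.k, "d": self.d}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FitnessEvaluatorSpec:
    """How the wrapper error inside the DE fitness is measured.

    inner_classifier : "logistic" (default; multinomial logistic regression,
        a fast linear classifier that handles multiclass problems natively),
        "ridge", "nearest_centroid", or "table" (a deterministic error lookup
        supplied via ``error_table``, for oracle/property tests).
    holdout_fraction / holdout_seed : stratified holdout validation; used
        unless ``k_fold`` is given.
    k_fold : optional stratified k-fold count replacing the holdout.
    cache : memoize errors by mask bits (DE revisits masks frequently).
    """

    inner_classifier: str = "logistic"
    holdout_fraction: float = 0.2
    holdout_seed: int = 0
    k_fold: int | None = None
    cache: bool = True
    error_table: dict[tuple[int, ...], float] | None = None

    def validate(self) -> None:
        if self.inner_classifier not in {
            "ridge", "logistic", "nearest_centroid", "table",
        }:
            raise InvalidConfigError(
                f"unknown inner classifier {self.inner_classifier!r}"
            )
        if not 0.0 < self.holdout_fraction < 1.0:
            raise InvalidConfigError("holdout_fraction must be in (0,1)")
        if self.inner_classifier == "table" and self.error_table is None:
            raise InvalidConfigError("table evaluator requires error_table")


@dataclass
class DEConfig:
    """All DE parameters.  Defaults follow the binary feature-selection
    configuration: small fixed population, 200 generations, F=0.5, Cr=0.7,
    and a 0.005 penalty weight on the selected-feature fraction."""

    pop_size: int = 10
    max_iter: int = 200
    mutation_factor: float = 0.5
    crossover_rate: float = 0.7
    alpha: float = 0.005
    seed: int = 0
    evaluator: FitnessEvaluatorSpec = field(default_factory=FitnessEvaluatorSpec)
    fitness_form: Literal["penalty", "convex"] = "penalty"

    def validate(self) -> None:
        if self.pop_size < 4:
            raise InvalidConfigError(
                "pop_size must be >= 4: mutation needs three donors besides the target"
            )
        if not 0.0 < self.crossover_rate <= 1.0:
            raise InvalidConfigError("crossover_rate must be in (0, 1]")
        if self.mutation_factor <= 0:
            raise InvalidConfigError("mutation_factor must be > 0")
        if self.alpha < 0:
            raise InvalidConfigError("alpha must be >= 0")
        if self.max_iter < 0:
            raise InvalidConfigError("max_iter must be >= 0")
        self.evaluator.validate()

    def to_dict(self) -> dict:
        return {
            "pop_size": self.pop_size,
            "max_iter": self.max_iter,
            "mutation_factor": self.mutation_factor,
            "crossover_rate": self.crossover_rate,
            "alpha": self.alpha,
            "seed": self.seed,
            "fitness_form": self.fitness_form,
            "evaluator": {
                "inner_classifier": self.evaluator.inner_classifier,
                "holdout_fraction": self.evaluator.holdout_fraction,
                "holdout_seed": self.evaluator.holdout_seed,
                "k_fold": self.evaluator.k_fold,
                "cache": self.evaluator.cache,
            },
        }


@dataclass
class DEState:
    """Evolving population with fitness bookkeeping."""

    population: np.ndarray  # (pop_size, d) uint8
    fitness: np.ndarray  # (pop_size,)
    best_mask: BinaryMask
    best_fitness: float
    generation: int
    history: list[dict]
    rng: np.random.Generator

    @property
    def d(self) -> int:
        return self.population.shape[1]

    def record(self) -> None:
        pop = self.population
        self.history.append(
            {
                "generation": self.generation,
                "best_fitness": float(self.best_fitness),
                "best_k": self.best_mask.k,
                "population_digest": hashlib.sha1(
                    np.ascontiguousarray(pop).tobytes()
                ).hexdigest(),
                "selection_counts": pop.sum(axis=0).astype(int).tolist(),
            }
        )


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def _build_inner(name: str):
    if name == "ridge":
        return RidgeClassifier()
    if name == "logistic":
        return LogisticRegression(max_iter=500)
    if name == "nearest_centroid":
        return NearestCentroid()
    raise InvalidConfigError(f"unknown inner classifier {name!r}")


class FitnessFunction:
    """Callable fitness bound to one dataset and one configuration.

    The validation split (stratified holdout at a fixed internal seed, or
    stratified k-fold) is frozen at construction so every mask is scored
    against the identical protocol; errors are cached by mask bits.
    """

    def __init__(self, data: FeatureMatrix | None, config: DEConfig):
        config.validate()
        self.config = config
        self.spec = config.evaluator
        self.data = data
        self._cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0
        if self.spec.inner_classifier == "table":
            self.d = len(next(iter(self.spec.error_table)))
            return
        if data is None:
            raise InvalidDatasetError("data required for a classifier evaluator")
        self.d = data.d
        y = data.labels
        if self.spec.k_fold:
            kf = StratifiedKFold(
                n_splits=self.spec.k_fold, shuffle=True,
                random_state=self.spec.holdout_seed,
            )
            self._folds = [
                (tr, te) for tr, te in kf.split(np.zeros(data.n), y)
            ]
        else:
            idx = np.arange(data.n)
            tr, te = train_test_split(
                idx, test_size=self.spec.holdout_fraction,
                random_state=self.spec.holdout_seed, stratify=y,
            )
            self._folds = [(tr, te)]

    def error(self, mask: BinaryMask) -> float:
        """Validation misclassification proportion of the inner classifier
        restricted to the selected columns; always in [0, 1]."""
        key = mask.bits
        if self.spec.cache and key in self._cache:
            return self._cache[key]
        if mask.k == 0:
            raise InvalidConfigError("empty mask: repair before evaluation")
        if self.spec.inner_classifier == "table":
            err = float(self.spec.error_table[key])
        else:
            cols = mask.indices()
            X = self.data.values[:, cols]
            y = self.data.labels.astype(str)
            errs = []
            for tr, te in self._folds:
                clf = _build_inner(self.spec.inner_classifier)
                clf.fit(X[tr], y[tr])
                errs.append(float(np.mean(clf.predict(X[te]) != y[te])))
            err = float(np.mean(errs))
        self.n_evaluations += 1
        if self.spec.cache:
            self._cache[key] = err
        return err

    def __call__(self, mask: BinaryMask) -> float:
        err = self.error(mask)
        frac = mask.k / self.d
        if self.config.fitness_form == "convex":
            return self.config.alpha * err + (1.0 - self.config.alpha) * frac
        return err + self.config.alpha * frac


def fitness(
    mask: BinaryMask,
    data: FeatureMatrix,
    config: DEConfig,
    fn: FitnessFunction | None = None,
) -> float:
    """Sparsity-penalized wrapper fitness of one mask.

    Pass a prebuilt :class:`FitnessFunction` as ``fn`` to reuse its frozen
    validation split and cache across calls.
    """
    if fn is None:
        fn = FitnessFunction(data, config)
    return fn(mask)


# ---------------------------------------------------------------------------
# DE primitives
# ---------------------------------------------------------------------------

def _repair_row(row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero masks are undefined under the wrapper error; set one
    uniformly random bit."""
    if row.sum() == 0:
        row = row.copy()
        row[rng.integers(row.shape[0])] = 1
    return row


def init_population(
    d: int, config: DEConfig, fn: FitnessFunction
) -> DEState:
    """Uniform random binary population; empty rows repaired; every row
    evaluated and the incumbent best tracked."""
    config.validate()
    if d < 1:
        raise InvalidConfigError("d must be >= 1")
    rng = np.random.default_rng(config.seed)
    pop = rng.integers(0, 2, size=(config.pop_size, d), dtype=np.uint8)
    for i in range(config.pop_size):
        pop[i] = _repair_row(pop[i], rng)
    fits = np.array([fn(BinaryMask.from_array(row)) for row in pop])
    best_i = int(np.argmin(fits))
    state = DEState(
        population=pop,
        fitness=fits,
        best_mask=BinaryMask.from_array(pop[best_i]),
        best_fitness=float(fits[best_i]),
        generation=0,
        history=[],
        rng=rng,
    )
    state.record()
    return state


def mutate(state: DEState, target_index: int, config: DEConfig) -> np.ndarray:
    """rand/1 mutant: v = x_r1 + F (x_r2 − x_r3), clipped into [0, 1].

    Donors r1, r2, r3 are mutually distinct and distinct from the target.
    """
    pop = state.population
    n = pop.shape[0]
    if n < 4:
        raise InvalidConfigError("mutation needs pop_size >= 4")
    candidates = np.delete(np.arange(n), target_index)
    r1, r2, r3 = state.rng.choice(candidates, size=3, replace=False)
    v = pop[r1].astype(np.float64) + config.mutation_factor * (
        pop[r2].astype(np.float64) - pop[r3].astype(np.float64)
    )
    return np.clip(v, 0.0, 1.0)


def crossover(
    target: BinaryMask,
    mutant: np.ndarray,
    config: DEConfig,
    rng: np.random.Generator,
) -> BinaryMask:
    """Binomial crossover with a forced ``jrand`` coordinate, then strict
    binarization (1 iff value > 0.5; exactly 0.5 maps to 0).  Empty trials
    are repaired."""
    mutant = np.asarray(mutant, dtype=np.float64)
    tbits = target.as_array()
    if mutant.shape[0] != tbits.shape[0]:
        raise InvalidConfigError("target and mutant lengths differ")
    d = tbits.shape[0]
    jrand = int(rng.integers(d))
    take = rng.random(d) <= config.crossover_rate
    take[jrand] = True
    mutant_bits = (mutant > 0.5).astype(np.uint8)
    trial = np.where(take, mutant_bits, tbits).astype(np.uint8)
    trial = _repair_row(trial, rng)
    return BinaryMask.from_array(trial)


def select(target_fitness: float, trial_fitness: float) -> bool:
    """Greedy one-to-one selection: replace iff strictly better (ties keep
    the incumbent).  Returns True when the trial replaces the target."""
    if not (np.isfinite(target_fitness) and np.isfinite(trial_fitness)):
        raise InvalidConfigError("fitness values must be finite")
    return trial_fitness < target_fitness


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def run_de(
    data: FeatureMatrix | None,
    config: DEConfig,
    fn: FitnessFunction | None = None,
) -> tuple[BinaryMask, DEState]:
    """Run binary DE for exactly ``max_iter`` generations and return the
    best-ever mask plus the full state (per-generation history included).

    Reproducible per ``config.seed``; evaluator failures are re-raised with
    the generation and target index for context.
    """
    if fn is None:
        fn = FitnessFunction(data, config)
    d = fn.d
    state = init_population(d, config, fn)
    for gen in range(1, config.max_iter + 1):
        for i in range(config.pop_size):
            v = mutate(state, i, config)
            trial = crossover(
                BinaryMask.from_array(state.population[i]), v, config, state.rng
            )
            try:
                tf = fn(trial)
            except Exception as exc:  # pragma: no cover - propagation path
                raise RuntimeError(
                    f"fitness evaluation failed at generation {gen}, target {i}"
                ) from exc
            if select(float(state.fitness[i]), tf):
                state.population[i] = trial.as_array()
                state.fitness[i] = tf
                if tf < state.best_fitness:
                    state.best_fitness = float(tf)
                    state.best_mask = trial
        state.generation = gen
        state.record()
    return state.best_mask, state


# ---------------------------------------------------------------------------
# Oracle and analytics
# ---------------------------------------------------------------------------

def exhaustive_oracle(
    data: FeatureMatrix | None,
    config: DEConfig,
    fn: FitnessFunction | None = None,
) -> tuple[BinaryMask, float]:
    """Evaluate every non-empty mask with the identical fitness and return
    the global minimizer (lexicographically smallest bits on ties).

    Refuses d > 15 to guard against the 2^d blow-up; use :func:`run_de` for
    larger dimensions.
    """
    if fn is None:
        fn = FitnessFunction(data, config)
    d = fn.d
    if d > 15:
        raise InvalidConfigError(
            f"exhaustive search over d={d} would evaluate 2^{d}-1 masks; "
            "restricted to d <= 15 — use run_de instead"
        )
    best_bits: tuple[int, ...] | None = None
    best_fit = np.inf
    for code in range(1, 2**d):
        bits = tuple((code >> (d - 1 - j)) & 1 for j in range(d))
        f = fn(BinaryMask(bits))
        if f < best_fit or (f == best_fit and (best_bits is None or bits < best_bits)):
            best_fit = float(f)
            best_bits = bits
    return BinaryMask(best_bits), best_fit


def selection_frequency(states: DEState | Iterable[DEState]) -> np.ndarray:
    """Per-feature fraction of (population member × generation) slots holding
    a 1, pooled over the supplied runs; values in [0, 1]."""
    if isinstance(states, DEState):
        states = [states]
    states = list(states)
    if not states:
        raise InvalidConfigError("at least one state required")
    d = states[0].d
    total = np.zeros(d, dtype=np.float64)
    slots = 0
    for st in states:
        if st.d != d:
            raise InvalidDatasetError("states have mismatched dimensions")
        pop_size = st.population.shape[0]
        for rec in st.history:
            total += np.asarray(rec["selection_counts"], dtype=np.float64)
            slots += pop_size
    return total / slots


def reduction_percentage(d: int, k: int) -> float:
    """Dimensionality reduction 100·(d−k)/d, rounded to 2 decimals."""
    if not 1 <= k <= d:
        raise InvalidConfigError(f"k={k} must satisfy 1 <= k <= d={d}")
    return round(100.0 * (d - k) / d, 2)
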