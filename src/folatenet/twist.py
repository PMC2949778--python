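"""Evolutionary train/test-split optimisation and input selection (TWIST).

A genome carries one bit per record (subset a or b) and one bit per
feature (selected or not). Fitness is the mean of the two directions'
generalisation accuracy: an inner perceptron trained on the masked
features of one subset and scored on the other, and vice versa. The
optimiser is a genetic algorithm with tournament selection, uniform
crossover, bit-flip mutation, elitism and "doping" — a fixed fraction of
random immigrant genomes injected each generation.

Exposed statsmodels-style: :class:`Twist` is built from an encoded matrix
and a config; ``fit()`` returns a :class:`TwistResults` with the selected
variables, the optimised split and the fitness history.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import EncodedMatrix
from .metrics import confusion_counts
from .mlp import Perceptron, TrainConfig
from .seeds import split_seed


@dataclass(frozen=True)
class TwistGenome:
    """Split bits (0 = subset a, 1 = subset b) + feature-mask bits."""

    split_bits: np.ndarray
    mask_bits: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "split_bits", np.asarray(self.split_bits, dtype=np.uint8))
        object.__setattr__(self, "mask_bits", np.asarray(self.mask_bits, dtype=np.uint8))

    def key(self) -> bytes:
        return self.split_bits.tobytes() + b"|" + self.mask_bits.tobytes()

    def is_valid(self, y: np.ndarray) -> bool:
        """At least one feature; both subsets hold both classes."""
        if self.mask_bits.sum() == 0:
            return False
        for side in (0, 1):
            ys = y[self.split_bits == side]
            if ys.size == 0 or len(np.unique(ys)) < 2:
                return False
        return True


@dataclass(frozen=True)
class TwistConfig:
    """Genetic-algorithm and inner-training settings.

    ``mutation_rate=None`` means 1/genome_length. ``doping_fraction`` is
    the random-immigrant share per generation (floor of fraction x
    population). The inner perceptron runs on a reduced epoch budget for
    tractability; report-quality networks are retrained at full budget by
    the validation stage.
    """

    population_size: int = 30
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    elite_count: int = 2
    doping_fraction: float = 0.1
    inner_train: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=100))
    hidden: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for name in ("crossover_rate", "doping_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be < population_size")


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lexicographic ordering of (row, label), so anything downstream is
    invariant to how the records happened to be listed."""
    keys = np.column_stack([X, y])
    return np.lexsort(keys.T[::-1])


def _direction_accuracy(
    X_train, y_train, X_test, y_test, cfg: TwistConfig
) -> float:
    res = Perceptron(y_train, X_train, hidden=cfg.hidden).fit(cfg.inner_train)
    scores = res.predict(X_test)
    tp, fn, tn, fp = confusion_counts(scores, y_test)
    return (tp + tn) / len(y_test)


def genome_fitness(g: TwistGenome, em: EncodedMatrix, cfg: TwistConfig) -> float:
    """Two-direction generalisation accuracy of the genome, in [0, 1].

    Invalid genomes (no features, or a subset missing a class) score 0.
    Training visit order is canonicalised so fitness depends only on the
    record sets, not their listing order.
    """
    if g.split_bits.shape[0] != em.X.shape[0] or g.mask_bits.shape[0] != em.n_features:
        raise ValueError("genome length does not match the encoded matrix")
    if not g.is_valid(em.y):
        return 0.0
    mask = g.mask_bits.astype(bool)
    X = em.X[:, mask]
    y = em.y
    accs = []
    for train_side in (0, 1):
        tr = np.flatnonzero(g.split_bits == train_side)
        te = np.flatnonzero(g.split_bits == 1 - train_side)
        Xtr, ytr = X[tr], y[tr]
        order = _canonical_order(Xtr, ytr)
        accs.append(_direction_accuracy(Xtr[order], ytr[order], X[te], y[te], cfg))
    return float(np.mean(accs))


def _random_genome(rng: np.random.Generator, n_records: int, n_features: int) -> TwistGenome:
    return TwistGenome(
        rng.integers(0, 2, size=n_records, dtype=np.uint8),
        rng.integers(0, 2, size=n_features, dtype=np.uint8),
    )


def _tournament(rng, fitnesses: np.ndarray) -> int:
    i, j = rng.integers(0, len(fitnesses), size=2)
    if fitnesses[i] == fitnesses[j]:
        return int(min(i, j))
    return int(i if fitnesses[i] > fitnesses[j] else j)


def gend_step(
    population: list[TwistGenome],
    fitnesses,
    cfg: TwistConfig,
    rng: np.random.Generator,
) -> list[TwistGenome]:
    """One generation: elitism, tournament/crossover/mutation offspring,
    and floor(doping_fraction x population) random immigrants in place of
    the worst slots. Population size is conserved."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) != cfg.population_size or len(fitnesses) != cfg.population_size:
        raise ValueError("population/fitness size must equal cfg.population_size")
    n_records = population[0].split_bits.shape[0]
    n_features = population[0].mask_bits.shape[0]
    genome_len = n_records + n_features
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / genome_len

    order = np.argsort(-fitnesses, kind="stable")
    elites = [population[i] for i in order[: cfg.elite_count]]
    n_dope = math.floor(cfg.doping_fraction * cfg.population_size)
    n_offspring = cfg.population_size - cfg.elite_count - n_dope
    if n_offspring < 0:
        raise ValueError("elite_count + doping exceed the population")

    offspring = []
    for _ in range(n_offspring):
        p1 = population[_tournament(rng, fitnesses)]
        p2 = population[_tournament(rng, fitnesses)]
        bits1 = np.concatenate([p1.split_bits, p1.mask_bits])
        bits2 = np.concatenate([p2.split_bits, p2.mask_bits])
        if rng.random() < cfg.crossover_rate:
            take2 = rng.random(genome_len) < 0.5
            child = np.where(take2, bits2, bits1)
        else:
            child = bits1.copy()
        flip = rng.random(genome_len) < mut
        child = np.where(flip, 1 - child, child).astype(np.uint8)
        offspring.append(TwistGenome(child[:n_records], child[n_records:]))

    doped = [_random_genome(rng, n_records, n_features) for _ in range(n_dope)]
    return elites + offspring + doped


@dataclass
class TwistResults:
    """Best genome found: its variables, split, and the fitness trace."""

    selected_features: list[str]
    split: np.ndarray  # 0 = subset a, 1 = subset b, aligned with records
    best_fitness_history: list[float]
    final_fitness: float
    best_genome: TwistGenome
    subject_ids: list[str] = field(default_factory=list)
    config: TwistConfig | None = None

    def split_assignment(self) -> dict[str, str]:
        ids = self.subject_ids or [str(i) for i in range(len(self.split))]
        return {sid: ("a" if s == 0 else "b") for sid, s in zip(ids, self.split)}

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_features": self.selected_features,
                "final_fitness": self.final_fitness,
                "best_fitness_history": self.best_fitness_history,
                "split": self.split_assignment(),
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            "TWIST variable selection results",
            "================================",
            f"selected variables ({len(self.selected_features)}):",
        ]
        lines += [f"  - {n}" for n in self.selected_features]
        lines += [
            f"final two-direction accuracy : {self.final_fitness:.4f}",
            f"generations                  : {len(self.best_fitness_history)}",
            f"split sizes (a/b)            : "
            f"{int(np.sum(self.split == 0))}/{int(np.sum(self.split == 1))}",
        ]
        return "\n".join(lines)


class Twist:
    """Model object: evolutionary split + variable selection on a cohort."""

    def __init__(self, em: EncodedMatrix, config: TwistConfig | None = None):
        self.em = em
        self.config = config or TwistConfig()
        if len(np.unique(em.y)) < 2:
            raise ValueError("both classes must be present")

    def fit(self) -> TwistResults:
        cfg = self.config
        em = self.em
        rng = np.random.default_rng(cfg.seed)
        n_records, n_features = em.X.shape[0], em.n_features
        population = [_random_genome(rng, n_records, n_features) for _ in range(cfg.population_size)]
        cache: dict[bytes, float] = {}

        def fit_of(g: TwistGenome) -> float:
            k = g.key()
            if k not in cache:
                cache[k] = genome_fitness(g, em, cfg)
            return cache[k]

        best_g: TwistGenome | None = None
        best_f = -1.0
        history: list[float] = []
        for _ in range(cfg.generations):
            fits = np.array([fit_of(g) for g in population])
            i = int(np.argmax(fits))
            if fits[i] > best_f:
                best_f = float(fits[i])
                best_g = population[i]
            history.append(best_f)
            population = gend_step(population, fits, cfg, rng)

        assert best_g is not None
        names = [n for n, m in zip(em.feature_names, best_g.mask_bits) if m]
        return TwistResults(
            selected_features=names,
            split=best_g.split_bits.copy(),
            best_fitness_history=history,
            final_fitness=best_f,
            best_genome=best_g,
            subject_ids=em.subject_ids,
            config=cfg,
        )


def evolve_twist(em: EncodedMatrix, cfg: TwistConfig | None = None) -> TwistResults:
    """Functional wrapper around :class:`Twist`."""
    return Twist(em, cfg).fit()
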