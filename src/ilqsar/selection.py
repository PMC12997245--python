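"""Descriptor-subset selection for GA-MLR QSAR models.

A genetic algorithm searches fixed-size descriptor subsets maximizing either
the cross-validated Q2 (leave-one-out, the default) or the training R2.
An exhaustive enumerator serves as the exact reference on small pools, and a
breaking-point scan locates the smallest subset size beyond which the fit
stops improving appreciably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable, correlation_matrix
from .mlr import MLRModel, fit_ols

NEG_INF = float("-inf")


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05  # per-gene
    elitism: int = 2
    fitness: str = "Q2_LOO"  # or "R2"
    seed: int = 0
    local_search: bool = True  # swap-refine the final best subset

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.fitness not in ("Q2_LOO", "R2"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


@dataclass
class SelectionResult:
    chosen_names: list[str]
    fitness_value: float
    model: MLRModel
    fitness_trace: list[float] = field(default_factory=list)
    correlation: pd.DataFrame | None = None


@dataclass
class BreakingPointTable:
    rows: pd.DataFrame  # columns k, fitness, r2
    plateau_k: int
    delta: float

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


class _FitnessEngine:
    """Vectorised subset fitness with memoisation.

    Rank-deficient subsets score -inf rather than raising, so the search
    can pass through them.
    """

    def __init__(self, table: DescriptorTable, pool: list[str], fitness: str):
        ids = table.response.index.intersection(table.data.index)
        self.pool = list(pool)
        self.X = table.data.loc[ids, self.pool].to_numpy(dtype=float)
        self.y = table.response.loc[ids].to_numpy(dtype=float)
        self.n = len(self.y)
        self.sstot = float(((self.y - self.y.mean()) ** 2).sum())
        self.fitness = fitness
        self._cache: dict[tuple[int, ...], tuple[float, float]] = {}

    def scores(self, subset: tuple[int, ...]) -> tuple[float, float]:
        """(configured fitness, training R2) for a sorted index subset."""
        hit = self._cache.get(subset)
        if hit is not None:
            return hit
        k = len(subset)
        Z = np.empty((self.n, k + 1))
        Z[:, 0] = 1.0
        Z[:, 1:] = self.X[:, subset]
        Q, R = np.linalg.qr(Z)
        diag = np.abs(np.diag(R))
        if diag.min() <= 1e-10 * max(diag.max(), 1.0):
            out = (NEG_INF, NEG_INF)
        else:
            coef = Q.T @ self.y
            resid = self.y - Q @ coef
            r2 = 1.0 - float((resid ** 2).sum()) / self.sstot
            if self.fitness == "R2":
                out = (r2, r2)
            else:
                h = (Q ** 2).sum(axis=1)
                cv = resid / (1.0 - h)
                q2 = 1.0 - float((cv ** 2).sum()) / self.sstot
                out = (q2, r2)
        self._cache[subset] = out
        return out

    def names(self, subset: tuple[int, ...]) -> list[str]:
        return [self.pool[i] for i in subset]


def _better(fit_a: float, sub_a, fit_b: float, sub_b, engine) -> bool:
    """True if (fit_a, sub_a) beats (fit_b, sub_b); ties go to the
    lexicographically smaller name tuple for cross-platform determinism."""
    if fit_a != fit_b:
        return fit_a > fit_b
    return tuple(engine.names(sub_a)) < tuple(engine.names(sub_b))


def _finalize(table: DescriptorTable, engine: _FitnessEngine,
              subset: tuple[int, ...], fitness_value: float,
              trace: list[float]) -> SelectionResult:
    names = engine.names(subset)
    model = fit_ols(table, names)
    corr = correlation_matrix(table, names) if len(names) > 1 else None
    return SelectionResult(chosen_names=names, fitness_value=fitness_value,
                           model=model, fitness_trace=trace, correlation=corr)


def exhaustive_select(table: DescriptorTable, pool: list[str], k: int,
                      fitness: str = "Q2_LOO",
                      budget: int = 1_000_000) -> SelectionResult:
    """Global optimum by full enumeration of all C(|pool|, k) subsets."""
    pool = list(pool)
    n_cand = math.comb(len(pool), k)
    if n_cand > budget:
        raise ValueError(f"{n_cand} candidate subsets exceed the budget {budget}")
    engine = _FitnessEngine(table, pool, fitness)
    best_fit, best_sub = NEG_INF, None
    for sub in combinations(range(len(pool)), k):
        f, _ = engine.scores(sub)
        if best_sub is None or _better(f, sub, best_fit, best_sub, engine):
            best_fit, best_sub = f, sub
    if best_fit == NEG_INF:
        raise ValueError("every candidate subset is rank-deficient")
    return _finalize(table, engine, best_sub, best_fit, [best_fit])


def ga_select(table: DescriptorTable, pool: list[str], k: int,
              config: GAConfig | None = None) -> SelectionResult:
    """Genetic-algorithm search for the best k-descriptor subset.

    Chromosomes are fixed-size index sets; uniform crossover and per-gene
    mutation are followed by a repair step (dedupe and refill) keeping
    exactly k genes.  With elitism the best-so-far fitness is monotone.
    Selection uses only the rows carried by *table* (hold the test set out
    upstream).
    """
    config = config or GAConfig()
    pool = list(pool)
    m = len(pool)
    if m < k:
        raise ValueError(f"pool of {m} descriptors cannot supply k={k}")
    ids = table.response.index.intersection(table.data.index)
    if len(ids) < k + 3:
        raise ValueError(f"need at least k+3={k + 3} training rows, got {len(ids)}")
    if m == k:
        engine = _FitnessEngine(table, pool, config.fitness)
        sub = tuple(range(m))
        f, _ = engine.scores(sub)
        return _finalize(table, engine, sub, f, [f])

    engine = _FitnessEngine(table, pool, config.fitness)
    rng = np.random.default_rng(config.seed)

    def repair(genes: np.ndarray) -> tuple[int, ...]:
        uniq = np.unique(genes)
        if uniq.size < k:
            others = np.setdiff1d(np.arange(m), uniq, assume_unique=False)
            fill = rng.choice(others, size=k - uniq.size, replace=False)
            uniq = np.concatenate([uniq, fill])
        return tuple(sorted(int(g) for g in uniq[:k]))

    pop = [tuple(sorted(rng.choice(m, size=k, replace=False))) for _ in
           range(config.population_size)]
    fits = [engine.scores(s)[0] for s in pop]
    best_sub = pop[int(np.argmax(fits))]
    best_fit = max(fits)
    for s, f in zip(pop, fits):
        if _better(f, s, best_fit, best_sub, engine):
            best_fit, best_sub = f, s
    trace = [best_fit]

    for _ in range(config.generations):
        order = sorted(range(len(pop)),
                       key=lambda i: (-fits[i], tuple(engine.names(pop[i]))))
        elites = [pop[i] for i in order[:config.elitism]]
        children: list[tuple[int, ...]] = list(elites)
        while len(children) < config.population_size:
            # binary tournaments
            a, b = rng.integers(len(pop), size=2)
            p1 = pop[a] if fits[a] >= fits[b] else pop[b]
            a, b = rng.integers(len(pop), size=2)
            p2 = pop[a] if fits[a] >= fits[b] else pop[b]
            g1, g2 = np.array(p1), np.array(p2)
            if rng.random() < config.crossover_rate:
                mask = rng.random(k) < 0.5
                child = np.where(mask, g1, g2)
            else:
                child = g1.copy()
            mut = rng.random(k) < config.mutation_rate
            if mut.any():
                child[mut] = rng.integers(m, size=int(mut.sum()))
            children.append(repair(child))
        pop = children
        fits = [engine.scores(s)[0] for s in pop]
        for s, f in zip(pop, fits):
            if _better(f, s, best_fit, best_sub, engine):
                best_fit, best_sub = f, s
        trace.append(best_fit)

    if best_fit == NEG_INF:
        raise ValueError("no full-rank subset found in the pool")
    if config.local_search:
        best_sub, best_fit = _swap_refine(engine, best_sub, best_fit)
        trace.append(best_fit)
    return _finalize(table, engine, best_sub, best_fit, trace)


def _swap_refine(engine: _FitnessEngine, subset: tuple[int, ...],
                 fit: float) -> tuple[tuple[int, ...], float]:
    """Steepest-ascent single-swap hill climb until no swap improves."""
    m = len(engine.pool)
    current, current_fit = subset, fit
    while True:
        in_set = set(current)
        best_cand, best_f = current, current_fit
        for pos in range(len(current)):
            for j in range(m):
                if j in in_set:
                    continue
                cand = tuple(sorted(current[:pos] + (j,) + current[pos + 1:]))
                f, _ = engine.scores(cand)
                if _better(f, cand, best_f, best_cand, engine):
                    best_cand, best_f = cand, f
        if best_cand == current:
            return current, current_fit
        current, current_fit = best_cand, best_f


def breaking_point(table: DescriptorTable, pool: list[str], k_range,
                   config: GAConfig | None = None, delta: float = 0.01,
                   exhaustive_budget: int = 2000) -> BreakingPointTable:
    """Best attainable fit for each subset size k, plus the plateau point.

    Small pools are enumerated exactly; larger ones use the GA (with the
    seed offset per k so scans are reproducible).  The plateau is the
    smallest k whose training R2 is within *delta* of the best over the
    scanned range.
    """
    config = config or GAConfig()
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    rows = []
    for k in ks:
        if math.comb(len(pool), k) <= exhaustive_budget:
            res = exhaustive_select(table, pool, k, fitness=config.fitness)
        else:
            cfg_k = GAConfig(**{**config.__dict__, "seed": config.seed + k})
            res = ga_select(table, pool, k, cfg_k)
        ids = res.model.meta["training_ids"]
        yhat = table.data.loc[ids, res.chosen_names].to_numpy() @ \
            res.model.coef_vector() + res.model.intercept
        y = table.response.loc[ids].to_numpy(dtype=float)
        r2 = 1.0 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        rows.append({"k": k, "fitness": res.fitness_value, "r2": float(r2)})
    df = pd.DataFrame(rows)
    best = df.r2.max()
    plateau_k = int(df.loc[df.r2 >= best - delta, "k"].min())
    return BreakingPointTable(rows=df, plateau_k=plateau_k, delta=delta)
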