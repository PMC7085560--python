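"""Elitist non-dominated-sorting genetic algorithm (NSGA-II), two objectives.

Canonical Deb et al. machinery: fast non-dominated sorting, crowding
distance, binary tournament on (rank, crowding), simulated binary
crossover, polynomial mutation, and (mu + lambda) survival truncated by
front then crowding.  The solver is generic over any callable mapping a
bounded real vector to an objective pair, so alternative optimizers with
the same contract can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvolutionConfig",
    "ParetoArchive",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "evolve",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """NSGA-II settings.

    ``pop_size`` must be even and >= 4.  ``mutation_prob`` defaults to
    1/n_variables when None (the canonical per-gene rate).  ``bounds``
    is the (lo, hi) box every gene is confined to; offspring are clipped
    back after variation.
    """

    pop_size: int = 50
    n_gen: int = 5000
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_prob: float | None = None
    mutation_eta: float = 20.0
    bounds: tuple = (-1.0, 1.0)
    seed: int | None = None

    def __post_init__(self):
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError(
                f"pop_size must be even and >= 4, got {self.pop_size}"
            )
        if self.n_gen < 1:
            raise ValueError(f"n_gen must be >= 1, got {self.n_gen}")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"invalid bounds {self.bounds}")


@dataclass
class ParetoArchive:
    """Final rank-1 front: decision vectors, objective pairs, provenance."""

    alphas: np.ndarray  # (m, d)
    F: np.ndarray  # (m, 2) objective pairs, minimized
    config: EvolutionConfig | None = None
    history: np.ndarray | None = None  # (n_gen+1, 2) per-generation minima

    def __len__(self) -> int:
        return len(self.F)


def dominates(a, b) -> bool:
    """Pareto dominance for minimization: a <= b everywhere, < somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return bool(np.all(a <= b) and np.any(a < b))


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition objective rows into fronts of mutually non-dominated points.

    Front r holds exactly the points that are non-dominated once fronts
    < r are removed; the union of fronts is the whole population.
    Returns index arrays in ascending rank order.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or not np.all(np.isfinite(F)):
        raise ValueError("objective matrix must be 2-D and fully evaluated")
    N = len(F)
    # pairwise dominance: i dominates j
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = n_dominators.copy()
    assigned = np.zeros(N, dtype=bool)
    while not assigned.all():
        current = np.flatnonzero((remaining == 0) & ~assigned)
        fronts.append(current)
        assigned[current] = True
        remaining = remaining - dom[current].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each point within one front.

    Per objective the front is sorted; boundary points get +inf and
    interior points accumulate the normalized gap between their
    neighbors.  A zero-range objective contributes nothing.
    """
    F = np.asarray(F, dtype=float)
    m = len(F)
    d = np.zeros(m)
    if m <= 2:
        d[:] = np.inf
        return d
    for j in range(F.shape[1]):
        order = np.argsort(F[:, j], kind="stable")
        v = F[order, j]
        d[order[0]] = d[order[-1]] = np.inf
        rng = v[-1] - v[0]
        if rng == 0:
            continue
        d[order[1:-1]] += (v[2:] - v[:-2]) / rng
    return d


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(fast_nondominated_sort(F)):
        ranks[front] = r
        crowd[front] = crowding_distance(F[front])
    return ranks, crowd


def _tournament(ranks, crowd, rng) -> int:
    i, j = rng.integers(len(ranks), size=2)
    if ranks[i] < ranks[j]:
        return i
    if ranks[j] < ranks[i]:
        return j
    if crowd[i] > crowd[j]:
        return i
    if crowd[j] > crowd[i]:
        return j
    return min(i, j)  # stable tie-break by population index


def _sbx(p1, p2, lo, hi, eta, prob, rng):
    """Simulated binary crossover; children clipped into bounds."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    cross = rng.random(p1.size) < 0.5
    u = rng.random(p1.size)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    h1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    h2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    c1[cross] = h1[cross]
    c2[cross] = h2[cross]
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _polynomial_mutation(x, lo, hi, eta, prob, rng):
    """Bounded polynomial mutation (Deb & Goyal), per-gene probability."""
    y = x.copy()
    do = rng.random(x.size) < prob
    if not do.any():
        return y
    u = rng.random(x.size)
    span = hi - lo
    d1 = (y - lo) / span
    d2 = (hi - y) / span
    mpow = 1.0 / (eta + 1.0)
    lhs = u < 0.5
    dq = np.where(
        lhs,
        (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1.0)) ** mpow - 1.0,
        1.0 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1.0)) ** mpow,
    )
    y[do] = y[do] + dq[do] * span
    return np.clip(y, lo, hi)


def _evaluate_population(pop, objective) -> np.ndarray:
    F = np.empty((len(pop), 2))
    for i, alpha in enumerate(pop):
        f = objective(alpha)
        if not np.all(np.isfinite(f)):
            raise ValueError(
                f"objective evaluation failed for individual {i}: {f!r}"
            )
        F[i] = f
    return F


def evolve(
    objective,
    n_variables: int,
    config: EvolutionConfig = EvolutionConfig(),
) -> ParetoArchive:
    """Run NSGA-II and return the final non-dominated front.

    ``objective`` maps a length-``n_variables`` vector to an (f1, f2)
    pair to minimize.  The run is fully reproducible from
    ``config.seed``; ``history`` records the per-generation minimum of
    each objective over the surviving population (non-increasing under
    elitism, since per-objective extremes carry infinite crowding).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    NP = config.pop_size
    pm = (
        config.mutation_prob
        if config.mutation_prob is not None
        else 1.0 / n_variables
    )

    pop = rng.uniform(lo, hi, size=(NP, n_variables))
    F = _evaluate_population(pop, objective)
    history = [F.min(axis=0)]

    for _ in range(config.n_gen):
        ranks, crowd = _rank_and_crowd(F)
        children = np.empty_like(pop)
        for k in range(0, NP, 2):
            p1 = pop[_tournament(ranks, crowd, rng)]
            p2 = pop[_tournament(ranks, crowd, rng)]
            c1, c2 = _sbx(
                p1, p2, lo, hi, config.crossover_eta, config.crossover_prob, rng
            )
            children[k] = _polynomial_mutation(
                c1, lo, hi, config.mutation_eta, pm, rng
            )
            children[k + 1] = _polynomial_mutation(
                c2, lo, hi, config.mutation_eta, pm, rng
            )
        F_children = _evaluate_population(children, objective)

        merged = np.vstack([pop, children])
        F_merged = np.vstack([F, F_children])
        survivors = _survival(F_merged, NP)
        pop, F = merged[survivors], F_merged[survivors]
        history.append(F.min(axis=0))

    front = fast_nondominated_sort(F)[0]
    return ParetoArchive(
        alphas=pop[front].copy(),
        F=F[front].copy(),
        config=config,
        history=np.asarray(history),
    )


def _survival(F: np.ndarray, NP: int) -> np.ndarray:
    """Elitist truncation: whole fronts, last one trimmed by crowding."""
    chosen = []
    for front in fast_nondominated_sort(F):
        if len(chosen) + len(front) <= NP:
            chosen.extend(front.tolist())
            if len(chosen) == NP:
                break
        else:
            crowd = crowding_distance(F[front])
            # descending crowding; ties broken by stable population index
            order = np.argsort(-crowd, kind="stable")
            chosen.extend(front[order[: NP - len(chosen)]].tolist())
            break
    return np.asarray(chosen)
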