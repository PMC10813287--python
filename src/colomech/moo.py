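"""A small real-coded NSGA-II: elitist non-dominated sorting genetic algorithm.

Standard components: fast non-dominated sorting, crowding-distance diversity
preservation, binary tournament selection on (rank, crowding), simulated
binary crossover (SBX) and polynomial mutation, both with boundary clipping.
All randomness flows through one integer-seeded ``numpy.random.Generator``,
so runs are reproducible bit-for-bit per seed.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["nsga2", "non_dominated_sort", "crowding_distance", "pareto_mask"]


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def pareto_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the non-dominated rows of an (n, m) objective array."""
    n = F.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        dominated = np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1)
        if np.any(dominated & mask):
            mask[i] = False
    return mask


def non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fronts of indices, best first (Deb's fast non-dominated sort)."""
    n = F.shape[0]
    S: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    fronts: list[list[int]] = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _dominates(F[p], F[q]):
                S[p].append(q)
            elif _dominates(F[q], F[p]):
                domination_count[p] += 1
        if domination_count[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt: list[int] = []
        for p in fronts[i]:
            for q in S[p]:
                domination_count[q] -= 1
                if domination_count[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(nxt)
    return [np.array(f, dtype=int) for f in fronts if len(f)]


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each row within one front."""
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


def _rank_and_crowding(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = np.empty(F.shape[0], dtype=int)
    crowd = np.empty(F.shape[0])
    for r, front in enumerate(non_dominated_sort(F)):
        rank[front] = r
        crowd[front] = crowding_distance(F[front])
    return rank, crowd


def _tournament(rng, rank, crowd, k: int) -> np.ndarray:
    """k binary tournaments on (rank asc, crowding desc)."""
    a = rng.integers(0, rank.size, size=k)
    b = rng.integers(0, rank.size, size=k)
    better_b = (rank[b] < rank[a]) | ((rank[b] == rank[a]) & (crowd[b] > crowd[a]))
    return np.where(better_b, b, a)


def _sbx(rng, p1, p2, low, high, eta: float, prob: float):
    """Simulated binary crossover, per-variable, with boundary clipping."""
    c1, c2 = p1.copy(), p2.copy()
    do = (rng.random(p1.shape) < prob) & (np.abs(p1 - p2) > 1e-14)
    u = rng.random(p1.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    mean = 0.5 * (p1 + p2)
    diff = 0.5 * np.abs(p2 - p1)
    c1[do] = (mean - beta * diff)[do]
    c2[do] = (mean + beta * diff)[do]
    return np.clip(c1, low, high), np.clip(c2, low, high)


def _polynomial_mutation(rng, x, low, high, eta: float, prob: float):
    y = x.copy()
    span = high - low
    do = rng.random(x.shape) < prob
    u = rng.random(x.shape)
    delta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    y[do] = (x + delta * span)[do]
    return np.clip(y, low, high)


def nsga2(
    objective: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    *,
    pop_size: int = 100,
    generations: int = 200,
    seed: int = 0,
    eta_crossover: float = 15.0,
    eta_mutation: float = 20.0,
    crossover_prob: float = 0.9,
    mutation_prob: float | None = None,
    callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize a vector objective; return (X, F) of the final Pareto set.

    Parameters
    ----------
    objective : callable
        Maps an (n, d) population matrix to an (n, m) objective matrix.
    bounds : (d, 2) array
        Per-variable [low, high]; the population is initialized uniformly
        inside and children are clipped to it.
    pop_size, generations : int
        GA size; pop_size must be even and >= 10.
    seed : int
        Seed of the single random generator used throughout.
    callback : callable, optional
        Called as ``callback(gen, X, F)`` once per generation.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a (d, 2) array")
    low, high = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(low >= high):
        raise ValueError("bounds must be finite with low < high")
    if pop_size < 10:
        raise ValueError("population size must be >= 10")
    if pop_size % 2:
        pop_size += 1
    d = bounds.shape[0]
    if mutation_prob is None:
        mutation_prob = 1.0 / d

    rng = np.random.default_rng(seed)
    X = rng.uniform(low, high, size=(pop_size, d))
    F = np.asarray(objective(X), dtype=float)
    rank, crowd = _rank_and_crowding(F)

    for gen in range(generations):
        parents = _tournament(rng, rank, crowd, pop_size)
        children = np.empty_like(X)
        for i in range(0, pop_size, 2):
            c1, c2 = _sbx(
                rng, X[parents[i]], X[parents[i + 1]], low, high,
                eta_crossover, crossover_prob,
            )
            children[i], children[i + 1] = c1, c2
        children = _polynomial_mutation(rng, children, low, high, eta_mutation, mutation_prob)
        Fc = np.asarray(objective(children), dtype=float)

        # elitist environmental selection on the combined population
        XA = np.vstack([X, children])
        FA = np.vstack([F, Fc])
        keep: list[int] = []
        for front in non_dominated_sort(FA):
            if len(keep) + front.size <= pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(FA[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order][: pop_size - len(keep)].tolist())
                break
        idx = np.array(keep, dtype=int)
        X, F = XA[idx], FA[idx]
        rank, crowd = _rank_and_crowding(F)
        if callback is not None:
            callback(gen, X, F)

    mask = pareto_mask(F)
    Xp, Fp = X[mask], F[mask]
    # drop duplicate objective rows, sort by first objective
    order = np.lexsort((Fp[:, 1], Fp[:, 0]))
    Xp, Fp = Xp[order], Fp[order]
    uniq = np.ones(Fp.shape[0], dtype=bool)
    if Fp.shape[0] > 1:
        uniq[1:] = np.any(np.abs(np.diff(Fp, axis=0)) > 0, axis=1)
    return Xp[uniq], Fp[uniq]
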