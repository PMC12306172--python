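"""Enterotype discovery on genus-level relative-abundance profiles.

The pipeline follows the canonical enterotyping protocol: pairwise
Jensen-Shannon dissimilarity (square root of the base-2 divergence, a
bounded metric), partitioning-around-medoids clustering on the distance
matrix, and selection of the cluster number maximising the
Calinski-Harabasz index. PAM is a deterministic BUILD + SWAP
implementation with all ties broken toward the smallest index, so runs are
bit-reproducible. The CH index and PCoA coordinates are computed on the
classical multidimensional-scaling embedding of the distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.special import xlogy
from sklearn.metrics import calinski_harabasz_score

from .io import RelativeProfileSet

DEFAULT_PSEUDOCOUNT = 1e-6
_LN2 = np.log(2.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.any(self.d < 0):
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class EnterotypeResult:
    k: int
    labels: np.ndarray            # per-sample cluster index, 0..k-1
    medoid_ids: list[str]
    ch_by_k: dict[int, float]
    objective: float
    driver_genus: dict[int, str] = field(default_factory=dict)
    driver_abundance: dict[int, float] = field(default_factory=dict)


def _apply_pseudocount(p: np.ndarray, pseudocount: float) -> np.ndarray:
    q = np.where(p == 0, pseudocount, p)
    return q / q.sum(axis=-1, keepdims=True)


def js_distance(p, q, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Square root of the base-2 Jensen-Shannon divergence between two
    probability vectors, with zeros replaced by ``pseudocount`` and
    renormalised first. Bounded in [0, 1]; zero iff ``p == q``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a probability vector")
    return float(jensenshannon(_apply_pseudocount(p, pseudocount),
                               _apply_pseudocount(q, pseudocount), base=2))


def jsd_matrix(profiles: RelativeProfileSet,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> DistanceMatrix:
    """All-pairs sqrt-JSD matrix, vectorised via the entropy identity
    JSD(p, q) = H(m) - (H(p) + H(q))/2 with m the midpoint mixture."""
    if profiles.n_samples < 2:
        raise ValueError("need at least 2 samples")
    P = _apply_pseudocount(profiles.profiles, pseudocount)
    n = P.shape[0]
    h = -xlogy(P, P).sum(axis=1) / _LN2  # per-sample entropy, bits
    d = np.zeros((n, n))
    for i in range(n - 1):
        m = 0.5 * (P[i] + P[i + 1 :])
        hm = -xlogy(m, m).sum(axis=1) / _LN2
        jsd = hm - 0.5 * (h[i] + h[i + 1 :])
        d[i, i + 1 :] = np.sqrt(np.clip(jsd, 0.0, 1.0))
    d = d + d.T
    return DistanceMatrix(list(profiles.sample_ids), d)


# ---------------------------------------------------------------------------
# PAM: deterministic BUILD + SWAP k-medoids on a precomputed distance matrix


def _objective(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


_EXACT_LIMIT = 3000  # max medoid subsets to enumerate exactly


def pam(D: DistanceMatrix | np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """Partitioning around medoids.

    Small instances (at most ``_EXACT_LIMIT`` candidate medoid subsets) are
    solved exactly by enumeration, because the BUILD+SWAP local search —
    like every PAM implementation — can stall in a local optimum even at
    n = 8. Larger instances use deterministic BUILD initialisation (greedy
    objective-minimising seeds) followed by best-improvement SWAP passes
    until no single medoid/non-medoid exchange lowers the total
    within-cluster distance to medoids.

    Returns ``(medoid_indices, labels, objective)`` where ``labels[i]`` is
    the position in ``medoid_indices`` of sample ``i``'s nearest medoid
    (ties toward the lowest medoid index).
    """
    from math import comb

    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")

    if comb(n, k) <= _EXACT_LIMIT:
        best_obj, best_medoids = np.inf, None
        for cand in combinations(range(n), k):
            obj = d[:, cand].min(axis=1).sum()
            if obj < best_obj - 1e-12:
                best_obj, best_medoids = obj, cand
        medoids = list(best_medoids)
        labels = np.argmin(d[:, medoids], axis=1)
        return medoids, labels, float(best_obj)

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of reductions in nearest-distance
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP
    best_obj = _objective(d, medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                obj = _objective(d, cand)
                if obj < best_obj - 1e-12:
                    best_obj = obj
                    best_swap = (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    return medoids, labels, _objective(d, medoids)


# ---------------------------------------------------------------------------
# Classical MDS embedding, PCoA, and the distance-based CH index


def _cmdscale(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical multidimensional scaling.

    Double-centers ``-d**2 / 2``, eigendecomposes, and returns coordinates
    for every strictly positive eigenvalue (descending) plus the
    eigenvalues themselves. Each axis's sign is fixed so its
    largest-magnitude loading is positive.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(evals.max(), 0.0))
    pos = evals > tol
    evals, evecs = evals[pos], evecs[:, pos]
    coords = evecs * np.sqrt(evals)
    for ax in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, ax])))
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return coords, evals


def pcoa(D: DistanceMatrix, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of the samples.

    Returns ``(coordinates, eigenvalues)``; coordinates have
    ``min(n_components, n_positive_eigenvalues)`` columns (truncation
    warns).
    """
    coords, evals = _cmdscale(D.d)
    if n_components > coords.shape[1]:
        warnings.warn(
            f"only {coords.shape[1]} positive eigenvalues; truncating "
            f"requested {n_components} components",
            stacklevel=2,
        )
        n_components = coords.shape[1]
    return coords[:, :n_components], evals


def ch_index(D: DistanceMatrix | np.ndarray, labels) -> float:
    """Calinski-Harabasz score of a labelling of a distance matrix.

    The matrix is embedded by classical MDS (all positive-eigenvalue axes)
    and the textbook Euclidean CH ratio [B/(k-1)] / [W/(n-k)] is evaluated
    on the embedding.
    """
    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n = d.shape[0]
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if len(uniq) >= n:
        raise ValueError("k must be smaller than the number of samples")
    coords, _ = _cmdscale(d)
    return float(calinski_harabasz_score(coords, labels))


def select_k(D: DistanceMatrix, k_min: int = 2, k_max: int | None = None) -> EnterotypeResult:
    """Run PAM for each candidate k and keep the clustering with the
    largest CH index (ties toward the smallest k)."""
    n = D.n
    if n <= 2:
        raise ValueError("need more than 2 samples")
    if k_max is None:
        k_max = min(10, n - 1)
    k_max = min(k_max, n - 1)
    ch_by_k: dict[int, float] = {}
    results: dict[int, tuple[list[int], np.ndarray, float]] = {}
    for k in range(k_min, k_max + 1):
        medoids, labels, obj = pam(D, k)
        ch_by_k[k] = ch_index(D, labels)
        results[k] = (medoids, labels, obj)
    best_k = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
    medoids, labels, obj = results[best_k]
    return EnterotypeResult(
        k=best_k,
        labels=labels,
        medoid_ids=[D.sample_ids[m] for m in medoids],
        ch_by_k=ch_by_k,
        objective=obj,
    )


def driver_genera(profiles: RelativeProfileSet, labels) -> tuple[dict[int, str], dict[int, float]]:
    """Per cluster, the genus with the highest mean relative abundance
    (ties toward the lexicographically smallest genus id), plus that mean."""
    labels = np.asarray(labels)
    drivers: dict[int, str] = {}
    abundances: dict[int, float] = {}
    order = np.argsort(np.asarray(profiles.genus_ids, dtype=object), kind="stable")
    for c in np.unique(labels):
        members = profiles.profiles[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c} is empty")
        means = members.mean(axis=0)
        best = order[int(np.argmax(means[order]))]  # lexicographic tie-break
        drivers[int(c)] = profiles.genus_ids[int(best)]
        abundances[int(c)] = float(means[best])
    return drivers, abundances


def annotate_drivers(result: EnterotypeResult, profiles: RelativeProfileSet) -> EnterotypeResult:
    drivers, abund = driver_genera(profiles, result.labels)
    result.driver_genus = drivers
    result.driver_abundance = abund
    return result
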