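"""Partitioning around medoids (PAM) with a randomized-null cluster-number
selection.

The clustering used throughout this package is the classic Kaufman–Rousseeuw
k-medoids algorithm: a greedy BUILD phase followed by a best-improvement SWAP
phase, with plain Euclidean distance on 3D micrometre coordinates. Cluster
number is selected by comparing the mean silhouette width of the real data at
each candidate k against the silhouettes obtained on spatially randomized
data (per-axis coordinate permutation, which preserves each marginal
distribution while destroying 3D association). The chosen k maximizes the
real-minus-null silhouette gap among the k whose real silhouette is within a
small tolerance of the best — a fixed, documented stand-in for the visual
inspection step a human analyst would perform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClusterResult",
    "SelectionReport",
    "pam",
    "silhouette_widths",
    "randomize_null",
    "select_k",
]

_TOL = 1e-9  # strict-improvement threshold for SWAP


@dataclass
class ClusterResult:
    """Result of one PAM run."""

    k: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    total_cost: float
    silhouette_per_point: np.ndarray | None = None
    mean_silhouette: float | None = None

    def validate(self, dist: np.ndarray | None = None) -> None:
        """Check internal consistency (medoid self-labels, cost)."""
        med = self.medoid_indices
        if not np.all(np.diff(med) > 0):
            raise ValueError("medoid_indices must be strictly increasing")
        for ci, m in enumerate(med):
            if self.labels[m] != ci:
                raise ValueError(f"medoid {m} not labelled with its own cluster")
        if dist is not None:
            cost = float(dist[np.arange(len(self.labels)), med[self.labels]].sum())
            if abs(cost - self.total_cost) > 1e-6 * max(1.0, cost):
                raise ValueError("total_cost inconsistent with assignments")


@dataclass
class SelectionReport:
    """Outcome of the randomized-null cluster-number selection."""

    k_grid: list[int]
    real_silhouette: dict[int, float]
    null_silhouettes: dict[int, list[float]]
    gap: dict[int, float]
    chosen_k: int
    seed: int
    results: dict[int, ClusterResult] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "k_grid": list(self.k_grid),
            "real_silhouette": {str(k): v for k, v in self.real_silhouette.items()},
            "null_silhouettes": {
                str(k): list(v) for k, v in self.null_silhouettes.items()
            },
            "gap": {str(k): v for k, v in self.gap.items()},
            "chosen_k": self.chosen_k,
            "seed": self.seed,
        }


def _distance_matrix(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    return squareform(pdist(points))


def _build(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: first medoid minimizes total distance; each subsequent
    medoid maximizes the reduction in total cost. Ties break to the lower
    point index."""
    n = len(dist)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    dn = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(dn[:, None] - dist, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        c = int(np.argmax(reduction))
        medoids.append(c)
        np.minimum(dn, dist[:, c], out=dn)
    return medoids


def _swap(dist: np.ndarray, medoids: list[int]) -> list[int]:
    """Best-improvement SWAP: evaluate every (medoid, non-medoid) exchange,
    apply the best strictly-improving one, repeat to convergence.

    The swap deltas for all pairs are computed vectorized from the nearest
    and second-nearest medoid distances; this reproduces exactly the classic
    exhaustive evaluation, only faster.
    """
    n = len(dist)
    k = len(medoids)
    if k >= n:
        return medoids
    while True:
        med = np.asarray(medoids)
        dm = dist[:, med]  # (n, k)
        nearest = np.argmin(dm, axis=1)
        rows = np.arange(n)
        dn = dm[rows, nearest]
        dm2 = dm.copy()
        dm2[rows, nearest] = np.inf
        ds = dm2.min(axis=1) if k > 1 else np.full(n, np.inf)

        cand = np.setdiff1d(rows, med, assume_unique=False)
        dh = dist[:, cand]  # (n, m)
        base = np.minimum(dh - dn[:, None], 0.0)
        base_sum = base.sum(axis=0)
        delta = np.empty((k, len(cand)))
        for a in range(k):
            mask = nearest == a
            if not mask.any():
                delta[a] = base_sum
                continue
            contrib = (
                np.minimum(dh[mask], ds[mask, None]) - dn[mask, None]
            ).sum(axis=0)
            delta[a] = base_sum - base[mask].sum(axis=0) + contrib
        flat = int(np.argmin(delta))
        if delta.flat[flat] >= -_TOL:
            return medoids
        a, h = divmod(flat, len(cand))
        medoids[a] = int(cand[h])


def pam(
    points: np.ndarray | None = None,
    k: int = 2,
    *,
    dist: np.ndarray | None = None,
    compute_silhouette: bool = True,
) -> ClusterResult:
    """Cluster points with PAM (k-medoids, BUILD + SWAP).

    Parameters
    ----------
    points:
        (n, d) coordinates in micrometres. May be omitted if ``dist`` is given.
    k:
        Number of clusters, ``1 <= k <= n``.
    dist:
        Optional precomputed (n, n) Euclidean distance matrix; supplying it
        lets callers reuse one matrix across many k.
    compute_silhouette:
        Fill the silhouette fields (requires ``2 <= k < n`` for a meaningful
        value; ``k == n`` yields the singleton convention of 0).

    The algorithm is deterministic given the input order. Point-to-medoid
    ties are resolved toward the lower medoid index.
    """
    if dist is None:
        if points is None:
            raise ValueError("either points or dist must be given")
        dist = _distance_matrix(points)
    n = len(dist)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    medoids = _swap(dist, _build(dist, k))
    med = np.array(sorted(medoids))
    labels = np.argmin(dist[:, med], axis=1)
    total_cost = float(dist[np.arange(n), med[labels]].sum())

    sil = mean_sil = None
    if compute_silhouette and k >= 2:
        sil, mean_sil = silhouette_widths(None, labels, dist=dist)
    return ClusterResult(
        k=k,
        labels=labels,
        medoid_indices=med,
        total_cost=total_cost,
        silhouette_per_point=sil,
        mean_silhouette=mean_sil,
    )


def silhouette_widths(
    points: np.ndarray | None,
    labels: np.ndarray,
    *,
    dist: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Kaufman–Rousseeuw silhouette widths.

    For point i with a(i) the mean distance to its own cluster (excluding
    itself) and b(i) the smallest mean distance to any other cluster,
    ``s(i) = (b - a) / max(a, b)``; members of singleton clusters get
    ``s(i) = 0``. Returns per-point widths and their mean.
    """
    if dist is None:
        dist = _distance_matrix(points)
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    masks = [labels == c for c in uniq]
    sizes = np.array([m.sum() for m in masks])
    # mean distance from every point to every cluster
    sums = np.stack([dist[:, m].sum(axis=1) for m in masks], axis=1)  # (n, C)
    s = np.zeros(n)
    for ci, mask in enumerate(masks):
        if sizes[ci] == 1:
            continue  # singleton convention: s = 0
        a = sums[mask, ci] / (sizes[ci] - 1)
        other = np.delete(sums[mask], ci, axis=1) / np.delete(sizes, ci)
        b = other.min(axis=1)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            si = np.where(denom > 0, (b - a) / denom, 0.0)
        s[mask] = si
    return s, float(s.mean())


def randomize_null(
    points: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Spatially randomize a point cloud by permuting each coordinate axis
    independently across points.

    The marginal distribution of every axis is preserved exactly (output
    columns are permutations of input columns) while all cross-axis
    association — and hence all genuine 3D clustering — is destroyed.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.empty_like(points)
    for j in range(points.shape[1]):
        out[:, j] = points[rng.permutation(len(points)), j]
    return out


def randomize_null_uniform(
    points: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Alternative null: points uniform in the data's axis-aligned bounding
    box. Looser than the permutation null (it also discards the marginal
    footprint of the organ); provided for comparison."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lo, hi = points.min(axis=0), points.max(axis=0)
    return rng.uniform(lo, hi, size=points.shape)


def select_k(
    points: np.ndarray,
    k_min: int = 2,
    k_max: int = 20,
    n_null: int = 10,
    seed: int = 0,
    *,
    eps: float = 0.01,
    null: str = "permute",
) -> SelectionReport:
    """Select the number of clusters by silhouette comparison against
    randomized data.

    For each k in ``[k_min, k_max]`` the real data and ``n_null`` randomized
    datasets are PAM-clustered and their mean silhouettes recorded. The
    candidate set is every k whose real silhouette is within ``eps`` of the
    maximum; among candidates the k with the widest real-minus-mean-null gap
    wins, ties going to the smaller k.

    The ``n_null`` randomized datasets are drawn once and each is clustered
    at every k, so their distance matrices are reused across the grid.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not 2 <= k_min <= k_max < n:
        raise ValueError("need 2 <= k_min <= k_max < n")
    if null not in ("permute", "uniform"):
        raise ValueError("null must be 'permute' or 'uniform'")
    randomizer = randomize_null if null == "permute" else randomize_null_uniform

    rng = np.random.default_rng(seed)
    dist_real = _distance_matrix(points)
    dists_null = [
        _distance_matrix(randomizer(points, rng)) for _ in range(n_null)
    ]

    k_grid = list(range(k_min, k_max + 1))
    real_sil: dict[int, float] = {}
    null_sils: dict[int, list[float]] = {}
    results: dict[int, ClusterResult] = {}
    for k in k_grid:
        res = pam(dist=dist_real, k=k)
        results[k] = res
        real_sil[k] = res.mean_silhouette
        null_sils[k] = [
            pam(dist=d, k=k).mean_silhouette for d in dists_null
        ]
    gap = {k: real_sil[k] - float(np.mean(null_sils[k])) for k in k_grid}

    best_sil = max(real_sil.values())
    candidates = [k for k in k_grid if real_sil[k] >= best_sil - eps]
    chosen = min(candidates, key=lambda k: (-gap[k], k))
    return SelectionReport(
        k_grid=k_grid,
        real_silhouette=real_sil,
        null_silhouettes=null_sils,
        gap=gap,
        chosen_k=chosen,
        seed=seed if isinstance(seed, int) else 0,
        results=results,
    )


def brute_force_pam_cost(dist: np.ndarray, k: int) -> float:
    """Exhaustive-enumeration optimum of the k-medoids objective (for
    oracle testing at small n): minimum over all C(n, k) medoid subsets of
    the summed point-to-nearest-medoid distance."""
    from itertools import combinations

    n = len(dist)
    best = np.inf
    for subset in combinations(range(n), k):
        cost = dist[:, subset].min(axis=1).sum()
        if cost < best:
            best = cost
    return float(best)
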