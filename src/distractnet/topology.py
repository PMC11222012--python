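"""Sparsity-thresholded binary graphs and global topology metrics.

A weighted connectivity matrix is binarized at a *sparsity* threshold s:
the round(s * n(n-1)/2) strongest off-diagonal weights become edges.
Features are computed over a sweep of sparsities (default 13%..47% in 1%
steps, 35 grid points) and aggregated by the normalized area under the
feature-vs-sparsity curve, making them threshold-robust.  Two admission
rules flag grid points: mean degree must exceed 2*log(n) (log base
configurable, default 10) and the small-world scalar sigma must exceed 1.1
against degree-preserving rewired null graphs.

Metric conventions on possibly disconnected graphs: the characteristic
path length averages over *reachable* pairs only (the disconnected-pair
fraction is logged); global efficiency counts disconnected pairs as zero
contribution; clustering and local efficiency give nodes with fewer than
two neighbors a zero contribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from distractnet.connectivity import ConnectivityMatrix, mean_strength

logger = logging.getLogger(__name__)

FEATURES: tuple[str, ...] = ("Lg", "Cg", "Eg", "El")


@dataclass
class BinaryAdjacency:
    """Symmetric 0/1 adjacency with zero diagonal at a given sparsity."""

    values: np.ndarray
    sparsity: float
    estimator: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.values)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.values = a.astype(np.uint8)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1).astype(int)


@dataclass(frozen=True)
class SparsitySweep:
    """Sparsity grid and admission-rule configuration."""

    s_min: float = 0.13
    s_max: float = 0.47
    step: float = 0.01
    log_base: float = 10.0
    sigma_threshold: float = 1.1
    n_null: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.s_min < self.s_max <= 1:
            raise ValueError(f"need 0 < s_min < s_max <= 1, got [{self.s_min}, {self.s_max}]")
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        return np.round(self.s_min + self.step * np.arange(n), 10)

    def degree_floor(self, n_nodes: int) -> float:
        return 2.0 * math.log(n_nodes) / math.log(self.log_base)


def _ranked_pairs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by weight descending, ties by (row, col)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_at_sparsity(
    mat: ConnectivityMatrix | np.ndarray, s: float, estimator: str = "", band: str = ""
) -> BinaryAdjacency:
    """Keep the round(s * n(n-1)/2) strongest off-diagonal weights as edges.

    Ties at the cut are broken deterministically by lexicographic
    (row, col) order after sorting by weight descending, so thresholded
    graphs are nested across increasing sparsity.
    """
    if isinstance(mat, ConnectivityMatrix):
        values, estimator, band = mat.values, mat.estimator, mat.band
    else:
        values = np.asarray(mat, dtype=float)
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must lie in (0, 1], got {s}")
    n = values.shape[0]
    n_possible = n * (n - 1) // 2
    n_edges = int(round(s * n_possible))
    ii, jj = _ranked_pairs(values)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:n_edges], jj[:n_edges]] = 1
    adj |= adj.T
    return BinaryAdjacency(adj, s, estimator, band)


def _dense_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of a small binary graph.

    Breadth-first expansion by boolean matrix products: at step d the
    newly reachable pairs get distance d.  O(diameter * n^3) bit
    operations — faster than sparse Dijkstra for the n <= ~128 graphs
    this pipeline works with.
    """
    n = a.shape[0]
    adj_b = a.astype(bool)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj_b] = 1.0
    known = adj_b | np.eye(n, dtype=bool)
    frontier = adj_b.copy()
    dist = 1
    while frontier.any():
        reach = frontier @ adj_b
        new = reach & ~known
        if not new.any():
            break
        dist += 1
        d[new] = dist
        known |= new
        frontier = new
    return d


def _distances(adj: BinaryAdjacency) -> np.ndarray:
    return _dense_distances(adj.values)


def char_path_length(adj: BinaryAdjacency) -> float:
    """Characteristic path length Lg: mean shortest path over reachable pairs."""
    if adj.n < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    d = _distances(adj)
    off = ~np.eye(adj.n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = int(off.sum())
    n_reach = int(finite.sum())
    if n_reach == 0:
        return float("inf")
    if n_reach < n_pairs:
        logger.debug(
            "Lg on disconnected graph: %.1f%% of pairs unreachable",
            100.0 * (1 - n_reach / n_pairs),
        )
    return float(d[finite].mean())


def clustering_coefficient(adj: BinaryAdjacency) -> float:
    """Mean over nodes of 2 e_x / (k_x (k_x - 1)); degree-<2 nodes count 0."""
    a = adj.values.astype(np.int64)
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a)  # 2 * e_x per node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(adj: BinaryAdjacency) -> float:
    """Mean inverse shortest path length; disconnected pairs contribute 0."""
    return _efficiency_from_distances(_distances(adj))


def local_efficiency(adj: BinaryAdjacency) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph."""
    a = adj.values
    effs = np.zeros(adj.n)
    for x in range(adj.n):
        nbrs = np.flatnonzero(a[x])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        effs[x] = _efficiency_from_distances(_dense_distances(sub))
    return float(effs.mean())


def _rewire(adj: np.ndarray, rng: np.random.Generator, swaps_per_edge: int = 10) -> np.ndarray:
    """Maslov-Sneppen degree-preserving rewiring.

    Attempts ``swaps_per_edge * n_edges`` double-edge swaps, skipping
    proposals that would create self-loops or multi-edges.  On saturated
    graphs (e.g. complete graphs) no swap is admissible and the graph is
    returned unchanged, which makes sigma exactly 1 there.
    """
    a = adj.copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    n_edges = len(edges)
    if n_edges < 2:
        return a
    target = swaps_per_edge * n_edges
    tries = 0
    done = 0
    max_tries = 20 * target
    while done < target and tries < max_tries:
        tries += 1
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        a2, b2 = edges[e2]
        if rng.random() < 0.5:
            a2, b2 = b2, a2
        # propose (a1, b2) and (a2, b1)
        if len({a1, b1, a2, b2}) < 4:
            continue
        if a[a1, b2] or a[a2, b1]:
            continue
        a[a1, b1] = a[b1, a1] = 0
        a[a2, b2] = a[b2, a2] = 0
        a[a1, b2] = a[b2, a1] = 1
        a[a2, b1] = a[b1, a2] = 1
        edges[e1] = (min(a1, b2), max(a1, b2))
        edges[e2] = (min(a2, b1), max(a2, b1))
        done += 1
    return a


def small_world_sigma(
    adj: BinaryAdjacency,
    n_null: int = 20,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> float:
    """Small-world scalar sigma = (Cg/C_rand) / (Lg/L_rand).

    ``C_rand`` and ``L_rand`` are means over ``n_null`` Maslov-Sneppen
    degree-preserving rewired null graphs; deterministic given ``seed``.
    Disconnected nulls use the same reachable-pair Lg convention.  Returns
    ``inf`` when the nulls are triangle-free but the graph is not.
    """
    if adj.n_edges < 1:
        raise ValueError("small-world sigma needs at least one edge")
    cg = clustering_coefficient(adj)
    lg = char_path_length(adj)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_null)
    l_rand = np.empty(n_null)
    for i in range(n_null):
        null = BinaryAdjacency(_rewire(adj.values, rng, swaps_per_edge), adj.sparsity)
        c_rand[i] = clustering_coefficient(null)
        l_rand[i] = char_path_length(null)
    c_bar, l_bar = c_rand.mean(), l_rand.mean()
    if c_bar == 0.0:
        return float("inf") if cg > 0 else 1.0
    if lg == 0.0 or not np.isfinite(l_bar):
        return float("nan")
    return float((cg / c_bar) / (lg / l_bar))


@dataclass
class SweepPoint:
    """One grid point of the sparsity sweep with admission flags."""

    sparsity: float
    adjacency: BinaryAdjacency
    mean_degree: float
    degree_ok: bool
    sigma: float | None = None
    sigma_ok: bool | None = None


def sweep_adjacencies(
    mat: ConnectivityMatrix | np.ndarray, sweep: SparsitySweep | None = None
) -> Iterator[tuple[float, BinaryAdjacency]]:
    sweep = sweep or SparsitySweep()
    for s in sweep.grid:
        yield float(s), threshold_at_sparsity(mat, float(s))


def sweep_and_validate(
    mat: ConnectivityMatrix | np.ndarray,
    sweep: SparsitySweep | None = None,
    seed: int = 0,
    compute_sigma: bool = True,
) -> list[SweepPoint]:
    """Threshold over the sparsity grid and record the two admission flags.

    Grid points failing the mean-degree > 2 log(n) rule or the sigma > 1.1
    rule are flagged, not dropped.  Sigma evaluation (the expensive part)
    can be switched off, leaving the flags unset.
    """
    sweep = sweep or SparsitySweep()
    points: list[SweepPoint] = []
    for s, adj in sweep_adjacencies(mat, sweep):
        mean_deg = float(adj.degrees.mean())
        degree_ok = mean_deg > sweep.degree_floor(adj.n)
        sigma = sigma_ok = None
        if compute_sigma:
            sigma = small_world_sigma(adj, n_null=sweep.n_null, seed=seed)
            sigma_ok = sigma > sweep.sigma_threshold
            if not sigma_ok:
                logger.debug("sparsity %.2f: sigma %.3f <= %.2f", s, sigma, sweep.sigma_threshold)
        points.append(SweepPoint(s, adj, mean_deg, degree_ok, sigma, sigma_ok))
    return points


def auc_average(grid: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal AUC of a feature curve normalized by the grid width.

    The normalization makes the scalar unit-compatible with the raw
    feature (a grid average).  A single grid point returns that value
    with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.shape != values.shape:
        raise ValueError(f"grid and values shapes differ: {grid.shape} vs {values.shape}")
    if grid.size == 0:
        raise ValueError("empty curve")
    if grid.size == 1:
        logger.warning("auc_average of a single point; returning the value itself")
        return float(values[0])
    return float(np.trapezoid(values, grid) / (grid[-1] - grid[0]))


@dataclass
class TopologyProfile:
    """Per-(estimator, band) topology feature curves and their AUC averages."""

    estimator: str
    band: str
    grid: np.ndarray
    curves: dict[str, np.ndarray]
    auc: dict[str, float]
    strength: float

    def as_features(self) -> dict[str, float]:
        """Flat feature dict: V plus the four AUC-aggregated metrics."""
        out = {f"{self.estimator}_{self.band}_V": self.strength}
        for feat in FEATURES:
            out[f"{self.estimator}_{self.band}_{feat}"] = self.auc[feat]
        return out

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "estimator": self.estimator,
                "band": self.band,
                "grid": self.grid.tolist(),
                "curves": {k: v.tolist() for k, v in self.curves.items()},
                "auc": self.auc,
                "strength": self.strength,
            },
            indent=1,
        )


def topology_profile(
    mat: ConnectivityMatrix, sweep: SparsitySweep | None = None
) -> TopologyProfile:
    """Compute the four feature curves over the sweep plus network strength V."""
    sweep = sweep or SparsitySweep()
    grid = sweep.grid
    curves: dict[str, list[float]] = {f: [] for f in FEATURES}
    for _, adj in sweep_adjacencies(mat, sweep):
        d = _distances(adj)
        off = ~np.eye(adj.n, dtype=bool)
        finite = np.isfinite(d) & off
        curves["Lg"].append(float(d[finite].mean()) if finite.any() else float("inf"))
        curves["Cg"].append(clustering_coefficient(adj))
        curves["Eg"].append(_efficiency_from_distances(d))
        curves["El"].append(local_efficiency(adj))
    arr = {f: np.asarray(v) for f, v in curves.items()}
    auc = {f: auc_average(grid, arr[f]) for f in FEATURES}
    return TopologyProfile(
        mat.estimator, mat.band, grid, arr, auc, mean_strength(mat)
    )
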