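"""Cost-thresholded binary brain networks and their graph attributes.

A weighted PLV matrix is binarized over a grid of cost (sparsity)
thresholds: at cost c the k = round(c * n(n-1)/2) strongest off-diagonal
weights become edges.  The grid spans the small-world regime
0.34 <= cost <= 0.73 in steps of 0.01 (the lower bound tracks the
2*ln(N)/N ~ 0.347 estimability guideline for N = 16 nodes).

Per cost the module computes four global attributes (clustering aCp,
characteristic path length aLp, global efficiency aEg, local efficiency
aEloc), three small-world indices against degree-matched Maslov-Sneppen
rewired nulls (aGamma = aCp/aCp_null, aLambda = aLp/aLp_null,
aSigma = aGamma/aLambda), and five nodal attributes (aNCp, aNLp, aNe,
aNLe, aDc).  Each attribute-versus-cost curve is collapsed to a single
feature by trapezoidal area under the curve, yielding per subject
8 bands x 7 global = 56 global and 8 x 5 x 16 = 640 nodal named features.

Conventions (binary undirected graphs throughout):
- disconnected pairs are excluded from path-length means and contribute
  zero to efficiency sums;
- nodal clustering and nodal local efficiency are zero for nodes with
  fewer than two neighbours;
- threshold tie-breaks use a fixed total order (weight descending, then
  row-major pair index) so edge sets are nested across costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PLVMatrix

__all__ = [
    "CostGraph",
    "GlobalMetrics",
    "NodalMetrics",
    "DEFAULT_COSTS",
    "GLOBAL_ATTRS",
    "NODAL_ATTRS",
    "binarize_at_cost",
    "global_metrics",
    "nodal_metrics",
    "rewired_null",
    "small_world_indices",
    "auc_over_costs",
    "metric_curves",
    "eeg_feature_vector",
]

#: Cost grid of the small-world regime: 0.34 ... 0.73, step 0.01 (40 points).
DEFAULT_COSTS: np.ndarray = np.round(np.arange(34, 74) / 100.0, 2)

GLOBAL_ATTRS: tuple[str, ...] = ("aCp", "aLp", "aEg", "aEloc", "aGamma", "aLambda", "aSigma")
NODAL_ATTRS: tuple[str, ...] = ("aNCp", "aNLp", "aNe", "aNLe", "aDc")

DEFAULT_N_NULL = 100


@dataclass
class CostGraph:
    """Binary undirected graph obtained at one cost threshold."""

    adjacency: np.ndarray  # (n, n) 0/1 symmetric, zero diagonal
    cost: float
    band_label: str = ""
    degenerate: bool = False  # set by rewired_null when no swap was possible

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class GlobalMetrics:
    aCp: float
    aLp: float  # NaN when no pair is connected
    aEg: float
    aEloc: float
    aGamma: float = np.nan
    aLambda: float = np.nan
    aSigma: float = np.nan


@dataclass
class NodalMetrics:
    aNCp: np.ndarray
    aNLp: np.ndarray
    aNe: np.ndarray
    aNLe: np.ndarray
    aDc: np.ndarray


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def pair_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs of a weight matrix in the fixed total order.

    Order: weight descending, ties broken by row-major pair index ascending.
    Returns (rows, cols) index arrays; taking a prefix of this order yields
    nested edge sets across costs.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    # stable sort on -w keeps the row-major order among ties
    order = np.argsort(-w, kind="stable")
    return iu[order], ju[order]


def binarize_at_cost(m: PLVMatrix, cost: float, band_label: str | None = None) -> CostGraph:
    """Retain the round(cost * n(n-1)/2) strongest off-diagonal weights as edges."""
    if not 0 < cost <= 1:
        raise ValueError("cost must be in (0, 1]")
    w = m.values
    n = w.shape[0]
    k = _round_half_up(cost * n * (n - 1) / 2)
    rows, cols = pair_order(w)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[rows[:k], cols[:k]] = 1
    adj |= adj.T
    return CostGraph(adj, cost=cost, band_label=band_label or m.band_label)


# ---------------------------------------------------------------------------
# metric kernels (plain numpy; hot path — called for every cost and null)
# ---------------------------------------------------------------------------

def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths of a binary graph (inf if disconnected)."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = adj.astype(bool) & ~reached
    d = 1
    while frontier.any():
        D[frontier] = d
        reached |= frontier
        nxt = (frontier.astype(np.uint8) @ adj) > 0
        frontier = nxt & ~reached
        d += 1
    return D


def _nodal_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering coefficient; zero for nodes of degree < 2."""
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * triangles per node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def _efficiency_terms(adj: np.ndarray) -> np.ndarray:
    """Matrix of 1/d_ij with zeros on the diagonal and for disconnected pairs."""
    D = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    return float(_efficiency_terms(adj).sum() / (n * (n - 1)))


def _clustering_and_pathlength(adj: np.ndarray) -> tuple[float, float]:
    """(mean nodal clustering, mean finite shortest path) — the null-model pair."""
    aCp = float(_nodal_clustering(adj).mean())
    D = _distances(adj)
    off = D[~np.eye(adj.shape[0], dtype=bool)]
    finite = off[np.isfinite(off)]
    aLp = float(finite.mean()) if finite.size else np.nan
    return aCp, aLp


def global_metrics(g: CostGraph) -> GlobalMetrics:
    """aCp, aLp, aEg, aEloc of a binary graph.

    aLp averages finite distances over ordered pairs (NaN for an edgeless
    graph); aEg averages 1/distance with zero for disconnected pairs; aEloc
    is the mean over nodes of the global efficiency of each node's
    neighbourhood subgraph.
    """
    adj = g.adjacency
    aCp, aLp = _clustering_and_pathlength(adj)
    aEg = _global_efficiency(adj)
    nodal_le = _nodal_local_efficiency(adj)
    return GlobalMetrics(aCp=aCp, aLp=aLp, aEg=aEg, aEloc=float(nodal_le.mean()))


def _nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    for i, nb in enumerate(nbrs):
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        out[i] = _global_efficiency(sub)
    return out


def nodal_metrics(g: CostGraph) -> NodalMetrics:
    """Per-node clustering, mean distance, efficiency, local efficiency, degree."""
    adj = g.adjacency
    n = adj.shape[0]
    D = _distances(adj)
    off_mask = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off_mask
    with np.errstate(invalid="ignore"):
        aNLp = np.where(
            finite.sum(axis=1) > 0,
            np.nansum(np.where(finite, D, np.nan), axis=1) / np.maximum(finite.sum(axis=1), 1),
            np.nan,
        )
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    aNe = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(
        aNCp=_nodal_clustering(adj),
        aNLp=aNLp,
        aNe=aNe,
        aNLe=_nodal_local_efficiency(adj),
        aDc=adj.sum(axis=1).astype(float),
    )


# ---------------------------------------------------------------------------
# degree-matched null models
# ---------------------------------------------------------------------------

def _edge_array(adj: np.ndarray) -> np.ndarray:
    rows, cols = np.where(np.triu(adj, k=1))
    return np.stack([rows, cols], axis=1)


def _rewire_once(
    adj: np.ndarray, rng: np.random.Generator, swap_factor: int = 10
) -> tuple[np.ndarray, bool]:
    """One Maslov-Sneppen degree-preserving rewiring of a binary graph.

    Performs at least ``swap_factor * n_edges`` successful double-edge swaps
    (or gives up after a proportional number of failed proposals, which only
    happens for swap-saturated graphs such as the complete graph).
    Returns (rewired adjacency, whether any swap succeeded).
    """
    n = adj.shape[0]
    edges: list[tuple[int, int]] = [
        (int(i), int(j)) for i, j in zip(*np.where(np.triu(adj, k=1)))
    ]
    eset = set(edges)
    m = len(edges)
    target = swap_factor * m
    max_tries = 100 * target
    swaps = tries = 0
    while swaps < target and tries < max_tries:
        batch = min(8192, max_tries - tries)
        e1 = rng.integers(0, m, size=batch).tolist()
        e2 = rng.integers(0, m, size=batch).tolist()
        flip = (rng.random(size=batch) < 0.5).tolist()
        for i, j, f in zip(e1, e2, flip):
            tries += 1
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if f:
                c, d = d, c
            # proposed new edges: (a, d) and (c, b)
            if a == d or c == b or a == c or b == d:
                continue
            new1 = (a, d) if a < d else (d, a)
            new2 = (c, b) if c < b else (b, c)
            if new1 in eset or new2 in eset:
                continue
            eset.remove(edges[i])
            eset.remove(edges[j])
            eset.add(new1)
            eset.add(new2)
            edges[i] = new1
            edges[j] = new2
            swaps += 1
            if swaps >= target:
                break
    A = np.zeros((n, n), dtype=np.uint8)
    if eset:
        rows, cols = zip(*eset)
        A[list(rows), list(cols)] = 1
        A |= A.T
    return A, swaps > 0


def rewired_null(
    g: CostGraph,
    n_rand: int = DEFAULT_N_NULL,
    seed: int = 0,
    swap_factor: int = 10,
) -> list[CostGraph]:
    """Ensemble of degree-matched random graphs via double-edge swaps.

    Every null has exactly the original degree sequence; connectedness is not
    enforced.  Graphs with no swappable edge pair are returned as flagged
    copies (``degenerate=True``) with a warning.
    """
    if g.n_edges < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(seed)
    out: list[CostGraph] = []
    for _ in range(n_rand):
        A, ok = _rewire_once(g.adjacency, rng, swap_factor)
        if not ok:
            warnings.warn("graph admits no degree-preserving swap; null equals input")
        out.append(CostGraph(A, cost=g.cost, band_label=g.band_label, degenerate=not ok))
    return out


def small_world_indices(
    g: CostGraph, ensemble: list[CostGraph]
) -> tuple[float, float, float]:
    """(aGamma, aLambda, aSigma) of a graph against a null ensemble.

    aGamma = aCp / mean null aCp, aLambda = aLp / mean null aLp,
    aSigma = aGamma / aLambda; NaN where a null mean is zero/undefined.
    """
    if not ensemble:
        raise ValueError("null ensemble is empty")
    aCp, aLp = _clustering_and_pathlength(g.adjacency)
    null_cp = []
    null_lp = []
    for h in ensemble:
        cp, lp = _clustering_and_pathlength(h.adjacency)
        null_cp.append(cp)
        null_lp.append(lp)
    mean_cp = float(np.mean(null_cp))
    mean_lp = float(np.nanmean(null_lp)) if np.any(np.isfinite(null_lp)) else np.nan
    gamma = aCp / mean_cp if mean_cp > 0 else np.nan
    lam = aLp / mean_lp if (np.isfinite(mean_lp) and mean_lp > 0) else np.nan
    sigma = gamma / lam if (np.isfinite(gamma) and np.isfinite(lam) and lam != 0) else np.nan
    return gamma, lam, sigma


# ---------------------------------------------------------------------------
# curves over the cost grid and AUC integration
# ---------------------------------------------------------------------------

def auc_over_costs(costs: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under an attribute-versus-cost curve.

    Non-finite points are excluded; with fewer than two finite points the
    feature is undefined (NaN), which the completeness filter later removes.
    """
    costs = np.asarray(costs, dtype=float)
    values = np.asarray(values, dtype=float)
    if costs.shape != values.shape or costs.ndim != 1:
        raise ValueError("costs and values must be 1-D of equal length")
    if costs.size >= 2 and np.any(np.diff(costs) <= 0):
        raise ValueError("costs must be strictly increasing")
    ok = np.isfinite(values)
    if ok.sum() < 2:
        return float("nan")
    return float(np.trapezoid(values[ok], costs[ok]))


def metric_curves(
    m: PLVMatrix,
    costs: np.ndarray = DEFAULT_COSTS,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """All attribute curves of one PLV matrix across the cost grid.

    Returns ``{"global": {attr: (n_costs,) array}, "nodal": {attr:
    (n_costs, n_nodes) array}}``.  The thresholded graphs are nested across
    costs (fixed tie-break order), and the small-world nulls (aGamma/aLambda)
    only require clustering and path length, which keeps the null loop cheap.
    """
    costs = np.asarray(costs, dtype=float)
    n = m.values.shape[0]
    n_pairs = n * (n - 1) // 2
    rows, cols = pair_order(m.values)
    rng = np.random.default_rng(seed)

    g_curves = {a: np.full(costs.size, np.nan) for a in GLOBAL_ATTRS}
    n_curves = {a: np.full((costs.size, n), np.nan) for a in NODAL_ATTRS}

    adj = np.zeros((n, n), dtype=np.uint8)
    k_prev = 0
    for ci, cost in enumerate(costs):
        k = _round_half_up(cost * n_pairs)
        if k > k_prev:
            r, c = rows[k_prev:k], cols[k_prev:k]
            adj[r, c] = 1
            adj[c, r] = 1
            k_prev = k
        g = CostGraph(adj.copy(), cost=float(cost), band_label=m.band_label)
        gm = global_metrics(g)
        nm = nodal_metrics(g)
        if n_null > 0 and g.n_edges >= 2:
            null_cp = np.empty(n_null)
            null_lp = np.empty(n_null)
            for t in range(n_null):
                A, _ = _rewire_once(adj, rng)
                null_cp[t], null_lp[t] = _clustering_and_pathlength(A)
            mean_cp = null_cp.mean()
            mean_lp = np.nanmean(null_lp)
            gm.aGamma = gm.aCp / mean_cp if mean_cp > 0 else np.nan
            gm.aLambda = gm.aLp / mean_lp if mean_lp > 0 else np.nan
            if np.isfinite(gm.aGamma) and np.isfinite(gm.aLambda) and gm.aLambda != 0:
                gm.aSigma = gm.aGamma / gm.aLambda
        for a in GLOBAL_ATTRS:
            g_curves[a][ci] = getattr(gm, a)
        for a in NODAL_ATTRS:
            n_curves[a][ci] = getattr(nm, a)
    return {"global": g_curves, "nodal": n_curves}


def eeg_feature_vector(
    band_plvs: dict[str, PLVMatrix],
    costs: np.ndarray = DEFAULT_COSTS,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> pd.Series:
    """Named AUC features of one subject across all bands.

    Requires all eight bands (seven subbands + whole).  Feature names follow
    ``band_attribute`` for global attributes and ``band_attribute_channel``
    for nodal ones, e.g. ``theta_aNLe_T6``; the full census is
    8 x 7 = 56 global plus 8 x 5 x 16 = 640 nodal names.
    """
    from .eeg_preprocess import DEFAULT_BANDS

    missing = [b for b in DEFAULT_BANDS if b not in band_plvs]
    if missing:
        raise ValueError(f"missing bands: {missing}")
    names: list[str] = []
    values: list[float] = []
    for bi, band in enumerate(DEFAULT_BANDS):
        m = band_plvs[band]
        curves = metric_curves(
            m, costs=costs, n_null=n_null, seed=int(np.random.default_rng([seed, bi]).integers(2**31))
        )
        for attr in GLOBAL_ATTRS:
            names.append(f"{band}_{attr}")
            values.append(auc_over_costs(costs, curves["global"][attr]))
        for attr in NODAL_ATTRS:
            for ch_i, ch in enumerate(m.channel_names):
                names.append(f"{band}_{attr}_{ch}")
                values.append(auc_over_costs(costs, curves["nodal"][attr][:, ch_i]))
    return pd.Series(values, index=names, dtype=float)
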