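"""Weighted global graph metrics for connectivity matrices and subnetworks.

All path-based quantities (efficiencies, characteristic path length,
betweenness) use the positive part of the weights with edge length = 1/weight;
negative weights enter only the negative strength, the signed modularity, and
functional complexity (via absolute values). Normalized clustering / path
length are referenced to an ensemble of surrogate graphs preserving the
positive-part degree sequence and weight multiset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .cartography import SignedGraph, louvain_consensus, signed_modularity


def _positive_part(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got {m.shape}")
    if np.max(np.abs(m - m.T)) > 1e-10:
        raise ValueError("matrix must be symmetric")
    w = np.clip((m + m.T) / 2.0, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w


def _distances(wpos: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(wpos > 0, 1.0 / wpos, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return dijkstra(lengths, directed=False)


# ---------------------------------------------------------------------------
# strengths / efficiencies / complexity
# ---------------------------------------------------------------------------

def strengths(matrix: np.ndarray) -> tuple[float, float]:
    """(S_pos, S_neg): mean node-level positive / negative strength.

    S_neg is reported as a magnitude (sum of |negative weights|).
    """
    m = np.asarray(matrix, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    s_pos = np.clip(m, 0.0, None).sum(axis=1).mean()
    s_neg = np.clip(-m, 0.0, None).sum(axis=1).mean()
    return float(s_pos), float(s_neg)


def global_efficiency(matrix: np.ndarray) -> float:
    """Mean over ordered node pairs of 1/d; disconnected pairs contribute 0."""
    wpos = _positive_part(matrix)
    n = wpos.shape[0]
    if n < 2:
        return 0.0
    if wpos.sum() == 0:
        warnings.warn("empty positive part: efficiency 0", stacklevel=2)
        return 0.0
    d = _distances(wpos)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(matrix: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced
    subgraph (weighted variant); nodes with < 2 neighbors contribute 0."""
    wpos = _positive_part(matrix)
    n = wpos.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(wpos[i] > 0)[0]
        if nb.size < 2:
            continue
        vals[i] = global_efficiency(wpos[np.ix_(nb, nb)])
    return float(vals.mean()) if n else 0.0


def efficiencies(matrix: np.ndarray) -> tuple[float, float]:
    return global_efficiency(matrix), local_efficiency(matrix)


def functional_complexity(
    matrix: np.ndarray, tau: float = 0.0, n_bins: int = 20
) -> float:
    """Similarity of the |connectivity| distribution to uniform, in [0, 1].

    Upper-triangle |w| >= tau are histogrammed into ``n_bins`` equal bins over
    [tau, 1]; complexity = 1 - D / D_max with D = sum_b |p_b - 1/n_bins| and
    D_max = 2 (n_bins - 1) / n_bins. Returns NaN (with a warning) when no
    edge survives the threshold.
    """
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    vals = np.abs(m[iu])
    vals = vals[vals >= tau]
    if vals.size == 0:
        warnings.warn(f"no edges with |w| >= {tau}: complexity undefined", stacklevel=2)
        return float("nan")
    counts, _ = np.histogram(np.clip(vals, tau, 1.0), bins=n_bins, range=(tau, 1.0))
    p = counts / counts.sum()
    d = np.abs(p - 1.0 / n_bins).sum()
    d_max = 2.0 * (n_bins - 1) / n_bins
    return float(1.0 - d / d_max)


# ---------------------------------------------------------------------------
# clustering / path length / small world
# ---------------------------------------------------------------------------

def onnela_clustering(matrix: np.ndarray) -> float:
    """Mean weighted clustering coefficient (Onnela: geometric-mean triangle
    weights normalized by the largest weight); nodes with degree < 2 count 0."""
    wpos = _positive_part(matrix)
    wmax = wpos.max()
    if wmax == 0:
        return 0.0
    w3 = np.cbrt(wpos / wmax)
    tri = np.diagonal(w3 @ w3 @ w3)
    k = (wpos > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def characteristic_path_length(matrix: np.ndarray) -> float:
    """Mean shortest-path length over finite off-diagonal pairs
    (infinite distances are excluded)."""
    wpos = _positive_part(matrix)
    d = _distances(wpos)
    mask = np.isfinite(d) & ~np.eye(d.shape[0], dtype=bool)
    if not mask.any():
        warnings.warn("no finite path between any pair", stacklevel=2)
        return float("nan")
    return float(d[mask].mean())


@dataclass
class NullEnsemble:
    """Degree-preserving, weight-multiset-preserving surrogate graphs."""

    matrices: list[np.ndarray] = field(repr=False)
    seed: int | None = None

    @property
    def n_nulls(self) -> int:
        return len(self.matrices)


def null_ensemble(
    matrix: np.ndarray, n_nulls: int = 100, seed: int | np.random.SeedSequence = 0
) -> NullEnsemble:
    """Surrogates that preserve the positive-part binary degree sequence
    (Maslov-Sneppen double-edge swaps) and reshuffle the positive weight
    multiset over the rewired edges."""
    wpos = _positive_part(matrix)
    n = wpos.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = wpos[iu][wpos[iu] > 0]
    g0 = nx.from_numpy_array((wpos > 0).astype(int))
    n_edges = g0.number_of_edges()
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    mats = []
    for child in root.spawn(n_nulls):
        rng = np.random.default_rng(child)
        g = g0.copy()
        if n_edges >= 2 and n >= 4:
            try:
                nx.double_edge_swap(
                    g,
                    nswap=4 * n_edges,
                    max_tries=400 * n_edges,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXException:
                # saturated topology (e.g. complete graph): keep edges,
                # reshuffling weights still randomizes the surrogate
                g = g0.copy()
        null = np.zeros_like(wpos)
        perm = rng.permutation(weights)
        for (u, v), w in zip(g.edges(), perm):
            null[u, v] = null[v, u] = w
        mats.append(null)
    return NullEnsemble(matrices=mats, seed=None)


def smallworld_suite(
    matrix: np.ndarray, null: NullEnsemble
) -> dict[str, float]:
    """C, L, and their null-normalized versions nC, nL, and SW = nC / nL."""
    if null.n_nulls == 0:
        raise ValueError("null ensemble is empty")
    c = onnela_clustering(matrix)
    length = characteristic_path_length(matrix)
    c_null = np.array([onnela_clustering(m) for m in null.matrices])
    l_null = np.array([characteristic_path_length(m) for m in null.matrices])
    nc = c / c_null.mean() if c_null.mean() > 0 else float("nan")
    nl = length / l_null.mean() if np.nanmean(l_null) > 0 else float("nan")
    sw = nc / nl if np.isfinite(nc) and np.isfinite(nl) and nl != 0 else float("nan")
    return {"C": float(c), "L": float(length), "nC": float(nc), "nL": float(nl), "SW": float(sw)}


def mean_betweenness(matrix: np.ndarray) -> float:
    """Mean unnormalized node betweenness (Brandes) with length = 1/weight."""
    wpos = _positive_part(matrix)
    g = nx.Graph()
    g.add_nodes_from(range(wpos.shape[0]))
    ii, jj = np.nonzero(np.triu(wpos, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / wpos[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return float(np.mean(list(bc.values())))


def modularity_metric(
    matrix: np.ndarray,
    gamma: float = 1.0,
    repetitions: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Q of the signed-Louvain consensus partition of the matrix."""
    graph = SignedGraph.from_weights(matrix)
    part = louvain_consensus(graph, gamma=gamma, repetitions=repetitions, seed=seed)
    return signed_modularity(graph, part)


# ---------------------------------------------------------------------------
# subnetworks and the full battery
# ---------------------------------------------------------------------------

def subnetwork_extract(
    matrix: np.ndarray, component_edges: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict the matrix to a component's edges.

    Returns ``(submatrix, nodes)`` where nodes are the regions incident to
    the component (sorted) and the submatrix keeps only component edges
    (everything else zeroed).
    """
    if not component_edges:
        raise ValueError("empty component")
    nodes = sorted({v for e in component_edges for v in e})
    index = {v: k for k, v in enumerate(nodes)}
    sub = np.zeros((len(nodes), len(nodes)))
    m = np.asarray(matrix, dtype=float)
    for i, j in component_edges:
        sub[index[i], index[j]] = sub[index[j], index[i]] = m[i, j]
    return sub, np.array(nodes)


def compute_metrics(
    matrix: np.ndarray,
    taus: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    n_nulls: int = 100,
    gamma: float = 1.0,
    louvain_repetitions: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, float]:
    """The full metric battery on one connectivity matrix."""
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    null_seed, q_seed = root.spawn(2)
    s_pos, s_neg = strengths(matrix)
    e_glob, e_loc = efficiencies(matrix)
    out = {
        "S_pos": s_pos,
        "S_neg": s_neg,
        "E_global": e_glob,
        "E_local": e_loc,
        "mBC": mean_betweenness(matrix),
        "Q": modularity_metric(
            matrix, gamma=gamma, repetitions=louvain_repetitions, seed=q_seed
        ),
    }
    for tau in taus:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f"complexity_tau{tau:g}"] = functional_complexity(matrix, tau)
    ens = null_ensemble(matrix, n_nulls=n_nulls, seed=null_seed)
    out.update(smallworld_suite(matrix, ens))
    return out
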