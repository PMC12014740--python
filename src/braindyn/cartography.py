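"""Signed community detection and cartographic profiling of windowed networks.

Each windowed correlation matrix is treated as a fully signed graph. Module
structure is found by maximizing an asymmetric signed modularity

    Q = (1/v+) sum_ij (w+_ij - g e+_ij) delta(M_i, M_j)
      - (1/(v+ + v-)) sum_ij (w-_ij - g e-_ij) delta(M_i, M_j)

where w+ / w- are the positive part and the magnitude of the negative part
of the weights, e^s_ij = s^s_i s^s_j / v^s is the per-sign configuration-model
expectation, v^s the full-matrix total weight of sign s, and g the resolution.
Positive edges are rewarded for falling within modules at full weight while
negative edges are penalized with the damped prefactor 1/(v+ + v-); this is
the standard asymmetric treatment for signed functional networks.

Given a partition, each node is placed on the (participation coefficient,
within-module degree z-score) plane; the joint histogram of all nodes is the
window's *cartographic profile*, summarizing how integrated (high, dispersed
participation) or segregated (low participation, strong within-module hubs)
the network is at that moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np

from .dfc import WindowedConnectivity


class ConsensusError(RuntimeError):
    """Consensus re-clustering failed to converge."""


@dataclass
class SignedGraph:
    """Symmetric signed weight matrix split into positive/negative parts."""

    wpos: np.ndarray  # positive part, >= 0
    wneg: np.ndarray  # magnitude of negative part, >= 0

    @classmethod
    def from_weights(cls, w: np.ndarray) -> "SignedGraph":
        w = np.asarray(w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got {w.shape}")
        if np.max(np.abs(w - w.T)) > 1e-10:
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        g = cls(wpos=np.clip(w, 0.0, None), wneg=np.clip(-w, 0.0, None))
        if g.vpos <= 0:
            raise ValueError("graph has no positive weight (v+ = 0)")
        return g

    @property
    def n_nodes(self) -> int:
        return self.wpos.shape[0]

    @property
    def vpos(self) -> float:
        return float(self.wpos.sum())

    @property
    def vneg(self) -> float:
        return float(self.wneg.sum())


@dataclass
class Partition:
    """Module assignment with contiguous ids starting at 0."""

    labels: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.size and not np.array_equal(uniq, np.arange(uniq.size)):
            # relabel to contiguous ids preserving order of first appearance
            _, self.labels = np.unique(self.labels, return_inverse=True)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class NodeCartography:
    """Per-node participation and within-module z-score for one window."""

    participation: np.ndarray  # B in [0, 1]
    within_module_z: np.ndarray  # W, dimensionless
    positive_strength: np.ndarray
    partition: Partition


@dataclass
class CartographicProfileSet:
    """One joint (B, W) histogram per window, plus the node values behind it."""

    histograms: np.ndarray  # (n_windows, b_bins, z_bins)
    b_edges: np.ndarray
    z_edges: np.ndarray
    cartographies: list[NodeCartography]

    @property
    def n_windows(self) -> int:
        return self.histograms.shape[0]

    def flattened(self) -> np.ndarray:
        """(n_windows, b_bins * z_bins) view for clustering."""
        return self.histograms.reshape(self.n_windows, -1)


# ---------------------------------------------------------------------------
# signed modularity
# ---------------------------------------------------------------------------

def _q_one_sign(w: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """sum_ij (w_ij - gamma * s_i s_j / v) delta(M_i, M_j), full-matrix sums."""
    s = w.sum(axis=1)
    v = s.sum()
    if v == 0:
        return 0.0
    nm = int(labels.max()) + 1
    within = 0.0
    mod_s = np.bincount(labels, weights=s, minlength=nm)
    for m in range(nm):
        idx = labels == m
        within += w[np.ix_(idx, idx)].sum()
    return within - gamma * float(mod_s @ mod_s) / v


def signed_modularity(graph: SignedGraph, partition: Partition, gamma: float | None = None) -> float:
    """Asymmetric signed modularity of a partition (see module docstring)."""
    g = partition.gamma if gamma is None else gamma
    labels = partition.labels
    if labels.shape[0] != graph.n_nodes:
        raise ValueError("partition does not cover all nodes")
    vpos, vneg = graph.vpos, graph.vneg
    qpos = _q_one_sign(graph.wpos, labels, g) / vpos
    if vneg > 0:
        qneg = _q_one_sign(graph.wneg, labels, g) / (vpos + vneg)
    else:
        qneg = 0.0
    return float(qpos - qneg)


# ---------------------------------------------------------------------------
# signed Louvain
# ---------------------------------------------------------------------------

def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules contiguously in order of first appearance, so that
    identical partitions compare equal regardless of internal module ids."""
    seen: dict[int, int] = {}
    out = np.empty(labels.shape[0], dtype=int)
    for i, v in enumerate(labels):
        v = int(v)
        if v not in seen:
            seen[v] = len(seen)
        out[i] = seen[v]
    return out


@numba.njit(cache=True)
def _local_move(wpos, wneg, gamma, seed, init_labels):  # pragma: no cover - compiled
    """One Louvain level: greedy node moves from a given starting partition.

    Works on matrices that may carry self-loops (aggregated levels); a node's
    self-loop follows it and cancels out of every move gain. A pass that
    improves the objective by less than a noise tolerance terminates the
    sweep, so near-tied assignments cannot ping-pong indefinitely.
    """
    np.random.seed(seed)
    n = wpos.shape[0]
    spos = np.zeros(n)
    sneg = np.zeros(n)
    for i in range(n):
        for j in range(n):
            spos[i] += wpos[i, j]
            sneg[i] += wneg[i, j]
    vpos = spos.sum()
    vneg = sneg.sum()
    labels = init_labels.copy()
    mod_spos = np.zeros(n)
    mod_sneg = np.zeros(n)
    for i in range(n):
        mod_spos[labels[i]] += spos[i]
        mod_sneg[labels[i]] += sneg[i]
    cpos = 2.0 / vpos
    cneg = 2.0 / (vpos + vneg) if vneg > 0 else 0.0
    min_gain = 1e-10
    pass_tol = 1e-7
    kpos = np.zeros(n)
    kneg = np.zeros(n)
    for _ in range(50):
        pass_gain = 0.0
        order = np.random.permutation(n)
        for oi in range(n):
            i = order[oi]
            c = labels[i]
            for m in range(n):
                kpos[m] = 0.0
                kneg[m] = 0.0
            for j in range(n):
                if j != i:
                    kpos[labels[j]] += wpos[i, j]
                    kneg[labels[j]] += wneg[i, j]
            best = -1
            best_gain = -1e300
            gain_c = 0.0
            for m in range(n):
                sp = mod_spos[m]
                sn = mod_sneg[m]
                if m == c:
                    sp -= spos[i]
                    sn -= sneg[i]
                g = cpos * (kpos[m] - gamma * spos[i] * sp / vpos)
                if vneg > 0:
                    g -= cneg * (kneg[m] - gamma * sneg[i] * sn / vneg)
                if m == c:
                    gain_c = g
                if g > best_gain:
                    best_gain = g
                    best = m
            if best != c and best_gain > gain_c + min_gain:
                mod_spos[c] -= spos[i]
                mod_sneg[c] -= sneg[i]
                mod_spos[best] += spos[i]
                mod_sneg[best] += sneg[i]
                labels[i] = best
                pass_gain += best_gain - gain_c
        if pass_gain <= pass_tol:
            break
    return labels


def _multi_level(
    wpos: np.ndarray,
    wneg: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    init: np.ndarray,
) -> np.ndarray:
    """Local moves from ``init`` followed by aggregation levels."""
    raw = _local_move(wpos, wneg, float(gamma), int(rng.integers(2**31)), init)
    _, node_labels = np.unique(raw, return_inverse=True)
    nm = int(node_labels.max()) + 1
    onehot = np.eye(nm)[node_labels]
    cur_pos = onehot.T @ wpos @ onehot
    cur_neg = onehot.T @ wneg @ onehot
    while cur_pos.shape[0] > 1:
        raw = _local_move(
            cur_pos, cur_neg, float(gamma), int(rng.integers(2**31)),
            np.arange(cur_pos.shape[0]),
        )
        _, labels = np.unique(raw, return_inverse=True)
        nm = int(labels.max()) + 1
        if nm == cur_pos.shape[0]:
            break
        onehot = np.eye(nm)[labels]
        cur_pos = onehot.T @ cur_pos @ onehot
        cur_neg = onehot.T @ cur_neg @ onehot
        node_labels = labels[node_labels]
    return node_labels


def _louvain_once(
    wpos: np.ndarray, wneg: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Multi-level Louvain with node-level refinement.

    After the aggregation levels converge, the partition is refined by a
    fresh round of node-level moves on the original graph (aggregation can
    lock individual nodes into early merges); refinement and re-aggregation
    alternate until the partition is stable.
    """
    wpos = np.ascontiguousarray(wpos, dtype=float)
    wneg = np.ascontiguousarray(wneg, dtype=float)
    node_labels = np.arange(wpos.shape[0])
    for _ in range(20):
        new_labels = _multi_level(wpos, wneg, gamma, rng, node_labels)
        if np.array_equal(
            _canonical_labels(new_labels), _canonical_labels(node_labels)
        ):
            break
        node_labels = new_labels
    return _canonical_labels(node_labels)


def louvain_partition(
    graph: SignedGraph, gamma: float = 1.0, seed: int | np.random.SeedSequence = 0
) -> Partition:
    """A single randomized Louvain run on the signed objective."""
    rng = np.random.default_rng(seed)
    return Partition(_louvain_once(graph.wpos, graph.wneg, gamma, rng), gamma=gamma)


def _agreement(label_runs: list[np.ndarray]) -> np.ndarray:
    n = label_runs[0].shape[0]
    a = np.zeros((n, n))
    for lab in label_runs:
        a += lab[:, None] == lab[None, :]
    a /= len(label_runs)
    np.fill_diagonal(a, 0.0)
    return a


def louvain_consensus(
    graph: SignedGraph,
    gamma: float = 1.0,
    repetitions: int = 100,
    seed: int | np.random.SeedSequence = 0,
    max_rounds: int = 20,
    tau: float = 0.5,
) -> Partition:
    """Consensus partition over repeated randomized Louvain runs.

    ``repetitions`` independent runs are combined into an agreement matrix
    (fraction of runs co-assigning each node pair); entries below ``tau``
    are zeroed and the thresholded matrix is re-clustered with the same
    algorithm, iterating until every run coincides. The result is
    deterministic for a given seed.
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )

    def _finalize(labels: np.ndarray) -> Partition:
        # the consensus of near-tied runs can be dominated in Q by one of
        # its constituent runs; since Q is the objective, return whichever
        # partition scores higher (consensus preferred on ties)
        consensus = Partition(labels, gamma=gamma)
        q_consensus = signed_modularity(graph, consensus)
        if best_run is not None and best_run_q > q_consensus + 1e-12:
            return Partition(best_run, gamma=gamma)
        return consensus

    best_run = None
    best_run_q = -np.inf
    wpos, wneg = graph.wpos, graph.wneg
    for round_idx in range(max_rounds):
        seeds = root.spawn(repetitions)
        runs = [
            _louvain_once(wpos, wneg, gamma, np.random.default_rng(s)) for s in seeds
        ]
        if round_idx == 0:
            for lab in runs:
                q = signed_modularity(graph, Partition(lab, gamma=gamma))
                if q > best_run_q:
                    best_run_q = q
                    best_run = lab
        first = runs[0]
        if all(np.array_equal(first, lab) for lab in runs[1:]):
            return _finalize(first)
        a = _agreement(runs)
        a[a < tau] = 0.0
        if a.sum() == 0:  # nothing co-assigns reliably: all singletons
            return _finalize(np.arange(graph.n_nodes))
        wpos, wneg = a, np.zeros_like(a)
        root = root.spawn(1)[0]
    raise ConsensusError(
        f"consensus did not converge within {max_rounds} rounds "
        f"(last round had {len({tuple(r) for r in runs})} distinct partitions)"
    )


# ---------------------------------------------------------------------------
# node roles
# ---------------------------------------------------------------------------

def participation_coefficient(graph: SignedGraph, partition: Partition) -> np.ndarray:
    """B_i = 1 - sum_s (K_is / K_i)^2 over positive weights.

    Nodes with zero positive strength get B = 0 by convention.
    """
    labels = partition.labels
    nm = partition.n_modules
    k_total = graph.wpos.sum(axis=1)
    onehot = np.eye(nm)[labels]
    k_per_module = graph.wpos @ onehot  # (n, nm)
    b = np.zeros(graph.n_nodes)
    nz = k_total > 0
    frac = k_per_module[nz] / k_total[nz, None]
    b[nz] = 1.0 - np.sum(frac**2, axis=1)
    return b


def within_module_zscore(graph: SignedGraph, partition: Partition) -> np.ndarray:
    """W_i = (K_is - mean_s) / sd_s with population SD over module members.

    Modules whose members all have equal within-module strength (including
    singletons) get W = 0 by convention.
    """
    labels = partition.labels
    w = np.zeros(graph.n_nodes)
    for m in range(partition.n_modules):
        idx = np.nonzero(labels == m)[0]
        k_within = graph.wpos[np.ix_(idx, idx)].sum(axis=1)
        sd = k_within.std()  # population SD
        if sd > 0:
            w[idx] = (k_within - k_within.mean()) / sd
    return w


def node_cartography(graph: SignedGraph, partition: Partition) -> NodeCartography:
    return NodeCartography(
        participation=participation_coefficient(graph, partition),
        within_module_z=within_module_zscore(graph, partition),
        positive_strength=graph.wpos.sum(axis=1),
        partition=partition,
    )


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def profile_bin_edges(
    b_bins: int = 50, z_bins: int = 50, z_range: tuple[float, float] = (-5.0, 5.0)
) -> tuple[np.ndarray, np.ndarray]:
    return np.linspace(0.0, 1.0, b_bins + 1), np.linspace(*z_range, z_bins + 1)


def cartographic_profile(
    cart: NodeCartography,
    b_edges: np.ndarray,
    z_edges: np.ndarray,
) -> np.ndarray:
    """Joint (B, W) histogram; out-of-range z values are clipped into the end
    bins so histogram mass always equals the node count."""
    b = np.clip(cart.participation, b_edges[0], b_edges[-1])
    z = np.clip(cart.within_module_z, z_edges[0], z_edges[-1])
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite cartography values")
    hist, _, _ = np.histogram2d(b, z, bins=[b_edges, z_edges])
    return hist


def window_cartography(
    wc: WindowedConnectivity,
    gamma: float = 1.0,
    repetitions: int = 100,
    seed: int | np.random.SeedSequence = 0,
    b_bins: int = 50,
    z_bins: int = 50,
    z_range: tuple[float, float] = (-5.0, 5.0),
) -> CartographicProfileSet:
    """Per-window consensus partition, node roles, and profile histograms."""
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    b_edges, z_edges = profile_bin_edges(b_bins, z_bins, z_range)
    hists = np.empty((wc.n_windows, b_bins, z_bins))
    carts: list[NodeCartography] = []
    for w, w_seed in enumerate(root.spawn(wc.n_windows)):
        graph = SignedGraph.from_weights(wc.matrices[w])
        part = louvain_consensus(graph, gamma=gamma, repetitions=repetitions, seed=w_seed)
        cart = node_cartography(graph, part)
        carts.append(cart)
        hists[w] = cartographic_profile(cart, b_edges, z_edges)
    return CartographicProfileSet(
        histograms=hists, b_edges=b_edges, z_edges=z_edges, cartographies=carts
    )
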