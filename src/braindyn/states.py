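"""Integrated/segregated state extraction from cartographic profiles.

Each subject's per-window profiles are clustered (k = 2) with k-means under
the correlation distance d(x, y) = 1 - corr(x, y). The cluster whose windows
have the higher mean participation coefficient is the *integrated* state;
the other is *segregated*. State-specific connectivity centroids are computed
on the Fisher-z scale and back-transformed, and the binary state sequence is
summarized by five dynamic measures: fraction time, dwell time, total
transitions, sample entropy, and Lempel-Ziv complexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_samples

from .cartography import CartographicProfileSet
from .dfc import WindowedConnectivity

INTEGRATED, SEGREGATED = "integrated", "segregated"


class DegenerateProfilesError(ValueError):
    """Profiles cannot be clustered under correlation distance."""


@dataclass
class StateResult:
    """Per-subject state decomposition."""

    state_labels: np.ndarray = field(repr=False)  # 'integrated'/'segregated' per window
    centroids: dict = field(repr=False)  # state -> region x region matrix
    mean_participation: dict  # state -> mean node participation over its windows
    dynamics: dict  # measure name -> value or {state: value}
    degenerate: bool = False


# ---------------------------------------------------------------------------
# correlation-distance k-means
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so that
    ||u - v||^2 / 2 = 1 - corr(x, y)."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = np.nonzero(norms.ravel() == 0)[0][:5].tolist()
        raise DegenerateProfilesError(
            f"constant (zero-variance) profile vector(s) at window(s) {bad}: "
            "correlation distance undefined"
        )
    return centered / norms

def correlation_distance_matrix(x: np.ndarray) -> np.ndarray:
    u = _standardize_rows(np.asarray(x, dtype=float))
    d = 1.0 - u @ u.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _lloyd(u: np.ndarray, init_idx: np.ndarray, max_iter: int = 100):
    """Lloyd iterations in the standardized space; returns labels, inertia.

    Returns None on an empty cluster so the caller can re-seed the restart.
    """
    k = init_idx.size
    centers = u[init_idx].copy()
    labels = None
    for _ in range(max_iter):
        sim = u @ centers.T  # corr with each center
        new_labels = np.argmax(sim, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = u[labels == c]
            if members.shape[0] == 0:
                return None
            m = members.mean(axis=0)
            m -= m.mean()
            norm = np.linalg.norm(m)
            if norm == 0:
                return None
            centers[c] = m / norm
    inertia = float(np.sum(1.0 - np.einsum("ij,ij->i", u, centers[labels])))
    return labels, centers, inertia


def kmeans_profiles(
    profiles: CartographicProfileSet | np.ndarray,
    k: int = 2,
    restarts: int = 300,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """k-means on flattened profiles with correlation distance.

    Best of ``restarts`` random initializations by total within-cluster
    distance. Returns ``(labels, centroids, degenerate)`` where ``centroids``
    are in the standardized (zero-mean, unit-norm) space and ``degenerate``
    flags inputs whose profiles are all perfectly correlated (everything is
    then assigned to cluster 0).
    """
    x = profiles.flattened() if isinstance(profiles, CartographicProfileSet) else profiles
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    u = _standardize_rows(x)
    distinct = np.unique(np.round(u, 12), axis=0).shape[0]
    if distinct < k:
        if k == 2 and distinct == 1:
            warnings.warn(
                "all profiles identical up to positive scaling: degenerate run, "
                "single cluster returned",
                stacklevel=2,
            )
            return np.zeros(n, dtype=int), u[:1].copy(), True
        raise DegenerateProfilesError(
            f"only {distinct} distinct profiles for k = {k}"
        )
    rng = np.random.default_rng(seed)
    best = None
    attempts = 0
    done = 0
    while done < restarts:
        attempts += 1
        if attempts > restarts * 20:
            raise DegenerateProfilesError("could not find a non-empty clustering")
        init = rng.choice(n, size=k, replace=False)
        res = _lloyd(u, init)
        if res is None:  # empty cluster: re-seed this restart
            continue
        done += 1
        labels, centers, inertia = res
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centers, inertia)
    return best[0], best[1], False


# ---------------------------------------------------------------------------
# labeling, centroids
# ---------------------------------------------------------------------------

def label_states(
    labels: np.ndarray, profiles: CartographicProfileSet
) -> dict[int, str]:
    """Map the two k-means clusters to integrated/segregated.

    The cluster whose windows have the higher mean participation coefficient
    is integrated. An exact tie is broken toward the lower cluster index
    (with a warning).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size != 2:
        raise ValueError(f"state labeling requires exactly 2 clusters, got {clusters.size}")
    mean_b = {}
    for c in clusters:
        windows = np.nonzero(labels == c)[0]
        mean_b[int(c)] = float(
            np.mean([profiles.cartographies[w].participation.mean() for w in windows])
        )
    c0, c1 = (int(c) for c in clusters)
    if mean_b[c0] == mean_b[c1]:
        warnings.warn(
            "clusters have exactly equal mean participation; tie-break: "
            f"cluster {min(c0, c1)} -> integrated",
            stacklevel=2,
        )
        integrated = min(c0, c1)
    else:
        integrated = c0 if mean_b[c0] > mean_b[c1] else c1
    other = c1 if integrated == c0 else c0
    return {integrated: INTEGRATED, other: SEGREGATED}


def fisher_z_mean(matrices: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """tanh(mean(atanh(r))) per entry, with r clipped to +/-(1 - clip)."""
    z = np.arctanh(np.clip(matrices, -1.0 + clip, 1.0 - clip))
    out = np.tanh(z.mean(axis=0))
    np.fill_diagonal(out, 1.0)
    return out


def state_centroids(
    wc: WindowedConnectivity, state_labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-state Fisher-z average connectivity matrices."""
    state_labels = np.asarray(state_labels)
    if state_labels.shape[0] != wc.n_windows:
        raise ValueError("one state label per window required")
    out = {}
    for state in np.unique(state_labels):
        mask = state_labels == state
        if not mask.any():
            raise ValueError(f"state {state!r} has no windows")
        out[str(state)] = fisher_z_mean(wc.matrices[mask])
    return out


# ---------------------------------------------------------------------------
# silhouette scan
# ---------------------------------------------------------------------------

def silhouette_scan(
    profiles: CartographicProfileSet | np.ndarray,
    k_range: range = range(2, 8),
    restarts: int = 50,
    seed: int | np.random.SeedSequence = 0,
) -> dict[int, float]:
    """Mean silhouette (correlation distance) for each k.

    Points in singleton clusters are excluded from the mean (warning).
    """
    x = profiles.flattened() if isinstance(profiles, CartographicProfileSet) else profiles
    x = np.asarray(x, dtype=float)
    if max(k_range) > x.shape[0]:
        raise ValueError(
            f"k up to {max(k_range)} requested but only {x.shape[0]} windows"
        )
    d = correlation_distance_matrix(x)
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    scores: dict[int, float] = {}
    for k, k_seed in zip(k_range, root.spawn(len(k_range))):
        labels, _, degenerate = kmeans_profiles(x, k=k, restarts=restarts, seed=k_seed)
        if degenerate:
            scores[k] = float("nan")
            continue
        sizes = np.bincount(labels)
        keep = sizes[labels] > 1
        if not keep.all():
            warnings.warn(
                f"k={k}: {np.sum(~keep)} point(s) in singleton clusters excluded "
                "from the silhouette mean",
                stacklevel=2,
            )
        s = silhouette_samples(d, labels, metric="precomputed")
        scores[k] = float(s[keep].mean())
    return scores


# ---------------------------------------------------------------------------
# dynamic measures
# ---------------------------------------------------------------------------

def _runs(seq: np.ndarray) -> list[tuple[int, int]]:
    """(value, length) run-length encoding."""
    change = np.nonzero(np.diff(seq))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [seq.size]])
    return [(int(seq[s]), int(e - s)) for s, e in zip(starts, ends)]


def sample_entropy(seq: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy with template length m, tolerance r = r_factor * SD,
    Chebyshev distance. A constant sequence returns 0 by convention; an
    undefined ratio (no template matches) returns NaN with a warning."""
    x = np.asarray(seq, dtype=float)
    n = x.size
    if n < m + 2:
        warnings.warn("sequence too short for sample entropy; returning NaN", stacklevel=2)
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    counts = []
    for length in (m, m + 1):
        templ = np.lib.stride_tricks.sliding_window_view(x, length)[: n - m]
        dist = np.max(
            np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1
        )
        match = dist <= r
        np.fill_diagonal(match, False)
        counts.append(match.sum())
    b, a = counts
    if a == 0 or b == 0:
        warnings.warn(
            "sample entropy undefined (zero template or match count)", stacklevel=2
        )
        return float("nan")
    return float(-np.log(a / b))


def lempel_ziv(seq: np.ndarray) -> tuple[int, float]:
    """LZ76 exhaustive-history phrase count and its n/log2(n) normalization."""
    s = "".join(str(int(v)) for v in seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    if n == 1:
        return 1, 1.0
    # Kaspar-Schuster exhaustive-history parsing
    c, i, k, k_max, l = 1, 0, 1, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    norm = c / (n / np.log2(n))
    return c, float(norm)


def dynamics_measures(
    state_labels: np.ndarray,
    integrated: str = INTEGRATED,
    segregated: str = SEGREGATED,
) -> dict:
    """The five dynamic measures of a binary state sequence.

    fraction_time and dwell_time (mean run length, window units) are per
    state; total_transitions counts label changes; sample entropy and
    Lempel-Ziv complexity are computed on the binary sequence directly
    (integrated = 1).
    """
    labels = np.asarray(state_labels)
    if labels.size < 2:
        raise ValueError("state sequence must have length >= 2")
    states = (integrated, segregated)
    binary = (labels == integrated).astype(int)
    runs = _runs(binary)
    frac = {s: float(np.mean(labels == s)) for s in states}
    dwell = {}
    for s, v in ((integrated, 1), (segregated, 0)):
        lengths = [ln for val, ln in runs if val == v]
        dwell[s] = float(np.mean(lengths)) if lengths else float("nan")
    transitions = len(runs) - 1
    lz_count, lz_norm = lempel_ziv(binary)
    return {
        "fraction_time": frac,
        "dwell_time": dwell,
        "total_transitions": int(transitions),
        "sample_entropy": sample_entropy(binary),
        "lempel_ziv_phrases": lz_count,
        "lempel_ziv": lz_norm,
    }


# ---------------------------------------------------------------------------
# subject-level assembly
# ---------------------------------------------------------------------------

def subject_states(
    wc: WindowedConnectivity,
    profiles: CartographicProfileSet,
    restarts: int = 300,
    seed: int | np.random.SeedSequence = 0,
) -> StateResult:
    """Cluster one subject's profiles and assemble the full state result."""
    labels, _, degenerate = kmeans_profiles(profiles, k=2, restarts=restarts, seed=seed)
    if degenerate:
        state_labels = np.array([SEGREGATED] * wc.n_windows)
        cents = state_centroids(wc, state_labels)
        mean_b = {
            SEGREGATED: float(
                np.mean([c.participation.mean() for c in profiles.cartographies])
            )
        }
        return StateResult(
            state_labels=state_labels,
            centroids=cents,
            mean_participation=mean_b,
            dynamics={},
            degenerate=True,
        )
    mapping = label_states(labels, profiles)
    state_labels = np.array([mapping[int(c)] for c in labels])
    cents = state_centroids(wc, state_labels)
    mean_b = {}
    for cluster, state in mapping.items():
        wins = np.nonzero(labels == cluster)[0]
        mean_b[state] = float(
            np.mean([profiles.cartographies[w].participation.mean() for w in wins])
        )
    return StateResult(
        state_labels=state_labels,
        centroids=cents,
        mean_participation=mean_b,
        dynamics=dynamics_measures(state_labels),
    )
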