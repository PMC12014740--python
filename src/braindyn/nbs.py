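"""Network-based statistic with edgewise ANCOVA and permutation FWE control.

Edgewise group differences in state-specific connectivity centroids are
tested on the Fisher-z scale with a partial F test for the group term given
nuisance covariates (age, sex, education, mean framewise displacement).
Edges passing a forming threshold on the edgewise p-value are collected into
connected components; the size (edge count, i.e. extent) of the largest
observed component is referred to a permutation null distribution built with
Freedman-Lane residual permutation, yielding a family-wise-corrected p-value
per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .io_core import AtlasTable, SubjectTable


@dataclass
class DesignMatrix:
    """Group indicator plus nuisance covariates (and an intercept)."""

    group: np.ndarray  # 1 = case, 0 = control
    covariates: np.ndarray  # (n, n_cov)
    covariate_names: tuple[str, ...] = ("age", "sex", "education", "mean_fd")

    @classmethod
    def from_subject_table(
        cls,
        subjects: SubjectTable,
        covariates: tuple[str, ...] = ("age", "sex", "education", "mean_fd"),
    ) -> "DesignMatrix":
        return cls(
            group=subjects.group_indicator(),
            covariates=subjects.covariate_matrix(covariates),
            covariate_names=covariates,
        )

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 2 or self.covariates.shape[0] != self.group.shape[0]:
            raise ValueError("covariates must be (n_subjects, n_covariates)")
        full = self.full()
        rank = np.linalg.matrix_rank(full)
        if rank < full.shape[1]:
            names = ("intercept", "group", *self.covariate_names)
            raise ValueError(
                f"rank-deficient design (rank {rank} < {full.shape[1]} columns "
                f"{names}); check for collinear covariates"
            )

    @property
    def n_subjects(self) -> int:
        return self.group.shape[0]

    def full(self) -> np.ndarray:
        n = self.n_subjects
        return np.column_stack([np.ones(n), self.group, self.covariates])

    def reduced(self) -> np.ndarray:
        """Covariates-only (nuisance) design."""
        n = self.n_subjects
        return np.column_stack([np.ones(n), self.covariates])


@dataclass
class NbsComponent:
    edges: list[tuple[int, int]]
    size: int
    p_fwe: float


@dataclass
class NbsResult:
    f_matrix: np.ndarray = field(repr=False)
    p_matrix: np.ndarray = field(repr=False)
    forming_threshold: float
    components: list[NbsComponent]
    n_permutations: int
    max_null_sizes: np.ndarray = field(repr=False)
    difference_matrix: np.ndarray = field(repr=False)  # tanh(mean z case - control)
    min_attainable_p: float = 1.0

    def significant_components(self, alpha: float = 0.05) -> list[NbsComponent]:
        return [c for c in self.components if c.p_fwe < alpha]


# ---------------------------------------------------------------------------
# edgewise ANCOVA
# ---------------------------------------------------------------------------

def _residual_maker(x: np.ndarray) -> np.ndarray:
    """I - X (X'X)^-1 X' via a pseudoinverse (numerically stable)."""
    n = x.shape[0]
    return np.eye(n) - x @ np.linalg.pinv(x)


def _partial_f(y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray):
    """Vectorized partial F for the columns dropped in x_reduced.

    y is (n_subjects, n_outcomes); returns (F, p) over outcomes with
    df = (q, n - p_full) where q = p_full - p_reduced.
    """
    n, p_full = x_full.shape
    q = p_full - x_reduced.shape[1]
    rss_full = np.sum((_residual_maker(x_full) @ y) ** 2, axis=0)
    rss_red = np.sum((_residual_maker(x_reduced) @ y) ** 2, axis=0)
    df2 = n - p_full
    if df2 <= 0:
        raise ValueError(f"not enough subjects ({n}) for {p_full} design columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / q) / (rss_full / df2)
    f = np.where(rss_full <= 0, np.inf, f)
    f = np.clip(f, 0.0, None)
    p = stats.f.sf(f, q, df2)
    return f, p


def _edge_z(centroids: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """Upper-triangle Fisher-z edges per subject: (n_subjects, n_edges)."""
    n_regions = centroids.shape[1]
    iu = np.triu_indices(n_regions, k=1)
    r = np.clip(centroids[:, iu[0], iu[1]], -1.0 + clip, 1.0 - clip)
    return np.arctanh(r)


def edgewise_ancova(
    centroids: np.ndarray | list[np.ndarray], design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Partial F (group | covariates) per edge on Fisher-z centroid edges.

    Returns symmetric region x region F and p matrices (diagonal 0 / 1).
    """
    centroids = np.asarray(centroids, dtype=float)
    n_sub, n_regions = centroids.shape[0], centroids.shape[1]
    for g, count in (("case", design.group.sum()), ("control", (1 - design.group).sum())):
        if count < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}, got {int(count)}")
    if n_sub != design.n_subjects:
        raise ValueError("centroid count does not match design rows")
    y = _edge_z(centroids)
    f, p = _partial_f(y, design.full(), design.reduced())
    iu = np.triu_indices(n_regions, k=1)
    f_mat = np.zeros((n_regions, n_regions))
    p_mat = np.ones((n_regions, n_regions))
    f_mat[iu] = f
    p_mat[iu] = p
    f_mat += f_mat.T
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)
    return f_mat, p_mat


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def nbs_components(
    p_matrix: np.ndarray, forming_threshold: float = 0.05
) -> list[list[tuple[int, int]]]:
    """Connected components (edge lists) among suprathreshold edges."""
    p_matrix = np.asarray(p_matrix)
    if np.max(np.abs(p_matrix - p_matrix.T)) > 1e-10:
        raise ValueError("p matrix must be symmetric")
    n = p_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = p_matrix[iu] < forming_threshold
    g = nx.Graph()
    g.add_edges_from(
        (int(i), int(j)) for i, j, m in zip(iu[0], iu[1], mask) if m
    )
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comps.append(sorted((min(u, v), max(u, v)) for u, v in sub.edges()))
    comps.sort(key=lambda edges: (-len(edges), edges))
    return comps


def _max_component_size(p_matrix: np.ndarray, threshold: float) -> int:
    comps = nbs_components(p_matrix, threshold)
    return len(comps[0]) if comps else 0


# ---------------------------------------------------------------------------
# permutation FWE
# ---------------------------------------------------------------------------

def nbs_fwe(
    centroids: np.ndarray | list[np.ndarray],
    design: DesignMatrix,
    forming_threshold: float = 0.05,
    n_permutations: int = 5000,
    seed: int | np.random.SeedSequence = 0,
) -> NbsResult:
    """Full NBS: observed components vs. a Freedman-Lane permutation null.

    Under Freedman-Lane, residuals of the nuisance-only model are permuted
    and added back to the nuisance fit, and the full-model partial F is
    recomputed; the null statistic is the largest suprathreshold component
    size. Component p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    centroids = np.asarray(centroids, dtype=float)
    f_mat, p_mat = edgewise_ancova(centroids, design)
    comps = nbs_components(p_mat, forming_threshold)

    x_full = design.full()
    x_red = design.reduced()
    y = _edge_z(centroids)
    hat_red = x_red @ np.linalg.pinv(x_red)
    fitted = hat_red @ y
    resid = y - fitted

    rng = np.random.default_rng(seed)
    n = design.n_subjects
    n_regions = centroids.shape[1]
    iu = np.triu_indices(n_regions, k=1)
    max_sizes = np.empty(n_permutations, dtype=int)
    p_perm = np.ones((n_regions, n_regions))
    for b in range(n_permutations):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        _, p_edges = _partial_f(y_star, x_full, x_red)
        p_perm[iu] = p_edges
        p_sym = np.minimum(p_perm, p_perm.T)
        np.fill_diagonal(p_sym, 1.0)
        max_sizes[b] = _max_component_size(p_sym, forming_threshold)

    components = []
    for edges in comps:
        size = len(edges)
        p_fwe = (1 + int(np.sum(max_sizes >= size))) / (1 + n_permutations)
        components.append(NbsComponent(edges=edges, size=size, p_fwe=p_fwe))

    # signed group difference (case - control) on back-transformed edges
    z = np.arctanh(np.clip(centroids, -1 + 1e-7, 1 - 1e-7))
    for m in z:
        np.fill_diagonal(m, 0.0)
    case = design.group == 1
    diff = np.tanh(z[case].mean(axis=0) - z[~case].mean(axis=0))
    np.fill_diagonal(diff, 0.0)

    return NbsResult(
        f_matrix=f_mat,
        p_matrix=p_mat,
        forming_threshold=forming_threshold,
        components=components,
        n_permutations=n_permutations,
        max_null_sizes=max_sizes,
        difference_matrix=diff,
        min_attainable_p=1.0 / (1 + n_permutations),
    )


# ---------------------------------------------------------------------------
# regional / network-level aggregation
# ---------------------------------------------------------------------------

def regional_edge_counts(
    component_edges: list[tuple[int, int]], n_regions: int
) -> np.ndarray:
    """Count of incident component edges per region."""
    counts = np.zeros(n_regions, dtype=int)
    for i, j in component_edges:
        if not (0 <= i < n_regions and 0 <= j < n_regions):
            raise ValueError(f"edge ({i}, {j}) references an unknown region")
        counts[i] += 1
        counts[j] += 1
    return counts


def network_edge_counts(
    component_edges: list[tuple[int, int]], atlas: AtlasTable
) -> tuple[np.ndarray, list[str]]:
    """Within/between-network significant-edge count matrix.

    Returns a symmetric n_networks x n_networks matrix whose (a, b) cell is
    the number of component edges joining networks a and b, and the ordered
    network labels.
    """
    nets = sorted(set(atlas.networks))
    index = {n: k for k, n in enumerate(nets)}
    mat = np.zeros((len(nets), len(nets)), dtype=int)
    for i, j in component_edges:
        if not (0 <= i < atlas.n_regions and 0 <= j < atlas.n_regions):
            raise ValueError(f"edge ({i}, {j}) references an unknown region")
        a, b = index[atlas.networks[i]], index[atlas.networks[j]]
        mat[a, b] += 1
        if a != b:
            mat[b, a] += 1
    return mat, nets
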