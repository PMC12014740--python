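"""Group statistics on graph metrics and spatially constrained map couplings.

Regional quantities derived from the NBS stage (significant-edge counts) are
correlated with per-region density maps using Spearman's rank correlation.
Significance must respect spatial autocorrelation, so the null distribution
is built by *spin* permutations for cortical parcels — random rotations of
the parcel coordinate sphere (mirrored between hemispheres) followed by a
one-to-one nearest-parcel reassignment, so every null map is a permutation of
the observed values — and by value shuffling within each hemisphere for
subcortical parcels. Group comparisons of scalar metrics reuse the partial-F
ANCOVA engine; consumption-pattern couplings use Pearson partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .io_core import AtlasTable
from .nbs import DesignMatrix, _partial_f


@dataclass
class AssociationResult:
    rho: float
    p_value: float
    scheme: str  # 'spin' | 'hemisphere-shuffle' | 'spin+shuffle'
    n_permutations: int
    p_fdr: float | None = None


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def spearman_map_association(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; constant inputs are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("maps must be aligned 1-D vectors")
    if x.size < 5:
        raise ValueError("need at least 5 regions")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant map: rank correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def _null_rhos(rank_x: np.ndarray, rank_y: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pearson correlation of permuted rank_x rows with rank_y, vectorized."""
    rx = rank_x[perms]  # (n_perm, n)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = rank_y - rank_y.mean()
    denom = np.linalg.norm(rx, axis=1) * np.linalg.norm(ry)
    return (rx @ ry) / denom


def _perm_p(rho_obs: float, rho_null: np.ndarray) -> float:
    # ties at float precision count as exceedances
    hits = np.sum(np.abs(rho_null) >= abs(rho_obs) - 1e-12)
    return float((1 + hits) / (1 + rho_null.size))


# ---------------------------------------------------------------------------
# spin permutations
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation in SO(3) via QR with sign fixing."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _one_to_one_assignment(d: np.ndarray) -> np.ndarray:
    """Optimal one-to-one original->rotated parcel matching (minimum total
    distance). Optimal matching preserves the rotated map's spatial
    autocorrelation as faithfully as a parcel-valued null can, which keeps
    the null distribution honestly wide."""
    row, col = linear_sum_assignment(d)
    assign = np.empty(d.shape[0], dtype=int)
    assign[row] = col
    return assign


def spin_permutations(
    atlas: AtlasTable,
    n_permutations: int,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """(n_permutations, n_cortical) permutation indices from mirrored rotations.

    Each row is a permutation of cortical parcel indices: left-hemisphere
    coordinates are rotated by a uniform random rotation, right-hemisphere
    coordinates by its x-mirrored counterpart, and parcels are reassigned
    one-to-one to nearest rotated positions within each hemisphere.
    """
    cort_idx = np.nonzero(atlas.cortical)[0]
    if cort_idx.size == 0:
        raise ValueError("atlas has no cortical regions")
    coords = atlas.coordinates[cort_idx]
    if not np.all(np.isfinite(coords)):
        missing = [atlas.region_ids[i] for i in cort_idx if not np.all(np.isfinite(atlas.coordinates[i]))]
        raise ValueError(f"cortical regions missing coordinates: {missing}")
    hemis = atlas.hemispheres[cort_idx]
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    n_c = cort_idx.size
    perms = np.empty((n_permutations, n_c), dtype=int)
    hemi_masks = {h: np.nonzero(hemis == h)[0] for h in ("L", "R")}
    identity = np.arange(n_c)
    for b in range(n_permutations):
        for _attempt in range(100):
            rot = _random_rotation(rng)
            perm = identity.copy()
            for h, local in hemi_masks.items():
                if local.size == 0:
                    continue
                r = rot if h == "L" else mirror @ rot @ mirror
                pts = coords[local]
                centre = pts.mean(axis=0)  # rotate about the hemisphere's centre
                rotated = (pts - centre) @ r.T + centre
                d = np.linalg.norm(pts[:, None, :] - rotated[None, :, :], axis=-1)
                perm[local] = local[_one_to_one_assignment(d)]
            # a near-identity rotation can reproduce the unpermuted map;
            # it carries no information about the null, so redraw
            if not np.array_equal(perm, identity):
                break
        else:
            warnings.warn("could not avoid identity spin; atlas too small", stacklevel=2)
        perms[b] = perm
    return perms


def spin_test(
    x: np.ndarray,
    y: np.ndarray,
    atlas: AtlasTable,
    n_permutations: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    permutations: np.ndarray | None = None,
) -> AssociationResult:
    """Spin permutation test of Spearman's rho between two cortical maps.

    ``x`` and ``y`` are aligned with the atlas's cortical regions. Precomputed
    ``permutations`` (from :func:`spin_permutations`) may be supplied to share
    nulls across many map pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_c = int(atlas.cortical.sum())
    if x.size != n_c or y.size != n_c:
        raise ValueError(f"maps must have one value per cortical region ({n_c})")
    rho_obs = spearman_map_association(x, y)
    if permutations is None:
        permutations = spin_permutations(atlas, n_permutations, seed)
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    rho_null = _null_rhos(rank_x, rank_y, permutations)
    return AssociationResult(
        rho=rho_obs,
        p_value=_perm_p(rho_obs, rho_null),
        scheme="spin",
        n_permutations=permutations.shape[0],
    )


# ---------------------------------------------------------------------------
# hemisphere shuffle
# ---------------------------------------------------------------------------

def hemisphere_permutations(
    hemispheres: np.ndarray,
    n_permutations: int,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Permutation indices that shuffle values only within each hemisphere."""
    hemispheres = np.asarray(hemispheres)
    rng = np.random.default_rng(seed)
    n = hemispheres.size
    groups = []
    for h in np.unique(hemispheres):
        idx = np.nonzero(hemispheres == h)[0]
        if idx.size < 2:
            warnings.warn(
                f"hemisphere {h!r} has {idx.size} region(s); it stays fixed",
                stacklevel=2,
            )
        groups.append(idx)
    perms = np.tile(np.arange(n), (n_permutations, 1))
    for b in range(n_permutations):
        for idx in groups:
            if idx.size >= 2:
                perms[b, idx] = idx[rng.permutation(idx.size)]
    return perms


def hemisphere_shuffle_test(
    x: np.ndarray,
    y: np.ndarray,
    hemispheres: np.ndarray,
    n_permutations: int = 10000,
    seed: int | np.random.SeedSequence = 0,
) -> AssociationResult:
    """Within-hemisphere shuffle test of Spearman's rho (subcortical maps)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = spearman_map_association(x, y)
    perms = hemisphere_permutations(hemispheres, n_permutations, seed)
    rho_null = _null_rhos(stats.rankdata(x), stats.rankdata(y), perms)
    return AssociationResult(
        rho=rho_obs,
        p_value=_perm_p(rho_obs, rho_null),
        scheme="hemisphere-shuffle",
        n_permutations=n_permutations,
    )


def map_association(
    x: np.ndarray,
    y: np.ndarray,
    atlas: AtlasTable,
    n_permutations: int = 10000,
    seed: int | np.random.SeedSequence = 0,
) -> AssociationResult:
    """Whole-brain map coupling: joint cortical spin + subcortical shuffle.

    ``x`` and ``y`` carry one value per atlas region. Each null iteration
    spins the cortical component and shuffles the subcortical component
    within hemisphere, producing a single whole-brain null rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != atlas.n_regions or y.size != atlas.n_regions:
        raise ValueError("maps must have one value per atlas region")
    rho_obs = spearman_map_association(x, y)
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    spin_seed, shuf_seed = root.spawn(2)
    cort = np.nonzero(atlas.cortical)[0]
    sub = np.nonzero(~atlas.cortical)[0]
    perms = np.tile(np.arange(atlas.n_regions), (n_permutations, 1))
    if cort.size:
        perms[:, cort] = cort[spin_permutations(atlas, n_permutations, spin_seed)]
    if sub.size:
        sub_perms = hemisphere_permutations(
            atlas.hemispheres[sub], n_permutations, shuf_seed
        )
        perms[:, sub] = sub[sub_perms]
    rho_null = _null_rhos(stats.rankdata(x), stats.rankdata(y), perms)
    return AssociationResult(
        rho=rho_obs,
        p_value=_perm_p(rho_obs, rho_null),
        scheme="spin+shuffle",
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# FDR, metric ANCOVA, partial correlation, normality
# ---------------------------------------------------------------------------

def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def ancova_metric(
    values: np.ndarray, design: DesignMatrix
) -> tuple[float, float]:
    """Partial F (group | covariates) for one scalar metric across subjects."""
    y = np.asarray(values, dtype=float).reshape(-1, 1)
    if y.shape[0] != design.n_subjects:
        raise ValueError("metric vector length does not match design rows")
    f, p = _partial_f(y, design.full(), design.reduced())
    return float(f[0]), float(p[0])


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if covariates is None or covariates.size == 0:
        return v - v.mean()
    x = np.column_stack([np.ones(v.shape[0]), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing covariates out of each.

    Returns (r, two-sided p) with t-based p on df = n - n_cov - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    covariates = (
        None
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    k = 0 if covariates is None else covariates.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("constant residuals: correlation undefined")
    r = float(rx @ ry / denom)
    df = n - k - 2
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * np.sqrt(df / (1.0 - r_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def residual_normality(
    x: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Shapiro-Wilk W and p on the residuals of x after covariate regression."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    covariates = (
        None
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(x.size, -1)
    )
    resid = _residualize(x, covariates)
    if np.allclose(resid, resid[0]):
        raise ValueError("constant residuals (perfect fit): normality test undefined")
    w, p = stats.shapiro(resid)
    return float(w), float(p)
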