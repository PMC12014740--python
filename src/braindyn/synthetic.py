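"""Synthetic multi-subject cohorts with planted integration/segregation structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage can be exercised and validated without
access to real imaging data:

* two connectivity *regimes* — a **segregated** regime with block-modular
  correlations (strong within-module, weak between-module) and an
  **integrated** regime with uniform global correlation — alternating through
  time as a two-state Markov chain;
* a planted **group effect**: a correlation offset added on a chosen edge set
  for case subjects;
* subject covariates (age, sex, education, head motion, consumption history)
  drawn from simple parametric models;
* spatially autocorrelated per-region maps standing in for receptor /
  transporter density maps.

Everything is deterministic given the seed in the spec objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import AtlasTable, ParcellatedTimeSeries, SubjectTable, NETWORK_LABELS
import pandas as pd


class GeneratorError(ValueError):
    """A generator spec is infeasible (e.g. a non-positive-definite request)."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class RegimeSpec:
    """Parameters of the two connectivity regimes.

    ``module_assignment`` maps each region index to a module id; the
    segregated regime has ``within_corr_segregated`` inside modules and
    ``between_corr_segregated`` across them, the integrated regime a uniform
    ``global_corr_integrated`` everywhere off-diagonal. ``noise_sd`` scales
    the marginal SD of every region (covariance = noise_sd^2 x correlation).
    """

    n_regions: int
    module_assignment: np.ndarray
    within_corr_segregated: float = 0.6
    between_corr_segregated: float = 0.0
    global_corr_integrated: float = 0.15
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape != (self.n_regions,):
            raise GeneratorError(
                "module_assignment must cover all regions: expected shape "
                f"({self.n_regions},), got {self.module_assignment.shape}"
            )
        if not (0 <= self.within_corr_segregated < 1):
            raise GeneratorError("within_corr_segregated must lie in [0, 1)")
        if not (0 <= self.global_corr_integrated < 1):
            raise GeneratorError("global_corr_integrated must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise GeneratorError("noise_sd must be positive")


def default_module_assignment(n_regions: int, n_modules: int = 5) -> np.ndarray:
    """Contiguous equal-sized blocks (remainder spread over the first modules)."""
    return np.sort(np.arange(n_regions) % n_modules)


def default_regimes(n_regions: int = 100, n_modules: int = 5) -> RegimeSpec:
    """The default study conditions: a 100-region parcellation with five
    equal modules, strong within-module correlation (0.6) against a flat
    background in the segregated regime, and weak uniform global correlation
    (0.15) in the integrated regime. The weak uniform coupling keeps the
    integrated regime's detected partitions dispersed (high participation)
    instead of collapsing into a single module."""
    return RegimeSpec(
        n_regions=n_regions,
        module_assignment=default_module_assignment(n_regions, n_modules),
    )


@dataclass
class CovariateModel:
    """Distributions for subject covariates.

    Defaults emulate an adult cocaine-use cohort: predominantly male,
    age 18-50, 6-20 years of education, resting-state head motion in the
    usable range, with consumption history (years of use, age of onset)
    drawn for case subjects only.
    """

    age_range: tuple[float, float] = (18.0, 50.0)
    p_male: float = 0.83
    education_range: tuple[float, float] = (6.0, 20.0)
    mean_fd_range: tuple[float, float] = (0.05, 0.4)
    years_of_use_mean_sd: tuple[float, float] = (10.24, 6.81)
    age_of_onset_mean_sd: tuple[float, float] = (21.13, 5.80)

    def draw(self, rng: np.random.Generator, group: str) -> dict:
        cov = {
            "age": float(rng.uniform(*self.age_range)),
            "sex": int(rng.random() < self.p_male),
            "education": float(rng.uniform(*self.education_range)),
            "mean_fd": float(rng.uniform(*self.mean_fd_range)),
        }
        if group == "case":
            m, s = self.years_of_use_mean_sd
            cov["years_of_use"] = float(max(0.5, rng.normal(m, s)))
            m, s = self.age_of_onset_mean_sd
            cov["age_of_onset"] = float(np.clip(rng.normal(m, s), 12.0, cov["age"]))
        else:
            cov["years_of_use"] = np.nan
            cov["age_of_onset"] = np.nan
        return cov


@dataclass
class CohortSpec:
    """Study-level design of a synthetic cohort."""

    n_per_group: tuple[int, int] = (20, 20)
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    stay_probability: float = 0.9
    integrated_occupancy: float = 0.64
    effect_edges: Sequence[tuple[int, int]] = ()
    effect_size: float = 0.0
    ar_coefficient: float = 0.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.stay_probability < 1.0):
            raise GeneratorError("stay_probability must lie strictly in (0, 1)")
        if not (0.0 <= self.integrated_occupancy <= 1.0):
            raise GeneratorError("integrated_occupancy must lie in [0, 1]")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise GeneratorError("ar_coefficient must lie in [0, 1)")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    series: ParcellatedTimeSeries
    covariates: dict
    regime_sequence: np.ndarray  # 1 = integrated, 0 = segregated, per TR


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    effect_edges: list[tuple[int, int]]
    effect_size: float
    integrated_occupancy: float
    regime_templates: dict  # group -> (segregated corr, integrated corr)

    def subject_table(self) -> SubjectTable:
        rows = []
        for s in self.subjects:
            rows.append({"subject_id": s.subject_id, "group": s.group, **s.covariates})
        return SubjectTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# covariance templates
# ---------------------------------------------------------------------------

def _check_pd(matrix: np.ndarray, what: str) -> None:
    lam = float(np.linalg.eigvalsh(matrix)[0])
    if lam <= 0:
        raise GeneratorError(
            f"{what} is not positive definite (smallest eigenvalue {lam:.3e})"
        )


def build_regime_covariances(spec: RegimeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Correlation->covariance templates for the two regimes.

    Returns ``(segregated, integrated)`` covariance matrices, each
    ``noise_sd^2`` times a unit-diagonal correlation matrix. Rejects any
    request whose implied correlation matrix is not positive definite,
    reporting the offending eigenvalue.
    """
    n = spec.n_regions
    same = spec.module_assignment[:, None] == spec.module_assignment[None, :]
    seg = np.where(same, spec.within_corr_segregated, spec.between_corr_segregated)
    np.fill_diagonal(seg, 1.0)
    integ = np.full((n, n), spec.global_corr_integrated)
    np.fill_diagonal(integ, 1.0)
    _check_pd(seg, "segregated correlation template")
    _check_pd(integ, "integrated correlation template")
    s2 = spec.noise_sd**2
    return s2 * seg, s2 * integ


def nearest_positive_definite(matrix: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Higham-style projection onto the PD cone (symmetrize, clip eigenvalues)."""
    sym = (matrix + matrix.T) / 2.0
    lam, vec = np.linalg.eigh(sym)
    lam = np.clip(lam, eps, None)
    return (vec * lam) @ vec.T


# ---------------------------------------------------------------------------
# regime sequence
# ---------------------------------------------------------------------------

def regime_transition_matrix(
    stay_probability: float, integrated_occupancy: float
) -> np.ndarray:
    """Two-state transition matrix (rows: from [segregated, integrated]).

    The chain is parameterized as a reversible exchange process: with
    switching rate r = 2 (1 - stay_probability), the per-TR transition
    probabilities are P(S->I) = r * pi_I and P(I->S) = r * (1 - pi_I), whose
    stationary distribution is exactly (1 - pi_I, pi_I). At occupancy 0.5
    both regimes keep ``stay_probability`` and the matrix is symmetric.
    """
    pi_i = integrated_occupancy
    r = 2.0 * (1.0 - stay_probability)
    q = r * pi_i  # segregated -> integrated
    p = r * (1.0 - pi_i)  # integrated -> segregated
    if q > 1.0 or p > 1.0:
        raise GeneratorError(
            f"stay_probability {stay_probability} too small for occupancy "
            f"{pi_i} (implied transition probability > 1)"
        )
    return np.array([[1.0 - q, q], [p, 1.0 - p]])


def sample_regime_sequence(
    stay_probability: float,
    integrated_occupancy: float,
    n_timepoints: int,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Sample the per-TR regime indicator (1 = integrated) Markov chain.

    The initial state is drawn from the stationary distribution. Occupancy
    0 or 1 degenerates to a constant sequence (with a warning).
    """
    rng = np.random.default_rng(seed)
    if integrated_occupancy in (0.0, 1.0):
        warnings.warn(
            f"degenerate occupancy {integrated_occupancy}: constant regime sequence",
            stacklevel=2,
        )
        return np.full(n_timepoints, int(integrated_occupancy), dtype=int)
    trans = regime_transition_matrix(stay_probability, integrated_occupancy)
    seq = np.empty(n_timepoints, dtype=int)
    state = int(rng.random() < integrated_occupancy)
    u = rng.random(n_timepoints)
    for t in range(n_timepoints):
        seq[t] = state
        state = int(u[t] < trans[state, 1])
    return seq


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _inject_effect(
    corr: np.ndarray, edges: Sequence[tuple[int, int]], effect: float
) -> np.ndarray:
    """Add a correlation offset on the given edges, repairing PD if needed."""
    out = corr.copy()
    for i, j in edges:
        r = out[i, j] + effect
        if not (-1.0 < r < 1.0):
            raise GeneratorError(
                f"effect pushes correlation of edge ({i}, {j}) to {r:.3f}, "
                "outside (-1, 1)"
            )
        out[i, j] = out[j, i] = r
    if np.linalg.eigvalsh(out)[0] <= 0:
        out = nearest_positive_definite(out)
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)  # back to unit diagonal
        _check_pd(out, "effect-adjusted correlation template")
    return out


def _sample_series(
    rng: np.random.Generator,
    regime_seq: np.ndarray,
    chols: tuple[np.ndarray, np.ndarray],
    ar: float,
) -> np.ndarray:
    """Draw the series: x_t = L_{regime(t)} z_t, optionally AR(1) in z."""
    n_t = regime_seq.size
    n = chols[0].shape[0]
    z = rng.standard_normal((n_t, n))
    if ar > 0:
        # stationary AR(1) innovations keep the per-regime covariance intact
        scale = np.sqrt(1.0 - ar**2)
        for t in range(1, n_t):
            z[t] = ar * z[t - 1] + scale * z[t]
    out = np.empty_like(z)
    for state in (0, 1):
        mask = regime_seq == state
        out[mask] = z[mask] @ chols[state].T
    return out


def generate_cohort(spec: CohortSpec, regimes: RegimeSpec) -> SyntheticCohort:
    """Generate the full synthetic cohort (controls first, then cases)."""
    seg_cov, int_cov = build_regime_covariances(regimes)
    sd = regimes.noise_sd
    seg_corr, int_corr = seg_cov / sd**2, int_cov / sd**2
    edges = [tuple(int(v) for v in e) for e in spec.effect_edges]
    for i, j in edges:
        if not (0 <= i < regimes.n_regions and 0 <= j < regimes.n_regions) or i == j:
            raise GeneratorError(f"effect edge ({i}, {j}) is not a valid region pair")

    templates = {"control": (seg_corr, int_corr)}
    if spec.effect_size != 0.0 and edges:
        templates["case"] = (
            _inject_effect(seg_corr, edges, spec.effect_size),
            _inject_effect(int_corr, edges, spec.effect_size),
        )
    else:
        templates["case"] = (seg_corr, int_corr)

    chols = {
        g: (
            np.linalg.cholesky(sd**2 * templates[g][0]),
            np.linalg.cholesky(sd**2 * templates[g][1]),
        )
        for g in ("control", "case")
    }

    root = np.random.SeedSequence(spec.seed)
    region_ids = [f"r{i:03d}" for i in range(regimes.n_regions)]
    subjects: list[SyntheticSubject] = []
    idx = 0
    for group, n_sub in zip(("control", "case"), spec.n_per_group):
        for _ in range(n_sub):
            child = root.spawn(1)[0]
            seq_ss, data_ss, cov_ss = child.spawn(3)
            regime_seq = sample_regime_sequence(
                spec.stay_probability,
                spec.integrated_occupancy,
                spec.n_timepoints,
                seq_ss,
            )
            values = _sample_series(
                np.random.default_rng(data_ss),
                regime_seq,
                chols[group],
                spec.ar_coefficient,
            )
            covariates = spec.covariate_model.draw(
                np.random.default_rng(cov_ss), group
            )
            subjects.append(
                SyntheticSubject(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    series=ParcellatedTimeSeries(
                        values=values,
                        tr_seconds=spec.tr_seconds,
                        region_ids=region_ids,
                    ),
                    covariates=covariates,
                    regime_sequence=regime_seq,
                )
            )
            idx += 1
    return SyntheticCohort(
        subjects=subjects,
        effect_edges=edges,
        effect_size=spec.effect_size,
        integrated_occupancy=spec.integrated_occupancy,
        regime_templates=templates,
    )


# ---------------------------------------------------------------------------
# synthetic atlas + spatial maps
# ---------------------------------------------------------------------------

def make_synthetic_atlas(
    n_cortical: int = 16,
    n_subcortical: int = 4,
    seed: int | np.random.SeedSequence = 0,
) -> AtlasTable:
    """A synthetic stand-in atlas: cortical parcels on a unit sphere split
    into two hemispheres by the x coordinate sign, plus subcortical parcels
    without coordinates. Network labels cycle over the Yeo-7 vocabulary for
    cortical parcels; subcortical parcels are SUB.
    """
    rng = np.random.default_rng(seed)
    half = n_cortical // 2
    # each hemisphere is modelled as its own full spherical surface (as in
    # surface-based registration), with quasi-uniform Fibonacci parcels;
    # the right hemisphere mirrors the left. Sphere centres are offset on
    # the x axis so hemispheres are distant in the map kernel.
    k = np.arange(half)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * k + 1) / half
    theta = 2 * np.pi * k / golden
    pts = np.column_stack(
        [np.sqrt(1 - z**2) * np.cos(theta), np.sqrt(1 - z**2) * np.sin(theta), z]
    )
    left = pts + np.array([-2.0, 0.0, 0.0])
    right = pts * np.array([-1.0, 1.0, 1.0]) + np.array([2.0, 0.0, 0.0])
    coords = np.vstack([left, right])
    n_cortical = coords.shape[0]
    cort_nets = [NETWORK_LABELS[i % 6] for i in range(n_cortical)]
    hemis = ["L"] * half + ["R"] * half
    sub_hemis = ["L", "R"] * ((n_subcortical + 1) // 2)
    sub_hemis = sub_hemis[:n_subcortical]
    all_coords = np.vstack([coords, np.full((n_subcortical, 3), np.nan)])
    n = n_cortical + n_subcortical
    return AtlasTable(
        region_ids=[f"r{i:03d}" for i in range(n)],
        names=[f"parcel_{i:03d}" for i in range(n)],
        hemispheres=np.array(hemis + sub_hemis),
        networks=np.array(cort_nets + ["SUB"] * n_subcortical),
        cortical=np.array([True] * n_cortical + [False] * n_subcortical),
        coordinates=all_coords,
    )


def generate_autocorrelated_map(
    atlas: AtlasTable,
    length_scale: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """A Gaussian-process-like per-region map.

    Cortical values are a zero-mean Gaussian field whose covariance is a
    squared-exponential kernel in chordal distance between parcel
    coordinates, so correlation decays monotonically with great-circle
    distance with characteristic length ``length_scale``; subcortical values
    are drawn independently per hemisphere.
    """
    rng = np.random.default_rng(seed)
    cort = atlas.cortical
    coords = atlas.coordinates[cort]
    missing = [
        atlas.region_ids[i]
        for i in np.nonzero(cort)[0]
        if not np.all(np.isfinite(atlas.coordinates[i]))
    ]
    if missing:
        raise GeneratorError(f"cortical regions missing coordinates: {missing}")
    values = np.empty(atlas.n_regions)
    if coords.shape[0]:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        if length_scale <= 0:
            k = np.eye(coords.shape[0])
        else:
            k = np.exp(-0.5 * (d / length_scale) ** 2)
            k += 1e-8 * np.eye(coords.shape[0])
        values[cort] = np.linalg.cholesky(k) @ rng.standard_normal(coords.shape[0])
    sub_idx = np.nonzero(~cort)[0]
    for hemi in ("L", "R"):
        m = [i for i in sub_idx if atlas.hemispheres[i] == hemi]
        values[m] = rng.standard_normal(len(m))
    return values


# ---------------------------------------------------------------------------
# connectivity-level cohorts (for group-statistics modules)
# ---------------------------------------------------------------------------

def generate_connectivity_cohort(
    n_regions: int,
    n_per_group: tuple[int, int],
    effect_edges: Sequence[tuple[int, int]] = (),
    effect_d: float = 0.0,
    subject_sd: float = 0.1,
    base_corr: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[np.ndarray], SubjectTable]:
    """Per-subject connectivity centroids with a planted standardized effect.

    Each subject's matrix is generated directly on the Fisher-z scale:
    ``z = atanh(base) + group * effect_d * subject_sd * 1[edge planted]
    + N(0, subject_sd^2)`` per upper-triangle edge, then back-transformed.
    ``effect_d`` is therefore the standardized (Cohen's d) group difference
    on the planted edges. Covariates are drawn from the default
    :class:`CovariateModel` and are independent of connectivity, so group is
    the only structured signal. Suitable for calibration / power studies of
    the group-statistics stages without simulating full time series.
    """
    rng = np.random.default_rng(seed)
    if base_corr is None:
        base_corr = np.full((n_regions, n_regions), 0.2)
        np.fill_diagonal(base_corr, 1.0)
    base_z = np.arctanh(np.clip(base_corr, -0.999999, 0.999999))
    np.fill_diagonal(base_z, 0.0)
    planted = np.zeros((n_regions, n_regions), dtype=bool)
    for i, j in effect_edges:
        planted[i, j] = planted[j, i] = True
    cov_model = CovariateModel()
    iu = np.triu_indices(n_regions, k=1)
    matrices: list[np.ndarray] = []
    rows = []
    idx = 0
    for group, n_sub in zip(("control", "case"), n_per_group):
        shift = effect_d * subject_sd if group == "case" else 0.0
        for _ in range(n_sub):
            noise = np.zeros((n_regions, n_regions))
            noise[iu] = rng.normal(0.0, subject_sd, size=iu[0].size)
            noise += noise.T
            z = base_z + noise + shift * planted
            mat = np.tanh(z)
            np.fill_diagonal(mat, 1.0)
            matrices.append(mat)
            rows.append(
                {
                    "subject_id": f"sub-{idx:03d}",
                    "group": group,
                    **cov_model.draw(rng, group),
                }
            )
            idx += 1
    return matrices, SubjectTable(pd.DataFrame(rows))
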