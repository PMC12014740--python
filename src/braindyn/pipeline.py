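"""End-to-end orchestration: per-subject state extraction, group statistics.

The full analysis is driven by one :class:`PipelineConfig`:

    subject series -> band-pass filter -> sliding windows -> per-window
    signed-Louvain consensus + cartographic profile -> k-means states ->
    state centroids + dynamic measures              (per subject)

    subject centroids -> NBS per state -> graph metrics on whole centroids
    and NBS subnetworks -> metric ANCOVA + FDR -> map associations on
    regional edge counts -> partial correlations with consumption patterns
                                                    (group level)

Determinism: every stage seed is derived from the master seed with
``np.random.SeedSequence(master_seed, spawn_key=...)``, so reruns with the
same config are bit-identical. Subject-level results are cached as JSON keyed
by the config hash.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import association, cartography, dfc, netmetrics, nbs, states
from .io_core import AtlasTable, ParcellatedTimeSeries, SubjectTable, write_json

STATES = (states.INTEGRATED, states.SEGREGATED)
_STAGE = {"subject": 1, "nbs": 2, "metrics": 3, "assoc": 4}


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis."""

    window_length: int = 22
    step: int = 1
    low_hz: float = 0.01
    high_hz: float = 0.08
    gamma: float = 1.0
    louvain_repetitions: int = 100
    kmeans_restarts: int = 300
    b_bins: int = 50
    z_bins: int = 50
    z_min: float = -5.0
    z_max: float = 5.0
    nbs_threshold: float = 0.05
    nbs_permutations: int = 5000
    metric_taus: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
    n_nulls: int = 100
    assoc_permutations: int = 10000
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.metric_taus = tuple(float(t) for t in self.metric_taus)
        if self.window_length < 2 or self.step < 1:
            raise ValueError("window_length >= 2 and step >= 1 required")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.nbs_permutations < 100:
            raise ValueError("nbs_permutations must be >= 100")
        if not (0 < self.nbs_threshold < 1):
            raise ValueError("nbs_threshold must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["metric_taus"] = list(d["metric_taus"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["metric_taus"] = list(d["metric_taus"])
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str, index: int = 0) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            self.master_seed, spawn_key=(_STAGE[stage], index)
        )


@dataclass
class SubjectRun:
    subject_id: str
    result: states.StateResult
    profiles: cartography.CartographicProfileSet = field(repr=False)
    windows: dfc.WindowedConnectivity = field(repr=False)


# ---------------------------------------------------------------------------
# per-subject stage
# ---------------------------------------------------------------------------

def run_subject(
    series: ParcellatedTimeSeries,
    config: PipelineConfig,
    subject_index: int = 0,
    subject_id: str = "sub-000",
) -> SubjectRun:
    """Filter -> windows -> cartography -> states for one subject."""
    seed = config.stage_seed("subject", subject_index)
    cart_seed, km_seed = seed.spawn(2)
    filtered = dfc.bandpass_filter(series, config.low_hz, config.high_hz)
    windows = dfc.sliding_window_dfc(filtered, config.window_length, config.step)
    profiles = cartography.window_cartography(
        windows,
        gamma=config.gamma,
        repetitions=config.louvain_repetitions,
        seed=cart_seed,
        b_bins=config.b_bins,
        z_bins=config.z_bins,
        z_range=(config.z_min, config.z_max),
    )
    result = states.subject_states(
        windows, profiles, restarts=config.kmeans_restarts, seed=km_seed
    )
    return SubjectRun(
        subject_id=subject_id, result=result, profiles=profiles, windows=windows
    )


def subject_run_to_dict(run: SubjectRun, config_hash: str) -> dict:
    """JSON-serializable summary of a subject run (for caching / reports)."""
    r = run.result
    return {
        "config_hash": config_hash,
        "subject_id": run.subject_id,
        "degenerate": r.degenerate,
        "state_labels": [str(s) for s in r.state_labels],
        "mean_participation": r.mean_participation,
        "dynamics": r.dynamics,
        "centroids": {k: v.tolist() for k, v in r.centroids.items()},
    }


# ---------------------------------------------------------------------------
# group stage
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    nbs_results: dict  # state -> NbsResult
    metric_tables: dict  # (state, scope) -> {metric: per-subject values}
    metric_tests: dict  # (state, scope) -> {metric: {F, p, p_fdr}}
    edge_counts: dict  # state -> per-region counts (largest significant comp)
    associations: dict  # state -> {map name: AssociationResult}
    consumption: dict  # state -> {(metric, pattern): {r, p}}
    notices: list[str]


def _metric_battery(
    matrices: list[np.ndarray], config: PipelineConfig, seed: np.random.SeedSequence
) -> dict[str, np.ndarray]:
    per_subject = []
    for mat, s in zip(matrices, seed.spawn(len(matrices))):
        per_subject.append(
            netmetrics.compute_metrics(
                mat,
                taus=config.metric_taus,
                n_nulls=config.n_nulls,
                gamma=config.gamma,
                louvain_repetitions=config.louvain_repetitions,
                seed=s,
            )
        )
    return {
        k: np.array([m[k] for m in per_subject]) for k in per_subject[0]
    }


def run_group(
    subject_runs: list[SubjectRun],
    subjects: SubjectTable,
    atlas: AtlasTable | None = None,
    config: PipelineConfig | None = None,
    density_maps: dict[str, np.ndarray] | None = None,
) -> GroupResult:
    """Group-level statistics over per-subject state centroids."""
    config = config or PipelineConfig()
    ids = [r.subject_id for r in subject_runs]
    if ids != subjects.subject_ids:
        raise ValueError("subject run order does not match subject table")
    design = nbs.DesignMatrix.from_subject_table(subjects)
    notices: list[str] = []
    nbs_results: dict = {}
    metric_tables: dict = {}
    metric_tests: dict = {}
    edge_counts: dict = {}
    associations: dict = {}
    consumption: dict = {}

    n_regions = subject_runs[0].windows.matrices.shape[1]
    for s_idx, state in enumerate(STATES):
        missing = [r.subject_id for r in subject_runs if state not in r.result.centroids]
        if missing:
            notices.append(
                f"state {state}: no windows for subject(s) {missing}; state skipped"
            )
            continue
        centroids = np.array([r.result.centroids[state] for r in subject_runs])
        res = nbs.nbs_fwe(
            centroids,
            design,
            forming_threshold=config.nbs_threshold,
            n_permutations=config.nbs_permutations,
            seed=config.stage_seed("nbs", s_idx),
        )
        nbs_results[state] = res

        # whole-network metrics
        metric_tables[(state, "whole")] = _metric_battery(
            list(centroids), config, config.stage_seed("metrics", 2 * s_idx)
        )

        sig = res.significant_components(config.alpha)
        if sig:
            comp = sig[0]
            edge_counts[state] = nbs.regional_edge_counts(comp.edges, n_regions)
            sub_mats = [
                netmetrics.subnetwork_extract(c, comp.edges)[0] for c in centroids
            ]
            metric_tables[(state, "nbs")] = _metric_battery(
                sub_mats, config, config.stage_seed("metrics", 2 * s_idx + 1)
            )
        else:
            notices.append(
                f"state {state}: no NBS component significant at alpha = "
                f"{config.alpha}; subnetwork metrics skipped"
            )

    # metric ANCOVA with FDR across metrics x states per scope
    for scope in ("whole", "nbs"):
        keys = [
            (state, metric)
            for state in STATES
            if (state, scope) in metric_tables
            for metric in metric_tables[(state, scope)]
        ]
        raw = {}
        for state, metric in keys:
            values = metric_tables[(state, scope)][metric]
            if not np.all(np.isfinite(values)):
                notices.append(
                    f"{scope}/{state}/{metric}: non-finite values, test skipped"
                )
                continue
            raw[(state, metric)] = association.ancova_metric(values, design)
        if raw:
            adj = association.fdr_bh([v[1] for v in raw.values()])
            for (key, (f, p)), q in zip(raw.items(), adj):
                state, metric = key
                metric_tests.setdefault((state, scope), {})[metric] = {
                    "F": f, "p": p, "p_fdr": float(q),
                }

    # spatial map associations on regional edge counts
    if density_maps and atlas is not None:
        for state, counts in edge_counts.items():
            res_maps = {}
            for m_idx, (name, dens) in enumerate(sorted(density_maps.items())):
                res_maps[name] = association.map_association(
                    counts.astype(float),
                    np.asarray(dens, dtype=float),
                    atlas,
                    n_permutations=config.assoc_permutations,
                    seed=config.stage_seed("assoc", 100 * STATES.index(state) + m_idx),
                )
            adj = association.fdr_bh([r.p_value for r in res_maps.values()])
            for r, q in zip(res_maps.values(), adj):
                r.p_fdr = float(q)
            associations[state] = res_maps

    # partial correlations of case-group metrics with consumption patterns
    case_mask = subjects.group_indicator() == 1
    case_table = subjects.table.loc[case_mask]
    covs = case_table[["age", "sex", "education", "mean_fd"]].to_numpy(dtype=float)
    for (state, scope), table in metric_tables.items():
        if scope != "nbs":
            continue
        for pattern in ("years_of_use", "age_of_onset"):
            y = case_table[pattern].to_numpy(dtype=float)
            if np.isnan(y).any():
                notices.append(f"{pattern} missing for some cases; skipped")
                continue
            for metric, values in table.items():
                x = values[case_mask]
                if not np.all(np.isfinite(x)):
                    continue
                try:
                    r, p = association.partial_pearson(x, y, covs)
                except ValueError as exc:
                    notices.append(f"{state}/{metric}~{pattern}: {exc}")
                    continue
                consumption.setdefault(state, {})[f"{metric}~{pattern}"] = {
                    "r": r, "p": p,
                }

    return GroupResult(
        nbs_results=nbs_results,
        metric_tables=metric_tables,
        metric_tests=metric_tests,
        edge_counts=edge_counts,
        associations=associations,
        consumption=consumption,
        notices=notices,
    )


# ---------------------------------------------------------------------------
# manifest / caching
# ---------------------------------------------------------------------------

def run_cohort(
    series_list: list[tuple[str, ParcellatedTimeSeries]],
    subjects: SubjectTable,
    config: PipelineConfig,
    atlas: AtlasTable | None = None,
    density_maps: dict[str, np.ndarray] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectRun], GroupResult]:
    """Run every subject then the group stage, optionally writing/caching
    per-subject JSON results under ``out_dir`` keyed by the config hash."""
    chash = config.config_hash()
    runs = []
    cache_dir = None
    if out_dir is not None:
        cache_dir = Path(out_dir) / "subjects"
        cache_dir.mkdir(parents=True, exist_ok=True)
    for idx, (sid, series) in enumerate(series_list):
        run = run_subject(series, config, subject_index=idx, subject_id=sid)
        runs.append(run)
        if cache_dir is not None:
            write_json(subject_run_to_dict(run, chash), cache_dir / f"{sid}.json")
    group = run_group(runs, subjects, atlas, config, density_maps)
    if out_dir is not None:
        write_json(group_result_to_dict(group, config), Path(out_dir) / "group.json")
        manifest = {
            "config_hash": chash,
            "n_subjects": len(runs),
            "subject_outputs": [f"subjects/{sid}.json" for sid, _ in series_list],
            "group_output": "group.json",
            "notices": group.notices,
        }
        write_json(manifest, Path(out_dir) / "manifest.json")
    return runs, group


def group_result_to_dict(group: GroupResult, config: PipelineConfig) -> dict:
    out: dict = {"notices": group.notices, "config_hash": config.config_hash()}
    out["nbs"] = {}
    for state, res in group.nbs_results.items():
        out["nbs"][state] = {
            "forming_threshold": res.forming_threshold,
            "n_permutations": res.n_permutations,
            "components": [
                {"size": c.size, "p_fwe": c.p_fwe, "edges": [list(e) for e in c.edges]}
                for c in res.components
            ],
        }
    out["metric_tests"] = {
        f"{state}|{scope}": tests
        for (state, scope), tests in group.metric_tests.items()
    }
    out["edge_counts"] = {k: v.tolist() for k, v in group.edge_counts.items()}
    out["associations"] = {
        state: {
            name: {
                "rho": r.rho,
                "p": r.p_value,
                "p_fdr": r.p_fdr,
                "scheme": r.scheme,
                "exploratory": False,
            }
            for name, r in maps.items()
        }
        for state, maps in group.associations.items()
    }
    # consumption-pattern couplings are exploratory: uncorrected by design
    out["consumption_exploratory"] = group.consumption
    return out
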