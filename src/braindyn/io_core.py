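"""Readers and writers for the package's plain-text data formats.

Everything on disk is TSV (tables, matrices) or JSON (results, manifests);
no binary formats. Readers validate strictly and fail with messages naming
the offending rows/columns, so that malformed inputs never propagate into
the numerical pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: the fixed vocabulary of functional-network labels: the Yeo-7 cortical
#: networks plus a subcortical catch-all.
NETWORK_LABELS = ("VIS", "SMN", "DAN", "VAN", "FPN", "DMN", "SUB")


class SchemaError(ValueError):
    """A file violated the documented schema."""


@dataclass
class AtlasTable:
    """Parcellation lookup: one row per region.

    Cortical regions carry spherical (unit-sphere or scanner-space)
    coordinates used by spatially constrained permutation tests; subcortical
    regions carry only a hemisphere label.
    """

    region_ids: list[str]
    names: list[str]
    hemispheres: np.ndarray  # array of 'L'/'R'
    networks: np.ndarray  # array of labels from NETWORK_LABELS
    cortical: np.ndarray  # bool mask
    coordinates: np.ndarray  # (n, 3); NaN rows allowed for subcortical only

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def __post_init__(self) -> None:
        ids = list(self.region_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({r for r in ids if ids.count(r) > 1})
            raise SchemaError(f"duplicated region_id(s): {dupes}")
        bad = sorted(set(self.networks) - set(NETWORK_LABELS))
        if bad:
            raise SchemaError(
                f"unknown network label(s) {bad}; allowed: {list(NETWORK_LABELS)}"
            )
        bad_hemi = sorted(set(self.hemispheres) - {"L", "R"})
        if bad_hemi:
            raise SchemaError(f"hemisphere labels must be L/R, got {bad_hemi}")
        self.cortical = np.asarray(self.cortical, dtype=bool)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(ids), 3):
            raise SchemaError(
                f"coordinates must be ({len(ids)}, 3), got {self.coordinates.shape}"
            )
        missing = [
            ids[i]
            for i in range(len(ids))
            if self.cortical[i] and not np.all(np.isfinite(self.coordinates[i]))
        ]
        if missing:
            raise SchemaError(f"cortical regions missing coordinates: {missing}")


@dataclass
class ParcellatedTimeSeries:
    """A single subject's parcellated BOLD series (time x region)."""

    values: np.ndarray
    tr_seconds: float
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("time series must be a 2-D time x region matrix")
        if self.values.shape[1] != len(self.region_ids):
            raise SchemaError(
                f"{self.values.shape[1]} columns but {len(self.region_ids)} region ids"
            )
        if self.tr_seconds <= 0:
            raise SchemaError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.values)):
            rows, cols = np.nonzero(~np.isfinite(self.values))
            cells = [
                (int(r), self.region_ids[c]) for r, c in zip(rows[:5], cols[:5])
            ]
            raise SchemaError(
                f"non-finite values at (row, region) cells {cells}"
                + ("..." if rows.size > 5 else "")
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class SubjectTable:
    """Per-subject covariates and group labels."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "group", "age", "sex", "education", "mean_fd")
    GROUPS = ("control", "case")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"subject table missing column(s): {missing}")
        bad_groups = sorted(set(df["group"]) - set(self.GROUPS))
        if bad_groups:
            raise SchemaError(
                f"group labels must be in {self.GROUPS}, got {bad_groups}"
            )
        if df["subject_id"].duplicated().any():
            raise SchemaError("duplicated subject_id in subject table")
        if (df["mean_fd"] < 0).any():
            bad = df.loc[df["mean_fd"] < 0, "subject_id"].tolist()
            raise SchemaError(f"negative mean_fd for subject(s) {bad}")
        self.table = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def covariate_matrix(self, columns: tuple[str, ...] = ("age", "sex", "education", "mean_fd")) -> np.ndarray:
        """Covariates for modelling; errors name any subject with a gap."""
        sub = self.table[list(columns)]
        if sub.isna().any().any():
            bad = self.table.loc[sub.isna().any(axis=1), "subject_id"].tolist()
            raise SchemaError(
                f"incomplete covariates {list(columns)} for subject(s) {bad}"
            )
        return sub.to_numpy(dtype=float)

    def group_indicator(self) -> np.ndarray:
        """1 for case, 0 for control."""
        return (self.table["group"] == "case").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_atlas(path: str | Path) -> AtlasTable:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    required = {"region_id", "name", "hemisphere", "network", "cortical", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"atlas missing column(s): {sorted(missing)}")
    return AtlasTable(
        region_ids=df["region_id"].tolist(),
        names=df["name"].tolist(),
        hemispheres=df["hemisphere"].to_numpy(),
        networks=df["network"].to_numpy(),
        cortical=df["cortical"].to_numpy(dtype=bool),
        coordinates=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_atlas(atlas: AtlasTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "name": atlas.names,
            "hemisphere": atlas.hemispheres,
            "network": atlas.networks,
            "cortical": atlas.cortical.astype(int),
            "x": atlas.coordinates[:, 0],
            "y": atlas.coordinates[:, 1],
            "z": atlas.coordinates[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def read_timeseries(
    path: str | Path, atlas: AtlasTable, tr_seconds: float
) -> ParcellatedTimeSeries:
    """Read a tab-separated time x region table whose columns follow the atlas."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != list(atlas.region_ids):
        if len(df.columns) != atlas.n_regions:
            raise SchemaError(
                f"{len(df.columns)} columns in {path} but atlas has "
                f"{atlas.n_regions} regions"
            )
        raise SchemaError(f"column order in {path} does not match atlas region order")
    return ParcellatedTimeSeries(
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_ids=list(atlas.region_ids),
    )


def write_timeseries(series: ParcellatedTimeSeries, path: str | Path) -> None:
    pd.DataFrame(series.values, columns=series.region_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_subjects(path: str | Path) -> SubjectTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return SubjectTable(df)


def write_subjects(subjects: SubjectTable, path: str | Path) -> None:
    subjects.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_matrix(matrix: np.ndarray, path: str | Path, region_ids: list[str] | None = None) -> None:
    """Write a square matrix as a dense TSV with region ids as header/index.

    Floats are written in `repr` form, which round-trips exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise SchemaError(f"matrix must be square, got shape {matrix.shape}")
    ids = region_ids or [f"r{i}" for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="region_id", float_format="%.17g"
    )


def read_matrix(
    path: str | Path, symmetry_tol: float = 1e-10
) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="region_id", float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise SchemaError(f"matrix in {path} has mismatched row/column labels")
    m = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(m)):
        raise SchemaError(f"matrix in {path} contains non-finite entries")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > symmetry_tol:
        raise SchemaError(
            f"matrix in {path} is not symmetric (max |A - A.T| = {asym:.3e})"
        )
    return m, [str(c) for c in df.columns]


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, stable float repr)."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
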