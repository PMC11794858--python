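"""Readers and writers for the delimited-text interchange formats.

Layout of an input bundle directory:

* ``atlas.tsv`` — roi_id / roi_name / hemisphere / network
* ``cohort.tsv`` — one row per subject (schema in :mod:`fcbiotype.cohort`)
* ``connectomes/`` — one ``<subject_id>.tsv`` P x P matrix per subject,
  plus ``manifest.tsv`` mapping subject_id to file name
* ``maps.tsv`` + ``maps.json`` — P x n_maps densities and metadata

Matrices are written with 12 significant digits, enough for a lossless
round trip at the package's symmetry tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas
from .cohort import REQUIRED_COLUMNS, CohortTable
from .connectome import ConnectomeStack, fisher_z, vectorize_upper
from .errors import DimensionError, FormatError
from .maps import MapTable

MATRIX_FMT = "%.12g"


# -- atlas -------------------------------------------------------------

def read_atlas(path) -> Atlas:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse atlas TSV: {exc}") from exc
    return Atlas(table)


def write_atlas(atlas: Atlas, path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


# -- cohort ------------------------------------------------------------

def read_cohort(path) -> CohortTable:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing column(s): {missing}")
    return CohortTable(table)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- connectomes -------------------------------------------------------

def write_connectomes(stack: ConnectomeStack, directory) -> None:
    """One P x P TSV per subject plus a manifest mapping id -> file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sid, mat in zip(stack.subject_ids, stack.matrices()):
        fname = f"{sid}.tsv"
        np.savetxt(directory / fname, mat, delimiter="\t", fmt=MATRIX_FMT)
        manifest.append((sid, fname))
    pd.DataFrame(manifest, columns=["subject_id", "file"]).to_csv(
        directory / "manifest.tsv", sep="\t", index=False
    )


def read_connectomes(
    directory,
    P: int | None = None,
    allow_nan: bool = False,
    fisher_transform: bool = False,
) -> ConnectomeStack:
    """Load a per-subject matrix directory via its manifest.

    Missing values are rejected unless ``allow_nan`` is set, in which
    case NaN cells are imputed with the edgewise mean across subjects
    (exploratory use only). ``fisher_transform`` applies arctanh for
    matrices that arrive as raw correlations; the default assumes
    inputs are already Fisher-z.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.tsv"
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path}: manifest not found")
    manifest = pd.read_csv(manifest_path, sep="\t")
    if manifest["subject_id"].duplicated().any():
        dups = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{manifest_path}: duplicate subject id(s): {dups}")
    ids, rows = [], []
    for _, rec in manifest.iterrows():
        fpath = directory / rec["file"]
        mat = np.loadtxt(fpath, delimiter="\t", ndmin=2)
        if P is not None and mat.shape != (P, P):
            raise DimensionError(
                f"{fpath}: matrix shape {mat.shape} does not match atlas P={P}"
            )
        try:
            rows.append(vectorize_upper(mat))
        except FormatError as exc:
            raise FormatError(f"{fpath}: {exc}") from exc
        ids.append(str(rec["subject_id"]))
    if not rows:
        raise FormatError(f"{manifest_path}: manifest lists no subjects")
    edges = np.asarray(rows)
    if np.isnan(edges).any():
        if not allow_nan:
            bad = [ids[i] for i in np.unique(np.nonzero(np.isnan(edges))[0])]
            raise FormatError(
                f"{directory}: missing values in matrices of subject(s) {bad}; "
                "pass allow_nan=True to impute edgewise means"
            )
        col_mean = np.nanmean(edges, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(edges))
        edges[nan_r, nan_c] = col_mean[nan_c]
    if fisher_transform:
        edges = fisher_z(edges, clamp=1e-7)
    if P is None:
        P = int(round((1 + np.sqrt(1 + 8 * edges.shape[1])) / 2))
    return ConnectomeStack(ids, edges, P=P)


# -- maps --------------------------------------------------------------

def write_maps(maps: MapTable, path, sidecar=None) -> None:
    path = Path(path)
    maps.values.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    sidecar.write_text(json.dumps(maps.metadata, indent=2, sort_keys=True))


def read_maps(path, P: int | None = None, sidecar=None) -> MapTable:
    path = Path(path)
    values = pd.read_csv(path, sep="\t").astype(float)
    if P is not None and len(values) != P:
        raise DimensionError(f"{path}: {len(values)} rows but atlas has P={P} ROIs")
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return MapTable(values, metadata)


# -- bundle ------------------------------------------------------------

def write_bundle(directory, atlas, cohort, stack, maps=None, ground_truth=None) -> None:
    """Write a complete input bundle (atlas, cohort, connectomes, maps)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_atlas(atlas, directory / "atlas.tsv")
    write_cohort(cohort, directory / "cohort.tsv")
    write_connectomes(stack, directory / "connectomes")
    if maps is not None:
        write_maps(maps, directory / "maps.tsv")
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2, default=_json_default)
        )


def read_bundle(directory):
    """Read an input bundle; returns (atlas, cohort, stack, maps-or-None)."""
    directory = Path(directory)
    atlas = read_atlas(directory / "atlas.tsv")
    cohort = read_cohort(directory / "cohort.tsv")
    stack = read_connectomes(directory / "connectomes", P=atlas.P)
    maps_path = directory / "maps.tsv"
    maps = read_maps(maps_path, P=atlas.P) if maps_path.exists() else None
    return atlas, cohort, stack, maps


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
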