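"""Plain-text readers/writers: maps, cohort manifests, databases, results.

Polar maps are stored as header-less CSV grids (one row per pixel row, empty
cells outside the validity disc) with full-precision decimal representations,
so write -> read round trips are value-exact.  Cohorts are driven by a CSV
manifest; databases and comparison results get CSV grids plus a JSON sidecar.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
import numpy as np
import pandas as pd

from .core import Cohort, PolarMap, SubjectMeta
from .database import NormalDatabase
from .errors import FormatError
from .geometry import Geometry, SEGMENT_NAMES, make_geometry
from .segmental import SegmentTable
from .stats import ComparisonResult

__all__ = [
    "read_polar_map",
    "write_polar_map",
    "read_cohort",
    "write_cohort",
    "write_database",
    "read_database",
    "write_segment_table",
    "write_comparison",
]

MANIFEST_COLUMNS = ["subject_id", "gender", "bmi_class", "correction", "normalized", "path"]


def _write_grid(grid: np.ndarray, mask: np.ndarray, path: Path, fmt=repr) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in range(grid.shape[0]):
            writer.writerow(
                [fmt(grid[r, c]) if mask[r, c] else "" for c in range(grid.shape[1])]
            )


def _read_grid(path: Path, geometry: Geometry) -> np.ndarray:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    n = geometry.grid_size
    if len(rows) != n:
        raise FormatError(f"{path}: expected {n} rows, found {len(rows)}")
    grid = np.full((n, n), np.nan)
    for r, row in enumerate(rows):
        if len(row) != n:
            raise FormatError(f"{path}: row {r} has {len(row)} cells, expected {n}")
        for c, cell in enumerate(row):
            inside = bool(geometry.valid_mask[r, c])
            if cell.strip() == "":
                if inside:
                    raise FormatError(f"{path}: empty cell inside the mask at ({r}, {c})")
                continue
            if not inside:
                raise FormatError(f"{path}: value present outside the mask at ({r}, {c})")
            try:
                grid[r, c] = float(cell)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell at ({r}, {c}): {cell!r}") from exc
    return grid


def write_polar_map(pmap: PolarMap, path) -> None:
    """Write one map as a header-less CSV grid (empty cells outside the disc)."""
    _write_grid(pmap.counts, pmap.geometry.valid_mask, Path(path), fmt=lambda v: repr(float(v)))


def read_polar_map(
    path, geometry: Geometry, meta: SubjectMeta | None = None, normalized: bool = False
) -> PolarMap:
    """Read a map grid, validating dimensions and mask consistency."""
    grid = _read_grid(Path(path), geometry)
    if meta is None:
        meta = SubjectMeta(Path(path).stem, "male", "normal", "NC")
    return PolarMap(counts=grid, meta=meta, geometry=geometry, normalized=normalized)


def write_cohort(cohort: Cohort, out_dir, map_dir_name: str = "maps") -> Path:
    """Write all maps plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    map_dir = out_dir / map_dir_name
    map_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for pm in cohort.maps:
        fname = f"{pm.meta.subject_id}_{pm.meta.correction}.csv"
        write_polar_map(pm, map_dir / fname)
        records.append(
            {
                "subject_id": pm.meta.subject_id,
                "gender": pm.meta.gender,
                "bmi_class": pm.meta.bmi_class,
                "correction": pm.meta.correction,
                "normalized": pm.normalized,
                "path": f"{map_dir_name}/{fname}",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path, geometry: Geometry | None = None) -> Cohort:
    """Load a cohort from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    frame = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns and c != "normalized"]
    if missing:
        raise FormatError(f"{manifest_path}: missing manifest columns {missing}")
    if "normalized" not in frame.columns:
        frame["normalized"] = False
    dupes = frame.duplicated(subset=["subject_id", "correction"])
    if dupes.any():
        rows = frame.loc[dupes, ["subject_id", "correction"]].values.tolist()
        raise FormatError(f"{manifest_path}: duplicate (subject_id, correction) rows: {rows}")
    geometry = geometry if geometry is not None else make_geometry()
    maps = []
    for rec in frame.to_dict("records"):
        map_path = manifest_path.parent / str(rec["path"])
        if not map_path.exists():
            raise FormatError(f"{manifest_path}: referenced map file missing: {map_path}")
        meta = SubjectMeta(
            subject_id=str(rec["subject_id"]),
            gender=str(rec["gender"]),
            bmi_class=str(rec["bmi_class"]),
            correction=str(rec["correction"]),
        )
        maps.append(
            read_polar_map(map_path, geometry, meta=meta, normalized=bool(rec["normalized"]))
        )
    return Cohort(maps=maps, geometry=geometry)


def write_database(db: NormalDatabase, path_prefix) -> None:
    """Write mean/SD CSV grids plus a JSON sidecar at ``<prefix>{_mean,_sd}.csv``."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mask = db.geometry.valid_mask
    _write_grid(db.mean_map, mask, prefix.with_name(prefix.name + "_mean.csv"),
                fmt=lambda v: repr(float(v)))
    _write_grid(db.sd_map, mask, prefix.with_name(prefix.name + "_sd.csv"),
                fmt=lambda v: repr(float(v)))
    sidecar = {
        "n": db.n,
        "group": {"gender": db.group.gender, "bmi": db.group.bmi,
                  "correction": db.group.correction},
        "grid_size": db.geometry.grid_size,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_database(path_prefix, geometry: Geometry | None = None) -> NormalDatabase:
    from .database import GroupSelector

    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    geometry = geometry if geometry is not None else make_geometry(sidecar["grid_size"])
    mean_map = _read_grid(prefix.with_name(prefix.name + "_mean.csv"), geometry)
    sd_map = _read_grid(prefix.with_name(prefix.name + "_sd.csv"), geometry)
    group = GroupSelector(
        correction=sidecar["group"]["correction"],
        gender=sidecar["group"]["gender"],
        bmi=sidecar["group"]["bmi"],
    )
    return NormalDatabase(mean_map=mean_map, sd_map=sd_map, n=int(sidecar["n"]),
                          group=group, geometry=geometry)


def write_segment_table(tables, path) -> None:
    """Write one or several segment tables as a CSV (rows = segments).

    ``tables`` is either a single :class:`SegmentTable` or a mapping of
    comparison label -> table; with several tables the CSV gets one
    ``<label>_mean_diff`` and one ``<label>_two_sd`` column per comparison.
    """
    if isinstance(tables, SegmentTable):
        tables = {f"{tables.label_a} vs {tables.label_b}": tables}
    data: dict[str, list] = {"segment": list(SEGMENT_NAMES)}
    for label, table in tables.items():
        data[f"{label}_mean_diff"] = [table.rows[s].mean_diff for s in SEGMENT_NAMES]
        data[f"{label}_two_sd"] = [table.rows[s].two_sd for s in SEGMENT_NAMES]
    pd.DataFrame(data).to_csv(path, index=False)


def write_comparison(result: ComparisonResult, path_prefix) -> None:
    """Write t-map CSV, signed significance CSV and a JSON sidecar."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mask = result.geometry.valid_mask
    _write_grid(result.t_map, mask, prefix.with_name(prefix.name + "_tmap.csv"),
                fmt=lambda v: repr(float(v)))
    signed = np.where(result.sig_higher, 1, np.where(result.sig_lower, -1, 0))
    _write_grid(signed, mask, prefix.with_name(prefix.name + "_sig.csv"),
                fmt=lambda v: str(int(v)))
    sidecar = {
        "design": result.design,
        "alpha": result.alpha,
        "n_A": result.n_A,
        "n_B": result.n_B,
        "threshold": result.threshold,
        "n_significant": result.n_significant,
        "max_t_distribution": [float(v) for v in result.max_t_distribution],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
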