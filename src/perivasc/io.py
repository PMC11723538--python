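"""Readers and writers for the pipeline's file formats.

Formats: cell tables as CSV; tissue/compartment and vessel geometry as
GeoJSON FeatureCollections (RFC 7946 geometry syntax with planar μm
coordinates — geographic CRS markers are rejected); counts as TSV or MTX
(with row/col id files); annotations as TSV; configs as YAML; reports as
JSON.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .geometry import TissueGeometry
from .phenotyping import MARKERS
from .transcriptomics import ExpressionMatrix
from .vasculature import VesselObject

__all__ = [
    "write_cells_csv", "read_cells_csv",
    "write_tissue_geojson", "read_tissue_geojson",
    "write_vessels_geojson", "read_vessels_geojson",
    "write_counts_tsv", "read_counts_tsv",
    "write_counts_mtx", "read_counts_mtx",
    "write_annotations_tsv", "read_annotations_tsv",
    "load_yaml", "dump_yaml", "write_json_report",
]

_GEOJSON_NOTE = ("planar coordinates in micrometres, origin at ROI top-left, "
                 "y increasing downward (image convention); not geographic")


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cols = ["cell_id", "x_um", "y_um", *MARKERS]
    if "compartment" in cells.columns:
        cols.append("compartment")
    cells[cols].to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = {"cell_id", "x_um", "y_um"} - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns {sorted(missing)}")
    for m in MARKERS:
        if m in cells.columns and cells[m].dtype != bool:
            col = cells[m]
            if set(col.unique()) <= {0, 1, True, False}:
                cells[m] = col.astype(bool)
    return cells


def _check_planar(obj: dict, path) -> None:
    crs = obj.get("crs")
    if crs is not None:
        name = json.dumps(crs)
        if "4326" in name or "CRS84" in name or "WGS" in name.upper():
            raise ValueError(
                f"{path}: geographic (lat/lon) CRS not supported; "
                "coordinates must be planar micrometres"
            )


def write_tissue_geojson(geometry: TissueGeometry, path) -> None:
    features = [{
        "type": "Feature",
        "properties": {"role": "tissue"},
        "geometry": mapping(geometry.tissue),
    }]
    for label, geom in geometry.compartments.items():
        features.append({
            "type": "Feature",
            "properties": {"role": "compartment", "label": label},
            "geometry": mapping(geom),
        })
    obj = {"type": "FeatureCollection", "note": _GEOJSON_NOTE,
           "features": features}
    Path(path).write_text(json.dumps(obj))


def read_tissue_geojson(path) -> TissueGeometry:
    obj = json.loads(Path(path).read_text())
    _check_planar(obj, path)
    tissue = None
    compartments = {}
    for feat in obj["features"]:
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("role") == "tissue":
            tissue = geom
        elif props.get("role") == "compartment":
            compartments[props["label"]] = geom
    if tissue is None:
        raise ValueError(f"{path}: no feature with role 'tissue'")
    return TissueGeometry(tissue=tissue, compartments=compartments)


def write_vessels_geojson(vessels, path) -> None:
    features = []
    for v in vessels:
        features.append({
            "type": "Feature",
            "properties": {
                "vessel_id": v.vessel_id,
                "vessel_class": v.vessel_class,
                "flags": {k: bool(f) for k, f in v.flags.items()},
                "member_cell_ids": list(v.member_cell_ids),
            },
            "geometry": mapping(v.boundary),
        })
    obj = {"type": "FeatureCollection", "note": _GEOJSON_NOTE,
           "features": features}
    Path(path).write_text(json.dumps(obj))


def read_vessels_geojson(path) -> list:
    obj = json.loads(Path(path).read_text())
    _check_planar(obj, path)
    vessels = []
    for feat in obj["features"]:
        props = feat["properties"]
        vessels.append(VesselObject(
            vessel_id=props["vessel_id"],
            boundary=shape(feat["geometry"]),
            member_cell_ids=list(props["member_cell_ids"]),
            flags=dict(props.get("flags") or {}),
            vessel_class=props.get("vessel_class", "non-activated"),
        ))
    return vessels


def write_counts_tsv(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t")


def read_counts_tsv(path, annotations: pd.DataFrame | None = None,
                    scale: str = "counts") -> ExpressionMatrix | pd.DataFrame:
    values = pd.read_csv(path, sep="\t", index_col=0)
    if annotations is None:
        return values
    return ExpressionMatrix(values=values, annotations=annotations, scale=scale)


def write_counts_mtx(em: ExpressionMatrix, prefix) -> None:
    """MTX triple: <prefix>.mtx plus <prefix>.genes.txt / .samples.txt."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(em.values.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(em.genes) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(em.samples) + "\n")


def read_counts_mtx(prefix, annotations: pd.DataFrame | None = None,
                    scale: str = "counts"):
    from scipy.io import mmread

    prefix = Path(prefix)
    mat = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    values = pd.DataFrame(mat, index=genes, columns=samples)
    if annotations is None:
        return values
    return ExpressionMatrix(values=values, annotations=annotations, scale=scale)


def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t")


def read_annotations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2))
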