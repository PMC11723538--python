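"""Blood-vessel objects from CD31+ endothelial cells.

A vessel is a single-linkage cluster of CD31+ cell centroids (a shipped,
reproducible surrogate for pixel-based vessel segmentation), with a
buffered convex-hull boundary.  Vessel activation follows the "any part"
rule: a vessel is positive for a marker as soon as one member endothelial
cell is, and the flag triplet (PDL1, VCAM1, ICAM1) maps deterministically
onto six mutually exclusive classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .geometry import TissueGeometry

__all__ = [
    "VesselObject",
    "VESSEL_CLASSES",
    "classify_flags",
    "detect_vessels",
    "phenotype_vessel",
    "phenotype_vessels",
    "vessel_and_ec_density",
]

VESSEL_CLASSES = (
    "non-activated",
    "PDL1+",
    "VCAM1+",
    "ICAM1+",
    "VCAM1+ICAM1+",
    "other-multi",
)

ACTIVATION_MARKERS = ("PDL1", "VCAM1", "ICAM1")


@dataclass
class VesselObject:
    """One blood vessel: boundary polygon (μm), member CD31+ cells, flags."""

    vessel_id: str
    boundary: object                    # shapely polygon
    member_cell_ids: list
    flags: dict = field(default_factory=lambda: {m: False for m in ACTIVATION_MARKERS})
    vessel_class: str = "non-activated"

    def __post_init__(self):
        if not self.member_cell_ids:
            raise ValueError("vessel must have at least one member cell")


def classify_flags(pdl1: bool, vcam1: bool, icam1: bool) -> str:
    """Deterministic, total map from the flag triplet to the exclusive
    class taxonomy (precedence: both adhesion molecules first)."""
    if vcam1 and icam1:
        return "VCAM1+ICAM1+"
    n_flags = int(pdl1) + int(vcam1) + int(icam1)
    if n_flags == 0:
        return "non-activated"
    if n_flags == 1:
        if vcam1:
            return "VCAM1+"
        if icam1:
            return "ICAM1+"
        return "PDL1+"
    return "other-multi"    # PDL1 with exactly one adhesion molecule


def detect_vessels(
    cells: pd.DataFrame,
    link_radius_um: float = 20.0,
    min_cells: int = 3,
    ec_radius_um: float = 5.0,
    id_prefix: str = "V",
) -> list[VesselObject]:
    """Group CD31+ centroids into vessels by single linkage at
    ``link_radius_um`` (connected components of the distance graph) and
    keep groups with at least ``min_cells`` members.

    The boundary is the convex hull of member centroids buffered by
    ``ec_radius_um`` (a 1- or 2-point group yields a buffered
    point/segment).  No CD31+ cells yields an empty list.
    """
    if link_radius_um <= 0:
        raise ValueError("link_radius_um must be positive")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    cd31 = cells[cells["CD31"].astype(bool)]
    if cd31.empty:
        return []
    xy = cd31[["x_um", "y_um"]].to_numpy(float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(link_radius_um, output_type="ndarray")
    n = len(xy)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    vessels = []
    for k, cid in enumerate(np.unique(comp)):
        idx = np.flatnonzero(comp == cid)
        if len(idx) < min_cells:
            continue
        hull = MultiPoint(xy[idx]).convex_hull.buffer(ec_radius_um, quad_segs=16)
        vessels.append(
            VesselObject(
                vessel_id=f"{id_prefix}{len(vessels) + 1:04d}",
                boundary=hull,
                member_cell_ids=list(cd31["cell_id"].iloc[idx]),
            )
        )
    return vessels


def phenotype_vessel(vessel: VesselObject, cells: pd.DataFrame) -> VesselObject:
    """Set the vessel's activation flags and class from its member cells.

    The flag for marker M is true iff at least one member cell is
    M-positive (whole-or-part positivity).
    """
    members = cells.set_index("cell_id").loc[vessel.member_cell_ids]
    if members.empty:
        raise ValueError("vessel has no member cells in the table")
    if not members["CD31"].astype(bool).all():
        raise ValueError(f"vessel {vessel.vessel_id} has non-CD31+ members")
    flags = {m: bool(members[m].astype(bool).any()) for m in ACTIVATION_MARKERS}
    vessel.flags = flags
    vessel.vessel_class = classify_flags(
        flags["PDL1"], flags["VCAM1"], flags["ICAM1"]
    )
    return vessel


def phenotype_vessels(vessels, cells: pd.DataFrame) -> list[VesselObject]:
    return [phenotype_vessel(v, cells) for v in vessels]


def vessel_and_ec_density(
    vessels,
    cells: pd.DataFrame,
    geometry: TissueGeometry,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Vessel (BV) and endothelial-cell (EC) densities over the whole ROI.

    BV rows: vessels/mm² overall, per exclusive class, and for the
    activated (any flag) vs non-activated split, with proportions of the
    vessel total.  EC rows: CD31+ cells/mm² overall, per activation
    marker (CD31+ and that marker), and activated (any marker) vs
    non-activated, with proportions of the CD31+ total.  The two levels
    deliberately differ: a cell is "activated" through its own markers, a
    vessel through any member's.
    """
    area = geometry.tissue_area_mm2
    if area <= 0:
        raise ValueError("tissue area must be positive")
    rows = []

    n_vessels = len(vessels)
    by_class = {c: 0 for c in VESSEL_CLASSES}
    for v in vessels:
        by_class[v.vessel_class] += 1
    n_activated = n_vessels - by_class["non-activated"]

    def bv_row(group, count):
        rows.append({
            "sample_id": sample_id, "unit": "BV", "group": group,
            "count": count, "area_mm2": area, "density": count / area,
            "proportion_pct": 100.0 * count / n_vessels if n_vessels else 0.0,
        })

    bv_row("all", n_vessels)
    bv_row("activated", n_activated)
    for cls in VESSEL_CLASSES:
        bv_row(cls, by_class[cls])

    cd31 = cells[cells["CD31"].astype(bool)]
    n_ec = len(cd31)
    any_marker = np.zeros(n_ec, dtype=bool)
    per_marker = {}
    for m in ACTIVATION_MARKERS:
        pos = cd31[m].astype(bool).to_numpy()
        per_marker[m] = int(pos.sum())
        any_marker |= pos

    def ec_row(group, count):
        rows.append({
            "sample_id": sample_id, "unit": "EC", "group": group,
            "count": count, "area_mm2": area, "density": count / area,
            "proportion_pct": 100.0 * count / n_ec if n_ec else 0.0,
        })

    ec_row("all", n_ec)
    ec_row("activated", int(any_marker.sum()))
    ec_row("non-activated", n_ec - int(any_marker.sum()))
    for m in ACTIVATION_MARKERS:
        ec_row(f"{m}+", per_marker[m])
    return pd.DataFrame(rows)
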