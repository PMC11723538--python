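"""Marker calls, compartment assignment and per-compartment cell densities.

Cells travel as a pandas DataFrame (one row per cell) with columns
``cell_id``, ``x_um``, ``y_um``, one boolean column per marker in
:data:`MARKERS`, and ``compartment``.  Densities are cells per mm² of
compartment area, as in standard multiplex-IF quantification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .geometry import COMPARTMENT_ORDER, TissueGeometry

__all__ = [
    "MARKERS",
    "call_phenotypes",
    "assign_compartments",
    "compartment_density",
    "phenotype_density_panel",
    "parse_phenotype",
]

log = logging.getLogger(__name__)

MARKERS = ("CD3", "PanCK", "CD31", "VCAM1", "ICAM1", "PDL1")

# the activation-marker combinations reported for CD3+ T cells
_PANEL_COMBOS = (
    ("CD3",),
    ("CD3", "VCAM1"),
    ("CD3", "ICAM1"),
    ("CD3", "PDL1"),
    ("CD3", "PDL1", "VCAM1"),
    ("CD3", "PDL1", "ICAM1"),
    ("CD3", "VCAM1", "ICAM1"),
    ("CD3", "PDL1", "VCAM1", "ICAM1"),
)


def parse_phenotype(expression) -> tuple:
    """Normalise a phenotype spec ('CD3+PDL1+', 'CD3,PDL1', list) to a
    tuple of marker names that must all be positive."""
    if isinstance(expression, str):
        parts = [p for p in expression.replace("+", ",").split(",") if p]
    else:
        parts = list(expression)
    for m in parts:
        if m not in MARKERS:
            raise KeyError(f"unknown marker {m!r}")
    return tuple(parts)


def phenotype_mask(cells: pd.DataFrame, expression) -> pd.Series:
    markers = parse_phenotype(expression)
    mask = pd.Series(True, index=cells.index)
    for m in markers:
        mask &= cells[m].astype(bool)
    return mask


def call_phenotypes(table: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Threshold marker intensities into boolean calls.

    A cell is positive for marker M iff its intensity is >= thresholds[M]
    (single global cutoff per marker; no per-cell background correction).
    Columns that already hold boolean calls pass through unchanged.
    """
    out = table.copy()
    for marker, cutoff in thresholds.items():
        if marker not in table.columns:
            raise KeyError(f"marker column {marker!r} missing from table")
        col = table[marker]
        if col.dtype == bool:
            continue
        vals = col.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative intensity in marker {marker!r}")
        out[marker] = vals >= cutoff
    return out


def assign_compartments(
    cells: pd.DataFrame,
    geometry: TissueGeometry,
    order: tuple = COMPARTMENT_ORDER,
) -> pd.Series:
    """Label each cell with the compartment containing its centroid.

    Containment is tested in the fixed label order, so a centroid exactly
    on a shared edge goes to the compartment listed first.  Cells inside
    the tissue but outside every compartment get ``other``; cells outside
    the tissue get ``unassigned`` (counted and logged, never dropped).
    """
    pts = shapely.points(cells["x_um"].to_numpy(float),
                         cells["y_um"].to_numpy(float))
    labels = np.full(len(cells), "", dtype=object)
    assigned = np.zeros(len(cells), dtype=bool)
    for label in order:
        geom = geometry.compartments.get(label)
        if geom is None:
            continue
        inside = shapely.covers(geom, pts) & ~assigned
        labels[inside] = label
        assigned |= inside
    in_tissue = shapely.covers(geometry.tissue, pts)
    labels[~assigned & in_tissue] = "other"
    labels[~in_tissue] = "unassigned"
    n_out = int((~in_tissue).sum())
    if n_out:
        log.warning("%d cells lie outside the tissue polygon (kept as "
                    "'unassigned')", n_out)
    return pd.Series(labels, index=cells.index, name="compartment")


def compartment_density(
    cells: pd.DataFrame,
    geometry: TissueGeometry,
    phenotype,
    compartment: str,
    sample_id: str = "sample",
) -> dict:
    """One density row: cells matching ``phenotype`` in ``compartment``
    per mm² of that compartment's area.

    ``compartment='total'`` uses the whole tissue area and every cell
    inside the tissue (all compartments combined).
    """
    area = geometry.compartment_area_mm2(compartment)
    if area <= 0:
        raise ValueError(f"compartment {compartment!r} has zero area")
    mask = phenotype_mask(cells, phenotype)
    if compartment == "total":
        mask &= cells["compartment"] != "unassigned"
    else:
        mask &= cells["compartment"] == compartment
    count = int(mask.sum())
    markers = parse_phenotype(phenotype)
    return {
        "sample_id": sample_id,
        "compartment": compartment,
        "phenotype": "+".join(markers) + "+",
        "count": count,
        "area_mm2": area,
        "density": count / area,
    }


def phenotype_density_panel(
    cells: pd.DataFrame,
    geometry: TissueGeometry,
    sample_id: str = "sample",
    compartments: tuple = ("total", "tumour", "stroma"),
) -> pd.DataFrame:
    """Densities and percentage-of-parent for the CD3 activation panel.

    For each compartment: CD3+; CD3+ with each single activation marker;
    and all double/triple activation combinations.  ``pct_of_parent`` is
    the combination count as a percentage of the compartment's CD3+ count.
    """
    if "compartment" not in cells.columns:
        raise ValueError("cells must carry compartment labels; "
                         "run assign_compartments first")
    rows = []
    for comp in compartments:
        if comp != "total" and comp not in geometry.compartments:
            continue
        parent = compartment_density(cells, geometry, ("CD3",), comp, sample_id)
        for combo in _PANEL_COMBOS:
            row = compartment_density(cells, geometry, combo, comp, sample_id)
            row["pct_of_parent"] = (
                100.0 * row["count"] / parent["count"] if parent["count"] else 0.0
            )
            rows.append(row)
    return pd.DataFrame(rows)
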