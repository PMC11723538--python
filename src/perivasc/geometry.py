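"""Tissue geometry: the tissue outline and its labelled compartments.

All coordinates are planar micrometres (image convention: origin at the
ROI top-left, y increasing downward); areas are reported in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

__all__ = ["TissueGeometry", "UM2_PER_MM2", "COMPARTMENT_ORDER"]

UM2_PER_MM2 = 1.0e6

# fixed label order; doubles as the tie rule for cells on shared edges
COMPARTMENT_ORDER = ("tumour", "stroma", "other")


@dataclass
class TissueGeometry:
    """Tissue polygon plus compartment polygons keyed by label (μm units)."""

    tissue: Polygon | MultiPolygon
    compartments: dict = field(default_factory=dict)
    um_per_unit: float = 1.0

    def __post_init__(self):
        if self.tissue.is_empty or self.tissue.area <= 0:
            raise ValueError("tissue polygon must have positive area")
        for label, geom in self.compartments.items():
            if geom.is_empty:
                raise ValueError(f"compartment {label!r} is empty")

    @property
    def tissue_area_mm2(self) -> float:
        return self.tissue.area * self.um_per_unit**2 / UM2_PER_MM2

    def compartment_area_mm2(self, label: str) -> float:
        if label == "total":
            return self.tissue_area_mm2
        if label not in self.compartments:
            raise KeyError(f"no compartment {label!r}")
        return self.compartments[label].area * self.um_per_unit**2 / UM2_PER_MM2

    def validate(self, tol_frac: float = 1e-3) -> None:
        """Check compartments lie inside the tissue and are mutually
        non-overlapping, both within an areal tolerance fraction."""
        tissue_area = self.tissue.area
        for label, geom in self.compartments.items():
            outside = geom.difference(self.tissue).area
            if outside > tol_frac * tissue_area:
                raise ValueError(f"compartment {label!r} extends outside tissue")
        labels = list(self.compartments)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                inter = self.compartments[a].intersection(self.compartments[b]).area
                if inter > tol_frac * tissue_area:
                    raise ValueError(f"compartments {a!r} and {b!r} overlap")

    @classmethod
    def rectangle(cls, width_um: float, height_um: float,
                  compartments: dict | None = None) -> "TissueGeometry":
        return cls(tissue=box(0.0, 0.0, width_um, height_um),
                   compartments=compartments or {})

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.tissue, pts)


def union_area_mm2(geoms) -> float:
    return unary_union(list(geoms)).area / UM2_PER_MM2
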