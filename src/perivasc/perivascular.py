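"""Annular distance-band analysis of cell density around phenotyped vessels.

For each vessel class, concentric 30 μm bands (default four, 0–120 μm)
are drawn around the union of that class's vessel boundaries.  A target
cell (CD3+ by default) contributes to the band of its distance to the
nearest vessel of the class — so one cell may appear in several classes'
profiles but in exactly one band within a class.  Cells inside a vessel
of the measured class count in band 1 (distance 0); vessel interiors are
excluded from band areas.  Band densities pool counts and areas over all
vessels of the class, matching one reported density per zone per
phenotype; per-vessel tables are available for re-aggregation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .geometry import UM2_PER_MM2, TissueGeometry
from .phenotyping import phenotype_mask
from .stats import TestResult, spearman, wilcoxon_signed_rank

__all__ = [
    "distance_to_class",
    "band_regions",
    "zonal_density",
    "per_vessel_zonal",
    "gradient_test",
    "proximal_vs_distal",
    "DEFAULT_BAND_WIDTH_UM",
    "DEFAULT_N_BANDS",
]

log = logging.getLogger(__name__)

DEFAULT_BAND_WIDTH_UM = 30.0
DEFAULT_N_BANDS = 4


def _class_union(vessels, vessel_class: str | None):
    polys = [v.boundary for v in vessels
             if vessel_class is None or v.vessel_class == vessel_class]
    if not polys:
        raise ValueError(f"no vessels of class {vessel_class!r}")
    return unary_union(polys)


def distance_to_class(cells: pd.DataFrame, vessels, vessel_class: str | None = None
                      ) -> np.ndarray:
    """Euclidean distance (μm) from each cell centroid to the nearest
    boundary of any vessel of the class; 0 for centroids inside a vessel.

    Raises ValueError when the class has no vessels (callers skip the
    class in that case).
    """
    union = _class_union(vessels, vessel_class)
    pts = shapely.points(cells["x_um"].to_numpy(float),
                         cells["y_um"].to_numpy(float))
    return shapely.distance(pts, union)


def band_regions(
    vessels,
    geometry: TissueGeometry,
    vessel_class: str | None = None,
    band_width_um: float = DEFAULT_BAND_WIDTH_UM,
    n_bands: int = DEFAULT_N_BANDS,
    clip: str = "tissue",
    quad_segs: int = 64,
) -> list:
    """Band polygons around the class's vessel union.

    Band k (1-based) covers distances [band_width*(k-1), band_width*k)
    from the union boundary, built as differences of buffered unions,
    minus the vessel interiors, and (with ``clip='tissue'``, the default)
    intersected with the tissue polygon; ``clip='nominal'`` keeps the full
    annuli.  Returns a list of ``n_bands`` shapely geometries.
    """
    if clip not in ("tissue", "nominal"):
        raise ValueError("clip must be 'tissue' or 'nominal'")
    if geometry.tissue.area <= 0:
        raise ValueError("degenerate tissue polygon")
    union = _class_union(vessels, vessel_class)
    bands = []
    inner = union
    for k in range(1, n_bands + 1):
        outer = union.buffer(band_width_um * k, quad_segs=quad_segs)
        band = outer.difference(inner)
        if clip == "tissue":
            band = band.intersection(geometry.tissue)
        bands.append(band)
        inner = outer
    return bands


def band_areas_mm2(bands) -> np.ndarray:
    return np.array([b.area for b in bands]) / UM2_PER_MM2


def zonal_density(
    cells: pd.DataFrame,
    vessels,
    geometry: TissueGeometry,
    classes=None,
    phenotype="CD3",
    band_width_um: float = DEFAULT_BAND_WIDTH_UM,
    n_bands: int = DEFAULT_N_BANDS,
    clip: str = "tissue",
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Zonal profile: per vessel class and band, the target-cell count,
    band area (mm²) and density (cells/mm²).

    Classes with zero vessels are omitted with a logged notice.  Band
    edges are half-open [w*(k-1), w*k), inner edge inclusive.
    """
    present = sorted({v.vessel_class for v in vessels})
    if classes is None:
        classes = present
    target = cells[phenotype_mask(cells, phenotype)]
    rows = []
    for cls in classes:
        if cls not in present:
            log.info("vessel class %r has no vessels; omitted from zonal "
                     "profile", cls)
            continue
        dist = distance_to_class(target, vessels, cls)
        bands = band_regions(vessels, geometry, cls, band_width_um, n_bands,
                             clip=clip)
        areas = band_areas_mm2(bands)
        band_idx = np.floor(dist / band_width_um).astype(int)
        for k in range(n_bands):
            count = int(np.sum(band_idx == k))
            area = float(areas[k])
            rows.append({
                "sample_id": sample_id,
                "vessel_class": cls,
                "band": k + 1,
                "band_lo_um": band_width_um * k,
                "band_hi_um": band_width_um * (k + 1),
                "count": count,
                "band_area_mm2": area,
                "density": count / area if area > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def per_vessel_zonal(
    cells: pd.DataFrame,
    vessels,
    geometry: TissueGeometry,
    vessel_class: str,
    phenotype="CD3",
    band_width_um: float = DEFAULT_BAND_WIDTH_UM,
    n_bands: int = DEFAULT_N_BANDS,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Raw per-vessel band counts for one class, for re-aggregation.

    Each target cell within range is attributed to its nearest vessel of
    the class (by boundary distance), so summing counts over vessels
    reproduces the pooled zonal counts exactly.  Per-vessel band areas are
    that vessel's own annuli clipped to tissue, minus the class's vessel
    interiors; they overlap between nearby vessels and are reported for
    reference, not for pooled-density computation.
    """
    members = [v for v in vessels if v.vessel_class == vessel_class]
    if not members:
        raise ValueError(f"no vessels of class {vessel_class!r}")
    target = cells[phenotype_mask(cells, phenotype)]
    pts = shapely.points(target["x_um"].to_numpy(float),
                         target["y_um"].to_numpy(float))
    dmat = np.stack([shapely.distance(pts, v.boundary) for v in members])
    nearest = dmat.argmin(axis=0)
    dist = dmat.min(axis=0)
    band_idx = np.floor(dist / band_width_um).astype(int)
    class_union = unary_union([v.boundary for v in members])
    rows = []
    for vi, v in enumerate(members):
        own_bands = band_regions([v], geometry, None, band_width_um, n_bands)
        for k in range(n_bands):
            area_geom = own_bands[k].difference(class_union)
            count = int(np.sum((nearest == vi) & (band_idx == k)))
            rows.append({
                "sample_id": sample_id,
                "vessel_class": vessel_class,
                "vessel_id": v.vessel_id,
                "band": k + 1,
                "count": count,
                "band_area_mm2": area_geom.area / UM2_PER_MM2,
            })
    return pd.DataFrame(rows)


def gradient_test(profile: pd.DataFrame, two_sided: bool = True) -> TestResult:
    """Spearman rank correlation of band density against band index.

    ``profile`` holds one vessel class, with columns ``band`` and
    ``density``; rows from multiple samples pool as (sample, band)
    observations.  A negative rho with small p indicates a proximal-to-
    distal density gradient.
    """
    prof = profile.dropna(subset=["density"])
    if prof["band"].nunique() < 2:
        raise ValueError("gradient test needs >= 2 bands with defined density")
    return spearman(prof["band"].to_numpy(float),
                    prof["density"].to_numpy(float), two_sided=two_sided)


def proximal_vs_distal(
    band1_densities, band4_densities, two_sided: bool = True
) -> TestResult:
    """Paired Wilcoxon signed-rank test of the most proximal band against
    the most distal band, one pair per sample.

    Pairs with a missing band are dropped and logged.  (The comparison is
    sometimes described as a paired rank-sum test; the rank-sum test has
    no paired form, so the signed-rank test on band1 - band4 differences
    is the procedure implemented.)
    """
    b1 = np.asarray(band1_densities, dtype=float)
    b4 = np.asarray(band4_densities, dtype=float)
    if b1.shape != b4.shape:
        raise ValueError("band-1 and band-4 vectors must align")
    ok = np.isfinite(b1) & np.isfinite(b4)
    dropped = int((~ok).sum())
    if dropped:
        log.info("proximal_vs_distal: dropped %d pairs with a missing band",
                 dropped)
    if ok.sum() < 1:
        raise ValueError("no usable sample pairs")
    return wilcoxon_signed_rank(b1[ok] - b4[ok], two_sided=two_sided)
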