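"""Synthetic multiplex-IF tissues: compartments, vessels and cell point
patterns with an optional perivascular T-cell density gradient.

The simulated ROI is a rectangle (default 2 x 2 mm, image convention).
Compartments are a blobby random partition from thresholded smoothed
noise, parameterised only by target area fractions.  Vessels are circles
(radius drawn from a configured range) placed uniformly without overlap;
each carries a ring of CD31+ member cells whose activation-marker calls
reproduce the planted vessel class under the any-member rule.

CD3+ cells follow an inhomogeneous Poisson process with intensity

    lambda(x) = beta0 * (1 + A * exp(-d(x) / tau))

where d(x) is the distance to the nearest anchor-class vessel boundary
(0 inside a vessel), beta0 the baseline density, A the gradient amplitude
and tau the decay length — the planted analogue of a T-cell gradient
around ICAM-1-activated vessels.  All other phenotypes are homogeneous
Poisson at their configured baseline densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, box
from shapely.ops import unary_union

from ..geometry import UM2_PER_MM2, TissueGeometry
from ..phenotyping import MARKERS, assign_compartments
from ..vasculature import VesselObject, classify_flags

__all__ = ["TissueSimConfig", "VesselPlacementError", "simulate_tissue"]


class VesselPlacementError(RuntimeError):
    """Raised when vessels cannot be placed without overlap; carries the
    count achieved before giving up."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved}/{requested} vessels without overlap "
            "(tissue too crowded)"
        )


DEFAULT_VESSELS = {
    # counts for a 2 x 2 mm ROI, mirroring the observed class mix:
    # VCAM1+ commonest, VCAM1+ICAM1+ and ICAM1+ sparser, PD-L1+ rare
    "VCAM1+": 25,
    "VCAM1+ICAM1+": 5,
    "ICAM1+": 5,
    "PDL1+": 2,
    "non-activated": 8,
}


@dataclass
class TissueSimConfig:
    """Study conditions for one simulated ROI.

    ``gradient`` is (anchor_class, amplitude A, decay tau μm) or None for
    a homogeneous CD3 field.  ``baseline_density`` maps a phenotype (a
    comma-joined list of positive markers, e.g. ``"CD3"`` or
    ``"CD3,PDL1"``) to cells/mm².
    """

    width_um: float = 2000.0
    height_um: float = 2000.0
    compartment_spec: list = field(
        default_factory=lambda: [("tumour", 0.45), ("stroma", 0.45)]
    )
    n_vessels_by_class: dict = field(default_factory=lambda: dict(DEFAULT_VESSELS))
    vessel_radius_um: tuple = (5.0, 15.0)
    baseline_density: dict = field(
        default_factory=lambda: {"CD3": 500.0, "PanCK": 800.0}
    )
    gradient: tuple | None = ("ICAM1+", 3.0, 25.0)
    ec_spacing_um: float = 10.0      # target spacing of member ECs on the ring
    member_marker_rate: float = 0.7  # per-member positivity within the class markers
    tile_um: float = 50.0            # compartment noise-grid resolution
    noise_sigma_tiles: float = 2.0   # smoothing of the compartment noise field
    max_place_tries: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI dimensions must be positive")
        fracs = [f for _, f in self.compartment_spec]
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise ValueError("compartment area fractions must be >= 0 and sum <= 1")
        for label, _ in self.compartment_spec:
            if label not in ("tumour", "stroma", "other"):
                raise ValueError(f"unknown compartment label {label!r}")
        lo, hi = (self.vessel_radius_um
                  if np.iterable(self.vessel_radius_um)
                  else (self.vessel_radius_um, self.vessel_radius_um))
        if not (0 < lo <= hi):
            raise ValueError("vessel_radius_um must be positive")
        if any(n < 0 for n in self.n_vessels_by_class.values()):
            raise ValueError("vessel counts must be non-negative")
        if any(d < 0 for d in self.baseline_density.values()):
            raise ValueError("densities must be non-negative")
        if self.gradient is not None:
            anchor, amp, tau = self.gradient
            if amp < 0:
                raise ValueError("gradient amplitude A must be >= 0")
            if tau <= 0:
                raise ValueError("gradient decay tau must be > 0")
            if anchor not in self.n_vessels_by_class:
                raise ValueError(f"gradient anchor class {anchor!r} has no vessels")


def _simulate_compartments(config: TissueSimConfig, rng) -> dict:
    """Blobby partition: threshold a smoothed noise grid at the quantiles
    matching the target area fractions; tiles -> unioned polygons."""
    if not config.compartment_spec:
        return {}
    nx = max(2, int(round(config.width_um / config.tile_um)))
    ny = max(2, int(round(config.height_um / config.tile_um)))
    noise = gaussian_filter(rng.standard_normal((ny, nx)),
                            sigma=config.noise_sigma_tiles)
    order = np.argsort(noise.ravel())
    n_tiles = nx * ny
    labels = np.full(n_tiles, "", dtype=object)
    start = 0
    for label, frac in config.compartment_spec:
        n_take = int(round(frac * n_tiles))
        take = order[start:start + n_take]
        labels[take] = label
        start += n_take
    dx = config.width_um / nx
    dy = config.height_um / ny
    compartments = {}
    for label in dict(config.compartment_spec):
        idx = np.flatnonzero(labels == label)
        if idx.size == 0:
            continue
        iy, ix = np.unravel_index(idx, (ny, nx))
        tiles = [box(x * dx, y * dy, (x + 1) * dx, (y + 1) * dy)
                 for x, y in zip(ix, iy)]
        compartments[label] = unary_union(tiles)
    return compartments


def _place_vessels(config: TissueSimConfig, rng) -> list:
    """Uniform non-overlapping circle placement with bounded retries.
    Returns (class, centre, radius) triples in a seed-stable order."""
    lo, hi = (config.vessel_radius_um
              if np.iterable(config.vessel_radius_um)
              else (config.vessel_radius_um, config.vessel_radius_um))
    placed = []   # (class, cx, cy, r)
    requested = sum(config.n_vessels_by_class.values())
    for cls in sorted(config.n_vessels_by_class):
        for _ in range(config.n_vessels_by_class[cls]):
            ok = False
            for _try in range(config.max_place_tries):
                r = rng.uniform(lo, hi)
                cx = rng.uniform(r, config.width_um - r)
                cy = rng.uniform(r, config.height_um - r)
                if all((cx - px) ** 2 + (cy - py) ** 2 > (r + pr + 1.0) ** 2
                       for _, px, py, pr in placed):
                    placed.append((cls, cx, cy, r))
                    ok = True
                    break
            if not ok:
                raise VesselPlacementError(requested, len(placed))
    return placed


def _member_calls(cls: str, n: int, rate: float, rng) -> np.ndarray:
    """Boolean (n x 3) activation calls (PDL1, VCAM1, ICAM1) for member
    ECs such that the any-member rule recovers exactly the planted class."""
    calls = np.zeros((n, 3), dtype=bool)
    need = {
        "non-activated": [],
        "PDL1+": [0],
        "VCAM1+": [1],
        "ICAM1+": [2],
        "VCAM1+ICAM1+": [1, 2],
        "other-multi": [0, 1],        # PD-L1 with one adhesion molecule
    }[cls]
    for col in need:
        calls[:, col] = rng.random(n) < rate
        calls[rng.integers(n), col] = True     # guarantee >= 1 positive member
    assert classify_flags(*calls.any(axis=0)) == cls
    return calls


def simulate_tissue(config: TissueSimConfig):
    """Draw one synthetic ROI, deterministically per seed.

    Returns ``(TissueGeometry, cells DataFrame, list of VesselObject)``.
    Every CD31+ cell belongs to exactly one vessel; every cell lies inside
    the tissue; vessels are pairwise disjoint and inside the tissue.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geometry = TissueGeometry.rectangle(
        config.width_um, config.height_um,
        compartments=_simulate_compartments(config, rng),
    )
    area_mm2 = geometry.tissue_area_mm2

    placed = _place_vessels(config, rng)
    vessels = []
    records = []
    cell_counter = 0

    def new_id():
        nonlocal cell_counter
        cell_counter += 1
        return f"C{cell_counter:06d}"

    for cls, cx, cy, r in placed:
        n_members = max(3, int(rng.poisson(2.0 * np.pi * r / config.ec_spacing_um)))
        theta = rng.uniform(0.0, 2.0 * np.pi, n_members)
        rad = rng.uniform(0.55 * r, 0.95 * r, n_members)
        xs = cx + rad * np.cos(theta)
        ys = cy + rad * np.sin(theta)
        calls = _member_calls(cls, n_members, config.member_marker_rate, rng)
        ids = []
        for i in range(n_members):
            cid = new_id()
            ids.append(cid)
            rec = {m: False for m in MARKERS}
            rec.update(cell_id=cid, x_um=xs[i], y_um=ys[i], CD31=True,
                       PDL1=bool(calls[i, 0]), VCAM1=bool(calls[i, 1]),
                       ICAM1=bool(calls[i, 2]))
            records.append(rec)
        boundary = Point(cx, cy).buffer(r, quad_segs=64)
        flags = dict(zip(("PDL1", "VCAM1", "ICAM1"), calls.any(axis=0)))
        vessels.append(VesselObject(
            vessel_id=f"V{len(vessels) + 1:04d}", boundary=boundary,
            member_cell_ids=ids,
            flags={k: bool(v) for k, v in flags.items()},
            vessel_class=cls,
        ))

    anchor_union = None
    if config.gradient is not None:
        anchor, amp, tau = config.gradient
        anchors = [v.boundary for v in vessels if v.vessel_class == anchor]
        if anchors:
            anchor_union = unary_union(anchors)
    # non-endothelial cells live in the parenchyma: vessel lumens are
    # excluded from every baseline point field
    vessel_union = unary_union([v.boundary for v in vessels]) if vessels else None

    for phenotype in sorted(config.baseline_density):
        beta0 = config.baseline_density[phenotype]
        markers = [m.strip() for m in phenotype.split(",")]
        use_gradient = (config.gradient is not None and "CD3" in markers
                        and anchor_union is not None)
        if use_gradient:
            _, amp, tau = config.gradient
            lam_max = beta0 * (1.0 + amp)
        else:
            amp, tau = 0.0, 1.0
            lam_max = beta0
        n_cand = rng.poisson(lam_max * area_mm2)
        x = rng.uniform(0.0, config.width_um, n_cand)
        y = rng.uniform(0.0, config.height_um, n_cand)
        if use_gradient and n_cand:
            d = shapely.distance(shapely.points(x, y), anchor_union)
            accept = rng.random(n_cand) < (1.0 + amp * np.exp(-d / tau)) / (1.0 + amp)
            x, y = x[accept], y[accept]
        if vessel_union is not None and len(x):
            outside = ~shapely.covers(vessel_union, shapely.points(x, y))
            x, y = x[outside], y[outside]
        for xi, yi in zip(x, y):
            rec = {m: False for m in MARKERS}
            rec.update(cell_id=new_id(), x_um=xi, y_um=yi)
            for m in markers:
                rec[m] = True
            records.append(rec)

    columns = ["cell_id", "x_um", "y_um", *MARKERS]
    cells = pd.DataFrame.from_records(records, columns=columns)
    cells["compartment"] = (
        assign_compartments(cells, geometry) if len(cells)
        else pd.Series(dtype=object)
    )
    return geometry, cells, vessels
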