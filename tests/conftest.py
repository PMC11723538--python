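import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from perivasc.geometry import TissueGeometry
from perivasc.synthetic import (
    ExprSimConfig,
    TissueSimConfig,
    simulate_expression,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def small_tissue():
    """A modest default-structure ROI shared by read-only tests."""
    cfg = TissueSimConfig(
        width_um=1500.0,
        height_um=1500.0,
        n_vessels_by_class={"ICAM1+": 5, "VCAM1+": 8, "non-activated": 5,
                            "VCAM1+ICAM1+": 3, "PDL1+": 2},
        baseline_density={"CD3": 400.0, "PanCK": 600.0},
        seed=42,
    )
    geometry, cells, vessels = simulate_tissue(cfg)
    return cfg, geometry, cells, vessels


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced expression cohort for fast unit tests."""
    cfg = ExprSimConfig(
        n_by_subtype={"Basal": 30, "LumA": 60, "LumB": 30, "HER2": 15},
        n_genes=150,
        seed=11,
    )
    return cfg, simulate_expression(cfg)


@pytest.fixture
def square_geometry():
    """1 x 1 mm tissue, left half tumour, right half stroma."""
    return TissueGeometry(
        tissue=box(0, 0, 1000, 1000),
        compartments={
            "tumour": box(0, 0, 500, 1000),
            "stroma": box(500, 0, 1000, 1000),
        },
    )


def make_cells(xy, **markers):
    """Build a minimal cell table at the given coordinates."""
    from perivasc.phenotyping import MARKERS

    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame({
        "cell_id": [f"C{i:04d}" for i in range(len(xy))],
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
    })
    for m in MARKERS:
        df[m] = markers.get(m, False)
    return df
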