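"""End-to-end orchestration: spatial arm, expression arm, and the
reproducible JSON + Markdown report.

A run is described by a :class:`RunConfig` (loadable from YAML).  The
spatial arm takes one or more samples (cell table + geometry, with
vessels either provided or detected), computes compartment densities,
vessel/EC densities and zonal profiles, and runs the gradient and
proximal-vs-distal tests pooled over samples.  The expression arm takes a
counts matrix with annotations, runs the vst/cluster/label/association
chain and basal-vs-rest differential expression.  Either arm may be
omitted.  Every intermediate table is written to the output directory;
the report records config, seed and package version.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .perivascular import gradient_test, proximal_vs_distal, zonal_density
from .phenotyping import assign_compartments, call_phenotypes, phenotype_density_panel
from .stats import bh_adjust
from .transcriptomics import (
    cluster_subtype_association,
    differential_expression,
    hierarchical_cluster,
    label_clusters,
    reverse_log_transform,
    size_factors,
    standardize_rows,
    vst,
)
from .vasculature import detect_vessels, phenotype_vessels, vessel_and_ec_density

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

DEFAULT_CLASSES = ("ICAM1+", "VCAM1+", "VCAM1+ICAM1+", "non-activated")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class SampleInput:
    sample_id: str
    cells: str
    geometry: str
    vessels: str | None = None


@dataclass
class RunConfig:
    """Everything a run needs; all tunables with their defaults."""

    out_dir: str = "perivasc_out"
    samples: list = field(default_factory=list)          # SampleInput or dicts
    thresholds: dict | None = None                       # marker -> cutoff
    link_radius_um: float = 20.0
    min_vessel_cells: int = 3
    ec_radius_um: float = 5.0
    band_width_um: float = 30.0
    n_bands: int = 4
    band_clip: str = "tissue"
    vessel_classes: tuple = DEFAULT_CLASSES
    alpha_spatial: float = 0.05
    alpha_de: float = 0.01
    counts: str | None = None                            # TSV path (genes x samples)
    counts_scale: str = "counts"                         # or "log2"
    annotations: str | None = None
    geneset: str | None = None                           # one gene id per line
    k_clusters: int = 4
    k_gene_clusters: int = 2
    ward_convention: str = "ward_d2"
    de_groups: str = "Basal:rest"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha_spatial < 1.0 or not 0.0 < self.alpha_de < 1.0:
            raise ValueError("alpha levels must be in (0, 1)")
        if self.band_width_um <= 0 or self.n_bands < 1:
            raise ValueError("band widths must be positive")
        self.samples = [
            s if isinstance(s, SampleInput) else SampleInput(**s)
            for s in self.samples
        ]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_yaml(path))


def _spatial_sample(cfg: RunConfig, sample: SampleInput):
    cells = io.read_cells_csv(sample.cells)
    geometry = io.read_tissue_geojson(sample.geometry)
    if cfg.thresholds:
        cells = call_phenotypes(cells, cfg.thresholds)
    if "compartment" not in cells.columns:
        cells["compartment"] = assign_compartments(cells, geometry)
    if sample.vessels:
        vessels = io.read_vessels_geojson(sample.vessels)
    else:
        vessels = detect_vessels(cells, cfg.link_radius_um,
                                 cfg.min_vessel_cells, cfg.ec_radius_um,
                                 id_prefix=f"{sample.sample_id}_V")
        vessels = phenotype_vessels(vessels, cells)
    return cells, geometry, vessels


def _run_spatial(cfg: RunConfig, out: Path, report: dict) -> None:
    panels, vessel_tabs, profiles = [], [], []
    for sample in cfg.samples:
        try:
            cells, geometry, vessels = _spatial_sample(cfg, sample)
        except Exception as exc:   # noqa: BLE001 - rewrap with stage context
            raise PipelineError("load", f"sample {sample.sample_id}: {exc}") from exc
        panels.append(phenotype_density_panel(cells, geometry, sample.sample_id))
        vessel_tabs.append(vessel_and_ec_density(vessels, cells, geometry,
                                                 sample.sample_id))
        profiles.append(zonal_density(
            cells, vessels, geometry, classes=list(cfg.vessel_classes),
            band_width_um=cfg.band_width_um, n_bands=cfg.n_bands,
            clip=cfg.band_clip, sample_id=sample.sample_id,
        ))
    panel = pd.concat(panels, ignore_index=True)
    vessel_tab = pd.concat(vessel_tabs, ignore_index=True)
    zonal = pd.concat(profiles, ignore_index=True)
    panel.to_csv(out / "densities.tsv", sep="\t", index=False)
    vessel_tab.to_csv(out / "vessel_density.tsv", sep="\t", index=False)
    zonal.to_csv(out / "zonal_profile.tsv", sep="\t", index=False)

    tests = {}
    raw_ps = []
    keys = []
    for cls in cfg.vessel_classes:
        prof = zonal[zonal["vessel_class"] == cls]
        if prof.empty or prof["band"].nunique() < 2:
            continue
        g = gradient_test(prof)
        entry = {"gradient": g.as_dict()}
        wide = prof.pivot_table(index="sample_id", columns="band",
                                values="density")
        if 1 in wide.columns and cfg.n_bands in wide.columns:
            both = wide[[1, cfg.n_bands]].dropna()
            if len(both) >= 1 and np.any(both[1] != both[cfg.n_bands]):
                w = proximal_vs_distal(both[1], both[cfg.n_bands])
                entry["proximal_vs_distal"] = w.as_dict()
                raw_ps.append(w.p_value)
                keys.append((cls, "proximal_vs_distal"))
        raw_ps.append(g.p_value)
        keys.append((cls, "gradient"))
        tests[cls] = entry
    if raw_ps:
        adj = bh_adjust(raw_ps)
        for (cls, which), q in zip(keys, adj):
            tests[cls][which]["p_adjusted"] = float(q)
    report["spatial"] = {
        "n_samples": len(cfg.samples),
        "cd3_density_total_median": float(
            panel.query("compartment == 'total' and phenotype == 'CD3+'")
            ["density"].median()
        ),
        "cd3_density_stroma_median": float(
            panel.query("compartment == 'stroma' and phenotype == 'CD3+'")
            ["density"].median()
        ) if (panel["compartment"] == "stroma").any() else None,
        "cd3_density_tumour_median": float(
            panel.query("compartment == 'tumour' and phenotype == 'CD3+'")
            ["density"].median()
        ) if (panel["compartment"] == "tumour").any() else None,
        "bv_density_median": float(
            vessel_tab.query("unit == 'BV' and group == 'all'")["density"].median()
        ),
        "zonal_tests": tests,
        "alpha": cfg.alpha_spatial,
    }


def _run_expression(cfg: RunConfig, out: Path, report: dict) -> None:
    if cfg.annotations is None:
        raise PipelineError("expression", "counts given without annotations")
    ann = io.read_annotations_tsv(cfg.annotations)
    em = io.read_counts_tsv(cfg.counts, annotations=ann, scale=cfg.counts_scale)
    counts = em.to_counts().values
    counts = counts.round().astype(np.int64)
    sf = size_factors(counts)
    transformed = vst(counts, sf)
    if cfg.geneset:
        genes = [g for g in Path(cfg.geneset).read_text().split() if g]
        missing = set(genes) - set(transformed.index)
        if missing:
            raise PipelineError("cluster", f"gene set ids absent: {sorted(missing)[:5]}")
        subset = transformed.loc[genes]
    else:
        subset = transformed
    std = standardize_rows(subset)
    std.to_csv(out / "standardized_matrix.tsv", sep="\t")
    labeling = hierarchical_cluster(std, cfg.k_clusters, cfg.k_gene_clusters,
                                    method=cfg.ward_convention)
    labeling = label_clusters(labeling, std)
    assign = pd.DataFrame({
        "cluster": labeling.sample_cluster,
        "label": labeling.sample_labels,
    })
    assign.to_csv(out / "cluster_assignment.tsv", sep="\t")
    expr_report = {
        "cluster_sizes": labeling.sample_cluster.value_counts().to_dict(),
        "cluster_medians_cd3d": labeling.cluster_medians,
        "cluster_labels": labeling.cluster_labels,
    }
    try:
        assoc = cluster_subtype_association(labeling, em.annotations["subtype"])
        io.write_json_report(assoc.as_dict(), out / "association.json")
        expr_report["association"] = {
            "chi2": assoc.statistic, "df": assoc.df, "p_value": assoc.p_value,
        }
    except ValueError as exc:
        expr_report["association"] = {"error": str(exc)}

    target, _, rest = cfg.de_groups.partition(":")
    subtype = em.annotations["subtype"]
    group_a = list(subtype.index[subtype != target]) if rest == "rest" else \
        list(subtype.index[subtype == rest])
    group_b = list(subtype.index[subtype == target])
    de = differential_expression(counts, group_a, group_b,
                                 alpha_level=cfg.alpha_de)
    de.to_csv(out / "de_table.tsv", sep="\t")
    expr_report["de"] = {
        "comparison": f"{target} vs {rest or 'rest'}",
        "n_tested": int((~de["filtered"]).sum()),
        "n_filtered_low_count": int(de["filtered"].sum()),
        "n_significant": int(de["significant"].sum()),
        "alpha": cfg.alpha_de,
    }
    report["expression"] = expr_report


def _markdown(report: dict) -> str:
    lines = ["# perivasc run report", ""]
    lines.append(f"- version: {report['version']}")
    lines.append(f"- seed: {report['seed']}")
    if "spatial" in report:
        sp = report["spatial"]
        lines += ["", "## Spatial arm",
                  f"- samples: {sp['n_samples']}",
                  f"- median CD3+ density, whole ROI: "
                  f"{sp['cd3_density_total_median']:.1f} cells/mm2"]
        for cls, entry in sp["zonal_tests"].items():
            g = entry["gradient"]
            lines.append(
                f"- {cls}: gradient rho = {g['estimate']:.3f}, "
                f"p = {g['p_value']:.4g}"
            )
    if "expression" in report:
        ex = report["expression"]
        lines += ["", "## Expression arm",
                  f"- cluster labels: {ex['cluster_labels']}"]
        if "chi2" in ex.get("association", {}):
            a = ex["association"]
            lines.append(f"- label x subtype chi2 = {a['chi2']:.2f}, "
                         f"df = {a['df']}, p = {a['p_value']:.3g}")
        lines.append(f"- DE ({ex['de']['comparison']}): "
                     f"{ex['de']['n_significant']} significant of "
                     f"{ex['de']['n_tested']} tested "
                     f"({ex['de']['n_filtered_low_count']} filtered)")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the report dict; artifacts land in ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": cfg.seed,
              "config": dataclasses.asdict(cfg)}
    if cfg.samples:
        _run_spatial(cfg, out, report)
    if cfg.counts:
        _run_expression(cfg, out, report)
    if not cfg.samples and not cfg.counts:
        raise PipelineError("config", "neither spatial samples nor counts given")
    io.write_json_report(report, out / "report.json")
    (out / "report.md").write_text(_markdown(report))
    io.dump_yaml(report["config"], out / "config_echo.yaml")
    return report
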