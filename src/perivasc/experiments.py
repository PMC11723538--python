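"""Multi-seed recovery experiments: the package's own power/calibration
studies on its synthetic generators.

These drive both the test suite's recovery checks and the reproduction
script.  Study conditions follow the planted-gradient and planted-block
designs the simulators encode: a 2 x 2 mm ROI with 20 anchor vessels and
an exponential CD3 decay (A = 3, tau = 25 μm, beta0 = 500 cells/mm²), and
an expression cohort at the 147/415/176/70 subtype sizes.  Cohorts of a
few tissue samples per seed mirror the pooled (sample, band) gradient
test design used on real sample sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .perivascular import gradient_test, zonal_density
from .synthetic import ExprSimConfig, TissueSimConfig, simulate_expression, simulate_tissue
from .transcriptomics import (
    cluster_subtype_association,
    differential_expression,
    hierarchical_cluster,
    label_clusters,
    size_factors,
    standardize_rows,
    vst,
)
from .synthetic.expression import simulate_de_counts

__all__ = [
    "gradient_tissue_config",
    "gradient_recovery_experiment",
    "cluster_pipeline_once",
    "cluster_recovery_experiment",
    "de_calibration_experiment",
]

GRADIENT_CLASSES = ("ICAM1+", "non-activated")


def gradient_tissue_config(seed: int, amplitude: float = 3.0,
                           tau_um: float = 25.0,
                           beta0: float = 500.0,
                           n_non_activated: int = 20) -> TissueSimConfig:
    """The planted-gradient ROI: 2 x 2 mm, 20 anchor (ICAM1+) vessels plus
    non-activated vessels for the type-I arm, no compartments (the
    zonal analysis does not use them)."""
    return TissueSimConfig(
        width_um=2000.0,
        height_um=2000.0,
        compartment_spec=[],
        n_vessels_by_class={"ICAM1+": 20, "non-activated": n_non_activated},
        baseline_density={"CD3": beta0},
        gradient=("ICAM1+", amplitude, tau_um),
        seed=seed,
    )


def gradient_recovery_experiment(
    n_seeds: int = 100,
    n_samples: int = 6,
    base_seed: int = 0,
    amplitude: float = 3.0,
    tau_um: float = 25.0,
    beta0: float = 500.0,
    n_non_activated: int = 20,
) -> pd.DataFrame:
    """Pooled-gradient Spearman test over ``n_seeds`` simulated cohorts of
    ``n_samples`` ROIs each; rows of (seed, vessel_class, rho, p)."""
    rows = []
    for i in range(n_seeds):
        profiles = []
        for j in range(n_samples):
            cfg = gradient_tissue_config(
                seed=int(base_seed + 1009 * i + j) % (2**31 - 1),
                amplitude=amplitude, tau_um=tau_um, beta0=beta0,
                n_non_activated=n_non_activated,
            )
            geometry, cells, vessels = simulate_tissue(cfg)
            profiles.append(zonal_density(
                cells, vessels, geometry, classes=list(GRADIENT_CLASSES),
                sample_id=f"s{j}",
            ))
        pooled = pd.concat(profiles, ignore_index=True)
        for cls in GRADIENT_CLASSES:
            res = gradient_test(pooled[pooled["vessel_class"] == cls])
            rows.append({"seed": i, "vessel_class": cls,
                         "rho": res.estimate, "p": res.p_value})
    return pd.DataFrame(rows)


def cluster_pipeline_once(config: ExprSimConfig) -> dict:
    """One cohort through counts -> size factors -> vst -> standardise ->
    Ward(k=4) -> CD3D labels -> association + Basal enrichment.

    Returns cluster labels, the chi-square p (NaN when the label table is
    degenerate), and the hypergeometric enrichment p of Basal samples in
    the pooled Upregulated cluster(s) (1.0 when no cluster is labelled
    Upregulated).
    """
    em = simulate_expression(config)
    sf = size_factors(em.values)
    transformed = vst(em.values, sf)
    std = standardize_rows(transformed.loc[config.signature_genes])
    labeling = label_clusters(hierarchical_cluster(std, 4, 2), std)
    labels = labeling.sample_labels
    out = {"labels": dict(labeling.cluster_labels),
           "medians": dict(labeling.cluster_medians)}
    try:
        assoc = cluster_subtype_association(labeling, em.annotations["subtype"])
        out["chi2"] = assoc.statistic
        out["chi2_df"] = assoc.df
        out["chi2_p"] = assoc.p_value
        out["residuals"] = assoc
    except ValueError:
        out["chi2"] = np.nan
        out["chi2_df"] = 0
        out["chi2_p"] = np.nan
        out["residuals"] = None
    up = labels == "Upregulated"
    basal = em.annotations["subtype"] == "Basal"
    n_up = int(up.sum())
    if n_up:
        out["enrichment_p"] = float(hypergeom.sf(
            int((up & basal).sum()) - 1, len(labels), int(basal.sum()), n_up
        ))
    else:
        out["enrichment_p"] = 1.0
    # sign of the Basal x Upregulated Pearson residual, when defined
    res = out["residuals"]
    out["basal_up_residual"] = np.nan
    if res is not None and "Upregulated" in res.row_labels and \
            "Basal" in res.col_labels:
        out["basal_up_residual"] = float(
            res.pearson_residuals[res.row_labels.index("Upregulated"),
                                  res.col_labels.index("Basal")]
        )
    return out


def cluster_recovery_experiment(
    n_seeds: int = 100,
    base_seed: int = 0,
    block_effect: float = 1.5,
) -> pd.DataFrame:
    rows = []
    for i in range(n_seeds):
        cfg = ExprSimConfig(block_effect=block_effect,
                            seed=int(base_seed + 7919 * i) % (2**31 - 1))
        out = cluster_pipeline_once(cfg)
        rows.append({"seed": i, "enrichment_p": out["enrichment_p"],
                     "chi2": out["chi2"], "chi2_p": out["chi2_p"],
                     "basal_up_residual": out["basal_up_residual"]})
    return pd.DataFrame(rows)


def de_calibration_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_per_group: int = 20,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    alpha_level: float = 0.01,
) -> dict:
    """Power and empirical FDR of the NB Wald DE over planted fixtures."""
    tp = fp = 0
    n_true = 0
    for i in range(n_seeds):
        counts, a, b, de_genes = simulate_de_counts(
            n_per_group=n_per_group, log2fc=log2fc, dispersion=dispersion,
            seed=int(base_seed + 104729 * i) % (2**31 - 1),
        )
        res = differential_expression(counts, a, b, alpha_level=alpha_level)
        called = set(res.index[res["significant"]])
        truth = set(de_genes)
        tp += len(called & truth)
        fp += len(called - truth)
        n_true += len(truth)
    return {
        "power": tp / n_true if n_true else np.nan,
        "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
        "n_seeds": n_seeds,
        "true_positives": tp,
        "false_positives": fp,
    }
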