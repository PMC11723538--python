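# perivasc

Spatial immune–vascular analysis of multiplex-immunofluorescence (mIF)
tissue, for tumour-immunology groups asking how T cells distribute around
activated blood vessels — plus a matched transcriptomic arm that asks the
same immune–endothelial question of bulk RNA-seq cohorts.

The package quantifies, from a phenotyped cell table and tissue geometry:

- **Compartment densities** — CD3⁺ T cells (and their PD-L1/VCAM-1/ICAM-1
  combinations) per mm² of tumour, stroma and whole tissue.
- **Vessel objects** — blood vessels (BVs) as single-linkage clusters of
  CD31⁺ endothelial cells, phenotyped by the any-member rule into
  mutually exclusive activation classes (non-activated, PD-L1⁺, VCAM-1⁺,
  ICAM-1⁺, VCAM-1⁺ICAM-1⁺, other-multi), with BV and EC densities.
- **Perivascular gradients** — CD3⁺ density in four concentric 30 μm
  bands (0–120 μm) around each vessel class; the gradient test is the
  Spearman correlation of band density against band index over pooled
  (sample, band) observations, and the proximal-vs-distal contrast is a
  paired Wilcoxon signed-rank test on band-1 − band-4 densities. The
  planted expectation is an exponential decay,
  λ(x) = β₀·(1 + A·e^(−d(x)/τ)), anchored on ICAM-1⁺ vessels.
- **Expression clustering and DE** — reverse the log2(x+1) transform,
  median-of-ratios size factors, a closed-form negative-binomial
  variance-stabilising transform, row standardisation, Ward (D2)
  hierarchical clustering cut at k = 4, cluster labels from the median
  standardised CD3D (< 0 Downregulated, [0, 1] Expressed, > 1
  Upregulated), a χ² label-by-subtype association with Pearson-residual
  contributions, and a simplified NB Wald differential expression with a
  "< 3 total reads" filter and BH adjustment at q < 0.01.

Synthetic generators (`perivasc.synthetic`) produce tissues and
four-subtype expression cohorts with these structures planted, so every
stage is testable end to end without any imaging data or download. All
statistics live in `perivasc.stats`, implemented from their definitions
and verified against enumeration oracles.

## Worked example

Simulate six 2 × 2 mm ROIs with a planted perivascular T-cell gradient
(A = 3, τ = 25 μm, β₀ = 500 cells/mm²) anchored on 20 ICAM-1⁺ vessels,
and test the gradient around ICAM-1⁺ versus non-activated vessels:

```python
import pandas as pd
from perivasc.experiments import gradient_tissue_config
from perivasc.synthetic import simulate_tissue
from perivasc.perivascular import zonal_density, gradient_test, proximal_vs_distal

profiles = []
for j in range(6):
    geometry, cells, vessels = simulate_tissue(gradient_tissue_config(seed=100 + j))
    profiles.append(zonal_density(cells, vessels, geometry,
                                  classes=["ICAM1+", "non-activated"],
                                  sample_id=f"s{j}"))
pooled = pd.concat(profiles, ignore_index=True)
print(pooled.groupby(["vessel_class", "band"])["density"].median().unstack().round(1))
for cls in ("ICAM1+", "non-activated"):
    sub = pooled[pooled["vessel_class"] == cls]
    g = gradient_test(sub)
    wide = sub.pivot_table(index="sample_id", columns="band", values="density")
    w = proximal_vs_distal(wide[1], wide[4])
    print(f"{cls}: gradient rho = {g.estimate:.2f} (p = {g.p_value:.2e}); "
          f"band1 vs band4 Wilcoxon p = {w.p_value:.3f}")
```

Output:

```
band                1      2      3      4
vessel_class
ICAM1+         1224.0  743.8  605.5  516.4
non-activated   616.4  532.1  540.5  527.4
ICAM1+: gradient rho = -0.95 (p = 2.23e-12); band1 vs band4 Wilcoxon p = 0.031
non-activated: gradient rho = -0.29 (p = 1.77e-01); band1 vs band4 Wilcoxon p = 0.312
```

The median band densities fall from ~1224 to ~516 cells/mm² moving away
from ICAM-1⁺ vessels (the planted decay), giving a strongly negative
pooled Spearman gradient and a significant proximal-vs-distal contrast,
while the profile around non-activated vessels in the same tissues stays
flat at the ~500 cells/mm² baseline and neither test rejects.

A shell workflow covers the same ground:

```sh
perivasc simulate-tissue --seed 7 --out roi/
perivasc phenotype --cells roi/cells.csv --geometry roi/tissue.geojson --out densities.tsv
perivasc zonal --cells roi/cells.csv --vessels roi/vessels.geojson \
               --geometry roi/tissue.geojson --out zonal/
perivasc simulate-counts --seed 7 --out expr/
perivasc de --counts expr/counts.tsv --annotations expr/annotations.tsv \
            --groups Basal:rest --out de.tsv
```

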