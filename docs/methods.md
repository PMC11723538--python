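# Methods

`perivasc` quantifies the spatial relationship between T cells and the
activated vasculature in multiplex-immunofluorescence (mIF) tissue, and
mirrors the same immune–endothelial question on bulk expression cohorts.
This note records the models, the tunable parameters, the numerical
choices, and what the synthetic generators do and do not emulate.

## Spatial arm

### Cell tables and phenotyping

Cells are rows of a table: centroid coordinates in planar micrometres
(image convention — origin at the ROI top-left, y downward) and boolean
calls for six markers: CD3 (T cells), pan-cytokeratin (epithelial/tumour
cells), CD31 (endothelium) and the activation markers VCAM-1, ICAM-1 and
PD-L1. When intensities are supplied instead of calls, a cell is positive
for a marker iff its intensity is at or above a single global per-marker
cutoff; no per-cell background correction is attempted. Compartment
assignment is polygon containment of the centroid, tested in the fixed
order tumour → stroma → other, so a centroid exactly on a shared edge
goes to the earlier label; cells inside the tissue but in no compartment
are `other`, cells outside the tissue are kept as `unassigned` and
logged. Densities are counts per mm² of compartment area; the `total`
compartment is the whole tissue (all compartments combined).

### Vessels

A blood vessel (BV) is a single-linkage cluster of CD31+ centroids at
link radius `link_radius_um` (default 20 μm, the scale of 1–2 endothelial
cell bodies) with at least `min_cells` members (default 3); the boundary
is the convex hull of members buffered by `ec_radius_um` (default 5 μm,
half a cell diameter). This is a deliberately simple, reproducible
detector for vessel cross-sections in 2-D sections; it does not attempt
lumen reconstruction, and its boundary is a declared surrogate for
pixel-level segmentation.

Vessel activation uses the any-member ("whole or part") rule: the vessel
is flagged for a marker as soon as one member EC carries it. The flag
triplet (PD-L1, VCAM-1, ICAM-1) maps onto six mutually exclusive classes
with both-adhesion precedence: VCAM1+ICAM1+ whenever both adhesion flags
are set (with or without PD-L1); otherwise a single flag names its class;
PD-L1 plus exactly one adhesion molecule is `other-multi`; no flags is
`non-activated`. Raw flags are always retained so alternative groupings
can be recomputed. At the EC level "activated" is the individual cell's
own markers — the two levels are intentionally different summaries.

### Annular band analysis

For each vessel class, four concentric bands of 30 μm (0–120 μm) are
built around the union of that class's boundaries as differences of
buffered unions, minus the vessel interiors, clipped to the tissue
polygon (a `nominal` option keeps full annuli; which normalisation a
pixel-based tool uses is generally not reported, so both are available).
Buffers use 64 segments per quarter circle; the polygonised annulus area
is within ~0.02% of the closed form. Band edges are half-open,
`[30(k-1), 30k)`, inner edge inclusive. A cell's band within a class is
set by its distance to the nearest boundary of that class (0 inside a
vessel, hence band 1; interiors are excluded from band area). One cell
may contribute to several classes' profiles but to exactly one band per
class. Densities pool counts over all vessels of the class divided by
pooled band area — one density per zone per phenotype — and a per-vessel
table is emitted for re-aggregation.

The gradient test is the Spearman rank correlation of band density
against band index, pooling (sample, band) observations when several
samples are supplied; the proximal-vs-distal comparison is a paired
Wilcoxon signed-rank test on per-sample band-1 minus band-4 densities
(the comparison is sometimes labelled a paired rank-sum test, but the
rank-sum test has no paired form, so the signed-rank reading is
implemented).

## Statistics

All named procedures are implemented from their definitions so that each
is checkable against brute-force enumeration: Welch's t (with the
Welch–Satterthwaite degrees of freedom), the Wilcoxon rank-sum (midranks;
exact enumeration for total n ≤ 12 without ties, else normal
approximation with tie and continuity corrections), the Wilcoxon
signed-rank (exact null by convolution for n < 25, handling midrank ties
exactly), Spearman (exact permutation p for n ≤ 8, else the t
approximation), Benjamini–Hochberg step-up adjustment, and the Pearson
chi-square test of independence with its residual decomposition
(contribution of cell (i,j) = r²ij/χ², summing to 1) and no continuity
correction (the r×c case; some packages default to Yates at 2×2).
Two-sided p-values for discrete exact nulls are 2·min(one-sided tails)
capped at 1. Exact/approximate cutoffs are arguments on every call.

## Expression arm

Input matrices are genes × samples, raw counts or log2(x+1) values; the
latter are reversed elementwise as 2^x − 1 (values within rounding
tolerance of integers are snapped, so a log round trip returns exact
counts). Normalisation is median-of-ratios size factors. The
variance-stabilising transform is the closed form for the negative
binomial with a parametric dispersion trend α(μ) = a₀ + a₁/μ:

    vst(q) = log2[ (1 + a₁ + 2a₀q + 2√(a₀q(1 + a₁ + a₀q))) / (4a₀) ]

with q the size-factor-normalised count; it is strictly increasing
(rank-preserving within samples) and approaches log2 q for large counts.
The trend is fitted by ordinary regression of gene-wise moment dispersion
estimates (s² − μ̄)/μ̄² on 1/μ̄ over well-expressed genes (normalised
mean ≥ 1, positive estimate), with a₀ floored at 1e-4 and a₁ at 0; this
ordinary-regression fit is simpler than a gamma-GLM trend and adequate
for the transform's purpose.

Rows (genes) are standardised to mean 0, sd 1 (denominator n − 1;
constant rows become zeros with a warning). Clustering is agglomerative
with Euclidean distance and Ward's minimum-variance criterion in the
Ward.D2 convention (squared-Euclidean merge costs, square-root heights);
a `ward_d` flag reproduces classic-Ward memberships on unsquared
dissimilarities. Clustering runs on a configured gene set (default: the
signature subset; a genome-wide flag exists). The column tree is cut at
k = 4 and the row tree at k = 2.

Sample clusters are labelled from the median standardised CD3D value per
cluster: median < 0 → Downregulated, median > 1 → Upregulated, the
closed interval [0, 1] → Expressed (the boundary convention is a package
decision; medians on the standardised scale because the 0/1 thresholds
presuppose a zero-centred unit scale, with a vst-scale option). Distinct
clusters may share a label. Label-by-subtype association is the
chi-square independence test with the Pearson-residual contribution
matrix; a table with fewer than two distinct labels (or subtypes) is
degenerate and raises rather than fabricating a p-value.

### Differential expression

A deliberately simplified two-group negative-binomial Wald test: genes
with fewer than 3 reads in total are removed before testing; per-gene
group means are fitted by Fisher scoring with size-factor offsets
(saturated two-group parametrisation, equivalent to an intercept+group
GLM); the gene-wise dispersion is the upper envelope of the within-group
moment estimate and the parametric trend — a conservative shrinkage that
protects false-discovery control at small n — clamped to [1e-8, 10]; and
the Wald statistic for the log fold change is referred to a t
distribution with n₁ + n₂ − 2 degrees of freedom, because the plug-in
dispersion makes the normal reference anti-conservative at n ≈ 20 per
group. p-values are BH-adjusted and calls made at q < 0.01 by default.
There is no Cox–Reid adjustment and no fold-change shrinkage; the engine
is validated against simulations with known truth, not against any
external implementation.

## Synthetic data

### Tissue generator

One ROI is a rectangle (default 2 × 2 mm — per-sample ROI sizes are
rarely reported, so this is an exposed default). Compartments are a
blobby partition obtained by thresholding Gaussian-smoothed noise on a
50 μm tile grid at quantiles matching the target area fractions (default
45% tumour / 45% stroma); tiles make the mask-versus-polygon question
exact. Vessels are circles with radius uniform in 5–15 μm, placed
uniformly without overlap inside the tissue (bounded retries; failure
reports the achieved count); circles make band areas analytically
checkable. Each vessel carries a ring of CD31+ member cells (~one per
10 μm of perimeter, at 0.55–0.95 radius) whose activation calls are
drawn so the any-member rule reproduces the planted class exactly. The
default class mix (25 VCAM1+ / 5 VCAM1+ICAM1+ / 5 ICAM1+ / 2 PDL1+ / 8
non-activated per ROI) mirrors the observed predominance of VCAM-1+
vessels.

CD3+ cells follow an inhomogeneous Poisson process with intensity
λ(x) = β₀(1 + A·e^(−d(x)/τ)), d(x) the distance to the nearest
anchor-class vessel boundary (default anchor ICAM1+, A = 3, τ = 25 μm,
β₀ = 500 cells/mm²), sampled by thinning a homogeneous field at
β₀(1 + A). All other phenotypes are homogeneous Poisson at their
configured densities. Vessel lumens are excluded from every
non-endothelial point field: T cells reside in the parenchyma, and
placing them inside lumens would — under the interior-cells-to-band-1
convention — plant a spurious negative gradient around every vessel
class and break the generator's own type-I calibration contract.

What the generator does not emulate: pixel-level image content, irregular
vessel shapes, cell-size exclusion effects, spatial clustering of T cells
beyond the vessel-anchored gradient, marker intensity distributions, and
tissue-scale heterogeneity between ROIs of one patient. Passing recovery
tests therefore demonstrates that the pipeline detects the planted
spatial structure at realistic densities and noise — not that it is
robust to every artefact of real mIF imagery.

### Expression generator

The cohort defaults to the four-subtype composition 147 Basal / 415
LumA / 176 LumB / 70 HER2 (N = 808). Per-sample TIL fractions are Beta
draws per subtype (Basal (5.2, 2.8), centred near 65%; LumA (2, 8);
LumB (2.5, 7.5); HER2 (3, 5)), so Basal samples are stochastically
TIL-high; a noisy "deep-learning TIL" duplicate annotation is included.
Counts are negative binomial (gamma–Poisson) with common dispersion
(default 0.15) around mean = library size × relative abundance
(log-normal, σ = 1.2, normalised) — and, for the signature block
(72 genes containing CD3D, ICAM1, VCAM1, CD274 plus filler ids, since
the real 72-gene set is not enumerated anywhere reusable), an elevation
of 2^block_effect (default 1.5) in high-TIL samples (TIL ≥ 0.5,
threshold configurable). The default transcriptome is 300 genes — a
desk-scale stand-in; a genome-scale matrix changes runtimes, not the
planted structure. Library sizes are uniform in 6×10⁵–1.2×10⁶ so
per-gene depths resemble well-expressed RNA-seq genes.

## Problem sizes used in the shipped studies

The recovery studies run at sizes chosen to make multi-seed calibration
loops a desk exercise: gradient recovery uses cohorts of 6 ROIs per seed
(the pooled (sample, band) Spearman then has the structure of a ~10-
sample study, at 24 pooled observations); cluster recovery uses the full
808-sample cohort with the 300-gene matrix; DE calibration uses 300
genes × 20 samples per group over 50 seeds. The reproduction script
(`scripts/acceptance.py`) uses 40-seed versions of the multi-seed loops.

## Known limitations

- The pooled-gradient Spearman treats (sample, band) densities as
  exchangeable under the null even though band variance shrinks with
  band area; with no planted gradient anywhere the test is exactly
  calibrated at the shipped study sizes (the A = 0 arm of the gradient
  recovery experiment).
- When a gradient IS planted on one vessel class, the profiles of the
  other classes in the same tissue are not perfectly null: vessels
  cannot overlap, so anchor-class vessels are excluded from the
  immediate vicinity of other vessels and band 1 of a non-anchored class
  receives slightly less halo elevation than its distal bands (a ~2%
  deficit, i.e. a weak spurious positive trend). Two-sided rejection
  around non-anchored vessels therefore runs above nominal, while the
  directional event of interest — a significant negative (proximal-
  enriched) gradient — stays at its nominal rate. Interpret non-anchored
  two-sided "rejections" in gradient tissues accordingly.
- The vessel detector merges adjacent vessels closer than the link
  radius and cannot split them; the buffered hull overestimates the
  lumen of very elongated vessels.
- The DE engine's conservative dispersion envelope costs power at very
  small fold changes; it is tuned for reliable error control rather than
  maximum sensitivity.
- The chi-square association is undefined when all clusters share one
  label; callers must handle the raised error (the pipeline reports it
  in place of a p-value).
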