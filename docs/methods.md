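# Methods

This note documents the models and procedures implemented in `heteroclust`,
the parameters that matter, the design choices that were genuinely open, and
what the synthetic-data generators do and do not emulate.

## Competition enrichment (`cytocompete`)

**Model.** A co-culture of tumour cells with a mix of antigen-specific and
non-specific T cells produces three flow populations: T singlets, tumour
singlets and double-positive heterotypic clusters. Within the T compartment,
the specific fraction among clustered events divided by the specific fraction
among singlet events is the fold enrichment FC. The estimator gates events by
per-channel thresholds (double positive ⇒ cluster), computes the two
fractions, and attaches a percentile bootstrap CI (default 1,000 resamples of
events within each population). When ≥3 replicate tables are available,
`replicate_fold_test` runs the donor-level paired t-test instead.

**Generator.** Marker intensities are lognormal with "negative" (median 10)
and "positive" (median 1,000) populations separated by ≫3 SD in log space, so
threshold gating is unambiguous; the generators are calibrated for
separability, not for matching any particular instrument's distributions.
Singlet T cells are specific with probability q_s (the input mix fraction)
and clustered T cells with q_c = min(1, FC_planted · q_s). The clamp is
recorded on the returned truth: at a 40% input and FC_planted = 2.7,
q_c saturates and the observable fold change is 1/0.40 = 2.5. This ceiling is
a property of the specified generative model, not of the estimator, and the
recovery checks use a tolerance wide enough to span it.

**Singlet gate.** Scatter surrogates give each cell a size-like "height";
singlet area tracks height, while a doublet's area is the sum of its members'
areas and its height the max, so doublets fall off the area~height diagonal.
The gate itself is not standardized anywhere we know of, so the package
declares one: a Huber robust regression of area on height fitted on
singlet-dominated events, widened to a ±20% relative band. Loss per cluster
class is the fraction of its events outside the band; a table with no
clustered events reports 0% loss by convention.

## Synapse relocalization (`imagesynapse`)

**Pipeline.** (1) Segmentation inputs: in vitro mode uses a variance filter
(square neighbourhood, radius 2 px, computed as E[x²] − E[x]²) of the
bright-field image as the membranous channel, plus the min–max-normalized sum
of the type-marker channels as the nuclear channel; patient mode combines all
normalized fluorescence channels with the normalized variance-filtered
bright-field into one channel. (2) Segmentation is a plug-in
(`image → label image`); the built-in segmenter is Otsu + hole filling +
distance-transform watershed, deliberately simple so the pipeline never
requires an external model. Labels are then contracted by 2 px (disk
erosion); labels that vanish are dropped. (3) Cell typing: k-means (10
restarts, fixed seed) on standardized per-cell channel means + area; each
k-means cluster receives the type whose marker has the highest
cluster-average standardized intensity, falling back to raw intensities when
standardization is degenerate (k = 1), with remaining ties broken by the
declared marker order. (4) Doublets: connected components of the touching
graph with exactly two cells of different types; larger components,
singletons and same-type pairs are excluded.

**Touching after contraction.** Two cells that touched in the raw
segmentation end up 2·2 + 1 = 5 px apart after both labels are contracted, so
the touching graph uses a Chebyshev distance of 5 on contracted labels
(plain 8-connectivity adjacency would never fire).

**Interface definition.** The membrane is the outer 3 px of the contracted
label. The interface is the membrane within Chebyshev distance 6 of the
*shared boundary line* of the uncontracted labels — the pixel set where the
two raw labels meet. This is the well-conditioned reading of a "touching
region": defining the interface by proximity to the (contracted) partner
label is ill-posed at the arc endpoints, where the dilated partner boundary
runs tangent to the membrane and a 1-px segmentation wobble sweeps many
pixels in or out. Partner-proximity remains available as a fallback when raw
labels are not supplied.

**Statistic.** Per doublet, the scored cell's marker mean on the interface
and on the rest of the membrane; the cohort test is a two-sided paired
Wilcoxon signed-rank on the differences (paired t-test available). Both cells
can be scored; by default the cell of the type expressing the marker is. The
*relocalized fraction* reported alongside is
(mass_fraction − area_fraction)/(1 − area_fraction), where mass_fraction is
the interface share of membrane marker mass and area_fraction its share of
membrane area; it is 0 for a uniform membrane stain and 1 for a fully
relocalized one, matching the generator's strength parameter.

**Generator.** Doublets are two touching disks (radii 10–14 px at 0.5 µm/px;
overlap pixels are assigned to the nearer centre, mimicking where a watershed
split falls). The synapse marker lives on the T cell's membrane band (6 px
wide, starting one pixel inside the boundary, with the boundary row itself at
half density) as a mixture: weight 1 − s uniform over the band plus weight s
on the contact arc (band within 6 px of the shared boundary line). A σ = 1 px
Gaussian blur emulates finite imaging resolution. The mixture form is forced
by the two calibration endpoints — s = 0 must be a uniform membrane stain and
s = 1 fully relocalized — and makes the relocalized-fraction estimator's
target identical to s. No point-spread-function optics, spectral overlap or
autofluorescence are modelled; passing the recovery tests shows the
*operators* are correct on geometrically clean cells, not that segmentation
of real ImageStream objects would be this accurate.

## Spatial proximity (`spatialprox`)

Reclassification resolves multi-positive marker flags in a fixed order:
tumour⁺CD8⁺ (and the triple positive) → Unclassified; tumour⁺CD11c⁺ → Tumour
and CD8⁺CD11c⁺ → CD8 (CD11c membrane protrusions cause false positives);
single positives keep their class; all-negative → Unclassified. Distances are
Euclidean centroid-to-centroid with self-exclusion; a CD8 cell strictly
closer than 10 µm to a tumour cell is a T–tumour cluster regardless of nearby
APCs (proximity to both is defined as T–tumour), else strictly closer than
10 µm to a CD11c cell is a T–APC cluster. The cutoff is strict (<), so cells
at exactly 10 µm are unclustered; 10 µm ≈ one cell diameter. The neighbour
search (scikit-learn) is verified exactly against an all-pairs distance
oracle. The generator plants a chosen fraction of CD8 cells 4–9 µm from a
tumour or APC anchor and keeps all other placements ≥12 µm apart, so planted
labels are unambiguous; it also appends one row per reclassification branch.

## Single-cell statistics (`scquant`)

**QC.** Cells are kept with detected-gene counts in [200, 8,000] and
mitochondrial percentage ≤15. "Gene counts" is read as *detected genes*
(not total UMIs); this is configurable.

**Hashtag demultiplexing.** Per channel, a Gaussian KDE of log1p counts; the
threshold is the lowest density minimum between the two highest modes.
Cells above both thresholds are cross-sample doublets and are removed; a
unimodal channel is an explicit failure, not a silent guess.

**Equal-patient weighting.** State frequencies are computed per patient per
origin and averaged unweighted over patients, so a patient contributing
10× the cells does not dominate; duplicating a patient's cells leaves the
result unchanged.

**Differential abundance.** Membership of a cell in a state is modelled as
logit P = β₀ + β₁·(cluster origin) + u_patient with u ~ N(0, σ²). The
likelihood integrates the random intercept by 25-node Gauss–Hermite
quadrature on per-patient binomial counts (exact to quadrature accuracy —
the same family of approximation as Laplace, refined), maximized by
Nelder–Mead; the Wald test on β₁ uses the observed information. P values are
Bonferroni-adjusted over the tested states. The independent oracle is a
stratified permutation test: interaction status is permuted within patient,
which makes the per-patient 2×2 count hypergeometric, so the permutation
distribution of the Mantel–Haenszel log odds ratio is sampled directly from
the table margins. Calibration at the study scale (4 patients × 2,000 cells)
gives Type-I error within 3 points of nominal and recovers a planted log-odds
of 1.0 to within 0.05 on average.

**CD39 status.** Dropout makes single-gene negativity unreliable, so the call
averages a cell's own normalized log expression (weight 0.5) with the mean of
its 10 nearest neighbours in the embedding (first 30 PCs of the normalized
matrix if no embedding is provided); CD39⁺ iff the smoothed value exceeds
τ = 0. Both the 50/50 combination and the neighbour space were open choices
and are configurable.

**Clonotypes.** A clonotype key is the sorted set of α-chain CDR3 amino-acid
sequences joined with the sorted set of β CDR3s; cells with multiple chains
therefore form their own unique clonotype, and cells missing either chain are
excluded. Rows with non-amino-acid CDR3 characters are rejected with a
warning. Comparisons report (i) per-patient top-15 clonotype frequencies in
single vs clustered cells, equal patient weights, and (ii) per-clonotype mean
signature scores between the two cluster origins for clonotypes with ≥10
cells in each, top 10 clonotypes per patient (ties broken lexicographically),
compared by paired Wilcoxon, with row-z-scored matrices for display.

## Signatures (`signature`)

DE between cluster- and singlet-origin cells defaults to a per-gene two-sided
Wilcoxon rank-sum on CP10K log1p expression with Bonferroni adjustment; any
`(x_cluster, x_singlet) → (log2FC, p)` callable can be plugged in (the
original analysis used a hurdle-model test with patient as a latent variable,
which lives in another ecosystem). Zero-variance genes get p = 1. Signature
construction preselects genes with −log₁₀ p_adj > 150 expressed in >30% of
cluster cells, orders by descending log₂FC (gene-name tie-break for
determinism) and truncates to 30 and 100; a shortage returns all qualifying
genes with a warning. Per-cell scoring is a ranking AUC: genes ranked by
expression per cell (stable ties on the fixed gene order), score = area under
the recovery curve of signature genes within the top 5% of the ranking,
normalized to [0, 1]; the score is invariant to monotone transformations of a
cell's expression. Tertile stratification pools all cells for the boundaries
(a configurable choice), computes per-patient tertile occupancies, and
compares responders vs non-responders per tertile by two-sided unpaired
t-test.

## Ligand–receptor rules (`lrnet`)

Curation keeps a pair iff weight > 0.75 AND (curated-annotation membership OR
experimental-PPI membership OR weight > 0.9 OR (weight > 0.8 AND membership
of a CellTalk-like or SingleCellSignalR-like list)) AND the receptor's
localization contains "cell membrane" or "surface" (case-insensitive
substring; missing localization drops the pair with a log entry). Expression
filtering keeps an edge iff the ligand has nonzero counts in ≥10% (or 35% for
the state-focused variant) of sender cells and the receptor in ≥10% of
receiver cells, restricted to cluster origins. Subgroup assignment computes
per-subgroup average expression (fine T states merged to six groups first),
thresholds at mean + 1 SD — population SD by default; configurable — and assigns the gene only if exactly one
subgroup exceeds it, otherwise "unspecific". Ligand-activity ranking is out
of scope; `activity_geneset` exports the upregulated-gene set
(p_adj < 0.05, log₂FC > 0.1, expressed in >5%) for any external scorer.

## Problem sizes and verification scales

The shipped checks run at sizes chosen to give stable statistics on a laptop:
competition recovery at 5×10⁴ T cells × 5 seeds; synapse calibration over 50
null cohorts of 20 doublets and recovery over 50 doublets; proximity
exactness on 2,000-cell fields; GLMM calibration over 200 datasets of
4 patients × 2,000 cells; curation equivalence over the full
flag × weight × localization truth table. Generators are pure functions of
their arguments (one `numpy` Generator per call; no global state), so every
number is reproducible from a seed.

## Known limitations

Synthetic intensities, images and counts are idealized: no spillover or
compensation structure in flow data; no optics beyond a 1-px blur in images;
no transcriptome co-expression structure, ambient RNA or doublet mixing in
counts; clonotype sequences are random strings with a power-law size law
(exponent 1.5 — a heavy tail with a few dominant clones). Passing recovery
tests therefore certifies the correctness of the estimators and rules on
data matching their stated assumptions, and says nothing about segmentation
quality, annotation quality or batch correction on real data, all of which
are out of scope.
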