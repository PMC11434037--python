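# Methods

`hypoximm` implements an analysis chain linking tumor hypoxia to
immune-microenvironment remodeling: single-sample hypoxia scoring,
tumor-boundary delineation on hexagonal spatial-transcriptomics lattices,
spot deconvolution and co-localization of *ALCAM*-high macrophages with
exhausted T cells (Tex), immunophenoscore (IPS) computation, a
pseudotime-based transcription-factor screen, and hypoxia-stratified
survival and checkpoint-blockade (ICB) response statistics. Every analysis
is exercised end to end on synthetic data with known ground truth; this
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Signature scoring

Two single-sample scorers are provided.

**Rank enrichment** is a weighted Kolmogorov–Smirnov random walk over
within-sample expression ranks (the ssGSEA construction). For a sample
with N genes and a signature of Ng matched genes, genes are visited in
decreasing expression order; a signature hit advances the hit CDF by
rank^τ (τ = 0.25 by default, average-rank tie handling, weights
normalized to sum 1), a miss advances the miss CDF by 1/(N−Ng), and the
score is the sum of the running (hit − miss) difference divided by N.
Because it depends only on within-sample ranks, the score is invariant to
any strictly monotone transformation of expression — the property the
test suite verifies against a brute-force positional oracle. GSVA's
kernel-CDF estimate is deliberately not reproduced: the rank walk is fully
specified, admits an exact small-instance oracle, and downstream analyses
only compare scores across samples. Ties in the walk order are broken by
gene index, which is stable under monotone maps.

**Mean-scaled** scoring (used when columns are cells) averages per-gene
z-scores taken across samples (sample standard deviation, ddof = 1;
zero-variance genes contribute 0) over the signature. It is equivariant
under per-gene affine rescaling.

The 15-gene HIF1A-associated hypoxia signature (ACOT7, ADM, ALDOA, CDKN3,
ENO1, LDHA, MIF, MRPS17, NDRG1, P4HA1, PGAM1, SLC2A1, TPI1, TUBB6, VEGFA)
ships as a packaged GMT, as does the Tex marker set (PDCD1, LAG3, HAVCR2,
CD8A, CD8B, CD3E, ENTPD1, BATF, NR4A1, plus ITGAE carried under both the
standard symbol and the legacy "TGAE" spelling so either is matched).

Median splits (hypoxia-high/low, ALCAM-high/low) send ties at the median
to the low group, deterministically.

## Synthetic data

The generators are pure functions of their parameter objects (identical
seeds give bit-identical output) and define the study conditions the
tests run under.

**Slides** (`simulate_slide`). Spots sit on an axial hexagonal lattice
(pixel centers x = q + r/2, y = r·√3/2, unit spacing, so the six
neighbors are exactly distance 1). Ring index ≤ `core_radius` is
malignant (Mal) truth, the next ring is boundary (Bdy), the rest
non-malignant (nMal); defaults `n_rings = 8`, `core_radius = 3` give a
217-spot slide with a 37-spot tumor and a 24-spot boundary ring. Each
spot draws a cell-type mixture over (malignant, macrophage, T cell,
stromal) from a region-specific Dirichlet — core concentrated on
malignant cells, boundary a macrophage/T-cell-rich mixed zone, exterior
stromal. Each cell type expresses its program (malignancy, macrophage,
Tex + effector, stroma) at `program_strength` = 2.5 natural-log-fold over
baseline. Stroma carrying its own strong program (collagens) is
deliberate: without it the exterior would have no highly expressed
competitor genes, and rank-based scores would dip at the boundary ring
for compositional rather than biological reasons. Hypoxia program means
are scaled by exp(gradient · (1 − ring/n_rings)) — e^1.5 ≈ 4.5-fold from
exterior to core by default — and counts are negative binomial (variance
μ + μ²/dispersion, dispersion 10) around the mixture scaled by a global
library-size constant, so hypoxia means depend only on the ring, not on
composition. Boundary spots get an extra ALCAM log-fold bump (1.0),
reproducing the boundary enrichment of ALCAM-high macrophages.
`SlideSimParams.strong_separation()` is the well-separated regime used
for recovery benchmarks: Dirichlet concentrations ×4 (mixture variance
÷4) and `program_strength` 3.0.

What the slides do not emulate: gene–gene correlation beyond program
co-membership, segmentation noise, doublets, spatial covariance within
regions, or histology. Passing recovery tests therefore shows the
algorithm is correct under its stated assumptions, not that it is robust
to every artifact of real slides.

**Staged cohorts** (`simulate_bulk_cohort`). A latent hypoxia activity
grows linearly with morphological stage (slope 0.5/stage over 9 stages of
20 samples by default, Gaussian noise SD 0.2) and shifts the hypoxia
genes' log-means. Survival is exponential with hazard (1/1000 days) ·
exp(HR · activity); censoring marks a fixed fraction (0.3) at a uniform
fraction of their event time. ICB response is Bernoulli with logit
decreasing in activity; responders are labeled CR/PR, non-responders
PD/SD. 40% of patients carry a paired on-treatment profile whose hypoxia
activity moves down by 0.5 for responders and up for non-responders.

**T-cell datasets** (`simulate_tcells`). Pseudotime is uniform on [0, 1];
naive markers (TCF7, SELL, CCR7, LEF1, IL7R) fall and exhaustion markers
(PDCD1, LAG3, HAVCR2, TIGIT, CTLA4, ENTPD1, TOX) plus the hypoxia program
rise log-linearly along it (±1.5 log-fold full-range, log-normal noise).
Designated TFs rise in a configurable number of the generated datasets,
exercising the cross-dataset consistency filter exhaustively.

## Spatial regions

QC keeps genes detected (count > 0) in ≥ 5 spots with total count ≥ 100,
then spots with ≥ 500 total transcripts over the retained genes (gene
filter first; the thresholds are tested on both sides). The neighbor
graph connects spots within 1.2× the minimal center distance, capturing
the six hex neighbors while tolerating slight lattice distortion.

The malignant core is seeded from the malignancy-signature rank score:
spots at or above the 0.90 quantile, restricted to the largest connected
component (replacing copy-number-based malignant calling, which is out of
scope and carries no signal in synthetic slides). The boundary is then
delineated by layer-wise frontier expansion: at each layer, unlabeled
neighbors of the current malignant set are accepted as Mal when their
expression-space distance to the core centroid is within an acceptance
threshold, and become Bdy otherwise; expansion stops when a layer adds no
Mal spot, and unreached spots are nMal. Distance is Euclidean in the top
10 principal components of log-normalized, per-gene-centered expression,
with a deterministic SVD sign convention (largest-magnitude loading
positive) — a reproducible stand-in for embedding distances.

The acceptance threshold deserves a note. The natural rule — the 0.95
quantile of the core spots' own distances to their centroid — proved
fragile: the core is a score-selected, unusually tight subsample, and
intratumoral gradients (hypoxia itself) widen the true malignant spread,
so the quantile systematically under-estimates it and rejects genuinely
malignant frontier spots. The implemented threshold therefore starts at
that quantile and extends it by a single-linkage walk up the sorted
slide-wide distance distribution, settling in the first gap wider than
0.25× the spread accepted so far (capped at the median distance; the
quantile is the floor, so `centroid_quantile` keeps its meaning). On
slides with a distinct malignant cluster this lands in the cluster's
actual margin; on homogeneous slides no qualifying gap exists and the
quantile rule stands. Recovery on strongly separated slides is
essentially exact (Jaccard ≥ 0.96 per region over 10 seeds).

Region summaries report per-region mean scores, a min–max normalization
of the three means to [0, 1], and two-sided Wilcoxon rank-sum p-values
for Mal vs Bdy and Bdy vs nMal.

## Deconvolution and co-localization

The reference is the per-type mean of linear-scale normalized single-cell
expression restricted to the top-50 type-specific genes per type (by
log-fold-change against all other cells; ≥ 10 cells per type required).
Spot composition solves non-negative least squares min‖y − S·w‖², w ≥ 0,
on linear counts-per-10k over the marker-gene union; proportions are
w/Σw, with all-zero solutions reported missing. Linear-scale NNLS
replaces the published log-normal deconvolution; downstream logic
consumes only proportions, and exact mixtures are recovered to 1e-6.

Macrophage spots (proportion ≥ 0.1, an explicit analysis knob the source
method leaves unstated) are median-split on log-normalized ALCAM. Tex
spots score at or above the 0.75 quantile of the Tex marker rank score
and, when proportions are available, carry ≥ 5% T-cell content. A Tex
spot is co-localized when it is itself ALCAM-high or any immediate
lattice neighbor (the "first outer circle") is; the exhaustion-score
contrast between co-localized and non-co-localized Tex spots is a
two-sided Wilcoxon rank-sum test (exact at small n). Regional enrichment
of any spot label uses the standard observed/expected ratio
(share of labeled spots in the region over the region's share of all
spots) with Fisher's exact test on the 2×2 table.

## Immunophenoscore

IPS sums four category values — effector cells (acCD4, acCD8, TemCD4,
TemCD8; +1), suppressor cells (Tregs, MDSCs; −1), 10 MHC molecules (+1),
and 10 checkpoints/immunomodulators (ICOS, CD27 +1; PD-1, CTLA4, LAG3,
TIGIT, TIM3, PD-L1, PD-L2, IDO1 −1). Each determinant is the mean sample
z-score (ddof = 1, zero-variance → 0) of its gene or metagene times its
weight; a category averages its determinants. The construction fixes only
part of the MHC and checkpoint membership and none of the cell-type
metagenes, so the packaged defaults flag every non-enumerated entry
(`unlisted_default`) and the whole configuration is replaceable via JSON.
IPS inherits affine invariance from the z-scores; negating all weights
negates the score exactly. The original 0–10 discretized scale is not
reproduced (not used downstream).

## Pseudotime and the TF screen

Trajectory reconstruction is replaced by a first-principal-component
ordering of log-normalized expression, oriented so the designated root
population (NaiveLike) has minimal mean projection and rescaled to
[0, 1]; externally computed pseudotime is accepted everywhere. This
preserves what the downstream claims use — monotone trends along an
ordering — and recovers the true axis at |Spearman| ≥ 0.8 on synthetic
data.

Per-gene trends are tested by an F-test of a natural cubic spline fit
(df = 3, R `ns()` basis with interior knots at the terciles, hand-rolled
~25-line construction) against the intercept-only model; constant genes
get p = 1. The test is exact under Gaussian noise, and its empirical
type-I error at α = 0.05 over 2000 null genes stays within [0.035,
0.065]. Direction compares mean expression in the top vs bottom
pseudotime terciles (the resolution chosen for the unstated
"start vs end state" comparison). Benjamini–Hochberg q-values are
computed natively and oracle-checked against statsmodels.

The TF filter retains a TF that, per dataset, satisfies p < 0.05 AND
q < 0.05 AND end-mean > start-mean, in at least half of all datasets
(ties at exactly half retained — the convention that makes 19-of-38
arithmetic come out). Retained TFs are classified against the hypoxia
score per dataset by Spearman correlation (positive / negative / ns at
α = 0.05), summarized as per-class proportions. Subset-proportion fold
changes between hypoxia-high and -low groups add 0.5 pseudo-cells to
every subset count before forming proportions, so absent subsets yield
finite fold changes.

## Survival and ICB statistics

Spearman screens use average-rank ties, exact permutation p-values at
n ≤ 9 (full enumeration) and the t-approximation otherwise, with BH
q-values across features and significance at FDR < 0.05. Group contrasts
are two-sided Wilcoxon tests — rank-sum unpaired, signed-rank paired —
exact for total n ≤ 25 without ties, normal approximation with tie
correction otherwise. ICB response pooling follows the two conventions:
PD vs CR/PR (SD excluded; default) and PD vs CR/PR/SD (the IMvigor
convention). Where paired pre/on samples exist, per-patient on-minus-pre
score deltas are contrasted between response groups.

Kaplan–Meier estimation and the two-group log-rank test (hypergeometric
variance) are implemented natively because the maximally selected
cutpoint scan evaluates the standardized log-rank statistic at every
admissible split — midpoints between consecutive distinct scores leaving
each group ≥ 10% of samples (the conventional maxstat default; the
analysis it mirrors states none). The scan returns the argmax of |z|
(ties toward the smaller cutpoint) and reports the uncorrected maximal
statistic plus the log-rank p of the chosen split; the improved-Bonferroni
correction for cutpoint selection is intentionally not applied, since the
cutpoint is used for stratification and display rather than for a
selection-corrected test. Median survival is the earliest time the KM
estimate drops to ≤ 0.5 (undefined if it never does). The native log-rank
and the full scan are cross-checked in the tests against lifelines as an
independent oracle.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded from a
single integer per generator or CLI invocation; the CLI writes a JSON
manifest with SHA-256 digests of every output, and two runs from the same
seed produce byte-identical manifests. PCA/SVD sign conventions, stable
sorts, and explicit tie rules (median splits low, walk order by gene
index, cutpoint ties small) remove the remaining indeterminacy.
Problem sizes in the test and acceptance runs — 217-spot slides, 180-
sample cohorts, 150-cell T-cell datasets, 2000-gene null calibrations —
were chosen as the smallest scales at which the measured properties are
stable across seeds.

## Known limitations

Rank-enrichment scores remain composition-sensitive: a spot's score for a
program depends on what else the spot expresses, which is visible
whenever regions differ strongly in cell-type content. Deconvolution
assumes the reference spans the types actually present and shares the
slide's scale after counts-per-10k normalization; collinear references
degrade NNLS identifiability. The boundary algorithm assumes the
malignant region is a single connected expression cluster; multifocal
tumors would need per-focus seeding. The 1-D pseudotime cannot represent
branching trajectories, and the TF screen inherits that restriction.
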