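# Methods

`holonet` implements a weighted co-abundance network analysis for paired
host/microbiota omics data — gene expression counts from host tissue and 16S
OTU counts from the associated microbial community — and an integrated
heatmap that predicts putative host–microbiota interactions from module-level
correlations. This note documents the model, the numerical choices, and what
the synthetic-data studies do and do not establish.

## Preprocessing

**Host counts** are normalized between samples by the trimmed mean of
M-values (TMM). The reference sample is the one whose upper-quartile /
library-size ratio is closest to the mean of that ratio. For each other
sample, per-feature log2 ratios against the reference (M) and average log
intensities (A) are computed over features nonzero in both samples; the
central 40% of the M mass (`trim_M = 0.30`) and the central 90% of the A
mass (`trim_A = 0.05`) are retained, and the scale factor is `2**` the mean
of the retained M-values weighted by the inverse asymptotic (binomial)
variance of M. Factors are rescaled to geometric mean 1, and expression is
reported as `log2((count + 0.5) / (library_size * factor) * 1e6)` (log2
counts per million). The trims and pseudocount are the canonical defaults of
the method.

Genes are then filtered on the normalized log2 scale: a gene is kept iff its
maximum expression reaches 1.0 in at least one sample **and** its standard
deviation (n−1 denominator) is at least 0.15. The 1.0 threshold is
interpreted on the post-normalization log2 scale; both thresholds are
configurable.

**Microbial counts** are filtered first, on raw relative abundance: an OTU
is kept iff it contributes at least 0.005% of the grand total (the boundary
is retained). Retained OTUs are normalized by cumulative-sum scaling (CSS):
each sample is divided by the sum of its counts at or below its median
nonzero count (`quantile = 0.5`, fixed rather than adaptively chosen — a
fixed quantile is deterministic and testable), then transformed as
`log2(x / factor * 1000 + 1)`.

**Outlier screening** min-max scales each sample to [0, 1], clusters samples
by average-linkage on Euclidean distance, and flags samples whose first
merge into the tree exceeds `median + 5 * MAD` of all merge heights
(unscaled MAD). Flags are advisory: the pipeline logs them and removes
samples only when asked (`apply_outlier_removal`), or removes an explicit
`drop_samples` list, because the original analysis removed two specific,
hand-identified samples rather than applying a numeric rule.

## Network inference

All steps operate on one kingdom's feature × sample matrix.

**Correlation.** The biweight midcorrelation (bicor) with
`maxPOutliers = 0.05`: observations are weighted by `(1 − u²)²` with
`u = (x − median) / (9 · MAD)`; `u` is rescaled separately on each side of
the median so that at most 5% of the observations on a side receive zero
weight. Features with zero MAD fall back to Pearson weighting (logged);
features that are constant outright have undefined correlations, which
become adjacency 0 downstream (the "replace missing adjacencies"
convention).

**Soft threshold.** Signed similarity `(1 + cor)/2` is raised to a power β.
β is the smallest candidate (default 1…30) whose connectivity distribution
reaches a scale-free fit index of 0.85 (R² of the log-frequency vs log-mean
connectivity regression over 10 log-spaced bins, signed by the slope). When
no candidate reaches the cut: if the best fit still shows a trend (≥ 0.5)
the argmax-fit candidate is used; otherwise — typical for designed
experiments whose connectivity distribution is nowhere near a power law —
the canonical signed-network power for the sample count is used (18 below
20 samples, 16 below 30, 14 below 40, else 12). The decision and fit table
are logged, and β can always be fixed in the configuration.

**TOM.** The signed weighted topological overlap,
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, combines
direct adjacency with shared-neighbor support; `1 − TOM` is the clustering
dissimilarity.

**Module detection** decomposes the average-linkage tree of `1 − TOM` into
branches. A branch qualifies as a module when:

1. it completes below the height cut
   `h* = min + span · (0.95 − 0.05 · (4 − deep_split))` — deeper split (the
   default 4) cuts higher, so branches completing higher in the tree still
   qualify and more (smaller) modules are caught;
2. it has ≥ `min_module_size` (default 2) leaves;
3. it is tight and distinct: its core (mean internal merge height) lies in
   the lower 80% of the merge-height span, and the stem between the core
   and the height where it joins the rest of the tree spans ≥ 15% of the
   range;
4. its mean within-branch correlation clears a size-adaptive signal floor
   `3 · (0.5 + 2/m) / √n_samples` for an `m`-leaf branch.

The tree is read top-down and the largest qualifying branch wins, so a
genuine module is reported whole rather than as its tightest fragments.
The signal floor is the absolute anchor that separates real co-abundance
from chance: the dendrogram of pure noise is self-similar, so any criterion
expressed purely in relative heights admits noise clusters, while the floor
tracks the chance level of the tightest clusters a random tree offers
(measured at ≈ 4.5/√n for pairs, falling toward 1.5/√n for large branches).
Unassigned features carry label 0; there is no post-hoc reassignment
(`reassign_threshold = 0`).

**Eigennodes.** Each module is summarized by the first principal component
of its standardized member profiles (zero mean, unit variance, n−1
denominator), restandardized over samples and oriented so its correlation
with the module's mean profile is non-negative; the orientation rule makes
heatmaps reproducible. `var_explained` is the leading squared singular value
over the total. Rows are named `hME<k>` (host) / `mME<k>` (microbiota) with
labels ordered by descending module size.

**Trimming and merging.** Members whose correlation to their own eigennode
(kME, computed with bicor) falls below `min_kme_to_stay = 0.5` are released
to label 0, and a module is dissolved unless ≥ `min_core_kme_size = 2`
remaining members exceed `min_core_kme = 0.5`. Modules are then merged
iteratively: eigennodes are clustered by average linkage on `1 − cor`
(Pearson — merging operates on eigennodes, not raw features) and every
cluster joined below `merge_cut_height` is merged; the loop repeats until
no final eigennode pair is closer than the cut. The default cut is 0.5 for
the host network and 0.4 for the microbiota network — deliberately
aggressive, so strongly redundant modules collapse. Because of trimming and
merging, final modules can be smaller than `min_module_size` (but not
smaller than the core) and can contain members below the kME threshold.

**Connectivity.** Per node: `kTotal` (adjacency sum over all other nodes),
`kWithin` (same-module neighbors; 0 for unassigned nodes),
`kOut = kTotal − kWithin`, `kDiff = kWithin − kOut`.

All computation is single-block and dense; the implementation targets
desk-scale data (up to a few thousand features per kingdom). The branch
decomposition keeps per-node member lists, so memory grows quadratically
with feature count.

## Large-effect removal

A dominant environmental axis (the fresh-/salt-water transition in the
motivating data) can mask secondary associations. The number of latent
large-effect variables is estimated by permutation: eigenvalue fractions of
the feature-standardized matrix are compared, rank by rank from the top,
against the `1 − α` quantile (α = 0.05) of `B = 100` spectra obtained by
permuting values independently within each feature row, stopping at the
first rank that fails. The corresponding number of leading
principal-component score vectors is regressed out of every centered
feature (intercept included); residuals are exactly orthogonal to the
removed scores. The seed for the permutations is mandatory, making the
estimate bit-for-bit reproducible. Correction is applied per kingdom before
re-running network inference.

## Traits and integration

Host variables are encoded per replicate group (feed × water × day):
ordinal `Day`; binary `WaterSW` (1 = salt water); a one-hot encoding of the
four feed categories (FO, VO, FOVO, VOFO); `Female_ratio`, the fraction of
sexed fish that are female (unknown-sex fish excluded from the denominator;
missing with a warning when no fish is sexed); and the condition factor
`CF = 10⁴ · W / L³` (W in grams, L in millimeters, N = 4 bringing the
range near 1), averaged per fish then per group.

The integrated heatmap correlates group-averaged host eigennodes with
traits (left block; Spearman for the ordinal Day, Pearson otherwise) and
with group-averaged microbiota eigennodes (right block; Pearson), across
sample groups ordered by feed, then water, then day. Two-sided p-values use
`t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom, with pairwise-complete
observations per cell; cells with zero variance are undefined (r = NaN,
p = 1, flagged), and |r| = 1 reports the smallest positive double rather
than an exact zero p. Stars annotate raw p-values (* ≤ 0.05, ** ≤ 0.01,
*** ≤ 0.001); no multiple-testing correction is applied by default, with
Benjamini–Hochberg available as a clearly marked option. The default row
rule keeps host modules with at least one trait association and at least
one microbiota association at p ≤ 0.05. The exported TSV blocks are the
source of truth; the figure is a pure view of them.

## Enrichment

Module annotation uses the classic one-sided hypergeometric test per term
(`P(X ≥ overlap)` on universe / term size / module size), with the universe
defaulting to all post-filter network genes and annotations accepted
pre-propagated. Ontology-graph-aware decorrelation (elim/weight-style) is
out of scope; raw p-values are reported with an optional BH column.

## Synthetic data

The generator plants known structure so every stage is testable without
external data: per-module latent factors (standard normal across samples),
member features loading `√r` on their factor to realize a within-module
correlation `r`, cross-kingdom couplings via a shared latent component,
and trait-driven large effects added to module factors (then renormalized
to unit variance). Host counts are Poisson draws from transcript fractions
at log-normal library depths — per-sample renormalization mirrors RNA-seq
compositionality. Microbe counts are negative-binomial draws from absolute
abundances scaled to a target depth on average: a constant scale rather
than a per-sample denominator, because with planted modules holding a
substantial share of a 60–120-taxon community, compositional closure would
cancel the very co-abundance being planted. Dropout is abundance-dependent
(probability quadratic in the rank of mean abundance, so the marginal zero
rate equals the configured value while detection failures concentrate in
rare taxa, as in real marker-gene data), and microbe module members are
drawn from the upper half of the abundance range — observable co-abundance
modules are made of reasonably abundant taxa, as in the motivating study
where modules held about a third of retained OTUs.

Features of real data the generator does **not** emulate: phylogenetic
structure among OTUs, taxon-specific dispersion, batch effects other than
the planted factors, library-preparation artifacts, and gene–gene
regulatory structure beyond block factors. Passing the synthetic studies
therefore establishes the statistical machinery (recovery, calibration,
power, correction), not robustness to every artifact of real sequencing
data.

**Study configurations.** Four named configurations fix the conditions of
the characterization studies (`holonet.synthgen`):

- *module recovery*: 200 genes, 56 samples, five modules of 10–40 features
  at within-module r ≈ 0.8;
- *null calibration*: fully decoupled host/microbe data over 14 groups
  (2 waters × 7 days, 2 replicates);
- *coupling power*: couplings planted at r = 0.8 over 14 groups with 4
  replicates each and clean count noise (no dropout, Poisson counts) — the
  study asks whether a coupling realized at ≈ 0.8 at the eigennode level is
  detected, so technical attenuation is removed by design; with realistic
  dropout the realized coupling drops to ≈ 0.66 and the study would measure
  data noise instead. Note the statistical ceiling: at exactly ρ = 0.8 and
  n = 14 groups the two-sided 0.05 test has power ≈ 0.95 even for an ideal
  analysis;
- *large effect*: a water-type factor (2 waters × 7 days) shifting three
  host modules by 1.5 latent standard deviations, the planted target of the
  estimation/removal study.

The bundled fixture (300 genes, 60 OTUs, 56 samples in a 4 feeds × 2 waters
× 7 days design) keeps realistic noise (15% zero inflation, NB dispersion
0.1, two cross-kingdom couplings, a water effect on two host and one
microbe module) and drives the end-to-end pipeline and determinism tests;
the full run takes a few seconds on one CPU.

## Numerical choices and degenerate inputs

- Standard deviations use the n−1 denominator throughout.
- Correlations are clipped to [−1, 1] after floating-point accumulation;
  adjacency and TOM are clipped to [0, 1] and symmetrized.
- Constant features: Pearson fallback in bicor when MAD = 0; correlation 0
  with a warning when both inputs are constant; adjacency 0 for undefined
  correlations; zero-variance members are dropped from eigennode
  computation with a warning.
- Ties in module-size ordering break by the smallest member position, so
  eigennode names are deterministic.
- Every stochastic step takes an explicit seed; the pipeline writes a
  manifest (input hashes, parameters, seed) and a rerun with the same
  configuration is byte-identical.

## Known limitations

- Dense single-block computation: no blockwise partitioning for very large
  gene sets.
- The branch-qualification constants (80% core-scatter bound, 15% stem
  fraction, signal-floor scale 3) are fixed heuristics calibrated on
  simulated trees; they are exposed for inspection but not per-dataset
  tuned.
- The fixed CSS quantile (0.5) omits the adaptive quantile-selection
  heuristic of the originating method.
- Group-level correlation with ~14 groups has limited power for couplings
  much below r ≈ 0.7; the heatmap reports raw p-values by design, so its
  star annotations are a screen, not a multiplicity-controlled inference.
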