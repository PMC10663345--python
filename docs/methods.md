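# Methods

`endostat` implements the downstream statistics of a spike-in-calibrated
amplicon survey of plant endophytic microbiomes: a genotype × tissue ×
developmental-stage field design read out as 16S (bacterial) and ITS1
(fungal) ASV count tables. This note records the models, the defaults and
why they were chosen, and the numerical decisions that matter for
reproducing results.

## Data model

An `AsvTable` is a samples × ASVs matrix of non-negative reals (integers
when raw). Sample metadata carries the design factors: plant, genotype
(`WT`, `efr`, `fls2`, `lore`, `lyk4`), tissue, stage, sequencing run, plate
and amplicon. Tissue availability is stage-dependent — a Vegetative plant
has only root and rosette; stems, cauline leaves and flowers appear at
flowering; immature and then mature siliques follow — and the validator
rejects combinations outside this seasonal schedule. Bulk-soil samples are
first-class but exempt from the plant-design constraints and excluded from
plant-only analyses.

## Spike-in quantitation

Synthetic spike DNA of known quantity co-amplifies with each sample and
appears in the table as ordinary ASV columns, recognised through a
registry. Per sample,

    scaled = raw × spike_median / spike_sample

converts read counts to a common absolute scale. A sample is admitted to
quantitation only when its spike fraction lies in [0.20, 0.80] of total
reads (bounds inclusive); outside that window the calibration is
unreliable. The median reference is computed **over admitted samples
only**, per amplicon: whether the reference median precedes or follows the
admission filter is genuinely open, and restricting it to admitted samples
makes the scale factor robust to the rejected outliers. The reference set
is an argument for users who prefer the other reading.

## Quality filtering

Samples with fewer than 500 reads are dropped first; ASVs with fewer than
10 reads dataset-wide (recounted over surviving samples) are dropped
second. The order is fixed and the operation is idempotent. Filtering acts
on raw counts, before any scaling.

## Repeated rarefaction and alpha diversity

Depth varies over orders of magnitude, so tables are rarefied without
replacement (multivariate hypergeometric) to a fixed depth — defaults 1380
(16S) and 751 (ITS1) — 100 times, and the entrywise mean table is used
downstream; every mean row sums exactly to the depth. Samples under the
depth are excluded, never zero-filled. Each (iteration, sample) pair gets
its own seeded generator stream, so results are independent of execution
order.

Alpha metrics are computed per iteration and averaged: Shannon H = −Σ pᵢ
ln pᵢ; Pielou J = H / ln S, reported missing at richness 1 (J is genuinely
undefined there, and substituting 1 would claim perfect evenness of a
single taxon); Faith's PD as the branch length of the minimal
root-spanning subtree of present tips. "Richness-corrected" PD defaults to
PD / S — branch length per observed taxon, the simplest reading — with a
null-model standardized effect size (random equally-rich tip sets)
available as `method="ses"`; neither is claimed as canonical.

## Transforms and beta diversity

Two families of inputs feed the distance grid: repeat-rarefied counts
(optionally spike-scaled to an absolute version) and log-ratio transforms.

* **rCLR**: samples are first scaled to the dataset's median total, then
  each nonzero entry maps to ln(value) − mean(ln nonzero); zeros stay
  missing rather than being imputed. Euclidean distances are computed over
  pairwise-complete coordinates and rescaled by √(D/D_complete) so pairs
  with different overlap remain comparable. Matrix-completion variants of
  the robust Aitchison distance are deliberately out of scope.
* **ALR by spike**: ln(count / spike_sample), the spike reads serving as
  the per-sample reference — an absolute-scale log abundance up to the
  calibration constant. A pseudocount of 1 replaces zero counts only
  (configurable); nonzero entries are untouched so the transform stays
  scale-free where the data are informative.

Metrics: Bray-Curtis, binary Jaccard, Euclidean, and weighted UniFrac
(16S only; ITS1 has no tree). UniFrac is the **unnormalized** variant
Σ bₑ |pₑ(x) − pₑ(y)| by default, matching the common toolchain default; a
normalized flag divides by Σ bₑ (pₑ(x)+pₑ(y)). On a star tree with unit
branches the raw variant reduces to the L1 distance between tip
proportions, which the tests exploit as a closed form. Natural logarithms
everywhere.

## Core microbiome rules

* Core A: ≥ 0.5% relative abundance in ≥ 4 samples anywhere.
* Core B: ≥ 1% relative abundance in ≥ 20% of the samples of at least one
  tissue × stage subset.
* Indicator core: ASVs with best IndVal group = plant (vs bulk soil) at
  permutation p ≤ α. IndVal g = √(A·B) with A the group-mean share
  (specificity) and B the within-group presence rate (fidelity); the
  group-total variant of A is available for unbalanced designs. All
  thresholds are inclusive ("at least"); relative abundance is measured
  against the post-quality-filter totals, since the rules are applied to
  the filtered data. Multiple testing across ASVs is off by default with a
  Benjamini-Hochberg flag, mirroring common practice in indicator
  analysis.

## Permutational statistics

PERMANOVA works on the Gower-centred matrix G = −½ J D² J. The SS
absorbed by a design X is tr(H G), H the projector onto col(X) (computed
through an orthonormal SVD basis, so over-parameterised dummy codings are
harmless); sequential (Type-I) SS are trace increments along the growing
design in the stated order, and a marginal mode computes each term's
unique increment instead. The batch structure — plate nested in sequencing
run, encoded as the run:plate interaction factor — enters as a blocking
term fitted first; the fitting function has no true random effects, so
"random effect" is realised as block-first sequential SS, with an option
to restrict permutations to within-block exchanges for the stricter
exchangeability reading. Pseudo-F = (SSₜ/dfₜ)/(SS_res/df_res); p-values
use the add-one estimator (1+B)/(1+N); ties count toward the numerator,
with a relative tolerance so that numerically-zero residuals (perfect
separation) compare consistently. For n ≤ 8 an exact mode enumerates all
n! sample relabelings and returns #{F* ≥ F}/n!. A term adding no rank
beyond its predecessors (confounded with the block, say) raises an error
naming it rather than silently reporting zero df.

Univariate permutational ANOVA is the same machinery on the Euclidean
distance matrix of a scalar response — SS and F coincide exactly with the
classical decomposition, permutation replaces the F distribution.
Pairwise post-hocs run one-factor PERMANOVAs per level pair with
Benjamini-Hochberg adjustment across the pair family; levels with fewer
than two samples are skipped with a log entry.

PCoA keeps negative eigenvalues as explicit "imaginary" axes (|λ| scaled
like the real ones); corrected squared inter-point distances (real −
imaginary) reproduce the input exactly, which the tests assert on random
non-Euclidean matrices. Eigenvalues within 1e-9 (relative) of zero are
dropped.

PERMDISP2 embeds the distance matrix this way, locates each group's
centre — spatial median by default (matching the "median community"
notion), centroid optionally — separately on the real and imaginary
blocks, and takes corrected distances to centre, floored at zero before
the square root. The permutation test **recomputes centres, distances and
F under every permuted grouping** (vectorised Weiszfeld across
permutations), which makes it an exact Monte-Carlo test when samples are
exchangeable under the null; the cheaper shortcut of shuffling fixed
distances is measurably miscalibrated in both directions depending on the
centre type. The spatial median itself uses damped (Vardi-Zhang) Weiszfeld
iteration, tolerance 1e-8, safe when an iterate lands on a data point.

## Within-individual homogeneity

For each plant owning every tissue its scheme requires (`root_rosette`;
`aerial_no_siliques` = rosette, stem, cauline leaf, flower; `all_tissues`
= the stage-present set), Bray-Curtis distances among its tissue samples
are embedded per plant, the plant's median community is the spatial median
in that embedding, and the homogeneity score is the mean corrected
distance of tissues to it. The per-plant embedding follows from "the
median community of an individual plant"; a global-ordination variant
exists behind a flag for sensitivity analysis, since the source procedure
is ambiguous on this point. Scores feed a Stage*Genotype univariate
permutational ANOVA plus pairwise stage post-hocs (B-H). For two tissues
at distance d the median is the midpoint and the score is d/2 — a
closed-form check in the tests.

## Synthetic data generator

The generator emulates the field design, not any particular dataset:
5 genotypes × 4 stages with stage-dependent tissues and per-genotype plant
counts of 8/8/18/8 (the seasonal harvest pattern), one sample per
(plant, tissue), plus bulk soil. Counts are Dirichlet-multinomial around a
log-additive composition: baseline (symmetric Dirichlet draw,
concentration 0.3, giving the skewed abundance distribution typical of
amplicon data; an infinite concentration yields a flat baseline for
closed-form tests) plus per-taxon Gaussian tissue (sd 1.0) and stage
(sd 0.6) effects — tissue chosen as the dominant axis because tissue
explains far more community variance than any host factor in such
surveys — a plant effect (sd 0.3) shared across a plant's tissues to
induce within-individual correlation, run/plate effects (sd 0.1 each,
plate nested in run, 2 × 2 by default), and an optional planted genotype
effect: a fixed log-fold change on a random fraction of taxa, applied only
to the target genotype in the target tissue × stage cells. The
Dirichlet-multinomial concentration is 30 — moderate overdispersion in the
range typical of plant-associated amplicon data. Depth is log-normal
(log₁₀ mean 3.6, sd 0.5: ±3 sd spans three orders of magnitude, the
depth heterogeneity the rarefaction machinery exists for), floored at 20
reads so the quality filter has something to reject. Spike reads are
appended as dedicated ASV columns to hit a per-sample spike fraction drawn
uniformly from (0.2, 0.8), the admission window. A random bifurcating tree
with exponential branch lengths (scale 0.1) covers the experimental ASVs
of 16S-like tables only.

`expected_cell_composition` returns the softmax of the configured
log-effects — exactly the generating mean when plant/batch scales are
zero, and the typical (median) composition otherwise — so tests can
compare Monte-Carlo means against a closed form.

What the generator does **not** emulate: taxonomy and phylogenetic signal
in effects (effects are iid across taxa, so tree-aware metrics gain no
planted structure), chimeras/contaminants, spike-count noise beyond
multinomial allocation, zero-inflation beyond what the DM process
produces, and temporal autocorrelation between stages (stages are
independent draws). Passing tests therefore demonstrate correctness and
calibration of the statistics under a plausible compositional model — not
that real field data meet those assumptions.

## Calibration and power experiments

Two standing experiments (in `endostat.experiments`, run by the test
suite and `scripts/acceptance.py`):

* **Null calibration** — 40-sample single-cell null datasets (root ×
  Vegetative, 8 plants × 5 genotypes, no genotype effect): genotype
  PERMANOVA and PERMDISP rejection rates at α = 0.05 over 500 datasets
  must sit inside the exact binomial band [0.033, 0.071]. Permutation
  and rarefaction streams are decoupled from the data seed: reusing one
  seed would replay the very stream that generated the data, correlating
  the permutations with it.
* **Effect recovery** — an ITS1-like ripe-silique cell (15 plants per
  genotype) with a planted ln 4 effect on 10% of taxa for `lore`:
  the pipeline (quality filter → repeat-rarefy at depth 751, 50
  iterations → Bray-Curtis → genotype PERMANOVA, 199 permutations) must
  reject in ≥ 80% of 100 simulations while matched zero-effect cells stay
  at the nominal rate. Rarefaction is essential here: on raw counts the
  three-orders-of-magnitude depth variation dominates Bray-Curtis and
  roughly halves the power.

Problem sizes in the analysis drivers (half-scale plant counts except the
final stage, 25 rarefaction iterations, 199 permutations) are desk-scale
choices; all statistics are unchanged by scaling up.

## Known limitations

* No true random-effects model: blocking is fixed-effect sequential SS.
* rCLR distances use pairwise-complete rescaling, not matrix completion.
* The exact permutation mode is limited to n ≤ 8 by design (n! growth).
* PERMDISP assumes exchangeability under the null; with strongly
  unbalanced groups and heteroscedastic depth its calibration is not
  guaranteed.
* The IndVal permutation test is per-ASV; dataset-level error control is
  the caller's choice of the B-H flag.
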