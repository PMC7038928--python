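# Methods

This note documents the models and procedures implemented in `m6acomod`, the
parameter defaults and why they are what they are, what the synthetic-data
generator does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Peak calling and quantification

Windows of 100 bp with 50-bp step tile each gene's *spliced* exonic sequence
(0-based, half-open coordinates throughout; exons are walked 5′→3′, so
windows cross junctions and minus-strand genes are handled by reverse
projection).  A terminal window shorter than 100 bp is kept and its true
length used in RPKM — discarding it would blind the caller to 3′-terminal
peaks.  RPKM is `count · 10⁹ / (library_size · length)`.

The per-window enrichment score is `winscore = (RPKM_IP + 1)/(RPKM_input + 1)`;
the +1 pseudocount penalizes low-coverage windows whose raw ratio is
unstable.  The peak-call threshold is strictly greater than 2.  Calls are
unioned across all samples at the window level; runs of consecutive windows
within one gene are merged, and runs longer than 5 windows are split
5′→3′ into chunks of at most 5 windows, remainder last — a deterministic
rule chosen because any split is arbitrary and this one is reproducible and
order-independent.  Two called windows separated by an uncalled window are
*not* merged: contiguity means adjacent indices on the 50-bp grid.

The m6A ratio of a peak in a sample is the maximum over its windows of
`RPKM_IP / RPKM_input` (no pseudocount), with any window missing when its
input RPKM is below 5.  The maximum is deliberate: fragment-length and
read-length differences between libraries shift peak summits, and the
summit ratio is comparable across labs where a fixed-span average is not.
A peak with every window missing is missing.

Metagene profiles assign each peak's center, in spliced coordinates, to one
of 10 proportional bins per region (5′UTR, CDS, 3′UTR); regions are
half-open so the last CDS nucleotide is CDS.  With `normalize="region-length"`
per-bin peak fractions are divided by the mean per-bin region-length
fraction across transcripts, giving the conventional normalized metagene in
which a uniform peak distribution is flat at 1.

## Matrix assembly

Peaks missing in more than half of the samples are removed (strictly more:
13/25 missing drops a peak, 12/25 keeps it).  Quantile normalization uses as
reference the mean of per-column quantile functions evaluated on the full
row grid; each column's observed values are replaced by the reference
interpolated to the column's observed count and mapped back by rank, ties
receiving the mean of their tied reference values.  This dialect preserves
within-column ranks exactly and is exactly idempotent for complete columns;
with missing cells a second application reproduces the first only up to
interpolation error (observed sup-norm error up to a few percent on
heavy-tailed data at 10% missingness), which is the price of the simple,
reproducible rank-interpolation rule.  Replicates are averaged per cell line
over observed values only.

The coefficient of variation uses the n−1 sample standard deviation over
observed cell lines, requires at least 3 observations and a positive mean,
and classifies a peak as variable iff CV > 0.3 (a CV of exactly 0.3 is
stable; the boundary case is otherwise ambiguous).  Sample clustering uses
1 − Pearson r on pairwise-complete observations of high-CV features
(CV > 0.7 or the top-k by CV) with average linkage.

## Co-methylation network

The signed adjacency is `a_ij = ((1 + r_ij)/2)^β` with β = 7: signed, so
anti-correlated peaks get adjacency near 0 rather than being conflated with
correlated ones, and the soft power sharpens moderate correlations toward 0.
Dissimilarity is `1 − a`; topological-overlap dissimilarity is available
behind `use_tom=True` for parity experiments but is not the default, since
the adjacency step alone defines the model here.

Module detection is a simplified dynamic hybrid cut of the average-linkage
tree:

1. **Branch detection.**  The tree is cut at the largest gap in its sorted
   merge heights, restricted to the upper half of merges and capped at
   0.985 × the maximum height.  Within-module merges concentrate at low
   heights and the joins between modules (and to background) at high
   heights, so the widest gap separates genuine branches from their gluing
   merges regardless of the absolute height scale.  A fixed-height cut was
   tried first and fails when two planted modules are correlated by chance
   (with 25 cell lines, |r| ≈ 0.4 between independent module profiles is
   common), which places their join below any fixed cut that keeps noise
   apart.
2. **Dissolution.**  Branches smaller than `min_module_size` (default 30)
   are dissolved, as are incoherent branches whose mean within-branch
   adjacency is not at least twice their mean adjacency to outside peaks
   and above the absolute floor `((1 + 0.3)/2)^7` (the adjacency of a
   modest r = 0.3 correlation).  The cohesion test is what keeps a
   pure-noise dataset fully grey even when the height cut happens to carve
   large clusters out of it.
3. **PAM-like attachment.**  Each unassigned peak joins the module with the
   highest mean adjacency to it, provided that mean exceeds both the floor
   and half the module's internal mean adjacency; otherwise it stays grey
   (module 0).  The half-internal-mean condition keeps background peaks
   with chance correlation to a module profile out of the module.

Eigengenes: member rows are standardized (mean 0, sd 1; missing cells
imputed at the row mean, i.e. 0 after centering), the first right singular
vector over cell lines is the unit-norm eigengene, sign-flipped so its mean
correlation with members is non-negative (required for interpretable
signed regulator correlations); variance explained is the top squared
singular value over the total.  Modules are merged by average-linkage
clustering of eigengenes at distance 1 − r, cut either at a correlation
threshold or to a target combined count, and combined eigengenes are
recomputed from pooled member peaks.

## Regulator screen

Candidate RBPs are those with mean expression above a floor (default 1
TPM-like unit).  For each (RBP, module) pair the screen computes the
full-data Pearson r and the jackknife p — the maximum of the n two-sided
leave-one-out correlation p-values (t-transform; |r| = 1 maps to p = 0; a
zero-variance subset contributes p = 1).  The maximum over deletions means a
single extreme cell line can never carry a significant call, at a known cost
in power; leave-one-out correlations are computed for the whole grid at once
from running sums.

The cutoff is calibrated empirically: each of 10 permutation rounds applies
one shared random permutation of cell-line labels to the expression matrix
(eigengenes fixed — one shared permutation preserves the RBP–RBP dependence
structure of the null) and repeats the full jackknife scan.  The chosen
cutoff is the largest observed p at which the mean number of null calls is
at most `target_fdr` (default 0.2) times the observed calls; significance is
inclusive (p ≤ cutoff).  If no cutoff qualifies, nothing is called.
Correlations of both signs are eligible, since erasers and negative
regulators anti-correlate with their modules.

## Binding enrichment and integration

For each RBP with CLIP peaks (≥ 1-bp interval overlap, strand-aware,
half-open abutment does not count) or an IUPAC consensus motif (scanned on
the transcript strand only; U ≡ T), each module's flagged fraction is
compared with the peaks of all *other* modules (grey excluded) by a Pearson
chi-square on the 2×2 table with no continuity correction — module sizes
are large enough that Yates correction only biases p upward — and p-values
are BH-adjusted across all tests jointly.  Tables with an expected cell
below 1 report p = 1 with a warning rather than an unreliable statistic.
An RBP is high-confidence when it has a significant correlation *and*
positive enrichment (q < 0.05) in the same module; RBPs with no binding
data at all are flagged unevaluable and stay low-confidence.  Motif–anchor
proximity histograms record center-to-center distances from each RBP-motif
match to its nearest DRACH match.

## Knockdown validation

Peaks qualify only with input window RPKM > 5 in *all* samples (both
conditions) and m6A ratio > 0.1 in *both control* replicates (the filter is
on controls only: the knockdown ratio may legitimately collapse).
Replicate ratios are averaged before the log2 fold change of knockdown over
control.  Strata (pooled modules of the regulator, CLIP-bound peaks) are
compared with the complement by a two-sided Wilcoxon rank-sum test, with
ECDF coordinates exported for cumulative-fraction plots.

## Synthetic data

The generators are pure functions of (parameters, seed).  The
`paper-scale-small` preset: 120 genes (log-normal region lengths around
150/1200/900 nt; 30% multi-exon, half minus-strand), 320 planted peaks
aligned to the window grid, 25 cell lines, 4 planted modules of 60 peaks
with per-cell-line IP enrichment `exp(log 8 + 0.5·profile + ε)`
(ε ~ N(0, 0.12)) and the remaining peaks at constant 8-fold (the stable
class), 30 input reads per window, 8 planted regulators (two per module,
opposite signs) among 60 RBPs, CLIP planted at odds ratio 6 over background
0.1 and one concrete motif instance per target peak at rate 0.6.  Recorded
library sizes are the window-count totals × 100, reflecting that exonic
windows hold a small share of a real library and putting window RPKMs near
10, where the winscore pseudocount and the input-RPKM missing rule operate
as intended.

Planted regulator expression is an affine image of the module profile plus a
noise component orthogonalized against the profile and scaled so the
*realized* sample correlation equals `target_r` (default 0.8) exactly — the
planted condition holds in every draw, not just in expectation, which makes
per-draw recovery claims meaningful.

What the generator does not emulate: overdispersed counts (a
negative-binomial switch exists for the coverage model but Poisson is the
default), fragment-level read placement, GC or mappability bias, isoform
mixtures, correlated missingness, batch structure between labs, and
realistic motif composition of background sequence.  Tests passing on this
generator therefore demonstrate the statistical machinery — calling,
normalization, module recovery, calibration, enrichment — under clean
conditions, not robustness to every artifact of real m6A-seq.

## Problem sizes and numerics

The test and acceptance workloads use the preset above plus stage-level
experiments at 2 000 peaks × 25 cell lines (module recovery), 100 RBPs × 10
modules (null calibration, 20 seeds) and 16 planted regulators × 8 modules
(power, 10 seeds) — sizes chosen so each planted effect is comfortably
identifiable while whole-suite runs stay in minutes on one core.
Correlations are clipped to [−1, 1] before the adjacency power and the
t-transform; eigengene SVD drops zero-variance rows with a warning;
tied quantile-normalization inputs map to equal outputs; all hierarchical
clustering uses scipy's average linkage on condensed distances.  One global
seed fans out to per-stage seeds via SHA-256, so stages can be rerun
independently yet reproducibly and full reruns are byte-identical.

## Known limitations

- The dynamic hybrid cut is a simplified re-implementation; it satisfies the
  planted-recovery contracts but is not claimed to be branch-for-branch
  equivalent to the reference WGCNA implementation.
- The largest-gap cut assumes modules merge internally well below the
  heights at which they join anything else; extremely hierarchical module
  structure (modules of modules) may be cut at the wrong level — the merged
  combined-module step is the intended remedy.
- Quantile normalization under missingness is idempotent only to
  interpolation error (see above).
- The jackknife guards against a single outlier cell line; two coordinated
  outliers can still fake significance, which the permutation calibration
  only partially absorbs.
- Chi-square enrichment treats peaks as exchangeable units; clustered CLIP
  peaks on paralogous genes violate independence and can inflate
  significance on real data.
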