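# Methods

## The classification model

The classifying feature is a single scalar per sample,
x = log10(CCND1/CDKN2A). Its biological rationale: in RB1-competent
cells CCND1 (cyclin D1) drives CDK4/6-mediated RB1 phosphorylation and
is comparatively high, while loss of functional RB1 de-represses the
feedback that accumulates CDKN2A (p16INK4a). High x therefore marks
RB1-positive samples, and this orientation is treated as biological
fact: a training panel whose positive class has the *lower* mean x
raises an orientation error instead of silently inverting the rule.

Classification is a threshold on x. The trained model is the
one-dimensional Fisher linear discriminant under equal priors and a
pooled within-class variance, for which the decision point is the
midpoint of the two class means:

    x0 = (mean_pos + mean_neg) / 2.

The stored decision function Y = a·x + b uses a = 1/pooled_sd and
b = −a·x0, so Y is a z-scaled margin and the trained threshold is always
the zero-crossing −b/a. Scores exactly at the threshold are called
positive; this boundary convention is a documented choice, since the
decision rule is naturally stated with strict inequalities and leaves
Y = 0 undefined.

A published reference model ships with the package: decision cutoff
x0 = 0.404 with coefficient pair (slope 0.54, intercept −2.051094) kept
as metadata. The coefficient pair is internally inconsistent with the
cutoff (its zero-crossing is ≈ 3.80), and no resolution is derivable
from the printed constants alone; since 0.404 is the value actually
used to call samples in the published figures and tables, the preset
stores the cutoff as authoritative and does not attempt to reconstruct
the intended coefficients. The trained-model zero-crossing invariant is
therefore exempted for presets.

## Measurement paths

Microarray path: both genes are measured as log10 ratios against a
common reference RNA, so the reference cancels and
x = log10r_CCND1 − log10r_CDKN2A. No normalization is performed here;
inputs are assumed to be already-processed log ratios.

qPCR path: with amplification efficiency E per cycle, template scales
as E^−Ct, hence

    x = (mean Ct_CDKN2A − mean Ct_CCND1) · log10(E),

with arithmetic means over replicate wells and E = 2 (perfect doubling)
by default, exposed as a parameter. The exact Ct-to-ratio transform and
any efficiency correction used in the original assay are not published;
this efficiency-E ΔCt transform is the standard relative-quantification
form, and deliberately involves no housekeeping gene — the two-target
ratio cancels the per-sample loading term, consistent with reporting
the ratio directly. The two paths agree to numerical precision on
idealized data (Ct = c − log2 expression), which is asserted as a
property test.

Ct values are validated to the open interval (0, 50) cycles; a 50-cycle
run that never crosses threshold is a failed well, not a measurement,
and must be removed upstream.

## Signature selection

Two sequential filters over a complete genes × samples log10-ratio
matrix with binary phenotype labels (1 = RB1-positive):

1. variance filter: per-gene sample standard deviation (ddof = 1)
   ≥ sd_min, default 0.1 log10 units. The n−1 denominator is a
   documented choice — the convention is not fixed by the procedure's
   definition, and the interpretation of the 0.1 cut depends on it.
2. correlation filter: two-sided p ≤ alpha (default 0.001) for the
   Pearson correlation between the gene and the 0/1 labels. The p-value
   uses the exact t transform t = r·sqrt((n−2)/(1−r²)) on n−2 degrees
   of freedom; for a binary regressor this is identical to the pooled
   two-sample t-test (point-biserial identity), which the tests assert
   to 1e-10 relative. |r| = 1 returns p = 0. A label-shuffling
   permutation p-value is available for very small panels.

Zero-variance genes have no defined correlation; they are flagged and
carried as (r, p) = (0, 1) so one flat probe cannot abort a run, and
they can never be selected. Selected genes are returned sorted by
ascending p with ties broken by gene id. No multiple-testing correction
is applied by default — the procedure is defined by a raw alpha cut —
but a Benjamini–Hochberg q column can be attached as side information.

## Clustering

Genes and samples are clustered independently with distance
1 − Pearson and average linkage (UPGMA). The metric and linkage are not
derivable from the published figure and are fixed here as the common
choice for log-ratio expression heatmaps. The implementation is an
explicit Lance–Williams agglomeration rather than a library call for
one reason: determinism under ties. When two candidate pairs are at
equal distance the pair whose (lexicographically smallest leaf id)
labels sort first is merged, so golden tests see a single canonical
tree; the result is cross-checked against SciPy's average-linkage
cophenetic distances on continuous random data, where ties have measure
zero. Zero-variance rows or columns are dropped with a warning (the
correlation metric is undefined on them); an all-constant matrix is a
degenerate-metric error. Trees are emitted as Newick with branch
lengths equal to merge-height differences.

## Enrichment

Upper-tail hypergeometric over-representation: for a query of n genes
from a universe of N containing K set members, p = P(overlap ≥ k),
evaluated through the log-space survival function of
`scipy.stats.hypergeom` and verified against exact rational arithmetic
in the tests. The universe defaults to all genes on the input matrix;
query genes outside the universe are dropped with their count reported,
and sets are intersected with the universe before testing. The
"up-regulated" query is defined as signature genes with r > 0 toward
the class coded 1, and the direction must be given explicitly — "up" is
meaningless without fixing the reference class. Raw p-values are
reported; BH is optional. The original study's specific enrichment
p-values are not reproducible because neither its signature gene list
nor its pathway annotation source is published; enrichment is validated
by oracle and calibration tests instead.

## Synthetic data

The generators produce the two study geometries:

* expression panel — 16 + 14 samples by default; n_signature = 20
  planted differential genes over n_null = 200 null genes. A planted
  gene's class means are ±effect/2 (default effect 1.0 log10 units,
  noise SD 0.2, i.i.d. Gaussian on the log10 scale — the standard noise
  model for log-ratio data). CCND1 and CDKN2A are always the first two
  planted genes, CCND1 up and CDKN2A down in the positive class; the
  remaining planted genes alternate direction.
* qPCR panel — 7 + 5 samples by default; each sample draws its true x
  from N(1.2, 0.15) (positive) or N(−0.4, 0.15) (negative) and emits
  triplicate wells per gene with N(0, 0.1 cycles) noise, CDKN2A
  anchored at 26 cycles and CCND1 at 26 − x/log10(2), so the mean ΔCt
  encodes x at efficiency 2 and absolute Ct values stay in a realistic
  15–35 band. The x class means and SDs are plausible values chosen to
  give the clear two-group separation the validation panel shows; they
  are not published constants.

Identical configurations (including seed) produce identical output;
generation uses `numpy.random.default_rng` throughout.

What the generators do *not* emulate: probe-level effects and
error-weighted probe summarization, FFPE RNA degradation, correlated
gene–gene noise, and batch structure. Passing tests therefore
demonstrate that the algorithms are implemented correctly and behave as
designed under their own assumptions — not that the two-gene assay
achieves any particular accuracy on real tumors.

## Problem sizes and numerical choices

The test suite and analysis scripts run the training-panel geometry at
220 genes × 30 samples and the validation panel at 12 samples, with
multi-seed studies at 5–50 seeds and the threshold-recovery study at
1,000 resimulated panels; these sizes give stable statistics for every
check while keeping each run to seconds. Other notable choices:

* correlation values are clipped to [−1, 1] before the t transform;
* tie heights in clustering compare within 1e-15 absolute;
* the permutation p uses the add-one estimator, so it is never 0;
* hypergeometric arguments are validated as integers with full bound
  checks before evaluation;
* training requires ≥ 2 samples per class and positive pooled variance.

## Limitations

* The preset coefficient/cutoff inconsistency above is inherited, not
  resolved; only the cutoff is operative.
* Enrichment and signature results on real data depend on annotation
  and platform choices outside this package's scope.
* The classifier is strictly one-dimensional by design; no multi-gene
  discriminant or ROC-based threshold search is provided.
* Missing expression values are rejected rather than imputed: the
  filters assume complete per-gene vectors.
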