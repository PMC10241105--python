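# Methods

This note documents the models, defaults and design choices behind
`mirgrn`, and what the synthetic-data tests do and do not establish about
real data.

## Differential expression model

Counts for feature *f* in sample *j* are modelled as negative binomial with
mean `s_j · μ_fg(j)` and variance `μ + φ_f μ²`, where `s_j` is a per-sample
size factor, `g(j)` the sample's time point and `φ_f` a per-feature
dispersion.

**Normalization.** Median-of-ratios against the geometric-mean
pseudo-reference, computed over features with strictly positive counts in
every sample. When no such feature exists the function raises and points
the caller at total-count normalization rather than silently switching —
in a low-depth dataset that situation deserves an explicit decision.

**Dispersion.** Per-feature pooled method of moments on normalized counts:
per group, `φ̂_g = (v_g − m_g)/m_g²`, pooled with weights `n_g − 1`, then
shrunk toward the across-feature mean of the positive raw estimates with
weight 0.2 (floor 1e-8). The mild shrinkage stabilizes 4-replicate
estimates without the trend-fitting machinery of full GLM pipelines;
features whose within-group variance does not exceed the mean sit at the
floor. With one feature the shrinkage target equals the raw estimate, so
single-feature simulations recover the true φ (checked at φ = 0.5,
n = 1000, estimate within [0.4, 0.6]).

**Test.** A plug-in Wald test on the log ratio of normalized group means,
with the delta-method variance `(1/μ̂ + φ)/n` per group. The fold change —
but not the test statistic — adds a pseudo-count ε = 0.5 to both group
means so that zeros produce finite, attenuated fold changes. Features with
zero counts in both groups are reported as FC = 1, p = 1 and flagged
degenerate. This chain is a deliberately transparent stand-in for the
dispersion-trend/GLM machinery of the established NB packages; no numerical
agreement with them is claimed, and its operating characteristics are
established by simulation instead: on null data (φ = 0.1, mean 1000,
4 vs 4, 500 features, 20 seeds) fewer than 1% of features are called, and
planted |log2FC| ≥ 1.5 at means ≥ 500 is recovered with sensitivity
well above 0.8.

**Thresholds.** Defaults FC ≥ 1.8 and BH-FDR ≤ 0.01, both inclusive
(boundary values accept; the choice between strict and non-strict
inequalities is measure-zero for real data but fixed for tests), both
configurable. The low-count filter removes features whose *raw* mean count
is below 300 at **every** time point, before testing and before BH; the
per-time-point reading (rather than a grand mean over all samples) is the
adopted interpretation of "low at all time points", and raw counts are used
because filtering precedes normalization in the stage order.

## Temporal classification

Comparisons form an ordered plan: an adjacent chain (P04–P01, P09–P04,
P23–P09) plus long-range "cumulative" comparisons (P09–P01, P23–P01). Scan
order is by later time point, adjacent windows before long-range ones
ending at the same point. Each miRNA's `first_comparison` is the earliest
DE call in that order; persistence and transience are then judged on the
*cumulative* windows relative to that first hit — comparisons whose later
point lies beyond the first window and whose baseline is at or before the
first window's baseline. For a P04–P01 hit these are P09–P01 and P23–P01;
for a P09–P04 hit, P23–P01. Persistent means every such window repeats the
direction (vacuously true for hits in the last window); transient means at
least one such window exists and all are ns; an opposite call marks the
miRNA non-monotone and excludes it from both flags. V-shaped recoveries
(down then back up) therefore fall out as non-persistent/non-monotone
rather than being forced into a named category.

## Target verification

Pure intersection per comparison: predicted(miRNA) ∩ genes moving opposite
to the miRNA in the same comparison's mRNA table. Gene symbols are matched
after stripping and uppercasing (predicted-target exports and transcriptome
tables disagree on capitalisation; no other namespace reconciliation is
attempted — an Ensembl-vs-symbol mismatch is out of scope and must be
resolved upstream). A miRNA absent from the prediction table yields an
empty set flagged `no_prediction`, which is distinct from a prediction that
verified nothing. The eligibility gate (≥ 40 verified targets) only flags;
nothing is deleted. In the pipeline each DE miRNA is verified at its first
DE comparison, mirroring the listed-once bookkeeping of the temporal
module; `verification_scope: per_comparison` verifies every DE miRNA in
every comparison instead.

## Enrichment

Exact one-sided hypergeometric tail `P(X ≥ k)` with X ~ Hypergeom(N, K, n),
computed by the survival function of the exact distribution (stable to
N = 1e5); the EASE mode decrements k by one first, reproducing the
conservative DAVID-style score. The default universe is measured genes
(those appearing in the differential mRNA input) intersected with
collection-annotated genes: genes that could not have been observed or are
unannotated carry no evidence either way. `annotated` and `measured`
universes are available because web annotation tools default to
genome-wide backgrounds. Significance is the raw p ≤ 0.05, matching how
such term lists are conventionally reported; a BH-adjusted column is
emitted but deliberately not used for the flag. Both fisher and ease modes
exist because which variant a given web service applied is generally not
recoverable.

## Network export

Only significant records become edges; weight = |overlap|. Term node size
is the sum of incident edge weights, i.e. per-(miRNA, term) overlaps are
summed rather than unioned across miRNAs — a gene targeted by two miRNAs
counts twice at the term, matching the "section size proportional to the
number of target genes" convention of chord figures. Sub-networks filter by
term-name regex (default `mitochondri`, case-insensitive) and carry their
edge weights over unchanged. Exports are plain TSV/JSON with fixed node
orders and sorted keys; rendering is intentionally out of scope.

## qPCR

ΔCt subtracts the mean of the chosen reference assays per sample (default
workflow: two references), ΔΔCt subtracts the control group's mean ΔCt, and
fold change is `2^(−ΔΔCt)` — amplification efficiency is fixed at 2 (the
base is configurable; no efficiency calibration is modelled). The control
group's own fold change is exactly 1 by construction. Group tests are
two-tailed two-sample t-tests on ΔCt values, pooled-variance by default
(Welch optional). Spike-in assays are validated for across-sample Cq
stability but never enter normalization. A failed (undetermined) reference
reaction is an error naming the sample and assay; a failed target reaction
only flags that observation missing.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the pipeline assumes: 4 time
points × 4 replicates, NB counts over lognormal-ish size factors
(SD 0.1 on the log scale), planted trajectories from five templates
(early_up, early_down, mid_down, late_up, transient) apportioned
1 : 5 : 10 : 19 : 1 to mirror the phenomenology of a postnatal heart time
course, |log2FC| uniform in [1.5, 3], dispersions log-uniform in
[0.01, 0.2], planted miRNA baselines in [500, 5000] (above the count
floor), 60 true repressive targets per DE miRNA in disjoint blocks plus 150
decoy predictions each, a background of spuriously-DE genes (15% of
untargeted genes, DE per comparison with probability 0.5), and one planted
gene program per DE miRNA (set size 60, 80% drawn from its true targets)
among 50 uniform background sets. The transient template dips by a fixed
−1.2 log2 at the third time point and recovers to −0.45, keeping every
cumulative later comparison below the call threshold — the planted analogue
of a single-window transient.

It does **not** emulate: correlated miRNAs or co-regulation, overlapping
target repertoires (true blocks are disjoint by design so precision against
planted truth is unambiguous), compositional/library-preparation biases
beyond a scalar size factor, mean–dispersion trends, partial repression
(every true target flips direction deterministically when its miRNA is DE),
or annotation noise in gene sets. Passing recovery tests on this generator
therefore demonstrates the pipeline's correctness and calibration under its
own model assumptions, not performance on real tissue data.

## Numerical and determinism choices

- BH step-up is a direct vectorised implementation (stable mergesort,
  running minimum from the largest rank, clipped at 1), checked against a
  definitional oracle over all permutations of short p-value lists.
- Wald p-values are clipped at 1 so exact nulls report p = 1.
- Result tables sort by FDR ascending, |log2FC| descending, feature id;
  filtered features trail with FDR = NaN.
- Every stochastic component takes an explicit seed through a single numpy
  Generator; identical config + seed give byte-identical files. Writers use
  a fixed float format (`%.6g`), sorted orders and sorted JSON keys, and the
  run manifest records version, config hash and input/output checksums with
  no timestamps.
- Problem sizes in the test-suite simulations (e.g. 150–200 miRNAs,
  1500–4000 genes, 10–50 seed panels) were chosen as the smallest designs
  at which the planted effects are comfortably identifiable under the
  default noise model; they keep the whole suite in the tens of seconds.

## Known limitations

- The NB test uses a plug-in dispersion and a delta-method SE; at very low
  counts (group means of a few reads) it is conservative relative to a full
  GLM likelihood — the low-count filter removes exactly that regime.
- Verification is binary intersection; no correlation strength, seed-match
  quality or binding-energy scoring enters the decision.
- Enrichment treats gene sets as flat lists: no GO-DAG propagation, no
  term-redundancy trimming.
- The pipeline assumes one prediction table for all comparisons; per-stage
  prediction updates (e.g. re-querying per time window) are not modelled.
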