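# Methods

## Scope

`mscmir` implements a complete analysis pipeline for single-color miRNA
microarray studies of cultured multipotent stromal cells (MSCs) followed
across expansion passages, together with a synthetic-data generator that
emulates the study design so every stage can be exercised and validated
without external data.  The pipeline stages are: outlier-array removal,
normalization, negative-control-based detection calls, a four-stage
variability/magnitude filter cascade, repeated-measures differential
expression across passages, a pooled-variance MSC-vs-cancer group contrast,
and an RT-qPCR confirmation arm.

## The experimental design being modeled

Eight MSC donors are expanded through passages P3, P5 and P7; each
donor/passage RNA sample is hybridized to three technical-replicate arrays
(a randomized block design).  Each array carries 2686 probe sequences
representing 939 mature miRNAs, each spotted in 4–8 on-array replicates,
plus 434 negative-control probes whose signal distribution defines the
detection background.  Two donors stop early (one after P3, one after P5),
giving 21 donor/passage groups and 63 arrays; two arrays with extremely
elevated background are excluded, leaving 61.  Some probe sequences come in
duplicate pairs differing by one terminal base that map to the same miRNA.
A two-sample cancer cohort (each hybridized in duplicate) accompanies the
MSC arrays for a group contrast against MSCs at P3.

## Generative model

On the log2 scale the simulated signal for sequence *s* on array *a*
(donor *d*, passage *p*) is

    y = b_s + delta_{d,s} + tau_{s,p} + alpha_a + eta_{s,a} + eps_probe

with baseline `b_s`, donor random effect `delta ~ N(0, 0.20^2)`, fixed
ground-truth passage effect `tau`, array offset `alpha ~ N(0, 0.15^2)`,
sequence-by-array technical noise `eta ~ N(0, (0.02 m_s)^2)` and
probe-replicate noise `eps ~ N(0, (0.05 m_s)^2)`.  Raw intensities are
`2^y`, so log2 of the raw signal reproduces the additive model exactly.
The raw-signal distribution family is not dictated by anything upstream;
lognormal is assumed.

Three choices matter and were made deliberately:

* **Continuous intensity density.**  Baselines are drawn from a background
  component (uniform on 3.8–5.1 log2) plus an expressed component with an
  exponential upper tail (5.1 + Exp(0.9), clipped at 10; fraction 0.10).
  Real arrays show a continuous right-skewed intensity density; a hard
  bimodal gap would leave the expressed stratum so sparse in rank space
  that quantile normalization becomes visibly granular there (a one-rank
  shift moves a value by the local inter-sequence spacing), which
  manufactures spurious passage differences no real array would show.

* **Intensity-dependent technical noise.**  The multiplier
  `m_s = 1 + 0.8 * max(0, b_s - 6)` makes probe and array-to-array noise
  grow with expression magnitude, as observed on this array platform:
  replicate variability rises with signal.  Constant-variance noise would
  give highly expressed sequences unrealistically tight filter cutoffs —
  tighter than the quantile-granularity floor — and any rank jitter there
  would survive filtering.

* **Effect placement and calibration.**  The default ground truth injects
  12 differentially expressed sequences whose P7/P3 and P5/P3 shifts equal
  the signed fold changes reported for this design (|fold| 1.05–1.49),
  placed at moderate baselines (5.9–6.3 log2) where their within- and
  between-chip cutoffs (~0.05 log2) sit below the smallest effect
  (|log2 1.05| = 0.070).  The noise scales were calibrated once so that
  this holds; with them, the pipeline recovers the injected set at an
  observed false-discovery proportion well under 0.10 and power above 0.9
  (measured over 50 simulations by the acceptance suite).

The defaults also include 41 duplicate pairs with the long member 0.74 log2
(1.67-fold) above the short one, 11 expressed sequences annotated as
tRNA/rRNA contaminants, negative controls at 5.29 ± 0.11 log2, two arrays
with +3 log2 elevated background (the outlier-removal targets), and 60
sequences shifted by ±(0.4–2.84) log2 in the cancer cohort (folds up to
~7.2).

An optional donor-by-passage interaction component
(`interaction_fraction`, default 0) gives a slice of expressed sequences
donor-specific passage trajectories — large but inconsistent changes, which
is precisely what the biological-variability filter stage exists to remove.
It is off by default so that the ground-truth recovery invariants
(significant set = injected set) remain exact.

### What the generator does not emulate

No image-level or spot-level simulation, no spike-in ladder, no dye bias
(single color), no probe-sequence-specific affinity, no batch structure
beyond per-array offsets, and by default no donor-inconsistent biology.
Passing tests therefore demonstrate that the *procedures* behave correctly
under the stated statistical structure, not that real arrays satisfy that
structure.

## Normalization

Two schemes are implemented; quantile normalization is the default input
for all downstream analysis.

* **Quantile**: each array's values are mapped rank-wise onto the mean of
  the arrays' order statistics; tied values receive the mean of the tied
  ranks' reference values (the standard convention).  Applied to the raw
  signal with no background correction.  Idempotent to 1e-12 and exactly
  column-order invariant.
* **75th-percentile scaling** of total gene signal: each array is scaled so
  its 75th percentile equals the geometric mean of all arrays' 75th
  percentiles (the scaling target is arbitrary and cancels in differences),
  then log2.

Probe replicates are collapsed to the per-(sequence, array) median on the
raw scale, by default before normalization (a switch normalizes at probe
level first; the two orders are distinct estimators that agree closely).

Negative controls are *not* pooled into the rank basis.  Each array's
monotone raw-to-normalized map is built from experimental probes and the
controls are passed through it, landing on the expression scale without
their i.i.d. scatter perturbing experimental ranks.  Pooling them visibly
inflates apparent passage differences for sequences whose intensities lie
inside the control cloud.

## Detection

Outlier arrays are flagged from raw (pre-normalization) negative-control
means exceeding the median + k·MAD (k = 5) of per-array means —
normalization would erase exactly the elevated-background signature the
rule looks for.  "Extremely elevated" is formalized as this robust rule;
k is configurable.

The background cutoff for each donor/passage group is the mean + 1 SD of
the group's pooled negative controls (all technical-replicate arrays
together, 3 × 434 values; a per-array variant is switchable).  A sequence
is expressed in a group when its median over the group's arrays exceeds the
group cutoff; commonly expressed when that holds in every group.  The
miRNA-level roll-up calls a miRNA commonly expressed when at least one of
its sequences is, after excluding tRNA/rRNA-class sequences.

The duplicate long/short comparison takes, per pair, the difference of the
members' mean log2 expression over all arrays and runs a paired t-test over
pairs; the fold change is `2^(mean difference)` with a signed convention
(below).  Zero-variance differences yield p = 0 (p = 1 when the difference
is also zero) with a warning rather than an exception, so deterministic
fixtures do not crash.

## The filter cascade

1. **Within-chip**: per sequence, the sample SD of its probe replicates is
   taken per array on normalized log2 values; the cutoff is the median SD
   over arrays.  A sequence passes when its |mean P7 − P3 difference|
   (donor-paired means, donors observed at both endpoints only) strictly
   exceeds the cutoff.
2. **Between-chip**: the cutoff is the median over donor/passage groups of
   the SD across the group's technical-replicate arrays.  The formula is a
   reconstruction (the replicate-axis SD is the only definition the design
   leaves); it is isolated behind one function so an alternative is a
   one-line swap.
3. **Biological variability**: paired t-test of donor-level P3 vs P7
   values; p ≤ 0.05 keeps (inclusive, configurable).
4. **Magnitude**: the mean expression at every passage must exceed the
   global negative-control cutoff, taken as mean + 1 SD of the pooled
   controls (configurable to mean-only).

Stages apply in order; later stages of a failed sequence are recorded as
not-evaluated in the FilterTrace, whose per-stage counts are conserved
(eliminated per stage + eligible = total).

## Differential expression

Technical replicates are averaged to donor/passage units before modeling —
the repeated measure is the donor across passages; mixing technical
replicates into the residual would misstate the degrees of freedom.  The
per-sequence model is a repeated-measures ANOVA with compound-symmetry
correlation across passages within a donor (equivalently a donor random
intercept).  For the balanced complete tables the operation requires
(donors missing a passage are dropped), the REML/GLS solution coincides
with the classical randomized-block ANOVA, which is used in closed form:

    MSE  = SS(donor x passage) / ((n-1)(k-1))
    F    = MS(passage) / MSE            on (k-1, (n-1)(k-1)) df
    t_ab = (ybar_a - ybar_b) / sqrt(2 MSE / n)   on (n-1)(k-1) df

With two passages this reduces exactly to the paired t-test (verified
against it, and against a REML mixed-model fit, in the test suite).
Degenerate inputs (MSE = 0) return p = 1 when the contrast is also zero and
p = 0 otherwise.

Benjamini–Hochberg adjustment is applied per contrast family across
sequences (one family per pairwise passage comparison); pooling all
families is available by configuration.  Significance is adjusted p < 0.05.
Fold changes use the signed convention: a log2 difference d maps to `2^d`
for d ≥ 0 and `-(2^-d)` otherwise, so the sign marks direction at the later
passage and |fold| ≥ 1 always.

The MSC-vs-cancer contrast is a classic pooled-variance (unequal sample
size, equal variance) two-sample t-test on biological-unit means, preceded
by the within/between technical filters with the group difference in place
of the passage difference, and a magnitude filter requiring the mean
expression to clear background **in at least one group** — a sequence
absent in MSCs but high in cancer is a real difference and must not be
discarded (the passage cascade, by contrast, requires all passages above
background, since a passage change is only interpretable for a measurable
sequence).  Significance is BH-adjusted p < 0.01.

## RT-qPCR arm

Targets are normalized by the geometric mean of five reference small RNAs
(SNORD61/68/72/95/96A); on the abundance scale this equals the arithmetic
mean of reference Cq, so ΔCq = mean(reference Cq) − target Cq is the
normalized log2 expression.  Well replicates are collapsed by median;
detection requires median Cq < 35; undetected wells are an explicit
sentinel, never numeric 0, and undetected targets are excluded from fold
tests.  Passage tests are paired across matched lines by default (the
lines are matched; an unpaired switch exists); the cross-set comparison is
a two-sample t-test on per-line ΔΔCq between the two MSC sets.  PPC/miRTC
run controls are validated against an acceptance band but never used in
normalization.  Fold estimates are invariant to any per-sample constant Cq
shift (reference normalization cancels it).

## Numerical and reporting choices

* All randomness flows from a single integer seed per generator call;
  identical seeds give byte-identical outputs.
* Heatmap clustering uses 1 − Pearson correlation distance with average
  linkage; PCA is centered, not scaled, with a supervised variant that
  restricts to a provided significant set.
* Readers are total on writer output (round-trip tested); the AFE-like
  dialect is a documented minimal column set with a configurable mapping,
  and the GEO series-matrix reader tolerates the `!`-preamble and
  `ID_REF`-keyed table.
* Problem sizes in the test suite: most unit tests run scaled-down designs
  (tens to hundreds of sequences, 3–6 donors); the calibration and
  recovery acceptance tests run 50 full-scale simulations (2686 sequences,
  61–63 arrays) each, and the acceptance script runs one full-scale
  experiment plus the qPCR arm.

## Known limitations

* The between-chip variability definition is a reconstruction; absolute
  filter counts are sensitive to it.
* Small-sample p-values from the closed-form CS ANOVA use containment
  degrees of freedom; other df conventions (e.g. Kenward–Roger) can differ
  in the third decimal.
* Under the default synthetic conditions the biological-variability stage
  removes few sequences, because donor-inconsistent passage changes are
  not generated by default (enable `interaction_fraction` to exercise it).
* In the simulated data within-chip variability is not smaller than
  between-chip variability; on the real platform the reverse is reported.
  The noise partition here was chosen so that filter cutoffs sit below the
  smallest injected effect while false discoveries stay controlled.
* Quantile normalization of granular data genuinely distorts sparse
  intensity regions; the generator's continuous density keeps this below
  the filter cutoffs, but very sparse real datasets would not enjoy that
  protection.
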