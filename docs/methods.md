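# Methods

This note records the models, estimators and numerical conventions behind
`monolens`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Fitness measure

Fitness is the relative doubling rate. Each well's OD600 series is
blank-corrected (per-time-point mean of same-plate medium-only wells
subtracted; values ≤ 0 floored at 1e-4 and flagged) and the doubling rate
DR (doublings/hour) is the **maximal least-squares slope of log2(OD)
versus time** over sliding windows of consecutive readings whose OD lies
in a fixed range. rDR is DR divided by the arithmetic mean DR of the
control strains on the same plate (median optional); replicates aggregate
to a mean with standard error, and `d = rDR − 1` exactly.

Window defaults: 9 points (4 h at 0.5-h readings), OD range 0.05–1.4.
Two effects drove these choices. First, blank subtraction amplifies
multiplicative reading noise at low OD — a reading near OD 0.11 with an
0.08 blank carries ~3.7× the nominal noise after correction — so the
window floor sits above the blank level. Second, "max over windows" is
biased upward under noise by roughly the extreme-value mean of the
per-window slope error; longer windows shrink that error. With 2%
reading noise the mean recovered DR is within 5% of truth for true rates
0.4–1.0 doublings/h (worst case ~4.4% at DR 0.4, the slowest rate, which
exposes the most windows to the maximum). Per-curve errors can reach
~8% at that noise level; the recovery guarantee is about the mean, not a
single well. Negative winning slopes are clamped to 0 and flagged —
measured doubling rates are non-negative; negative values exist only as
predictions.

## Epistasis model

Absence of epistasis is modelled multiplicatively: a genotype's fitness
is the product of per-locus quotients, hence additive in deviations after
log transformation. For a chromosome whose assayed deletions have
replicate-mean deviations `d_i`,

    rDR_E = 1 + Σ d_i        (both signs of d included, no truncation)

and for the corresponding monosomic strain ε = rDR_M − rDR_E. Negative
rDR_E values are retained as "effectively lethal" predictions. Both
signs of `d` enter because the deviation distribution includes
measurement and plasticity noise on both sides; truncating at zero would
bias the load estimate. Per-deletion deviations use replicate means (the
plausible convention; pooled estimates differ negligibly at 4
replicates). ε is reported on the rDR (difference) scale; a log-scale
multiplicative variant (`multiplicative_expectation`) is provided but
secondary.

### Bootstrap uncertainty

A percentile bootstrap resamples replicates within each strain (deletion
strains and the monosomic) and recomputes ε B=2000 times. With ~4
replicates per strain the plug-in bootstrap variance of a strain mean is
`s²(n−1)/n²` and the sample SD itself underestimates σ, which together
would shrink the interval to ~80% of nominal width (predicted ~88%
coverage). Centered resampled means are therefore inflated by
`sqrt(n/(n−1))/c4(n)` — unbiased variance plus normal-theory SD
unbiasing. Measured coverage of a planted ε across simulation batches is
94–96.5% at the 95% level. Strains with a single replicate contribute a
point mass (no variance estimate is possible); the interval is then
anti-conservative and the result flags should be heeded.

### Panel set arithmetic

Expected overlap of two screens of sizes n₁, n₂ drawn from N genes is
`n₁·n₂/N` (the hypergeometric mean); the enrichment tail
`P(X ≥ observed)` uses the exact hypergeometric survival function. Panel
size is `|A| + |B| − overlap − missing − dropped`; with explicit member
sets the union-minus-exclusions membership is cross-checked against the
count arithmetic.

## Karyotype calling

Bin depths (default 1 kb) are divided by the **genome-wide median** bin
depth — robust to one halved chromosome, which contributes < 10% of bins
(mean optional). A chromosome is *monosomic* when its mean ratio lies in
(0.35, 0.65) and ≥ 80% of its smoothed bins do; *euploid* analogously in
(0.85, 1.15); *segmental* when a contiguous run ≥ 20% of the chromosome
sits in one band and ≥ 80% of the remainder in the other; otherwise
*ambiguous*. Band membership is evaluated on non-overlapping 10-bin
(10 kb) mean ratios: at ~80× depth the raw 1-kb Poisson ratio noise
straddles both band edges (only ~82% of euploid bins fall inside
0.85–1.15, and a 20%-contaminated monosomic chromosome at ratio ~0.61
leaves ~16% of 5-kb aggregates outside the monosomy band), whereas 10-kb
aggregates keep both call types several σ clear of the 80% threshold.
The chromosome-mean condition is unchanged by smoothing.

For monosomic calls the revertant fraction — disomic cells arising from
endoreduplication of the remaining homolog — follows from the copy
mixture: expected ratio `r = 0.5(1+f)`, hence `f̂ = 2r − 1`, clipped to
[0, 1]. At 80× and 1-kb bins, f̂ recovers planted fractions 0–0.2 within
±0.05 (typically ±0.03; a small +0.01–0.02 bias comes from the Poisson
median sitting just below the mean). High-copy regions (mitochondria,
the rDNA array) can be excluded via a chromosome blacklist; GC
correction is omitted — a 2× signal at 80× depth does not need it — and
would be the first extension for real libraries.

## Dosage analysis

Expected counts under genome-wide constant expression are
**length-proportional**: `expected_i = L · length_i / Σ length_j` over
non-spike genes with library size L, because read counts scale with
transcript length at constant molar expression (per-gene-equal expected
counts are available as an option; the choice is a config flag).
Σ expected = Σ observed exactly. Per-gene ratios keep exact zeros
(flagged); chromosome summaries are unweighted means of member-gene
ratios. Note one structural property: the halved chromosome shrinks its
own sample's library, so all within-sample ratios are inflated by
`1/(1 − 0.5·w)` where `w` is the chromosome's expected library share —
about +1.3% for a mid-sized chromosome. The affected chromosome's mean
ratio therefore sits at ~0.506, not exactly 0.5, under perfectly
uncompensated halving.

log2 fold changes versus control scale counts by **median-of-ratios size
factors** (reference = per-gene geometric mean across samples over genes
positive everywhere; spikes excluded), then compare group means with a
0.5 pseudocount (exact-zero pairs report 0). This module quantifies
dosage ratios and correlations, not differential-expression calls; no
TMM/exact-test machinery is reimplemented. p-values are uncorrected by
design (a Benjamini–Hochberg helper exists, off by default).

Spearman's r_s is the Pearson correlation of average (tie-aware) ranks;
the two-sided p-value is the exact permutation probability for n ≤ 8
(all n! relabelings, enumerated) and the t approximation with n−2 df
otherwise. The fitness–expression correlation pairs each assayed
deletion's `d` with its gene's log2FC on the stated chromosome only.

## Spike-in transcriptome sizing

Raw spike counts are multiplied by per-sample adjustment factors that
equalize spike amount per unit cell volume (the reference sample has
factor 1); non-spike rows are untouched. The spike fraction is the spike
share of total counts (reported both pre- and post-adjustment, since
conventions differ). Relative mRNA per unit volume is the
non-spike/adjusted-spike count ratio normalized to the reference sample,
optionally rescaled by measured total cell volumes. Cell volume treats
the microscope long/short axes as ellipsoid **diameters** with the two
short axes equal: `V = (π/6)·L·W²` µm³ (semi-axis reading would differ
by 8×; the diameter convention matches how calipers on a micrograph are
used).

## Synthetic data: what it emulates, and what not

Growth: `OD(t) = blank + A·min(2^(DR·t), K/A)` with A = 0.05, K = 1.6
OD, blank 0.08, 0.5-h readings — exponential-with-ceiling rather than a
full logistic, the simplest shape whose early phase has a constant
doubling rate. Noise is a lognormal factor of unit mean (default CV 2%)
on the whole reading, the reader-noise model; there is no lag phase, no
death phase and no well-position (edge) effect. Plates are 8×12 with
blanks in the first and last wells and controls in two designated
columns (16 wells), mirroring a two-control-panel layout.

Coverage: independent Poisson bins at mean depth 80, scaled by
`0.5(1+f)` on the monosomic chromosome. Real libraries add GC waves,
mappability gaps and the rDNA hotspot — none are emulated, which is why
the caller's blacklist/GC story above stays conservative.

Counts: negative-binomial with mean `baseline_i·length_i`, dosage factor
(default 0.5) on the monosomic chromosome and an indiscriminate
ribosomal-protein upregulation (default 1.5×) in monosomic samples —
the RP response is deliberately dosage-blind, matching its biological
character. Cellular genes use dispersion α = 0.05 (biological
replicates); spikes use α = 0.005, technical noise only. Per-gene
baselines are lognormal with σ = 0.10 — deliberately far narrower than
real expression (orders of magnitude) so that chromosome-level summaries
are stable at realistic per-chromosome gene counts (~115–780 genes);
with real heavy-tailed expression, chromosome means of per-gene ratios
would need robust summaries (medians, trimming) that are available but
not the tested default. Passing tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to
heavy-tailed expression, batch effects or mapping artifacts.

The panel fitness tables produced by `synthetic_panel_tables` are a
**synthetic stand-in** for a per-strain replicate rDR source table: the
per-chromosome deviation sums and the monosomic replicate means are
calibrated exactly to the reference panel summaries in
`monolens.reference`, while individual deletion effects and replicate
noise are random. They exercise the loader → replicate-mean → deviation-sum
pipeline end to end; they carry no information about real individual
deletions.

Seeding: one global seed fans out to named child streams
(`child_rng(seed, component)`), so any layer regenerates bit-identically
in isolation; identical seeds give identical outputs everywhere,
including bootstrap intervals.

## Problem sizes used in the test suite

Recovery tests run at the scales the generators default to: 100
plates/condition for DR recovery; 50 coverage simulations (~12,000 bins
each) for detection; 3 replicate count samples at 5×10⁶ reads for
dosage; 200 simulations × B=1000 for bootstrap coverage (B=2000 is the
analysis default; coverage is insensitive to B beyond ~500). The whole
suite runs in well under a minute on one CPU.

## Known limitations

* The growth model has no lag phase; curves whose in-range segment is
  shorter than one window raise rather than degrade gracefully.
* Bootstrap intervals assume exchangeable replicates within strain; no
  plate/batch random effects.
* The karyotype caller targets whole-chromosome 2n−1 events; small
  segmental events below the run threshold are reported as ambiguous.
* Dosage ratios inherit the within-sample normalization inflation noted
  above; comparisons against a control-sample expectation would remove
  it but change the statistic's definition.
* The spike workflow assumes the adjustment factors are configuration
  (known from the experiment), not inferred from data.
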