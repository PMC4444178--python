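# Methods

This note documents the statistical procedures implemented in `cnvcc`,
the assumptions they make, the defaults and why, and what the
synthetic-data tests do and do not demonstrate.

## Data model and conventions

A CNV call is an interval on a chromosome with a probe count and an
integer copy-number state in {0, 1, 3, 4}; state 2 (copy-neutral) is
never stored. Input positions are 1-based inclusive, as in PennCNV
output. The span of a call or segment is defined as `end − start`:
equivalently, an interval [s, e] is treated as covering bases
s..e−1 (half-open [s, e)). This is the convention under which
published segment spans equal the difference of their printed
coordinates, and it makes the breakpoint partition exact with no
double counting. BED export uses the standard 0-based half-open
conversion (`s−1`, `e`). The redundant `length=` token in rawcnv
files is ignored and recomputed; a disagreement greater than 1 bp is
logged.

## QC

Two filters, in a fixed order. First, calls spanning fewer than
`min_probes` (default 30) probes are dropped — call reliability scales
with probe support. Second, subjects with more than
`max_calls_per_subject` (default 50) *qualifying* calls are removed
with all their calls; the count is taken after the probe filter, which
is what "more than 50 CNVs spanning at least 30 probes" requires.
Subjects with zero calls are always retained: controls without CNVs
belong in every denominator. Deletions and duplications count jointly
toward the limit. Controls with a depression history can optionally be
excluded; an absent MDD flag raises rather than silently passing
everything. Both filters are idempotent, and removed subjects are
written to an audit TSV.

## Segmentation

Segments are the breakpoint-union decomposition: within each
chromosome the sorted set of all call starts and ends partitions the
covered genome into maximal intervals on which every subject's copy
state is constant. Uncovered genome is not enumerated ("defined by a
change in at least one subject" implies change-defined segments only).
By construction every call interval is a union of whole segments; the
matrix builder verifies this and raises on partial overlap, which can
only indicate a bug or a mismatched call set. One caveat: two abutting
same-state calls of the same subject would split one constant run into
two cosmetic segments; array pipelines do not emit such calls, and the
random-instance oracle tests avoid generating them.

The subjects × segments matrix holds copy states (default 2);
*carrier* means state ≠ 2, deletions and duplications combined, which
is the analysis's explicit choice. Per-state matrices remain available
via the copy-state matrix itself for diagnostics.

## Segment association

Three per-segment statistics are provided:

* **Fisher's exact test** on the carrier × case 2×2 table (no
  covariates) — the reference for small counts.
* **Logistic score test** for the carrier term, evaluated at the null
  model fit (covariates only).
* **Firth penalized logistic Wald** — Newton iterations on the
  Jeffreys-prior-modified score `U*(β) = X'(y − p + h(½ − p))`, with
  `h` the hat diagonal. Estimates and standard errors remain finite
  under complete separation, which genuinely occurs here: the
  interesting segments are case-only. Ordinary ML logistic regression
  diverges on them, so some penalization or exact method is
  mathematically required.

Genome-wide (family-wise) p-values come from the max-statistic
permutation procedure: case/control labels are permuted B times
(default 10,000, seed mandatory and echoed in the output), the
genome-wide extreme of the statistic is recorded per permutation, and
each segment's genome-wide p is `(1 + #{extreme ≥ observed})/(1 + B)`
— the finite-sample "+1" correction guarantees validity. Two-sidedness
is the extreme over |statistic| (minimum two-sided p for Fisher).
Pointwise permutation p-values use the same counts segment-wise, so
genome-wide ≥ pointwise holds by construction. An `exhaustive=True`
mode enumerates all distinct label assignments and returns exact
fractions; it is tested against an independent enumeration oracle.

When batch is a covariate, labels are permuted within batch strata,
preserving the structure the regression adjusts for. This enables a
fully vectorised fast path for the score statistic: within-stratum
permutation fixes each batch's case count, hence the null fitted
probabilities (per-batch case fractions) and all score variances are
permutation-invariant, and each permutation reduces to one matrix
product. The default `fit()` therefore uses the score statistic for
the permutation null — its ordering agrees with the Wald statistic
under the null — while reporting Firth odds ratios and Wald p-values
per segment as the effect estimates. Permuting with the Firth
statistic itself is supported for small problems only; it costs one
penalized fit per segment per permutation.

Phenotype stratification runs the same scan for all cases, suicides
only, and attempters only versus controls, with the same seed policy
and no cross-stratum correction (the comparisons are reported
separately, as in the source analysis). Untestable segments (zero or
all carriers) get statistic 0 and p = 1; a constant phenotype is an
error.

FWER calibration is verified empirically: on 500 null cohorts
(200 subjects at the cohort's case fraction, 500 segments with
carrier frequencies drawn from the generator's spectrum, 1,000
permutations) the fraction of replicates with any genome-wide
p < 0.05 must lie within 3 binomial standard errors of 0.05.

## Rare-CNV burden

Rarity is defined per segment either by overall carrier frequency
(≤ 0.1 %, ≤ 0.5 %, ≤ 1.0 %; the full post-QC cohort is the
denominator, matching "population frequency") or by span (≥ 100, 200,
500 kb). The first threshold is printed without "≤" in the source
table; it is read as ≤ 0.1 % for consistency with its siblings. A
subject's burden is its count of rare carrier segments, truncated at
20 so single outlier individuals cannot drive group effects. Case
status is regressed on the count with batch adjustment
(statsmodels Logit; a Firth fallback covers separated or sparse
settings); the OR per additional rare CNV is the exponentiated slope,
and `p_bonferroni = min(1, 6·p_raw)` across the six settings. Both a
distinct-rare-segment count and a carrier-event total are reported,
since either reading of a "total" column is defensible. The
mean-burden comparison reports mean(case)/mean(control) with a
two-sided permutation p on |log ratio|.

Burden counting is at segment resolution (a subject's burden is the
number of rare segments it carries), consistent with segment-level
rarity definitions.

## Power

The analytic power operation is the two-sided pooled two-proportion
z-test. The control carrier frequency f is converted to the case
frequency on the odds scale, `p1 = OR·f/(1−f) / (1 + OR·f/(1−f))`;
with SE₀ the pooled-variance standard error under the null and SE₁
the unpooled one under the alternative,

    power = Φ((Δ − z₁₋α/₂·SE₀)/SE₁) + Φ((−Δ − z₁₋α/₂·SE₀)/SE₁),

Δ = |p1 − f|. This specification was verified against an independent
numerical computation before the build and reproduces the full
published eight-entry power grid at 475/1,133 and α = 0.05 to the
printed two decimals; reported values are rounded half-up as power
tables conventionally are. Expected carrier counts below 1 trigger a
normal-approximation warning.

Burden-regression power is Monte-Carlo: control counts are
Poisson(μ), case counts follow the exponential tilting implied by a
logistic model with slope log(OR) — for a Poisson baseline exactly
Poisson(μ·OR) — both truncated at the cap; power is the fraction of
replicates with slope p < α. The published burden-power column is not
treated as a reproduction target because its method and inputs are
unstated; the simulation takes both as explicit inputs.

## qPCR copy-number calling

Wells are multiplexed, so replicate i's ΔCt pairs target and
reference Ct from the same well. A sample's ΔΔCt is its mean ΔCt
minus the calibrator's (the calibrator is known to carry two copies),
and estimated copies = 2·2^(−ΔΔCt). Replicate ΔCt standard deviation
above 0.5 cycles flags an outlier. The integer call is the nearest
integer; the reported copy range is the min–max of per-replicate copy
estimates.

Call confidence is a documented behavioural stand-in for the
unpublished confidence score of the commercial analysis software: the
copy interval (call ± 0.5) is mapped to the ΔΔCt scale through
c ↦ −log₂(c/2) and the normal-curve mass of the combined
sample-plus-calibrator standard error falling inside it is reported.
A small-sample t-interval was considered and rejected: at
quadruplicate scale its tail mass keeps plate-wide confidence below
0.99 even at negligible replicate variance, whereas the described
behaviour of the reference tool — all-two-copy samples called 2 with
> 99 % confidence at ordinary replicate precision — is reproduced by
the normal propagation (plate-level simulation: 0.2 % vs 25–50 %
failure at a typical 0.05-cycle per-channel precision). Estimates at
a rounding boundary (e.g. 1.5 copies) correctly yield confidence near
0.5 and a low-confidence flag. Single replicates yield no confidence.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes:
475 cases (276 suicides, 199 attempters) and 1,133 controls by
default; rare non-overlapping CNV loci with log-uniform carrier
frequencies 0.05–2 % and log-uniform probe counts 20–2,000 at ~1.5 kb
probe spacing (sizes ~30 kb–3 Mb, with a small tail below the
30-probe QC line so the probe filter is exercised; planted risk loci
are forced past 30 probes because they model well-supported CNVs);
60:40 deletion:duplication mix; four assay batches of mildly unequal
size; 30 % of controls flagged with MDD history; an optional fraction
of hypervariable subjects given 55–85 artifact calls; ages N(45, 12²)
clipped to 18–90 and a 52:48 sex ratio. Planted effects convert the
control frequency to a group-specific case frequency on the odds
scale — the same arithmetic the power module uses — so logistic
regression on carrier status recovers log(OR) despite the fixed
retrospective group sizes. A cohort-wide `burden_effect` applies one
OR to every locus, under which the burden regression's slope on the
carried-locus count equals log(OR) exactly (the per-locus odds-scale
construction makes the posterior log-odds linear in the count).

All randomness flows from one `numpy` generator seeded from the
config; outputs are byte-identical across reruns. Loci are
non-overlapping by default so the segment decomposition equals the
locus list and planted truth is exactly recoverable; `overlap=True`
jitters call boundaries to exercise the breakpoint-union machinery.

What the generator does **not** emulate: probe-level intensities and
the calling HMM, GC-content artefacts, linkage between loci,
recurrent-locus boundary heterogeneity, ancestry structure, or
site/batch confounding with phenotype. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under
the stated sampling model, not robustness to array artefacts.

## Problem sizes used in the test suite

The suite verifies exact oracles at enumerable scale (6 subjects for
full label enumeration; 1,000-bp toy chromosomes for the per-base
segmentation oracle, 1,000 random instances), FWER calibration at
200 subjects × 500 segments × 1,000 permutations × 500 replicates,
and parameter recovery at the full 1,608-subject scale (12 replicates
for the planted-locus OR, 6 for the burden slope). These sizes give
standard errors small enough for 3-sigma acceptance bands while
keeping the whole suite under a minute of CPU.

## Known limitations

* The per-segment test under separation, the permutation count, and
  whether the original permutations respected batch are not stated in
  the source analysis; the defaults here (Firth estimates,
  score-statistic permutation within batch strata, B = 10,000 with
  the +1 correction) are documented choices, not claims about the
  original software.
* Adjacent segments with identical carrier patterns are all tested;
  the collapsed pattern count is available as a diagnostic
  (`collapse_identical_columns`).
* The qPCR confidence is a calibrated stand-in, not the commercial
  algorithm.
* Age and sex covariates in the permutation scan fall back to a slow
  generic path (per-permutation refits); batch is the fast path.
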