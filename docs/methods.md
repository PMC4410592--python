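# Methods

## The single-case inference problem

Array methylation studies normally compare groups. For rare imprinting
disorders each patient is their own study: one case hybridised in a batch
with N healthy controls, and the question at every CpG is whether the
case's methylation is abnormally low for that control population. Using
the control sample mean x̄ and SD s as if they were population parameters
(the one-sample t-test, or referring (x − x̄)/s to the normal curve)
ignores their sampling error and inflates the false-positive rate — badly
so at the 5–20 controls that a diagnostic batch affords.

The Crawford-Howell statistic corrects this by treating the case as a
sample of one from the control population:

    t_CH = (x* − x̄) / (s·√((n+1)/n)),  df = n − 1.

Under normality t_CH is exactly Student-t distributed, so its one-tailed
P is calibrated at any n ≥ 2. The Weisberg outlier statistic
t_WB = (x* − x̄)/(s·√(n/(n−1))) on n − 2 df is the third method exposed;
it is slightly conservative relative to CH (|t_WB| < |t_CH| always, and
it pays one extra degree of freedom). All three share one sign/tail
convention in the pipeline: `p_one_tailed` is the probability of the
hypomethylation direction. Both one- and two-sided tails are reported on
every result; the familiar textbook probabilities for the (0.4 vs
0.5 ± 0.1, n = 10) example — 0.365, 0.012, 0.371 — are the two-sided
tails of the three statistics.

Degenerate inputs: sd = 0 with the case equal to the control mean yields
t = 0; sd = 0 otherwise raises (the statistic is infinite, and silently
returning ±inf would poison downstream FDR and Fisher steps). Missing
control values are dropped per probe and the effective n is recorded;
rows with fewer than 2 usable controls (3 for Weisberg) are flagged
untestable rather than dropped, so probe tables keep one row per probe.

## Effect size and its interval

The case-controls index z_cc = (x − x̄)/s measures the magnitude of the
methylation loss in control-SD units. Its confidence interval follows
the noncentral-t construction: the observed w = z_cc·√n is Student-t
with n − 1 df and noncentrality δ = ζ·√n, where ζ is the population
effect. The 95% limits are therefore the roots of

    F_nct(w; n−1, δ_L) = 0.975   and   F_nct(w; n−1, δ_U) = 0.025,

divided by √n. The CDF is strictly decreasing in δ, so each root is
found by bracketed bisection (brentq, relative tolerance 1e-8 on δ,
bracket grown geometrically from [w − 10, w + 10]). scipy's noncentral-t
CDF returns NaN very deep in its tails; those evaluations fall back to
the Abramowitz–Stegun normal approximation, whose error there is orders
of magnitude below the root tolerance. Root-finding failure raises with
diagnostics — a clamped interval is never returned silently.

The "abnormality" point estimate is 100 × the lower-tail CH probability:
the percentage of the control population expected to score below the
case. Its interval maps the z-scale limits through the standard normal
CDF, Φ(δ/√n scaled) — consistent with the point estimate's asymptotic
meaning and monotone in the z limits.

Verified behaviour (all computed by the test suite): exact identities
t_OS = −t_CH·√(n+1) and t_WB = t_CH·√(n²−1)/n; CH type-I error within
binomial noise of 0.05 at 20 000 null replicates while the one-sample
test exceeds 0.07 at n = 10; 95% interval coverage within 2 Monte-Carlo
SE of 0.95 at 2000 replicates; interval width strictly decreasing in n
at fixed summary statistics.

## Pre-processing

Order: complete-case probe filter → sample detection-p QC (remove
samples with >90% of probes at detection P > 0.05; removing the case is
a hard error) → probe detection-p QC (>75% of samples at P > 10⁻⁵) →
sex-chromosome removal (chromosome dialects "X"/"23"/"chrX" normalised
to chrN form) → M = log2(β/(1−β)) with β clamped to [1e-6, 1−1e-6] →
quantile normalization → peak correction. All detection-p inequalities
are strict, matching the stated thresholds. Every step logs its removal
count and is recorded in the M-matrix provenance. Batch correction is
deliberately absent: the design requires case and controls from one
batch.

Quantile normalization replaces each column by the row-mean of the
per-column sorted values at its ranks; ties share the mean of the
reference values at the tied positions. The transform is idempotent and
leaves within-column rank order unchanged. It operates on M values —
raw intensities are not available downstream of beta extraction.

Peak correction: per sample, the unmethylated (M < 0) and methylated
(M > 0) density modes of the type-I and type-II strata are located by
Gaussian KDE (Silverman bandwidth, 512-point grid); type-II values are
rescaled by peakI/peakII on each side so the compressed type-II peaks
land on the type-I scale. Type-I values are untouched; a sample whose
stratum lacks a mode on either side (fewer than 10 points or a
single-signed distribution) is skipped with a warning rather than
corrupted. Hemimethylated values near M = 0 change at most by the mode
ratio and never flip sign.

## Region calling

Candidates are probes with mean control M in [−1, +1] (hemimethylation
band — the β equivalents 1/3–2/3 under a pure base-2 logit; the band
bounds are configurable), one-tailed P < 0.05, and Δβ < 0. The stringent
variant (off by default) BH-FDR-adjusts the one-tailed P and thresholds
at 10⁻⁷, reproducing the earlier cohort pipeline's rule as a config
option. Multiplicity adjustment is deliberately off in the default mode:
the region-consistency requirement (below) supplies the false-positive
control.

A region is a maximal run of candidates that is consecutive among the
retained hemimethylated probes of its chromosome — an intervening
hemimethylated probe that failed the candidate filter breaks the run —
with adjacent members ≤ 2000 nt apart and k ≥ 3 members. Both the
consecutiveness scope (hemimethylated vs all retained probes) and the
gap semantics (adjacent-pair vs whole-span) are config switches, since
either reading is defensible; the defaults are the ones stated above.
Position ties order by probe id for determinism. An independent O(n²)
all-windows enumeration of the same rule serves as the oracle in tests.

Fisher's combination over the member probes' one-tailed P values:
X² = −2·Σ ln pᵢ against χ² with 2k df. The survival function is
evaluated with the even-df Erlang closed form entirely in log space, so
log10 P is finite (e.g. −156 for a 10-probe complete-loss DMR) even
where the displayed P, reported as 0 below 10⁻³⁵⁰, underflows. At k = 1
the combination is the identity on p (exact χ²₂ property). Hypomethylation
is the analysis target; hypermethylation calling exists behind a flag,
off by default.

## Synthetic data generator

The generator emulates what the pipeline's filters key on, not the full
covariance structure of a real array:

- **Background** (default 1000 probes, chr1–22, spaced 1–2 Mb so they
  cannot form runs): a bimodal beta mixture centred at 0.1/0.9 with
  per-probe logit-normal spread (SD 0.6 M units) and ~10% intermediate
  probes (β uniform on 0.25–0.75). The intermediate mass matters: with
  two bare spikes and an empty middle, quantile normalization maps every
  case value between the modes onto one rank window and erases moderate
  mosaic effects — an artifact of degenerate synthetic data, not a
  property of the method.
- **DMRs**: control β centred at 0.5 (hemimethylation, M ≈ 0); the case
  carries mosaic loss, β_case = (1 − effect)·β_pattern, linear mixing on
  the beta scale as in a cellular mosaic (effect 1 = complete loss).
- **Noise** is drawn on the logit scale (default SD 0.2 M units ≈ beta
  SD 0.035 at a hemimethylated probe, typical of blood controls) and
  back-transformed, keeping β in (0, 1).
- **Type-II compression**: ~70% of probes are type II and their M values
  are shrunk toward 0 by 0.67 before back-transformation — the target
  that peak correction must undo.
- **Missingness** 0.001 per cell (higher rates make the complete-case
  filter discard implausibly many rows in a 50-control batch) and
  **detection failures** 0.002 per cell, drawn independently of beta (a
  simplification adequate for filter testing).

Everything flows from one seeded generator; identical seeds give
identical datasets. What passing tests on this generator do **not**
show: robustness to probe-level spatial correlation, SNP-affected or
cross-reactive probes, cell-composition shifts, or batch effects — none
of which the generator models.

## Problem sizes and defaults

Calibration experiments run at 20 000 null replicates (type-I error),
2000 replicates (interval coverage), 600–1000-probe synthetic arrays
with 20–50 controls, and 3–4 seeds × 3 subsample replicates for the
control-size titration — sizes at which the Monte-Carlo error is well
inside the asserted tolerances while the whole suite stays fast. The
default control-group sizes for titration (5, 10, 20, 30, 40, 50)
mirror diagnostic practice; 20 batch-matched controls is the
recommended operating point, with 10 feasible.

## Known limitations

- The hemimethylation band is applied to the post-normalization control
  mean M; probes whose controls sit just outside [−1, +1] are invisible
  regardless of effect size.
- Peak correction assumes both strata are bimodal per sample; arrays
  dominated by intermediate methylation would skip correction.
- Fisher's combination treats member CpGs as independent; neighbouring
  CpGs are positively correlated in reality, so region-level P values
  are anti-conservative and should be read as ranking scores.
- The interval construction assumes normal control scores; departures
  mostly widen rather than bias the interval, but heavy tails at very
  small n are not handled specially.
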