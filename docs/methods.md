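# Methods

## Problem setting

A tumor-informed liquid-biopsy assay tracks 1–3 somatic point mutations,
identified in a patient's resected tumor, in plasma cell-free DNA (cfDNA)
by deep amplicon sequencing. Two physical limits govern what such an assay
can see:

1. **Template molecules.** At ~3 pg per haploid human genome, `m` ng of
   cfDNA contains `floor(1000·m/3)` analyzable copies of each locus. A
   mutant allele can only be detected if at least one mutant molecule is
   pipetted into the reaction; at 5 ng (1,666 copies) and a true VAF of
   0.01%, that probability is only `1 − (1 − 10⁻⁴)^1666 ≈ 0.15`.
2. **Sequencing background.** Even error-reduced chemistry mistakes a few
   reads per hundred thousand. The background is strongly structured by
   substitution class: transitions run around 1.6×10⁻⁵ per read (0.0016%),
   transversions around 3×10⁻⁶ (0.0003%), indel artefacts are negligible
   at these loci.

`ctdnakit` implements the calling rules, an explicit generative model of
the assay, and the evaluation and monitoring analyses built on them.

## Background-error model and limit of detection

For each marker, wild-type control cfDNA samples (healthy donors, n ≥ 2,
default n = 9) yield per-sample false-positive VAFs `100·alt/total`. The
error profile stores their mean and sample standard deviation (n − 1
denominator — the unbiased convention; the choice matters little at n = 9
but is fixed and documented). The limit of detection follows the
empirical rule for a roughly normal background:

    LOD = mean + k·SD,  k = 3 by default,

so ~99.73% of wild-type observations fall below it. With the measured
KRAS c.35G>A control moments (0.0016 ± 0.0007%) this gives 0.0037%, i.e.
one mutant allele in 27,027. Markers without dedicated controls fall back
to the median background of profiled markers of the same mutation class,
since class is the dominant error factor.

## Calling

- VAF is `100·alt/total` in percent (percent is the canonical external
  unit; fractions are internal).
- Replicate PCRs are integrated by **summing raw reads** before the VAF
  is computed (pooled barcoded replicates on the sequencer behave as one
  library). The pooled VAF is the mediant of the replicate VAFs and lies
  within their range.
- The effective cutoff for a marker is `max(0.01%, LOD)`. The global
  0.01% cutoff is the assay-wide decision threshold; taking the max
  guards markers whose own background (e.g. the noisiest transition
  contexts, mean ≈ 0.0051%) approaches the global cutoff.
- Coverage below 10,000 reads yields `insufficient_coverage` (at 0.01% a
  positive call would rest on < 1 expected read); calls between 10,000
  and the 100,000-read design target carry a low-coverage warning.
- A sample is positive if **any** marker is positive; inconclusive only
  if every marker lacked coverage. The any-rule maximizes sensitivity for
  multi-marker panels and is a package design decision — other
  combination rules are defensible, and the rule is isolated in
  `call_sample` so it can be swapped.

## Generative model (synthetic_data)

Each simulated sample passes through three stages, all driven by one
`numpy.random.Generator` seeded from `SimConfig.seed`:

1. **Template sampling** — mutant copies ~ Binomial(copies, VAF/100).
   Binomial (with replacement) approximates aliquoting from a plasma
   extract; a hypergeometric refinement is unnecessary at plasma scale.
2. **Amplification** — proportional, with optional per-template Bernoulli
   dropout (success probability `dropout`, default 1.0). This is a
   deliberately coarse stand-in for branching-process PCR efficiency; it
   exists to let the all-or-nothing low-copy regime and the
   triplicate-pooling benefit be explored, not to fit real PCR kinetics.
   Zero surviving templates raise an explicit `LibraryFailure` rather
   than returning a silent zero.
3. **Sequencing** — coverage ~ Uniform(0.8·target, 1.2·target) around a
   150,000-read default (the uniform band mimics the printed per-run
   coverage ranges; the true distribution is unspecified), and
   alt reads ~ Binomial(coverage, p) with
   `p = f·(1−e) + (1−f)·e`, `f` the surviving template alt fraction and
   `e` the class error rate. Error is symmetric per substitution class,
   not per position, because only class-level medians are available to
   calibrate against.

Default conditions: 9-sample control cohorts, 150,000× coverage target
(115,000× where a specificity experiment is being emulated), 20 ng input
per PCR, transition error 1.6×10⁻⁵, transversion 3×10⁻⁶.

**What the generator does not emulate:** position-specific error motifs,
strand asymmetry, homopolymer/indel chemistry, UMI consensus, batch
effects, and biological variation in ctDNA shedding. Tests passing on
synthetic data therefore validate the statistical machinery under the
stated model, not the wet-lab assay itself.

### Dilution linearity and the template-limited switch

`simulate_dilution_series` defaults to the faithful physics: each level
binomially samples templates from the configured input mass. At 30 ng
(10,000 copies) the lowest level of the standard 45 → 0.0045% series
expects only 0.45 mutant molecules, so single-replicate quantification
there is all-or-nothing and the log–log r² of a single run fluctuates
well below 0.99. The linearity *property* — r² ≥ 0.99 across 100 seeds —
is a statement about read-binomial noise propagation, so the linearity
checks run with `template_limited=False`, which idealizes the template
pool as effectively infinite (a 10⁷-molecule pool holding each level's
expected fraction exactly) and isolates sequencing noise. Both regimes
are exposed; the test suite asserts the linear one passes and the
template-limited one visibly degrades.

## Assay evaluation

- **Linearity** is fitted by least squares of log₁₀(observed VAF) on
  log₁₀(expected VAF). The series spans four orders of magnitude, where a
  linear-space fit is dominated by the top level; slope 1/intercept 0
  mean unbiased quantification, and a multiplicative bias moves only the
  intercept. Levels with non-positive observed VAF are excluded with a
  warning; at least three usable levels are required.
- **Sensitivity/specificity** always report the raw confusion counts next
  to the percentages: at n = 25 the counts are the primary result and a
  rounded percentage hides the denominator.
- **Detection power**: the analytic bound `p_template = 1 − (1 − v)^(R·C)`
  versus a simulated `p_detect` that runs templates through sequencing,
  pooling and calling. With dropout 1 and no error, `p_detect` converges
  to `p_template` as coverage grows (verified at 10⁶ reads within
  Monte-Carlo tolerance 0.02). The single-20 ng vs pooled-3×5 ng
  comparison reports both designs: with faithful amplification the single
  reaction wins (6,666 vs 4,998 total copies, template bounds 0.486 vs
  0.393 at 0.01% VAF); with per-reaction dropout below 1 the pooled
  design hedges and can overtake it. The empirically reported pooling
  gain is dropout-model dependent and is treated as an exploratory
  simulation, not a calibration target.

## Longitudinal monitoring

A patient series holds day-stamped samples (day 0 = resection), the
marker panel, and the imaging relapse day. First-positive day applies the
full pooling + cutoff machinery per sample; lead time is
`imaging_day − ctdna_day` (negative leads are representable and warned,
so the tool generalizes beyond cohorts where molecular detection always
leads). The accumulation rate is the least-squares slope of percent VAF
on day over positive samples at or before the imaging day; fewer than two
usable samples yield no rate.

The packaged 14-patient retrospective relapse cohort table
(`data/retrospective_cohort.tsv`, transcribed published per-patient
values) is the reference input for cohort summaries. Medians use the
midpoint-of-central-pair convention for even n. Follow-up is summarized
over patients contributing a lead-time observation (n = 13; median 381,
range 163–962 days) — the one never-detected patient contributes no
delta — and the all-patient value (median 343 for n = 14) is reported
alongside, because the two denominators genuinely differ under the
midpoint convention.

The synthetic patient trajectory is piecewise linear: VAF 0 through a
30-day post-operative clearance window, then growth at a configurable
0.003–0.012 %/day toward the relapse day. Linear accrual is the simplest
shape consistent with the observed daily rates; exponential growth would
be equally defensible but adds a parameter the monitoring statistics do
not need.

## Numerical choices and edge cases

- Copy counts floor (a fractional molecule cannot amplify); the
  mass↔copies↔limit round-trip is exact to within one copy's mass
  (0.003 ng).
- `pg_per_haploid_copy` defaults to 3 exactly (not 3.3): the assay's own
  arithmetic (25 ng → 8,333 copies → 0.012%; 300 ng → 100,000 → 0.001%)
  uses 3, and consistency with it matters more than the textbook genome
  mass. Configurable. The heterozygosity factor of 2 is deliberately not
  applied — "copies" are haploid locus copies and one mutant copy defines
  the quantification limit.
- Allele-ratio conversion rounds to the nearest integer (`100/LOD`).
- Zero-coverage VAF, empty call sets, empty cohorts, single-control
  cohorts, and mixed-marker pooling are all explicit errors, not NaNs.

## Problem sizes

Stochastic checks use 100-seed repetitions for linearity and error-model
recovery, 1,000 seeded 9-control cohorts for the specificity estimate,
10⁶ binomial draws for the closed-form power oracle, and a few hundred
to 2,000 simulations per detection-power point. These sizes put the
Monte-Carlo standard errors comfortably inside the assertion tolerances
while keeping the full suite to a few seconds.

## Known limitations

- The dropout knob is a Bernoulli caricature of PCR efficiency; absolute
  `p_detect` values under dropout < 1 should be read qualitatively.
- Per-class symmetric error cannot reproduce locus-specific outliers
  (e.g. an unusually noisy transition context) except through a
  marker-specific profile supplied by the user.
- The monitoring model assumes days as integers relative to resection;
  calendar handling, survival modeling, and imaging data are out of
  scope.
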