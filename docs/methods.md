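# Methods

## Data model

One row per resection event: operator id, seniority group (`junior` /
`senior`, defined in the source study by prior conventional-resection
volume below / at-or-above 100 cases), 1-based serial procedure index,
procedure time in minutes, and three binary outcomes — perforation
(safety failure), en bloc status (`en_bloc = 0` means piecemeal
resection, a quality failure), and detrusor-muscle presence in the
specimen (pathological quality marker). Logs are plain CSV; booleans
are 0/1 and times carry two decimals, so write∘read is the identity.
Serial indices must be consecutive from 1 per operator, and an operator
has a single seniority.

## Learning-curve statistic

The group-level learning curve is the per-serial-index arithmetic mean
of procedure time over the group's operators (all operators must share
the same series length). Its CUSUM is the running sum of deviations
from the grand mean of that aggregated series; the final value is zero
by construction (checked to 1e−9 relative tolerance). The CUSUM is
invariant under adding a constant to every time and scales linearly
with the times, so it reflects only the *shape* of the decline.

The inflection point — the boundary between the initial (learning) and
consolidation phases — is the serial index of the CUSUM peak. Two
detectors are implemented:

- `raw_argmax` (default): the maximum of the CUSUM series, earliest
  index on ties. Ties are broken early deliberately, so recommended
  training volumes are never overstated.
- `poly_peak`: least-squares polynomial fit to the CUSUM series against
  serial index, maximized continuously over [1, n] (stationary points of
  the fitted polynomial plus the interval endpoints), rounded to the
  nearest integer index. The source study's description of a "CUSUM
  regression line" is ambiguous about whether the peak was read from the
  raw or the fitted curve; both are exposed, and the assumption-free raw
  argmax is the default.

The polynomial degree is unstated in the source material; under the
`auto` policy degrees 2–4 are fitted and the one with the highest
adjusted R² kept, with a fixed-degree override. Whether the polynomial
regression was applied to the time series, the CUSUM, or both is also
ambiguous; `fit_polynomial` accepts any series, and the bundled analysis
fits the CUSUM.

The inflection procedure is *included* in the initial phase: an
inflection at k on a 30-procedure series gives phase cells of k and
30 − k procedures per operator (e.g. k = 16 with 4 operators gives
64/56, k = 13 gives 52/68).

## Comparison battery

- Procedure time: pooled-variance two-sample Student t-test (not
  Welch), from raw values or from mean ± sd ± n summaries; the two paths
  are exactly equivalent. Degenerate zero-variance inputs: equal means
  give p = 1, unequal means p = 0.
- Binary outcomes: uncorrected Pearson chi-squared on the 2×2 table,
  df = 1. The continuity correction is off by default because the
  published p-values being reproduced (0.316 for 16/64 vs 9/52, and
  0.269 for 1/56 vs 0/68, which matches chi-squared rather than Fisher
  even at these small expected counts) follow the uncorrected
  statistic; a correction flag exists. A zero
  column marginal (no events anywhere) carries no information: χ² = 0,
  p = 1 by convention, and report rows where both cells have zero events
  print "—" for p.
- Fisher's exact test (option): exact integer hypergeometric
  enumeration; the two-sided p sums all tables with the same margins
  whose probability does not exceed the observed one within a relative
  tolerance of 1e−7 (the convention shared by mainstream
  implementations); the statistic reported is the observed table's
  hypergeometric probability.
- No multiple-testing adjustment: each p is reported marginally at
  α = 0.05, matching the analysis being reproduced.
- Display: p-values are printed to three decimals, values below 0.0005
  as "0.000"; machine precision is preserved in the CSV output
  (`p_raw`).

Reports carry both layouts — initial vs consolidation within each
group, and junior vs senior within each phase — plus overall counts and
rates. If a log contains a single seniority group the group layout is
skipped with a notice.

## Synthetic cohorts

The generator emulates the study design: two seniority groups of four
operators, 30 serial procedures each. Per operator, mean time starts at
`time_initial_mean`, reaches `time_plateau_mean` after the change point
k*, under one of three shapes: `step` (constant–jump–constant),
`linear_decay` (linear decline across the initial phase, plateau after
— the default preset, matching the gradual decline of real aggregated
curves), or `exponential_decay` (relaxation reaching within ~5% of the
plateau at k*). Observed times add independent Gaussian noise
(`time_noise_sd`), truncated below at 1 minute and rounded to the log's
two-decimal precision. Gaussian noise is the minimal assumption
consistent with the mean ± sd summaries the generator mimics. Each
binary outcome is an independent Bernoulli draw with an initial-phase
probability through k* and a consolidation probability after.

Preset parameters follow the published cell statistics: junior
52.61 → 26.36 min, noise sd 9, k* = 16, perforation (0.25, 0.018),
piecemeal (0.156, 0), DM absent (0.094, 0); senior 46.35 → 23.41 min,
noise sd 8, k* = 13, perforation (0.173, 0), piecemeal (0.115, 0),
DM absent (0.115, 0).

Reproducibility: operator i in a cohort draws from the sub-seed
`SeedSequence(master_seed, spawn_key=(i,))`, so cohorts are
byte-reproducible and operators independent. Within-operator outcomes
are independent across procedures — the serial correlation of real
trainees is not modelled, and no bleeding, obturator-reflex or
lesion-size/location effects are simulated.

What recovery on synthetic data does and does not show: under the
`step` shape the CUSUM peak coincides with the generative change point,
so detection can be scored against a well-defined truth — exactly with
zero noise, within ±2 in ≥90% of 200 noisy cohorts in the bundled
experiment (noise sd 6 over 4 operators). Under `linear_decay` the
CUSUM peak sits where the declining curve crosses the grand mean, a few
procedures *before* the configured end of decline (the demo cohort
detects 12/10 against configured 16/13); that is a property of the
CUSUM statistic itself, not an estimation error, which is why recovery
experiments use the step shape. Passing these tests shows the pipeline
is correct under its own generative assumptions; it cannot certify
behaviour under real-data features the generator omits (serial
correlation, operator heterogeneity, non-Gaussian noise).

## Numerical and design choices

- Problem sizes: the recovery experiment uses 200 replicate cohorts;
  the generator-moment checks use 500–700 replicate operators (~10⁴
  Bernoulli draws per phase, asserted within 3 standard errors). These
  sizes give Monte-Carlo error comfortably below the tolerances tested.
- The exhaustive Fisher validation sweeps every 2×2 table with positive
  row totals and N ≤ 60 (631,595 tables) against an exact rational
  enumeration.
- Aggregation requires equal series lengths; degenerate polynomial
  designs (n ≤ degree + 1) and inflections with no consolidation phase
  (k = n) are rejected rather than guessed at.
- Adjusted R² of a constant series fitted exactly is defined as 1.

## Limitations

- The raw per-procedure data behind the published tables are not
  public; the headline inflection points (16/13) are therefore covered
  by simulation recovery, while every published p-value and rate is
  recomputed from the printed cells.
- The published grand time mean (35.85 ± 15.47 min) is not consistent
  with the sample-size-weighted mean of the four published phase cells
  (≈36.9); without the raw data this cannot be resolved, so the overall
  summary reports whatever the supplied log contains and the printed
  grand mean is not used as a check.
- The retrospective, descriptive CUSUM variant is implemented; no
  sequential control-charting with decision limits.
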