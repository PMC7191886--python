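# Methods

## Model

Workplace dust concentrations are treated as lognormal, so the
respirable concentration c_R (mg m⁻³) is modelled on the inhalable
concentration c_I within a group of paired measurements by simple
linear regression in log space,

    ln(c_R) = k · ln(c_I) + C0 + ε,     ε ~ Normal(0, σ²),

fitted by ordinary least squares (closed-form normal equations).
Back-transformed this is the power-law conversion function
c_R = c_I^k · e^C0. The model assumes

- a single predictor: working activity and material are *not* entered
  as covariates (they co-determine c_I, violating the independence a
  multiple regression would need); instead the data are split into
  groups and fitted separately;
- homoskedastic, normal, serially uncorrelated residuals in log space —
  checked per fit by a Monte-Carlo Lilliefors test and the
  Durbin–Watson statistic;
- no calendar-time effect (exposure ratios are treated as homogeneous
  over the covered period).

Since respirable dust is a physical subfraction of inhalable dust,
admissible fits have k ≤ 1 and C0 < 0. For k < 1 the fitted power law
crosses the identity line at ci* = exp(C0/(1−k)); below that
concentration it would predict c_R > c_I. Each conversion function
therefore carries a validity range [max(0.01, ci*), 100] mg m⁻³ and
warns (but still computes) outside it. This per-entry lower bound
replaces a flat 0.01 mg m⁻³ bound, which would leave most entries
unphysical at its low end.

## Fit statistics

For each group fit the package reports the coefficient standard errors,
the Pearson correlation R, the sample-size adjusted coefficient of
determination

    adj R² = R² − m/(n − m − 1) · (1 − R²),   m = 1 predictor,

and the standard error of the fitted regression mean at a query point x,

    s_Fit(x) = s · sqrt(1/n + (x − x̄)²/Sxx),

where s is the residual standard error. s_Fit is smallest at the
predictor mean (s·sqrt(1/n), reported as `s_fit_min`) and largest at the
most extreme observed ln(c_I) (`s_fit_max`); the extremes are taken over
observed values, not a trimmed range. Confidence bands use normal
quantiles (±1.96·s_Fit at 95%), not t quantiles — group sizes make the
difference negligible. Published registry entries carry only the s_Fit
range, so intervals built from them use `s_fit_min` and are flagged
"minimum-width"; functions fitted freshly from data carry their design
summaries (x̄, Sxx, s) and give exact bands.

Residual order for the Durbin–Watson statistic is measurement start
time (ties by record id) — the natural autocorrelation axis; no other
ordering is defined for these data.

The Lilliefors-corrected Kolmogorov–Smirnov p-value is computed by
Monte Carlo: the sample is standardised with its own estimated mean and
sd, and its KS distance is ranked within `n_mc` (default 10 000)
standard-normal samples of the same size run through the same
estimation step, p = (1 + #{D_null ≥ D})/(n_mc + 1). This avoids
table-approximation ambiguity and is exactly reproducible given the
mandatory seed. Null tables are cached per (n, n_mc, seed) and
generated in memory-bounded chunks.

## Record selection and pairing

Single-fraction records are excluded (with per-record reasons) when the
duration is below 2 h, the value is below the limit of quantification
(LOQ is an input flag — samplers' LOQ values are not computed), or the
concentration exceeds 100 mg m⁻³ (inhalable) / 10 mg m⁻³ (respirable).
Cutoffs are strict as stated: exactly 100/10 mg m⁻³ or exactly 2 h is
retained. Below-LOQ records are kept at read time and dropped by the
filter so exclusions stay countable.

Pairs are formed deterministically: an inhalable and a respirable
record match if they share factory, location within the factory,
calendar day (of the start), industrial sector, report number, sampling
type and working activity, their start times and end times each differ
by at most 5 min (inclusive), and c_R ≤ c_I. Matching proceeds greedily
over inhalable records sorted by (start, record id); among several
admissible respirable candidates the one with the smallest
|Δstart| + |Δend| wins, ties broken by record id. Each record is used
at most once and the result is independent of input order. The
original study names twelve matching variables but enumerates only
examples; the implemented set is documented as an approximation. The
c_R ≤ c_I check runs after metadata/time matching so its rejection
count is reported separately. Rejected near-matches are attributed to
the most specific criterion they got past (concentration ordering, then
time window, then metadata); records with no same-factory/location/day
counterpart are not near-matches and are not counted.

## Group taxonomy

Activity codes map to six groups (surface treatment, high-temperature
processing, filling/transport/storage, machining/abrasive techniques,
forming, others); unknown codes fall back to group 6. Ten printed
material subcategories pool into mineral- (A), metal- (B) and
fiber-dominated (C) groups; unknown materials become "unclassified".
(The source text mentions twelve initial material groups but prints ten
named subcategories; the taxonomy ships the printed ten.) Four
activity×material combinations (1-A, 2-B, 4-A, 6-B) and seven heuristic
activity subsets (alpha–eta) have their own published functions; the
heuristic groups require their stated material (metal for soldering,
casting, welding, cutting, wire drawing; mineral for chiseling; any for
blasting). The taxonomy is an editable YAML data file, seeded with
every activity string printed in the source, because the full activity
code list of the underlying database is not public. Wood dust is
deliberately left unmapped: it is predominantly inhalable and must not
borrow the mineral-group function.

Conversion-group resolution prefers the most specific level:
heuristic → combined → activity → material. A fallback-to-6 activity
assignment (unknown code) is not accepted at the activity level — it
carries no information — so such pairs resolve via material, or fail
with an explicit error. The whole-dataset function is returned only on
explicit request, with a warning. One source-internal contradiction is
recorded in the taxonomy file: the chiseling group's originating group
is listed as 4-A in the defining table but called 5-A in the text; the
table value is used.

## Synthetic data

The generator emulates the nonpublic source database so that every
pipeline stage is testable. Per scenario: ln c_I ~ Normal(mu_lnI,
sigma_lnI) with defaults (0, 1) — median 1 mg m⁻³ spanning roughly
0.05–20 mg m⁻³, a convention; ln c_R = k_true·ln c_I + C0_true +
Normal(0, sigma_res). Draws violating c_R ≤ c_I or the concentration
cutoffs are resampled with counts reported; a scenario whose rejection
rate exceeds 50% raises. The default sigma_res = 0.2 keeps that
rejection below ~2% of draws: with larger residual scatter the emitted
sample follows a *truncated* model whose OLS slope is attenuated away
from k_true, and the generator is meant to produce data that genuinely
follow the stated linear model. Consequently the synthetic groups are
more tightly correlated than the published pooled groups — the
generator emulates idealised homogeneous working conditions, and
passing recovery tests demonstrate correctness of the estimator and
pipeline, not that real pooled exposure groups are this clean. Real
features not emulated: sampler-specific measurement error, secular
trends, within-group heterogeneity of processes, and correlated
repeated measurements at one site.

Records carry consistent metadata per duo (unique report number, so
duos cannot cross-pair), start times on working days with the
respirable member offset by 0–5 min, and durations of 2.5–8 h.
Configurable decoys each violate exactly one rule: start/end shifted by
more than 5 min, mismatched report number, c_R > c_I, below-LOQ flag,
sub-2 h duration, over-cutoff concentration. A manifest records the
expected pairs and decoy classes so selection and pairing bookkeeping
can be asserted exactly. One global seed expands into per-scenario
streams via `SeedSequence([seed, crc32(group_id)])`, so adding a
scenario never perturbs another's draws.

## Numerical and testing choices

- Natural logarithms throughout; all concentrations in mg m⁻³.
- OLS is closed-form; tests cross-check coefficients, standard errors
  and R² against an independent library implementation to 10
  significant digits up to n = 10⁵, and pairing against an O(N²)
  brute-force matcher on decoy-laden instances.
- Parameter-recovery simulations derive the residual sd from the
  published smallest s_Fit (σ = s_fit_min·√n) and the predictor spread
  from the published slope error (σ_x = σ/(se_k·√n)), which makes the
  simulated design consistent with the published uncertainties. The
  published intercept errors are smaller than s_fit_min, which no
  design can reproduce under this model (se_C0 ≥ s·√(1/n) by
  construction), so intercept recovery is judged against its estimated
  standard error.
- The slope-recovery acceptance computation uses the unconstrained
  generative model (no c_R ≤ c_I rejection), 50 seeded replicates at
  n = 15 120; the end-to-end pipeline recovery test runs 50 replicates
  of three 500-pair scenarios; the Lilliefors calibration uses a few
  hundred replicates against a shared cached null table. These problem
  sizes keep the whole suite fast while leaving Monte-Carlo slack well
  inside the asserted tolerances.
- Registry coefficients are data, protected by a SHA-256 transcription
  checksum; the loader refuses a mismatching file. The source summary
  quotes exponents down to 0.454, but the smallest tabulated exponent
  is 0.500; the registry stores only tabulated values.

## Known limitations

- The conversion functions describe average relations for German
  industrial working conditions 1998–2016; individual workplaces can
  deviate substantially, and careful matching of the working condition
  to a group matters more than the statistical error terms.
- No thoracic-fraction conversion, no wood dust, no extrapolation model
  outside the validity ranges.
- Published entries cannot yield exact confidence bands (only the s_Fit
  range was published); their intervals are lower bounds on the width.
- The pairing variable set approximates the original twelve-variable
  procedure from its published examples.
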