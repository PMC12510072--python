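# Methods

This note records the models, parameter choices and numerical decisions
behind `szproject`, and what the synthetic experiments do and do not
establish about real recordings.

## The virtual participant

No public recording pairs continuous seizure detections with hourly IED
rates over multiple years, so all experiments run on a generative model
with known ground truth.

Daily seizure counts are drawn from an inhomogeneous Poisson process

λ(t) = λ₀ · (1 + Σ_k d_k cos(2πt/T_k + φ_k)) · drug(t),

a multiplicative-cosine intensity: the simplest structure that carries
"seizure cycles" into the event stream while keeping λ > 0 whenever
Σ d_k < 1. Event times are uniform within their day; no circadian
structure is modelled. The hourly IED rate shares the same cycle phases,

ied(t) = μ₀ · (1 + Σ_k g_k cos(2πt/T_k + φ_k)) + ε_t,  ε ~ N(0, σ²),

truncated at zero — the truncation keeps rates physical without moving
the cycle phase. `drug(t)` is 1 before the change day, a constant factor
after, optionally preceded by a short transient factor that emulates a
titration dip followed by tolerance.

Defaults emulate the targeted study conditions: 1095 days (~3 years),
λ₀ = 3 seizures/day, cycles of 20 d (depth 0.4) and 5 d (depth 0.2),
μ₀ = 60 IEDs/hour with matching relative gains and noise SD 6, a drug
change at day 300 (the observed change occurred roughly ten months into
the recording), two extended recording gaps (14 d and 10 d), and a diary
reporting probability of 0.3744 (the reported diary concordance, 1169 of
3122 detected seizures = 37.44%). Where an experiment needs an *active*
drug, the default effect is 0.5 — a halving of seizure rate, the
conventional "responder" threshold in epilepsy drug trials and of the
order implied by the study's 3–4× pre/post error ratios.

What the generator does **not** emulate: circadian and circannual
rhythms, seizure clustering beyond the Poisson-cycle structure,
detector false positives/negatives (all events carry probability 1.0
unless set otherwise), drifting cycle periods, and state-dependent diary
behaviour (thinning is independent per event). Green tests therefore
show the pipeline recovers the structure it assumes; they do not show
robustness to structure it does not model.

## Preprocessing

Detections with probability < 0.99 are dropped (inclusive threshold).
Days are half-open `[00:00, 24:00)` bins at fixed-offset midnight. Gap
filling replaces each missing run by the straight line between flanking
observations plus zero-mean Gaussian noise; the noise SD is estimated as
SD(first differences of observed samples)/√2 — the innovation SD if the
series were a noisy local trend. Leading/trailing missing samples are
trimmed (interpolation needs two anchors). The smoothed seizure rate is
a causal (trailing) 90-day mean; its first 89 days are warm-up, flagged
and excluded from modelling.

## Cycle detection

The continuous wavelet transform uses the analytic Morlet mother with
centre frequency ω₀ = 6, implemented in the standard FFT form with a
precomputed daughter bank (period ≈ 1.033 · scale; cone of influence =
√2·scale e-folding from each edge; zero padding to the next fast FFT
length with a two-e-folding margin so circular wraparound is
negligible). The candidate grid is 24 log-spaced periods per octave over
1–45 days (133 periods). Edge-affected (COI) samples are excluded from
time-averaged power.

Significance: the observed global power per period is ranked against
n_perm whole-series sample shufflings (block shuffling available);
p = (1 + #{null ≥ observed})/(n_perm + 1), Benjamini–Hochberg at
q = 1 − fdr_level (0.05 at the default level 0.95, i.e. 95% of
discoveries expected true). Contiguous significant periods collapse to
the locally maximal one. Hourly series are block-averaged to 6-hour
resolution before the transform: periods ≥ 1 day remain fully resolved
and the permutation loop is ~20× cheaper.

Two calibration facts, established by simulation and worth knowing:

* The test's *type-I rate is conservative*, not nominal. Permutation
  p-values are multiples of 1/(n_perm+1) while the BH threshold at rank
  i is 0.05·i/133; at n_perm = 200 any detection requires ≥ 14 periods
  whose observed power beats all 200 null draws simultaneously. Measured
  any-detection rate on white noise: ~0.002–0.01 versus the nominal
  0.05 (rising to ~0.02 at n_perm = 500). False-positive control holds
  one-sidedly with a wide margin; exact calibration does not.
* Power is nonetheless high for realistic modulation: injected 5-d and
  20-d cycles at depth 0.3 in two years of hourly data are both
  recovered within one grid step in ≥ 90% of simulations.

Phases are the arguments of the wavelet coefficients at the significant
scales; the 12:00 sample represents each day (midpoint of the bin). For
projection beyond the data, phase advances at constant angular velocity
2π/T per day. Phases are estimated on the full IED series: the rolling
forecast needs regressors at every origin, and a strictly causal
per-origin re-transform would multiply the cost for negligible change in
the regressors away from the series edge. This mirrors an offline
analysis; an online deployment would need causal phase estimation (a
known limitation).

## Forecasting

Models are estimated by exact maximum likelihood in state-space form
(statsmodels SARIMAX; trend constant for d = 0, none otherwise).
Non-convergent fits are flagged and excluded from order selection.

Rolling protocol: coefficients are estimated once on the
training/validation span (369 days by default) and held fixed
(`refit_policy="fixed"`; daily re-estimation with warm starts is
available). Each origin conditions on a fixed-length trailing window —
the longest lag duration plus one day by default. Fixed-length
conditioning matters: it makes the projection, and hence the residual
distribution, translation-invariant, so a residual cannot look unusual
merely because the recording was young when it was made. With fixed
coefficients the windowed forecast is an affine function of the window
values; the implementation recovers that function once from impulse
responses and evaluates the whole rolling run as a sliding dot product,
verified exact against per-origin Kalman filtering. Intervals are
Gaussian, ±1.96·√(h-step forecast variance).

Order selection repeats a 70/30 hold-out 100 times: each iteration draws
a random contiguous 30% validation block, fits on the data before it,
and scores horizon-ahead rolling MSE across the block; candidates are
ranked by mean MSE with ties to the simpler model. Naive benchmarks
AR(1) and MA(5) run the same protocol without exogenous inputs. The
smoothed rate is modelled on its natural scale (no log transform).

## Segment comparison and monitoring

Per-segment performance is the MSE of the 14-day-ahead projections,
grouped by the segment containing each target date (a 369-day
training/validation span and four ~3-month test segments, two per
regimen, mirroring the targeted study design).

The statistical comparison runs on the *magnitudes of one-step
residuals*. Two findings, each verified by simulation, force this
routing. First, consecutive h-step-ahead residuals share h−1 days of
their forecast window; treating them as independent samples makes the
Kruskal–Wallis test reject regimen differences for an inert drug in
over 90% of simulations, while subsampling to non-overlapping windows
leaves ~7 values per segment and no power. One-step residuals are the
model's innovations and restore daily sample size. Second, the regimen
signal is a *scale* difference — a drug that changes the seizure rate
changes the size of projection errors (Poisson variance scales with
intensity), not their sign — so rank tests compare |r|, the natural
rank-based analogue of comparing MSEs.

Even one-step residual magnitudes carry weak short-range dependence
(shared conditioning windows; a lag-90 component inherited from the
90-day smoother's bookkeeping). The reference distributions of the KW
and pairwise rank-sum statistics are therefore obtained by a
block-permutation null: the concatenated in-segment residual stream is
circularly offset and its 30-day blocks are permuted against the fixed
segment masks. Within-block dependence is preserved (calibration), the
alignment between residuals and segments — the quantity under test — is
destroyed (power). Thirty days exceeds every dependence scale the model
leaves in the innovations and is short relative to the ~3-month
segments. The H statistic itself is the conventional tie-corrected
Kruskal–Wallis statistic; pairwise p-values are Bonferroni-corrected
over the number of pairs. Measured operating characteristics at the
default study conditions: active drug (effect 0.5) rejected in 25/25
simulations, inert drug in 1/25, surrogate familywise false positives
0/10.

The surrogate control shuffles the smoothed-rate values uniformly
(dates, splits and analysis unchanged), refits on the shuffled training
span, and re-runs projection and comparison: destroying temporal
structure should destroy the regimen signal.

Monitoring uses the 14-day-ahead residuals, indexed by target date —
the horizon-ahead error is what "projected seizure rate" means
clinically. The band is mean ± 3 SD of the training/validation
residuals. A changepoint is declared at the first day of a run of at
least `persistence_days` (default 14, one horizon) in a flag state that
differs from the current effective state; runs shorter than the
persistence cannot switch the state, so single-day flickers neither
raise a change nor create a spurious return-to-normal.

## Numerical and degenerate-input conventions

Probabilities and thresholds are inclusive (≥). Constant series give
H = 0 and p = 1 in the rank tests (the asymptotic statistic is
undefined under total ties). A constant series fit yields σ² ≈ 0 with
the level in the intercept. Gap filling clips negative filled values at
0. Phase regressors satisfy sin² + cos² = 1 to 1e-12 by construction.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seeds give
byte-identical artifacts.

## Problem sizes used in the shipped experiments

Cycle recovery: 100 two-year hourly simulations, n_perm = 200.
Type-I calibration: 500 one-year daily white-noise series, n_perm = 200.
Parameter recovery: 50 AR(1) series of n = 5000. End-to-end
discrimination: 25 virtual participants per arm at the full 3-year
default configuration. Surrogate control: 10 shuffles of one
participant. The acceptance script runs the same computations at
smaller replicate counts (recorded in its `n` fields).

## Known limitations

* Cycle phases come from the full series (offline estimation); causal
  deployment would need online phase tracking.
* The 90-day smoother leaves a lag-90 structure in innovations that the
  low-order ARIMA does not capture; the block-permutation null absorbs
  it for testing, but a model with explicit long-lag terms could remove
  it at the source.
* The permutation/FDR cycle test is conservative at practical n_perm
  (see above); borderline cycles near the detection threshold will be
  missed more often than the nominal FDR suggests.
* Poisson counts understate the overdispersion and clustering of real
  seizure diaries; discrimination rates on real data will be lower than
  the synthetic operating characteristics.
* Fixed-offset time only; daylight-saving and timezone arithmetic are
  out of scope.
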