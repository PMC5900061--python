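# Methods

## Signal model and preprocessing

The package operates on beat-annotated normal-to-normal RR series.  The
editing chain mirrors standard nocturnal Holter practice:

1. **Beat editing.**  Runs of fewer than 5 consecutive non-normal beats are
   substituted by the median of the 7 preceding *normal* beats; runs of 5 or
   more are deleted and the next surviving beat carries a gap-boundary flag.
   "Fewer than 5" is read as runs of length 1–4 substituted, length ≥ 5
   deleted.  The substitution median deliberately skips previously edited
   beats so synthetic values never cascade; a short run without 7 normal
   predecessors is deleted rather than filled from thin history.
2. **Hour-quality filter.**  One-hour blocks, tiled from the recording start
   by cumulative RR time (no wall clock exists in RR-only input), are
   removed entirely when their pre-edit fraction of normal beats falls below
   0.95.  Edited beats count against the fraction because they were
   non-normal before substitution.
3. **Nocturnal selection.**  Mean heart rate is computed per one-hour block;
   the analysed segment starts at the first beat of the slowest block
   (earliest block on ties, for reproducibility) and comprises the next
   20,000 beats.  Non-overlapping hour tiling is used throughout.  Shorter
   remainders are truncated with a `short_signal` flag rather than rejected;
   series already at or below the target length are passed through
   unchanged, which also makes the full chain idempotent.

Gap-boundary flags propagate into the increment series: any increment or
L-gram window spanning a deletion is excluded from every count, and the
number of valid windows is reported alongside each estimate.

## Symbolization

Increments are quantized to the nearest multiple of the resolution ε, exact
ties away from zero.  For odd integer ε this reproduces the symmetric
banding {…, (−3..3) → 0, (4..10) → 7, …} at ε = 7, and it is well defined
for arbitrary positive ε.  The default ε = 8 ms corresponds to R-peak
timing at a 128-Hz sampling rate; coarser landscapes are obtained by
raising ε.

Two alphabets coexist: the **full** alphabet (all observed multiples of ε)
and the **ternary** view a/d/0 obtained from the sign of the quantized
action.  Entropies default to the full alphabet — transplant-cohort H1
values above ln 3 are impossible on three symbols — while fragmentation is
defined on the ternary view.  Summing full-alphabet probabilities by sign
reproduces the ternary distribution exactly, which is enforced as a test
invariant.

L-gram distributions use overlapping windows at step 1 (the standard
plug-in choice, maximizing counts at 20,000 beats).

## Entropic measures

H1, H2 and H3 are plug-in (maximum-likelihood) Shannon entropies in nats,
each computed from its own window count rather than from one marginalized
trigram table; the resulting boundary inconsistencies are of order 1/n and
are covered by stated tolerances (monotonicity H3 ≥ H2 ≥ H1 is asserted
within 3/n).  No bias correction is applied: with n ≈ 20,000 windows and
modest alphabets the plug-in bias (≈ (K−1)/2n per entropy) is well below
the between-signal variability the cohort statistics consume.

S_T = H2 − H1 estimates the entropy rate of the best first-order Markov
model.  sTE = (H3 − H2) − (H2 − H1) is reported exactly as this difference,
unclamped.  Two properties are worth stating plainly:

- For a stationary process, sTE = −I(X_{t+1}; X_{t−1} | X_t) ≤ 0: the
  transfer-entropy convention differs from this difference only in sign, so
  tests that need "memory present" bound |sTE| away from zero and the
  dependence test on cohorts is two-sided.
- The plug-in estimate of sTE carries a negative finite-sample bias of
  order (K³ − 2K² + K)/2n; it is left visible (never clamped at zero) so
  implementation errors cannot hide behind a truncation.  A practical
  consequence for the cohort-level sTE = 0 test: on cohorts of long,
  homogeneous signals the per-signal noise is an order of magnitude smaller
  than this bias, so the paired test rejects even for genuinely first-order
  dynamics.  Rejections whose median sTE magnitude is at the bias scale
  should be read as estimator bias, not memory; genuine lag-2 memory
  announces itself orders of magnitude above it.

`analytic_profile` supplies exact ground truth for first- and second-order
chains: H1 = H(π), S_T = −Σ_i π_i Σ_j T_ij ln T_ij, sTE = 0 for order 1;
for order 2 the profile comes from the stationary pair distribution of the
lifted chain.

## Fragmentation

Pattern probabilities are per overlapping window.  In the default
**zero-inclusive** mode, denominators count every valid pair/triple window,
zeros included, so P(ada) + P(dad) < 1 strictly whenever zeros occur;
`pattern_coverage` (= P(aa)+P(dd)+P(ad)+P(da)) reports how much of the
dynamics the four zero-free pair patterns describe.  The **zero-excluded**
mode deletes 0 actions inside each contiguous valid stretch before
windowing — the only reading under which excluding zeros still yields PSS
from triple counts — and approximates the original fragmentation-index
definitions.  Windows never span gap boundaries in either mode.

## Standard HRV indices

SDNN uses the population (divide-by-N) standard deviation, negligible
versus the sample convention at N = 20,000.  pNNx uses strict inequality
(|δRR| > 20 ms, > 50 ms).  RMSSD and pNNx exclude increments across gap
boundaries.

The spectral estimator is a filled design gap — band definitions
(VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz) do not pin down an
estimator — and is recorded in output metadata: cubic-spline interpolation
of the tachogram onto a 4-Hz grid over the longest contiguous valid
stretch, Welch periodogram with Hann window, 300-s segments, 50% overlap
and per-segment linear detrend, band powers integrated by the trapezoid
rule in ms².  A pure 25-ms tone recovers its analytic power amp²/2 within
15%, which is the calibration test.

## Cohort statistics

Signals (not subjects) are the sampling unit, matching the follow-up design
in which each subject contributes several nocturnal recordings; the
repeated-measures caveat is acknowledged and `compare_groups` offers a
subject-median aggregation as a sensitivity option.  Group differences use
Kruskal–Wallis on ranks with tie correction; descriptive quantiles use the
median-unbiased convention.  Paired dependence tests (S_T < H1, H2 < 2H1,
H3 < 3H1 one-sided; sTE = 0 two-sided) gate between a paired t-test and the
Wilcoxon signed-rank test on a Shapiro–Wilk normality check of the
differences at α = 0.05, and report which branch ran; identical columns
return p = 1 by convention.  Classification counts come from an in-sample
logistic fit thresholded at 0.5; under perfect separation (or any
maximum-likelihood failure) a ridge-penalized fit (penalty 10⁻⁴) keeps the
counts defined, since counts — not coefficients — are the quantity of
interest.  Time-trend regressions are OLS of index on years
(months / 12; slopes are reported per 12 months), with Pearson R and the
slope t-test p; the equal-slopes test is the ANCOVA interaction term of the
joint model value ~ time + group + time×group.  Leave-one-subject-out
refits report one regression per excluded subject plus the slope range.  No
multiple-testing correction is applied across the index panel; this is a
deliberate property of the protocol being implemented, documented rather
than silently changed.

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of parameters and a mandatory seed.

- **Markov action chains** realize "increments-first" generation: actions
  are sampled, then integrated onto a mean RR level with reflection at
  physiologic bounds [300, 2000] ms.  The run errors if more than 0.1% of
  beats have their increment altered by folding — a mirrored stretch of a
  sign-symmetric chain is statistically identical, so only genuine fold
  points count.  Because any stationary increment chain integrates to a
  random walk, the stock chains are strongly antipersistent (near-certain
  alternation), which both caricatures erratic rhythm and keeps 20,000-beat
  walks inside the bounds; weakly antipersistent chains legitimately
  trigger the guard.
- The **lag-2 mirror chain** (next action = negated lag-2 action with
  probability 0.9) injects memory invisible to any first-order transition
  matrix; its analytic |sTE| ≈ 0.70 nats versus a first-order noise floor
  below 0.01.
- **Modulated rhythms** add HF/LF sinusoids and Gaussian jitter on the
  cumulative-RR time base, for spectral-band calibration.
- **Erratic bursts** superimpose Poisson-placed, strictly alternating
  ±amplitude episodes on a background series.
- **Longitudinal cohorts** follow the 6-subject/24-signal and
  8-subject/34-signal visit structure typical of long-term HTX follow-up.
  Per-signal target H1 follows intercept + slope·years with between-subject
  SD 0.10 and within-subject SD 0.08 nats; defaults place the stable arm at
  1.38 nats with slope 0 and the complicated arm at 1.30 nats gaining 0.15
  nats/year — the magnitudes typical of transplant recipients.  Targets are
  realized by a **quantized-Gaussian level-noise generator**
  (RR = mean + ε·round(z/ε), z ~ N(0, σ²) i.i.d.): its increment marginal is
  the autocorrelation of a discretized Gaussian, so H1(σ) is analytic and
  inverted by bisection, and the signal is stationary and bounded.  The
  cohort family therefore departs from increments-first generation by
  design: integrating increments would random-walk through physiologic
  bounds at 20,000 beats, and the level-noise construction keeps the
  H1 ground truth exact instead.

What passing the synthetic suite does **not** show: the generators have no
circadian structure, no respiratory non-stationarity, no correlated
artifact bursts, and the cohort model's linear-in-time index trajectory
with Gaussian subject effects is an idealization.  Recovery of designed
parameters validates the estimators and the statistical protocol, not the
clinical claims one might base on real recordings.

## Numerical choices and degenerate inputs

- Natural logarithms throughout; 0·ln 0 := 0.
- Quantization ties round away from zero (symmetric banding for odd ε).
- Tie-break for the slowest hour: earliest block.
- Entropy/fragmentation require at least one valid triplet window (three at
  L = 3 for the entropy profile); otherwise an insufficient-data error
  names the shortfall.
- Constant series produce all-zero entropies, PIP = PAS = 0, PSS = 1,
  SDNN = RMSSD = 0 and ≈ 0 band powers, without errors.
- Distribution sums are validated to 1 ± 10⁻⁹; probabilities are exact
  count ratios, never renormalized floats.
- Problem sizes in the validation suite: 20,000-beat signals for recovery
  tests (the analysed segment length), 20 seeds for the Markov consistency
  check, 100 replicate cohorts for slope recovery — sizes at which
  binomial/regression standard errors make the stated tolerances sharp.

## Known limitations

- The hour filter recomputes block membership on the edited series; beats
  deleted during editing slightly shift later block boundaries relative to
  filtering the raw series first.  Both orders are defensible; this one is
  deterministic and single-pass.
- Entropies at coarse resolutions (large ε) have small alphabets where
  plug-in bias is no longer negligible relative to small group effects.
- `analytic_profile` requires an irreducible chain; reducible inputs
  surface as eigen-solver ambiguity rather than a dedicated error.
- The spectral estimator assumes the tachogram is interpolable — dense
  gap-boundary flags shrink the longest valid stretch and below 5 minutes
  the frequency indices are refused.
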