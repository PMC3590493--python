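# Methods

## The data model

A CIT session produces, per participant, one temperature trajectory per
sub-question: 10 s of the per-frame maximum temperature inside a
periorbital area of interest, at 30 Hz (300 samples). Participants
belong to one of two conditions (guilty / innocent); questions are
relevant (RE) or irrelevant (IR). The working assumption of the
functional approach is that each trajectory is a smooth underlying
function observed with measurement noise, so adjacent samples carry
overlapping, not independent, information.

## Synthetic-session generator

Real recordings of this kind are not publicly deposited, so the
generator is a first-class module, not a test fixture. Each trajectory

    temp(t) = b_p + d_q · t/T + Δ_{c,r} · g(t) + ε_smooth(t) + ε_sensor(t),

quantized to the camera step, with

- **b_p** — one baseline per participant, N(35.83, 0.59²) °C for guilty
  and N(36.03, 0.78²) for innocent, reused across that participant's 15
  questions;
- **d_q** — a per-question linear drift slope, N(0, 0.05²) °C over the
  window;
- **g(t)** — a fixed smooth unit-peak onset, sin²(π·min(t, 5)/10): zero
  at stimulus onset, plateau at 1 from 5 s. Any smooth monotone-onset
  template would serve; this one is differentiable and bounded, and its
  time-to-peak (5 s) is a free choice since only the curves' magnitudes,
  not their time courses, are constrained by the emulated study;
- **Δ_{c,r}** — the cell elevation, composed from three amplitudes in
  sum-to-zero terms: Δ = (a·s_c + b·s_r + c·s_c·s_r)/2 with signs
  s_guilty = s_RE = +1. The amplitudes a, b, c are *factor-level
  differences* (defaults 0.55, 0.33, 0.90 °C), so e.g. an
  interaction-only design gives GC-RE − GC-IR = c·g(t) exactly. The
  FANOVA ground truth is therefore α(t) = a·g(t)/2, etc., available from
  `thermocit.generate.true_effects`;
- **ε_smooth** — stationary AR(1) on the sample grid, correlation 0.95
  per 30 Hz step, marginal SD 0.15 °C by default: a cheap stand-in for
  smooth physiological variation;
- **ε_sensor** — white noise, SD 0.02 °C, plus quantization to the
  camera's 0.08 °C heat resolution.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: participant-level variation in *response
magnitude* (every guilty participant warms by exactly the same Δ·g, so
scalar paired-*t* values are enormously larger than any real study's),
head motion and tracking loss, ambient drift, habituation across the 15
questions, and within-participant correlation beyond the shared
baseline. The within-window noise level and autocorrelation are
plausible choices, not study-derived values.

The frame renderer (`generate_frames`) exists to exercise the AOI
extraction: each frame carries the trajectory value in a single in-mask
hotspot pixel, a cool background, and a cold "metallic fiducial" pixel
outside the AOI, so in-mask maximum extraction round-trips exactly.

## Preprocessing

Windows are taken as delivered (sample 0 = end of the question's last
word); decimation keeps phase 0 (indices 0, k, 2k, …); runs of at most 3
consecutive missing frames are linearly interpolated and longer gaps
invalidate the sample. FTCV = mean over a relevance class's windows of
the window-mean temperature, minus the participant's baseline mean.
Baseline correction subtracts the participant's measured baseline from
every sample of every window; the functional stages (FANOVA and
discriminant) operate on corrected functions, which removes the
between-participant baseline variance that would otherwise dominate
their error terms.

## Scalar inference

Unbiased (n−1) variance estimators throughout. The two-sample baseline
comparison uses the pooled (not Welch) statistic with n₁+n₂−2 df.
Directional paired tests are one-sided Student *t*; the Bonferroni
multiplier is m = 2, the number of directional paired tests run (one per
condition). Shapiro–Wilk is delegated to scipy and cross-checked in the
tests against R's implementation on a fixed vector.

## Roughness-penalty smoothing

Cubic B-splines (order 4) on a clamped uniform knot vector with one knot
per observation point (n_basis = n + 2), the saturated default of the
penalized-spline tradition; λ multiplies ∫(x″)² with time in seconds,
default λ = 10. The penalty and Gram matrices are assembled by
per-interval Gauss–Legendre quadrature with enough nodes to be exact for
the piecewise-polynomial integrands.

Numerical choice worth noting: the penalized normal equations
(ΦᵀΦ + λR)c = Φᵀy lose accuracy for λ ≳ 10⁹ because R's two null
eigenvalues (the constant/linear span) are only zero to ~1e−14 and get
amplified by λ. The solver therefore works with the augmented
least-squares system [Φ; √λ·L]c ≈ [y; 0], L the eigen square root of R
with numerically-null eigenvalues clipped to exact zeros. This is
algebraically the same minimizer and reproduces the λ→∞ ordinary-least-
squares-line limit to ~1e−8. A rank-deficient augmented system raises a
degenerate-input error rather than silently returning a minimum-norm
solution.

## Functional ANOVA

Per-observation least squares at each grid point with ±1 sum-to-zero
coding and the full interaction (saturated) model. Saturation means the
fitted cell means equal the observed cell means even with unbalanced
cells (18 vs 12 participants, 3 vs 12 questions), and the effect
functions are the unweighted cell-mean decomposition; recovery against
the generator's truth is then exact on noiseless data. The FANOVA runs
on the decimated 60-point grid — the decimation exists purely to keep
this stage small — while smoothing is applied per trajectory before
fitting.

Confidence bands are pointwise *t* intervals: estimate ±
t_{N−4,(1+level)/2}·s(t)·√[(XᵀX)⁻¹]_jj with s²(t) the pointwise residual
variance. Functions are treated as independent observations — the
remaining within-participant correlation after baseline correction
(drift, shared response quirks) is ignored, so on real data these bands
would be anticonservative. No multiplicity adjustment across time
points.

## Penalized functional discriminant

In basis coordinates with Gram matrix G and coefficient rows c_i, scores
are ∫w·x = w_cᵀGc_x (exact, no Riemann sums). The criterion maximizes
wᵀBw / wᵀ(W + ρR)w with B the between-class scatter and W the pooled
within-class *covariance* (scatter/(n−2)) of the Gc rows. Penalizing the
covariance rather than the raw scatter is the standard penalized-
discriminant normalization and fixes the meaning of ρ independently of
sample size. For two classes B has rank one, so the leading generalized
eigenvector is computed in closed form as (W + ρR)⁻¹G(m₁ − m₂); the test
suite verifies the equivalence against an explicit generalized
eigensolver. The threshold is the midpoint of the projected class means
(equal-prior rule, chosen because the class imbalance is modest and no
prior information is available); the sign convention makes the guilty
class project higher.

The discriminant consumes the **undecimated** 300-point smoothed
functions: decimation was a FANOVA-only economy, and with ~302 basis
functions against 90 observations the within-class covariance is
singular, which is exactly the regime where the roughness penalty ρ has
work to do. ρ is selected by leave-one-*function*-out cross-validation
(classification error; ties toward larger ρ, preferring the smoother
weight function), implemented with rank-one downdates of the class sums
so each fold costs one Cholesky factorization. Leaving out a function
rather than a participant ignores the (weak, post-correction)
within-participant dependence; with strong participant-level response
heterogeneity a participant-level fold would be the honest choice.
Classification rates are reported for the training set alongside the
clearly-labelled LOOCV error, since published rates of this kind are
typically training-set numbers.

One behaviour worth knowing: on *signal-free* data (labels shuffled),
the LOOCV error curve is nearly flat in ρ and, if anything, slightly
favors small ρ — an adaptive direction inflates its apparent class-mean
margin and thereby masks the leave-one-out mean-shift penalty that the
near-fixed smooth-limit direction suffers in full. Heavy smoothing is
systematically selected when there is a *weak smooth* signal, not when
there is none; see the test suite's no-signal selection check, which
documents the observed selection frequencies.

## Sizes and tolerances

Exact identities (decomposition, round trips, quadrature) are asserted
at 1e−6 to 1e−12. Stochastic checks are seeded: FANOVA effect-function
RMSE < 0.05 °C at the full design size with 0.1 °C noise; pointwise-band
coverage 95% ± 2% over 1,000 replicates of a reduced 8+8-participant,
6-question design at 6 Hz (reduced so the replication loop stays cheap;
coverage is a per-point property and does not depend on the grid size);
null rejection of the one-sided paired *t* within 3 binomial SEs over
10,000 replicates; discriminant checks on the full 90-function RE set.

## Known limitations

- The generator's fixed response magnitude makes every scalar and
  classification result optimistic relative to real data; it is designed
  for estimator verification, not power analysis.
- Confidence bands and LOOCV both assume independent functions.
- No automatic λ selection (λ is a config value); no AOI tracking — the
  mask is an input; no multi-class discriminant.
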