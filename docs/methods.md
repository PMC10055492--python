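# Methods

## Problem

`kinpost` studies amortized Bayesian inference for tracer kinetic modelling
in dynamic brain PET. The unknown is the kinetic-parameter triple
x = (DVR, k2, R1) of the simplified reference tissue model (SRTM); the
measurement y is a 54-frame time-activity curve (TAC) in a target region.
Given a prior p(x) and a noisy y, the object of interest is the posterior
p(x | y). Two routes to it are implemented and compared:

* a random-walk Metropolis–Hastings (MH) sampler — asymptotically unbiased,
  but run per measurement;
* three conditional variational auto-encoders (CVAEs) trained once on
  simulated (x, y) pairs, which then emit posterior draws for any y in
  milliseconds.

## Forward model

SRTM relates the target-region activity concentration C_T(t) to a
reference-region curve C_R(t):

    dC_T/dt = R1 dC_R/dt + k2 C_R − (k2/DVR) C_T,

with closed form

    C_T = R1 C_R + (k2 − R1 k2/DVR) · (C_R ⊗ e^{−(k2/DVR) t}).

The convolution is evaluated on a uniform 1-s grid by an exponentially
weighted trapezoidal recursion (algebraically identical to trapezoidal
quadrature of the convolution integral, O(n) via a linear filter); the
shortest frame is 10 s, and the 1-s grid keeps quadrature error well below
0.1 % (verified against adaptive ODE integration in the test suite). k2 is
carried in min⁻¹ — the field's unit — and converted to s⁻¹ exactly once at
the forward-model boundary.

The measurement is the vector of frame integrals y_n = ∫ C_T dt over the
54-frame schedule 6×10 s, 8×15 s, 6×30 s, 8×60 s, 8×120 s, 18×300 s
(total T = 7200 s), plus independent Gaussian noise

    ε_n ~ N(0, (σ · (Δt_n/T)^p)²),  p = 0.5 by default,

so the noise standard deviation grows with the square root of the frame's
share of scan time, consistent with counting statistics on frame integrals.
The exponent p is a config knob because the precise weighting is a modelling
choice; σ is drawn once per TAC from 10⁻⁴·Gamma(1, 1) and stored with it.

### Reference curve and activity units

C_R(t) is a fixed parametric curve: a gamma-variate bolus
A·(t/τ)·exp(1 − t/τ) plus a slow washout term
B·(e^{−t/τ_w} − e^{−t/τ_r}), with τ = τ_r = 90 s, τ_w = 4000 s. It
vanishes at injection, peaks inside the first five minutes, and washes out
monotonically — the standard shape for a region without specific binding.

The activity amplitude (A = 0.2, B = 0.4 in arbitrary activity units) is a
free calibration: the noise scale σ ~ 10⁻⁴ is absolute, so the amplitude
fixes the signal-to-noise regime of the whole study. It was calibrated once
against the MH convergence requirement below. Because the SRTM likelihood
ties DVR and k2 along a ridge (posterior correlation ≈ −0.999), a
diagonal-proposal random walk mixes with an autocorrelation time of order
10³; the early/late segment-mean convergence gap of a 60,000-iteration chain
is then of the order of the marginal DVR posterior width. The amplitude is
set so that this gap stays below 10⁻³ with a comfortable margin across noise
realizations — `scripts/acceptance.py` recomputes the gap for any seed —
which makes the default-TAC posterior sharply identified (DVR width ~10⁻⁴).
The flip side, discussed under Limitations, is that posteriors this tight
are much harder for a small amortized network to match in width than the
broad posteriors a lower-amplitude regime would produce.

### Priors, training data, test set

Baseline prior (setting 1): DVR ~ N(1.0, sd 1.0), k2 ~ N(0.0006 min⁻¹,
sd 0.01 min⁻¹), R1 ~ N(0.74, sd 1.0). The second arguments are treated as
standard deviations — they are printed with min⁻¹ units, which a variance
would not carry. Setting 2 scales the means by 1.2, setting 3 the variances
by 1.2 (so sds by √1.2), setting 4 both. All priors are rejection-truncated
to DVR > 0, k2 ≥ 0, R1 > 0: the forward model divides by DVR and negative
rates are unphysical. The truncation constant is parameter-independent, so
MH ratios are unaffected.

Training data are 10,000 prior draws (2,000 in the scaled-down preset) with
one σ and one noise realization each. The test set keeps prior draws with
|x_i − loc_i|/loc_i < α for all three components (α = 0.26), collected until
M = 200 (desk: 20) points are found; this concentrates test cases around the
prior location while leaving the training distribution untouched.

## MH-MCMC reference sampler

Random-walk MH with a symmetric Gaussian proposal and diagonal covariance;
60,000 iterations, the first 15,000 discarded, 45,000 retained. The
posterior is evaluated as Gaussian log-likelihood (per-frame variances from
the noise model, with the σ realized at simulation time treated as known)
plus the truncated-Gaussian log-prior; −∞ outside the support.

Numerical choices:

* **Initialization** — a deterministic MAP point (Nelder–Mead from the prior
  location). Test parameters sit up to 26 % from the prior location while
  posterior widths are ~10⁻⁴ relative, so a random walk started at the prior
  location would spend far more than the burn-in traversing to the mode;
  the MAP start is equally reproducible and removes that transient.
* **Proposal scales** — initialized from the Laplace approximation at the
  mode (2.38/√3 × marginal sds from the inverse Hessian), then a pilot phase
  adapts a global factor by multiplicative stochastic-approximation updates
  until the acceptance rate lies in [0.2, 0.5] (centered on the classic
  0.23–0.44 range for low-dimensional random walks), with one per-parameter
  shape re-estimation from in-band pilot draws. Scales are frozen before any
  retained draw, so the retained chain has the exact stationary law. The
  per-parameter parameterization matters: k2 lives three orders of magnitude
  below DVR and R1.
* **Convergence check** — per parameter, |mean of the first 10 % − mean of
  the last 50 %| of post-burn-in samples, passing below 0.001.

The sampler itself is validated on analytic targets (1-D standard normal;
conjugate linear-Gaussian posterior; binned-occupancy χ² test) before being
trusted on SRTM posteriors.

## CVAE posterior estimators

All three variants share a latent code z of dimension K = 10 and the same
encoder/decoder skeletons: encoder φ([x, y]) with four fully connected
ReLU layers (128, 100, 50, 20) and two linear K-node heads for the mean and
log-variance of z; decoder θ([y, z]) with layers (128, 100, 50, 3), ReLU on
hidden layers, linear output. Per training pair, with z = μ + σ⊙ε (one
Monte-Carlo draw of ε per example per step):

| variant | loss | inference path |
|---|---|---|
| dual-encoder | ½‖x−x̃‖² + β·KL(φ(x,y) ‖ φ′(y)) | z from φ′(y*), x̃ = θ(y*, z) |
| dual-decoder | ½‖x−x̃‖² + β·KL(φ(x,y) ‖ N(0,I)) + λ·½‖y−θ′(z)‖² | z ~ N(0,I), x̃ = θ(y*, z) |
| vanilla | ½‖x−x̃‖² + β·KL(φ(x,y) ‖ N(0,I)) | z ~ N(0,I), x̃ = θ(y*, z) |

φ′ mirrors φ (unshared weights); θ′ has layers (16, 16, 32, 54). The
vanilla variant is the structural restriction of both dual variants (the
test suite asserts this on the loss-graph structure). β = λ = 1 by default.

Training: minibatch SGD with momentum 0.9, learning rate 10⁻⁴, batch size
64, a fixed 200-epoch budget (desk: 50), no early stopping; a 10 % holdout
loss is logged for diagnostics only. The networks are small enough that the
whole forward/backward pass is hand-written on numpy arrays; every analytic
gradient (including the reparameterization and both KL terms) is pinned by
finite-difference checks in the test suite.

Numerical choices that matter:

* **Standardization** — x (per parameter) and y (per frame) are z-scored
  with training-set statistics; draws are de-standardized before evaluation.
  Without this, k2 (~6×10⁻⁴) would contribute ~10⁻⁷ of the reconstruction
  loss and could not be learned. This is the single most consequential
  choice in the training setup.
* **Log-variance heads** — initialized near zero (weights ×0.01) and clamped
  to ±8. The KL terms contain exp(±log σ²) factors whose gradients diverge
  as σ → 0; without the clamp the dual-encoder loss blows up within a few
  SGD steps.
* **Initialization** — He (Kaiming) normal, matching the ReLU hidden units.

## Evaluation metrics

Per test TAC and per parameter marginal, both posteriors are summarized by a
Gaussian fitted by least squares to the normalized histogram (√n bins capped
at 200 over the 0.1–99.9 % range); sample moments are the recorded fallback
if the fit degenerates. Metrics across the test set:

* δ̄μ, δ̄σ — mean over cases of |μ^MCMC − μ^DL|/μ^MCMC (and likewise for σ),
  reported in percent; signed per-case values are retained so bias direction
  can be inspected.
* D̄ — mean over cases of the histogram estimate of KL(p^MCMC ‖ p^DL) per
  marginal: shared bins over the pooled 0.1–99.9 % range, √n bins capped at
  200, 0.5 pseudo-counts per bin. The smoothing keeps the estimate finite
  when supports barely overlap (it then behaves like a negative log-density
  of the reference mass under the amortized posterior, a meaningful score).
  Self-KL bias of the estimator is below 0.01 at 10⁵ draws, and it tracks
  closed-form Gaussian KLs within 5 % for true KL in [0.05, 1.0] (both
  verified in the suite).

Experiment drivers reproduce the study designs: per-setting variant tables;
β/λ sweeps over [0.6, 1.8] with three training seeds per point (error bars =
across-seed sd); training-size sweeps (error bars = across-test-case sd);
and a data-shift sweep generating test TACs at DVR* with k2, R1 at prior
locations, scored against fresh MCMC references, with the coverage threshold
1 + FWHM(N(1,1)) ≈ 3.35 recorded in the output.

## Scaled-down preset and problem sizes

The `desk` preset — 2,000 training pairs, 50 epochs, M = 20 test TACs,
20,000/5,000 MCMC iterations, 5,000 posterior draws — preserves the
qualitative comparisons (variant orderings, sweep trends) at roughly
one-hundredth the computation of the study-scale preset, and is what the
test suite exercises end to end. MCMC references for a given seeded test set
are memoized within a process, since every sweep point scores against the
same reference posteriors.

## What the generator emulates, and limits of what passing tests show

The simulator emulates region-level dynamic-PET kinetics with a fixed,
noise-free reference-region input and additive Gaussian frame noise. It does
not emulate image reconstruction, scanner geometry, attenuation or scatter,
reference-region noise, inter-subject input-function variability, or the
heavy-tailed, correlated noise of real TACs. Results therefore speak to the
method's behaviour under a correctly specified forward model, not to
real-tracer transfer.

Known limitations:

* In the calibrated high-signal regime, MCMC posterior widths (~10⁻⁴
  relative) are far below what these small networks learn to produce at
  scaled-down training budgets, so the absolute width-agreement metrics
  (δ̄σ, and consequently the absolute size of D̄) are dominated by the
  width mismatch; variant *orderings* remain informative, absolute values
  are not comparable across regimes.
* The sampler inherits the diagonal-proposal design; with the DVR–k2 ridge
  this costs ~10³ in effective sample size. The Laplace-shaped proposal and
  MAP initialization mitigate but cannot remove this.
* The σ asymmetry: MCMC receives the σ realized at simulation time, while
  the CVAEs implicitly marginalize over the σ distribution seen in training.
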