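# kinpost

Posterior estimation of SRTM kinetic parameters from dynamic-PET
time-activity curves: an asymptotically unbiased MCMC reference sampler and
amortized conditional-VAE estimators, with the machinery to compare them.

## The problem

In dynamic brain PET with a reference-region model, the quantity of interest
is the kinetic-parameter triple **x** = (DVR, k2, R1) of the simplified
reference tissue model (SRTM), inferred from a measured time-activity curve
(TAC) **y** — here 54 frame integrals over a two-hour acquisition. Point
estimates alone hide the uncertainty that matters for diagnosis and trials;
the Bayesian object is the full posterior p(**x** | **y**).

`kinpost` implements, on fully synthetic data:

* an **SRTM simulator** — reference-region input curve, target-region
  kinetics via

  C_T = R1·C_R + (k2 − R1·k2/DVR)·(C_R ⊗ e^{−(k2/DVR)t}),

  frame integration on the 54-frame schedule, frame-weighted Gaussian noise
  with per-TAC scale σ ~ 10⁻⁴·Gamma(1,1), and truncated-Gaussian priors
  over (DVR, k2, R1) in four settings;
* a **random-walk Metropolis–Hastings sampler** (60,000 iterations, 15,000
  burn-in, diagonal proposal, early/late segment-mean convergence check) as
  the gold-standard posterior;
* three **conditional-VAE posterior estimators** — dual-encoder,
  dual-decoder, and vanilla — trained on simulated (x, y) pairs so that a
  trained decoder turns latent draws into posterior draws for any new TAC
  in milliseconds;
* **evaluation metrics** comparing amortized posteriors to MCMC per
  parameter: average relative differences of Gaussian-fitted means and
  standard deviations (δ̄μ, δ̄σ, in %) and an average histogram KL
  divergence D̄, plus drivers for hyperparameter, training-size and
  data-shift sweeps.

The networks are small MLPs trained by SGD with momentum; the forward and
backward passes are written directly on numpy arrays and validated by
finite-difference gradient checks. See `docs/methods.md` for the model,
all numerical choices, and known limitations.

## Worked example

```python
import numpy as np
from kinpost import (KineticParams, MCMCConfig, TrainConfig,
                     build_frame_schedule, forward_tac, make_dataset,
                     make_prior, make_reference_curve, run_mh,
                     sample_posterior, train, convergence_check)
from kinpost.simulator import add_noise, sample_noise_sigma

schedule = build_frame_schedule()
ref = make_reference_curve()
prior = make_prior(1)

# one noisy measurement at the default parameter point
rng = np.random.default_rng(5)
truth = KineticParams(dvr=1.0, k2_per_min=0.0006, r1=0.74)
sigma = sample_noise_sigma(rng)
tac = add_noise(forward_tac(truth, ref, schedule), sigma, rng)

# reference posterior by MH-MCMC (60,000 iterations, 15,000 burn-in)
mcmc = run_mh(tac, sigma, prior, MCMCConfig(), np.random.default_rng(6))
gaps = convergence_check(mcmc.provenance["full_chain"], 15_000).gaps
print(f"MCMC acceptance {mcmc.acceptance_rate:.2f}, "
      f"max convergence gap {gaps.max():.1e}")
print("MCMC mean", np.round(mcmc.samples.mean(0), 5))

# amortized posterior from a CVAE trained on 2,000 simulated pairs
data = make_dataset(prior, 2000, np.random.default_rng(7))
model, _ = train("dual_encoder", data, TrainConfig(epochs=50, seed=0))
cvae = sample_posterior(model, tac, n_draws=45_000,
                        rng=np.random.default_rng(8))
print("CVAE mean", np.round(cvae.samples.mean(0), 5))
```

prints

```
MCMC acceptance 0.44, max convergence gap 4.1e-05
MCMC mean [1.00006e+00 6.00000e-04 7.40000e-01]
CVAE mean [1.0441  0.00653 0.74315]
```

The chain passes its convergence check (gap far below the 0.001 threshold)
and its posterior mean recovers the generating parameters; at this
high-signal calibration the MCMC posterior is extremely sharp. The
scaled-down CVAE lands within ~4 % on DVR and recovers R1 well, while its
k2 marginal stays close to the (truncated) prior — at 2,000 training pairs
and 50 epochs the network has not yet extracted the subtle k2 signature
from the TAC, which is exactly the kind of gap the δ̄μ/δ̄σ/D̄ metrics are
designed to expose against the MCMC reference.

## Command line

Every step is also a CLI subcommand writing plain-text artifacts (TSV
tables, JSON run manifests with seeds and content hashes):

```sh
kinpost simulate --setting 1 --n 100 --seed 7 --out tacs.tsv
kinpost mcmc --tac tacs.tsv --tac-id 0 --seed 7 --out posterior.tsv
kinpost train --variant dual-encoder --scale desk --seed 7 --out model.npz
kinpost infer --model model.npz --tac tacs.tsv --n-draws 45000 --out dl.tsv
kinpost evaluate --setting 1 --scale desk --out metrics.tsv
kinpost sweep --kind beta --scale desk --out beta_sweep.tsv
kinpost reproduce-tables --scale desk --out-dir results/
```

`--scale desk` selects a scaled-down preset (2,000 training pairs, 50
epochs, 20 test TACs, 20,000-iteration chains) that preserves the
qualitative comparisons at a fraction of the study-scale cost; YAML configs
(`--config`) override any default and are schema-validated.

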