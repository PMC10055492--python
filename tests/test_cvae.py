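"""Tests of the CVAE losses, gradients, training loop, and inference paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinpost.cvae import (
    VARIANTS,
    CvaeModel,
    CvaeSpec,
    LatentGaussian,
    TrainConfig,
    kl_pair,
    kl_to_standard,
    load_model,
    measurement_loss,
    reconstruction_loss,
    reparameterize,
    sample_posterior,
    save_model,
    total_loss,
    train,
)
from kinpost.simulator import make_dataset, make_prior


def _small_spec(variant):
    return CvaeSpec(variant=variant, latent_dim=4, x_dim=3, y_dim=6,
                    encoder_widths=(8, 5), decoder_widths=(7,),
                    aux_decoder_widths=(5,))


def _random_latent(rng, k=10):
    return LatentGaussian(mu=rng.normal(size=k),
                          logvar=rng.normal(scale=0.7, size=k))


class TestReparameterize:
    def test_zero_eps_returns_mean(self, rng):
        lat = _random_latent(rng)
        assert np.array_equal(reparameterize(lat, np.zeros(10)), lat.mu)

    def test_degenerate_variance_returns_mean(self, rng):
        lat = LatentGaussian(mu=rng.normal(size=10),
                             logvar=np.full(10, -1e3))
        z = reparameterize(lat, rng.normal(size=10))
        assert np.allclose(z, lat.mu)

    def test_sample_moments(self, rng):
        lat = _random_latent(rng, k=3)
        draws = np.array(
            [reparameterize(lat, e) for e in rng.normal(size=(100_000, 3))]
        )
        se_mean = lat.sigma / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(0) - lat.mu) < 4 * se_mean)
        se_std = lat.sigma / np.sqrt(2 * draws.shape[0])
        assert np.all(np.abs(draws.std(0) - lat.sigma) < 4 * se_std)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            reparameterize(_random_latent(rng), np.zeros(3))


class TestKlDivergences:
    def test_identical_pair_is_zero(self, rng):
        lat = _random_latent(rng)
        assert kl_pair(lat, lat) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_shift_spot_value(self):
        a = LatentGaussian(mu=np.array([1.0]), logvar=np.array([0.0]))
        b = LatentGaussian(mu=np.array([0.0]), logvar=np.array([0.0]))
        assert kl_pair(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_standard_kl_spot_values(self):
        std1 = LatentGaussian(mu=np.zeros(4), logvar=np.zeros(4))
        assert kl_to_standard(std1) == pytest.approx(0.0, abs=1e-12)
        lat = LatentGaussian(mu=np.array([2.0]), logvar=np.array([0.0]))
        assert kl_to_standard(lat) == pytest.approx(2.0, abs=1e-12)

    def test_standard_is_special_case_of_pair(self, rng):
        lat = _random_latent(rng)
        std = LatentGaussian.standard(10)
        assert kl_to_standard(lat) == pytest.approx(kl_pair(lat, std),
                                                    abs=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegativity(self, seed):
        r = np.random.default_rng(seed)
        a, b = _random_latent(r), _random_latent(r)
        assert kl_pair(a, b) >= 0.0
        assert kl_to_standard(a) >= 0.0

    def test_monte_carlo_oracle(self, rng):
        """kl_pair agrees with a sampled log-density-ratio estimate."""
        a, b = _random_latent(rng, 5), _random_latent(rng, 5)
        n = 200_000
        z = a.mu + a.sigma * rng.normal(size=(n, 5))
        log_ratio = (
            -0.5 * np.sum(((z - a.mu) / a.sigma) ** 2 + a.logvar, axis=1)
            + 0.5 * np.sum(((z - b.mu) / b.sigma) ** 2 + b.logvar, axis=1)
        )
        est, se = log_ratio.mean(), log_ratio.std() / np.sqrt(n)
        assert abs(kl_pair(a, b) - est) < 3 * se


class TestPointLosses:
    def test_zero_and_unit_cases(self):
        x = np.array([1.0, 2.0, 3.0])
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(x, x - np.array([1.0, 0, 0])) == 0.5
        y = np.zeros(54)
        assert measurement_loss(y, y) == 0.0

    def test_matches_arithmetic_oracle(self, rng):
        x, xh = rng.normal(size=3), rng.normal(size=3)
        assert reconstruction_loss(x, xh) == pytest.approx(
            0.5 * sum((a - b) ** 2 for a, b in zip(x, xh))
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros(3), np.zeros(4))


class TestTotalLoss:
    def test_zero_weights_leave_reconstruction_only(self, rng):
        m = CvaeModel(_small_spec("dual_decoder"), np.random.default_rng(0))
        xs, ys = rng.normal(size=(8, 3)), rng.normal(size=(8, 6))
        eps = rng.normal(size=(8, 4))
        full = m.loss_and_grad(xs, ys, eps, beta=0.0, lam=0.0,
                               compute_grad=False)
        assert full["total"] == pytest.approx(full["recon"])

    def test_vanilla_equals_dual_decoder_without_aux_terms(self, rng):
        """Same seed -> shared phi/theta weights; losses agree at lambda=0."""
        van = CvaeModel(_small_spec("vanilla"), np.random.default_rng(3))
        dd = CvaeModel(_small_spec("dual_decoder"), np.random.default_rng(3))
        xs, ys = rng.normal(size=(8, 3)), rng.normal(size=(8, 6))
        eps = rng.normal(size=(8, 4))
        loss_v = total_loss("vanilla", (xs, ys), van, eps=eps, beta=1.3)
        parts_d = dd.loss_and_grad(xs, ys, eps, beta=1.3, lam=1.0,
                                   compute_grad=False)
        assert loss_v == pytest.approx(parts_d["recon"] + 1.3 * parts_d["kl"])

    def test_variant_mismatch_rejected(self, rng):
        m = CvaeModel(_small_spec("vanilla"), np.random.default_rng(0))
        with pytest.raises(ValueError):
            total_loss("dual_encoder",
                       (rng.normal(size=(2, 3)), rng.normal(size=(2, 6))), m)

    def test_finite_on_random_model(self, rng):
        for variant in VARIANTS:
            m = CvaeModel(_small_spec(variant), np.random.default_rng(1))
            val = total_loss(
                variant, (rng.normal(size=(16, 3)), rng.normal(size=(16, 6))),
                m, rng=np.random.default_rng(2),
            )
            assert np.isfinite(val)


class TestLossGraphStructure:
    def test_vanilla_is_restriction_of_dual_encoder(self):
        de = CvaeModel(_small_spec("dual_encoder"), np.random.default_rng(0))
        van = CvaeModel(_small_spec("vanilla"), np.random.default_rng(0))
        reduced = tuple(
            (kind, p, "standard_normal" if q == "phi_prime(y)" else q)
            for kind, p, q in de.loss_graph()
        )
        assert reduced == van.loss_graph()

    def test_vanilla_is_dual_decoder_without_measurement_term(self):
        dd = CvaeModel(_small_spec("dual_decoder"), np.random.default_rng(0))
        van = CvaeModel(_small_spec("vanilla"), np.random.default_rng(0))
        stripped = tuple(t for t in dd.loss_graph() if t[0] != "meas")
        assert stripped == van.loss_graph()


class TestGradients:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_analytic_gradients_match_finite_differences(self, variant):
        rng = np.random.default_rng(0)
        m = CvaeModel(_small_spec(variant), np.random.default_rng(1))
        xs, ys = rng.normal(size=(5, 3)), rng.normal(size=(5, 6))
        eps = rng.normal(size=(5, 4))
        for g in m.grads:
            g[...] = 0.0
        m.loss_and_grad(xs, ys, eps, beta=0.7, lam=1.3)
        pick = np.random.default_rng(2)
        for p, g in zip(m.params, m.grads):
            for fi in pick.choice(p.size, size=min(4, p.size), replace=False):
                ii = np.unravel_index(fi, p.shape)
                h, orig = 1e-6, p[ii]
                p[ii] = orig + h
                lp = m.loss_and_grad(xs, ys, eps, 0.7, 1.3,
                                     compute_grad=False)["total"]
                p[ii] = orig - h
                lm = m.loss_and_grad(xs, ys, eps, 0.7, 1.3,
                                     compute_grad=False)["total"]
                p[ii] = orig
                fd = (lp - lm) / (2 * h)
                assert g[ii] == pytest.approx(fd, rel=1e-4, abs=1e-8)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_dataset(make_prior(1), 400, np.random.default_rng(21))


class TestTraining:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_loss_descends(self, variant, tiny_dataset):
        _, log = train(variant, tiny_dataset, TrainConfig(epochs=15, seed=0))
        assert log[-1]["total"] < log[0]["total"]

    def test_reproducible(self, tiny_dataset):
        m1, _ = train("vanilla", tiny_dataset, TrainConfig(epochs=3, seed=4))
        m2, _ = train("vanilla", tiny_dataset, TrainConfig(epochs=3, seed=4))
        for a, b in zip(m1.params, m2.params):
            assert np.array_equal(a, b)

    def test_nan_data_aborts_with_diagnostic(self, tiny_dataset):
        xs = tiny_dataset.params.copy()
        xs[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            train("vanilla", (xs, tiny_dataset.tacs),
                  TrainConfig(epochs=1, seed=0, val_fraction=0.0))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train("vanilla", (np.empty((0, 3)), np.empty((0, 54))))


@pytest.fixture(scope="module")
def trained(tiny_dataset):
    models = {}
    for variant in VARIANTS:
        models[variant], _ = train(
            variant, tiny_dataset, TrainConfig(epochs=10, seed=0)
        )
    return models


class TestPosteriorSampling:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_draw_count_and_determinism(self, variant, trained, tiny_dataset):
        y = tiny_dataset.tacs[0]
        a = sample_posterior(trained[variant], y, 2000,
                             np.random.default_rng(6))
        b = sample_posterior(trained[variant], y, 2000,
                             np.random.default_rng(6))
        assert a.n == 2000
        assert a.source == f"cvae-{variant}"
        assert np.array_equal(a.samples, b.samples)

    def test_untrained_model_rejected(self, rng):
        m = CvaeModel(_small_spec("vanilla"), np.random.default_rng(0))
        with pytest.raises(RuntimeError):
            m.posterior_draws(np.zeros(6), 10, rng)

    def test_checkpoint_roundtrip(self, trained, tiny_dataset, tmp_path):
        path = str(tmp_path / "model.npz")
        save_model(trained["dual_encoder"], path)
        loaded = load_model(path)
        y = tiny_dataset.tacs[3]
        a = sample_posterior(trained["dual_encoder"], y, 500,
                             np.random.default_rng(8))
        b = sample_posterior(loaded, y, 500, np.random.default_rng(8))
        assert np.array_equal(a.samples, b.samples)
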