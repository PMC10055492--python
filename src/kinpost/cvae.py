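"""Conditional-VAE posterior estimators for SRTM kinetic parameters.

Three amortized estimators of p(x | y) are trained on simulated pairs
(x = kinetic parameters, y = noisy TAC), all built from the same blocks:

* ``dual_encoder`` — encoder phi([x, y]) -> z, decoder theta([y, z]) -> x,
  plus a second encoder phi'(y) -> z.  Training matches phi to phi' through
  a Gaussian KL term; inference draws z from phi'(y*) and decodes.
* ``dual_decoder`` — encoder phi([x, y]) -> z, decoder theta([y, z]) -> x,
  plus a second decoder theta'(z) -> y.  Training pulls phi(z | x, y) toward
  the standard normal and asks z alone to reconstruct y; inference draws
  z ~ N(0, I) and decodes.
* ``vanilla`` — the conventional conditional VAE: encoder phi([x, y]),
  decoder theta([y, z]), KL to the standard normal; inference draws
  z ~ N(0, I).  It is the structural restriction of both dual variants.

Losses per training pair (beta, lambda are weights, default 1):

    dual_encoder:  1/2 ||x - x~||^2 + beta * KL(N(mu, s^2) || N(mu', s'^2))
    dual_decoder:  1/2 ||x - x~||^2 + beta * KL(N(mu, s^2) || N(0, I))
                                    + lambda * 1/2 ||y - y~||^2
    vanilla:       1/2 ||x - x~||^2 + beta * KL(N(mu, s^2) || N(0, I))

with z = mu + s (.) eps the reparameterized latent draw (K = 10).

Both x (per parameter) and y (per frame) are z-scored with training-set
statistics before entering any network; posterior draws are mapped back to
native units.  Without this the k2 component (~6e-4 min^-1) would contribute
~1e-7 of the reconstruction loss and could not be learned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .mcmc import PosteriorSamples
from .nn import MLP, Linear, SGDMomentum
from .simulator import Dataset, Tac

__all__ = [
    "VARIANTS",
    "LatentGaussian",
    "CvaeSpec",
    "TrainConfig",
    "Standardizer",
    "CvaeModel",
    "reparameterize",
    "kl_pair",
    "kl_to_standard",
    "reconstruction_loss",
    "measurement_loss",
    "total_loss",
    "train",
    "sample_posterior",
    "save_model",
    "load_model",
]

VARIANTS = ("dual_encoder", "dual_decoder", "vanilla")


@dataclass(frozen=True)
class LatentGaussian:
    """Diagonal Gaussian over the latent code: mean and log-variance."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        lv = np.asarray(self.logvar, dtype=float)
        if mu.shape != lv.shape:
            raise ValueError("mu and logvar must have the same shape")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
            raise ValueError("latent parameters must be finite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "logvar", lv)

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.logvar)

    @classmethod
    def standard(cls, k: int) -> "LatentGaussian":
        return cls(mu=np.zeros(k), logvar=np.zeros(k))


@dataclass(frozen=True)
class CvaeSpec:
    """Architecture hyperparameters shared by the three variants."""

    variant: str = "dual_encoder"
    latent_dim: int = 10
    x_dim: int = 3
    y_dim: int = 54
    encoder_widths: tuple[int, ...] = (128, 100, 50, 20)
    decoder_widths: tuple[int, ...] = (128, 100, 50)
    aux_decoder_widths: tuple[int, ...] = (16, 16, 32)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: SGD with momentum, fixed epoch budget."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 64
    beta: float = 1.0
    lam: float = 1.0
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.lam <= 0:
            raise ValueError("beta and lambda must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class Standardizer:
    """Per-feature z-scoring statistics computed from the training set only."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    @classmethod
    def fit(cls, xs: np.ndarray, ys: np.ndarray) -> "Standardizer":
        def _std(a: np.ndarray) -> np.ndarray:
            s = a.std(axis=0)
            return np.where(s > 0, s, 1.0)

        return cls(xs.mean(axis=0), _std(xs), ys.mean(axis=0), _std(ys))

    def x_fwd(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x_mean) / self.x_std

    def x_inv(self, x: np.ndarray) -> np.ndarray:
        return x * self.x_std + self.x_mean

    def y_fwd(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_std


# ---------------------------------------------------------------------------
# Loss primitives (operate on 1-D vectors / LatentGaussian; used verbatim by
# the unit tests, and in batched form inside the training loop)
# ---------------------------------------------------------------------------

def reparameterize(lat: LatentGaussian, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma (.) eps with sigma = exp(logvar / 2)."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape[-1] != lat.mu.shape[-1]:
        raise ValueError("eps length does not match the latent dimension")
    return lat.mu + lat.sigma * eps


def kl_pair(lat_a: LatentGaussian, lat_b: LatentGaussian) -> float:
    """KL(N(mu, s^2) || N(mu', s'^2)) for diagonal Gaussians.

    Equals ``-1/2 sum_k [1 + log(s_k^2/s'_k^2) - s_k^2/s'_k^2
    - (mu_k - mu'_k)^2 / s'_k^2]``; non-negative, zero iff identical.
    """
    if lat_a.mu.shape != lat_b.mu.shape:
        raise ValueError("latent dimensions differ")
    dlv = lat_a.logvar - lat_b.logvar
    ratio = np.exp(dlv)
    dmu2 = (lat_a.mu - lat_b.mu) ** 2 * np.exp(-lat_b.logvar)
    return float(-0.5 * np.sum(1.0 + dlv - ratio - dmu2))


def kl_to_standard(lat: LatentGaussian) -> float:
    """KL(N(mu, s^2) || N(0, I)) = -1/2 sum_k (1 + log s_k^2 - s_k^2 - mu_k^2)."""
    return float(
        -0.5 * np.sum(1.0 + lat.logvar - np.exp(lat.logvar) - lat.mu**2)
    )


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Half squared Euclidean distance between parameter vectors."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("shape mismatch")
    return float(0.5 * np.sum((x - x_hat) ** 2))


def measurement_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Half squared Euclidean distance between measurement vectors."""
    return reconstruction_loss(y, y_hat)


class _Encoder:
    """Trunk MLP with ReLU throughout plus linear mean / log-variance heads.

    The log-variance head starts near zero (small-weight init) and its output
    is clamped to [-LOGVAR_CLAMP, LOGVAR_CLAMP]: the KL terms contain
    exp(+-logvar) factors whose gradients otherwise blow up as sigma -> 0.
    """

    LOGVAR_CLAMP = 8.0

    def __init__(self, n_in: int, widths: Sequence[int], k: int,
                 rng: np.random.Generator) -> None:
        self.trunk = MLP([n_in, *widths], rng, relu_last=True)
        self.mu_head = Linear(widths[-1], k, rng)
        self.logvar_head = Linear(widths[-1], k, rng)
        self.logvar_head.W *= 0.01
        self._clamp_mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward(x)
        lv = self.logvar_head.forward(h)
        c = self.LOGVAR_CLAMP
        self._clamp_mask = (lv > -c) & (lv < c)
        return self.mu_head.forward(h), np.clip(lv, -c, c)

    def backward(self, g_mu: np.ndarray, g_logvar: np.ndarray) -> np.ndarray:
        g_h = self.mu_head.backward(g_mu) + self.logvar_head.backward(
            g_logvar * self._clamp_mask
        )
        return self.trunk.backward(g_h)

    @property
    def params(self) -> list[np.ndarray]:
        return self.trunk.params + self.mu_head.params + self.logvar_head.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.trunk.grads + self.mu_head.grads + self.logvar_head.grads


class CvaeModel:
    """One CVAE variant: networks, loss/gradient evaluation, inference path."""

    def __init__(self, spec: CvaeSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        k, xd, yd = spec.latent_dim, spec.x_dim, spec.y_dim
        self.encoder = _Encoder(xd + yd, spec.encoder_widths, k, rng)
        self.decoder = MLP([yd + k, *spec.decoder_widths, xd], rng)
        self.aux_encoder: _Encoder | None = None
        self.aux_decoder: MLP | None = None
        if spec.variant == "dual_encoder":
            self.aux_encoder = _Encoder(yd, spec.encoder_widths, k, rng)
        elif spec.variant == "dual_decoder":
            self.aux_decoder = MLP([k, *spec.aux_decoder_widths, yd], rng)
        self.standardizer: Standardizer | None = None
        self.trained = False

    @property
    def variant(self) -> str:
        return self.spec.variant

    def _modules(self) -> list:
        mods = [self.encoder, self.decoder]
        if self.aux_encoder is not None:
            mods.append(self.aux_encoder)
        if self.aux_decoder is not None:
            mods.append(self.aux_decoder)
        return mods

    @property
    def params(self) -> list[np.ndarray]:
        return [p for m in self._modules() for p in m.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for m in self._modules() for g in m.grads]

    def loss_graph(self) -> tuple[tuple[str, str, str], ...]:
        """Symbolic structure of the training loss, for structural checks."""
        recon = ("recon", "x", "theta(y,z)")
        if self.variant == "dual_encoder":
            return (recon, ("kl", "phi(x,y)", "phi_prime(y)"))
        if self.variant == "dual_decoder":
            return (
                recon,
                ("kl", "phi(x,y)", "standard_normal"),
                ("meas", "y", "theta_prime(z)"),
            )
        return (recon, ("kl", "phi(x,y)", "standard_normal"))

    # -- training-time loss with analytic gradients -------------------------

    def loss_and_grad(
        self,
        xs: np.ndarray,
        ys: np.ndarray,
        eps: np.ndarray,
        beta: float = 1.0,
        lam: float = 1.0,
        compute_grad: bool = True,
    ) -> dict[str, float]:
        """Batch-mean loss; accumulates parameter gradients when asked.

        ``xs`` (B, 3) and ``ys`` (B, 54) must already be standardized; ``eps``
        is the (B, K) standard-normal draw for the reparameterization (one
        Monte-Carlo z per example).
        """
        b = xs.shape[0]
        mu, logvar = self.encoder.forward(np.concatenate([xs, ys], axis=1))
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * eps
        x_hat = self.decoder.forward(np.concatenate([ys, z], axis=1))
        recon = 0.5 * np.sum((xs - x_hat) ** 2) / b

        parts: dict[str, float] = {"recon": recon}
        if self.variant == "dual_encoder":
            assert self.aux_encoder is not None
            mu2, logvar2 = self.aux_encoder.forward(ys)
            dlv = logvar - logvar2
            ratio = np.exp(dlv)
            iv2 = np.exp(-logvar2)
            dmu = mu - mu2
            kl = -0.5 * np.sum(1.0 + dlv - ratio - dmu**2 * iv2) / b
        else:
            ev = np.exp(logvar)
            kl = -0.5 * np.sum(1.0 + logvar - ev - mu**2) / b
        parts["kl"] = kl
        total = recon + beta * kl

        meas = 0.0
        y_hat = None
        if self.variant == "dual_decoder":
            assert self.aux_decoder is not None
            y_hat = self.aux_decoder.forward(z)
            meas = 0.5 * np.sum((ys - y_hat) ** 2) / b
            parts["meas"] = meas
            total = total + lam * meas
        parts["total"] = total

        if not compute_grad:
            return parts

        g_xhat = (x_hat - xs) / b
        g_dec_in = self.decoder.backward(g_xhat)
        g_z = g_dec_in[:, self.spec.y_dim :]
        if y_hat is not None:
            g_yhat = lam * (y_hat - ys) / b
            g_z = g_z + self.aux_decoder.backward(g_yhat)

        if self.variant == "dual_encoder":
            g_mu = g_z + (beta / b) * dmu * iv2
            g_logvar = g_z * (0.5 * sigma * eps) - (beta / (2 * b)) * (1.0 - ratio)
            g_mu2 = -(beta / b) * dmu * iv2
            g_logvar2 = -(beta / (2 * b)) * (-1.0 + ratio + dmu**2 * iv2)
            self.aux_encoder.backward(g_mu2, g_logvar2)
        else:
            g_mu = g_z + (beta / b) * mu
            g_logvar = g_z * (0.5 * sigma * eps) - (beta / (2 * b)) * (1.0 - ev)
        self.encoder.backward(g_mu, g_logvar)
        return parts

    # -- inference path ------------------------------------------------------

    def posterior_draws(self, y: np.ndarray, n_draws: int,
                        rng: np.random.Generator) -> np.ndarray:
        """Draws from the learned posterior for one native-unit TAC vector."""
        if not self.trained or self.standardizer is None:
            raise RuntimeError("model has not been trained")
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        k = self.spec.latent_dim
        y_s = self.standardizer.y_fwd(np.asarray(y, dtype=float))
        eps = rng.normal(size=(n_draws, k))
        if self.variant == "dual_encoder":
            assert self.aux_encoder is not None
            mu2, logvar2 = self.aux_encoder.forward(y_s[None, :])
            z = mu2 + np.exp(0.5 * logvar2) * eps
        else:
            z = eps
        out = np.empty((n_draws, self.spec.x_dim))
        y_tile_max = 8192
        for start in range(0, n_draws, y_tile_max):
            zc = z[start : start + y_tile_max]
            yc = np.broadcast_to(y_s, (zc.shape[0], y_s.size))
            out[start : start + y_tile_max] = self.decoder.forward(
                np.concatenate([yc, zc], axis=1)
            )
        return self.standardizer.x_inv(out)


def total_loss(
    variant: str,
    batch: tuple[np.ndarray, np.ndarray],
    model: CvaeModel,
    eps: np.ndarray | None = None,
    beta: float = 1.0,
    lam: float = 1.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Batch-mean training loss of a model on one (xs, ys) standardized batch."""
    if model.variant != variant:
        raise ValueError(
            f"model variant {model.variant!r} does not match {variant!r}"
        )
    xs, ys = batch
    if eps is None:
        rng = rng or np.random.default_rng()
        eps = rng.normal(size=(xs.shape[0], model.spec.latent_dim))
    parts = model.loss_and_grad(xs, ys, eps, beta, lam, compute_grad=False)
    return parts["total"]


def train(
    variant: str,
    dataset: Dataset | tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
    spec: CvaeSpec | None = None,
) -> tuple[CvaeModel, list[dict]]:
    """Train one CVAE variant by minibatch SGD with momentum.

    Returns the trained model (with embedded standardization statistics) and
    a per-epoch log of loss components.  Training is fully determined by
    ``config.seed``.
    """
    if isinstance(dataset, Dataset):
        xs_raw, ys_raw = dataset.params, dataset.tacs
    else:
        xs_raw, ys_raw = dataset
    n = xs_raw.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if spec is None:
        spec = CvaeSpec(
            variant=variant, x_dim=xs_raw.shape[1], y_dim=ys_raw.shape[1]
        )
    elif spec.variant != variant:
        raise ValueError("spec.variant does not match requested variant")

    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.val_fraction * n)) if n >= 20 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    std = Standardizer.fit(xs_raw[train_idx], ys_raw[train_idx])
    xs = std.x_fwd(xs_raw[train_idx])
    ys = std.y_fwd(ys_raw[train_idx])
    xs_val = std.x_fwd(xs_raw[val_idx]) if n_val else None
    ys_val = std.y_fwd(ys_raw[val_idx]) if n_val else None

    model = CvaeModel(spec, rng)
    model.standardizer = std
    opt = SGDMomentum(model.params, model.grads, config.learning_rate,
                      config.momentum)
    k = spec.latent_dim
    n_train = xs.shape[0]
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            eps = rng.normal(size=(idx.size, k))
            opt.zero_grad()
            parts = model.loss_and_grad(
                xs[idx], ys[idx], eps, config.beta, config.lam
            )
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{parts}"
                )
            opt.step()
            for key, val in parts.items():
                sums[key] = sums.get(key, 0.0) + val
            n_batches += 1
        entry = {"epoch": epoch, **{k_: v / n_batches for k_, v in sums.items()}}
        if n_val:
            eps_val = rng.normal(size=(n_val, k))
            val_parts = model.loss_and_grad(
                xs_val, ys_val, eps_val, config.beta, config.lam,
                compute_grad=False,
            )
            entry["val_total"] = val_parts["total"]
        log.append(entry)
    model.trained = True
    return model, log


def sample_posterior(
    model: CvaeModel,
    y: Tac | np.ndarray,
    n_draws: int = 45_000,
    rng: np.random.Generator | None = None,
) -> PosteriorSamples:
    """Amortized posterior draws for one measured TAC, in native units."""
    rng = rng or np.random.default_rng()
    y_vec = y.values if isinstance(y, Tac) else np.asarray(y, dtype=float)
    draws = model.posterior_draws(y_vec, n_draws, rng)
    return PosteriorSamples(
        samples=draws,
        source=f"cvae-{model.variant}",
        provenance={"n_draws": n_draws},
    )


# ---------------------------------------------------------------------------
# Checkpoints: portable npz archives with an embedded JSON manifest
# ---------------------------------------------------------------------------

def save_model(model: CvaeModel, path: str, extra_meta: dict | None = None
               ) -> None:
    """Serialize parameters + manifest (variant, spec, standardization)."""
    if model.standardizer is None:
        raise ValueError("cannot save an untrained model")
    std = model.standardizer
    meta = {
        "variant": model.variant,
        "spec": asdict(model.spec),
        "trained": model.trained,
        **(extra_meta or {}),
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez(
        path,
        manifest=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        x_mean=std.x_mean, x_std=std.x_std,
        y_mean=std.y_mean, y_std=std.y_std,
        **arrays,
    )


def load_model(path: str) -> CvaeModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["manifest"].tobytes()).decode())
        spec_d = meta["spec"]
        for key in ("encoder_widths", "decoder_widths", "aux_decoder_widths"):
            spec_d[key] = tuple(spec_d[key])
        spec = CvaeSpec(**spec_d)
        model = CvaeModel(spec, np.random.default_rng(0))
        for i, p in enumerate(model.params):
            p[...] = data[f"param_{i}"]
        model.standardizer = Standardizer(
            data["x_mean"], data["x_std"], data["y_mean"], data["y_std"]
        )
        model.trained = bool(meta.get("trained", True))
    return model
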