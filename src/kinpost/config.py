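"""Declarative experiment configuration, seed streams, and run manifests.

A single YAML file (or nothing: every field has a default pinned to the
study-scale settings) describes an experiment: prior setting, noise model,
reference-curve shape, MCMC run lengths, network training settings, and
evaluation options.  Unknown keys are rejected so typos fail loudly.

A root seed spawns independent named random streams (simulation / mcmc /
train / infer), so changing one stage's seed does not perturb the others,
and a :class:`RunManifest` records everything needed to replay a run.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .evaluation import DESK_PRESET

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "SeedStreams",
    "load_config",
    "save_config",
]

_STREAMS = ("simulation", "mcmc", "train", "infer")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ReferenceCurveConfig(_Strict):
    grid_step_s: float = Field(1.0, gt=0)
    bolus_amplitude: float = Field(0.2, gt=0)
    bolus_peak_time_s: float = Field(90.0, gt=0)
    washout_amplitude: float = Field(0.4, ge=0)
    washout_time_s: float = Field(4000.0, gt=0)
    rise_time_s: float = Field(90.0, gt=0)

    def shape_params(self) -> dict[str, float]:
        d = self.model_dump()
        d.pop("grid_step_s")
        return d


class NoiseConfig(_Strict):
    sigma_scale: float = Field(1e-4, gt=0)
    duration_exponent: float = 0.5


class MCMCSettings(_Strict):
    n_iterations: int = Field(60_000, ge=2)
    n_burn_in: int = Field(15_000, ge=0)
    target_acceptance: tuple[float, float] = (0.2, 0.5)

    @model_validator(mode="after")
    def _check(self) -> "MCMCSettings":
        if self.n_burn_in >= self.n_iterations:
            raise ValueError("n_burn_in must be < n_iterations")
        return self


class TrainSettings(_Strict):
    learning_rate: float = Field(1e-4, gt=0)
    momentum: float = Field(0.9, ge=0, lt=1)
    epochs: int = Field(200, ge=1)
    batch_size: int = Field(64, ge=1)
    beta: float = Field(1.0, gt=0)
    lam: float = Field(1.0, gt=0)


class NetworkSettings(_Strict):
    latent_dim: int = Field(10, ge=1)
    encoder_widths: tuple[int, ...] = (128, 100, 50, 20)
    decoder_widths: tuple[int, ...] = (128, 100, 50)
    aux_decoder_widths: tuple[int, ...] = (16, 16, 32)


class EvalSettings(_Strict):
    m_test: int = Field(200, ge=1)
    alpha: float = Field(0.26, gt=0)
    n_posterior_draws: int = Field(45_000, ge=1)
    train_n: int = Field(10_000, ge=1)


class ExperimentConfig(_Strict):
    """Validated experiment description with study-scale defaults."""

    setting: Literal[1, 2, 3, 4] = 1
    scale: Literal["study", "desk"] = "study"
    seed: int = Field(0, ge=0, lt=2**31)
    reference_curve: ReferenceCurveConfig = ReferenceCurveConfig()
    noise: NoiseConfig = NoiseConfig()
    mcmc: MCMCSettings = MCMCSettings()
    training: TrainSettings = TrainSettings()
    network: NetworkSettings = NetworkSettings()
    evaluation: EvalSettings = EvalSettings()

    @model_validator(mode="after")
    def _apply_scale(self) -> "ExperimentConfig":
        if self.scale == "desk":
            unset_m = "mcmc" not in self.model_fields_set
            unset_t = "training" not in self.model_fields_set
            unset_e = "evaluation" not in self.model_fields_set
            if unset_m:
                object.__setattr__(
                    self, "mcmc",
                    MCMCSettings(
                        n_iterations=DESK_PRESET["mcmc_iterations"],
                        n_burn_in=DESK_PRESET["mcmc_burn_in"],
                    ),
                )
            if unset_t:
                object.__setattr__(
                    self, "training",
                    TrainSettings(epochs=DESK_PRESET["epochs"]),
                )
            if unset_e:
                object.__setattr__(
                    self, "evaluation",
                    EvalSettings(
                        m_test=DESK_PRESET["m_test"],
                        n_posterior_draws=DESK_PRESET["n_draws"],
                        train_n=DESK_PRESET["train_n"],
                    ),
                )
        return self


class SeedStreams:
    """Named, independent random streams spawned from one root seed."""

    def __init__(self, root_seed: int) -> None:
        self.root_seed = int(root_seed)

    def rng(self, name: str, *subkey: int) -> np.random.Generator:
        if name not in _STREAMS:
            raise KeyError(f"unknown stream {name!r}; choose from {_STREAMS}")
        idx = _STREAMS.index(name)
        return np.random.default_rng(
            np.random.SeedSequence(self.root_seed, spawn_key=(idx, *subkey))
        )

    def as_dict(self) -> dict[str, list[int]]:
        return {name: [self.root_seed, _STREAMS.index(name)]
                for name in _STREAMS}


class RunManifest:
    """Record of one CLI run: config, seeds, artifact hashes, timestamps."""

    def __init__(self, command: str, config: ExperimentConfig,
                 streams: SeedStreams) -> None:
        from . import __version__

        self.data = {
            "command": command,
            "software_version": __version__,
            "started_utc": datetime.datetime.now(
                datetime.timezone.utc
            ).isoformat(),
            "config": config.model_dump(),
            "seed_streams": streams.as_dict(),
            "artifacts": {},
        }

    def add_artifact(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["artifacts"][path.name] = digest

    def write(self, path: str | Path) -> None:
        self.data["finished_utc"] = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load and validate a YAML config; an empty/absent file means defaults."""
    if path is None:
        return ExperimentConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        return ExperimentConfig()
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False)
    )
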