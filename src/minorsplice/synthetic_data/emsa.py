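"""Saturation-binding curve simulation from the one-site model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..binding import BindingDataset, BindingObservation, predict_fraction_bound
from ..errors import InvalidArgumentError

__all__ = ["BindingConfig", "simulate_emsa", "DEFAULT_CONCENTRATIONS_UM"]

# Seven-point titration spanning the 0.25-25 uM protein range.
DEFAULT_CONCENTRATIONS_UM = (0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0)


@dataclass(frozen=True)
class BindingConfig:
    """Ground-truth parameters and noise model for one titration."""

    kd_true: float
    bmax_true: float = 1.0
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kd_true <= 0:
            raise InvalidArgumentError(f"kd_true must be > 0, got {self.kd_true}")
        if self.bmax_true <= 0:
            raise InvalidArgumentError(f"bmax_true must be > 0, got {self.bmax_true}")
        if any(c <= 0 for c in self.concentrations):
            raise InvalidArgumentError("all concentrations must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")


def simulate_emsa(config: BindingConfig) -> BindingDataset:
    """Draw fraction-bound observations from the one-site model.

    y = Bmax * x / (Kd + x) + eps with eps ~ Normal(0, noise_sd), clipped
    to [0, Bmax]; one observation per (concentration, replicate);
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    obs: list[BindingObservation] = []
    for rep in range(1, config.n_replicates + 1):
        for x in config.concentrations:
            y = predict_fraction_bound(x, config.kd_true, config.bmax_true)
            if config.noise_sd > 0:
                y += rng.normal(0.0, config.noise_sd)
            y = float(np.clip(y, 0.0, config.bmax_true))
            obs.append(BindingObservation(x, y, f"r{rep}"))
    return BindingDataset(observations=obs)
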