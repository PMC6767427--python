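"""Prior distributions for the co-divergence model, with the named presets
used in the gecko analyses.

All priors are positive-support distributions on the expected-substitutions
scale (the mutation rate is fixed at 1):

* divergence time tau ~ Exponential(mean), the base distribution of the
  Dirichlet process over events;
* population sizes theta1, theta2 ~ Gamma(shape, mean), default
  Gamma(shape=4, mean=0.004);
* ancestral-size multiplier ~ Gamma(shape, mean), default
  Gamma(shape=100, mean=1), relative to the mean of the descendant sizes;
* concentration alpha ~ Gamma(shape, scale) hyperprior, or a fixed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dpp import GammaPrior

__all__ = ["ExponentialPrior", "PriorSet", "TAU_PRESETS", "ALPHA_PRESETS", "default_priors"]


@dataclass(frozen=True)
class ExponentialPrior:
    mean: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("exponential prior mean must be positive")

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.exponential(self.mean, size=size)

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -math.inf
        return -math.log(self.mean) - x / self.mean


@dataclass(frozen=True)
class PriorSet:
    tau: ExponentialPrior = ExponentialPrior(mean=0.005)
    theta: GammaPrior = field(default_factory=lambda: GammaPrior.from_shape_mean(4.0, 0.004))
    root_multiplier: GammaPrior = field(default_factory=lambda: GammaPrior.from_shape_mean(100.0, 1.0))
    concentration: GammaPrior | float = field(default_factory=lambda: GammaPrior(1.1, 56.1))

    def fixed_alpha(self) -> float | None:
        return float(self.concentration) if isinstance(self.concentration, (int, float)) else None


# tau prior means: 0.005 for Cyrtodactylus, 0.0005 for Gekko, 0.05 diffuse
TAU_PRESETS = {
    "cyrtodactylus-default": ExponentialPrior(0.005),
    "gekko-default": ExponentialPrior(0.0005),
    "diffuse": ExponentialPrior(0.05),
}

ALPHA_PRESETS = {
    "independent-heavy": GammaPrior(1.1, 56.1),  # ~half prior mass on k = n
    "mean-five-events": GammaPrior(1.5, 3.13),  # prior mean of 5 events for n = 8
    "shared-heavy": GammaPrior(0.5, 1.31),  # ~half prior mass on k = 1
}


def default_priors(tau_preset: str = "cyrtodactylus-default",
                   alpha_preset: str = "independent-heavy") -> PriorSet:
    return PriorSet(tau=TAU_PRESETS[tau_preset], concentration=ALPHA_PRESETS[alpha_preset])
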