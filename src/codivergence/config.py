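"""Run configuration: one YAML file drives every subcommand.

Gamma priors on theta and the root multiplier are specified by (shape, mean)
and the concentration hyperprior by (shape, scale), matching how each is
conventionally reported; both forms use explicit keys so there is no
ambiguity.  Missing prior sections fall back to the defaults
(theta ~ Gamma(shape 4, mean 0.004), root ~ Gamma(shape 100, mean 1),
alpha ~ Gamma(1.1, 56.1)) and every applied default is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .data_io import PopulationMap
from .dpp import GammaPrior
from .mcmc import McmcSettings
from .priors import ALPHA_PRESETS, TAU_PRESETS, ExponentialPrior, PriorSet

__all__ = ["RunConfig", "ConfigError", "load_config"]

logger = logging.getLogger("codivergence")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonSpec:
    label: str
    path: Path | None
    population_map: PopulationMap


@dataclass(frozen=True)
class RunConfig:
    comparisons: tuple[ComparisonSpec, ...]
    priors: PriorSet
    mcmc: McmcSettings
    polyallelic_mode: str
    output_dir: Path

    def digest(self) -> str:
        payload = json.dumps(
            {
                "comparisons": [
                    [c.label, str(c.path), sorted(c.population_map.assignment.items())]
                    for c in self.comparisons
                ],
                "priors": repr(self.priors),
                "mcmc": repr(self.mcmc),
                "polyallelic_mode": self.polyallelic_mode,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_TOP_KEYS = {"comparisons", "priors", "mcmc", "polyallelic_mode", "output_dir"}
_PRIOR_KEYS = {"tau", "theta", "root_multiplier", "concentration"}


def _require_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_tau(spec: dict | None) -> ExponentialPrior:
    if spec is None:
        logger.info("tau prior defaulted to Exponential(mean=0.005)")
        return ExponentialPrior(0.005)
    _require_keys(spec, {"preset", "mean"}, "priors.tau")
    if "preset" in spec:
        try:
            return TAU_PRESETS[spec["preset"]]
        except KeyError:
            raise ConfigError(
                f"unknown tau preset {spec['preset']!r}; options: {sorted(TAU_PRESETS)}"
            ) from None
    mean = float(spec["mean"])
    if mean <= 0:
        raise ConfigError("priors.tau.mean must be positive")
    return ExponentialPrior(mean)


def _parse_gamma_shape_mean(spec: dict | None, name: str, default: tuple[float, float]) -> GammaPrior:
    if spec is None:
        logger.info("%s prior defaulted to Gamma(shape=%g, mean=%g)", name, *default)
        return GammaPrior.from_shape_mean(*default)
    _require_keys(spec, {"shape", "mean"}, f"priors.{name}")
    shape, mean = float(spec.get("shape", default[0])), float(spec.get("mean", default[1]))
    if shape <= 0 or mean <= 0:
        raise ConfigError(f"priors.{name}: shape and mean must be positive")
    return GammaPrior.from_shape_mean(shape, mean)


def _parse_concentration(spec: dict | None) -> GammaPrior | float:
    if spec is None:
        logger.info("concentration hyperprior defaulted to Gamma(shape=1.1, scale=56.1)")
        return GammaPrior(1.1, 56.1)
    _require_keys(spec, {"preset", "shape", "scale", "fixed"}, "priors.concentration")
    if "fixed" in spec:
        alpha = float(spec["fixed"])
        if alpha <= 0:
            raise ConfigError("fixed concentration must be positive")
        return alpha
    if "preset" in spec:
        try:
            return ALPHA_PRESETS[spec["preset"]]
        except KeyError:
            raise ConfigError(
                f"unknown concentration preset {spec['preset']!r}; options: "
                f"{sorted(ALPHA_PRESETS)}"
            ) from None
    try:
        return GammaPrior(float(spec["shape"]), float(spec["scale"]))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"priors.concentration: {exc}") from None


def _parse_comparison(spec: dict, base_dir: Path) -> ComparisonSpec:
    _require_keys(spec, {"label", "path", "populations"}, "comparisons[]")
    try:
        label = str(spec["label"])
        populations = spec["populations"]
    except KeyError as exc:
        raise ConfigError(f"comparison entry missing {exc}") from None
    if not isinstance(populations, dict) or len(populations) != 2:
        raise ConfigError(f"comparison {label!r}: exactly two populations required")
    assignment = {}
    for pop, seq_ids in populations.items():
        for sid in seq_ids:
            if sid in assignment:
                raise ConfigError(f"comparison {label!r}: sequence {sid!r} mapped twice")
            assignment[sid] = pop
    pop_map = PopulationMap(
        label=label, population_labels=tuple(populations), assignment=assignment
    )
    path = spec.get("path")
    return ComparisonSpec(
        label=label,
        path=None if path is None else (base_dir / path),
        population_map=pop_map,
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are
    rejected with field-level messages."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _require_keys(raw, _TOP_KEYS, str(path))
    if not raw.get("comparisons"):
        raise ConfigError("at least one comparison is required")
    base_dir = path.parent
    comparisons = tuple(_parse_comparison(c, base_dir) for c in raw["comparisons"])
    if len({c.label for c in comparisons}) != len(comparisons):
        raise ConfigError("comparison labels must be unique")

    priors_raw = raw.get("priors") or {}
    _require_keys(priors_raw, _PRIOR_KEYS, "priors")
    priors = PriorSet(
        tau=_parse_tau(priors_raw.get("tau")),
        theta=_parse_gamma_shape_mean(priors_raw.get("theta"), "theta", (4.0, 0.004)),
        root_multiplier=_parse_gamma_shape_mean(
            priors_raw.get("root_multiplier"), "root_multiplier", (100.0, 1.0)
        ),
        concentration=_parse_concentration(priors_raw.get("concentration")),
    )

    mcmc_raw = raw.get("mcmc") or {}
    _require_keys(
        mcmc_raw,
        {"generations", "sample_interval", "burn_in", "chains", "seed", "proposal_scale"},
        "mcmc",
    )
    try:
        mcmc = McmcSettings(
            generations=int(mcmc_raw.get("generations", 1000)),
            sample_interval=int(mcmc_raw.get("sample_interval", 1)),
            burn_in=int(mcmc_raw.get("burn_in", 101)),
            n_chains=int(mcmc_raw.get("chains", 2)),
            seed=int(mcmc_raw.get("seed", 0)),
            proposal_scale=float(mcmc_raw.get("proposal_scale", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"mcmc: {exc}") from None

    mode = raw.get("polyallelic_mode", "recode")
    if mode not in ("recode", "remove"):
        raise ConfigError(f"polyallelic_mode must be 'recode' or 'remove', got {mode!r}")
    out = base_dir / raw.get("output_dir", "codivergence-output")
    return RunConfig(
        comparisons=comparisons,
        priors=priors,
        mcmc=mcmc,
        polyallelic_mode=mode,
        output_dir=out,
    )
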