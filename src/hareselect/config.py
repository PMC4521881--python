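"""Run configuration.

One flat YAML mapping mirrors :class:`AnalysisConfig`; every analysis
parameter flows through it so a config file plus a seed fully determines a
run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import yaml

from .errors import ConfigError
from .vocab import DM_COMPONENTS

#: Gross-energy coefficients, kJ per g of each crude fraction. These are
#: generic combustion values for forage analysis, NOT taken from any specific
#: calibration study — override them in the config when a calibrated set is
#: available for your system.
DEFAULT_ENERGY_COEFFICIENTS: dict[str, float] = {
    "ash": 0.0,
    "carbohydrates": 17.5,
    "fat": 39.8,
    "fibre": 18.8,
    "protein": 23.9,
}

ZERO_AVAILABILITY_POLICIES = ("drop_renormalise", "floor")
ELIGIBILITY_BASES = ("used", "available")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the diet-selection analysis.

    Parameters
    ----------
    bootstrap_B
        Number of bootstrap resamples per item (default 1000).
    ci_level
        Two-sided confidence level for the BCa interval (default 0.95).
    min_n
        Minimum number of contributing hares for an item to be
        bootstrapped (default 7; smaller samples give unreliable intervals).
    coverage_threshold
        Minimum fraction of a hare's circular plot inside the study area
        (default 0.75, inclusive).
    energy_coefficients
        kJ/g per DM component for the gross-energy computation.
    rng_seed
        Master seed; per-item substreams are derived from it.
    zero_availability_policy
        How to treat food items used but absent from the plot:
        ``drop_renormalise`` removes them and renormalises use;
        ``floor`` assigns availability ``floor_value`` instead.
    floor_value
        Availability assigned under the ``floor`` policy.
    eligibility_basis
        ``used``: an item's contributing hares are those with use > 0
        (the default reading of "selected by n hares"); ``available``:
        every hare with the item available contributes.
    """

    bootstrap_B: int = 1000
    ci_level: float = 0.95
    min_n: int = 7
    coverage_threshold: float = 0.75
    energy_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_COEFFICIENTS)
    )
    rng_seed: int = 0
    zero_availability_policy: str = "drop_renormalise"
    floor_value: float = 1e-6
    eligibility_basis: str = "used"

    def __post_init__(self) -> None:
        if self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be a positive integer")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.min_n < 1:
            raise ConfigError("min_n must be a positive integer")
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ConfigError("coverage_threshold must lie in (0, 1]")
        missing = [c for c in DM_COMPONENTS if c not in self.energy_coefficients]
        if missing:
            raise ConfigError(f"energy_coefficients missing {missing}")
        if self.zero_availability_policy not in ZERO_AVAILABILITY_POLICIES:
            raise ConfigError(
                f"zero_availability_policy must be one of {ZERO_AVAILABILITY_POLICIES}"
            )
        if self.floor_value <= 0:
            raise ConfigError("floor_value must be positive")
        if self.eligibility_basis not in ELIGIBILITY_BASES:
            raise ConfigError(f"eligibility_basis must be one of {ELIGIBILITY_BASES}")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["energy_coefficients"] = dict(self.energy_coefficients)
        return d

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
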