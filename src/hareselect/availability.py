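"""Per-hare chemical availability of forage.

The botanical inventory of a hare's 10-ha plot, combined with the seasonal
plant composition table, yields the average chemical make-up of the forage
available to that individual: DM fractions as proportions of the summed
measured components, FA as proportions of total FA, and a gross energy
density in kJ/g.

The DM availability is deliberately expressed on the same 5-component
simplex as the stomach assay so that use and availability are comparable
proportion vectors — the form the electivity index requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .config import DEFAULT_ENERGY_COEFFICIENTS
from .errors import (
    CompositionLookupError,
    ConfigError,
    DegenerateInputError,
    PairingError,
    ValidationError,
)
from .inference import bca_interval
from .io import CompositionProfile, PlotInventory, composition_for
from .vocab import DM_COMPONENTS, FA_COMPONENTS


@dataclass(frozen=True)
class ChemicalAvailability:
    """Average composition of the forage available to one hare.

    ``dm_available`` and ``fa_available`` are proportion vectors (sum 1)
    over the 5 DM and 7 FA components; ``gross_energy_available`` is the
    energy density of the availability-weighted mean forage in kJ/g.
    """

    hare_id: str
    dm_available: Mapping[str, float]
    fa_available: Mapping[str, float]
    gross_energy_available: float

    def __post_init__(self) -> None:
        for name, mapping, keys in (
            ("dm_available", self.dm_available, DM_COMPONENTS),
            ("fa_available", self.fa_available, FA_COMPONENTS),
        ):
            if set(mapping) != set(keys):
                raise ValidationError(f"{name} must cover exactly {keys}")
            total = sum(mapping.values())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(f"{name} sums to {total:.8g}, expected 1")
        if self.gross_energy_available < 0:
            raise ValidationError("gross energy must be non-negative")


@dataclass(frozen=True)
class CoverageFilterResult:
    retained: tuple[PlotInventory, ...]
    removed: tuple[PlotInventory, ...]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_by_coverage(
    inventories: Iterable[PlotInventory], threshold: float = 0.75
) -> CoverageFilterResult:
    """Keep hares whose plot coverage is at least ``threshold`` (inclusive).

    Hares shot near the study-area boundary have plots partly outside the
    surveyed area; their availability is unrepresentative and they are
    excluded.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("coverage threshold must lie in (0, 1]")
    retained, removed = [], []
    for inv in inventories:
        (retained if inv.coverage >= threshold else removed).append(inv)
    return CoverageFilterResult(tuple(retained), tuple(removed))


def gross_energy(
    profile: CompositionProfile | Mapping[str, float],
    coefficients: Mapping[str, float] = DEFAULT_ENERGY_COEFFICIENTS,
) -> float:
    """Gross energy density in kJ/g: sum over components of (mg/g / 1000) × kJ/g."""
    dm = profile.dm if isinstance(profile, CompositionProfile) else profile
    missing = [c for c in DM_COMPONENTS if c not in coefficients]
    if missing:
        raise ConfigError(f"energy coefficient(s) missing for {missing}")
    return float(sum((dm[c] / 1000.0) * coefficients[c] for c in DM_COMPONENTS))


def chemical_availability(
    inventory: PlotInventory,
    compositions: Mapping[tuple[str, str], CompositionProfile],
    season: str | None = None,
    energy_coefficients: Mapping[str, float] = DEFAULT_ENERGY_COEFFICIENTS,
) -> ChemicalAvailability:
    """Availability-weighted mean composition of a hare's plot.

    For each DM component c the available proportion is
    ``sum_t a_t dm_t(c) / sum_t a_t sum_c' dm_t(c')`` — i.e. the plot is
    treated as a pooled forage sample mixed according to the botanical
    availability weights ``a_t``. FA availability is the analogous weighted
    mean of the taxon FA simplexes, renormalised. The result is invariant
    to uniform rescaling of the weights.
    """
    season = season or inventory.season
    weights, dm_rows, fa_rows = [], [], []
    for taxon, avail in inventory.taxa:
        if avail <= 0:
            continue
        profile = composition_for(compositions, taxon, season)
        if profile is None:
            raise CompositionLookupError(
                f"no composition for taxon {taxon!r} in season {season!r} "
                f"(hare {inventory.hare_id})"
            )
        weights.append(avail)
        dm_rows.append(profile.dm_vector())
        fa_rows.append(profile.fa_vector())
    w = np.asarray(weights)
    dm = np.asarray(dm_rows)  # (T, 5) in mg/g
    fa = np.asarray(fa_rows)  # (T, 7) simplex rows
    dm_mass = w @ dm  # weighted mg per component
    total_mass = dm_mass.sum()
    if total_mass <= 0:
        raise DegenerateInputError(
            f"hare {inventory.hare_id}: weighted DM of available forage is zero"
        )
    dm_avail = dm_mass / total_mass
    fa_mix = w @ fa
    fa_avail = fa_mix / fa_mix.sum()
    mean_dm_mg = dm_mass / w.sum()  # mean mg/g profile for energy
    energy = gross_energy(dict(zip(DM_COMPONENTS, mean_dm_mg)), energy_coefficients)
    return ChemicalAvailability(
        hare_id=inventory.hare_id,
        dm_available=dict(zip(DM_COMPONENTS, map(float, dm_avail))),
        fa_available=dict(zip(FA_COMPONENTS, map(float, fa_avail))),
        gross_energy_available=energy,
    )


@dataclass(frozen=True)
class PairedEnergySummary:
    """Descriptive comparison of available vs used gross energy.

    This is a plain paired summary (means, SEs, bootstrap CI of the mean
    within-hare difference); it makes no adjustment for season or year.
    """

    n: int
    mean_available: float
    se_available: float
    mean_used: float
    se_used: float
    mean_difference: float
    ci_low: float
    ci_high: float
    B: int
    ci_level: float


def paired_energy_summary(
    available: Mapping[str, float],
    used: Mapping[str, float],
    B: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> PairedEnergySummary:
    """Summarise within-hare differences between used and available energy.

    ``available`` and ``used`` map hare ids to kJ/g and must cover the same
    hares. The difference is used − available, so positive values mean the
    diet is more energy-dense than the plot average.
    """
    if set(available) != set(used):
        only_a = sorted(set(available) - set(used))[:5]
        only_u = sorted(set(used) - set(available))[:5]
        raise PairingError(
            f"hare sets differ (only available: {only_a}, only used: {only_u})"
        )
    hares = sorted(available)
    if len(hares) < 1:
        raise ValidationError("no hares to summarise")
    a = np.array([available[h] for h in hares])
    u = np.array([used[h] for h in hares])
    d = u - a
    n = len(hares)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    if n >= 2:
        ci_low, ci_high = bca_interval(d, B=B, level=ci_level, seed=seed)
    else:
        ci_low = ci_high = float(d.mean())
    return PairedEnergySummary(
        n=n,
        mean_available=float(a.mean()),
        se_available=se(a),
        mean_used=float(u.mean()),
        se_used=se(u),
        mean_difference=float(d.mean()),
        ci_low=ci_low,
        ci_high=ci_high,
        B=B,
        ci_level=ci_level,
    )
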