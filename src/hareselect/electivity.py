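"""Manly's alpha and Chesson's electivity index.

Manly's alpha normalises the per-item use/availability ratio across the m
food items available to one individual:

    alpha_i = (u_i / a_i) / sum_j (u_j / a_j)

Under foraging where intake probability is proportional to preference
weight times availability, alpha estimates the normalised preference
weights. Chesson's electivity maps alpha onto [-1, +1] so that individuals
facing different numbers of available items m are comparable:

    epsilon_i = (m * alpha_i - 1) / ((m - 2) * alpha_i + 1)

epsilon is 0 at the neutral value alpha = 1/m, +1 iff the item is the
entire diet (alpha = 1) and -1 iff an available item is never used
(alpha = 0, m > 1). The epsilon formula string is exported as
``EPSILON_FORMULA`` and recorded in run metadata so any variant
substitution stays visible.

Four item schemes share this machinery: plant taxa, plant groups (taxa
pooled via the plant-group table), the 5 DM components and the 7 FA
components. For the chemical schemes, "use" is the stomach assay and
"availability" the plot-averaged forage composition, both as proportion
vectors on the same simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .availability import ChemicalAvailability
from .config import AnalysisConfig
from .errors import (
    DegenerateDietError,
    UndefinedIndexError,
    ValidationError,
)
from .io import PlotInventory, StomachSample, TaxonGroupMap
from .vocab import DM_COMPONENTS, FA_COMPONENTS, GROUPS, SCHEMES, canonical

logger = logging.getLogger(__name__)

EPSILON_FORMULA = "epsilon = (m*alpha - 1) / ((m - 2)*alpha + 1)"

_SUM_TOL = 1e-6


def manly_alpha(use: Sequence[float], availability: Sequence[float]) -> np.ndarray:
    """Normalised use/availability ratios; sums to 1.

    Both vectors must be aligned proportion vectors summing to 1, with
    strictly positive availability for every retained item (apply a
    zero-availability policy first).
    """
    u = np.asarray(use, dtype=float)
    a = np.asarray(availability, dtype=float)
    if u.shape != a.shape or u.ndim != 1 or u.size == 0:
        raise ValidationError("use and availability must be aligned 1-d vectors")
    if np.any(u < 0) or np.any(a < 0):
        raise ValidationError("proportions must be non-negative")
    if u.sum() <= 0:
        raise DegenerateDietError("total use is zero; Manly's alpha is undefined")
    if np.any(a <= 0):
        raise ValidationError(
            "zero availability with the item retained: resolve via the "
            "zero-availability policy before computing alpha"
        )
    if abs(u.sum() - 1.0) > _SUM_TOL or abs(a.sum() - 1.0) > _SUM_TOL:
        raise ValidationError("use and availability must each sum to 1")
    r = u / a
    return r / r.sum()


def chesson_epsilon(alpha, m: int):
    """Chesson's electivity for alpha in [0, 1] and m >= 2 available items.

    Strictly increasing in alpha, 0 at alpha = 1/m, and attains -1 and +1
    exactly at alpha = 0 and alpha = 1.
    """
    if int(m) != m or m < 2:
        raise UndefinedIndexError(
            f"electivity undefined for m = {m}: at least 2 available items required"
        )
    m = int(m)
    a = np.asarray(alpha, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValidationError("alpha must lie in [0, 1]")
    eps = (m * a - 1.0) / ((m - 2) * a + 1.0)
    eps = np.clip(eps, -1.0, 1.0)
    return float(eps) if np.isscalar(alpha) or eps.ndim == 0 else eps


@dataclass(frozen=True)
class UseAvailabilityPair:
    """Aligned use and availability proportions for one individual."""

    hare_id: str
    scheme: str
    items: tuple[str, ...]
    use: np.ndarray
    availability: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        u = np.asarray(self.use, dtype=float)
        a = np.asarray(self.availability, dtype=float)
        if not (len(self.items) == u.size == a.size) or u.size == 0:
            raise ValidationError("items, use and availability must be aligned")
        if np.any((a <= 0) & (u > 0)):
            raise ValidationError(
                "use without availability: apply the zero-availability policy first"
            )
        object.__setattr__(self, "use", u)
        object.__setattr__(self, "availability", a)

    @property
    def m(self) -> int:
        """Number of items available to this individual."""
        return int(np.count_nonzero(self.availability > 0))


@dataclass(frozen=True)
class ElectivityRecord:
    """Alpha and epsilon for one hare × scheme × item, with hare metadata."""

    hare_id: str
    scheme: str
    item: str
    alpha: float
    epsilon: float
    m: int
    season: str
    year: int
    sex: str
    age: str

    @property
    def used(self) -> bool:
        return self.alpha > 0


def apply_zero_availability_policy(
    items: Sequence[str],
    use: np.ndarray,
    availability: np.ndarray,
    policy: str = "drop_renormalise",
    floor_value: float = 1e-6,
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray, tuple[str, ...]]:
    """Resolve items that were used but have zero availability.

    ``drop_renormalise`` keeps only items with availability > 0 and
    renormalises use over them (used-but-unavailable items are dropped with
    a warning). ``floor`` assigns ``floor_value`` availability to zero-
    availability items that were used and renormalises availability.
    Returns (items, use, availability, dropped_items).
    """
    u = np.asarray(use, dtype=float)
    a = np.asarray(availability, dtype=float)
    if policy == "drop_renormalise":
        keep = a > 0
        dropped = tuple(np.asarray(items, dtype=object)[(~keep) & (u > 0)])
        if dropped:
            logger.warning("dropping used-but-unavailable item(s): %s", ", ".join(map(str, dropped)))
        items2 = tuple(np.asarray(items, dtype=object)[keep])
        u2, a2 = u[keep], a[keep]
        if u2.sum() <= 0:
            raise DegenerateDietError("diet empty after dropping unavailable items")
        return items2, u2 / u2.sum(), a2 / a2.sum(), dropped
    if policy == "floor":
        floored = (a <= 0) & (u > 0)
        a2 = a.copy()
        a2[floored] = floor_value
        keep = a2 > 0
        items2 = tuple(np.asarray(items, dtype=object)[keep])
        u2, a2 = u[keep], a2[keep]
        if u2.sum() <= 0:
            raise DegenerateDietError("diet is entirely zero")
        return items2, u2 / u2.sum(), a2 / a2.sum(), ()
    raise ValidationError(f"unknown zero-availability policy {policy!r}")


def pool_to_groups(
    pair: UseAvailabilityPair,
    group_map: TaxonGroupMap,
    context_tags: Mapping[str, str] | None = None,
) -> UseAvailabilityPair:
    """Pool a taxa-scheme pair into the plant-group scheme.

    Group use/availability are the sums over member taxa; dual-membership
    taxa are resolved through ``context_tags`` (taxon → tag).
    """
    if pair.scheme != "taxa":
        raise ValidationError("pooling applies to the taxa scheme")
    context_tags = {canonical(k): v for k, v in (context_tags or {}).items()}
    use = {g: 0.0 for g in GROUPS}
    avail = {g: 0.0 for g in GROUPS}
    for taxon, u, a in zip(pair.items, pair.use, pair.availability):
        group = group_map.lookup(taxon, context_tags.get(canonical(taxon)))
        use[group] += float(u)
        avail[group] += float(a)
    items = tuple(g for g in GROUPS if use[g] > 0 or avail[g] > 0)
    return UseAvailabilityPair(
        hare_id=pair.hare_id,
        scheme="groups",
        items=items,
        use=np.array([use[g] for g in items]),
        availability=np.array([avail[g] for g in items]),
    )


def _records_from_pair(pair: UseAvailabilityPair, sample: StomachSample) -> list[ElectivityRecord]:
    m = pair.m
    if m < 2:
        logger.warning(
            "hare %s excluded from scheme %s: only %d item(s) available",
            pair.hare_id, pair.scheme, m,
        )
        return []
    alphas = manly_alpha(pair.use, pair.availability)
    eps = chesson_epsilon(alphas, m)
    return [
        ElectivityRecord(
            hare_id=pair.hare_id,
            scheme=pair.scheme,
            item=str(item),
            alpha=float(al),
            epsilon=float(e),
            m=m,
            season=sample.season,
            year=sample.year,
            sex=sample.sex,
            age=sample.age,
        )
        for item, al, e in zip(pair.items, alphas, eps)
    ]


def _taxa_pair_raw(
    sample: StomachSample, inventory: PlotInventory
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Aligned raw use/availability over the union of diet and plot taxa."""
    avail = {canonical(t): (t, a) for t, a in inventory.taxa}
    use = {canonical(t): (t, u) for t, u in sample.diet}
    keys = list(dict.fromkeys([*avail, *use]))
    items = tuple((avail.get(k) or use[k])[0] for k in keys)
    u = np.array([use.get(k, (None, 0.0))[1] for k in keys])
    a = np.array([avail.get(k, (None, 0.0))[1] for k in keys])
    return items, u, a


def electivity_per_individual(
    sample: StomachSample,
    inventory: PlotInventory,
    chem_avail: ChemicalAvailability | None,
    scheme: str,
    config: AnalysisConfig,
    group_map: TaxonGroupMap | None = None,
    context_tags: Mapping[str, str] | None = None,
) -> list[ElectivityRecord]:
    """Electivity records for one hare under one item scheme.

    Returns one record per item with availability > 0; an empty list means
    the hare is excluded from this scheme (fewer than two available items,
    or an empty diet after the zero-availability policy).
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if sample.hare_id != inventory.hare_id:
        raise ValidationError("stomach sample and inventory belong to different hares")

    if scheme in ("taxa", "groups"):
        items, u, a = _taxa_pair_raw(sample, inventory)
        if scheme == "groups":
            if group_map is None:
                raise ValidationError("groups scheme requires a plant-group table")
            # pool on the raw vectors (pre-policy) so a used taxon missing
            # from the plot still counts toward a group available via other
            # members; the policy is then applied at group level
            pooled_use = {g: 0.0 for g in GROUPS}
            pooled_avail = {g: 0.0 for g in GROUPS}
            tags = {canonical(k): v for k, v in (context_tags or {}).items()}
            for taxon, uu, aa in zip(items, u, a):
                group = group_map.lookup(taxon, tags.get(canonical(taxon)))
                pooled_use[group] += float(uu)
                pooled_avail[group] += float(aa)
            items = tuple(g for g in GROUPS if pooled_use[g] > 0 or pooled_avail[g] > 0)
            u = np.array([pooled_use[g] for g in items])
            a = np.array([pooled_avail[g] for g in items])
        try:
            items, u, a, _dropped = apply_zero_availability_policy(
                items, u, a, config.zero_availability_policy, config.floor_value
            )
        except DegenerateDietError:
            logger.warning(
                "hare %s excluded from scheme %s: empty diet after "
                "zero-availability policy", sample.hare_id, scheme,
            )
            return []
        pair = UseAvailabilityPair(sample.hare_id, scheme, items, u, a)
        return _records_from_pair(pair, sample)

    if chem_avail is None:
        raise ValidationError(f"scheme {scheme!r} requires a ChemicalAvailability")
    if scheme == "dm":
        comps = DM_COMPONENTS
        avail_map = chem_avail.dm_available
        dm_vec = sample.stomach_composition.dm_vector()
        if dm_vec.sum() <= 0:
            logger.warning("hare %s excluded from scheme dm: all-zero stomach DM", sample.hare_id)
            return []
        use_vec = dm_vec / dm_vec.sum()
    else:  # fa
        comps = FA_COMPONENTS
        avail_map = chem_avail.fa_available
        use_vec = sample.stomach_composition.fa_vector()
    items = tuple(comps)
    a = np.array([avail_map[c] for c in comps])
    try:
        items, u, a, _dropped = apply_zero_availability_policy(
            items, use_vec, a, config.zero_availability_policy, config.floor_value
        )
    except DegenerateDietError:
        logger.warning("hare %s excluded from scheme %s", sample.hare_id, scheme)
        return []
    pair = UseAvailabilityPair(sample.hare_id, scheme, items, u, a)
    return _records_from_pair(pair, sample)
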