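"""Tabular input/output and core record types.

All tables are comma-separated with a header row, read and written with
pandas. Proportion vectors are validated on construction: raw sums within
[0.98, 1.02] (rounded field data) are renormalised to exactly 1, anything
outside that band is rejected as a data error.

Tables
------
inventories
    long format, one row per (hare, taxon):
    ``hare_id,season,year,taxon,availability,coverage``
compositions
    one row per (taxon, season): ``taxon,season`` + the 5 DM columns (mg/g)
    + the 7 FA columns (proportions of total FA)
stomachs
    long format, one row per (hare, taxon) with the hare's stomach assay
    repeated on every row: ``hare_id,season,year,sex,age,taxon,use`` + DM/FA
    columns
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousGroupError,
    FormatError,
    UnknownTaxonError,
    ValidationError,
)
from .vocab import (
    AGE_ALIASES,
    AGES,
    DM_COMPONENTS,
    FA_COMPONENTS,
    GROUPS,
    SEASON_ALIASES,
    SEX_ALIASES,
    canonical,
    canonical_taxon,
)

#: Raw proportion sums inside this band are renormalised; outside → error.
SUM_TOLERANCE_BAND = (0.98, 1.02)

#: Post-validation proportion vectors sum to 1 within this tolerance.
SUM_EXACT_TOL = 1e-6


def _normalise_proportions(values: np.ndarray, what: str, owner: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError(f"{owner}: empty {what} vector")
    if np.any(values < 0):
        raise ValidationError(f"{owner}: negative {what} proportion")
    total = float(values.sum())
    lo, hi = SUM_TOLERANCE_BAND
    if not (lo <= total <= hi):
        raise ValidationError(
            f"{owner}: {what} proportions sum to {total:.6g}, outside [{lo}, {hi}]"
        )
    return values / total


def _alias(value: str, table: Mapping[str, str], what: str, owner: str) -> str:
    key = canonical(value)
    if key not in table:
        raise ValidationError(f"{owner}: unknown {what} {value!r}")
    return table[key]


@dataclass(frozen=True)
class PlotInventory:
    """Available forage in one hare's 10-ha circular plot.

    ``taxa`` holds (taxon, availability proportion) pairs; proportions are
    renormalised to sum to 1 on construction. ``coverage`` is the fraction
    of the circular plot falling inside the study area.
    """

    hare_id: str
    season: str
    year: int
    taxa: tuple[tuple[str, float], ...]
    coverage: float

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValidationError(f"hare {self.hare_id}: inventory has no taxa")
        names = [canonical_taxon(t) for t, _ in self.taxa]
        if len({canonical(n) for n in names}) != len(names):
            raise ValidationError(f"hare {self.hare_id}: duplicate taxon in inventory")
        season = _alias(self.season, SEASON_ALIASES, "season", f"hare {self.hare_id}")
        props = _normalise_proportions(
            np.array([a for _, a in self.taxa]), "availability", f"hare {self.hare_id}"
        )
        if not (0.0 <= self.coverage <= 1.0):
            raise ValidationError(
                f"hare {self.hare_id}: coverage {self.coverage} outside [0, 1]"
            )
        object.__setattr__(self, "season", season)
        object.__setattr__(
            self, "taxa", tuple(zip(names, (float(p) for p in props)))
        )

    @property
    def availability(self) -> dict[str, float]:
        return dict(self.taxa)


@dataclass(frozen=True)
class CompositionProfile:
    """Chemical composition of a plant sample or a stomach content.

    ``dm``: the five crude fractions in mg per g dry matter (sum ≤ 1000).
    ``fa``: the seven fatty acids as proportions of total identified FA,
    renormalised to sum to 1 on construction.
    """

    dm: Mapping[str, float]
    fa: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.dm) != set(DM_COMPONENTS):
            raise ValidationError(
                f"DM components must be exactly {DM_COMPONENTS}, got {sorted(self.dm)}"
            )
        if set(self.fa) != set(FA_COMPONENTS):
            raise ValidationError(
                f"FA components must be exactly {FA_COMPONENTS}, got {sorted(self.fa)}"
            )
        dm = {c: float(self.dm[c]) for c in DM_COMPONENTS}
        for c, v in dm.items():
            if v < 0:
                raise ValidationError(f"negative DM value for {c}")
            if v > 1000:
                raise ValidationError(f"DM value for {c} exceeds 1000 mg/g")
        if sum(dm.values()) > 1000 + 1e-9:
            raise ValidationError(f"DM components sum to {sum(dm.values()):.6g} > 1000 mg/g")
        fa_raw = np.array([float(self.fa[c]) for c in FA_COMPONENTS])
        if np.any(fa_raw < 0):
            raise ValidationError("negative FA proportion")
        total = fa_raw.sum()
        if total <= 0:
            raise ValidationError("FA proportions sum to zero")
        fa = {c: float(v) for c, v in zip(FA_COMPONENTS, fa_raw / total)}
        object.__setattr__(self, "dm", dm)
        object.__setattr__(self, "fa", fa)

    def dm_vector(self) -> np.ndarray:
        return np.array([self.dm[c] for c in DM_COMPONENTS])

    def fa_vector(self) -> np.ndarray:
        return np.array([self.fa[c] for c in FA_COMPONENTS])


@dataclass(frozen=True)
class StomachSample:
    """One hare's stomach content: botanical use proportions plus assay."""

    hare_id: str
    season: str
    year: int
    sex: str
    age: str
    diet: tuple[tuple[str, float], ...]
    stomach_composition: CompositionProfile

    def __post_init__(self) -> None:
        owner = f"hare {self.hare_id}"
        season = _alias(self.season, SEASON_ALIASES, "season", owner)
        sex = _alias(self.sex, SEX_ALIASES, "sex", owner)
        age_raw = str(self.age).strip()
        try:
            float(age_raw)
        except ValueError:
            pass
        else:
            raise ValidationError(
                f"{owner}: age given as a number ({age_raw}); a categorical age "
                f"class {AGES} is required (lens-mass ageing is not supported here)"
            )
        age = _alias(age_raw, AGE_ALIASES, "age", owner)
        if not self.diet:
            raise ValidationError(f"{owner}: empty diet")
        names = [canonical_taxon(t) for t, _ in self.diet]
        if len({canonical(n) for n in names}) != len(names):
            raise ValidationError(f"{owner}: duplicate taxon in diet")
        props = _normalise_proportions(
            np.array([u for _, u in self.diet]), "use", owner
        )
        object.__setattr__(self, "season", season)
        object.__setattr__(self, "sex", sex)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "diet", tuple(zip(names, (float(p) for p in props))))

    @property
    def use(self) -> dict[str, float]:
        return dict(self.diet)


class TaxonGroupMap:
    """Taxon → plant-group mapping with context-dependent dual membership.

    Most taxa belong to one group. A few crop species also occur as
    volunteers or intertillage; those map to two groups and require a
    ``context_tag`` at lookup time to disambiguate.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str | None]]):
        self._rows: list[tuple[str, str, str | None]] = []
        self._by_taxon: dict[str, list[tuple[str, str | None]]] = {}
        self._display: dict[str, str] = {}
        for taxon, group, tag in rows:
            name = canonical_taxon(taxon)
            key = canonical(name)
            if group not in GROUPS:
                raise ValidationError(f"unknown plant group {group!r} for {name}")
            tag = canonical(tag) if tag else None
            self._rows.append((name, group, tag))
            self._by_taxon.setdefault(key, []).append((group, tag))
            self._display.setdefault(key, name)
        for key, memberships in self._by_taxon.items():
            if len(memberships) > 1 and any(tag is None for _, tag in memberships):
                raise ValidationError(
                    f"dual-membership taxon {self._display[key]} has a row "
                    "without a context_tag"
                )

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._display.values()))

    def groups_for(self, taxon: str) -> tuple[str, ...]:
        key = canonical(taxon)
        if key not in self._by_taxon:
            raise UnknownTaxonError(f"taxon {taxon!r} not in the plant-group table")
        return tuple(g for g, _ in self._by_taxon[key])

    def lookup(self, taxon: str, context_tag: str | None = None) -> str:
        key = canonical(taxon)
        if key not in self._by_taxon:
            raise UnknownTaxonError(f"taxon {taxon!r} not in the plant-group table")
        memberships = self._by_taxon[key]
        if len(memberships) == 1:
            return memberships[0][0]
        if context_tag is None:
            tags = sorted(t for _, t in memberships if t)
            raise AmbiguousGroupError(
                f"taxon {self._display[key]} belongs to several groups; "
                f"a context_tag from {tags} is required"
            )
        tag = canonical(context_tag)
        for group, t in memberships:
            if t == tag:
                return group
        raise AmbiguousGroupError(
            f"context_tag {context_tag!r} does not resolve {self._display[key]}"
        )

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPS}
        for _, group, _ in self._rows:
            counts[group] += 1
        return counts


def load_plant_groups() -> TaxonGroupMap:
    """The packaged plant-group table for the study flora.

    Five groups — cereals, intertillage, other field crops, trees/shrubs,
    weeds/grasses — with two context-dependent dual-membership species
    (Fagopyrum esculentum, Pisum sativum).
    """
    with resources.files("hareselect.data").joinpath("plant_groups.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    return TaxonGroupMap(
        (r.taxon, r.group, r.context_tag or None) for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_inventories(path) -> list[PlotInventory]:
    """Read the long-format plot inventory table; one inventory per hare."""
    df = pd.read_csv(path)
    _require_columns(df, ["hare_id", "season", "year", "taxon", "availability", "coverage"], path)
    inventories = []
    for hare_id, sub in df.groupby("hare_id", sort=False):
        for col in ("season", "year", "coverage"):
            if sub[col].nunique() != 1:
                raise ValidationError(f"{path}: hare {hare_id} has conflicting {col} values")
        first = sub.iloc[0]
        inventories.append(
            PlotInventory(
                hare_id=str(hare_id),
                season=str(first["season"]),
                year=int(first["year"]),
                taxa=tuple(zip(sub["taxon"].astype(str), sub["availability"].astype(float))),
                coverage=float(first["coverage"]),
            )
        )
    return inventories


def read_compositions(path) -> dict[tuple[str, str], CompositionProfile]:
    """Read the plant composition table keyed by (taxon, season)."""
    df = pd.read_csv(path)
    _require_columns(df, ["taxon", "season", *DM_COMPONENTS, *FA_COMPONENTS], path)
    out: dict[tuple[str, str], CompositionProfile] = {}
    for row in df.itertuples(index=False, name=None):
        # plain tuples: itertuples would mangle column names like "C14:0"
        values = dict(zip(df.columns, row))
        taxon = canonical_taxon(values["taxon"])
        season = _alias(values["season"], SEASON_ALIASES, "season", f"taxon {taxon}")
        key = (canonical(taxon), season)
        if key in out:
            raise ValidationError(f"{path}: duplicate composition for {taxon}/{season}")
        out[key] = CompositionProfile(
            dm={c: float(values[c]) for c in DM_COMPONENTS},
            fa={c: float(values[c]) for c in FA_COMPONENTS},
        )
    return out


def composition_for(
    compositions: Mapping[tuple[str, str], CompositionProfile], taxon: str, season: str
) -> CompositionProfile | None:
    return compositions.get((canonical(taxon), season))


def read_stomachs(path) -> list[StomachSample]:
    """Read the long-format stomach table; one sample per hare."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["hare_id", "season", "year", "sex", "age", "taxon", "use", *DM_COMPONENTS, *FA_COMPONENTS],
        path,
    )
    samples = []
    for hare_id, sub in df.groupby("hare_id", sort=False):
        for col in ("season", "year", "sex", "age", *DM_COMPONENTS, *FA_COMPONENTS):
            if sub[col].nunique() != 1:
                raise ValidationError(f"{path}: hare {hare_id} has conflicting {col} values")
        first = dict(zip(sub.columns, sub.iloc[0]))
        samples.append(
            StomachSample(
                hare_id=str(hare_id),
                season=str(first["season"]),
                year=int(first["year"]),
                sex=str(first["sex"]),
                age=str(first["age"]),
                diet=tuple(zip(sub["taxon"].astype(str), sub["use"].astype(float))),
                stomach_composition=CompositionProfile(
                    dm={c: float(first[c]) for c in DM_COMPONENTS},
                    fa={c: float(first[c]) for c in FA_COMPONENTS},
                ),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# writers


def write_inventories(inventories: Iterable[PlotInventory], path) -> None:
    rows = [
        {
            "hare_id": inv.hare_id,
            "season": inv.season,
            "year": inv.year,
            "taxon": taxon,
            "availability": repr(avail),
            "coverage": repr(inv.coverage),
        }
        for inv in inventories
        for taxon, avail in inv.taxa
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_compositions(
    compositions: Mapping[tuple[str, str], CompositionProfile], path, *, display_names=None
) -> None:
    display_names = display_names or {}
    rows = []
    for (taxon_key, season), profile in compositions.items():
        row = {"taxon": display_names.get(taxon_key, taxon_key), "season": season}
        row.update({c: repr(profile.dm[c]) for c in DM_COMPONENTS})
        row.update({c: repr(profile.fa[c]) for c in FA_COMPONENTS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_stomachs(samples: Iterable[StomachSample], path) -> None:
    rows = []
    for s in samples:
        for taxon, use in s.diet:
            row = {
                "hare_id": s.hare_id,
                "season": s.season,
                "year": s.year,
                "sex": s.sex,
                "age": s.age,
                "taxon": taxon,
                "use": repr(use),
            }
            row.update({c: repr(s.stomach_composition.dm[c]) for c in DM_COMPONENTS})
            row.update({c: repr(s.stomach_composition.fa[c]) for c in FA_COMPONENTS})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
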