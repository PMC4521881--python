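"""Synthetic landscapes, plant compositions and hare stomachs.

The generator encodes the foraging model under which Manly's alpha is the
natural estimator: each hare's plot offers taxon availabilities drawn from
a Dirichlet, and the hare takes a fixed number of feeding "bites" as a
multinomial with intake probabilities proportional to preference weight
times availability (p_i ∝ w_i · a_i). With all weights equal the forager
is neutral and expected use equals availability; boosting a weight makes
alpha recover the normalised weights, so parameter recovery is a
meaningful end-to-end check.

The stomach chemical assay is the use-weighted mix of the taxon
composition templates with per-sample Dirichlet noise (noise on the
simplex keeps every invariant valid by construction). The plant
composition table itself is emitted noise-free: it plays the role of the
measured ground truth that the availability computation assumes.

What this generator does NOT emulate: spatial structure of plots,
phenological change within a season beyond fixed per-season template
shifts, partial consumption of plant parts, and digestion-rate distortion
of stomach proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ValidationError
from .io import (
    CompositionProfile,
    PlotInventory,
    StomachSample,
    write_compositions,
    write_inventories,
    write_stomachs,
)
from .vocab import DM_COMPONENTS, FA_COMPONENTS, SEASONS, canonical

# ---------------------------------------------------------------------------
# taxon templates: a 10-taxon pool spanning four plant groups, with
# plausible crude-fraction (mg/g DM) and fatty-acid (simplex) profiles.
# Energy-dense seed crops are low in fibre, leafy forage is fibrous and
# ALA-rich, seed oils are LA-rich — the gradients the diet-selection
# analysis is about.

_LEAFY_FA = {"C14:0": 0.010, "C16:0": 0.160, "C16:1": 0.020, "C18:0": 0.020,
             "C18:1": 0.050, "LA": 0.170, "ALA": 0.570}
_SEED_FA = {"C14:0": 0.005, "C16:0": 0.120, "C16:1": 0.005, "C18:0": 0.040,
            "C18:1": 0.220, "LA": 0.520, "ALA": 0.090}
_ROOT_FA = {"C14:0": 0.010, "C16:0": 0.220, "C16:1": 0.015, "C18:0": 0.030,
            "C18:1": 0.100, "LA": 0.350, "ALA": 0.275}

#: taxon -> (group, DM mg/g, FA simplex)
BASE_TEMPLATES: dict[str, tuple[str, dict[str, float], dict[str, float]]] = {
    "Triticum aestivum": ("cereals",
        {"ash": 80, "carbohydrates": 400, "fat": 25, "fibre": 280, "protein": 180}, _LEAFY_FA),
    "Hordeum vulgare": ("cereals",
        {"ash": 75, "carbohydrates": 420, "fat": 28, "fibre": 270, "protein": 170}, _LEAFY_FA),
    "Zea mays": ("cereals",
        {"ash": 55, "carbohydrates": 580, "fat": 35, "fibre": 200, "protein": 100}, _SEED_FA),
    "Beta vulgaris": ("other field crops",
        {"ash": 70, "carbohydrates": 720, "fat": 8, "fibre": 90, "protein": 80}, _ROOT_FA),
    "Glycine max": ("other field crops",
        {"ash": 60, "carbohydrates": 340, "fat": 180, "fibre": 110, "protein": 280}, _SEED_FA),
    "Helianthus annuus": ("other field crops",
        {"ash": 65, "carbohydrates": 390, "fat": 150, "fibre": 130, "protein": 160}, _SEED_FA),
    "Medicago sativa": ("weeds/grasses",
        {"ash": 95, "carbohydrates": 340, "fat": 30, "fibre": 280, "protein": 220}, _LEAFY_FA),
    "Trifolium pratense": ("weeds/grasses",
        {"ash": 90, "carbohydrates": 380, "fat": 32, "fibre": 260, "protein": 210}, _LEAFY_FA),
    "Stellaria media": ("weeds/grasses",
        {"ash": 120, "carbohydrates": 440, "fat": 40, "fibre": 170, "protein": 190}, _LEAFY_FA),
    "Sinapis arvensis": ("intertillage",
        {"ash": 85, "carbohydrates": 400, "fat": 45, "fibre": 220, "protein": 200}, _LEAFY_FA),
}

DEFAULT_TAXA: tuple[str, ...] = tuple(BASE_TEMPLATES)

#: Taxa boosted by the taxa_selector preset.
BOOSTED_TAXA: tuple[str, ...] = ("Beta vulgaris", "Medicago sativa", "Glycine max")

# mild deterministic per-season modulation of the DM templates: winter
# forage is more fibrous, spring growth is protein-rich, autumn crops
# carry more storage carbohydrate.
_SEASON_DM_SHIFT: dict[str, dict[str, float]] = {
    "winter": {"fibre": 1.12, "protein": 0.92},
    "spring": {"protein": 1.12, "fibre": 0.92},
    "summer": {},
    "autumn": {"carbohydrates": 1.08, "fat": 1.05},
}
_SEASON_ALA_SHIFT = {"winter": 0.95, "spring": 1.08, "summer": 1.05, "autumn": 0.95}


def seasonal_template(taxon: str, season: str) -> CompositionProfile:
    """The (noise-free) composition template of a taxon in a season."""
    group, dm, fa = BASE_TEMPLATES[taxon]
    dm = {c: v * _SEASON_DM_SHIFT[season].get(c, 1.0) for c, v in dm.items()}
    total = sum(dm.values())
    if total > 1000:
        dm = {c: v * 1000.0 / total for c, v in dm.items()}
    fa = dict(fa)
    fa["ALA"] = fa["ALA"] * _SEASON_ALA_SHIFT[season]
    return CompositionProfile(dm=dm, fa=fa)  # FA renormalised on construction


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one simulated study.

    Defaults describe a modest field season: 15 hares per season over four
    seasons of one year, a 10-taxon flora with moderately heterogeneous
    plots (symmetric Dirichlet concentration 4 per taxon), 200 feeding
    bites per hare, stomach-assay noise as Dirichlet concentration 2500
    (a ~5% coefficient of variation on major components, the order of a
    routine chromatography/proximate assay), and plot coverage uniform on
    [0.6, 1] so the 75% filter bites.
    """

    name: str = "custom"
    taxa: tuple[str, ...] = DEFAULT_TAXA
    weights: Mapping[str, float] = field(default_factory=dict)
    n_hares_per_season: int = 15
    seasons: tuple[str, ...] = SEASONS
    years: tuple[int, ...] = (2003,)
    availability_concentration: float = 4.0
    bites: int = 200
    composition_noise: float = 2500.0
    coverage_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self) -> None:
        if self.bites < 1:
            raise ValidationError("bites must be at least 1")
        if self.availability_concentration <= 0:
            raise ValidationError("Dirichlet concentration must be positive")
        unknown = set(self.weights) - set(self.taxa)
        if unknown:
            raise ValidationError(f"weights given for taxa outside the pool: {sorted(unknown)}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValidationError("preference weights must be positive")
        if not (0.0 <= self.coverage_range[0] <= self.coverage_range[1] <= 1.0):
            raise ValidationError("coverage_range must be an ordered pair within [0, 1]")
        for t in self.taxa:
            if t not in BASE_TEMPLATES:
                raise ValidationError(f"no composition template for taxon {t!r}")

    def weight_vector(self) -> np.ndarray:
        return np.array([float(self.weights.get(t, 1.0)) for t in self.taxa])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "taxa": list(self.taxa),
            "weights": {t: float(self.weights.get(t, 1.0)) for t in self.taxa},
            "n_hares_per_season": self.n_hares_per_season,
            "seasons": list(self.seasons),
            "years": list(self.years),
            "availability_concentration": self.availability_concentration,
            "bites": self.bites,
            "composition_noise": self.composition_noise,
            "coverage_range": list(self.coverage_range),
        }


def preset_scenarios() -> dict[str, SyntheticScenario]:
    """Three canned scenarios.

    ``neutral``: all weights 1, no preference anywhere. ``fat_seeker``:
    weights equal to the taxon's rank by template crude-fat content, so
    fat-rich (and fibre-poor) forage is taken disproportionately — the
    energy-maximising forager. ``taxa_selector``: weight 10 on three crop
    taxa against 1 elsewhere.
    """
    fat_order = sorted(DEFAULT_TAXA, key=lambda t: BASE_TEMPLATES[t][1]["fat"])
    fat_weights = {t: float(rank + 1) for rank, t in enumerate(fat_order)}
    return {
        "neutral": SyntheticScenario(name="neutral"),
        "fat_seeker": SyntheticScenario(name="fat_seeker", weights=fat_weights),
        "taxa_selector": SyntheticScenario(
            name="taxa_selector",
            weights={t: (10.0 if t in BOOSTED_TAXA else 1.0) for t in DEFAULT_TAXA},
        ),
    }


def simulate_plot(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    hare_id: str,
    season: str,
    year: int,
) -> PlotInventory:
    """One hare's plot: Dirichlet availabilities and a coverage draw."""
    conc = np.full(len(scenario.taxa), scenario.availability_concentration)
    avail = rng.dirichlet(conc)
    lo, hi = scenario.coverage_range
    coverage = float(rng.uniform(lo, hi))
    return PlotInventory(
        hare_id=hare_id,
        season=season,
        year=year,
        taxa=tuple(zip(scenario.taxa, map(float, avail))),
        coverage=coverage,
    )


def simulate_diet(
    scenario: SyntheticScenario,
    plot: PlotInventory,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    bites: int | None = None,
) -> StomachSample:
    """One hare's stomach: multinomial bites with p_i ∝ w_i · a_i.

    Use proportions are bite counts divided by the bite total; the stomach
    assay is the use-weighted template mix with Dirichlet noise.
    """
    w = scenario.weight_vector() if weights is None else np.asarray(weights, dtype=float)
    bites = scenario.bites if bites is None else int(bites)
    avail = plot.availability
    a = np.array([avail[t] for t in scenario.taxa])
    p = w * a
    p = p / p.sum()
    counts = rng.multinomial(bites, p)
    use = counts / counts.sum()

    dm_mix = np.zeros(len(DM_COMPONENTS))
    fa_mix = np.zeros(len(FA_COMPONENTS))
    for taxon, u in zip(scenario.taxa, use):
        if u == 0:
            continue
        tpl = seasonal_template(taxon, plot.season)
        dm_mix += u * tpl.dm_vector()
        fa_mix += u * tpl.fa_vector()
    kappa = scenario.composition_noise
    dm_total = dm_mix.sum()
    dm_simplex = rng.dirichlet(np.maximum(dm_mix / dm_total, 1e-12) * kappa)
    dm_obs = dm_simplex * dm_total
    fa_obs = rng.dirichlet(np.maximum(fa_mix / fa_mix.sum(), 1e-12) * kappa)

    diet = tuple((t, float(u)) for t, u in zip(scenario.taxa, use) if u > 0)
    return StomachSample(
        hare_id=plot.hare_id,
        season=plot.season,
        year=plot.year,
        sex=str(rng.choice(["male", "female"])),
        age=str(rng.choice(["adult", "subadult"], p=[0.6, 0.4])),
        diet=diet,
        stomach_composition=CompositionProfile(
            dm=dict(zip(DM_COMPONENTS, map(float, dm_obs))),
            fa=dict(zip(FA_COMPONENTS, map(float, fa_obs))),
        ),
    )


@dataclass(frozen=True)
class SyntheticDataset:
    """A full simulated study, in the exact containers the readers produce."""

    scenario: SyntheticScenario
    seed: int
    inventories: tuple[PlotInventory, ...]
    compositions: dict[tuple[str, str], CompositionProfile]
    stomachs: tuple[StomachSample, ...]


def simulate_dataset(scenario: SyntheticScenario, seed: int) -> SyntheticDataset:
    """Simulate plots, the composition table and stomachs for one study."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) % 2**31))
    compositions = {
        (canonical(taxon), season): seasonal_template(taxon, season)
        for taxon in scenario.taxa
        for season in scenario.seasons
    }
    inventories: list[PlotInventory] = []
    stomachs: list[StomachSample] = []
    idx = 0
    for year in scenario.years:
        for season in scenario.seasons:
            for _ in range(scenario.n_hares_per_season):
                hare_id = f"H{idx:04d}"
                idx += 1
                plot = simulate_plot(scenario, rng, hare_id, season, year)
                inventories.append(plot)
                stomachs.append(simulate_diet(scenario, plot, rng))
    return SyntheticDataset(
        scenario=scenario,
        seed=int(seed),
        inventories=tuple(inventories),
        compositions=compositions,
        stomachs=tuple(stomachs),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset in the table dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "inventories": out / "inventories.csv",
        "compositions": out / "compositions.csv",
        "stomachs": out / "stomachs.csv",
        "scenario": out / "scenario.yaml",
    }
    write_inventories(dataset.inventories, paths["inventories"])
    display = {canonical(t): t for t in dataset.scenario.taxa}
    write_compositions(dataset.compositions, paths["compositions"], display_names=display)
    write_stomachs(dataset.stomachs, paths["stomachs"])
    with open(paths["scenario"], "w", encoding="utf-8") as fh:
        yaml.safe_dump({**dataset.scenario.to_dict(), "seed": dataset.seed}, fh, sort_keys=True)
    return paths
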