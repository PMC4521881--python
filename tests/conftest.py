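import numpy as np
import pytest
from hypothesis import settings

from hareselect import AnalysisConfig, CompositionProfile, PlotInventory, StomachSample
from hareselect.vocab import FA_COMPONENTS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

UNIFORM_FA = {c: 1.0 / len(FA_COMPONENTS) for c in FA_COMPONENTS}


def make_profile(dm=None, fa=None) -> CompositionProfile:
    dm = dm or {"ash": 50, "carbohydrates": 500, "fat": 100, "fibre": 150, "protein": 200}
    fa = fa or dict(UNIFORM_FA)
    return CompositionProfile(dm=dm, fa=fa)


def make_inventory(hare_id="H1", taxa=None, coverage=0.9, season="winter", year=2003):
    if taxa is None:
        taxa = (("Triticum aestivum", 0.5), ("Beta vulgaris", 0.3), ("Medicago sativa", 0.2))
    return PlotInventory(hare_id=hare_id, season=season, year=year, taxa=tuple(taxa), coverage=coverage)


def make_stomach(hare_id="H1", diet=None, profile=None, season="winter", year=2003,
                 sex="female", age="adult"):
    diet = diet or (("Triticum aestivum", 0.5), ("Beta vulgaris", 0.3), ("Medicago sativa", 0.2))
    return StomachSample(
        hare_id=hare_id, season=season, year=year, sex=sex, age=age,
        diet=tuple(diet), stomach_composition=profile or make_profile(),
    )


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def group_map():
    from hareselect import load_plant_groups

    return load_plant_groups()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
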