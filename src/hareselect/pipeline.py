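"""End-to-end orchestration: read → filter → availability → electivity →
bootstrap inference → report.

The same `analyse` function serves in-memory objects (synthetic studies,
tests) and the file-based `run` entry point used by the command line. A
run directory contains the long-format electivity table, the bootstrap
summary table, the skipped item × stratum list and a JSON manifest with
the config snapshot, input digests and stage-wise exclusion counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .availability import ChemicalAvailability, chemical_availability, filter_by_coverage
from .config import AnalysisConfig
from .electivity import EPSILON_FORMULA, ElectivityRecord, electivity_per_individual
from .errors import ValidationError
from .inference import BootstrapSummary, SkippedStratum, stratified_summaries
from .io import (
    CompositionProfile,
    PlotInventory,
    StomachSample,
    TaxonGroupMap,
    load_plant_groups,
    read_compositions,
    read_inventories,
    read_stomachs,
)
from .simulate import SyntheticDataset, preset_scenarios, simulate_dataset, write_dataset
from .vocab import SCHEMES

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["hare_id", "scheme", "item", "alpha", "epsilon", "m",
                  "season", "year", "sex", "age"]
SUMMARY_COLUMNS = ["scheme", "item", "stratum", "n", "mean_epsilon",
                   "ci_low", "ci_high", "significant", "B", "ci_level", "seed"]


@dataclass
class RunManifest:
    """Reproducibility metadata for one analysis run."""

    config: dict
    seed: int
    version: str = __version__
    epsilon_formula: str = EPSILON_FORMULA
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    scenario: dict | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class AnalysisResult:
    records: list[ElectivityRecord]
    summaries: list[BootstrapSummary]
    skipped: list[SkippedStratum]
    manifest: RunManifest
    chemical: dict[str, ChemicalAvailability]

    def records_frame(self) -> pd.DataFrame:
        rows = [[getattr(r, c) for c in RECORD_COLUMNS] for r in self.records]
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    def summaries_frame(self) -> pd.DataFrame:
        rows = [[getattr(s, c) for c in SUMMARY_COLUMNS] for s in self.summaries]
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    def skipped_frame(self) -> pd.DataFrame:
        cols = ["scheme", "item", "stratum", "n", "reason"]
        return pd.DataFrame([[getattr(s, c) for c in cols] for s in self.skipped], columns=cols)


def analyse(
    inventories: Sequence[PlotInventory],
    compositions: Mapping[tuple[str, str], CompositionProfile],
    stomachs: Sequence[StomachSample],
    config: AnalysisConfig | None = None,
    group_map: TaxonGroupMap | None = None,
    schemes: Sequence[str] = SCHEMES,
    strata: Sequence[str] = ("all",),
    context_tags: Mapping[str, str] | None = None,
) -> AnalysisResult:
    """Run the full diet-selection analysis on in-memory tables."""
    config = config or AnalysisConfig()
    for scheme in schemes:
        if scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {scheme!r}")
    if "groups" in schemes and group_map is None:
        group_map = load_plant_groups()

    cov = filter_by_coverage(inventories, config.coverage_threshold)
    inv_by_hare = {inv.hare_id: inv for inv in cov.retained}
    matched = [s for s in stomachs if s.hare_id in inv_by_hare]
    unmatched = len(stomachs) - len(matched)
    if unmatched:
        logger.info("%d stomach sample(s) without a retained inventory", unmatched)

    need_chemistry = bool({"dm", "fa"} & set(schemes))
    chemical: dict[str, ChemicalAvailability] = {}
    if need_chemistry:
        for s in matched:
            inv = inv_by_hare[s.hare_id]
            chemical[s.hare_id] = chemical_availability(
                inv, compositions, energy_coefficients=config.energy_coefficients
            )

    records: list[ElectivityRecord] = []
    excluded_per_scheme = {scheme: 0 for scheme in schemes}
    for s in matched:
        inv = inv_by_hare[s.hare_id]
        for scheme in schemes:
            recs = electivity_per_individual(
                s, inv, chemical.get(s.hare_id), scheme, config,
                group_map=group_map, context_tags=context_tags,
            )
            if recs:
                records.extend(recs)
            else:
                excluded_per_scheme[scheme] += 1

    summaries, skipped = stratified_summaries(records, strata=strata, config=config)

    counts = {
        "stomachs_read": len(stomachs),
        "inventories_read": len(inventories),
        "excluded_by_coverage": cov.n_removed,
        "stomachs_without_inventory": unmatched,
        "hares_analysed": len(matched),
        "excluded_per_scheme": excluded_per_scheme,
        "records": len(records),
        "items_bootstrapped": len(summaries),
        "item_strata_skipped": len(skipped),
    }
    manifest = RunManifest(config=config.to_dict(), seed=config.rng_seed, counts=counts)
    return AnalysisResult(records, summaries, skipped, manifest, chemical)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(
    inventories_path,
    compositions_path,
    stomachs_path,
    out_dir,
    config: AnalysisConfig | None = None,
    schemes: Sequence[str] = SCHEMES,
    strata: Sequence[str] = ("all", "season"),
    group_map: TaxonGroupMap | None = None,
) -> AnalysisResult:
    """File-based pipeline: read the three tables, analyse, write a run dir."""
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hareselect")
    root.addHandler(handler)
    try:
        inventories = read_inventories(inventories_path)
        compositions = read_compositions(compositions_path)
        stomachs = read_stomachs(stomachs_path)
        result = analyse(
            inventories, compositions, stomachs,
            config=config, group_map=group_map, schemes=schemes, strata=strata,
        )
        result.manifest.input_digests = {
            "inventories": _digest(inventories_path),
            "compositions": _digest(compositions_path),
            "stomachs": _digest(stomachs_path),
        }
        result.records_frame().to_csv(out / "electivity.csv", index=False)
        result.summaries_frame().to_csv(out / "summary.csv", index=False)
        result.skipped_frame().to_csv(out / "skipped.csv", index=False)
        (out / "manifest.json").write_text(result.manifest.to_json(), encoding="utf-8")
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


def simulate(scenario_name: str, out_dir, seed: int, **overrides) -> SyntheticDataset:
    """Simulate a preset scenario and write its input tables to ``out_dir``."""
    presets = preset_scenarios()
    if scenario_name not in presets:
        raise ValidationError(
            f"unknown scenario {scenario_name!r}; choose from {sorted(presets)}"
        )
    scenario = presets[scenario_name]
    if overrides:
        from dataclasses import replace
        scenario = replace(scenario, **overrides)
    dataset = simulate_dataset(scenario, seed)
    write_dataset(dataset, out_dir)
    return dataset
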