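"""Eligibility, BCa bootstrap and stratified summaries."""

import numpy as np
import pytest
from scipy import stats

from hareselect import (
    AnalysisConfig,
    ElectivityRecord,
    bca_interval,
    classify_selection,
    eligible_items,
    percentile_interval,
    stratified_summaries,
)
from hareselect.errors import ValidationError
from hareselect.inference import _adjusted_percentiles, substream_seed


def record(hare, item, epsilon, alpha=0.2, scheme="taxa", season="winter",
           sex="female", age="adult", year=2003, m=4):
    return ElectivityRecord(
        hare_id=hare, scheme=scheme, item=item, alpha=alpha, epsilon=epsilon,
        m=m, season=season, year=year, sex=sex, age=age,
    )


class TestEligibility:
    def _records(self, n_users, n_nonusers=0, item="X"):
        recs = [record(f"H{i}", item, 0.1) for i in range(n_users)]
        recs += [record(f"Z{i}", item, -1.0, alpha=0.0) for i in range(n_nonusers)]
        return recs

    def test_six_users_excluded_seven_included(self):
        assert eligible_items(self._records(6), min_n=7) == []
        assert eligible_items(self._records(7), min_n=7) == [("taxa", "X")]

    def test_min_n_one_keeps_everything_used(self):
        assert eligible_items(self._records(1), min_n=1) == [("taxa", "X")]

    def test_available_basis_counts_nonusers(self):
        recs = self._records(5, n_nonusers=2)
        assert eligible_items(recs, min_n=7) == []
        assert eligible_items(recs, min_n=7, basis="available") == [("taxa", "X")]


class TestBcaInterval:
    def test_constant_sample_degenerates(self):
        with pytest.warns(UserWarning):
            lo, hi = bca_interval([0.3] * 10, seed=0)
        assert (lo, hi) == (0.3, 0.3)

    def test_reduces_to_percentile_when_corrections_vanish(self):
        """With z0 = 0 and a = 0 the BCa endpoints are exactly the simple
        percentile endpoints of the same resamples."""
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 40)
        forced = bca_interval(x, B=1000, seed=7, z0_override=0.0, acceleration_override=0.0)
        plain = percentile_interval(x, B=1000, seed=7)
        assert forced == plain
        diag = bca_interval(x, B=1000, seed=7, z0_override=0.0,
                            acceleration_override=0.0, return_diagnostics=True)
        assert diag["percentiles"] == (0.025, 0.975)
        assert forced == tuple(np.quantile(diag["boot_means"], [0.025, 0.975]))

    def test_adjusted_percentiles_identity_at_zero(self):
        lo, hi = _adjusted_percentiles(0.0, 0.0, 0.95)
        assert lo == pytest.approx(0.025, abs=1e-12)
        assert hi == pytest.approx(0.975, abs=1e-12)

    def test_agrees_with_scipy_bca(self):
        """Independent oracle: scipy's BCa on the same data (different
        resample streams, so agreement is approximate)."""
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 1.0, 60)  # skewed, so z0 and a both matter
        lo, hi = bca_interval(x, B=4000, seed=11)
        sp = stats.bootstrap(
            (x,), np.mean, n_resamples=4000, confidence_level=0.95,
            method="BCa", random_state=np.random.default_rng(5),
        ).confidence_interval
        width = sp.high - sp.low
        assert lo == pytest.approx(sp.low, abs=0.1 * width)
        assert hi == pytest.approx(sp.high, abs=0.1 * width)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(1).normal(size=25)
        assert bca_interval(x, seed=123) == bca_interval(x, seed=123)

    def test_wider_level_never_narrows(self):
        x = np.random.default_rng(2).normal(size=30)
        lo90, hi90 = bca_interval(x, B=2000, level=0.90, seed=9)
        lo99, hi99 = bca_interval(x, B=2000, level=0.99, seed=9)
        assert lo99 <= lo90 and hi99 >= hi90

    def test_needs_two_values_and_enough_resamples(self):
        with pytest.raises(ValidationError):
            bca_interval([1.0], seed=0)
        with pytest.raises(ValidationError):
            bca_interval([1.0, 2.0], B=10, seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "ci,expected",
        [((0.1, 0.5), "preference"), ((-0.1, 0.2), "none"), ((-0.5, 0.0), "none"),
         ((0.0, 0.4), "none"), ((-0.6, -0.2), "avoidance")],
    )
    def test_same_sign_rule_with_strict_zero(self, ci, expected):
        assert classify_selection(*ci) == expected


class TestStratifiedSummaries:
    def _records(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(20):
            season = "winter" if i < 12 else "spring"
            recs.append(record(f"H{i}", "X", float(rng.normal(0.4, 0.1)), season=season))
        for i in range(5):
            recs.append(record(f"S{i}", "Y", 0.2, season="winter"))
        return recs

    def test_small_stratum_skipped_with_reason(self):
        config = AnalysisConfig(min_n=7)
        summaries, skipped = stratified_summaries(self._records(), ("all",), config)
        assert [s.item for s in summaries] == ["X"]
        assert [(s.item, s.n) for s in skipped] == [("Y", 5)]
        assert "min_n" in skipped[0].reason

    def test_all_stratum_reproduces_unstratified(self):
        config = AnalysisConfig(min_n=7)
        all_sum, _ = stratified_summaries(self._records(), ("all",), config)
        both, _ = stratified_summaries(self._records(), ("all", "season"), config)
        assert [s for s in both if s.stratum == "all"] == all_sum

    def test_partitioning_strata_sum_to_overall_n(self):
        config = AnalysisConfig(min_n=1)
        summaries, skipped = stratified_summaries(self._records(), ("all", "season"), config)
        x = {s.stratum: s.n for s in summaries if s.item == "X"}
        assert x["all"] == x["season:winter"] + x["season:spring"]

    def test_identical_inputs_and_seed_are_bit_identical(self):
        config = AnalysisConfig(min_n=7, rng_seed=77)
        a, _ = stratified_summaries(self._records(), ("all", "season"), config)
        b, _ = stratified_summaries(self._records(), ("all", "season"), config)
        assert a == b

    def test_adding_an_item_leaves_other_intervals_untouched(self):
        """Per-item substreams: another item's records must not perturb X."""
        config = AnalysisConfig(min_n=7, rng_seed=5)
        base = self._records()
        extra = base + [record(f"Q{i}", "Z", 0.1 * i) for i in range(10)]
        a, _ = stratified_summaries(base, ("all",), config)
        b, _ = stratified_summaries(extra, ("all",), config)
        ax = next(s for s in a if s.item == "X")
        bx = next(s for s in b if s.item == "X")
        assert (ax.ci_low, ax.ci_high) == (bx.ci_low, bx.ci_high)

    def test_substreams_differ_between_items(self):
        s1 = substream_seed(1, "taxa", "X", "all")
        s2 = substream_seed(1, "taxa", "Y", "all")
        r1 = np.random.default_rng(s1).integers(0, 10**9)
        r2 = np.random.default_rng(s2).integers(0, 10**9)
        assert r1 != r2
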