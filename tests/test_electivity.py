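"""Manly's alpha, Chesson's electivity, pooling and per-hare records."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hareselect import (
    UseAvailabilityPair,
    chesson_epsilon,
    electivity_per_individual,
    manly_alpha,
    pool_to_groups,
)
from hareselect.electivity import apply_zero_availability_policy
from hareselect.errors import (
    DegenerateDietError,
    UndefinedIndexError,
    ValidationError,
)
from conftest import make_inventory, make_profile, make_stomach


def alpha_oracle(use, avail):
    """Ratio normalisation in exact rational arithmetic."""
    ratios = [Fraction(u).limit_denominator(10**9) / Fraction(a).limit_denominator(10**9)
              for u, a in zip(use, avail)]
    total = sum(ratios)
    return [float(r / total) for r in ratios]


class TestManlyAlpha:
    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    def test_neutral_forager_gets_uniform_alpha(self, m):
        v = np.full(m, 1.0 / m)
        assert np.allclose(manly_alpha(v, v), 1.0 / m, atol=1e-15)

    def test_ratio_normalisation_matches_hand_computation(self):
        alpha = manly_alpha([0.5, 0.5, 0.0], [0.25, 0.25, 0.5])
        assert np.allclose(alpha, [0.5, 0.5, 0.0], atol=1e-15)

    def test_exclusive_use_concentrates_alpha(self):
        alpha = manly_alpha([1.0, 0.0, 0.0], [0.2, 0.3, 0.5])
        assert np.allclose(alpha, [1.0, 0.0, 0.0])

    def test_zero_total_use_is_degenerate(self):
        with pytest.raises(DegenerateDietError):
            manly_alpha([0.0, 0.0], [0.5, 0.5])

    def test_zero_availability_is_contract_violation(self):
        with pytest.raises(ValidationError):
            manly_alpha([0.5, 0.5], [1.0, 0.0])

    def test_brute_force_oracle_on_random_rational_instances(self, rng):
        """Formula vs exact ratio normalisation, 1000 instances with m <= 6."""
        worst = 0.0
        for _ in range(1000):
            m = int(rng.integers(2, 7))
            use = rng.integers(0, 10, m).astype(float)
            if use.sum() == 0:
                use[int(rng.integers(m))] = 1.0
            avail = rng.integers(1, 10, m).astype(float)
            use /= use.sum()
            avail /= avail.sum()
            got = manly_alpha(use, avail)
            want = alpha_oracle(use, avail)
            worst = max(worst, float(np.max(np.abs(np.asarray(want) - got))))
        assert worst < 1e-12


class TestChessonEpsilon:
    @pytest.mark.parametrize("m", [2, 3, 4, 7, 12])
    def test_neutral_alpha_gives_zero(self, m):
        assert chesson_epsilon(1.0 / m, m) == pytest.approx(0.0, abs=1e-15)

    def test_bounds_attained_exactly(self):
        assert chesson_epsilon(1.0, 4) == 1.0
        assert chesson_epsilon(0.0, 4) == -1.0

    def test_half_alpha_four_items(self):
        # (4*0.5 - 1) / (2*0.5 + 1) = 1/2
        assert chesson_epsilon(0.5, 4) == pytest.approx(0.5, abs=1e-15)

    def test_m_below_two_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            chesson_epsilon(0.5, 1)

    @given(
        m=st.integers(2, 10),
        a1=st.floats(0, 1),
        a2=st.floats(0, 1),
    )
    def test_strictly_increasing_in_alpha(self, m, a1, a2):
        if a1 == a2:
            return
        lo, hi = sorted((a1, a2))
        assert chesson_epsilon(lo, m) <= chesson_epsilon(hi, m)

    @given(m=st.integers(2, 10), alpha=st.floats(0, 1))
    def test_range_is_minus_one_to_one(self, m, alpha):
        eps = chesson_epsilon(alpha, m)
        assert -1.0 <= eps <= 1.0


class TestZeroAvailabilityPolicy:
    def test_drop_renormalise_removes_unavailable_used_items(self):
        items, u, a, dropped = apply_zero_availability_policy(
            ("A", "B", "C"), np.array([0.5, 0.3, 0.2]), np.array([0.6, 0.4, 0.0]),
            "drop_renormalise",
        )
        assert items == ("A", "B") and dropped == ("C",)
        assert np.allclose(u, [0.625, 0.375]) and np.allclose(a, [0.6, 0.4])

    def test_drop_renormalise_empty_diet_is_degenerate(self):
        with pytest.raises(DegenerateDietError):
            apply_zero_availability_policy(
                ("A", "B"), np.array([0.0, 1.0]), np.array([1.0, 0.0]), "drop_renormalise"
            )

    def test_floor_keeps_used_items_with_tiny_availability(self):
        items, u, a, dropped = apply_zero_availability_policy(
            ("A", "B"), np.array([0.5, 0.5]), np.array([1.0, 0.0]), "floor", 1e-6
        )
        assert items == ("A", "B") and dropped == ()
        assert a[1] > 0 and np.isclose(a.sum(), 1.0)


class TestPoolToGroups:
    def _pair(self, items, use, avail):
        return UseAvailabilityPair("H1", "taxa", tuple(items), np.asarray(use, float),
                                   np.asarray(avail, float))

    def test_member_availability_adds_up(self, group_map):
        pair = self._pair(
            ["Hordeum vulgare", "Triticum aestivum", "Medicago sativa"],
            [0.2, 0.3, 0.5], [0.1, 0.2, 0.7],
        )
        pooled = pool_to_groups(pair, group_map)
        got = dict(zip(pooled.items, pooled.availability))
        assert got["cereals"] == pytest.approx(0.3)
        assert got["weeds/grasses"] == pytest.approx(0.7)

    def test_pooling_then_alpha_equals_alpha_on_presummed_vectors(self, group_map):
        pair = self._pair(
            ["Hordeum vulgare", "Zea mays", "Beta vulgaris", "Stellaria media"],
            [0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.25, 0.25],
        )
        pooled = pool_to_groups(pair, group_map)
        alpha = manly_alpha(pooled.use, pooled.availability)
        want = manly_alpha([0.3, 0.3, 0.4], [0.5, 0.25, 0.25])
        assert np.allclose(alpha, want)

    def test_single_group_pair_is_degenerate_downstream(self, group_map):
        pair = self._pair(["Hordeum vulgare", "Zea mays"], [0.4, 0.6], [0.5, 0.5])
        pooled = pool_to_groups(pair, group_map)
        assert pooled.items == ("cereals",) and pooled.m == 1
        with pytest.raises(UndefinedIndexError):
            chesson_epsilon(1.0, pooled.m)


class TestPerIndividual:
    def test_chemical_schemes_have_fixed_m(self, config, group_map):
        from hareselect import chemical_availability
        from hareselect.vocab import canonical

        inv = make_inventory(taxa=(("Poa sp.", 1.0),))
        comps = {(canonical("Poa sp."), "winter"): make_profile()}
        ca = chemical_availability(inv, comps)
        stomach = make_stomach(diet=(("Poa sp.", 1.0),))
        dm_recs = electivity_per_individual(stomach, inv, ca, "dm", config)
        fa_recs = electivity_per_individual(stomach, inv, ca, "fa", config)
        assert {r.m for r in dm_recs} == {5} and len(dm_recs) == 5
        assert {r.m for r in fa_recs} == {7} and len(fa_recs) == 7

    def test_diet_of_unavailable_taxon_excludes_hare_under_drop_policy(self, config):
        inv = make_inventory(taxa=(("Poa sp.", 0.5), ("Bromus sp.", 0.5)))
        stomach = make_stomach(diet=(("Zea mays", 1.0),))
        assert electivity_per_individual(stomach, inv, None, "taxa", config) == []

    def test_neutral_hare_scores_zero_on_all_schemes(self, config, group_map):
        """Stomach equal to availability → epsilon 0 everywhere."""
        from hareselect import chemical_availability
        from hareselect.vocab import canonical

        taxa = (("Hordeum vulgare", 0.5), ("Medicago sativa", 0.3), ("Beta vulgaris", 0.2))
        inv = make_inventory(taxa=taxa)
        comps = {
            (canonical(t), "winter"): make_profile()
            for t, _ in taxa
        }
        ca = chemical_availability(inv, comps)
        stomach = make_stomach(
            diet=taxa,
            profile=make_profile(
                dm={c: v * 1000 for c, v in ca.dm_available.items()},
                fa=dict(ca.fa_available),
            ),
        )
        for scheme in ("taxa", "groups", "dm", "fa"):
            recs = electivity_per_individual(
                stomach, inv, ca, scheme, config, group_map=group_map
            )
            assert recs, scheme
            assert all(abs(r.epsilon) < 1e-9 for r in recs), scheme

    def test_alpha_sums_to_one_per_scheme(self, config, group_map, rng):
        from hareselect import chemical_availability
        from hareselect.vocab import canonical

        taxa_names = ["Hordeum vulgare", "Medicago sativa", "Beta vulgaris", "Zea mays"]
        a = rng.dirichlet(np.ones(4))
        u = rng.dirichlet(np.ones(4))
        inv = make_inventory(taxa=tuple(zip(taxa_names, a)))
        comps = {(canonical(t), "winter"): make_profile() for t in taxa_names}
        ca = chemical_availability(inv, comps)
        stomach = make_stomach(diet=tuple(zip(taxa_names, u)))
        for scheme in ("taxa", "groups", "dm", "fa"):
            recs = electivity_per_individual(stomach, inv, ca, scheme, config, group_map=group_map)
            assert sum(r.alpha for r in recs) == pytest.approx(1.0, abs=1e-9)
            assert all(-1.0 <= r.epsilon <= 1.0 for r in recs)

    def test_scheme_results_are_independent(self, config, group_map):
        """Taxa records do not change when chemical schemes are also computed."""
        from hareselect import chemical_availability
        from hareselect.vocab import canonical

        taxa = (("Hordeum vulgare", 0.6), ("Medicago sativa", 0.4))
        inv = make_inventory(taxa=taxa)
        comps = {(canonical(t), "winter"): make_profile() for t, _ in taxa}
        ca = chemical_availability(inv, comps)
        stomach = make_stomach(diet=(("Hordeum vulgare", 0.3), ("Medicago sativa", 0.7)))
        alone = electivity_per_individual(stomach, inv, None, "taxa", config)
        with_chem = electivity_per_individual(stomach, inv, ca, "taxa", config)
        assert alone == with_chem

    def test_monotone_use_never_decreases_epsilon(self, config):
        """Raising one item's use (others renormalised) cannot lower its epsilon."""
        avail = np.array([0.3, 0.3, 0.4])
        last = -np.inf
        for u0 in np.linspace(0.05, 0.95, 10):
            rest = (1 - u0) * np.array([0.5, 0.5])
            alpha = manly_alpha([u0, *rest], avail)
            eps = chesson_epsilon(alpha[0], 3)
            assert eps >= last - 1e-12
            last = eps
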