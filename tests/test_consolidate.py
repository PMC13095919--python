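"""Exact Wilcoxon signed-rank test, pair tests, eligibility, merge plans."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon
from shapely.geometry import box

from heatregions import spatial as sp
from heatregions.consolidate import (
    MergeDirective,
    MergePlan,
    apply_merges,
    merge_eligibility,
    pairwise_region_tests,
    propose_merges,
    wilcoxon_signed_rank_exact,
)


def brute_force_wilcoxon(diffs):
    """Independent oracle: enumerate every sign pattern explicitly."""
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0]
    m = len(nz)
    ranks = rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=m)
    ]
    stats = np.array(stats)
    p_ge = (stats >= w_obs - 1e-12).mean()
    p_le = (stats <= w_obs + 1e-12).mean()
    return w_obs, min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxonExact:
    def test_five_same_signed_differences_give_p_0625(self):
        res = wilcoxon_signed_rank_exact([2.6, 2.4, 2.2, 2.8, 3.1])
        assert res.w_plus == 15.0
        assert res.p_two_sided == 0.0625
        assert round(res.p_two_sided, 2) == 0.06

    def test_antisymmetric_pair_is_uninformative(self):
        assert wilcoxon_signed_rank_exact([1.0, -1.0]).p_two_sided == 1.0

    def test_all_zero_input_degenerates_to_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank_exact([0.0, 0.0, 0.0])
        assert res.p_two_sided == 1.0
        assert res.method == "degenerate"

    def test_matches_brute_force_enumeration(self):
        # 200 random cases, m <= 10, with ties and zeros
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(1, 11)
            d = rng.integers(-4, 5, size=m).astype(float) / 2.0
            if not np.any(d):
                d[0] = 1.0
            res = wilcoxon_signed_rank_exact(d)
            w_o, p_o = brute_force_wilcoxon(d)
            assert res.w_plus == pytest.approx(w_o)
            assert res.p_two_sided == pytest.approx(p_o, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            d = rng.normal(size=8)  # continuous: no ties or zeros
            ours = wilcoxon_signed_rank_exact(d)
            ref = scipy_wilcoxon(d, method="exact", alternative="two-sided")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_m_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.3, 1.0, size=30)
        res = wilcoxon_signed_rank_exact(d)
        assert res.method == "normal"
        ref = scipy_wilcoxon(d, method="approx", correction=True).pvalue
        assert res.p_two_sided == pytest.approx(ref, rel=1e-6)

    @given(
        d=st.lists(
            st.floats(0.1, 10.0), min_size=5, max_size=5
        ),
        flip=st.booleans(),
    )
    def test_minimum_two_sided_p_at_five_pairs(self, d, flip):
        # any uniformly signed 5-vector attains exactly 2/32
        signs = -1.0 if flip else 1.0
        res = wilcoxon_signed_rank_exact(signs * np.asarray(d))
        assert res.p_two_sided == 0.0625

    @given(d=st.lists(st.floats(-5, 5).filter(lambda x: x != 0), min_size=1, max_size=12))
    def test_sign_flip_symmetry(self, d):
        a = wilcoxon_signed_rank_exact(d)
        b = wilcoxon_signed_rank_exact([-x for x in d])
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)
        assert a.w_plus + b.w_plus == pytest.approx(len(d) * (len(d) + 1) / 2)


class TestPairTests:
    @staticmethod
    def _monthly():
        return pd.DataFrame(
            {
                5: [20.0, 20.0, 23.0],
                6: [24.0, 24.0, 26.5],
                7: [28.0, 28.0, 30.1],
                8: [27.0, 27.0, 29.3],
                9: [22.0, 22.0, 25.0],
            },
            index=["A", "B", "C"],
        )

    def test_identical_regions_are_not_significant(self):
        tests = pairwise_region_tests(self._monthly(), alpha=0.1)
        t = tests[frozenset(("A", "B"))]
        assert t.p_two_sided == 1.0
        assert not t.significant

    def test_uniformly_warmer_region_is_not_significant_at_alpha_01(self):
        # p floor at five pairs is 0.0625 < 0.1, so uniform sign IS significant
        tests = pairwise_region_tests(self._monthly(), alpha=0.1)
        t = tests[frozenset(("A", "C"))]
        assert t.p_two_sided == 0.0625
        assert t.significant  # 0.0625 < 0.1
        # at alpha = 0.05 the same pair is not significant
        tests05 = pairwise_region_tests(self._monthly(), alpha=0.05)
        assert not tests05[frozenset(("A", "C"))].significant

    def test_flags_symmetric_in_pair_order(self):
        monthly = self._monthly()
        a = pairwise_region_tests(monthly, pairs=[("A", "C")])[frozenset(("A", "C"))]
        b = pairwise_region_tests(monthly, pairs=[("C", "A")])[frozenset(("A", "C"))]
        assert a.p_two_sided == b.p_two_sided
        assert a.significant == b.significant

    def test_missing_months_rejected(self):
        monthly = self._monthly()
        monthly.loc["A", 9] = np.nan
        with pytest.raises(ValueError):
            pairwise_region_tests(monthly)


class TestEligibility:
    def test_strict_threshold_boundary(self):
        pops = {"A": 10_999.0, "B": 11_000.0, "C": 5_000.0}
        eligible = merge_eligibility(pops, fragmented=["A", "B"], threshold=11_000)
        assert eligible == {"A"}  # "fewer than" is strict; B at the threshold stays

    def test_fragmentation_required_under_conjunctive_rule(self):
        pops = {"A": 5_000.0, "B": 20_000.0}
        assert merge_eligibility(pops, fragmented=["B"], threshold=11_000) == set()
        assert merge_eligibility(pops, fragmented=["B"], threshold=11_000, rule="disjunctive") == {
            "A",
            "B",
        }

    def test_percentile_threshold(self):
        pops = {str(i): float(i * 1000) for i in range(1, 11)}
        eligible = merge_eligibility(pops, fragmented=list(pops), percentile=10)
        # 10th percentile of 1k..10k (linear interpolation) = 1900
        assert eligible == {"1"}


def _four_region_scene():
    """Row of boxes: A | B | A | C | D with A fragmented."""
    cells = [box(i, 0, i + 1, 1) for i in range(5)]
    return sp.dissolve_by_label(cells, ["A", "B", "A", "C", "D"])


def _tests_from_diffs(diffs_by_pair):
    out = {}
    for (a, b), diffs in diffs_by_pair.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon_signed_rank_exact(diffs)
        from heatregions.consolidate import PairTest

        out[frozenset((a, b))] = PairTest(
            a, b, np.asarray(diffs, dtype=float), res.w_plus, res.p_two_sided,
            res.p_two_sided < 0.1,
        )
    return out


class TestProposeAndApply:
    def test_single_admissible_partner_is_chosen(self):
        regions = sp.dissolve_by_label([box(0, 0, 1, 1), box(1, 0, 2, 1)], ["A", "B"])
        tests = _tests_from_diffs({("A", "B"): [0.1, -0.2, 0.1, 0.0, -0.1]})
        plan = propose_merges({"A"}, tests, regions)
        assert [(d.source, d.target) for d in plan.directives] == [("A", "B")]

    def test_candidates_ranked_by_mean_absolute_difference(self):
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(0, 1, 1, 2)]
        regions = sp.dissolve_by_label(cells, ["A", "B", "C"])
        tests = _tests_from_diffs(
            {
                ("A", "B"): [1.2, -1.1, 1.1, -1.0, 1.1],  # mean |diff| = 1.1
                ("A", "C"): [0.4, -0.3, 0.2, -0.3, 0.3],  # mean |diff| = 0.3
            }
        )
        plan = propose_merges({"A"}, tests, regions)
        assert plan.directives[0].target == "C"

    def test_fragments_can_take_different_targets(self):
        regions = _four_region_scene()
        tests = _tests_from_diffs(
            {
                ("A", "B"): [0.2, -0.2, 0.3, -0.3, 0.2],  # mean |diff| 0.24
                ("A", "C"): [0.05, -0.05, 0.05, -0.05, 0.05],  # mean |diff| 0.05
            }
        )
        plan = propose_merges({"A"}, tests, regions)
        # fragment 0 (x in [0,1]) only touches B; fragment 1 touches B and C
        # and prefers C on the smaller monthly differences
        by_frag = {d.fragment_index: d.target for d in plan.directives}
        assert len(plan.directives) == 2
        assert by_frag == {0: "B", 1: "C"}

    def test_region_with_no_admissible_partner_left_unmerged(self):
        regions = sp.dissolve_by_label([box(0, 0, 1, 1), box(1, 0, 2, 1)], ["A", "B"])
        tests = _tests_from_diffs({("A", "B"): [2.0, 2.1, 2.2, 2.3, 2.4]})  # p=0.0625<0.1
        plan = propose_merges({"A"}, tests, regions)
        assert plan.directives == []
        assert plan.unmerged == ["A"]

    def test_covariate_gate_excludes_dissimilar_partner(self):
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(0, 1, 1, 2)]
        regions = sp.dissolve_by_label(cells, ["A", "B", "C"])
        tests = _tests_from_diffs(
            {
                ("A", "B"): [0.1, -0.1, 0.1, -0.1, 0.1],
                ("A", "C"): [0.5, -0.5, 0.5, -0.5, 0.5],
            }
        )
        cov = {"A": 100.0, "B": 2000.0, "C": 150.0}  # elevation-style
        plan = propose_merges({"A"}, tests, regions, covariate=cov, tau=500.0)
        assert plan.directives[0].target == "C"

    def test_relaxing_alpha_never_shrinks_admissible_partners(self):
        # a merge needs p >= alpha, so lowering alpha can only admit more
        # partners, never fewer
        regions = _four_region_scene()
        tests = _tests_from_diffs(
            {
                ("A", "B"): [0.1, -0.1, 0.2, -0.2, 0.1],
                ("A", "C"): [0.3, 0.2, 0.1, 0.3, -0.2],
            }
        )
        admissible = {}
        for alpha in (0.05, 0.1, 0.3, 0.6):
            plan = propose_merges({"A"}, tests, regions, alpha=alpha)
            admissible[alpha] = {(d.fragment_index, d.target) for d in plan.directives}
        alphas = sorted(admissible)
        for lo, hi in zip(alphas, alphas[1:]):
            assert admissible[hi] <= admissible[lo]

    def test_empty_plan_is_identity(self, regions35):
        merged, _ = apply_merges(regions35, MergePlan())
        assert sorted(merged) == sorted(regions35)

    def test_cyclic_plan_rejected(self):
        plan = MergePlan([MergeDirective("A", "B"), MergeDirective("B", "C")])
        with pytest.raises(ValueError, match="cyclic"):
            plan.validate()

    def test_duplicate_source_rejected(self):
        plan = MergePlan([MergeDirective("A", "B"), MergeDirective("A", "C")])
        with pytest.raises(ValueError):
            plan.validate()

    def test_merge_conserves_area_and_population(self, regions35):
        plan = MergePlan(
            [
                MergeDirective("5", "4"),
                MergeDirective("7", "8", fragment_index=0),
                MergeDirective("7", "17", fragment_index=1),
                MergeDirective("22", "24"),
                MergeDirective("27", "29"),
                MergeDirective("30", "31"),
            ]
        )
        zips = [
            sp.ZipUnit(f"Z{i}", box(i + 0.25, 0.25, i + 0.75, 0.75), 100.0)
            for i in range(36)
        ]
        for z in zips:
            z.weighted_centroid = z.polygon.centroid
        sp.assign_zip_to_region(zips, regions35)
        merged, assignments = apply_merges(regions35, plan, zips)
        assert sum(r.area for r in merged.values()) == pytest.approx(36.0, rel=1e-9)
        pops = sp.region_population(
            assignments, {z.zip_id: 100.0 for z in zips}, merged.keys()
        )
        assert sum(pops.values()) == 3600.0
        assert set(assignments) == {z.zip_id for z in zips}
        assert set(assignments.values()) <= set(merged)
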