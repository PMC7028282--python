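"""Tests for value-choice Monte Carlo, enumeration and one-way sensitivity."""

import dataclasses
from collections import Counter

import numpy as np
import pytest

from rsbr import (
    FactorPools,
    HandprintNormalizationSet,
    MonteCarloConfig,
    NormalizationSet,
    SensitivityAxis,
    ValidationError,
    WeightingSet,
    enumerate_combinations,
    one_way_sensitivity,
    paper_shaped_pools,
    run_monte_carlo,
    sample_iteration,
)

from conftest import make_pools


class TestFactorPools:
    def test_paper_shaped_combination_count(self):
        assert paper_shaped_pools(seed=0).combination_count == 4 * 4 * 26 * 3 == 1248

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            FactorPools(footprint_nfs=[], handprint_nfs=[], wf_main_sets={})

    def test_empty_main_set_rejected(self, sth_reference):
        nf, hnf, wf = sth_reference
        with pytest.raises(ValidationError):
            FactorPools(
                footprint_nfs=[nf],
                handprint_nfs=[hnf],
                wf_main_sets={"a": [wf], "b": []},
            )


class TestSampleIteration:
    def test_hierarchical_frequencies(self):
        """Main sets are equiprobable; sub-sets uniform within their set.

        With panels of 4/19/3 sub-sets each panel has probability 1/3, each
        sub-set of the 4-member panel 1/3 x 1/4 = 8.33%, and each of the
        19-member panel 1/3 x 1/19 = 1.75%.
        """
        pools = paper_shaped_pools(seed=0)
        rng = np.random.default_rng(12345)
        n = 100_000
        main_counts: Counter = Counter()
        sub_counts: Counter = Counter()
        for _ in range(n):
            _, _, wf, _ = sample_iteration(pools, rng)
            main_counts[wf.main_set] += 1
            sub_counts[wf.id] += 1
        assert main_counts["EI99"] / n == pytest.approx(1 / 3, abs=0.005)
        for wf in pools.wf_main_sets["EI99"]:
            assert sub_counts[wf.id] / n == pytest.approx(1 / 12, abs=0.005)
        for wf in pools.wf_main_sets["Itsubo"]:
            assert sub_counts[wf.id] / n == pytest.approx(1 / 57, abs=0.003)

    def test_singleton_pools_deterministic(self, singleton_pools):
        rng = np.random.default_rng(0)
        draws = {sample_iteration(singleton_pools, rng) for _ in range(10)}
        assert len(draws) == 1

    def test_nf_draws_uniform(self, small_pools):
        rng = np.random.default_rng(5)
        counts = Counter(
            sample_iteration(small_pools, rng)[0].id for _ in range(20_000)
        )
        for nf in small_pools.footprint_nfs:
            assert counts[nf.id] / 20_000 == pytest.approx(
                1 / len(small_pools.footprint_nfs), abs=0.02
            )


class TestEnumeration:
    def test_paper_shaped_row_count(self, sth_case):
        table = enumerate_combinations(sth_case, paper_shaped_pools(seed=0))
        assert len(table) == 1248

    def test_single_combination(self, sth_case, singleton_pools):
        assert len(enumerate_combinations(sth_case, singleton_pools)) == 1

    def test_cross_check_30_rows_bracket_samples(self, sth_case):
        pools = make_pools(n_fp=2, n_hp=3, wf_shape=(5,), variants=("base",))
        table = enumerate_combinations(sth_case, pools)
        assert len(table) == 30
        enum_values = set(np.round(table["combined_rsbr"].astype(float), 9))
        cfg = MonteCarloConfig(pools=pools, iterations=200, seed=3)
        summary = run_monte_carlo(sth_case, cfg, keep_samples=True)
        sampled = set(np.round(summary.samples["combined_rsbr"].astype(float), 9))
        assert sampled <= enum_values
        assert summary.combined_rsbr.min >= table["combined_rsbr"].min() - 1e-12
        assert summary.combined_rsbr.max <= table["combined_rsbr"].max() + 1e-12

    def test_provenance_columns(self, sth_case, small_pools):
        table = enumerate_combinations(sth_case, small_pools)
        for col in ("nf_id", "handprint_nf_id", "wf_id", "variant"):
            assert col in table.columns


class TestMonteCarlo:
    def test_degenerate_equals_deterministic(self, sth_case, singleton_pools, sth_reference):
        """Pools collapsed to the reference set reproduce the pipeline value."""
        from rsbr import evaluate_case

        cfg = MonteCarloConfig(pools=singleton_pools, iterations=50, seed=1)
        summary = run_monte_carlo(sth_case, cfg)
        exact = evaluate_case(sth_case, *sth_reference).combined_rsbr
        stats = summary.combined_rsbr
        assert stats.median == stats.min == stats.max == pytest.approx(exact, rel=1e-12)
        assert exact == pytest.approx(56.25, abs=0.15)

    def test_same_seed_identical_different_seed_differs(self, sth_case, small_pools):
        cfg = MonteCarloConfig(pools=small_pools, iterations=300, seed=11)
        a = run_monte_carlo(sth_case, cfg)
        b = run_monte_carlo(sth_case, cfg)
        assert dataclasses.asdict(a.combined_rsbr) == dataclasses.asdict(b.combined_rsbr)
        assert a.single_scores == b.single_scores
        c = run_monte_carlo(
            sth_case, MonteCarloConfig(pools=small_pools, iterations=300, seed=12)
        )
        assert dataclasses.asdict(a.combined_rsbr) != dataclasses.asdict(c.combined_rsbr)

    def test_median_brackets_exact_enumeration_median(self, sth_case):
        """The MC median sits between the enumeration order statistics
        adjacent to the exact median (small enumerable pools, 10k draws)."""
        pools = make_pools(n_fp=2, n_hp=2, wf_shape=(3,), variants=("base",))
        table = enumerate_combinations(sth_case, pools)
        values = np.sort(table["combined_rsbr"].astype(float).to_numpy())
        cfg = MonteCarloConfig(pools=pools, iterations=10_000, seed=7)
        summary = run_monte_carlo(sth_case, cfg)
        k = len(values) // 2
        lo, hi = values[max(k - 1, 0)], values[min(k + 1, len(values) - 1)]
        assert lo - 1e-9 <= summary.combined_rsbr.median <= hi + 1e-9

    def test_na_iterations_counted_and_excluded(self, small_pools):
        """A footprint-only comparison with an unassessed comparator yields
        NA footprint RSBRs that are counted, not folded into statistics."""
        from rsbr import CaseStudy, HandprintEstimate, ImpactVector, Scenario

        case = CaseStudy(
            name="na_case",
            comparator=Scenario(
                name="c",
                footprint=ImpactVector(),
                handprint=HandprintEstimate(base=10, min=9, max=11),
            ),
            treatment=Scenario(
                name="t",
                footprint=ImpactVector(human_health=1, ecosystems=1, resources=1),
                handprint=HandprintEstimate(base=5, min=4, max=6),
            ),
        )
        cfg = MonteCarloConfig(pools=small_pools, iterations=40, seed=2)
        summary = run_monte_carlo(case, cfg)
        assert summary.na_counts["footprint_rsbr"] == 40
        assert summary.footprint_rsbr is None
        assert summary.combined_rsbr is not None

    def test_variant_override(self, sth_case, small_pools):
        cfg = MonteCarloConfig(pools=small_pools, iterations=30, seed=4, variant="base")
        summary = run_monte_carlo(sth_case, cfg, keep_samples=True)
        assert set(summary.samples["variant"]) == {"base"}

    def test_summary_orderings(self, sth_case, small_pools):
        cfg = MonteCarloConfig(pools=small_pools, iterations=500, seed=9)
        s = run_monte_carlo(sth_case, cfg).combined_rsbr
        assert s.min <= s.p2_5 <= s.median <= s.p97_5 <= s.max

    def test_handprint_only_case_constant_per_variant(self, small_pools):
        """Scale invariance: with no footprints, every iteration with the
        same variant yields the same RSBR regardless of factors drawn."""
        from rsbr import CaseStudy, HandprintEstimate, Scenario

        case = CaseStudy(
            name="hp_only",
            comparator=Scenario(name="c", handprint=HandprintEstimate(base=100, min=90, max=110)),
            treatment=Scenario(name="t", handprint=HandprintEstimate(base=60, min=50, max=70)),
        )
        cfg = MonteCarloConfig(pools=small_pools, iterations=60, seed=5, variant="base")
        summary = run_monte_carlo(case, cfg)
        assert summary.combined_rsbr.min == pytest.approx(summary.combined_rsbr.max)
        assert summary.combined_rsbr.median == pytest.approx(40.0)


class TestOneWaySensitivity:
    def test_single_wf_axis_zero_spread(self, sth_case, sth_reference):
        nf, hnf, wf = sth_reference
        pools = FactorPools(
            footprint_nfs=[nf],
            handprint_nfs=[hnf],
            wf_main_sets={wf.main_set: [wf]},
            handprint_variants=("base",),
        )
        res = one_way_sensitivity(
            sth_case, SensitivityAxis.FIX_NF_VARY_WF, pools, (nf, hnf, wf),
            iterations=50, seed=1,
        )
        for name in res.single_scores:
            assert res.spread(name) == pytest.approx(0.0, abs=1e-18)

    def test_constructed_dominance_ordering(self, sth_case, sth_reference):
        """Wildly differing weights with near-identical NFs must show more
        spread when varying WF than when varying NF."""
        nf, hnf, wf = sth_reference
        wfs = [
            WeightingSet(id="w_hh", main_set="m", human_health=0.98, ecosystems=0.01, resources=0.01),
            WeightingSet(id="w_eco", main_set="m", human_health=0.01, ecosystems=0.98, resources=0.01),
            WeightingSet(id="w_res", main_set="m", human_health=0.01, ecosystems=0.01, resources=0.98),
        ]
        nfs = [
            NormalizationSet(
                id=f"nf{i}",
                human_health=nf.human_health * (1 + 1e-4 * i),
                ecosystems=nf.ecosystems * (1 + 1e-4 * i),
                resources=nf.resources * (1 + 1e-4 * i),
            )
            for i in range(3)
        ]
        hnfs = [
            HandprintNormalizationSet(id=f"h{i}", factor=hnf.factor * (1 + 1e-4 * i))
            for i in range(3)
        ]
        pools = FactorPools(
            footprint_nfs=nfs, handprint_nfs=hnfs,
            wf_main_sets={"m": wfs}, handprint_variants=("base",),
        )
        vary_wf = one_way_sensitivity(
            sth_case, SensitivityAxis.FIX_NF_VARY_WF, pools, (nfs[0], hnfs[0], wfs[0]),
            iterations=200, seed=2,
        )
        vary_nf = one_way_sensitivity(
            sth_case, SensitivityAxis.FIX_WF_VARY_NF, pools, (nfs[0], hnfs[0], wfs[0]),
            iterations=200, seed=2,
        )
        name = sth_case.treatment.name
        assert vary_wf.spread(name) > vary_nf.spread(name)

    def test_both_singleton_deterministic(self, sth_case, singleton_pools, sth_reference):
        from rsbr import score_scenario

        nf, hnf, wf = sth_reference
        exact = score_scenario(sth_case.treatment, nf, hnf, wf).score
        for axis in SensitivityAxis:
            res = one_way_sensitivity(
                sth_case, axis, singleton_pools, (nf, hnf, wf), iterations=20, seed=0
            )
            s = res.single_scores[sth_case.treatment.name]
            assert s.min == s.max == pytest.approx(exact, rel=1e-12)
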