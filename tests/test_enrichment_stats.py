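"""Hypergeometric, trendline normalization, triplet tables, t-tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from repag import enrichment_stats as es


def enumerate_tail(k: int, n: int, K: int, N: int) -> float:
    """Oracle: enumerate every possible draw of n from a labelled population."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_worked_example_exact_fraction(self):
        assert es.hypergeometric_tail(4, 4, 5, 10) == pytest.approx(
            5 / 210, abs=1e-15
        )

    def test_k_zero_is_full_tail(self):
        assert es.hypergeometric_tail(0, 4, 5, 10) == 1.0

    def test_all_successes_population(self):
        assert es.hypergeometric_tail(3, 3, 8, 8) == 1.0

    @pytest.mark.parametrize("N,K,n", [(6, 3, 3), (8, 5, 4), (9, 2, 5)])
    def test_matches_enumeration_oracle(self, N, K, n):
        for k in range(n + 1):
            assert es.hypergeometric_tail(k, n, K, N) == pytest.approx(
                enumerate_tail(k, n, K, N), abs=1e-12
            )

    def test_lower_tail_complements_upper(self):
        p_lo = es.hypergeometric_lower_tail(2, 4, 5, 10)
        p_hi = es.hypergeometric_tail(3, 4, 5, 10)
        assert p_lo + p_hi == pytest.approx(1.0, abs=1e-12)

    def test_impossible_parameters_rejected(self):
        with pytest.raises(ValueError):
            es.hypergeometric_tail(5, 4, 5, 10)
        with pytest.raises(ValueError):
            es.hypergeometric_tail(1, 11, 5, 10)


class TestTrendline:
    def test_collinear_points_recovered_exactly(self):
        fit = es.fit_trendline([(30, 10), (40, 14), (50, 18)])
        assert fit.slope == pytest.approx(0.4)
        assert fit.intercept == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_gives_zero_slope_and_r2(self):
        fit = es.fit_trendline([(30, 5), (40, 5), (50, 5)])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            es.fit_trendline([(30, 10), (40, 14)])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            es.fit_trendline([(30, 10), (30, 14), (30, 18)])


def _summary(species, group, repag, purine=1000, total=10000, g=40.0):
    return es.SpeciesSummary(species, group, total, purine, repag, g)


class TestEnrichmentIndex:
    def test_single_fungal_species_self_normalizes_to_one(self):
        fit = es.TrendlineFit(slope=0.0, intercept=10.0, r_squared=0.0)
        [idx] = es.enrichment_index([_summary("f1", "fungi", 100)], fit, ["f1"])
        assert idx.normalized == 1.0

    def test_double_raw_ratio_normalizes_to_two(self):
        fit = es.TrendlineFit(0.0, 10.0, 0.0)
        out = es.enrichment_index(
            [_summary("f1", "fungi", 100), _summary("m1", "metazoa", 200)],
            fit, ["f1"],
        )
        by = {i.species: i for i in out}
        assert by["m1"].normalized == pytest.approx(2.0)

    def test_rescaling_invariance(self):
        # multiplying every repag% by a constant leaves normalized unchanged
        fit = es.TrendlineFit(0.0, 10.0, 0.0)
        base = [_summary("f1", "fungi", 80), _summary("f2", "fungi", 120),
                _summary("m1", "metazoa", 300)]
        scaled = [_summary("f1", "fungi", 160, purine=2000),
                  _summary("f2", "fungi", 240, purine=2000),
                  _summary("m1", "metazoa", 600, purine=2000)]
        a = {i.species: i.normalized for i in es.enrichment_index(base, fit, ["f1", "f2"])}
        b = {i.species: i.normalized for i in es.enrichment_index(scaled, fit, ["f1", "f2"])}
        for sp in a:
            assert a[sp] == pytest.approx(b[sp])

    def test_fungal_mean_exactly_one(self):
        fit = es.TrendlineFit(0.1, 5.0, 0.5)
        out = es.enrichment_index(
            [_summary(f"f{i}", "fungi", 50 + 30 * i, g=30 + 5 * i)
             for i in range(5)],
            fit, [f"f{i}" for i in range(5)],
        )
        assert np.mean([i.normalized for i in out]) == pytest.approx(1.0, abs=1e-12)

    def test_simulated_group_effect_recovered(self):
        # metazoan raw ratios drawn 1.8x fungal: recovered near 1.8
        rng = np.random.default_rng(5)
        fit = es.TrendlineFit(0.0, 10.0, 0.0)
        fungal = [_summary(f"f{i}", "fungi",
                           int(100 * rng.normal(1.0, 0.1)))
                  for i in range(30)]
        metazoa = [_summary(f"m{i}", "metazoa",
                            int(100 * 1.8 * rng.normal(1.0, 0.1)))
                   for i in range(30)]
        out = es.enrichment_index(fungal + metazoa, fit,
                                  [s.species for s in fungal])
        mean_m = np.mean([i.normalized for i in out if i.group == "metazoa"])
        sem = np.std([i.normalized for i in out if i.group == "metazoa"]) / math.sqrt(30)
        assert abs(mean_m - 1.8) < 3 * sem + 0.05

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            es.SpeciesSummary("x", "g", 100, 50, 60, 40.0)


class TestTriplets:
    def test_counting_window_and_presence_mode(self):
        # one GGG wholly inside -15..-3, counted once despite GGGG run
        w = "T" * 5 + "GGGG" + "T" * 9 + "AG"
        table = es.TripletCountTable.from_windows([w])
        assert table.counts["GGG"] == 1
        occ = es.TripletCountTable.from_windows([w], mode="occurrence")
        assert occ.counts["GGG"] == 2

    def test_triplet_outside_window_ignored(self):
        w = "GGG" + "T" * 15 + "AG"  # GGG ends upstream of -15
        assert es.TripletCountTable.from_windows([w]).counts["GGG"] == 0

    def test_equal_percentages_give_unit_ratio(self):
        a = es.TripletCountTable({"GGG": 10}, 100)
        b = es.TripletCountTable({"GGG": 20}, 200)
        df = es.triplet_enrichment(a, b)
        assert df.loc["GGG", "ratio"] == pytest.approx(1.0)

    def test_zero_canonical_flagged_unavailable(self):
        a = es.TripletCountTable({"AGG": 5}, 100)
        b = es.TripletCountTable({"AGG": 0}, 100)
        df = es.triplet_enrichment(a, b)
        assert not df.loc["AGG", "available"]
        assert math.isnan(df.loc["AGG", "ratio"])

    def test_twofold_example_against_enumeration(self):
        a = es.TripletCountTable({"GGG": 20}, 100)
        b = es.TripletCountTable({"GGG": 10}, 100)
        df = es.triplet_enrichment(a, b)
        assert df.loc["GGG", "ratio"] == pytest.approx(2.0)
        # frozen oracle: enumeration of the pooled 2x2 (k=20,n=100,K=30,N=200)
        assert df.loc["GGG", "p"] == pytest.approx(0.03671379486068819, rel=1e-9)

    def test_swapping_tables_inverts_ratio(self):
        a = es.TripletCountTable({"AAA": 30, "GGG": 12}, 150)
        b = es.TripletCountTable({"AAA": 10, "GGG": 24}, 120)
        fwd = es.triplet_enrichment(a, b)["ratio"]
        rev = es.triplet_enrichment(b, a)["ratio"]
        for t in ("AAA", "GGG"):
            assert fwd[t] == pytest.approx(1.0 / rev[t])

    def test_mixed_triplet_rejected(self):
        with pytest.raises(ValueError):
            es.TripletCountTable({"AGT": 1}, 10)


class TestPairedT:
    def test_identical_samples(self):
        assert es.paired_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_constant_nonzero_difference(self):
        t, p = es.paired_t_test([2, 3, 4, 5], [1, 2, 3, 4])
        assert math.isinf(t) and t > 0
        assert p == 0.0

    def test_hand_computed_statistic(self):
        # d=[1,2,3]: mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3)
        t, p = es.paired_t_test([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        # closed-form two-sided p for df=2: 1 - t/sqrt(t^2+2)
        assert p == pytest.approx(1 - t / math.sqrt(t * t + 2), rel=1e-9)

    def test_matches_textbook_formula_on_random_data(self):
        rng = np.random.default_rng(17)
        x = rng.normal(5, 1, size=40)
        y = x - rng.normal(0.3, 0.5, size=40)
        t, _ = es.paired_t_test(x.tolist(), y.tolist())
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert t == pytest.approx(t_ref, abs=1e-10)


class TestRelativeStrength:
    def test_identical_scores_baseline_one(self):
        scores = {f"s{i}": 7.0 for i in range(5)}
        cmp = es.relative_strength(scores, scores,
                                   {f"s{i}": f"s{i}" for i in range(5)})
        assert cmp.mean_ratio == pytest.approx(1.0)
        assert all(cmp.ratios == 1.0)

    def test_half_strength(self):
        ab = {f"a{i}": 4.0 for i in range(4)}
        can = {f"c{i}": 8.0 for i in range(4)}
        cmp = es.relative_strength(ab, can, {f"a{i}": f"c{i}" for i in range(4)})
        assert cmp.mean_ratio == pytest.approx(0.5)

    def test_unpaired_sites_dropped_with_count(self):
        ab = {"a1": 4.0, "a2": 5.0}
        can = {"c1": 8.0}
        cmp = es.relative_strength(ab, can, {"a1": "c1", "a2": "missing"})
        assert cmp.n_pairs == 1
        assert cmp.n_unpaired_dropped == 1
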