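"""Prioritization, pair enumeration, scans, permutation FWER, correlations."""

import numpy as np
import pytest
from scipy import stats

from episcape import (EffectSpec, SimConfig, additive_fit, build_table,
                      correlate_methods, enumerate_pairs, multiplicative_fit,
                      permute_fwer, prioritize, recode_preventive,
                      scan_regression, simulate, top_fraction)
from episcape.scan import ScanResult


@pytest.fixture(scope="module")
def null_data():
    return simulate(SimConfig(n_cases=150, n_controls=150, n_markers=15,
                              missing_rate=0.02, seed=17))


class TestEnumeration:
    def test_study_scale_bookkeeping(self):
        seeds = [f"rs{i}" for i in range(92)]
        markers = [f"rs{i}" for i in range(3704)]
        enum = enumerate_pairs(seeds, markers, "seeds_x_all")
        assert enum.n_evaluations == 340768
        # unique unordered non-self pairs exclude the 92 self pairs and the
        # C(92,2) duplicated seed-seed orderings
        assert len(enum.pairs) == 92 * 3704 - 92 - 92 * 91 // 2

    def test_exhaustive_matches_brute_force(self):
        markers = [f"m{i}" for i in range(9)]
        enum = enumerate_pairs(None, markers, "exhaustive")
        brute = {(a, b) for i, a in enumerate(markers)
                 for b in markers[i + 1:]}
        assert set(enum.pairs) == brute
        assert enum.n_evaluations == 36

    def test_three_markers(self):
        enum = enumerate_pairs(None, ["a", "b", "c"], "exhaustive")
        assert len(enum.pairs) == 3


class TestScans:
    def test_vectorized_scan_matches_per_table_fits(self, null_data):
        """The fast scan path must agree with the reference per-pair fits."""
        g, p = null_data.genotypes, null_data.phenotype
        enum = enumerate_pairs(None, g.marker_ids, "exhaustive")
        mult = scan_regression(g, p, enum, "multiplicative", "dominant")
        add = scan_regression(g, p, enum, "additive", "recessive")
        for _, rec in mult.table.head(20).iterrows():
            t = build_table(g, p, (rec["marker_1"], rec["marker_2"]),
                            "dominant")
            ref = multiplicative_fit(t)
            assert rec["or3"] == pytest.approx(ref.or3, rel=1e-9)
            assert rec["p_value"] == pytest.approx(ref.p_value, rel=1e-9)
        for _, rec in add.table.head(20).iterrows():
            t = build_table(g, p, (rec["marker_1"], rec["marker_2"]),
                            "recessive")
            rt = recode_preventive(t)
            ref = additive_fit(rt)
            assert rec["ap"] == pytest.approx(ref.ap, rel=1e-9)
            assert rec["p_value"] == pytest.approx(ref.p_value, rel=1e-9)
            assert rec["recoding"] == rt.recoding

    def test_embedded_multiplicative_pair_ranks_first(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_cases=1000, n_controls=1000, n_markers=12,
                effects=[EffectSpec("multiplicative_pair", (0, 1),
                                    or_a=1.1, or_b=1.1, or_interaction=3.0)],
                seed=seed,
            )
            res = simulate(cfg)
            enum = enumerate_pairs(None, res.genotypes.marker_ids,
                                   "exhaustive")
            sr = scan_regression(res.genotypes, res.phenotype, enum,
                                 "multiplicative", "dominant")
            best = tuple(sr.table.iloc[0][["marker_1", "marker_2"]])
            hits += set(best) == {"sim1", "sim2"}
        assert hits >= 16  # >= 80% of runs


class TestPrioritize:
    def test_threshold_one_puts_everything_in_main(self, null_data):
        g, p = null_data.genotypes, null_data.phenotype
        seeds = prioritize(g, p, p_threshold=1.0, n_filter=5)
        assert len(seeds.main_effect) == g.n_markers
        assert seeds.filter_selected == []

    def test_main_effect_marker_always_selected(self):
        for seed in range(10):
            cfg = SimConfig(
                n_cases=2000, n_controls=2000, n_markers=10,
                effects=[EffectSpec("main", (0,), or_main=1.8)],
                seed=seed,
            )
            res = simulate(cfg)
            seeds = prioritize(res.genotypes, res.phenotype, n_filter=2,
                               seed=seed)
            assert "sim1" in seeds.main_effect

    def test_filter_truncated_to_available(self, null_data):
        g, p = null_data.genotypes, null_data.phenotype
        seeds = prioritize(g, p, p_threshold=0.05, n_filter=10_000)
        assert len(seeds) == g.n_markers
        assert set(seeds.main_effect).isdisjoint(seeds.filter_selected)


class TestPermutation:
    def test_permuted_p_bounds_and_monotonicity(self, null_data):
        g, p = null_data.genotypes, null_data.phenotype
        enum = enumerate_pairs(None, g.marker_ids, "exhaustive")
        sr = scan_regression(g, p, enum, "multiplicative", "dominant")
        pr = permute_fwer(g, p, sr, "multiplicative", "dominant", b=99,
                          seed=3, enumeration=enum)
        assert ((pr.permuted_p >= 1 / 100) & (pr.permuted_p <= 1.0)).all()
        # observed records are sorted by stat: permuted P non-decreasing
        assert (np.diff(pr.permuted_p) >= 0).all()

    def test_reproducible_under_seed(self, null_data):
        g, p = null_data.genotypes, null_data.phenotype
        enum = enumerate_pairs(None, g.marker_ids, "exhaustive")
        sr = scan_regression(g, p, enum, "multiplicative", "dominant")
        a = permute_fwer(g, p, sr, "multiplicative", "dominant", 50, 7,
                         enumeration=enum)
        b = permute_fwer(g, p, sr, "multiplicative", "dominant", 50, 7,
                         enumeration=enum)
        assert (a.best_stats == b.best_stats).all()

    def test_dominant_statistic_gets_resolution_p(self, null_data):
        g, p = null_data.genotypes, null_data.phenotype
        enum = enumerate_pairs(None, g.marker_ids, "exhaustive")
        sr = scan_regression(g, p, enum, "multiplicative", "dominant")
        # inject an observed statistic beyond every permutation best
        sr.table.loc[0, "stat"] = 1e6
        pr = permute_fwer(g, p, sr, "multiplicative", "dominant", b=50,
                          seed=3, enumeration=enum)
        assert pr.permuted_p[0] == pytest.approx(1 / 51)

    def test_b_must_be_positive(self, null_data):
        g, p = null_data.genotypes, null_data.phenotype
        enum = enumerate_pairs(None, g.marker_ids, "exhaustive")
        sr = scan_regression(g, p, enum, "multiplicative", "dominant")
        with pytest.raises(ValueError):
            permute_fwer(g, p, sr, "multiplicative", "dominant", 0, 1,
                         enumeration=enum)


def _fake_scan(name, pairs, stats_):
    import pandas as pd

    df = pd.DataFrame(
        {
            "marker_1": [a for a, _ in pairs],
            "marker_2": [b for _, b in pairs],
            "stat": stats_,
        }
    ).sort_values("stat", ascending=False).reset_index(drop=True)
    return ScanResult(name, df, len(pairs), len(pairs))


class TestTopFractionAndCorrelation:
    def test_ceiling_arithmetic(self):
        pairs = [(f"a{i}", f"b{i}") for i in range(50)]
        sr = _fake_scan("x", pairs, np.arange(50.0))
        sr.n_tests = 340768
        assert int(np.ceil(0.005 * 340768)) == 1704
        sr.n_tests = 50
        assert len(top_fraction(sr, 0.005)) == 1  # smaller than 1/n
        assert len(top_fraction(sr, 1.0)) == 50

    def test_self_correlation_is_one(self):
        pairs = [(f"a{i}", f"b{i}") for i in range(30)]
        sr = _fake_scan("x", pairs, np.linspace(0, 5, 30))
        cr = correlate_methods(sr, sr, q=1.0)
        assert cr.r == pytest.approx(1.0)
        assert cr.n_joined == 30

    def test_shuffled_statistics_uncorrelated(self, rng):
        pairs = [(f"a{i}", f"b{i}") for i in range(400)]
        rs = []
        for _ in range(20):
            a = _fake_scan("a", pairs, rng.normal(size=400))
            b = _fake_scan("b", pairs, rng.normal(size=400))
            rs.append(correlate_methods(a, b, q=1.0).r)
        assert abs(np.mean(rs)) < 0.05

    def test_small_join_matches_direct_formula(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")]
        xa = np.array([4.0, 3.0, 2.0, 1.0])
        xb = np.array([1.2, 0.7, 2.0, 0.1])
        a = _fake_scan("a", pairs, xa)
        b = _fake_scan("b", pairs, xb)
        cr = correlate_methods(a, b, q=1.0)
        # hand-expanded covariance formula (pairing is order-invariant)
        mx, my = xa.mean(), xb.mean()
        expected = ((xa - mx) * (xb - my)).sum() / np.sqrt(
            ((xa - mx) ** 2).sum() * ((xb - my) ** 2).sum()
        )
        assert cr.r == pytest.approx(expected, rel=1e-12)

    def test_tiny_join_signalled(self):
        a = _fake_scan("a", [("a", "b"), ("c", "d")], [1.0, 2.0])
        b = _fake_scan("b", [("x", "y")], [1.0])
        with pytest.raises(ValueError):
            correlate_methods(a, b, q=1.0)
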