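"""Replicate-assay statistics: ANOVA, Duncan letters, t-tests, d, CIs, OSI."""

import itertools

import numpy as np
import pytest
from scipy import stats

import extractopt as eo
from extractopt.biostats import AssaySummary, duncan_critical, load_assay_table


def anova_loop_oracle(groups):
    """Two-pass raw-data sums-of-squares ANOVA, written independently."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ssb / df_b) / (ssw / df_w), ssb / (ssb + ssw)


class TestAnova:
    def test_table1_f_statistic(self, table1_groups):
        res = eo.one_way_anova(table1_groups)
        assert (res.df_between, res.df_within) == (26, 54)
        assert res.F == pytest.approx(3205.78, rel=0.01)
        assert res.p < 1e-10
        # eta-squared consistent with F, not with any externally quoted value
        assert res.eta_squared == pytest.approx(
            res.F * 26 / (res.F * 26 + 54), abs=1e-12
        )

    def test_equal_means_give_zero_f(self):
        gs = [AssaySummary(str(i), 5.0, 0.1, 3) for i in range(4)]
        res = eo.one_way_anova(gs)
        assert res.F == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_raw_data_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [list(rng.normal(rng.uniform(0, 3), 1.0, rng.integers(3, 8)))
                  for _ in range(rng.integers(3, 6))]
        res = eo.one_way_anova(groups)
        f_ref, eta_ref = anova_loop_oracle(groups)
        assert res.F == pytest.approx(f_ref, abs=1e-10)
        assert res.eta_squared == pytest.approx(eta_ref, abs=1e-10)

    def test_sufficient_statistics_equal_raw(self):
        rng = np.random.default_rng(10)
        raw = [list(rng.normal(i, 0.5, 4)) for i in range(3)]
        from_raw = eo.one_way_anova(raw)
        from_summary = eo.one_way_anova(
            [AssaySummary.from_raw(str(i), g) for i, g in enumerate(raw)]
        )
        assert from_raw.F == pytest.approx(from_summary.F, abs=1e-10)

    def test_zero_within_variance_warns_infinite_f(self):
        gs = [AssaySummary("a", 1.0, 0.0, 3), AssaySummary("b", 2.0, 0.0, 3)]
        with pytest.warns(UserWarning):
            res = eo.one_way_anova(gs)
        assert np.isinf(res.F) and res.p == 0.0

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(500):
            groups = [list(rng.normal(0, 1, 3)) for _ in range(27)]
            ps.append(eo.one_way_anova(groups).p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestDuncan:
    def test_identical_groups_share_a_letter(self):
        gs = [AssaySummary("a", 5.0, 0.05, 3), AssaySummary("b", 5.0, 0.05, 3)]
        disp = eo.duncan_mrt(gs)
        assert disp.share_letter("a", "b")

    def test_table1_homogeneous_subsets(self, table1_groups):
        """The three 55 degC / 10 h conditions form one subset and the three
        65 degC / 15 h conditions form the lowest subset, distinct from all
        other conditions — the published superscripts k and a."""
        disp = eo.duncan_mrt(table1_groups)
        top = ["55/10/0", "55/10/50", "55/10/100"]
        bottom = ["65/15/0", "65/15/50", "65/15/100"]
        by = disp.letters_by_label()
        assert len({by[l] for l in top}) == 1
        assert len({by[l] for l in bottom}) == 1
        others = [l for l in by if l not in top + bottom]
        for l in others:
            assert not disp.share_letter(l, top[0])
            assert not disp.share_letter(l, bottom[0])
        # lowest subset carries the first letter of the alphabet, as printed
        assert by[bottom[0]] == "a"

    def test_table1_full_letter_display_matches_print(self, table1_groups):
        """All 27 published superscripts (a..k, incl. the overlapping fg/cd)."""
        printed = {
            "45/5/0": "fg", "45/10/0": "i", "45/15/0": "cd",
            "45/5/50": "g", "45/10/50": "i", "45/15/50": "c",
            "45/5/100": "f", "45/10/100": "i", "45/15/100": "d",
            "55/5/0": "j", "55/10/0": "k", "55/15/0": "h",
            "55/5/50": "j", "55/10/50": "k", "55/15/50": "h",
            "55/5/100": "j", "55/10/100": "k", "55/15/100": "h",
            "65/5/0": "b", "65/10/0": "e", "65/15/0": "a",
            "65/5/50": "b", "65/10/50": "e", "65/15/50": "a",
            "65/5/100": "b", "65/10/100": "e", "65/15/100": "a",
        }
        assert eo.duncan_mrt(table1_groups).letters_by_label() == printed

    def test_outlier_gets_unique_letter_vs_pairwise_oracle(self):
        rng = np.random.default_rng(12)
        gs = [
            AssaySummary("g1", 5.00, 0.1, 3),
            AssaySummary("g2", 5.05, 0.1, 3),
            AssaySummary("g3", 4.95, 0.1, 3),
            AssaySummary("out", 9.0, 0.1, 3),
        ]
        disp = eo.duncan_mrt(gs)
        assert all(not disp.share_letter("out", g) for g in ("g1", "g2", "g3"))
        # brute-force check every pair against its own least significant range
        an = eo.one_way_anova(gs)
        means = {g.label: g.mean for g in gs}
        ranked = sorted(means, key=means.get, reverse=True)
        for a, b in itertools.combinations(range(len(ranked)), 2):
            span = b - a + 1
            lsr = duncan_critical(0.05, span, an.df_within) * np.sqrt(
                an.ms_within / 3
            )
            pair_sig = means[ranked[a]] - means[ranked[b]] > lsr
            shared = disp.share_letter(ranked[a], ranked[b])
            if pair_sig:
                assert not shared
            else:
                assert shared

    def test_letter_display_is_transitively_consistent(self, table1_groups):
        disp = eo.duncan_mrt(table1_groups)
        # sharing is interval-structured on the ranked means: if i and k share
        # a letter, every j ranked between them shares it too
        for letter in set("".join(disp.letters)):
            idx = [i for i, ls in enumerate(disp.letters) if letter in ls]
            assert idx == list(range(min(idx), max(idx) + 1))


class TestPairwise:
    def test_identical_summaries_null_result(self):
        s = AssaySummary("x", 5.0, 0.3, 3)
        t, df, p = eo.independent_t_test(s, s)
        assert (t, df, p) == (0.0, 4, 1.0)
        assert eo.cohens_d(s, s) == 0.0

    def test_tpc_difference_is_significant_with_huge_effect(self):
        a = AssaySummary("TPC", 148.880, 1.571, 3, group="RSM")
        b = AssaySummary("TPC", 209.467, 3.590, 3, group="ANN-GA")
        t, df, p = eo.independent_t_test(a, b)
        assert df == 4 and p < 0.05
        assert eo.cohens_d(a, b) > 1.4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_raw_groups(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1.2, 7)
        t, df, p = eo.independent_t_test(list(a), list(b))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_unit_cohens_d(self):
        a = AssaySummary("a", 1.0, 1.0, 10)
        b = AssaySummary("b", 0.0, 1.0, 10)
        assert eo.cohens_d(a, b) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", ["table2_antioxidant", "table4_phenolics"]
    )
    def test_all_published_row_pairs_have_large_effects(self, table):
        rows = load_assay_table(table)
        by_param = {}
        for r in rows:
            by_param.setdefault(r.label, []).append(r)
        for param, grp in by_param.items():
            assert len(grp) == 2
            assert eo.cohens_d(*grp) > 1.4, param


class TestConfidenceIntervals:
    @pytest.mark.parametrize(
        "table", ["table2_antioxidant", "table3_anticholinesterase"]
    )
    def test_reproduces_every_printed_bracket(self, table):
        """mean +/- 1.96 sd/sqrt(3) reproduces all printed CIs to +/-0.002."""
        import pandas as pd

        from extractopt.design import _fixture_path

        df = pd.read_csv(_fixture_path(table))
        for _, r in df.iterrows():
            s = AssaySummary(r["parameter"], r["mean"], r["sd"], int(r["n"]))
            lo, hi = eo.ci_bounds(s)
            assert lo == pytest.approx(r["ci_lower"], abs=0.002)
            assert hi == pytest.approx(r["ci_upper"], abs=0.002)

    def test_zero_dispersion_degenerate_interval(self):
        s = AssaySummary("x", 5.0, 0.0, 3)
        assert eo.ci_bounds(s) == (5.0, 5.0)

    def test_width_scales_inverse_sqrt_n(self):
        w = {}
        for n in (3, 12):
            s = AssaySummary("x", 5.0, 1.0, n)
            lo, hi = eo.ci_bounds(s)
            assert lo + hi == pytest.approx(10.0)  # symmetric about the mean
            w[n] = hi - lo
        assert w[3] / w[12] == pytest.approx(2.0, abs=1e-12)

    def test_t_based_option_is_wider_at_small_n(self):
        s = AssaySummary("x", 5.0, 1.0, 3)
        z_lo, z_hi = eo.ci_bounds(s)
        t_lo, t_hi = eo.ci_bounds(s, use_t=True)
        assert (t_hi - t_lo) > (z_hi - z_lo)


class TestOsi:
    def test_published_osi_values(self):
        assert round(eo.osi(8.238, 18.614), 3) == 0.226
        assert round(eo.osi(8.623, 19.184), 3) == 0.222

    def test_edge_cases(self):
        assert eo.osi(5.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            eo.osi(0.0, 1.0)
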