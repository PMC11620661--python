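"""Cross-decoding ratio, t tests, BH correction, RM-ANOVA, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vwmgeom as vg
from vwmgeom.stats import significance_stars

try:
    import pingouin
    HAVE_PINGOUIN = True
except Exception:  # pragma: no cover
    HAVE_PINGOUIN = False


class TestCrossDecodingRatio:
    @pytest.mark.parametrize("within,cross,expected", [
        (0.75, 0.75, 1.0),   # equal performance: complete generalization
        (0.75, 0.50, 0.0),   # cross at chance: no generalization
        (0.70, 0.60, 0.5),
    ])
    def test_worked_examples(self, within, cross, expected):
        r = vg.cross_decoding_ratio(within, cross)
        assert r.valid
        assert r.ratio == pytest.approx(expected)

    def test_guard_band_flags_invalid(self):
        r = vg.cross_decoding_ratio(0.51, 0.70)
        assert not r.valid and r.ratio is None

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            vg.cross_decoding_ratio(1.2, 0.5)


class TestTTest:
    def test_hand_computed_oracle(self):
        r = vg.t_test([0.6, 0.7, 0.8], 0.5)
        assert r.statistic == pytest.approx(3.4641016, abs=1e-6)
        assert r.df == 2

    def test_identical_paired_samples(self):
        r = vg.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True, tails=2)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_one_tailed_is_half_of_two_tailed_for_positive_t(self):
        x = [0.6, 0.7, 0.8]
        assert vg.t_test(x, 0.5, tails=1).p == \
            pytest.approx(vg.t_test(x, 0.5, tails=2).p / 2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            vg.t_test([1.0, 1.0, 1.0], 0.5)


def _bh_bruteforce(p):
    """Literal step-up definition: find largest k with p_(k) <= k/m * alpha,
    expressed as adjusted p values via min over j >= k of m/j * p_(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [m / j * p[order[j - 1]] for j in range(rank, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBhAdjust:
    def test_worked_example_all_significant(self):
        adj = vg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.all(adj <= 0.05)
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert vg.bh_adjust([0.123]) == pytest.approx([0.123])

    def test_matches_bruteforce_on_all_permutations(self):
        base = [0.005, 0.011, 0.02, 0.2, 0.8, 0.04]
        for perm in itertools.permutations(base):
            assert np.allclose(vg.bh_adjust(list(perm)), _bh_bruteforce(perm))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_random(self, p):
        assert np.allclose(vg.bh_adjust(p), _bh_bruteforce(p))

    def test_family_grouping_is_per_family(self):
        p = [0.01, 0.04, 0.01, 0.04]
        fam = ["a", "a", "b", "b"]
        grouped = vg.bh_adjust(p, fam)
        assert np.allclose(grouped[:2], vg.bh_adjust(p[:2]))
        assert np.allclose(grouped[2:], vg.bh_adjust(p[2:]))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        assert np.all(vg.bh_adjust(p) >= p - 1e-12)


def _toy_2x2():
    cells = [[[1, 2], [3, 4]], [[2, 3], [4, 6]], [[1, 3], [3, 5]]]
    rows = [(s, a, b, m[i][j])
            for s, m in enumerate(cells)
            for i, a in enumerate("XY") for j, b in enumerate("PQ")]
    return pd.DataFrame(rows, columns=["subject", "A", "B", "value"])


class TestRmAnova2:
    def test_all_cells_identical_gives_zero_f(self):
        rows = [(s, a, b, 2.5) for s in range(4)
                for a in "XY" for b in "PQ"]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "value"])
        res = vg.rm_anova2(df)
        assert np.allclose(res["F"], 0.0)

    def test_toy_table_matches_sums_of_squares_oracle(self):
        res = vg.rm_anova2(_toy_2x2()).set_index("effect")
        # hand oracle: SS_A=14.0833, SS_B=6.75, SS_AB=.0833 against their
        # subject-interaction error terms (df 1, 2 each)
        assert res.loc["A", "F"] == pytest.approx(169.0, abs=1e-9)
        assert res.loc["B", "F"] == pytest.approx(27.0, abs=1e-9)
        assert res.loc["A:B", "F"] == pytest.approx(1.0, abs=1e-9)
        assert (res["df1"] == 1).all() and (res["df2"] == 2).all()

    @pytest.mark.skipif(not HAVE_PINGOUIN, reason="pingouin not installed")
    def test_matches_pingouin(self):
        rng = np.random.default_rng(5)
        rows = [(s, a, b, rng.normal()) for s in range(6)
                for a in "XYZ" for b in "PQ"]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "value"])
        mine = vg.rm_anova2(df)
        ref = pingouin.rm_anova(data=df, dv="value", within=["A", "B"],
                                subject="subject")
        assert np.allclose(mine["F"], ref["F"], atol=1e-8)
        assert np.allclose(mine["p"], ref["p_unc"], atol=1e-8)

    def test_additive_effects_rarely_show_interaction(self):
        """Planted main effects without interaction: the interaction test
        should stay non-significant in at least 90% of simulations."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            rows = []
            for s in range(10):
                subj = rng.normal(0, 0.5)
                for i, a in enumerate("XY"):
                    for j, b in enumerate("PQ"):
                        rows.append((s, a, b,
                                     subj + 0.5 * i + 0.3 * j
                                     + rng.normal(0, 0.2)))
            df = pd.DataFrame(rows, columns=["subject", "A", "B", "value"])
            p = vg.rm_anova2(df).set_index("effect").loc["A:B", "p"]
            hits += p > 0.05
        assert hits >= 0.90 * n_sim

    def test_incomplete_design_rejected(self):
        df = _toy_2x2().iloc[:-1]
        with pytest.raises(ValueError, match="incomplete|unbalanced"):
            vg.rm_anova2(df)


class TestPowerPairedT:
    def test_noncentral_t_oracles(self):
        assert vg.power_paired_t(1.0, 0.8, 0.05, tails=1) == 8
        assert vg.power_paired_t(0.5, 0.8, 0.05, tails=2) == 34

    def test_monotone_in_effect_size_and_power(self):
        ns = [vg.power_paired_t(dz, 0.8, 0.05, 1)
              for dz in (0.2, 0.4, 0.8, 1.6)]
        assert ns == sorted(ns, reverse=True)
        assert vg.power_paired_t(0.5, 0.95, 0.05, 1) >= \
            vg.power_paired_t(0.5, 0.80, 0.05, 1)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            vg.power_paired_t(0.0)


class TestReport:
    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""

    def test_report_adjusts_within_family(self):
        rows = [
            dict(analysis="a1", family="f1", statistic=2.5, df=10, p=0.01),
            dict(analysis="a2", family="f1", statistic=2.0, df=10, p=0.04),
            dict(analysis="a3", family="f2", statistic=1.0, df=10, p=0.30),
        ]
        rep = vg.stats_report(rows)
        assert (rep["p_adjusted"] >= rep["p"] - 1e-12).all()
        assert rep.loc[2, "p_adjusted"] == pytest.approx(0.30)
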