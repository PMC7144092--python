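"""Unit and property tests for the from-scratch statistical machinery.

Independent oracles: exact rational enumeration for Fisher's test,
brute-force rank/permutation enumeration for the Mann-Whitney U, textbook
sums-of-squares formulas for the mixed ANOVA, and scipy / statsmodels /
pingouin as external cross-checks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from modscreen import core_stats as cs
from modscreen import synthetic_data as synth


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration of all tables with
    the observed margins, via factorial-ratio hypergeometric probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n, c2 = r1 + r2, b + d
    fact = math.factorial
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {}
    for k in range(lo, hi + 1):
        kb, kc, kd = r1 - k, c1 - k, r2 - (c1 - k)
        probs[k] = Fraction(
            fact(r1) * fact(r2) * fact(c1) * fact(c2),
            fact(n) * fact(k) * fact(kb) * fact(kc) * fact(kd),
        )
    return float(min(1, sum(q for q in probs.values() if q <= probs[a])))


def mwu_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every split of the
    pooled sample (midranks, deviation-from-mean two-sided rule)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mean_u = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisher:
    def test_published_screen_table_value(self):
        # GstO1-O4 thorax row vs the no-deficiency control
        res = cs.fisher_exact([[105, 45], [40, 4]])
        assert res.p_value == pytest.approx(0.0052, abs=5e-5)

    def test_identical_proportions_give_p_one(self):
        assert cs.fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    def test_hand_enumerated_symmetric_table(self):
        # margins (3,3)/(3,3): masses 0.05, 0.45, 0.45, 0.05; observed 0.45
        assert cs.fisher_exact([[2, 1], [1, 2]]).p_value == pytest.approx(1.0)

    def test_odds_ratio_conventions(self):
        assert cs.fisher_exact([[4, 2], [1, 3]]).odds_ratio == pytest.approx(6.0)
        res = cs.fisher_exact([[3, 0], [1, 2]])
        assert math.isinf(res.odds_ratio)
        res0 = cs.fisher_exact([[0, 3], [0, 2]])
        assert not res0.odds_ratio_defined and math.isnan(res0.odds_ratio)

    @pytest.mark.parametrize("table", [[[-1, 2], [3, 4]], [[0, 0], [0, 0]]])
    def test_invalid_tables_rejected(self, table):
        with pytest.raises(ValueError):
            cs.fisher_exact(table)

    def test_two_sided_p_is_orientation_invariant(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, 4)
            if a + b + c + d == 0:
                continue
            p1 = cs.fisher_exact([[a, b], [c, d]]).p_value
            p2 = cs.fisher_exact([[c, d], [a, b]]).p_value
            assert p1 == pytest.approx(p2, abs=1e-12)

    @given(st.tuples(*[st.integers(0, 10)] * 4).filter(lambda t: sum(t) > 0))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_rational_enumeration(self, cells):
        a, b, c, d = cells
        p = cs.fisher_exact([[a, b], [c, d]]).p_value
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, 4)
            if a + b + c + d == 0:
                continue
            ours = cs.fisher_exact([[a, b], [c, d]]).p_value
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_null_rejection_rate_controlled(self, rng):
        # 2000 null 2x2 tables (both rows Binomial(n, 0.3)): rejections at
        # alpha=0.05 stay below alpha + 2 Monte-Carlo SE (exact tests are
        # conservative on discrete data).
        alpha, sims = 0.05, 2000
        rejections = 0
        for _ in range(sims):
            x, y = rng.binomial(25, 0.3, 2)
            if x + y in (0, 50):
                continue
            p = cs.fisher_exact([[x, 25 - x], [y, 25 - y]]).p_value
            rejections += p < alpha
        assert rejections / sims <= alpha + 2 * math.sqrt(alpha * (1 - alpha) / sims)


# ---------------------------------------------------------------------------
# Multiplicity adjustments
# ---------------------------------------------------------------------------

class TestAdjustments:
    def test_bonferroni_threshold(self):
        assert cs.bonferroni_threshold(0.05, 11) == pytest.approx(0.05 / 11)
        assert cs.bonferroni_threshold(0.05, 1) == 0.05
        assert cs.bonferroni_threshold(0.01, 4) == 0.0025
        with pytest.raises(ValueError):
            cs.bonferroni_threshold(0.05, 0)

    def test_bh_step_up_hand_example(self):
        # p(i) * m / i = 0.04 for every i, cumulative min from the top
        np.testing.assert_allclose(cs.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bh_edge_cases(self):
        assert cs.bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert cs.bh_adjust([0.2, 1.0, 0.01])[1] == 1.0

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        np.testing.assert_allclose(cs.bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_holm_sidak_hand_example(self):
        np.testing.assert_allclose(
            cs.holm_sidak_adjust([0.01, 0.04]), [1 - 0.99**2, 0.04], atol=1e-12
        )

    def test_holm_sidak_edge_cases(self):
        assert cs.holm_sidak_adjust([0.5])[0] == pytest.approx(0.5)
        np.testing.assert_array_equal(cs.holm_sidak_adjust([0.0, 0.0, 0.0]), np.zeros(3))

    def test_holm_sidak_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=20)
        np.testing.assert_allclose(
            cs.holm_sidak_adjust(p), multipletests(p, method="holm-sidak")[1], atol=1e-12
        )

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_adjustments_are_monotone(self, p):
        for adjust in (cs.bh_adjust, cs.holm_sidak_adjust):
            adj = adjust(p)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)
            assert np.all((adj >= np.asarray(p) - 1e-12) & (adj <= 1))

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            cs.holm_sidak_adjust([-0.1])


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        res = cs.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.u == pytest.approx(4.5)  # n1*n2/2

    def test_fully_separated_small_case(self):
        res = cs.mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_exact_path_equals_enumeration_with_ties(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 6, 2)
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            res = cs.mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(mwu_oracle(x, y), abs=1e-12)

    def test_normal_path_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=35)
        ours = cs.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_detects_two_sd_shift(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        assert cs.mann_whitney_u(x, y).p_value < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        res = cs.kruskal_wallis([[3, 3, 3], [3, 3, 3]])
        assert res.h == 0.0 and res.p_value == 1.0

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 10, 20).astype(float) for _ in range(3)]
        ours = cs.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.h == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_two_group_case_agrees_with_mann_whitney(self, rng):
        x, y = rng.normal(size=25), rng.normal(0.5, 1, 25)
        kw = cs.kruskal_wallis([x, y])
        mw = cs.mann_whitney_u(x, y, continuity=False)
        assert abs(kw.p_value - mw.p_value) < 0.02

    def test_null_rejection_rate(self, rng):
        alpha, sims = 0.05, 2000
        rejections = sum(
            cs.kruskal_wallis([rng.normal(size=30) for _ in range(3)]).p_value < alpha
            for _ in range(sims)
        )
        se = math.sqrt(alpha * (1 - alpha) / sims)
        assert rejections / sims <= alpha + 2 * se

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            cs.kruskal_wallis([[1.0, 2.0]])


class TestDunn:
    def test_identical_groups_adjust_to_one(self):
        g = {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "ctrl": [1, 2, 3, 4]}
        assert (cs.dunn_posthoc(g, "ctrl")["p_adj"] == 1.0).all()

    def test_shifted_group_detected(self, rng):
        g = {
            "ctrl": rng.normal(0, 1, 30),
            "null": rng.normal(0, 1, 30),
            "shifted": rng.normal(3, 1, 30),
        }
        res = cs.dunn_posthoc(g, "ctrl")
        assert res.loc["shifted", "p_adj"] < 0.001
        assert res.loc["null", "p_adj"] > 0.05

    def test_two_group_case_matches_normal_rank_test(self, rng):
        x, y = rng.normal(size=20), rng.normal(1, 1, 20)
        res = cs.dunn_posthoc({"a": x, "ctrl": y}, "ctrl")
        mw = cs.mann_whitney_u(x, y, continuity=False)
        assert res.loc["a", "p_raw"] == pytest.approx(mw.p_value, abs=1e-10)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            cs.dunn_posthoc({"a": [1.0], "b": [2.0]}, "ctrl")


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _long_table(cube, genotypes=None):
    g, n, t = cube.shape
    genotypes = genotypes or [f"g{i}" for i in range(g)]
    rows = [
        (genotypes[i], f"{genotypes[i]}/s{j}", k, cube[i, j, k])
        for i in range(g)
        for j in range(n)
        for k in range(t)
    ]
    return pd.DataFrame(rows, columns=["genotype", "subject", "time", "value"])


def anova_ss_oracle(cube):
    """Textbook sums of squares computed by explicit loops."""
    g, n, t = cube.shape
    grand = cube.mean()
    ss_geno = sum(n * t * (cube[i].mean() - grand) ** 2 for i in range(g))
    ss_subj = sum(
        t * (cube[i, j].mean() - cube[i].mean()) ** 2 for i in range(g) for j in range(n)
    )
    ss_time = sum(g * n * (cube[:, :, k].mean() - grand) ** 2 for k in range(t))
    ss_inter = sum(
        n * (cube[i, :, k].mean() - cube[i].mean() - cube[:, :, k].mean() + grand) ** 2
        for i in range(g)
        for k in range(t)
    )
    ss_err = sum(
        (
            cube[i, j, k]
            - cube[i, :, k].mean()
            - cube[i, j].mean()
            + cube[i].mean()
        )
        ** 2
        for i in range(g)
        for j in range(n)
        for k in range(t)
    )
    return ss_geno, ss_subj, ss_time, ss_inter, ss_err


class TestRMAnova:
    def test_identical_genotypes_give_zero_f(self):
        base = np.array([[0.1, 0.4, 0.8], [0.2, 0.5, 0.7]])  # subjects x time
        cube = np.stack([base, base])
        res = cs.rm_anova_two_way(_long_table(cube))
        assert res.f_genotype == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_ss_oracle(self, rng):
        cube = rng.random((2, 3, 4))
        res = cs.rm_anova_two_way(_long_table(cube))
        expected = anova_ss_oracle(cube)
        got = res.table["SS"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_matches_pingouin_mixed_anova(self, rng):
        import pingouin as pg

        cube = rng.random((3, 5, 4))
        df = _long_table(cube)
        res = cs.rm_anova_two_way(df)
        ref = pg.mixed_anova(
            df, dv="value", within="time", between="genotype", subject="subject"
        ).set_index("Source")
        assert res.f_genotype == pytest.approx(ref.loc["genotype", "F"], rel=1e-8)
        assert res.f_time == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)
        assert res.p_genotype == pytest.approx(ref.loc["genotype", "p_unc"], rel=1e-6)

    def test_unbalanced_design_rejected(self, rng):
        df = _long_table(rng.random((2, 3, 4)))
        with pytest.raises(ValueError, match="unbalanced"):
            cs.rm_anova_two_way(df.iloc[:-1])
        with pytest.raises(ValueError, match="unbalanced"):
            cs.rm_anova_two_way(df[df["subject"] != "g0/s0"])

    def test_greenhouse_geisser_epsilon_bounds(self, rng):
        cube = rng.random((2, 6, 5))
        res = cs.rm_anova_two_way(_long_table(cube), sphericity_correction="greenhouse-geisser")
        assert 1.0 / 4 <= res.gg_epsilon <= 1.0

    def test_detects_hazard_ratio_three(self, rng):
        # Genotypes with 3x different seizure onset hazards, 3 replicate
        # groups of 30 flies: the between-genotype effect should be found
        # in at least 90% of simulations.
        from modscreen import seizure_recovery as sr

        hits = 0
        sims = 200
        for _ in range(sims):
            courses = synth.gen_seizure(0.01, genotype="a", seed=rng) + synth.gen_seizure(
                0.03, genotype="b", seed=rng
            )
            res = sr.compare_incidence(courses, "a", "b")
            hits += res.p_genotype < 0.05
        assert hits / sims >= 0.90

    def test_pairwise_report_shape_and_adjustment(self, rng):
        cube = rng.random((2, 3, 4))
        res = cs.rm_anova_two_way(_long_table(cube))
        assert len(res.pairwise) == 4  # one comparison per time bin
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()
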