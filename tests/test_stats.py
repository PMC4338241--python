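import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cranioreg.stats import (
    AgreementSummary,
    Permanova,
    UnbalancedDesignError,
    bland_altman,
    pairwise_posthoc,
    permanova,
    permdisp,
)


def _two_groups(values_a, values_b):
    return pd.DataFrame(
        {
            "D": np.concatenate([values_a, values_b]),
            "g": ["a"] * len(values_a) + ["b"] * len(values_b),
        }
    )


class TestPermanova:
    def test_exhaustive_p_matches_brute_force(self):
        y = np.array([1.0, 1.5, 1.2, 2.1, 2.4, 2.2])
        res = permanova(_two_groups(10 ** y[:3], 10 ** y[3:]), ["g"], n_perm="exhaustive")

        def f_of(idx):
            a = y[list(idx)]
            b = np.delete(y, list(idx))
            gm = y.mean()
            ssb = 3 * (a.mean() - gm) ** 2 + 3 * (b.mean() - gm) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 4)

        f_obs = f_of([0, 1, 2])
        fs = [f_of(c) for c in itertools.combinations(range(6), 3)]
        p_brute = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.p_value("g") == pytest.approx(p_brute, abs=1e-12)

    def test_pseudo_f_equals_classical_anova_f(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.normal(0, 1, 7), rng.normal(0.5, 1, 7), rng.normal(1, 1, 7)
        df = pd.DataFrame(
            {"D": np.concatenate([a, b, c]), "g": ["a"] * 7 + ["b"] * 7 + ["c"] * 7}
        )
        res = permanova(df, ["g"], transform="none", n_perm=99)
        expected = sps.f_oneway(a, b, c).statistic
        assert res.table.iloc[0]["pseudo_F"] == pytest.approx(expected, rel=1e-10)

    def test_all_equal_responses_reported_undefined(self):
        res = permanova(_two_groups([1.0] * 4, [1.0] * 4), ["g"], n_perm=99)
        assert np.isnan(res.p_value("g"))
        assert res.table.loc[res.table.source == "Total", "SS"].iloc[0] == 0.0

    def test_ss_decomposition_additivity_balanced_crossed(self):
        rng = np.random.default_rng(1)
        rows = [
            dict(technique=t, operator=o, time=s, D=float(10 ** rng.normal(0, 0.2)))
            for t in "ABCDE" for o in range(3) for s in range(2) for _ in range(4)
        ]
        res = permanova(
            pd.DataFrame(rows), ["technique", "operator", "time"],
            random_factors=["operator"], n_perm=99,
        )
        tab = res.table
        total = tab.loc[tab.source == "Total", "SS"].iloc[0]
        parts = tab.loc[tab.source != "Total", "SS"].sum()
        assert parts == pytest.approx(total, abs=1e-9)
        assert tab.loc[tab.source != "Total", "df"].sum() == tab.loc[
            tab.source == "Total", "df"
        ].iloc[0]

    def test_mixed_model_uses_interaction_denominator(self):
        rng = np.random.default_rng(2)
        rows = [
            dict(technique=t, operator=o, D=float(10 ** rng.normal(0, 0.2)))
            for t in "AB" for o in range(3) for _ in range(4)
        ]
        res = permanova(
            pd.DataFrame(rows), ["technique", "operator"],
            random_factors=["operator"], n_perm=99,
        )
        tab = res.table.set_index("source")
        f_tech = tab.loc["technique", "MS"] / tab.loc["technique x operator", "MS"]
        assert tab.loc["technique", "pseudo_F"] == pytest.approx(f_tech, rel=1e-12)

    def test_unbalanced_design_rejected(self):
        df = _two_groups([1.0, 2.0, 3.0], [1.0, 2.0])
        with pytest.raises(UnbalancedDesignError):
            permanova(df, ["g"], n_perm=99)

    def test_seed_invariance_within_monte_carlo_error(self):
        rng = np.random.default_rng(3)
        df = _two_groups(10 ** rng.normal(0, 0.3, 8), 10 ** rng.normal(0.3, 0.3, 8))
        p1 = permanova(df, ["g"], n_perm=999, seed=1).p_value("g")
        p2 = permanova(df, ["g"], n_perm=999, seed=2).p_value("g")
        tol = 3 * np.sqrt(max(p1 * (1 - p1), 1e-4) / 999)
        assert abs(p1 - p2) <= tol


class TestPairwisePosthoc:
    def test_identical_distributions_give_p_one(self):
        vals = [1.0, 1.2, 1.4, 1.6]
        df = _two_groups(vals, vals)
        out = pairwise_posthoc(df, "g", n_perm=199)
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_bonferroni_arithmetic_five_levels(self):
        rng = np.random.default_rng(4)
        rows = [
            dict(g=lev, D=float(10 ** rng.normal(i * 0.1, 0.2)))
            for i, lev in enumerate("ABCDE") for _ in range(6)
        ]
        out = pairwise_posthoc(pd.DataFrame(rows), "g", n_perm=99)
        assert len(out) == 10
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, 10 * out["p_raw"]), atol=1e-12
        )
        assert np.all(out["p_adjusted"] >= out["p_raw"])  # never decreases

    def test_power_on_well_separated_groups(self):
        rng = np.random.default_rng(5)
        a = 10 ** rng.normal(0.0, 0.1, 24)
        b = 10 ** rng.normal(1.0, 0.1, 24)  # 10 sd separation on log scale
        out = pairwise_posthoc(_two_groups(a, b), "g", n_perm=1999)
        assert out["p_adjusted"].iloc[0] <= 0.005

    def test_single_observation_level_rejected(self):
        df = _two_groups([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            pairwise_posthoc(df, "g", n_perm=19)


class TestPermdisp:
    def test_identical_groups_f_zero(self):
        vals = [1.0, 1.3, 1.7, 2.0]
        f, p = permdisp(_two_groups(vals, vals), "g", n_perm=99)
        assert f == 0.0

    def test_null_p_values_roughly_uniform_for_location_shift(self):
        # groups differing only in location: the test must not reject
        ps = []
        for sim in range(200):
            rng = np.random.default_rng(100 + sim)
            a = 10 ** rng.normal(0.0, 0.3, 10)
            b = 10 ** rng.normal(1.0, 0.3, 10)
            _, p = permdisp(_two_groups(a, b), "g", n_perm=199, seed=sim)
            ps.append(p)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_spread_difference(self):
        hits = 0
        for sim in range(100):
            rng = np.random.default_rng(300 + sim)
            a = 10 ** rng.normal(0, 0.1, 20)
            b = 10 ** rng.normal(0, 0.5, 20)  # x5 spread on log scale
            _, p = permdisp(_two_groups(a, b), "g", n_perm=199, seed=sim)
            hits += p < 0.05
        assert hits >= 80

    def test_single_member_group_rejected(self):
        df = _two_groups([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            permdisp(df, "g", n_perm=19)


class TestBlandAltman:
    def test_identical_methods(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        s = bland_altman(ref, ref)
        assert s.median == 0.0
        assert s.iqr == (0.0, 0.0)

    def test_pure_systematic_offset(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        s = bland_altman(ref, ref + 0.5)
        assert s.median == pytest.approx(0.5)
        assert s.iqr[1] - s.iqr[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_quartiles(self):
        # differences {-0.3, -0.2, -0.1, 0, 0.1} under the (n+1)p rule
        ref = np.zeros(5)
        alt = np.array([-0.3, -0.2, -0.1, 0.0, 0.1])
        s = bland_altman(ref, alt)
        assert s.median == pytest.approx(-0.1)
        assert s.iqr == (pytest.approx(-0.25), pytest.approx(0.05))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=30),
    )
    def test_median_always_within_iqr(self, diffs):
        ref = np.zeros(len(diffs))
        s = bland_altman(ref, np.array(diffs))
        assert s.iqr[0] - 1e-12 <= s.median <= s.iqr[1] + 1e-12


class TestCrossValidationAgainstIndependentEngine:
    def test_one_way_pseudo_f_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(6)
        y = np.log10(10 ** rng.normal(0, 0.3, 18))
        grouping = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        df = pd.DataFrame({"D": 10**y, "g": grouping})
        mine = permanova(df, ["g"], n_perm=99)
        dm = DistanceMatrix(squareform(pdist(y[:, None])))
        theirs = skbio_permanova(dm, grouping, permutations=99)
        assert mine.table.iloc[0]["pseudo_F"] == pytest.approx(
            theirs["test statistic"], rel=1e-9
        )
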