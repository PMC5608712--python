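"""Group summaries, t tests, ANOVA with post hoc contrasts, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vasoelast.stats import (
    anova_posthoc,
    mean_sem,
    modulus_correlations,
    pearson,
    summarize_groups,
    two_group_test,
)


class TestSummaries:
    def test_hand_arithmetic(self):
        m, s, n = mean_sem([1.0, 2.0, 3.0])
        assert m == pytest.approx(2.0)
        assert s == pytest.approx(1.0 / np.sqrt(3), abs=1e-12)  # SD = 1
        assert n == 3

    def test_degenerate_cases(self):
        assert mean_sem([4.2]) == (4.2, 0.0, 1)
        _, s, _ = mean_sem([5.0, 5.0, 5.0])
        assert s == 0.0
        with pytest.raises(ValueError):
            mean_sem([])

    def test_summarize_groups_frame(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 2, "m": [1, 2, 3, 10, 10]})
        out = summarize_groups(df, "m")
        assert list(out["group"]) == ["a", "b"]
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[1, "sem"] == 0.0


class TestTwoGroupTest:
    def test_identical_samples(self):
        r = two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computation(self):
        # pooled SD = 1, se = sqrt(2/3), t = -3/se = -3.674, df = 4
        r = two_group_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4

    def test_symmetry_of_p(self):
        a, b = [1.0, 2.0, 3.5], [4.0, 5.5, 6.0]
        assert two_group_test(a, b).p_value == pytest.approx(
            two_group_test(b, a).p_value, rel=1e-12
        )

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [2.0, 3.0])

    def test_anova_reduces_to_squared_t_on_two_groups(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 9)
        df = pd.DataFrame(
            {"group": ["a"] * 8 + ["b"] * 9, "m": np.concatenate([a, b])}
        )
        t = two_group_test(a, b).statistic
        from scipy.stats import f_oneway

        F, _ = f_oneway(a, b)
        assert F == pytest.approx(t**2, abs=1e-10)


class TestAnovaPosthoc:
    def _table(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        groups, vals = [], []
        for i, g in enumerate(["g1", "g2", "g3", "g4"]):
            v = rng.normal(0.0, 1.0, 5)
            if g == "g4":
                v = v + shift
            groups += [g] * 5
            vals.append(v)
        return pd.DataFrame({"group": groups, "m": np.concatenate(vals)})

    def test_identical_groups_no_posthoc(self):
        df = pd.DataFrame({"group": np.repeat(["g1", "g2", "g3", "g4"], 3),
                           "m": np.tile([5.0, 5.0, 5.0], 4)})
        out = anova_posthoc(df, "m", ["g1", "g2", "g3", "g4"])
        assert out[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert len(out) == 1  # no post hoc contrasts run

    def test_one_shifted_group_flags_its_three_contrasts(self):
        df = self._table(shift=10.0, seed=1)
        out = anova_posthoc(df, "m", ["g1", "g2", "g3", "g4"])
        assert out[0].p_value < 0.05
        posthoc = out[1:]
        assert len(posthoc) == 6
        sig = {r.name for r in posthoc if r.p_value < 0.05}
        involving_g4 = {r.name for r in posthoc if "g4" in r.name}
        assert sig == involving_g4
        assert len(sig) == 3

    def test_f_matches_direct_mean_square_ratio(self):
        # 4 x 3 toy table, F computed from between/within mean squares by hand
        data = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0],
                "g3": [5.0, 5.0, 5.0], "g4": [8.0, 9.0, 10.0]}
        df = pd.DataFrame(
            {"group": np.repeat(list(data), 3),
             "m": np.concatenate([data[g] for g in data])}
        )
        grand = df["m"].mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in data.values())
        f_hand = (ss_between / 3) / (ss_within / 8)
        out = anova_posthoc(df, "m", list(data))
        assert out[0].statistic == pytest.approx(f_hand, rel=1e-12)

    def test_fewer_than_four_groups_rejected(self):
        df = self._table()
        with pytest.raises(ValueError):
            anova_posthoc(df, "m", ["g1", "g2"])


class TestCorrelations:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_missing_pairs_excluded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([2.0, 4.0, 6.0, 8.0, 100.0])
        assert pearson(x, y).statistic == pytest.approx(1.0)
        assert pearson(x, y).summaries["n"][2] == 4

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])

    def test_sign_structure_on_constructed_ligated_cohort(self):
        """Modulus tracks intima volume and opposes strain (the remodeling
        sign structure), on a cohort built with that coupling plus noise."""
        rng = np.random.default_rng(12)
        n = 12
        intima = rng.uniform(1e7, 6e7, n)
        modulus = 18.0 + 30.0 * (intima / 6e7) + rng.normal(0, 1.0, n)
        strain = 30.0 - 20.0 * (modulus / 50.0) + rng.normal(0, 1.0, n)
        media = rng.normal(4e7, 2e6, n)
        df = pd.DataFrame(
            {
                "wall_modulus_kpa": modulus,
                "intima_volume_um3": intima,
                "im_ratio": intima / media,
                "strain_pct": strain,
                "media_volume_um3": media,
                "adventitia_volume_um3": media * 1.3,
            }
        )
        res = {r.name: r for r in modulus_correlations(df)}
        assert res["wall_modulus_kpa vs intima_volume_um3"].statistic > 0
        assert res["wall_modulus_kpa vs im_ratio"].statistic > 0
        assert res["wall_modulus_kpa vs strain_pct"].statistic < 0

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        r0 = pearson(x, y).statistic
        r1 = pearson(a * x + b, y).statistic
        assert r1 == pytest.approx(r0, rel=1e-9)
        assert -1 <= r1 <= 1
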