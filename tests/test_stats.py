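"""Tests for behavioral statistics, the mixed RM ANOVA and permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from megbeta import stats


class TestDprime:
    def test_symmetric_example(self):
        assert stats.dprime(0.95, 0.05) == pytest.approx(2 * norm.ppf(0.95))

    def test_equal_rates_zero(self):
        assert stats.dprime(0.3, 0.3) == pytest.approx(0.0)
        assert stats.dprime(0.5, 0.5) == 0.0

    def test_extreme_rate_rejected_without_correction(self):
        with pytest.raises(ValueError):
            stats.dprime(1.0, 0.05)

    def test_loglinear_correction(self):
        d = stats.dprime(1.0, 0.0, n_targets=8, n_nontargets=152,
                         correct=True)
        expected = norm.ppf(8.5 / 9) - norm.ppf(0.5 / 153)
        assert d == pytest.approx(expected)


class TestIndependentT:
    def test_summary_statistics_example(self):
        t, df = stats.independent_t(3.15, 1.12, 12, 1.95, 1.3, 10)
        assert df == 20
        assert t == pytest.approx(2.3271, abs=1e-4)

    def test_equal_means_zero(self):
        t, _ = stats.independent_t(2.0, 1.0, 10, 2.0, 1.5, 12)
        assert t == pytest.approx(0.0)

    def test_doubling_sds_halves_t(self):
        t1, _ = stats.independent_t(3.0, 1.0, 10, 2.0, 1.2, 10)
        t2, _ = stats.independent_t(3.0, 2.0, 10, 2.0, 2.4, 10)
        assert t2 == pytest.approx(t1 / 2)


def _long_dataset(rng, n_controls=12, n_patients=10, n_bins=18,
                  networks=("insula", "motor"), effect=0.0):
    rows = []
    for i in range(n_controls + n_patients):
        g = "control" if i < n_controls else "patient"
        base = rng.normal()
        for n in networks:
            for r in ("relevant", "irrelevant"):
                bump = effect if (g == "control") == (r == "relevant") else 0.0
                for b in range(1, n_bins + 1):
                    rows.append(dict(
                        subject=f"s{i:02d}", group=g, network=n, relevance=r,
                        time_bin=b, value=base + bump + rng.normal(),
                    ))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_pooled_degrees_of_freedom(self, rng):
        df = _long_dataset(rng)
        res = stats.rm_anova(df, within=("network", "relevance", "time_bin"),
                             between=None)
        assert res.df("time_bin") == (17, 357)
        assert res.contrasts["time_bin"]["cubic"]["df"] == (1, 21)
        assert res.contrasts["time_bin"]["quadratic"]["df"] == (1, 21)

    def test_mixed_degrees_of_freedom(self, rng):
        df = _long_dataset(rng)
        res = stats.rm_anova(df, within=("network", "relevance", "time_bin"),
                             between="group")
        assert res.df("relevance:time_bin:group") == (17, 340)
        assert res.df("network:relevance:group") == (1, 20)
        assert res.df("group") == (1, 20)

    def test_covariate_degrees_of_freedom(self, rng):
        df = _long_dataset(rng)
        ages = {s: rng.uniform(20, 50) for s in df.subject.unique()}
        df["age"] = df.subject.map(ages)
        res = stats.rm_anova(df, within=("relevance", "time_bin"),
                             between="group", covariate="age")
        assert res.df("relevance:time_bin:group") == (17, 323)
        assert res.df("relevance:group") == (1, 19)

    def test_group_f_equals_t_squared(self, rng):
        df = _long_dataset(rng, effect=0.4)
        res = stats.rm_anova(df, within=("network", "relevance", "time_bin"),
                             between="group")
        means = df.groupby(["subject", "group"]).value.mean().reset_index()
        c = means[means.group == "control"].value
        p = means[means.group == "patient"].value
        t, _ = stats.independent_t(c.mean(), c.std(ddof=1), len(c),
                                   p.mean(), p.std(ddof=1), len(p))
        assert res.F("group") == pytest.approx(t**2, rel=1e-9)

    def test_cubic_trend_detected_with_sign(self, rng):
        rows = []
        x = np.linspace(-1, 1, 18)
        trend = -(x**3)
        for i in range(12):
            for b in range(18):
                rows.append(dict(subject=i, time_bin=b + 1,
                                 value=trend[b] + 0.05 * rng.normal()))
        res = stats.rm_anova(pd.DataFrame(rows), within=("time_bin",),
                             between=None)
        cub = res.contrasts["time_bin"]["cubic"]
        quad = res.contrasts["time_bin"]["quadratic"]
        assert cub["F"] > 50
        assert cub["sign"] == -1
        assert quad["F"] < cub["F"] / 10

    def test_matches_pingouin_balanced_mixed(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _long_dataset(rng, n_controls=11, n_patients=11,
                           networks=("insula",), n_bins=1, effect=0.5)
        res = stats.rm_anova(df, within=("relevance",), between="group")
        ref = pg.mixed_anova(df, dv="value", within="relevance",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert res.F("group") == pytest.approx(ref.loc["group", "F"])
        assert res.F("relevance") == pytest.approx(ref.loc["relevance", "F"])
        assert res.F("relevance:group") == pytest.approx(
            ref.loc["Interaction", "F"]
        )

    def test_matches_statsmodels_pure_within(self, rng):
        anova_rm = pytest.importorskip("statsmodels.stats.anova")
        df = _long_dataset(rng, networks=("insula", "motor"), n_bins=3)
        res = stats.rm_anova(df, within=("network", "time_bin"), between=None)
        ref = anova_rm.AnovaRM(
            df.groupby(["subject", "network", "time_bin"], as_index=False)
            .value.mean(),
            "value", "subject", within=["network", "time_bin"],
        ).fit().anova_table
        for mine, theirs in [("network", "network"), ("time_bin", "time_bin"),
                             ("network:time_bin", "network:time_bin")]:
            assert res.F(mine) == pytest.approx(ref.loc[theirs, "F Value"])

    def test_missing_cell_names_subject(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=2)
        df = df[~((df.subject == "s03") & (df.relevance == "relevant")
                  & (df.time_bin == 1))]
        with pytest.raises(ValueError, match="s03"):
            stats.rm_anova(df, within=("relevance", "time_bin"),
                           between="group")

    def test_constant_shift_invariance(self, rng):
        df = _long_dataset(rng, effect=0.3)
        within = ("network", "relevance", "time_bin")
        a = stats.rm_anova(df, within=within, between="group")
        df2 = df.assign(value=df.value + 7.0)
        b = stats.rm_anova(df2, within=within, between="group")
        for e in a.table.index:
            if e != "(Intercept)":
                assert a.F(e) == pytest.approx(b.F(e))

    def test_subject_relabeling_invariance(self, rng):
        df = _long_dataset(rng, effect=0.3)
        within = ("network", "relevance", "time_bin")
        a = stats.rm_anova(df, within=within, between="group")
        relabel = {s: f"x{s}" for s in df.subject.unique()}
        b = stats.rm_anova(df.assign(subject=df.subject.map(relabel)),
                           within=within, between="group")
        for e in a.table.index:
            assert a.F(e) == pytest.approx(b.F(e))


class TestPermutationSchemes:
    def test_group_sizes_preserved(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=1)
        g = np.random.default_rng(0)
        for _ in range(20):
            null = stats.perm_null_group(df, g)
            sizes = null.groupby("group").subject.nunique()
            assert sizes["control"] == 12
            assert sizes["patient"] == 10
            # rows move with their subject
            assert (null.groupby("subject").group.nunique() == 1).all()

    def test_group_label_marginal_probability(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=1)
        g = np.random.default_rng(1)
        count = 0
        n_draw = 2000
        for _ in range(n_draw):
            null = stats.perm_null_group(df, g)
            if null[null.subject == "s00"].group.iloc[0] == "patient":
                count += 1
        expect = 10 / 22
        se = np.sqrt(expect * (1 - expect) / n_draw)
        assert abs(count / n_draw - expect) < 4 * se

    def test_condition_flip_preserves_pairs(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=1)
        g = np.random.default_rng(2)
        null = stats.perm_null_condition(df, g, factor="relevance")
        for s, sub in df.groupby("subject"):
            orig = set(map(tuple, sub[["relevance", "value"]].to_numpy()))
            got = null[null.subject == s]
            vals = dict(zip(got.relevance, got.value))
            flipped = {("relevant", v) if c == "irrelevant" else ("irrelevant", v)
                       for c, v in orig}
            assert set(map(tuple, got[["relevance", "value"]].to_numpy())) in (
                orig, flipped
            )

    def test_condition_flip_probability(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=1)
        g = np.random.default_rng(3)
        n_draw = 1000
        flips = 0
        ref = df[df.subject == "s00"].set_index("relevance").value
        for _ in range(n_draw):
            null = stats.perm_null_condition(df, g)
            got = null[null.subject == "s00"].set_index("relevance").value
            flips += got["relevant"] != ref["relevant"]
        assert abs(flips / n_draw - 0.5) < 0.05

    def test_more_than_two_levels_rejected(self, rng):
        df = _long_dataset(rng, networks=("a", "b", "c"), n_bins=1)
        with pytest.raises(ValueError, match="2 levels"):
            stats.perm_null_condition(df, np.random.default_rng(0),
                                      factor="network")

    def test_two_bin_enumeration(self):
        x = np.array([1.0, 5.0])
        outs = {tuple(stats.perm_null_time(x, np.random.default_rng(s)))
                for s in range(20)}
        m = 3.0
        assert outs <= {(m, m + 4.0), (m, m - 4.0)}
        assert (m, m + 4.0) in outs

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=18))
    def test_step_multiset_preserved(self, xs):
        x = np.asarray(xs)
        null = stats.perm_null_time(x, np.random.default_rng(0))
        assert np.allclose(sorted(np.diff(null)), sorted(np.diff(x)),
                           atol=1e-9)
        assert null[0] == pytest.approx(x.mean())

    def test_constant_series_fixed_point(self):
        c = np.full(7, 2.2)
        assert np.allclose(stats.perm_null_time(c, np.random.default_rng(1)),
                           2.2)


class TestPermPvalue:
    def test_counting_rule(self):
        nulls = np.arange(100.0)
        assert stats.perm_pvalue(1000.0, nulls) == 0.0
        assert stats.perm_pvalue(50.0, nulls) == 0.5
        assert stats.perm_pvalue(-1.0, nulls) == 1.0

    def test_add_one_smoothing(self):
        nulls = np.arange(100.0)
        assert stats.perm_pvalue(1000.0, nulls, add_one=True) == pytest.approx(
            1 / 101
        )

    def test_uniform_null_quantile(self, rng):
        nulls = rng.uniform(size=10_000)
        obs = np.quantile(nulls, 0.95)
        assert stats.perm_pvalue(obs, nulls) == pytest.approx(0.05, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.perm_pvalue(1.0, np.array([]))


class TestPermutationAnova:
    def test_detects_planted_interaction(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=2, effect=1.5)
        res = stats.permutation_anova(
            df, effects=["relevance:group"], n_iter=400, seed=0,
            within=("relevance", "time_bin"), between="group",
        )
        assert res.p_perm["relevance:group"] < 0.05

    def test_null_distribution_symmetric_for_flip(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=1)
        res = stats.permutation_anova(
            df, effects=["relevance"], n_iter=400, seed=0,
            within=("relevance",), between="group",
        )
        # F >= 0 always; sanity on distribution shape and p validity
        assert (res.null_F["relevance"] >= 0).all()
        assert 0.0 <= res.p_perm["relevance"] <= 1.0

    def test_time_effect_uses_step_scheme(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=6)
        res = stats.permutation_anova(
            df, effects=["time_bin"], n_iter=200, seed=0,
            within=("relevance", "time_bin"), between="group",
            contrast_factor="time_bin",
        )
        assert 0.0 <= res.p_perm["time_bin"] <= 1.0
        assert set(res.contrast_p["time_bin"]) == {"quadratic", "cubic"}

    def test_reproducible_with_seed(self, rng):
        df = _long_dataset(rng, networks=("insula",), n_bins=1)
        kw = dict(effects=["relevance:group"], n_iter=100, seed=5,
                  within=("relevance",), between="group")
        a = stats.permutation_anova(df, **kw)
        b = stats.permutation_anova(df, **kw)
        assert a.p_perm == b.p_perm
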