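import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from smrloop import (CohortSpec, analytic_power, ancova_change, cohens_d,
                     fdr_correct, generate_cohort, mixed_rmanova,
                     partial_correlation, required_sample_size,
                     standardized_mean_difference)


def _mixed_table(rng, n_per_group=8, shift=0.0):
    rows = []
    for i in range(2 * n_per_group):
        g = "real" if i < n_per_group else "sham"
        b = rng.normal(0, 1)
        for t in ("pre", "post"):
            y = b + rng.normal(0, 1) + (shift if (g, t) == ("real", "post")
                                        else 0.0)
            rows.append({"participant": f"P{i}", "group": g, "time": t,
                         "y": y})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_pingouin(self, rng):
        """Two-way mixed model agrees with an independent implementation."""
        df = _mixed_table(rng, shift=1.0)
        mine = mixed_rmanova(df, "y", within="time", between="group")
        ref = pg.mixed_anova(data=df, dv="y", within="time", between="group",
                             subject="participant")
        for src, ref_src in [("group", "group"), ("time", "time"),
                             ("time * group", "Interaction")]:
            row = mine.effect(src)
            rrow = ref[ref["Source"] == ref_src].iloc[0]
            assert row["F"] == pytest.approx(rrow["F"], rel=1e-9)
            assert row["p"] == pytest.approx(rrow["p_unc"], rel=1e-9)

    def test_symmetric_construction_zero_interaction(self):
        # change scores +-1 in both groups: group change means are equal, so
        # the interaction SS vanishes while the error term stays positive
        rows = []
        for i, (g, b, dt) in enumerate([("real", 0.0, 1.0), ("real", 1.0, -1.0),
                                        ("sham", 2.0, 1.0), ("sham", 3.0, -1.0)]):
            for t in ("pre", "post"):
                rows.append({"participant": f"P{i}", "group": g, "time": t,
                             "y": b + (dt if t == "post" else 0.0)})
        res = mixed_rmanova(pd.DataFrame(rows), "y", within="time",
                            between="group")
        assert res.effect("time * group")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_t_squared(self, rng):
        """Two-level within-only design: F is the squared paired t."""
        df = _mixed_table(rng)
        res = mixed_rmanova(df, "y", within="time")
        wide = df.pivot(index="participant", columns="time", values="y")
        t = sps.ttest_rel(wide["post"], wide["pre"]).statistic
        assert res.effect("time")["F"] == pytest.approx(t ** 2, abs=1e-8)

    def test_sphericity_violation_triggers_gg(self, rng):
        rows = []
        for i in range(14):
            base = rng.normal()
            c = rng.normal(scale=3.0)
            for j, cond in enumerate(("a", "b", "c")):
                # condition c carries most of the shared variability
                y = base + (c * (4.0 if j == 2 else 0.1)) + rng.normal(0, .2)
                rows.append({"participant": f"P{i}", "condition": cond,
                             "y": y})
        res = mixed_rmanova(pd.DataFrame(rows), "y", within="condition")
        row = res.effect("condition")
        assert row["eps_GG"] < 0.8
        assert row["GG_applied"]
        assert row["p_GG"] == pytest.approx(
            sps.f.sf(row["F"], row["eps_GG"] * row["df1"],
                     row["eps_GG"] * row["df2"]))

    def test_missing_cell_raises(self, rng):
        df = _mixed_table(rng).drop(index=[1])
        with pytest.raises(ValueError, match="missing design cells"):
            mixed_rmanova(df, "y", within="time", between="group")

    def test_power_increases_with_effect_size(self):
        """Interaction detection rate grows with the injected shift."""
        rates = []
        for d in (0.0, 0.6, 1.5):
            hits = 0
            for seed in range(60):
                tab = generate_cohort(CohortSpec(
                    baseline={"y": 0.0}, shift_real={"y": d}, shift_sham={},
                    between_sd=1.0, within_sd=1.0, seed=seed + int(1e4 * d)))
                r = mixed_rmanova(tab, "y", within="time", between="group")
                hits += r.p("time * group") < 0.05
            rates.append(hits / 60)
        assert rates[0] < rates[1] < rates[2]

    def test_posthoc_bonferroni(self, rng):
        df = _mixed_table(rng, shift=2.0)
        res = mixed_rmanova(df, "y", within="time", between="group",
                            posthoc=True)
        assert res.posthoc is not None
        if len(res.posthoc):
            assert (res.posthoc["p_bonf"] >= res.posthoc["p"] - 1e-12).all()


class TestAncova:
    def test_covariate_model_runs_and_detects_group(self, rng):
        df = _mixed_table(rng, shift=2.0)
        cov = {p: rng.normal() for p in df["participant"].unique()}
        df["mep_baseline"] = df["participant"].map(cov)
        res = ancova_change(df, "y", "mep_baseline")
        assert res.p("group") < 0.05
        assert "mep_baseline" in list(res.table["Source"])

    def test_via_mixed_rmanova_dispatch(self, rng):
        df = _mixed_table(rng)
        df["cov"] = 0.5
        df["cov"] = df["participant"].map(
            {p: rng.normal() for p in df["participant"].unique()})
        res = mixed_rmanova(df, "y", within="time", between="group",
                            covariate="cov")
        assert res.design.get("model") == "ancova_change"


class TestEffectSizes:
    def test_cohens_d_values(self):
        x = np.array([1.0, 2.0, 3.0])
        # paired with constant diff has zero sd -> error
        with pytest.raises(ValueError, match="zero variance"):
            cohens_d(x, x + 1.0, paired=True)
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1, 1, 2000)
        assert cohens_d(b, a) == pytest.approx(1.0, abs=0.1)
        assert cohens_d(a, a) == 0.0

    def test_smd_and_ci(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(1.0, 1, 40), rng.normal(0.0, 1, 40)
        res = standardized_mean_difference(x, y)
        assert res.ci_low < res.smd < res.ci_high
        small = standardized_mean_difference(x[:10], y[:10])
        # CI shrinks roughly as 1/sqrt(n)
        assert (res.ci_high - res.ci_low) < 0.6 * (small.ci_high - small.ci_low)
        assert standardized_mean_difference(y, y).smd == pytest.approx(0.0)


class TestPartialCorrelation:
    def test_conditional_independence(self, rng):
        n = 500
        z = rng.normal(size=n)
        df = pd.DataFrame({"x": z + rng.normal(size=n),
                           "y": z + rng.normal(size=n), "z": z})
        res = partial_correlation(df, [("x", "y")], ["z"])
        assert abs(res["r"].iloc[0]) < 0.1
        raw = partial_correlation(df, [("x", "y")], [])
        assert raw["r"].iloc[0] > 0.3

    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30),
                           "z": rng.normal(size=30)})
        res = partial_correlation(df, [("x", "x")], ["z"])
        assert res["r"].iloc[0] == 1.0

    def test_no_controls_reduces_to_pearson(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=60),
                           "y": rng.normal(size=60)})
        mine = partial_correlation(df, [("x", "y")], [])["r"].iloc[0]
        ref = np.corrcoef(df["x"], df["y"])[0, 1]
        assert mine == pytest.approx(ref, abs=1e-9)

    def test_too_few_cases(self, rng):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 1, 3],
                           "z": [0.0, 1, 2]})
        with pytest.raises(ValueError, match="complete cases"):
            partial_correlation(df, [("x", "y")], ["z"])


def brute_force_bh(p):
    """Benjamini–Hochberg from its step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestFdr:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([1.0, 1.0], [1.0, 1.0]),
    ])
    def test_enumerated(self, pvals, expected):
        np.testing.assert_allclose(fdr_correct(pvals), expected)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(fdr_correct(p), brute_force_bh(p),
                                       atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestSampleSize:
    def test_reproduces_printed_value(self):
        assert required_sample_size(0.60, 0.05, 0.80, "paired") == 24

    def test_monte_carlo_power_brackets_threshold(self):
        """Simulated paired-t power crosses 0.8 exactly at the returned n."""
        d = 0.6
        n = required_sample_size(d, 0.05, 0.8, "paired")
        rng = np.random.default_rng(0)

        def mc_power(n, reps=2000):
            x = rng.normal(d, 1.0, size=(reps, n))
            t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
            crit = sps.t.ppf(0.975, n - 1)
            return np.mean(np.abs(t) > crit)

        assert mc_power(n) >= 0.78
        assert mc_power(n - 1) < 0.80

    def test_large_effect_returns_minimum(self):
        assert required_sample_size(50.0) == 2

    def test_validation(self):
        with pytest.raises(ValueError):
            required_sample_size(0.6, alpha=1.5)
        with pytest.raises(ValueError):
            required_sample_size(-1.0)

    def test_two_sample_design(self):
        n = required_sample_size(0.6, design="two-sample")
        assert analytic_power(0.6, n, design="two-sample") >= 0.8
        assert analytic_power(0.6, n - 1, design="two-sample") < 0.8
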