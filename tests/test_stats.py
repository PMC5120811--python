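import itertools

import numpy as np
import pandas as pd
import pytest

from topoerp import stats as tstats


def brute_force_rm_anova(Y):
    """Textbook two-way within-subject ANOVA via explicit marginal means
    (independent of the package's inclusion-exclusion implementation)."""
    n, a, b = Y.shape
    gm = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mAB = Y.mean(axis=0)
    mAS = Y.mean(axis=2)
    mBS = Y.mean(axis=1)
    ss = {}
    ss["A"] = n * b * np.sum((mA - gm) ** 2)
    ss["B"] = n * a * np.sum((mB - gm) ** 2)
    ss["AB"] = n * np.sum((mAB - mA[:, None] - mB[None, :] + gm) ** 2)
    ss["AS"] = b * np.sum((mAS - mS[:, None] - mA[None, :] + gm) ** 2)
    ss["BS"] = a * np.sum((mBS - mS[:, None] - mB[None, :] + gm) ** 2)
    ss["ABS"] = np.sum((Y - mAB[None] - mAS[:, :, None] - mBS[:, None, :]
                        + mA[None, :, None] + mB[None, None, :]
                        + mS[:, None, None] - gm) ** 2)
    out = {}
    for eff, err, df1, df2 in (("A", "AS", a - 1, (n - 1) * (a - 1)),
                               ("B", "BS", b - 1, (n - 1) * (b - 1)),
                               ("AB", "ABS", (a - 1) * (b - 1),
                                (n - 1) * (a - 1) * (b - 1))):
        out[eff] = (ss[eff] / df1) / (ss[err] / df2), df1, df2
    return out


def brute_force_gg_epsilon(Y2):
    """Box/Greenhouse-Geisser epsilon from the double-centered covariance
    of a one-factor (subjects x levels) table."""
    S = np.cov(Y2, rowvar=False, ddof=1)
    k = S.shape[0]
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    lam = np.linalg.eigvalsh(Sc)
    return float(lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum()))


def _long(Y, factors):
    n = Y.shape[0]
    rows = []
    for s in range(n):
        for idx in itertools.product(*(range(l) for l in Y.shape[1:])):
            row = {"subject": f"S{s}", "dv": Y[(s, *idx)]}
            for f, i in zip(factors, idx):
                row[f] = f"{f}{i}"
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    @pytest.mark.parametrize("n,a,b", [(3, 2, 2), (4, 2, 3), (3, 2, 3), (4, 3, 3)])
    def test_matches_brute_force_sums_of_squares(self, n, a, b):
        rng = np.random.default_rng(n * 100 + a * 10 + b)
        Y = rng.standard_normal((n, a, b))
        res = tstats.rm_anova(_long(Y, ["A", "B"]), "dv", ["A", "B"])
        oracle = brute_force_rm_anova(Y)
        for eff, key in (("A", "A"), ("B", "B"), ("A:B", "AB")):
            F, df1, df2 = oracle[key]
            r = res.effects[eff]
            assert r["F"] == pytest.approx(F, abs=1e-8)
            assert (r["df1"], r["df2"]) == (df1, df2)

    def test_matches_gg_epsilon_oracle(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((10, 4)) * np.array([1.0, 1.5, 0.5, 2.0])
        res = tstats.rm_anova(_long(Y, ["A"]), "dv", ["A"])
        assert res.effects["A"]["epsilon"] == pytest.approx(
            brute_force_gg_epsilon(Y), abs=1e-10)

    def test_cross_check_statsmodels_three_factor(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(12)
        Y = rng.standard_normal((6, 2, 3, 2))
        df = _long(Y, ["gaze", "freq", "hemi"])
        res = tstats.rm_anova(df, "dv", ["gaze", "freq", "hemi"])
        sm = AnovaRM(df, "dv", "subject",
                     within=["gaze", "freq", "hemi"]).fit().anova_table
        for eff in res.effects:
            sm_name = eff.replace(":", ":")
            assert res.effects[eff]["F"] == pytest.approx(
                sm.loc[sm_name, "F Value"], abs=1e-8)
            assert res.effects[eff]["p"] == pytest.approx(
                sm.loc[sm_name, "Pr > F"], abs=1e-8)

    def test_cross_check_pingouin_sphericity(self):
        import pingouin as pg

        rng = np.random.default_rng(13)
        Y = rng.standard_normal((9, 3)) * np.array([1.0, 2.0, 0.4])
        df = _long(Y, ["A"])
        res = tstats.rm_anova(df, "dv", ["A"]).effects["A"]
        sph = pg.sphericity(df, dv="dv", subject="subject", within="A")
        eps = pg.epsilon(df, dv="dv", subject="subject", within="A",
                         correction="gg")
        assert res["mauchly_W"] == pytest.approx(sph.W, abs=1e-10)
        assert res["mauchly_p"] == pytest.approx(sph.pval, abs=1e-10)
        assert res["epsilon"] == pytest.approx(float(eps), abs=1e-10)

    def test_constant_dv(self):
        Y = np.full((4, 2, 3), 3.14)
        res = tstats.rm_anova(_long(Y, ["A", "B"]), "dv", ["A", "B"])
        for r in res.effects.values():
            assert r["F"] == 0.0
            assert r["p"] == 1.0

    def test_two_level_factor_no_correction(self):
        rng = np.random.default_rng(14)
        Y = rng.standard_normal((6, 2))
        res = tstats.rm_anova(_long(Y, ["A"]), "dv", ["A"])
        r = res.effects["A"]
        assert r["epsilon"] == 1.0
        assert np.isnan(r["mauchly_W"])
        assert not res.reported("A")["correction_applied"]

    def test_gg_correction_never_lowers_p(self):
        # the correction can only be anticonservative when F < 1, where no
        # one reports it; assert the invariant in the F > 1 regime
        rng = np.random.default_rng(15)
        checked = 0
        while checked < 10:
            Y = rng.standard_normal((8, 4)) * rng.uniform(0.2, 3.0, size=4)
            Y += np.array([0.0, 0.8, 1.6, 2.4])  # real effect
            res = tstats.rm_anova(_long(Y, ["A"]), "dv", ["A"])
            r = res.effects["A"]
            if r["F"] <= 2.0:  # the regime where the correction is at stake
                continue
            checked += 1
            assert r["p_gg"] >= r["p"] - 1e-12
            assert r["epsilon"] <= 1.0 + 1e-12
            assert r["epsilon"] >= 1.0 / 3 - 1e-12

    def test_unbalanced_rejected_naming_cells(self):
        Y = np.random.default_rng(16).standard_normal((4, 2, 2))
        df = _long(Y, ["A", "B"]).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            tstats.rm_anova(df, "dv", ["A", "B"])

    def test_too_few_subjects(self):
        Y = np.zeros((2, 2))
        with pytest.raises(ValueError, match="3 subjects"):
            tstats.rm_anova(_long(Y, ["A"]), "dv", ["A"])


class TestPosthoc:
    def test_identical_levels_degenerate(self):
        df = _long(np.tile(np.arange(6.0)[:, None], (1, 2)), ["A"])
        out = tstats.posthoc(df, "dv", "A")
        assert out.loc[0, "p_corrected"] == 1.0
        assert out.loc[0, "cohen_d"] == 0.0

    def test_three_levels_bonferroni_factor(self):
        rng = np.random.default_rng(17)
        df = _long(rng.standard_normal((6, 3)), ["A"])
        out = tstats.posthoc(df, "dv", "A")
        assert len(out) == 3
        assert (out["n_comparisons"] == 3).all()
        assert (out["p_corrected"] >= out["p_uncorrected"] - 1e-15).all()
        assert (out["p_corrected"] <= 1.0).all()

    def test_planted_shift_t_matches_closed_form_and_wilcoxon_agrees(self):
        rng = np.random.default_rng(18)
        n = 15
        base = rng.standard_normal(n)
        shift = 1.0 + rng.normal(0.0, 1.0, n)  # paired shift of ~1 SD
        Y = np.column_stack([base + shift, base])
        df = _long(Y, ["A"])
        out_t = tstats.posthoc(df, "dv", "A", method="paired_t")
        d = Y[:, 0] - Y[:, 1]
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert out_t.loc[0, "t"] == pytest.approx(t_hand, abs=1e-10)
        assert out_t.loc[0, "cohen_d"] == pytest.approx(
            d.mean() / d.std(ddof=1), abs=1e-12)
        out_w = tstats.posthoc(df, "dv", "A", method="wilcoxon")
        assert np.sign(out_t.loc[0, "t"]) > 0
        assert out_w.loc[0, "p_corrected"] < 0.05

    def test_unknown_effect(self):
        df = _long(np.zeros((3, 2)), ["A"])
        with pytest.raises(ValueError, match="unknown effect"):
            tstats.posthoc(df, "dv", "Z")


class TestSummarizeRt:
    def _trials(self, rts, corrects=None, subject="S1", cond="a"):
        corrects = corrects if corrects is not None else [True] * len(rts)
        return pd.DataFrame({"subject": subject, "condition": cond,
                             "rt_ms": rts, "correct": corrects})

    def test_bound_semantics_inclusive(self):
        df = self._trials([199.0, 200.0, 1500.0, 1501.0])
        out = tstats.summarize_rt(df)
        # {200, 1500} retained -> median 850
        assert out.loc[0, "median_rt_ms"] == 850.0
        assert out.loc[0, "accuracy"] == 1.0

    def test_median_and_log(self):
        out = tstats.summarize_rt(self._trials([500.0, 600.0, 700.0]))
        assert out.loc[0, "median_rt_ms"] == 600.0
        assert out.loc[0, "log_median_rt"] == pytest.approx(np.log(600.0))

    def test_accuracy_before_filtering_median_correct_only(self):
        df = self._trials([100.0, 500.0, 600.0, 900.0],
                          [True, True, False, True])
        out = tstats.summarize_rt(df)
        assert out.loc[0, "accuracy"] == 0.75          # all four trials
        assert out.loc[0, "median_rt_ms"] == 700.0     # {500, 900} correct+in-bounds

    def test_empty_cell_error(self):
        df = self._trials([100.0, 1600.0])  # everything filtered out
        with pytest.raises(ValueError, match="S1"):
            tstats.summarize_rt(df)

    def test_planted_rt_advantage_detected(self):
        """A 24 ms condition advantage over 15 subjects is detected by a
        paired t-test on log-medians at alpha = .05."""
        rng = np.random.default_rng(19)
        rows = []
        for s in range(15):
            base = rng.normal(580, 30)
            for cond, shift in (("direct", -12.0), ("averted", 12.0)):
                for _ in range(40):
                    rows.append({"subject": f"S{s:02d}", "condition": cond,
                                 "rt_ms": max(210.0, rng.normal(base + shift, 80)),
                                 "correct": rng.random() < 0.95})
        out = tstats.summarize_rt(pd.DataFrame(rows))
        res = tstats.posthoc(out, "log_median_rt", "condition",
                             method="paired_t")
        direction = out.groupby("condition")["median_rt_ms"].mean()
        assert direction["direct"] < direction["averted"]
        assert res.loc[0, "p_corrected"] < 0.05
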