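"""Tests for stage aggregation, OLS fits, repeated-measures ANOVA and ROC."""

import numpy as np
import pandas as pd
import pytest

import pulsedecomp as pdc
from pulsedecomp.errors import InvalidParameterError
from pulsedecomp.stats import rm_anova_f, simulate_cohort


def beats_frame(t13_values, onsets_s, valid=None, fs=512.0):
    n = len(t13_values)
    valid = [True] * n if valid is None else valid
    return pd.DataFrame(
        {
            "onset_sample": (np.asarray(onsets_s) * fs).astype(int),
            "t13": t13_values,
            "p2p1": [0.3] * n,
            "valid": valid,
        }
    )


class TestStageAggregate:
    def test_constant_input(self):
        beats = beats_frame([240.0] * 5, [1, 2, 3, 4, 5])
        schedule = [{"lbnp_mmhg": 0, "duration_s": 10.0}]
        out = pdc.stage_aggregate(beats, schedule, 512.0)
        assert out.loc[0, "mean_t13"] == pytest.approx(240.0)
        assert out.loc[0, "se_t13"] == pytest.approx(0.0)

    def test_two_stage_delta(self):
        rng = np.random.default_rng(0)
        a = 240.0 + rng.normal(0, 1.0, 40)
        b = 220.0 + rng.normal(0, 1.0, 40)
        onsets = np.concatenate([np.linspace(0.5, 39, 40), np.linspace(40.5, 79, 40)])
        beats = beats_frame(np.concatenate([a, b]), onsets)
        schedule = [
            {"lbnp_mmhg": 0, "duration_s": 40.0},
            {"lbnp_mmhg": -30, "duration_s": 40.0},
        ]
        out = pdc.stage_aggregate(beats, schedule, 512.0)
        delta = out.loc[1, "mean_t13"] - out.loc[0, "mean_t13"]
        assert delta == pytest.approx(-20.0, abs=3.0)

    def test_missing_stage_flagged(self):
        beats = beats_frame([240.0] * 3, [1, 2, 3])
        schedule = [
            {"lbnp_mmhg": 0, "duration_s": 10.0},
            {"lbnp_mmhg": -15, "duration_s": 10.0},
        ]
        out = pdc.stage_aggregate(beats, schedule, 512.0)
        assert not out.loc[0, "missing"]
        assert bool(out.loc[1, "missing"])

    def test_invalid_beats_excluded(self):
        beats = beats_frame([240.0, 500.0], [1, 2], valid=[True, False])
        schedule = [{"lbnp_mmhg": 0, "duration_s": 10.0}]
        out = pdc.stage_aggregate(beats, schedule, 512.0)
        assert out.loc[0, "mean_t13"] == pytest.approx(240.0)
        assert out.loc[0, "n_beats"] == 1


class TestFits:
    def test_known_line_self_consistency(self):
        # self-consistency fixture: a known line y = 0.19 x + 2.58
        x = np.linspace(150.0, 250.0, 12)
        y = 0.19 * x + 2.58
        fit = pdc.fit_linear(x, y)
        assert fit.coefficients["slope"] == pytest.approx(0.19, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(2.58, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = pdc.fit_linear(x, np.full(4, 7.0))
        assert fit.coefficients["slope"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == 1.0

    def test_quadratic_on_symmetric_design(self):
        # closed form: y = x^2 on symmetric x has zero linear covariance
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x**2
        lin = pdc.fit_linear(x, y)
        assert lin.coefficients["slope"] == pytest.approx(0.0, abs=1e-12)
        quad = pdc.fit_quadratic(x, y)
        assert quad.coefficients["b2"] == pytest.approx(1.0, abs=1e-10)
        assert quad.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(InvalidParameterError):
            pdc.fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            pdc.fit_linear([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            pdc.fit_quadratic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestRmAnova:
    def test_no_effect_gives_p_one(self):
        data = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 4))  # constant per subject
        res = rm_anova_f(data)
        assert res.p_value == 1.0

    def test_strong_effect_resolved(self):
        rng = np.random.default_rng(2)
        n, effect, noise = 15, 5.0, 0.5
        base = rng.normal(200.0, 4.0, n)[:, None]
        levels = np.arange(3)[None, :] * effect
        data = base + levels + rng.normal(0, noise, (n, 3))
        res = rm_anova_f(data)
        assert res.p_value < 0.01

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        n, k = 12, 4
        data = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "level": np.tile(np.arange(k), n),
                "y": data.ravel(),
            }
        )
        oracle = AnovaRM(long, "y", "subject", within=["level"]).fit()
        f_oracle = float(oracle.anova_table["F Value"].iloc[0])
        p_oracle = float(oracle.anova_table["Pr > F"].iloc[0])
        res = rm_anova_f(data)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-8)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-8)

    def test_null_p_values_uniform(self):
        # permutation/null oracle: iid data has uniform p-values
        rng = np.random.default_rng(11)
        pvals = [
            rm_anova_f(rng.normal(0, 1, (8, 4))).p_value for _ in range(300)
        ]
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_table_interface_and_listwise_deletion(self):
        rng = np.random.default_rng(3)
        table = simulate_cohort(8, rng, stage_lbnp=(0, -15, -30))
        # drop one subject's -30 row -> listwise deletion warning
        table = table.drop(table[(table.subject_id == "s00") & (table.lbnp_mmhg == -30)].index)
        with pytest.warns(UserWarning):
            res = pdc.rm_anova(table, stages=[-15, -30])
        assert res.n_subjects == 7

    def test_pooled_mode(self):
        rng = np.random.default_rng(4)
        table = simulate_cohort(10, rng, stage_lbnp=(0, -15, -30))
        res = pdc.rm_anova(table, stages=[-15, -30], mode="pooled")
        assert res.df_effect == 1.0
        assert 0.0 < res.p_value <= 1.0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(5)
        table = simulate_cohort(1, rng, stage_lbnp=(0, -15))
        with pytest.raises(InvalidParameterError):
            pdc.rm_anova(table, stages=[-15])


class TestRoc:
    @staticmethod
    def _table(vals_a, vals_b, base=200.0):
        rows = []
        for i, (a, b) in enumerate(zip(vals_a, vals_b)):
            sid = f"s{i:02d}"
            rows += [
                {"subject_id": sid, "lbnp_mmhg": 0, "mean_t13": base},
                {"subject_id": sid, "lbnp_mmhg": -15, "mean_t13": base + a},
                {"subject_id": sid, "lbnp_mmhg": -30, "mean_t13": base + b},
            ]
        return pd.DataFrame(rows)

    def test_perfect_separation(self):
        table = self._table([-1.0, -2.0, -1.5, -1.2, -0.8], [-10.0, -11.0, -9.0, -12.0, -8.0])
        res = pdc.roc_stage(table, -30, -15)
        assert res.auc == pytest.approx(1.0)

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(6)
        table = self._table(rng.normal(0, 1, 60), rng.normal(0, 1, 60))
        res = pdc.roc_stage(table, -30, -15, direction="greater")
        assert res.auc == pytest.approx(0.5, abs=0.12)

    def test_curve_endpoints(self):
        table = self._table([-1.0] * 5, [-10.0] * 5)
        res = pdc.roc_stage(table, -30, -15)
        assert res.sensitivity[0] == 1.0 and res.specificity[0] == 0.0
        assert res.sensitivity[-1] == 0.0 and res.specificity[-1] == 1.0

    def test_too_few_pairs_rejected(self):
        table = self._table([-1.0] * 3, [-2.0] * 3)
        with pytest.raises(InvalidParameterError):
            pdc.roc_stage(table, -30, -15)

    def test_t13_outranks_noisy_pp(self):
        rng = np.random.default_rng(8)
        table = simulate_cohort(15, rng, stage_lbnp=(0, -15, -30))
        auc_t13 = pdc.roc_stage(table, -30, -15, dv="mean_t13").auc
        auc_pp = pdc.roc_stage(table, -30, -15, dv="mean_pp_cuff").auc
        assert auc_t13 > auc_pp
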