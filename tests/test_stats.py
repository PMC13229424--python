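"""Group-comparison mixed models, normality gate, Gamma fallback."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from vaviq.stats import (
    GroupComparisonModel,
    bonferroni,
    fit_lmm,
    permutation_test,
    shapiro_wilk,
    summarize_groups,
)
from vaviq.synthetic import SyntheticPreset, simulate_slice_table


def make_table(group_means, n_patients=3, n_slices=25, within_sd=1.0,
               between_sd=0.0, seed=0, metric="amp_um"):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mean in group_means.items():
        for i in range(n_patients):
            pid = f"{g[:2]}{i}"
            pm = mean + between_sd * rng.standard_normal()
            vals = pm + within_sd * rng.standard_normal(n_slices)
            for k, v in enumerate(vals):
                rows.append(
                    dict(
                        patient_id=pid,
                        group_label=g,
                        slice_index=k,
                        arclength_mm=k + 0.5,
                        metric_name=metric,
                        mean_value=v,
                    )
                )
    return pd.DataFrame(rows)


class TestBonferroni:
    def test_three_comparison_level(self):
        assert bonferroni(0.05, 3) == 0.0167

    def test_identity_and_arithmetic(self):
        assert bonferroni(0.05, 1) == 0.05
        assert bonferroni(0.10, 4) == 0.025

    def test_monotone_decreasing(self):
        vals = [bonferroni(0.05, n) for n in range(1, 8)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestShapiroWilk:
    def test_reference_implementation_oracle(self):
        # reference W computed with R's shapiro.test
        w, p = shapiro_wilk([-2, -1, -1, 0, 0, 0, 0, 1, 1, 2])
        assert w == pytest.approx(0.9528768050, abs=1e-6)
        assert p == pytest.approx(0.7025891774, abs=1e-6)

    def test_power_against_exponential(self):
        rng = np.random.default_rng(0)
        hits = sum(
            shapiro_wilk(rng.exponential(size=100))[1] < 0.05 for _ in range(100)
        )
        assert hits >= 99

    def test_perfect_normal_quantiles(self):
        q = sp_stats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, _ = shapiro_wilk(q)
        assert w > 0.99

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestGroupComparison:
    def test_balanced_design_matches_closed_form_gls(self):
        # balanced random-intercept design: the GLS fixed effects are the
        # plain group means, whatever the variance components
        table = make_table(
            {"patency": 5.0, "stenosis": 9.0}, n_patients=3, between_sd=1.0, seed=4
        )
        res = GroupComparisonModel(table, "amp_um", "two_group", family="gaussian").fit()
        df = table[table.metric_name == "amp_um"]
        m_pat = df[df.group_label == "patency"]["mean_value"].mean()
        m_adv = df[df.group_label != "patency"]["mean_value"].mean()
        assert res.fixed_effects["intercept"][0] == pytest.approx(m_pat, abs=1e-6)
        assert res.fixed_effects["adverse_vs_patency"][0] == pytest.approx(
            m_adv - m_pat, abs=1e-6
        )

    def test_near_degenerate_separation(self):
        # vanishing noise: contrast equals the mean difference, p ~ 0
        table = make_table(
            {"patency": 5.0, "stenosis": 9.0}, within_sd=1e-6, seed=1
        )
        res = GroupComparisonModel(table, "amp_um", "two_group", family="gaussian").fit()
        assert res.fixed_effects["adverse_vs_patency"][0] == pytest.approx(4.0, abs=1e-4)
        assert res.p_values["adverse_vs_patency"] < 1e-6

    def test_gamma_glmm_matches_glmmTMB_reference(self):
        # reference values computed with R glmmTMB (Gamma, log link) on
        # this exact table
        t = simulate_slice_table(seed=0)
        res = GroupComparisonModel(t, "amp_um", "two_group", family="gamma").fit()
        est, se = res.fixed_effects["intercept"]
        assert est == pytest.approx(2.0300930, abs=1e-4)
        assert se == pytest.approx(0.1614462, abs=1e-3)
        est, se = res.fixed_effects["adverse_vs_patency"]
        assert est == pytest.approx(0.9638232, abs=1e-4)
        assert se == pytest.approx(0.1977306, abs=1e-3)
        assert res.var_patient == pytest.approx(0.04934832, rel=1e-2)
        assert res.var_resid == pytest.approx(0.06944604, rel=1e-2)

    def test_normality_gate_selects_family(self):
        gauss = make_table({"patency": 5.0, "stenosis": 9.0}, seed=2)
        res = fit_lmm(gauss, "amp_um", "two_group")
        assert res.model_family == "gaussian"
        skewed = gauss.copy()
        rng = np.random.default_rng(3)
        skewed["mean_value"] = rng.lognormal(
            np.log(skewed["mean_value"].clip(lower=0.5)), 0.6
        )
        res2 = fit_lmm(skewed, "amp_um", "two_group")
        assert res2.shapiro_p < 0.05
        assert res2.model_family == "gamma_log"

    def test_families_agree_in_sign_on_separated_data(self):
        table = make_table({"patency": 5.0, "stenosis": 20.0}, between_sd=1.0, seed=6)
        g = GroupComparisonModel(table, "amp_um", "two_group", family="gaussian").fit()
        gm = GroupComparisonModel(table, "amp_um", "two_group", family="gamma").fit()
        assert np.sign(g.fixed_effects["adverse_vs_patency"][0]) == np.sign(
            gm.fixed_effects["adverse_vs_patency"][0]
        )

    def test_three_group_contrasts_and_bonferroni_level(self):
        t = simulate_slice_table(seed=9)
        res = fit_lmm(t, "amp_um", "three_group")
        assert set(res.p_values) == {"stenosis_vs_patency", "dilatation_vs_patency"}
        assert res.alpha_adjusted == 0.025  # 0.05 / 2 contrasts reported
        res2 = fit_lmm(t, "amp_um", "two_group")
        assert res2.alpha_adjusted == 0.05

    def test_parameter_recovery_within_reported_interval(self):
        # >= 93% of fits recover the true contrast within the model's own
        # 95% interval (t with between-cluster df; plain 2*SE cannot reach
        # nominal coverage with six clusters) at the six-patient design size
        hits, n_rep = 0, 100
        truth = 10.0
        for s in range(n_rep):
            table = make_table(
                {"patency": 20.0, "stenosis": 20.0 + truth},
                n_patients=3,
                between_sd=2.0,
                within_sd=3.0,
                seed=100 + s,
            )
            res = GroupComparisonModel(
                table, "amp_um", "two_group", family="gaussian"
            ).fit()
            est, se = res.fixed_effects["adverse_vs_patency"]
            half = sp_stats.t.ppf(0.975, res.df_contrast) * se
            hits += abs(est - truth) <= half
        assert hits / n_rep >= 0.93

    def test_refuses_single_patient(self):
        table = make_table({"patency": 5.0}, n_patients=1)
        with pytest.raises(ValueError, match="< 2 patients"):
            GroupComparisonModel(table, "amp_um")

    def test_summary_renders(self):
        res = fit_lmm(simulate_slice_table(seed=1), "amp_um")
        text = res.summary()
        assert "adverse_vs_patency" in text and "family=" in text


class TestSummaries:
    def test_constant_metric_sd_zero(self):
        t = make_table({"patency": 3.0}, n_patients=1, within_sd=0.0)
        out = summarize_groups(t)
        assert out["group_sd"].iloc[0] == pytest.approx(0.0)

    def test_sample_sd_convention(self):
        t = pd.DataFrame(
            {
                "patient_id": ["P1", "P1"],
                "group_label": ["g", "g"],
                "slice_index": [0, 1],
                "arclength_mm": [0.5, 1.5],
                "metric_name": ["m", "m"],
                "mean_value": [1.0, 3.0],
            }
        )
        out = summarize_groups(t)
        assert out["group_mean"].iloc[0] == pytest.approx(2.0)
        assert out["group_sd"].iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups(pd.DataFrame())


class TestPermutation:
    def test_exact_enumeration_floor(self):
        # 2 vs 4 patients with homogeneous groups: 15 label assignments,
        # only the true one is maximal, so p = 1/15 exactly
        t = simulate_slice_table(n_per_group={"patency": 2, "stenosis": 4}, seed=0)
        p = permutation_test(t, "amp_um")
        assert p == pytest.approx(1.0 / 15.0)

    def test_null_is_not_small(self):
        preset = {
            g: SyntheticPreset(
                group_label=g,
                vib_bands=((90.0, 130.0, 1.0),),
                target_timeavg_amp_um=6.6,
                target_strain_e3=0.3,
                amp_sd_um=2.0,
                strain_sd_e3=0.1,
            )
            for g in ("patency", "stenosis", "dilatation")
        }
        ps = [
            permutation_test(simulate_slice_table(presets=preset, seed=s), "amp_um")
            for s in range(20)
        ]
        assert np.mean([p <= 1.0 / 15.0 for p in ps]) <= 0.3
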