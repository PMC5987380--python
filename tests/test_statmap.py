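"""Factorial ANOVA maps: p-values, bands, diagnostics, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonemap import phantom, statmap
from bonemap.statmap import (EFFECTS, anova_many, fit_factorial_anova,
                             group_summary, heatmap_statmap, residual_checks,
                             significance_bands)


class TestBands:
    @pytest.mark.parametrize("p,band", [
        (0.0009, "red"), (0.001, "yellow"), (0.0099, "yellow"),
        (0.01, "green"), (0.049, "green"), (0.05, "blue"), (0.9, "blue"),
        (0.0, "red"),
    ])
    def test_half_open_boundaries(self, p, band):
        assert significance_bands(p) == band

    def test_nan_maps_to_na(self):
        assert significance_bands(float("nan")) == "na"

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_band_is_pure_function_of_p(self, p):
        band = significance_bands(p)
        edges = {"red": p < 0.001, "yellow": 0.001 <= p < 0.01,
                 "green": 0.01 <= p < 0.05, "blue": p >= 0.05}
        assert edges[band]


class TestAnova:
    def test_matches_statsmodels_type3_on_unbalanced_data(self,
                                                          factorial_table):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        tbl = factorial_table.drop(index=[0, 6, 31]).reset_index(drop=True)
        fit = fit_factorial_anova(tbl, "y")
        m = smf.ols("y ~ C(genotype, Sum)*C(sex, Sum)*C(age, Sum)",
                    data=tbl).fit()
        a = anova_lm(m, typ=3)
        names = {
            "genotype": "C(genotype, Sum)", "sex": "C(sex, Sum)",
            "age": "C(age, Sum)",
            "genotype:sex": "C(genotype, Sum):C(sex, Sum)",
            "genotype:age": "C(genotype, Sum):C(age, Sum)",
            "sex:age": "C(sex, Sum):C(age, Sum)",
            "genotype:sex:age": "C(genotype, Sum):C(sex, Sum):C(age, Sum)",
        }
        for eff, row in names.items():
            assert fit.p_values[eff] == pytest.approx(a.loc[row, "PR(>F)"],
                                                      rel=1e-9)
        assert fit.r_squared == pytest.approx(m.rsquared, rel=1e-12)

    def test_balanced_type1_equals_type3(self, factorial_table):
        """For balanced designs sequential and marginal tests agree."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        fit = fit_factorial_anova(factorial_table, "y")
        m = smf.ols("y ~ C(genotype, Sum)*C(sex, Sum)*C(age, Sum)",
                    data=factorial_table).fit()
        a1 = anova_lm(m, typ=1)
        names = {"genotype": "C(genotype, Sum)", "sex": "C(sex, Sum)",
                 "age": "C(age, Sum)"}
        for eff, row in names.items():
            assert fit.p_values[eff] == pytest.approx(a1.loc[row, "PR(>F)"],
                                                      rel=1e-9)

    def test_strong_genotype_shift_detected_only_there(self, factorial_table):
        tbl = factorial_table.copy()
        tbl["y"] = tbl["y"] + 10.0 * (tbl.genotype == "STR")
        fit = fit_factorial_anova(tbl, "y")
        assert fit.p_values["genotype"] < 0.001
        assert all(fit.p_values[e] > 0.001 for e in EFFECTS
                   if e != "genotype")

    def test_constant_response_flagged_degenerate(self, factorial_table):
        tbl = factorial_table.copy()
        tbl["y"] = 3.0
        fit = fit_factorial_anova(tbl, "y")
        assert fit.degenerate
        assert fit.r_squared == 0.0
        assert all(np.isnan(p) for p in fit.p_values.values())

    def test_permutation_invariance(self, factorial_table):
        fit1 = fit_factorial_anova(factorial_table, "y")
        shuffled = factorial_table.sample(frac=1.0, random_state=5
                                          ).reset_index(drop=True)
        fit2 = fit_factorial_anova(shuffled, "y")
        for e in EFFECTS:
            assert fit1.p_values[e] == pytest.approx(fit2.p_values[e],
                                                     rel=1e-9)

    def test_empty_cell_named_in_error(self, factorial_table):
        tbl = factorial_table[~((factorial_table.genotype == "CBA")
                                & (factorial_table.sex == "F")
                                & (factorial_table.age == 40))]
        with pytest.raises(ValueError, match="empty factorial cell"):
            fit_factorial_anova(tbl, "y")

    def test_single_replicate_cell_rejected(self, factorial_table):
        cell = ((factorial_table.genotype == "CBA")
                & (factorial_table.sex == "F")
                & (factorial_table.age == 40))
        tbl = pd.concat([factorial_table[~cell],
                         factorial_table[cell].head(1)])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_factorial_anova(tbl, "y")

    def test_null_type1_error_rate_in_binomial_band(self, factorial_table):
        rates = statmap.simulate_null_rejection_rates(
            factorial_table[["genotype", "sex", "age"]], n_reps=400, seed=0)
        for eff, r in rates.items():
            assert 0.02 <= r <= 0.08, f"{eff}: {r}"


class TestResiduals:
    def test_gaussian_residuals_pass_both_screens(self, factorial_table):
        fit = fit_factorial_anova(factorial_table, "y")
        diag = residual_checks(fit)
        assert diag.shapiro_p > 0.05
        assert diag.bartlett_p > 0.05
        assert diag.warnings == []

    def test_lognormal_noise_flags_normality(self, factorial_table):
        rng = np.random.default_rng(0)
        tbl = factorial_table.copy()
        tbl["y"] = rng.lognormal(0.0, 1.2, len(tbl))
        diag = residual_checks(fit_factorial_anova(tbl, "y"))
        assert diag.shapiro_p < 0.05
        assert any("normality" in w for w in diag.warnings)

    def test_variance_ratio_flags_bartlett(self, factorial_table):
        rng = np.random.default_rng(1)
        tbl = factorial_table.copy()
        cell = (tbl.genotype == "CBA") & (tbl.sex == "M") & (tbl.age == 10)
        y = rng.normal(0, 1, len(tbl))
        y[cell.to_numpy()] = rng.normal(0, 16.0, int(cell.sum()))
        tbl["y"] = y
        diag = residual_checks(fit_factorial_anova(tbl, "y"))
        assert diag.bartlett_p < 0.05


class TestGroupSummary:
    def test_hand_computed_t_interval(self):
        tbl = pd.DataFrame({
            "genotype": ["CBA"] * 5, "sex": ["M"] * 5, "age": [10] * 5,
            "y": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = group_summary(tbl, "y")
        assert out.iloc[0]["mean"] == pytest.approx(3.0)
        assert out.iloc[0].ci95_half == pytest.approx(1.9632, abs=1e-3)

    def test_single_animal_ci_undefined(self):
        tbl = pd.DataFrame({"genotype": ["CBA"], "sex": ["M"], "age": [10],
                            "y": [1.0]})
        out = group_summary(tbl, "y")
        assert np.isnan(out.iloc[0].ci95_half)

    def test_zero_variance_zero_halfwidth(self):
        tbl = pd.DataFrame({"genotype": ["CBA"] * 3, "sex": ["M"] * 3,
                            "age": [10] * 3, "y": [2.0, 2.0, 2.0]})
        out = group_summary(tbl, "y")
        assert out.iloc[0].ci95_half == 0.0


class TestHeatmap:
    @pytest.fixture(scope="class")
    def interaction_cohort(self):
        design = phantom.CohortDesign(
            n_per_cell=5,
            effect_map=[phantom.Effect(
                "bump_amount", {"genotype": "STR", "sex": "M"}, add=0.3)],
            noise_map={"ellipticity": 0.05},
            seed=0)
        animals, cov = phantom.generate_cohort(design)
        return phantom.cohort_groundtruth_profiles(
            animals, cov, np.arange(10.0, 91.0),
            measurement_sd={"ellipticity": 0.01}, seed=0)

    def test_localized_interaction_recovered(self, interaction_cohort):
        res = heatmap_statmap(interaction_cohort,
                              ["ellipticity"])["ellipticity"]
        row = list(EFFECTS).index("genotype:sex")
        percents = res.percents
        inside = (percents >= 30) & (percents <= 40)
        assert (res.bands[row][inside] != "blue").all()
        assert (res.bands[row][~inside] == "blue").mean() >= 0.95

    def test_grid_mismatch_rejected(self, interaction_cohort):
        broken = interaction_cohort[
            ~((interaction_cohort.animal == "a000")
              & (interaction_cohort.percent == 50.0))]
        with pytest.raises(ValueError, match="percent grid"):
            heatmap_statmap(broken, ["ellipticity"])

    def test_render_heatmap_deterministic(self, interaction_cohort, tmp_path):
        res = heatmap_statmap(interaction_cohort,
                              ["ellipticity"])["ellipticity"]
        statmap.render_heatmap(res, tmp_path / "a.png")
        statmap.render_heatmap(res, tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == \
            (tmp_path / "b.png").read_bytes()

    def test_fdr_only_weakens_significance(self, interaction_cohort):
        raw = heatmap_statmap(interaction_cohort,
                              ["ellipticity"])["ellipticity"]
        adj = heatmap_statmap(interaction_cohort, ["ellipticity"],
                              fdr=True)["ellipticity"]
        ok = ~np.isnan(raw.p_values)
        assert np.all(adj.p_values[ok] >= raw.p_values[ok] - 1e-12)
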