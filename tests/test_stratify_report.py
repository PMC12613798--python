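"""Stratified analyses, slope-homogeneity F-test, BCF assessment, pipeline."""

import numpy as np
import pandas as pd
import pytest

from thermotk import (
    GeneratorConfig,
    UnfittableError,
    assess_bcf_temperature_dependence,
    fit_arrhenius,
    holm_adjust,
    run_pipeline,
    stratified_fits,
)
from thermotk.stratify_report import pairwise_slope_tests
from thermotk.stratify_report import test_slope_equality as slope_equality_test

from conftest import make_records


def stratum(chemical, slope, intercept, n=10, sigma=0.0, rng=None, species="sp"):
    temps = np.linspace(278.0, 303.0, n)
    noise = rng.normal(0, sigma, n) if (rng is not None and sigma > 0) else 0.0
    k = np.exp(intercept + slope / temps + noise)
    return make_records(temps, k, chemical=chemical, species=species)


class TestStratifiedFits:
    def test_five_chemicals_five_temperatures_all_fitted(self):
        frames = [stratum(f"c{i}", -9000.0 - 200 * i, 30.0, n=5) for i in range(5)]
        analysis = stratified_fits(pd.concat(frames, ignore_index=True), "chemical")
        assert len(analysis.strata) == 5
        assert analysis.excluded == []

    def test_sparse_stratum_excluded_and_reported(self):
        good = stratum("c_good", -9000.0, 30.0, n=6)
        sparse = make_records([280.0, 285.0, 290.0], [1.0, 2.0, 3.0],
                              chemical="c_sparse")
        analysis = stratified_fits(pd.concat([good, sparse], ignore_index=True),
                                   "chemical")
        assert [s.stratum_key for s in analysis.strata] == ["c_good"]
        assert analysis.excluded[0][0] == "c_sparse"
        assert "3 distinct" in analysis.excluded[0][1]

    def test_noiseless_strata_sharing_slope_agree_to_machine_precision(self):
        frames = [stratum(f"c{i}", -8500.0, 25.0 + i, n=6) for i in range(4)]
        analysis = stratified_fits(pd.concat(frames, ignore_index=True), "chemical")
        slopes = [s.result.slope_K for s in analysis.strata]
        assert np.allclose(slopes, -8500.0, rtol=1e-9)

    def test_single_stratum_equals_pooled_fit(self):
        df = stratum("only", -9100.0, 28.0, n=8, sigma=0.3,
                     rng=np.random.default_rng(5))
        analysis = stratified_fits(df, "chemical")
        pooled = fit_arrhenius(df)
        assert analysis.strata[0].result.slope_K == pytest.approx(pooled.slope_K)
        assert analysis.strata[0].result.se_slope == pytest.approx(pooled.se_slope)

    def test_equal_width_dow_binning_option(self):
        from thermotk import assign_dow_bins

        frames = [stratum(f"c{i}", -9000.0, 30.0, n=5) for i in range(6)]
        df = pd.concat(frames, ignore_index=True)
        df["log_dow"] = np.tile([0.5, 2.5, 4.5, 6.5, 7.5, 1.5], 5)
        binned = assign_dow_bins(df, n_bins=2)
        assert binned["dow_bin"].nunique() == 2
        analysis = stratified_fits(binned, "dow_bin")
        assert len(analysis.strata) == 2

    def test_strata_frame_carries_holm_column(self):
        rng = np.random.default_rng(3)
        frames = [stratum(f"c{i}", -9000.0, 30.0, n=8, sigma=0.4, rng=rng)
                  for i in range(3)]
        analysis = stratified_fits(pd.concat(frames, ignore_index=True), "chemical")
        table = analysis.to_frame()
        assert "p_value_holm" in table.columns
        assert (table["p_value_holm"] >= table["p_value_slope"] - 1e-15).all()


class TestSlopeEquality:
    def test_duplicated_stratum_gives_f_zero_p_one(self):
        rng = np.random.default_rng(1)
        a = stratum("A", -9000.0, 30.0, n=8, sigma=0.5, rng=rng)
        b = a.copy()
        b["chemical"] = "B"
        t = slope_equality_test(pd.concat([a, b], ignore_index=True), "chemical")
        assert t.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert t.p_value == pytest.approx(1.0)
        assert t.df_num == 1

    def test_invariant_to_relabeling_and_y_shift(self):
        rng = np.random.default_rng(2)
        frames = [stratum(c, -9000.0 + off, 30.0, n=10, sigma=0.5, rng=rng)
                  for c, off in (("A", 0.0), ("B", 1500.0), ("C", -800.0))]
        df = pd.concat(frames, ignore_index=True)
        t1 = slope_equality_test(df, "chemical")
        relabeled = df.copy()
        relabeled["chemical"] = relabeled["chemical"].map(
            {"A": "zz", "B": "aa", "C": "mm"})
        t2 = slope_equality_test(relabeled, "chemical")
        shifted = df.copy()
        shifted["k"] = shifted["k"] * np.exp(3.0)  # adds a constant to ln k
        t3 = slope_equality_test(shifted, "chemical")
        assert t1.f_statistic == pytest.approx(t2.f_statistic, rel=1e-12)
        assert t1.f_statistic == pytest.approx(t3.f_statistic, rel=1e-9)

    def test_needs_two_fittable_strata(self):
        only = stratum("A", -9000.0, 30.0, n=6)
        with pytest.raises(UnfittableError, match=">= 2 strata"):
            slope_equality_test(only, "chemical")
        tiny = make_records([280.0, 290.0], [1.0, 2.0], chemical="B")
        with pytest.raises(UnfittableError, match="need >= 3"):
            slope_equality_test(pd.concat([only, tiny], ignore_index=True), "chemical")

    def test_detects_a_divergent_slope(self):
        """Monte-Carlo power at one stratum offset +3000 K (4 strata, n=40,
        sigma=0.5): rejection rate sits far above the 5% level (the seeded
        oracle run puts it near 0.59)."""
        rng = np.random.default_rng(0)
        reps, rejections = 200, 0
        for _ in range(reps):
            frames = []
            for g in range(4):
                slope = -10_000.0 + (3000.0 if g == 0 else 0.0)
                temps = rng.uniform(278.0, 303.0, 40)
                k = np.exp(30.0 + slope / temps + rng.normal(0, 0.5, 40))
                frames.append(make_records(temps, k, chemical=f"c{g}"))
            t = slope_equality_test(pd.concat(frames, ignore_index=True), "chemical")
            rejections += t.p_value < 0.05
        assert rejections / reps > 0.45

    def test_pairwise_variant_flags_the_divergent_pair(self):
        rng = np.random.default_rng(4)
        frames = [stratum("A", -10_000.0, 30.0, n=40, sigma=0.3, rng=rng),
                  stratum("B", -10_000.0, 31.0, n=40, sigma=0.3, rng=rng),
                  stratum("C", -4000.0, 12.0, n=40, sigma=0.3, rng=rng)]
        table = pairwise_slope_tests(pd.concat(frames, ignore_index=True), "chemical")
        assert len(table) == 3
        ab = table[(table.stratum_a == "A") & (table.stratum_b == "B")]
        assert float(ab["p_value"].iloc[0]) > 0.05
        ac = table[(table.stratum_a == "A") & (table.stratum_b == "C")]
        assert float(ac["p_value_holm"].iloc[0]) < 0.01

    def test_holm_adjustment_is_step_down(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])


class TestBCFAssessment:
    def _fit(self, slope, sigma, rng, n=100, rate_type="uptake"):
        temps = rng.uniform(278.0, 303.0, n)
        k = np.exp(30.0 + slope / temps + rng.normal(0, sigma, n))
        return fit_arrhenius(make_records(temps, k, rate_type=rate_type))

    def test_identical_fits_give_zero_delta(self):
        rng = np.random.default_rng(6)
        fit = self._fit(-9000.0, 0.5, rng)
        res = assess_bcf_temperature_dependence(fit, fit)
        assert res.delta_slope_K == 0.0
        assert res.temperature_independent

    def test_antisymmetric_in_fit_order(self):
        rng = np.random.default_rng(7)
        fu = self._fit(-10_000.0, 0.5, rng)
        fe = self._fit(-7800.0, 0.5, rng, rate_type="elimination")
        a = assess_bcf_temperature_dependence(fu, fe)
        b = assess_bcf_temperature_dependence(fe, fu)
        assert a.delta_slope_K == pytest.approx(-b.delta_slope_K)
        assert a.se_delta == pytest.approx(b.se_delta)

    def test_widely_separated_slopes_flagged_dependent(self):
        rng = np.random.default_rng(8)
        fu = self._fit(-10_000.0, 0.1, rng)
        fe = self._fit(-5000.0, 0.1, rng, rate_type="elimination")
        res = assess_bcf_temperature_dependence(fu, fe)
        assert not res.temperature_independent

    def test_paired_regression_of_ln_bcf(self):
        temps = np.linspace(278.0, 303.0, 10)
        paired = pd.DataFrame({
            "temperature_K": temps,
            "k_u": np.exp(40.0 - 9000.0 / temps),
            "k_e": np.exp(25.0 - 9000.0 / temps),
        })
        rng = np.random.default_rng(9)
        fu = self._fit(-9000.0, 0.3, rng)
        fe = self._fit(-9000.0, 0.3, rng, rate_type="elimination")
        res = assess_bcf_temperature_dependence(fu, fe, paired_records=paired)
        # equal generating slopes: ln BCF flat in 1/T
        assert res.paired_fit.slope_K == pytest.approx(0.0, abs=1e-6)
        assert res.paired_fit.intercept == pytest.approx(15.0, rel=1e-9)


class TestPipeline:
    def test_end_to_end_produces_four_pooled_fits(self, tmp_path):
        cfg = GeneratorConfig(seed=31, n_uptake=200, n_elimination=200)
        result = run_pipeline(cfg, out_dir=tmp_path)
        fits = [result.pooled[rt].uncorrected for rt in ("uptake", "elimination")]
        fits += [result.pooled[rt].corrected for rt in ("uptake", "elimination")]
        assert len(fits) == 4
        assert {f.rate_type for f in fits} == {"uptake", "elimination"}
        for name in ("dataset.csv", "pooled_fits.csv", "report.txt",
                     "strata_chemical_uptake.csv"):
            assert (tmp_path / name).exists()

    def test_rerun_same_seed_identical_report(self):
        cfg = GeneratorConfig(seed=32, n_uptake=150, n_elimination=150)
        a = run_pipeline(cfg)
        b = run_pipeline(cfg)
        assert a.report_text == b.report_text

    def test_relaxing_distinct_temps_only_affects_strata(self):
        cfg = GeneratorConfig(seed=33, n_uptake=150, n_elimination=150)
        strict = run_pipeline(cfg, min_distinct_temps=4)
        loose = run_pipeline(cfg, min_distinct_temps=3)
        assert loose.pooled["uptake"].uncorrected.slope_K == pytest.approx(
            strict.pooled["uptake"].uncorrected.slope_K)
        n_strict = sum(len(s.strata) for s in strict.species_strata.values())
        n_loose = sum(len(s.strata) for s in loose.species_strata.values())
        assert n_loose >= n_strict

    def test_bcf_verdict_present_in_report(self):
        cfg = GeneratorConfig(seed=34, n_uptake=150, n_elimination=150)
        result = run_pipeline(cfg)
        assert "Bioconcentration factor" in result.report_text
        assert "dslope" in result.report_text


class TestCLI:
    def test_simulate_then_full_run(self, tmp_path):
        from click.testing import CliRunner
        from thermotk.cli import main

        runner = CliRunner()
        ds = tmp_path / "ds.csv"
        r1 = runner.invoke(main, ["simulate", "--seed", "41", "--out", str(ds)])
        assert r1.exit_code == 0, r1.output
        assert ds.exists()
        out = tmp_path / "results"
        r2 = runner.invoke(main, ["all", "--dataset", str(ds), "--out", str(out)])
        assert r2.exit_code == 0, r2.output
        assert (out / "report.txt").exists()
        r3 = runner.invoke(main, ["fit", str(ds), "--rate-type", "uptake"])
        assert r3.exit_code == 0, r3.output
        assert "slope [K]" in r3.output
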