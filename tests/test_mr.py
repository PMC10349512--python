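import numpy as np
import pandas as pd
import pytest

from crossfdr import (
    InstrumentError,
    MRInstrumentSet,
    MRSimSpec,
    ValidationError,
    egger,
    harmonize_instruments,
    ivw,
    mode_based,
    mr_plot_data,
    run_all_methods,
    simulate_mr_instruments,
    wald_ratios,
    weighted_median,
)


def iset_from(beta_exp, beta_out, se_exp=0.05, se_out=0.05):
    n = len(beta_exp)
    return MRInstrumentSet(
        table=pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(n)],
                "beta_exp": beta_exp,
                "se_exp": np.broadcast_to(se_exp, n).astype(float),
                "beta_out": beta_out,
                "se_out": np.broadcast_to(se_out, n).astype(float),
            }
        )
    )


def sim_iset(**kwargs):
    return MRInstrumentSet.from_frame(simulate_mr_instruments(MRSimSpec(**kwargs)))


def instrument_table(snps, betas, ea="A", oa="G"):
    n = len(snps)
    return pd.DataFrame(
        {
            "snp": snps,
            "beta_exp": betas,
            "beta": betas,
            "se": 0.05,
            "effect_allele": [ea] * n if isinstance(ea, str) else ea,
            "other_allele": [oa] * n if isinstance(oa, str) else oa,
        }
    ).drop(columns=["beta_exp"])


class TestHarmonizeInstruments:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = instrument_table(["rs1", "rs2"], [0.2, 0.3])
        out = instrument_table(["rs1", "rs2"], [0.1, 0.2], ea=["A", "G"], oa=["G", "A"])
        iset = harmonize_instruments(exp, out)
        got = iset.table.set_index("snp")["beta_out"]
        assert got["rs1"] == 0.1
        assert got["rs2"] == -0.2

    def test_palindromic_dropped_with_count(self):
        exp = instrument_table(["rs1", "rs2"], [0.2, 0.3], ea=["A", "A"], oa=["G", "T"])
        out = instrument_table(["rs1", "rs2"], [0.1, 0.2], ea=["A", "A"], oa=["G", "T"])
        iset = harmonize_instruments(exp, out)
        assert len(iset) == 1 and iset.n_palindromic_dropped == 1

    def test_aligned_set_round_trips(self):
        df = simulate_mr_instruments(MRSimSpec(n_instruments=10, true_effect=0.3, seed=1))
        exp = df[["snp", "beta_exp", "se_exp", "effect_allele", "other_allele"]].rename(
            columns={"beta_exp": "beta", "se_exp": "se"}
        )
        out = df[["snp", "beta_out", "se_out", "effect_allele", "other_allele"]].rename(
            columns={"beta_out": "beta", "se_out": "se"}
        )
        iset = harmonize_instruments(exp, out)
        np.testing.assert_allclose(iset.table["beta_out"], df["beta_out"])
        assert iset.n_palindromic_dropped == 0


class TestWaldRatios:
    def test_direct_arithmetic(self):
        wr = wald_ratios(iset_from([0.2, 0.2, 0.2], [0.1, 0.0, 0.2], se_out=0.02))
        assert wr["theta"].iloc[0] == pytest.approx(0.5)
        assert wr["se"].iloc[0] == pytest.approx(0.1)
        assert wr["theta"].iloc[1] == 0.0

    def test_noiseless_simulation_all_equal_true_effect(self):
        iset = sim_iset(n_instruments=10, true_effect=0.3, pleiotropy_sd=0, se_out=0, seed=2)
        wr = wald_ratios(iset)
        np.testing.assert_allclose(wr["theta"], 0.3, atol=1e-12)

    def test_zero_exposure_effect_lists_snps(self):
        with pytest.raises(InstrumentError, match="rs0"):
            wald_ratios(iset_from([0.0, 0.2, 0.3], [0.1, 0.1, 0.1]))


class TestIVW:
    def test_degenerate_heterogeneity(self):
        iset = iset_from([0.2, 0.4, 0.5], [0.2 * 0.7, 0.4 * 0.7, 0.5 * 0.7], se_out=[0.1, 0.2, 0.25])
        res = ivw(iset)
        assert res.b == pytest.approx(0.7)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-20)

    def test_equal_weights_average(self):
        # three ratios 0.1/0.2/0.3 with equal se 0.1 (beta_exp=1)
        iset = iset_from([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], se_out=0.1)
        res = ivw(iset, random_effects=False)
        assert res.b == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1 / np.sqrt(3))

    def test_parameter_recovery(self):
        iset = sim_iset(n_instruments=50, true_effect=0.3, se_exp=0.02, se_out=0.05, seed=11)
        res = ivw(iset)
        assert abs(res.b - 0.3) < 3 * res.se

    def test_too_few_instruments(self):
        with pytest.raises(ValidationError):
            ivw(iset_from([0.2], [0.1]))


class TestEgger:
    def test_exact_line_through_origin(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(iset_from(be, 0.5 * be))
        assert res.b == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(iset_from(be, 0.5 * be + 0.1))
        assert res.b == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)

    def test_wls_matches_normal_equations_oracle(self):
        # closed-form weighted normal equations on a 5-row toy
        be = np.array([0.11, 0.23, 0.31, 0.42, 0.5])
        bo = np.array([0.09, 0.1, 0.22, 0.16, 0.3])
        so = np.array([0.05, 0.04, 0.06, 0.05, 0.07])
        res = egger(iset_from(be, bo, se_out=so))
        w = 1 / so**2
        X = np.column_stack([np.ones(5), be])
        coef = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * bo))
        assert res.intercept == pytest.approx(coef[0], abs=1e-12)
        assert res.b == pytest.approx(coef[1], abs=1e-12)

    def test_intercept_recovers_directional_pleiotropy(self):
        iset = sim_iset(
            n_instruments=50, true_effect=0.3, pleiotropy_mean=0.1, pleiotropy_sd=0.02,
            se_exp=0.01, se_out=0.03, seed=4,
        )
        res = egger(iset)
        assert abs(res.intercept - 0.1) < 3 * res.intercept_se
        assert abs(res.b - 0.3) < 3 * res.se

    def test_collinear_design_rejected(self):
        with pytest.raises(ValidationError, match="collinear|variation"):
            egger(iset_from([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]))


class TestWeightedMedian:
    def test_odd_count_equal_weights(self):
        iset = iset_from([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], se_out=0.1)
        res = weighted_median(iset, n_boot=200, seed=0)
        assert res.b == pytest.approx(0.2)

    def test_dominant_weight_returns_its_ratio(self):
        # first instrument holds > 50% of the inverse-variance weight
        iset = iset_from([1.0, 1.0, 1.0], [0.7, 0.1, 0.2], se_out=[0.01, 0.1, 0.1])
        res = weighted_median(iset, n_boot=200, seed=0)
        assert res.b == pytest.approx(0.7)

    def test_breakdown_robustness_to_invalid_instruments(self):
        rng = np.random.default_rng(8)
        n, n_bad = 30, 9
        be = rng.uniform(0.1, 0.5, n)
        bo = 0.3 * be + rng.normal(0, 0.02, n)
        bo[:n_bad] += 0.5  # strong directional pleiotropy in 30% of instruments
        iset = iset_from(be, bo, se_exp=0.01, se_out=0.02)
        wm = weighted_median(iset, n_boot=500, seed=1)
        fixed = ivw(iset, random_effects=False)
        assert abs(wm.b - 0.3) < 3 * wm.se
        assert abs(fixed.b - 0.3) > 3 * fixed.se  # plain fixed-effect IVW is biased here

    def test_small_n_boot_warns(self):
        iset = iset_from([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(iset, n_boot=50, seed=0)

    def test_bootstrap_reproducible(self):
        iset = sim_iset(n_instruments=20, true_effect=0.2, seed=3)
        r1 = weighted_median(iset, n_boot=300, seed=5)
        r2 = weighted_median(iset, n_boot=300, seed=5)
        assert r1.se == r2.se and r1.b == r2.b


class TestModeBased:
    def test_all_ratios_equal(self):
        iset = iset_from([0.2, 0.3, 0.4], [0.2 * 0.7, 0.3 * 0.7, 0.4 * 0.7])
        res = mode_based(iset, n_boot=200, seed=0)
        assert res.b == pytest.approx(0.7, abs=1e-9)

    def test_bimodal_cluster_wins(self):
        be = np.ones(10)
        bo = np.array([0.3] * 7 + [1.5] * 3) + np.linspace(-0.01, 0.01, 10)
        iset = iset_from(be, bo, se_out=0.05)
        res = mode_based(iset, n_boot=200, seed=0)
        # dense grid-search oracle over the same kernel density
        from crossfdr.mr import _mode_bandwidth

        theta = bo / be
        h = _mode_bandwidth(theta, 1.0)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 20001)
        dens = np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2).sum(axis=0)
        oracle = grid[np.argmax(dens)]
        assert abs(res.b - oracle) < h / 2
        assert abs(res.b - 0.3) < h + 0.05

    def test_weighted_equals_simple_under_equal_weights(self):
        iset = iset_from([1.0] * 5, [0.1, 0.25, 0.3, 0.32, 0.8], se_out=0.05)
        simple = mode_based(iset, weighted=False, n_boot=100, seed=0)
        weighted = mode_based(iset, weighted=True, n_boot=100, seed=0)
        assert simple.b == pytest.approx(weighted.b, abs=1e-12)

    def test_zero_bandwidth_factor_rejected(self):
        iset = iset_from([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValidationError, match="bandwidth"):
            mode_based(iset, bandwidth_factor=0.0)


@pytest.fixture(scope="module")
def base():
    return sim_iset(n_instruments=40, true_effect=0.25, se_exp=0.02, se_out=0.04, seed=6)


class TestInvariances:
    def negate_outcome(self, iset):
        t = iset.table.copy()
        t["beta_out"] = -t["beta_out"]
        return MRInstrumentSet(table=t)

    def scale_exposure(self, iset, k):
        t = iset.table.copy()
        t["beta_exp"] *= k
        t["se_exp"] *= k
        return MRInstrumentSet(table=t)

    def test_sign_equivariance(self, base):
        neg = self.negate_outcome(base)
        for fn in (
            lambda s: ivw(s).b,
            lambda s: egger(s).b,
            lambda s: weighted_median(s, n_boot=100, seed=0).b,
            lambda s: mode_based(s, n_boot=100, seed=0).b,
            lambda s: mode_based(s, weighted=True, n_boot=100, seed=0).b,
        ):
            assert fn(neg) == pytest.approx(-fn(base), abs=1e-9)

    def test_scale_equivariance(self, base):
        k = 2.5
        scaled = self.scale_exposure(base, k)
        for fn in (
            lambda s: ivw(s).b,
            lambda s: egger(s).b,
            lambda s: weighted_median(s, n_boot=100, seed=0).b,
        ):
            assert fn(scaled) == pytest.approx(fn(base) / k, rel=1e-9)

    def test_methods_agree_without_pleiotropy(self):
        iset = sim_iset(n_instruments=200, true_effect=0.3, se_exp=0.01, se_out=0.03, seed=12)
        results = run_all_methods(iset, n_boot=300, seed=0)
        bs = np.array([r.b for r in results])
        ses = np.array([r.se for r in results])
        assert np.all(np.abs(bs - 0.3) < 3 * np.maximum(ses, 1e-3))


class TestPlotData:
    def test_forest_row_count(self):
        iset = iset_from([0.2, 0.3, 0.4], [0.1, 0.15, 0.2])
        results = [ivw(iset), egger(iset)]
        forest, _ = mr_plot_data(iset, results)
        assert len(forest) == 5
        assert (forest["kind"] == "snp").sum() == 3

    def test_ivw_line_through_origin_and_egger_intercept(self):
        iset = iset_from(np.array([0.1, 0.2, 0.3, 0.4]), np.array([0.1, 0.2, 0.3, 0.4]) * 0.5 + 0.1)
        results = [ivw(iset), egger(iset)]
        _, scatter = mr_plot_data(iset, results)
        lines = scatter[scatter["kind"] == "line"].set_index("method")
        assert lines.loc["Inverse variance weighted", "intercept"] == 0.0
        assert lines.loc["MR Egger", "intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_empty_results_rejected(self):
        iset = iset_from([0.2, 0.3, 0.4], [0.1, 0.15, 0.2])
        with pytest.raises(ValidationError):
            mr_plot_data(iset, [])
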