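"""Metric suite, DE nonlinear fitting, linear-transform fitting, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorptionlab.fitting import DeConfig, compare_methods, compute_metrics, de_fit, linear_fit
from sorptionlab.models import (
    REFERENCE_ISOTHERMS_NL,
    REFERENCE_KINETICS_NL,
    isotherm_predict,
    kinetic_predict,
)
from sorptionlab.synthetic import DEFAULT_CE_GRID, gen_equilibrium

FAST_DE = DeConfig(maxiter=400, seed=1)


def _naive_metrics(obs, pred):
    """Loop-based oracle for the five-metric suite."""
    n = len(obs)
    sae = sum(abs(p - o) for o, p in zip(obs, pred))
    sse = sum((p - o) ** 2 for o, p in zip(obs, pred))
    rmse = (sse / (n - 1)) ** 0.5
    mean = sum(obs) / n
    ss_tot = sum((o - mean) ** 2 for o in obs)
    r2 = 1 - sse / ss_tot
    are = 100.0 / n * sum(abs(p - o) / o for o, p in zip(obs, pred))
    return r2, rmse, sae, sse, are


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], p=2)
        assert (m.sae, m.sse, m.rmse, m.are) == (0, 0, 0, 0)
        assert m.r2 == 1.0

    def test_hand_arithmetic_example(self):
        m = compute_metrics([1, 2, 3], [1.1, 1.9, 3.2], p=2)
        assert m.sae == pytest.approx(0.4)
        assert m.sse == pytest.approx(0.06)
        assert m.rmse == pytest.approx(np.sqrt(0.06 / 2), abs=1e-5)
        assert m.are == pytest.approx(100 / 3 * (0.1 + 0.05 + 0.2 / 3), abs=1e-4)
        assert m.r2 == pytest.approx(0.97)

    def test_null_model_r2_zero(self):
        obs = [1.0, 2.0, 3.0]
        m = compute_metrics(obs, [2.0, 2.0, 2.0], p=1)
        assert m.r2 == pytest.approx(0.0)

    def test_zero_observation_suppresses_are(self):
        with pytest.warns(UserWarning, match="ARE"):
            m = compute_metrics([0.0, 1.0, 2.0], [0.1, 1.0, 2.0], p=1)
        assert m.are is None

    def test_are_divisor_p_variant(self):
        m = compute_metrics([1, 2], [1.1, 2.2], p=4, are_divisor="p")
        assert m.are == pytest.approx(100 / 4 * (0.1 + 0.1))

    def test_r2_as_printed_is_error_ratio(self):
        obs, pred = [1.0, 2.0, 3.0], [1.1, 1.9, 3.2]
        m = compute_metrics(obs, pred, p=2, r2_as_printed=True)
        num = sum((p - o) ** 2 for o, p in zip(obs, pred))
        den = sum((p - 2.0) ** 2 for p in pred)
        assert m.r2 == pytest.approx(num / den)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0], p=1)

    @given(
        st.lists(st.floats(0.5, 50), min_size=3, max_size=20),
        st.integers(0, 10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_naive_loop_oracle(self, obs, shift_seed):
        rng = np.random.default_rng(shift_seed)
        obs = np.asarray(obs)
        if np.allclose(obs, obs[0]):
            obs = obs + np.arange(len(obs))
        pred = obs + rng.normal(0, 0.1, obs.size)
        m = compute_metrics(obs, pred, p=2)
        r2, rmse, sae, sse, are = _naive_metrics(list(obs), list(pred))
        assert m.r2 == pytest.approx(r2, abs=1e-12)
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.sae == pytest.approx(sae, abs=1e-12)
        assert m.sse == pytest.approx(sse, abs=1e-12)
        assert m.are == pytest.approx(are, abs=1e-10)


class TestDeFit:
    def test_langmuir_round_trip_from_reference_params(self):
        df, _ = gen_equilibrium(REFERENCE_ISOTHERMS_NL["langmuir"])
        fit = de_fit("langmuir", df.ce_mg_L, df.qe_mg_g, FAST_DE)
        assert fit.params["K_L"] == pytest.approx(10.42, rel=1e-3)
        assert fit.params["b_L"] == pytest.approx(0.161, rel=1e-3)

    def test_one_parameter_model_matches_closed_form(self):
        # qt = k * sqrt(t): least squares k = sum(qt*sqrt(t))/sum(t)
        t = np.array([1.0, 4.0, 9.0])
        qt = np.array([2.1, 3.9, 6.2])
        fit = de_fit("weber_morris", t, qt, DeConfig(maxiter=300, seed=2), bounds=[(1e-6, 10)])
        u = np.sqrt(t)
        k_closed = float(np.sum(qt * u) / np.sum(t))
        assert fit.params["K_id"] == pytest.approx(k_closed, rel=1e-8)

    def test_de_sse_never_worse_than_linear_fit(self):
        rng = np.random.default_rng(7)
        ce = np.asarray(DEFAULT_CE_GRID)
        qe = isotherm_predict(REFERENCE_ISOTHERMS_NL["langmuir"], ce)
        qe = qe * (1 + rng.normal(0, 0.05, ce.size))  # heteroscedastic noise
        de = de_fit("langmuir", ce, qe, FAST_DE)
        lin = linear_fit("langmuir", ce, qe)
        assert de.metrics.sse <= lin.metrics.sse + 1e-9

    def test_seeded_reproducibility(self):
        df, _ = gen_equilibrium(REFERENCE_ISOTHERMS_NL["langmuir"])
        fits = [de_fit("langmuir", df.ce_mg_L, df.qe_mg_g, DeConfig(maxiter=200, seed=9))
                for _ in range(2)]
        assert fits[0].params == fits[1].params

    def test_parameter_spread_across_seeds_on_noiseless_data(self):
        df, _ = gen_equilibrium(REFERENCE_ISOTHERMS_NL["langmuir"])
        kls = [
            de_fit("langmuir", df.ce_mg_L, df.qe_mg_g, DeConfig(maxiter=400, seed=s)).params["K_L"]
            for s in range(10)
        ]
        assert (max(kls) - min(kls)) / 10.42 < 1e-4

    def test_matches_dense_grid_search_on_two_parameter_models(self):
        """DE lands within one cell of a 3-decimal local grid, 5 datasets."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            k_true = rng.uniform(5, 15)
            b_true = rng.uniform(0.05, 0.5)
            ce = np.linspace(0.5, 50, 21)
            qe = k_true * b_true * ce / (1 + b_true * ce) + rng.normal(0, 0.05, ce.size)
            fit = de_fit("langmuir", ce, qe, DeConfig(maxiter=600, seed=seed))
            # vectorized grid at 0.001 resolution around the DE estimate
            kg = np.arange(fit.params["K_L"] - 0.05, fit.params["K_L"] + 0.05, 0.001)
            bg = np.arange(max(fit.params["b_L"] - 0.05, 1e-4), fit.params["b_L"] + 0.05, 0.001)
            K, B = np.meshgrid(kg, bg, indexing="ij")
            pred = K[..., None] * B[..., None] * ce / (1 + B[..., None] * ce)
            sse = ((pred - qe) ** 2).sum(axis=-1)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            assert abs(fit.params["K_L"] - kg[i]) <= 0.001 + 1e-9
            assert abs(fit.params["b_L"] - bg[j]) <= 0.001 + 1e-9

    def test_langmuir_capacity_bias_under_noise(self):
        """K_L relative bias < 2 % over 50 noisy replicates (sd = 2 % of q_max)."""
        spec = REFERENCE_ISOTHERMS_NL["langmuir"]
        ce = np.asarray(DEFAULT_CE_GRID)
        clean = isotherm_predict(spec, ce)
        sd = 0.02 * 10.42
        cfg_pool = [DeConfig(maxiter=300, seed=s, tol=1e-8) for s in range(50)]
        estimates = []
        for s, cfg in enumerate(cfg_pool):
            rng = np.random.default_rng(1000 + s)
            qe = np.maximum(clean + rng.normal(0, sd, ce.size), 0.0)
            estimates.append(de_fit("langmuir", ce, qe, cfg).params["K_L"])
        bias = abs(np.mean(estimates) - 10.42) / 10.42
        assert bias < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            de_fit("langmuir", [1.0, 2.0], [0.5, 0.8], FAST_DE)


class TestLinearFit:
    def test_perfect_langmuir_matches_de(self):
        df, _ = gen_equilibrium(REFERENCE_ISOTHERMS_NL["langmuir"])
        lin = linear_fit("langmuir", df.ce_mg_L, df.qe_mg_g)
        de = de_fit("langmuir", df.ce_mg_L, df.qe_mg_g, FAST_DE)
        assert lin.params["K_L"] == pytest.approx(de.params["K_L"], rel=1e-4)
        assert lin.params["b_L"] == pytest.approx(de.params["b_L"], rel=1e-4)

    def test_heteroscedastic_noise_favors_de(self):
        """Original-scale SSE of the linear route >= DE's, 20 replicates."""
        spec = REFERENCE_ISOTHERMS_NL["langmuir"]
        ce = np.asarray(DEFAULT_CE_GRID)
        clean = isotherm_predict(spec, ce)
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            qe = np.maximum(clean * (1 + rng.normal(0, 0.08, ce.size)), 1e-3)
            lin = linear_fit("langmuir", ce, qe)
            de = de_fit("langmuir", ce, qe, DeConfig(maxiter=300, seed=s, tol=1e-8))
            assert de.metrics.sse <= lin.metrics.sse + 1e-9

    def test_weber_morris_exact(self):
        t = np.arange(1.0, 13.0)
        fit = linear_fit("weber_morris", t, 2.0 * np.sqrt(t))
        assert fit.params["K_id"] == pytest.approx(2.0, rel=1e-12)

    def test_three_parameter_isotherm_grid_flagged_approximate(self):
        spec = REFERENCE_ISOTHERMS_NL["sips"]
        ce = np.asarray(DEFAULT_CE_GRID)
        qe = isotherm_predict(spec, ce)
        fit = linear_fit("sips", ce, qe)
        assert any("approximate" in n for n in fit.notes)
        assert fit.params["K_s"] == pytest.approx(10.54, rel=0.05)

    def test_pfo_linearization_uses_qe_exp(self):
        spec = REFERENCE_KINETICS_NL["pfo"]
        t = np.arange(3.0, 31.0, 3.0)
        qt = kinetic_predict(spec, t)
        fit = linear_fit("pfo", t, qt, qe_exp=3.49)
        assert fit.params["K1"] == pytest.approx(0.044, rel=1e-6)
        assert fit.params["qe"] == pytest.approx(3.49, rel=1e-6)


class TestCompareMethods:
    def test_langmuir_generated_data_ranks_langmuir_best(self):
        df, _ = gen_equilibrium(REFERENCE_ISOTHERMS_NL["langmuir"])
        table = compare_methods(
            ["freundlich", "langmuir", "temkin", "sips"],
            df.ce_mg_L, df.qe_mg_g, cfg=DeConfig(maxiter=400, seed=3),
        )
        nl = table[table.method == "nonlinear-DE"].set_index("model")
        # the generator's own family must fit at least as well as the others
        assert nl.loc["langmuir", "RMSE"] <= nl["RMSE"].min() + 1e-9

    def test_table_has_metric_columns_per_method(self):
        df, _ = gen_equilibrium(REFERENCE_ISOTHERMS_NL["langmuir"])
        table = compare_methods(["langmuir"], df.ce_mg_L, df.qe_mg_g, cfg=FAST_DE)
        assert set(table.method) == {"linear", "nonlinear-DE"}
        for col in ("R2", "SAE", "SSE", "ARE", "RMSE", "params"):
            assert col in table.columns

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([], [1, 2], [1, 2])
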