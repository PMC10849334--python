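"""Multi-kernel Bayesian GBLUP: kernels, sampler behavior, recovery."""

import numpy as np
import pandas as pd
import pytest

from abweight.data import standardize_markers
from abweight.gblup import (
    KernelGBLUP,
    MCMCSettings,
    ModelSpec,
    build_kernels,
    fit_predict,
)
from abweight.grm import compute_grm


def two_env_spec():
    """2 environments x 3 lines (6 obs) with identity G."""
    obs = pd.DataFrame(
        {
            "line": ["L1", "L2", "L3", "L1", "L2", "L3"],
            "env": ["E1", "E1", "E1", "E2", "E2", "E2"],
        }
    )
    return ModelSpec(
        obs=obs,
        y=np.arange(6, dtype=float),
        G=np.eye(3),
        line_ids=["L1", "L2", "L3"],
    )


class TestKernels:
    def test_identity_g_two_envs_hand_case(self):
        ks = build_kernels(two_env_spec())
        expected_Kg = np.kron(np.ones((2, 2)), np.eye(3))
        np.testing.assert_allclose(ks.K_g, expected_Kg)
        # same line, different env must be zero in the G-by-E kernel
        assert ks.K_gE[0, 3] == 0.0
        assert ks.K_gE[0, 0] == 1.0
        np.testing.assert_allclose(ks.K_gE, np.kron(np.eye(2), np.eye(3)))

    def test_single_environment_has_no_gxe_kernel(self):
        obs = pd.DataFrame({"line": ["L1", "L2", "L3"], "env": "E1"})
        spec = ModelSpec(obs=obs, y=np.ones(3), G=np.eye(3), line_ids=["L1", "L2", "L3"])
        ks = build_kernels(spec)
        assert ks.K_gE is None
        assert len(ks.kernels) == 1

    def test_kernels_are_psd(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(5, 12)).astype(float)
        X = X[:, X.std(axis=0) > 0]
        G = compute_grm(standardize_markers(X)).values
        obs = pd.DataFrame(
            {"line": [f"L{i}" for i in range(5)] * 2, "env": ["E1"] * 5 + ["E2"] * 5}
        )
        spec = ModelSpec(obs=obs, y=np.ones(10), G=G, line_ids=[f"L{i}" for i in range(5)])
        for K in build_kernels(spec).kernels:
            assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_dimension_mismatch_rejected(self):
        obs = pd.DataFrame({"line": ["L1", "L2"], "env": "E1"})
        spec = ModelSpec(obs=obs, y=np.ones(2), G=np.eye(3), line_ids=["L1", "L2"])
        with pytest.raises(ValueError, match="shape"):
            build_kernels(spec)


def simulate_gblup_data(seed, n=60, p=80, h2=0.5, n_masked=10):
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.2, 0.8, p)
    X = rng.binomial(2, freq, size=(n, p)).astype(float)
    X = X[:, X.std(axis=0) > 0]
    M = standardize_markers(X)
    G = compute_grm(M).values
    L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
    g = L @ rng.standard_normal(n) * np.sqrt(h2)
    y = g + rng.standard_normal(n) * np.sqrt(1 - h2)
    line_ids = [f"L{i}" for i in range(n)]
    obs = pd.DataFrame({"line": line_ids, "env": "E1"})
    y_masked = y.copy()
    y_masked[:n_masked] = np.nan
    return obs, y, y_masked, G, line_ids


class TestSampler:
    def test_intercept_only_limit(self):
        """Constant observed response: masked predictions approach it."""
        obs = pd.DataFrame({"line": [f"L{i}" for i in range(15)], "env": "E1"})
        c = 4.2
        y = np.full(15, c)
        y[:3] = np.nan
        spec = ModelSpec(obs=obs, y=y, G=np.eye(15), line_ids=list(obs["line"]))
        s = fit_predict(spec, MCMCSettings(n_iter=1500, burn_in=300, seed=0))
        assert np.abs(s.predictions["y_pred"] - c).max() < 0.05 * abs(c) + 0.05

    def test_location_equivariance(self):
        obs, y, y_masked, G, line_ids = simulate_gblup_data(1)
        mcmc = MCMCSettings(n_iter=1200, burn_in=300, seed=7)
        s0 = fit_predict(ModelSpec(obs, y_masked, G, line_ids), mcmc)
        c = 113.0
        s1 = fit_predict(ModelSpec(obs, y_masked + c, G, line_ids), mcmc)
        np.testing.assert_allclose(
            s1.predictions["y_pred"], s0.predictions["y_pred"] + c, atol=1e-6
        )

    def test_chain_is_deterministic_under_seed(self):
        obs, y, y_masked, G, line_ids = simulate_gblup_data(2)
        mcmc = MCMCSettings(n_iter=800, burn_in=200, seed=3)
        a = fit_predict(ModelSpec(obs, y_masked, G, line_ids), mcmc)
        b = fit_predict(ModelSpec(obs, y_masked, G, line_ids), mcmc)
        np.testing.assert_array_equal(
            a.predictions["y_pred"], b.predictions["y_pred"]
        )

    def test_chain_length_stability(self):
        """Doubling the chain moves masked predictions by < 0.02 sd(y)."""
        obs, y, y_masked, G, line_ids = simulate_gblup_data(3, n=80)
        base = fit_predict(
            ModelSpec(obs, y_masked, G, line_ids),
            MCMCSettings(n_iter=4000, burn_in=1000, thin=1, seed=5),
        )
        double = fit_predict(
            ModelSpec(obs, y_masked, G, line_ids),
            MCMCSettings(n_iter=8000, burn_in=1000, thin=1, seed=5),
        )
        sd = np.nanstd(y_masked)
        diff = np.abs(
            base.predictions["y_pred"].to_numpy()
            - double.predictions["y_pred"].to_numpy()
        )
        assert diff.mean() < 0.02 * sd + 1e-6

    def test_h2_recovery_smoke(self):
        """Posterior h2 lands near the simulated value (single replicate;
        the acceptance suite repeats this across 20 replicates)."""
        obs, y, y_masked, G, line_ids = simulate_gblup_data(4, n=150, p=300)
        s = fit_predict(
            ModelSpec(obs, y_masked, G, line_ids),
            MCMCSettings(n_iter=2500, burn_in=500, seed=11),
        )
        assert abs(s.h2 - 0.5) < 0.2
        assert all(v > 0 for v in s.variance_components.values())

    def test_too_few_observed_rejected(self):
        obs = pd.DataFrame({"line": [f"L{i}" for i in range(8)], "env": "E1"})
        y = np.full(8, np.nan)
        y[:5] = 1.0
        spec = ModelSpec(obs=obs, y=y, G=np.eye(8), line_ids=list(obs["line"]))
        with pytest.raises(ValueError, match="observed"):
            fit_predict(spec, MCMCSettings(n_iter=100, burn_in=10, seed=0))

    def test_non_psd_kernel_rejected(self):
        obs = pd.DataFrame({"line": ["L1", "L2", "L3"], "env": "E1"})
        G = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        spec = ModelSpec(obs=obs, y=np.ones(3), G=G, line_ids=["L1", "L2", "L3"])
        with pytest.raises(ValueError, match="PSD"):
            build_kernels(spec)


class TestEstimatorApi:
    def test_fit_predict_roundtrip(self):
        obs, y, y_masked, G, line_ids = simulate_gblup_data(6)
        est = KernelGBLUP(G=G, line_ids=line_ids, n_iter=800, burn_in=200, random_state=1)
        est.fit(obs, y_masked)
        assert est.predictions_.shape == (10,)
        # predict on explicit cells matches the stored linear predictor
        np.testing.assert_allclose(est.predict(obs.iloc[:10]), est.predictions_)
        params = est.get_params()
        assert params["n_iter"] == 800

    def test_unknown_cell_rejected_in_predict(self):
        obs, y, y_masked, G, line_ids = simulate_gblup_data(7)
        est = KernelGBLUP(G=G, line_ids=line_ids, n_iter=400, burn_in=100, random_state=1)
        est.fit(obs, y_masked)
        bad = pd.DataFrame({"line": ["nope"], "env": ["E1"]})
        with pytest.raises(ValueError, match="not part"):
            est.predict(bad)


def test_multi_environment_fit_runs_and_recovers_env_offsets():
    rng = np.random.default_rng(8)
    n = 40
    line_ids = [f"L{i}" for i in range(n)]
    obs = pd.DataFrame(
        {"line": line_ids * 2, "env": ["E1"] * n + ["E2"] * n}
    )
    G = np.eye(n)
    g = rng.standard_normal(n) * 0.7
    env_offset = 3.0
    y = np.r_[g + rng.normal(0, 0.5, n), g + env_offset + rng.normal(0, 0.5, n)]
    y_masked = y.copy()
    y_masked[[0, 1, n, n + 1]] = np.nan
    s = fit_predict(
        ModelSpec(obs, y_masked, G, line_ids),
        MCMCSettings(n_iter=2000, burn_in=500, seed=2),
    )
    assert "E2" in s.env_effects
    assert abs(s.env_effects["E2"] - env_offset) < 0.8
    assert "sigma2_gE" in s.variance_components
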