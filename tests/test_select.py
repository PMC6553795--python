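import numpy as np
import pytest

from giddi import SelectionConfig, firm_threshold, group_mcp_select, mcp_penalty


class TestMcpPenalty:
    def test_piecewise_values(self):
        lam, gamma = 1.0, 3.0
        assert mcp_penalty(0.0, lam, gamma) == 0.0
        assert mcp_penalty(1.0, lam, gamma) == pytest.approx(1 - 1 / 6)
        # flat beyond gamma*lam at gamma*lam^2/2
        assert mcp_penalty(3.0, lam, gamma) == pytest.approx(1.5)
        assert mcp_penalty(10.0, lam, gamma) == pytest.approx(1.5)

    def test_even_and_monotone(self):
        ts = np.linspace(0, 6, 200)
        vals = [mcp_penalty(t, 0.7, 2.5) for t in ts]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert mcp_penalty(-2.0, 0.7, 2.5) == mcp_penalty(2.0, 0.7, 2.5)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcp_penalty(1.0, 1.0, 1.0)


class TestFirmThreshold:
    def test_three_regimes(self):
        lam, gamma = 1.0, 3.0
        assert firm_threshold(0.5, lam, gamma) == 0.0
        assert firm_threshold(2.0, lam, gamma) == pytest.approx((2 - 1) / (1 - 1 / 3))
        assert firm_threshold(5.0, lam, gamma) == 5.0
        assert firm_threshold(-5.0, lam, gamma) == -5.0

    def test_minimizes_scalar_objective(self):
        # exhaustive check against grid minimization of (b-z)^2/2 + MCP(b)
        grid = np.linspace(-8, 8, 8001)
        for z in (-4.0, -1.2, 0.3, 0.9, 1.5, 2.9, 3.5, 6.0):
            for lam, gamma in ((1.0, 3.0), (0.5, 2.0), (2.0, 4.0)):
                obj = 0.5 * (grid - z) ** 2 + np.array(
                    [mcp_penalty(b, lam, gamma) for b in grid]
                )
                best = grid[np.argmin(obj)]
                assert firm_threshold(z, lam, gamma) == pytest.approx(best, abs=5e-3)


def orthonormal_design(n, p, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    return q * np.sqrt(n)  # columns with unit sample second moment


class TestGroupMcpSelect:
    def test_orthonormal_singleton_groups_match_firm_threshold(self):
        # with X'X/n = I, squared loss and one feature per group, the path
        # solution is exactly the firm threshold of the OLS coefficients
        n, p = 60, 4
        X = orthonormal_design(n, p, seed=0)
        rng = np.random.default_rng(1)
        beta_true = np.array([2.0, 0.8, 0.0, -1.5])
        y = X @ beta_true + rng.normal(0, 0.3, size=n)
        z = X.T @ y / n
        lam_path = [1.2, 0.6, 0.1]
        cfg = SelectionConfig(
            groups={f"x{i}": f"g{i}" for i in range(p)},
            gamma=3.0,
            lambda_path=lam_path,
            loss="squared",
            standardize=False,
            fit_intercept=False,
            cv_trials=0,
            tol=1e-12,
        )
        res = group_mcp_select(X, y, cfg)
        for li, lam in enumerate(lam_path):
            expected = [firm_threshold(zj, lam, 3.0) for zj in z]
            assert np.max(np.abs(res.coef_path[:, li] - expected)) < 1e-6

    def test_large_lambda_kills_everything_small_keeps_all(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 6))
        y = (X[:, 0] + rng.normal(0, 0.5, 120) > 0).astype(int)
        groups = {f"x{i}": "a" if i < 3 else "b" for i in range(6)}
        big = group_mcp_select(
            X, y, SelectionConfig(groups=groups, lambda_path=[1e3], cv_trials=0)
        )
        assert big.selected == ()
        small = group_mcp_select(
            X, y, SelectionConfig(groups=groups, lambda_path=[1e-4], cv_trials=0)
        )
        assert len(small.selected) == 6

    def test_groups_enter_and_leave_together(self):
        # features within a group share one latent driver, so along the path
        # every group block is either entirely zero or entirely nonzero
        rng = np.random.default_rng(3)
        n = 300
        latent = rng.normal(size=(n, 2))
        X = np.column_stack(
            [
                latent[:, 0] + 0.3 * rng.normal(size=n),
                latent[:, 0] + 0.3 * rng.normal(size=n),
                latent[:, 1] + 0.3 * rng.normal(size=n),
                latent[:, 1] + 0.3 * rng.normal(size=n),
            ]
        )
        y = (latent[:, 0] + rng.normal(0, 0.7, n) > 0).astype(int)
        groups = {"x0": "g1", "x1": "g1", "x2": "g2", "x3": "g2"}
        res = group_mcp_select(
            X, y, SelectionConfig(groups=groups, n_lambda=40, cv_trials=0)
        )
        for li in range(res.coef_path.shape[1]):
            for idx in ([0, 1], [2, 3]):
                nz = np.abs(res.coef_path[idx, li]) > 1e-12
                assert nz.all() or not nz.any()

    def test_cv_selects_informative_groups(self):
        rng = np.random.default_rng(4)
        n = 400
        X = rng.normal(size=(n, 8))
        eta = 1.2 * (X[:, 0] + X[:, 1]) + 1.2 * (X[:, 2] + X[:, 3])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        groups = {f"x{i}": f"g{i // 2}" for i in range(8)}
        res = group_mcp_select(
            X, y, SelectionConfig(groups=groups, n_lambda=30, cv_trials=3, seed=0)
        )
        assert {"g0", "g1"} <= set(res.selected_groups)
        assert res.cv_deviance is not None
        assert res.lambda_index == int(np.argmin(res.cv_deviance))

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        X[:, 2] = 1.0
        y = (X[:, 0] > 0).astype(int)
        groups = {"x0": "a", "x1": "a", "x2": "b"}
        with pytest.warns(UserWarning, match="constant"):
            res = group_mcp_select(
                X, y, SelectionConfig(groups=groups, n_lambda=10, cv_trials=0)
            )
        assert "x2" not in res.selected
        assert res.coef_path.shape[0] == 3
        assert np.all(res.coef_path[2] == 0.0)

    def test_unassigned_feature_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="without a group"):
            group_mcp_select(X, np.zeros(10), SelectionConfig(groups={"x0": "a"}))

    def test_drug_based_cv_is_deterministic(self):
        rng = np.random.default_rng(6)
        drugs = [f"D{i}" for i in range(15)]
        pairs = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1 :]]
        X = rng.normal(size=(len(pairs), 4))
        y = (X[:, 0] + rng.normal(0, 1, len(pairs)) > 0).astype(int)
        groups = {f"x{i}": "a" if i < 2 else "b" for i in range(4)}
        cfg = SelectionConfig(groups=groups, n_lambda=15, cv_trials=3, seed=9)
        r1 = group_mcp_select(X, y, cfg, pair_drugs=pairs)
        r2 = group_mcp_select(X, y, cfg, pair_drugs=pairs)
        assert r1.selected == r2.selected
        assert np.array_equal(r1.cv_deviance, r2.cv_deviance)
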