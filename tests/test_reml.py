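import numpy as np
import pytest
from scipy import optimize, stats

from mrnm.covariance import build_covariance, make_model
from mrnm.genotypes import GRM, compute_grm, simulate_genotypes
from mrnm.reml import RemlOptions, _design, fit, lrt, reml_loglik
from mrnm.simulate import PRESETS, simulate_full
from oracles import reml_loglik_oracle


def _grm(n, m, seed):
    A = compute_grm(simulate_genotypes(n, m, seed=seed), maf_min=0.01)
    A.eig()
    return A


OPTS = RemlOptions(min_n=10)


class TestLoglik:
    def test_identity_grm_confounds_components(self):
        # with A = I the GREML likelihood is flat along sg2 + se2 = const
        y = np.array([0.3, -1.2, 0.8, 0.1, -0.5, 1.0])
        A = np.eye(6)
        spec = make_model("GREML")
        l1 = reml_loglik(spec, np.array([1.0, 1.0]), y, None, A, None)
        l2 = reml_loglik(spec, np.array([0.5, 1.5]), y, None, A, None)
        assert np.isclose(l1, l2, atol=1e-10)

    @pytest.mark.parametrize("variant", ["GREML", "RNM_GC", "RNM_FULL",
                                         "MVGREML", "MRNM_GC", "MRNM_FULL"])
    def test_matches_contrast_oracle(self, variant, rng):
        # independent dense multivariate-normal REML evaluation, coded apart
        n = 6
        W = rng.standard_normal((n, 30))
        A = W @ W.T / 30
        c = rng.standard_normal(n)
        spec = make_model(variant)
        theta = {p: 1.0 if p in ("ky00", "my00", "vbeta", "veps") else 0.05
                 for p in spec.params}
        vec = np.array([theta[p] for p in spec.params])
        y = rng.standard_normal(2 * n if spec.bivariate else n)
        ll = reml_loglik(spec, vec, y, None, A, c)
        model = build_covariance(spec, A, c)
        V = model.V(vec)
        X = _design(spec, n, None)
        assert abs(ll - reml_loglik_oracle(V, y, X)) < 1e-8

    def test_nonpd_raises(self):
        spec = make_model("GREML")
        with pytest.raises(Exception):
            reml_loglik(spec, np.array([-5.0, 0.001]), np.zeros(4), None, np.eye(4) * 2, None)


class TestFit:
    def test_scale_equivariance(self, grm_small, rng):
        sim = simulate_full(grm_small, PRESETS["null_independent"], seed=4)
        d1 = {"y": sim.y, "A": grm_small}
        d2 = {"y": 2.0 * sim.y, "A": grm_small}
        f1 = fit(make_model("GREML"), d1, OPTS)
        f2 = fit(make_model("GREML"), d2, OPTS)
        assert np.isclose(f2.params["ky00"], 4 * f1.params["ky00"], rtol=1e-3)
        assert np.isclose(f2.params["my00"], 4 * f1.params["my00"], rtol=1e-3)

    def test_kron_and_dense_paths_agree(self, grm_small):
        sim = simulate_full(grm_small, PRESETS["gc_correlation_null"], seed=6)
        c = (sim.c - sim.c.mean()) / sim.c.std()
        for variant in ("GREML", "MVGREML"):
            data = {"y": sim.y, "c": c, "A": grm_small}
            fk = fit(make_model(variant), data, OPTS)
            fd = fit(make_model(variant), data, OPTS, engine="dense")
            assert abs(fk.loglik - fd.loglik) < 1e-5
            for p in fk.params:
                assert np.isclose(fk.params[p], fd.params[p], rtol=1e-3, atol=1e-5)

    @pytest.mark.parametrize("variant", ["GREML", "RNM_GC", "MVGREML", "MRNM_GC"])
    def test_matches_generic_optimizer_on_oracle_surface(self, variant, rng):
        """Fitted maximum agrees with directly optimising the dense likelihood."""
        n = 60
        A = _grm(n, 400, seed=31)
        sim = simulate_full(A, PRESETS["gc_correlation_null"], seed=32)
        c = (sim.c - sim.c.mean()) / sim.c.std()
        spec = make_model(variant)
        data = {"y": sim.y, "c": c, "A": A}
        ours = fit(spec, data, OPTS)
        model = build_covariance(spec, A.values, c)
        y_obs = np.concatenate([sim.y, c]) if spec.bivariate else sim.y
        X = _design(spec, n, None)

        def neg(theta):
            V = model.V(theta)
            try:
                np.linalg.cholesky(V)  # search the valid (PD) parameter region
                return -reml_loglik_oracle(V, y_obs, X)
            except (AssertionError, np.linalg.LinAlgError):
                return 1e10

        bounds = [(1e-8, None) if nn else (None, None) for nn in spec.nonneg_mask()]
        best_scipy = -np.inf
        best_ours = ours.loglik
        for trial in range(3):
            x0 = ours.theta * (1 + 0.3 * rng.standard_normal(spec.n_params)) if trial else ours.theta
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
            best_scipy = max(best_scipy, -res.fun)
            restart = fit(spec, data, OPTS,
                          start=dict(zip(spec.params, np.abs(x0))))
            best_ours = max(best_ours, restart.loglik)
            # both optimizers climb the same surface; either may warm-start
            # from the other's solution
            polish = fit(spec, data, OPTS, start=dict(zip(spec.params, res.x)))
            best_ours = max(best_ours, polish.loglik)
        # conventions coincide (both drop the same constants)
        assert best_ours >= best_scipy - 1e-3

    def test_nonconvergence_is_flagged_not_raised(self, grm_small):
        sim = simulate_full(grm_small, PRESETS["null_independent"], seed=9)
        res = fit(make_model("RNM_FULL"), {"y": sim.y, "c": sim.c, "A": grm_small},
                  RemlOptions(max_iter=1, min_n=10))
        assert isinstance(res.converged, bool)

    def test_permutation_invariance(self, rng):
        n = 80
        A = _grm(n, 500, seed=41)
        sim = simulate_full(A, PRESETS["gc_interaction"], seed=42)
        c = (sim.c - sim.c.mean()) / sim.c.std()
        perm = rng.permutation(n)
        Ap = GRM(A.values[np.ix_(perm, perm)], [A.ids[i] for i in perm], A.n_snps)
        spec = make_model("RNM_GC")
        f1 = fit(spec, {"y": sim.y, "c": c, "A": A}, OPTS, engine="dense")
        f2 = fit(spec, {"y": sim.y[perm], "c": c[perm], "A": Ap}, OPTS, engine="dense")
        assert abs(f1.loglik - f2.loglik) < 1e-5
        for p in spec.params:
            assert np.isclose(f1.params[p], f2.params[p], rtol=1e-4, atol=1e-6)

    def test_min_n_enforced(self):
        with pytest.raises(ValueError):
            fit(make_model("GREML"), {"y": np.zeros(10), "A": np.eye(10)})


class TestLrt:
    def _fr(self, variant, loglik, converged=True, groups=None, rr_order=None):
        spec = make_model(variant, groups=groups, rr_order=rr_order)
        from mrnm.reml import FitResult
        return FitResult(spec, {p: 0.0 for p in spec.params}, {}, loglik, 5, converged)

    def test_identical_loglik(self):
        res = lrt(self._fr("GREML", -10.0), self._fr("RNM_GC", -10.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_closed_form(self):
        res = lrt(self._fr("GREML", -13.0), self._fr("RNM_GC", -10.0))
        assert res.df == 2
        assert np.isclose(res.p_value, np.exp(-3.0), atol=1e-4)  # chi2(2) tail

    def test_df_greml_vs_rnm_full(self):
        res = lrt(self._fr("GREML", -10.0), self._fr("RNM_FULL", -9.0))
        assert res.df == 4

    def test_negative_statistic_clamped(self):
        res = lrt(self._fr("GREML", -9.0), self._fr("RNM_GC", -9.5))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fr("RNM_GC", -10.0), self._fr("RNM_RC", -9.0))

    def test_unconverged_flagged(self):
        res = lrt(self._fr("GREML", -10.0, converged=False), self._fr("RNM_GC", -9.0))
        assert not res.valid
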