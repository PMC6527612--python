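import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrnm.covariance import (
    CoefCovariance,
    ModelSpec,
    build_covariance,
    genetic_covariance,
    joint_covariance,
    make_model,
    polynomial_basis,
    residual_covariance,
)
from oracles import joint_covariance_bruteforce

UNI = ["GREML", "RNM_GC", "RNM_RC", "RNM_FULL"]
BIV = ["MVGREML", "MRNM_GC", "MRNM_RC", "MRNM_FULL"]


def _random_A(n, rng):
    W = rng.standard_normal((n, 4 * n))
    A = W @ W.T / (4 * n)
    return A


class TestPolynomialBasis:
    def test_examples(self):
        assert np.allclose(polynomial_basis([0.5], 1).values, [[1, 0.5]])
        assert np.allclose(polynomial_basis([3.0, -2.0], 0).values, [[1], [1]])
        assert np.allclose(
            polynomial_basis([-1, 0, 2], 2).values,
            [[1, -1, 1], [1, 0, 0], [1, 2, 4]],
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            polynomial_basis([1.0, np.nan], 1)


class TestBlockFormulas:
    def test_genetic_reduces_to_greml(self, rng):
        A = _random_A(5, rng)
        c = rng.standard_normal(5)
        Phi = polynomial_basis(c, 1)
        out = genetic_covariance(A, [[1, 0], [0, 0]], Phi)
        assert np.allclose(out, A)

    def test_genetic_zero_covariate_rows(self):
        A = np.eye(3) * 1.5
        Phi = polynomial_basis(np.zeros(3), 1)
        out = genetic_covariance(A, [[1, 0.05], [0.05, 0.25]], Phi)
        assert np.allclose(out, A)

    def test_genetic_per_pair_expansion(self, rng):
        A = _random_A(5, rng)
        c = rng.standard_normal(5)
        K = np.array([[1.0, 0.05], [0.05, 0.25]])
        out = genetic_covariance(A, K, polynomial_basis(c, 1))
        expect = np.array(
            [[A[i, j] * (K[0, 0] + K[0, 1] * (c[i] + c[j]) + K[1, 1] * c[i] * c[j])
              for j in range(5)] for i in range(5)]
        )
        assert np.abs(out - expect).max() < 1e-12

    def test_asymmetric_K_rejected(self, rng):
        with pytest.raises(ValueError):
            genetic_covariance(np.eye(3), [[1, 0.2], [0.1, 1]], polynomial_basis(np.ones(3), 1))

    def test_residual_diagonal_expansion(self):
        M = np.array([[1.0, 0.05], [0.05, 0.42]])
        out = residual_covariance(M, polynomial_basis(np.array([1.0, 0.0]), 1))
        assert np.isclose(out[0, 0], 1 + 0.10 + 0.42)  # m00 + 2 m01 c + m11 c^2
        assert np.isclose(out[1, 1], 1.0)
        assert np.count_nonzero(out - np.diag(np.diag(out))) == 0

    def test_homogeneous_residual(self):
        out = residual_covariance([[1, 0], [0, 0]], polynomial_basis(np.array([3.0, -1.0, 2.0]), 1))
        assert np.allclose(out, np.eye(3))


class TestMakeModel:
    @pytest.mark.parametrize(
        "variant,count",
        [("GREML", 2), ("RNM_GC", 4), ("RNM_RC", 4), ("RNM_FULL", 6),
         ("MVGREML", 6), ("MRNM_GC", 9), ("MRNM_RC", 9), ("MRNM_FULL", 12)],
    )
    def test_free_parameter_counts(self, variant, count):
        assert make_model(variant).n_params == count

    def test_gci_greml_mask(self):
        spec = make_model("GCI_GREML", groups=4)
        assert spec.n_params == 3
        assert "vgxe" in spec.params  # interaction variance, constrained >= 0
        assert spec.nonneg_mask()[spec.params.index("vgxe")]

    def test_rr_greml_masks(self):
        h0 = make_model("RR_GREML", groups=4, rr_order=0)
        h1 = make_model("RR_GREML", groups=4, rr_order=1)
        assert h0.n_params == 5 and h1.n_params == 7
        assert h0.nested_in(h1)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            make_model("NOT_A_MODEL")

    @pytest.mark.parametrize("h0,h1", [("GREML", "RNM_GC"), ("GREML", "RNM_RC"),
                                       ("GREML", "RNM_FULL"), ("RNM_GC", "RNM_FULL"),
                                       ("RNM_RC", "RNM_FULL"), ("MVGREML", "MRNM_GC"),
                                       ("MVGREML", "MRNM_RC"), ("MVGREML", "MRNM_FULL"),
                                       ("MRNM_GC", "MRNM_FULL"), ("MRNM_RC", "MRNM_FULL")])
    def test_nesting_of_test_pairs(self, h0, h1):
        assert make_model(h0).nested_in(make_model(h1))

    def test_greml_vs_rnm_full_df(self):
        assert make_model("RNM_FULL").n_params - make_model("GREML").n_params == 4

    def test_spec_text_round_trip(self):
        for spec in (make_model("MRNM_GC"), make_model("RR_GREML", groups=4, rr_order=1),
                     make_model("GCI_GREML", groups=3)):
            again = ModelSpec.from_text(spec.to_text())
            assert again == spec


@st.composite
def _instances(draw):
    n = draw(st.integers(3, 8))
    seed = draw(st.integers(0, 10_000))
    variant = draw(st.sampled_from(UNI + BIV))
    return n, seed, variant


class TestJointCovariance:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(_instances())
    def test_matches_per_pair_bruteforce(self, inst):
        n, seed, variant = inst
        rng = np.random.default_rng(seed)
        A = _random_A(n, rng)
        c = rng.standard_normal(n)
        spec = make_model(variant)
        theta = rng.normal(0, 0.5, spec.n_params) ** 2 + 0.1
        # make covariances signed
        for i, p in enumerate(spec.params):
            if p in ("ky01", "kyc0", "kyc1", "my01", "myc0", "myc1"):
                theta[i] = rng.normal(0, 0.3)
        sc = joint_covariance(spec, theta, A, c)
        oracle = joint_covariance_bruteforce(
            dict(zip(spec.params, theta)), A, c, spec.bivariate
        )
        assert np.abs(sc.V - oracle).max() < 1e-12

    def test_greml_covariance_closed_form(self, rng):
        A = _random_A(6, rng)
        sc = joint_covariance(make_model("GREML"), np.array([2.0, 3.0]), A, None)
        assert np.allclose(sc.V, 2.0 * A + 3.0 * np.eye(6))

    def test_derivatives_are_finite_difference_limits(self, rng):
        A = _random_A(5, rng)
        c = rng.standard_normal(5)
        spec = make_model("MRNM_FULL")
        theta = np.full(spec.n_params, 0.3)
        sc = joint_covariance(spec, theta, A, c)
        h = 1e-6
        for k in range(spec.n_params):
            up = theta.copy()
            up[k] += h
            fd = (joint_covariance(spec, up, A, c).V - sc.V) / h
            assert np.abs(fd - sc.derivs[k]).max() < 1e-7  # V is linear in theta

    def test_derivatives_symmetric(self, rng):
        A = _random_A(4, rng)
        c = rng.standard_normal(4)
        for variant in UNI + BIV:
            sc = joint_covariance(make_model(variant), np.zeros(make_model(variant).n_params), A, c)
            for D in sc.derivs:
                assert np.allclose(D, D.T)

    def test_h1_at_h0_point_reproduces_h0(self, rng):
        A = _random_A(6, rng)
        c = rng.standard_normal(6)
        pairs = [("GREML", "RNM_FULL"), ("MVGREML", "MRNM_FULL"), ("RNM_GC", "RNM_FULL")]
        for v0, v1 in pairs:
            s0, s1 = make_model(v0), make_model(v1)
            th0 = dict(zip(s0.params, 0.2 + np.arange(s0.n_params) * 0.1))
            V0 = joint_covariance(s0, th0, A, c).V
            V1 = joint_covariance(s1, th0, A, c).V  # absent entries fixed at 0
            assert np.abs(V0 - V1).max() < 1e-14  # identical up to BLAS summation order

    def test_theta_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            joint_covariance(make_model("GREML"), np.ones(3), np.eye(4), None)


class TestCoefCovariance:
    def test_param_round_trip(self):
        cc = CoefCovariance(K_y=[[1, 0.05], [0.05, 0.25]], M_y=[[1, 0], [0, 0]],
                            K_yc=[0.5, 0.0], M_yc=[0.3, 0.0], var_beta=1, var_eps=1)
        again = CoefCovariance.from_params(cc.to_params())
        assert np.allclose(again.genetic_3x3(), cc.genetic_3x3())
        assert np.allclose(again.residual_3x3(), cc.residual_3x3())

    def test_stacked_3x3_layout(self):
        cc = CoefCovariance(K_y=[[1, 0.05], [0.05, 0.25]], K_yc=[0.5, 0.1], var_beta=2.0)
        g = cc.genetic_3x3()  # ordered (a0, beta, a1)
        assert g[0, 1] == 0.5 and g[1, 2] == 0.1 and g[0, 2] == 0.05 and g[1, 1] == 2.0


class TestMultiCovariate:
    def test_parameter_count_and_mask(self):
        spec = make_model("RNM_MULTI", n_effects=2)
        assert spec.n_params == 7  # 3 per effect + shared residual
        assert spec.params[-1] == "my00"
        again = ModelSpec.from_text(spec.to_text())
        assert again == spec

    def test_assembly_is_sum_of_per_effect_kernels(self, rng):
        n = 6
        effects = []
        for seed in (1, 2):
            r = np.random.default_rng(seed)
            W = r.standard_normal((n, 30))
            effects.append((W @ W.T / 30, r.standard_normal(n)))
        spec = make_model("RNM_MULTI", n_effects=2)
        theta = {"ky00_e1": 1.0, "ky01_e1": 0.1, "ky11_e1": 0.3,
                 "ky00_e2": 0.5, "ky01_e2": -0.05, "ky11_e2": 0.2, "my00": 0.8}
        sc = joint_covariance(spec, theta, None, None, effects=effects)
        expect = 0.8 * np.eye(n)
        for j, (Aj, cj) in enumerate(effects, start=1):
            K = np.array([[theta[f"ky00_e{j}"], theta[f"ky01_e{j}"]],
                          [theta[f"ky01_e{j}"], theta[f"ky11_e{j}"]]])
            Phi = np.column_stack([np.ones(n), cj])
            expect = expect + Aj * (Phi @ K @ Phi.T)
        assert np.abs(sc.V - expect).max() < 1e-12

    def test_fit_recovers_two_component_split(self):
        # two independent GRMs each contributing genetic variance 1
        from mrnm.genotypes import compute_grm, simulate_genotypes
        from mrnm.reml import RemlOptions, fit
        from mrnm.simulate import draw_correlated_effects
        n = 300
        A1 = compute_grm(simulate_genotypes(n, 800, seed=61), maf_min=0.01)
        A2 = compute_grm(simulate_genotypes(n, 800, seed=62), maf_min=0.01)
        e1 = draw_correlated_effects(A1, np.diag([1.0, 0, 0]), np.zeros((3, 3)), seed=63)
        e2 = draw_correlated_effects(A2, np.diag([1.0, 0, 0]), np.zeros((3, 3)), seed=64)
        rng = np.random.default_rng(65)
        y = e1["a0"] + e2["a0"] + rng.standard_normal(n)
        c1, c2 = rng.standard_normal(n), rng.standard_normal(n)
        spec = make_model("RNM_MULTI", n_effects=2)
        f = fit(spec, {"y": y, "effects": [(A1, c1), (A2, c2)]}, RemlOptions(min_n=10))
        assert f.converged
        # each component's level variance near 1, residual near 1 (large SEs at n=300)
        assert 0.3 < f.params["ky00_e1"] < 2.0
        assert 0.3 < f.params["ky00_e2"] < 2.0
        assert 0.5 < f.params["my00"] < 1.6
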