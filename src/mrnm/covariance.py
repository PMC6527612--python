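"""Structured covariance models for reaction-norm variance components.

Every model variant here describes the covariance of the observation vector
(the trait ``y`` alone, or ``y`` stacked above the covariate ``c``) as a linear
combination of fixed pattern matrices, one per free variance/covariance
parameter.  With one record per individual and a unique covariate value per
individual, the incidence matrices of the general random-regression notation
collapse to identity selectors, so the blocks assemble as Hadamard and
diagonal products:

    V_yy = A o (Phi K_y Phi') + Diag(Phi M_y Phi')
    V_yc = (kyc0 I + kyc1 Dc) A + (myc0 I + myc1 Dc)
    V_cc = var_beta A + var_eps I

where ``A`` is the genomic relationship matrix, ``Phi = [1 c]`` the polynomial
basis of the covariate, ``Dc = diag(c)``, ``K_y``/``M_y`` the coefficient
covariances of the genetic/residual random regressions, ``K_yc``/``M_yc`` the
cross-covariances with the covariate's genetic and residual parts.  Since V is
linear in the parameters, each derivative matrix dV/dtheta_p is a constant
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolynomialBasis",
    "CoefCovariance",
    "ModelSpec",
    "StructuredCovariance",
    "VARIANTS",
    "polynomial_basis",
    "genetic_covariance",
    "residual_covariance",
    "make_model",
    "build_covariance",
    "joint_covariance",
]


# ---------------------------------------------------------------------------
# polynomial basis
# ---------------------------------------------------------------------------


@dataclass
class PolynomialBasis:
    order: int
    values: np.ndarray  # n x (k+1), column j = c**j


def polynomial_basis(c: np.ndarray, k: int = 1) -> PolynomialBasis:
    """Matrix of covariate powers [c^0, c^1, ..., c^k] (one row per record)."""
    c = np.asarray(c, dtype=float)
    if not np.isfinite(c).all():
        raise ValueError("covariate contains non-finite values")
    if k < 0:
        raise ValueError("polynomial order must be >= 0")
    return PolynomialBasis(k, np.vander(c, k + 1, increasing=True))


# ---------------------------------------------------------------------------
# coefficient covariances
# ---------------------------------------------------------------------------


def _sym2(mat) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise ValueError("coefficient covariance must be symmetric 2x2")
    return m


@dataclass
class CoefCovariance:
    """Full parameter set of the order-1 (M)RNM; subsets for simpler models.

    K_y / M_y: 2x2 covariances of the genetic / residual random regression
    coefficients (a0, a1) and (t0, t1).  K_yc / M_yc: covariances of those
    coefficients with the covariate's genetic (beta) and residual (eps) parts.
    """

    K_y: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    M_y: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    K_yc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    M_yc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    var_beta: float = 0.0
    var_eps: float = 0.0

    def __post_init__(self) -> None:
        self.K_y = _sym2(self.K_y)
        self.M_y = _sym2(self.M_y)
        self.K_yc = np.asarray(self.K_yc, dtype=float).reshape(2)
        self.M_yc = np.asarray(self.M_yc, dtype=float).reshape(2)

    def genetic_3x3(self) -> np.ndarray:
        """Stacked covariance over (a0, beta, a1) as used for simulation."""
        k = self.K_y
        return np.array(
            [
                [k[0, 0], self.K_yc[0], k[0, 1]],
                [self.K_yc[0], self.var_beta, self.K_yc[1]],
                [k[0, 1], self.K_yc[1], k[1, 1]],
            ]
        )

    def residual_3x3(self) -> np.ndarray:
        """Stacked covariance over (t0, eps, t1)."""
        m = self.M_y
        return np.array(
            [
                [m[0, 0], self.M_yc[0], m[0, 1]],
                [self.M_yc[0], self.var_eps, self.M_yc[1]],
                [m[0, 1], self.M_yc[1], m[1, 1]],
            ]
        )

    def to_params(self) -> dict[str, float]:
        return {
            "ky00": self.K_y[0, 0],
            "ky01": self.K_y[0, 1],
            "ky11": self.K_y[1, 1],
            "my00": self.M_y[0, 0],
            "my01": self.M_y[0, 1],
            "my11": self.M_y[1, 1],
            "kyc0": self.K_yc[0],
            "kyc1": self.K_yc[1],
            "myc0": self.M_yc[0],
            "myc1": self.M_yc[1],
            "vbeta": self.var_beta,
            "veps": self.var_eps,
        }

    @classmethod
    def from_params(cls, params: dict[str, float]) -> "CoefCovariance":
        g = lambda k: float(params.get(k, 0.0))
        return cls(
            K_y=[[g("ky00"), g("ky01")], [g("ky01"), g("ky11")]],
            M_y=[[g("my00"), g("my01")], [g("my01"), g("my11")]],
            K_yc=[g("kyc0"), g("kyc1")],
            M_yc=[g("myc0"), g("myc1")],
            var_beta=g("vbeta"),
            var_eps=g("veps"),
        )


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

# free-parameter masks per variant, in canonical order
_UNI_GENETIC = ["ky00", "ky01", "ky11"]
_UNI_RES = ["my00", "my01", "my11"]

VARIANTS = {
    "GREML": ["ky00", "my00"],
    "RNM_GC": ["ky00", "ky01", "ky11", "my00"],
    "RNM_RC": ["ky00", "my00", "my01", "my11"],
    "RNM_FULL": _UNI_GENETIC + _UNI_RES,
    "MVGREML": ["ky00", "kyc0", "vbeta", "my00", "myc0", "veps"],
    "MRNM_GC": ["ky00", "ky01", "ky11", "kyc0", "kyc1", "vbeta", "my00", "myc0", "veps"],
    "MRNM_RC": ["ky00", "kyc0", "vbeta", "my00", "my01", "my11", "myc0", "myc1", "veps"],
    "MRNM_FULL": _UNI_GENETIC
    + ["kyc0", "kyc1", "vbeta"]
    + _UNI_RES
    + ["myc0", "myc1", "veps"],
    # comparison models; parameter lists are completed per group count
    "RR_GREML": None,
    "GCI_GREML": ["ky00", "vgxe", "my00"],
    # multiple (GRM, covariate) random effects, zero correlation across
    # effects, shared homogeneous residual; completed per effect count
    "RNM_MULTI": None,
}

_BIVARIATE = {"MVGREML", "MRNM_GC", "MRNM_RC", "MRNM_FULL"}

# base variances that must stay non-negative for a well-defined model
_NONNEG = {"ky00", "my00", "vbeta", "veps", "vgxe"}
# the interaction variances are left unconstrained (as in the reference REML
# fits this mirrors); only GCI-GREML's vgxe is hard-constrained at zero
_HARD_ZERO = {"vgxe"}


@dataclass
class ModelSpec:
    """Declarative description of one model variant.

    ``params`` is the ordered free-parameter mask; everything absent is fixed
    at zero.  ``stratified`` marks the comparison models that replace the
    continuous covariate with discrete group levels (RR-GREML, GCI-GREML).
    """

    variant: str
    params: list[str]
    bivariate: bool = False
    order: int = 1
    n_groups: int | None = None
    rr_order: int | None = None
    n_effects: int | None = None

    @property
    def stratified(self) -> bool:
        return self.n_groups is not None

    @property
    def n_params(self) -> int:
        return len(self.params)

    def nonneg_mask(self) -> np.ndarray:
        return np.array([
            p in _NONNEG or p.startswith("res_g") or p.startswith("ky00_e")
            for p in self.params
        ])

    def nested_in(self, other: "ModelSpec") -> bool:
        return set(self.params) <= set(other.params)

    # -- plain-text serialization -------------------------------------------
    def to_text(self) -> str:
        lines = [f"variant {self.variant}", f"order {self.order}"]
        if self.n_groups is not None:
            lines.append(f"groups {self.n_groups}")
        if self.rr_order is not None:
            lines.append(f"rr_order {self.rr_order}")
        if self.n_effects is not None:
            lines.append(f"n_effects {self.n_effects}")
        lines.append("free " + ",".join(self.params))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelSpec":
        kv = {}
        for line in text.splitlines():
            if line.strip():
                key, _, val = line.partition(" ")
                kv[key] = val.strip()
        spec = make_model(
            kv["variant"],
            groups=int(kv["groups"]) if "groups" in kv else None,
            k=int(kv.get("order", 1)),
            rr_order=int(kv["rr_order"]) if "rr_order" in kv else None,
            n_effects=int(kv["n_effects"]) if "n_effects" in kv else None,
        )
        if kv.get("free") and kv["free"].split(",") != spec.params:
            raise ValueError("free-parameter mask does not match variant")
        return spec


def make_model(
    variant: str,
    groups: int | None = None,
    k: int = 1,
    rr_order: int | None = None,
    n_effects: int | None = None,
) -> ModelSpec:
    """Build the free-parameter mask for a named model variant.

    ``RR_GREML`` needs ``groups`` (and ``rr_order`` 0 or 1: whether the
    genetic effect regresses on the group-level covariate); ``GCI_GREML``
    needs ``groups`` for the same-group indicator; ``RNM_MULTI`` needs
    ``n_effects``, the number of (GRM, covariate) random effects.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if variant == "RNM_MULTI":
        if not n_effects or n_effects < 1:
            raise ValueError("RNM_MULTI requires n_effects >= 1")
        params = [
            f"{nm}_e{j + 1}"
            for j in range(n_effects)
            for nm in ("ky00", "ky01", "ky11")
        ] + ["my00"]
        return ModelSpec(variant, params, n_effects=n_effects)
    if variant == "RR_GREML":
        if groups is None:
            raise ValueError("RR_GREML requires a group count")
        order = 1 if rr_order is None else rr_order
        gen = ["ky00"] if order == 0 else ["ky00", "ky01", "ky11"]
        params = gen + [f"res_g{g + 1}" for g in range(groups)]
        return ModelSpec(variant, params, n_groups=groups, rr_order=order)
    if variant == "GCI_GREML":
        if groups is None:
            raise ValueError("GCI_GREML requires a group count")
        return ModelSpec(variant, list(VARIANTS[variant]), n_groups=groups)
    return ModelSpec(variant, list(VARIANTS[variant]), bivariate=variant in _BIVARIATE)


# ---------------------------------------------------------------------------
# covariance assembly
# ---------------------------------------------------------------------------


def genetic_covariance(A: np.ndarray, K_y, Phi: np.ndarray | PolynomialBasis) -> np.ndarray:
    """Genetic block A o (Phi K_y Phi'): relatedness times reaction-norm kernel."""
    K_y = np.asarray(K_y, dtype=float)
    if not np.allclose(K_y, K_y.T):
        raise ValueError("K_y must be symmetric")
    P = Phi.values if isinstance(Phi, PolynomialBasis) else np.asarray(Phi)
    return np.asarray(A) * (P @ K_y @ P.T)


def residual_covariance(M_y, Phi: np.ndarray | PolynomialBasis) -> np.ndarray:
    """Diagonal residual block with entries (Phi M_y Phi')_ii."""
    M_y = np.asarray(M_y, dtype=float)
    if not np.allclose(M_y, M_y.T):
        raise ValueError("M_y must be symmetric")
    P = Phi.values if isinstance(Phi, PolynomialBasis) else np.asarray(Phi)
    return np.diag(np.einsum("ij,jk,ik->i", P, M_y, P))


def _group_indicator(groups: np.ndarray) -> np.ndarray:
    g = np.asarray(groups)
    return (g[:, None] == g[None, :]).astype(float)


def _fill_pattern(out, name, A, cs, groups, bivariate) -> None:
    """Write one parameter's pattern into a zeroed (nobs x nobs) view."""
    n = A.shape[0]
    idx = np.arange(n)

    def uni(tgt, name):
        if name == "ky00":
            tgt[:] = A
        elif name == "ky01":
            np.multiply(A, cs[:, None] + cs[None, :], out=tgt)
        elif name == "ky11":
            np.multiply(A, np.outer(cs, cs), out=tgt)
        elif name == "my00":
            tgt[idx, idx] = 1.0
        elif name == "my01":
            tgt[idx, idx] = 2.0 * cs
        elif name == "my11":
            tgt[idx, idx] = cs**2
        elif name == "vgxe":
            np.multiply(A, _group_indicator(groups), out=tgt)
        elif name.startswith("res_g"):
            g = int(name[5:]) - 1
            tgt[idx, idx] = (np.asarray(groups) == g).astype(float)
        else:
            raise KeyError(name)

    if not bivariate:
        uni(out, name)
        return
    if name in ("ky00", "ky01", "ky11", "my00", "my01", "my11"):
        uni(out[:n, :n], name)
    elif name == "vbeta":
        out[n:, n:] = A
    elif name == "veps":
        out[n + idx, n + idx] = 1.0
    elif name == "kyc0":
        out[:n, n:] = A
        out[n:, :n] = A
    elif name == "kyc1":
        B = cs[:, None] * A  # Dc A
        out[:n, n:] = B
        out[n:, :n] = B.T
    elif name == "myc0":
        out[idx, n + idx] = 1.0
        out[n + idx, idx] = 1.0
    elif name == "myc1":
        out[idx, n + idx] = cs
        out[n + idx, idx] = cs
    else:
        raise KeyError(name)


def pattern_matrix(
    name: str,
    A: np.ndarray,
    c: np.ndarray,
    groups: np.ndarray | None = None,
    bivariate: bool = False,
) -> np.ndarray:
    """Fixed derivative matrix dV/dtheta for one named parameter."""
    n = A.shape[0]
    nobs = 2 * n if bivariate else n
    out = np.zeros((nobs, nobs))
    _fill_pattern(out, name, np.asarray(A, float), np.asarray(c, float), groups, bivariate)
    return out


@dataclass
class StructuredCovariance:
    """Joint covariance V of the observation vector plus per-parameter derivatives."""

    V: np.ndarray
    derivs: list[np.ndarray]
    params: list[str]


@dataclass
class CovarianceModel:
    """A ModelSpec bound to data: explicit derivative matrices, ready to fit."""

    spec: ModelSpec
    derivs: list[np.ndarray]
    nobs: int
    groups: np.ndarray | None = None
    _stack: np.ndarray | None = field(default=None, repr=False, compare=False)

    def deriv_stack(self) -> np.ndarray:
        """Patterns flattened to (p, nobs*nobs) for single-pass BLAS kernels."""
        if self._stack is None:
            self._stack = np.ascontiguousarray(
                np.stack([D.ravel() for D in self.derivs])
            )
        return self._stack

    def V(self, theta: np.ndarray) -> np.ndarray:
        V = np.asarray(theta, dtype=float) @ self.deriv_stack()
        return V.reshape(self.nobs, self.nobs)


def build_covariance(
    spec: ModelSpec,
    A: np.ndarray,
    c: np.ndarray | None,
    groups: np.ndarray | None = None,
    group_values: np.ndarray | None = None,
    effects: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CovarianceModel:
    """Materialise the derivative matrices of ``spec`` for one data set.

    For the stratified comparison models, ``groups`` holds integer group
    labels; RR-GREML regresses the genetic effect on ``group_values`` (the
    per-individual representative covariate level of the assigned group).
    The multiple-random-effect variant takes ``effects``, a list of
    (GRM array, covariate) pairs, one per random effect.
    """
    if spec.variant == "RNM_MULTI":
        if not effects or len(effects) != spec.n_effects:
            raise ValueError(f"RNM_MULTI needs {spec.n_effects} (A, c) pairs")
        mats = [(np.asarray(getattr(Aj, "values", Aj), float),
                 np.asarray(cj, float)) for Aj, cj in effects]
        n = mats[0][0].shape[0]
        stack = np.zeros((spec.n_params, n, n))
        for k, p in enumerate(spec.params):
            if p == "my00":
                _fill_pattern(stack[k], p, mats[0][0], np.zeros(n), None, False)
            else:
                nm, _, tag = p.partition("_e")
                Aj, cj = mats[int(tag) - 1]
                _fill_pattern(stack[k], nm, Aj, cj, None, False)
        model = CovarianceModel(spec, list(stack), n, groups=None)
        model._stack = stack.reshape(spec.n_params, -1)
        return model
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if spec.stratified:
        if groups is None:
            raise ValueError(f"{spec.variant} requires group labels")
        basis = group_values if group_values is not None else np.zeros(n)
    else:
        basis = np.zeros(n) if c is None else np.asarray(c, dtype=float)
        if basis.shape[0] != n:
            raise ValueError("covariate length does not match GRM dimension")
    nobs = 2 * n if spec.bivariate else n
    stack = np.zeros((spec.n_params, nobs, nobs))
    for k, p in enumerate(spec.params):
        _fill_pattern(stack[k], p, A, basis, groups, spec.bivariate)
    model = CovarianceModel(spec, list(stack), nobs, groups=groups)
    model._stack = stack.reshape(spec.n_params, -1)
    return model


def joint_covariance(
    spec: ModelSpec,
    theta: CoefCovariance | np.ndarray | dict,
    A: np.ndarray,
    c: np.ndarray | None,
    groups: np.ndarray | None = None,
    group_values: np.ndarray | None = None,
    effects: list | None = None,
) -> StructuredCovariance:
    """Assemble V and its derivative matrices at a parameter point.

    ``theta`` may be a CoefCovariance (entries outside the spec's mask must be
    zero-consistent), a dict of named parameters, or a vector in spec order.
    """
    model = build_covariance(spec, A, c, groups=groups, group_values=group_values,
                             effects=effects)
    if isinstance(theta, CoefCovariance):
        vec = np.array([theta.to_params()[p] for p in spec.params])
    elif isinstance(theta, dict):
        vec = np.array([float(theta.get(p, 0.0)) for p in spec.params])
    else:
        vec = np.asarray(theta, dtype=float)
        if vec.shape != (spec.n_params,):
            raise ValueError(
                f"theta has {vec.shape} entries, spec frees {spec.n_params}"
            )
    return StructuredCovariance(model.V(vec), model.derivs, list(spec.params))
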