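"""AI-REML estimation and likelihood-ratio testing for structured covariances.

The restricted log-likelihood used throughout (constant terms dropped, so that
differences between nested fits are convention-free) is

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Maximisation is average-information REML: an EM warm-up step, then AI
quasi-Newton updates with step-halving whenever a proposal decreases the
likelihood or leaves the positive-definite cone.  All model variants are
linear in their parameters (V = sum_p theta_p D_p with fixed patterns D_p),
which the engine exploits.

Two execution paths produce identical likelihoods:

* a dense path for any variant, working with the explicit n x n (or 2n x 2n)
  pattern matrices;
* a rotated path for the two-kernel variants (GREML, MVGREML), whose
  covariance is Bg (x) A + Br (x) I.  One eigendecomposition of A per GRM
  turns every likelihood and derivative evaluation into O(n) work on per-
  individual t x t blocks, which is what makes large replicate grids cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

import logging

from .covariance import CovarianceModel, ModelSpec, build_covariance
from .genotypes import GRM

logger = logging.getLogger("mrnm")

__all__ = ["FitResult", "LRTResult", "RemlOptions", "reml_loglik", "fit", "lrt"]


@dataclass
class RemlOptions:
    max_iter: int = 100
    tol_loglik: float = 1e-4
    tol_param: float = 1e-6
    em_steps: int = 1
    max_halvings: int = 12
    min_n: int = 50
    ridge: float = 1e-8


@dataclass
class FitResult:
    spec: ModelSpec
    params: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool
    boundary: dict[str, bool] = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.spec.params])

    def report(self) -> str:
        lines = [f"variant\t{self.spec.variant}"]
        for p in self.spec.params:
            flag = "B" if self.boundary.get(p) else "."
            lines.append(f"{p}\t{self.params[p]:.6g}\t{self.se.get(p, float('nan')):.4g}\t{flag}")
        lines.append(f"logL\t{self.loglik:.6f}")
        lines.append(f"converged\t{self.converged}\titerations\t{self.n_iter}")
        return "\n".join(lines) + "\n"


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    valid: bool = True


# ---------------------------------------------------------------------------
# dense path
# ---------------------------------------------------------------------------


def _loglik_dense(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    """(logL, chol) or (None, None) if V is not positive definite."""
    try:
        L = sla.cholesky(V, lower=True, check_finite=False, overwrite_a=True)
    except sla.LinAlgError:
        return None, None
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    sol = sla.cho_solve((L, True), np.column_stack([y, X]), check_finite=False)
    Viy, ViX = sol[:, 0], sol[:, 1:]
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None, None
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    yPy = y @ Viy - (ViX.T @ y) @ beta
    return -0.5 * (logdetV + logdetX + yPy), L


class _DenseEngine:
    """Score/AI computations over explicit pattern matrices.

    The Cholesky factor from the most recent likelihood evaluation is cached,
    so the accepted point of one line search is not refactorised when the
    next iteration asks for derivatives at the same theta.
    """

    def __init__(self, model: CovarianceModel, y: np.ndarray, X: np.ndarray):
        self.model = model
        self.y = y
        self.X = X
        self._cache: tuple[np.ndarray, float, np.ndarray] | None = None

    def loglik(self, theta):
        if self._cache is not None and np.array_equal(self._cache[0], theta):
            return self._cache[1]
        ll, L = _loglik_dense(self.model.V(theta), self.y, self.X)
        if ll is not None:
            self._cache = (np.array(theta, dtype=float), ll, L)
        return ll

    def derivatives(self, theta):
        """Returns (logL, score, AI, trPD, Py) at theta, or None if V not PD."""
        if self._cache is not None and np.array_equal(self._cache[0], theta):
            _, ll, L = self._cache
        else:
            ll, L = _loglik_dense(self.model.V(theta), self.y, self.X)
        if ll is None:
            return None
        inv, info = sla.lapack.dpotri(L, lower=1)
        if info != 0:
            return None
        Vi = np.tril(inv) + np.tril(inv, -1).T
        ViX = Vi @ self.X
        C = np.linalg.inv(self.X.T @ ViX)
        P = Vi - ViX @ C @ ViX.T
        Py = P @ self.y
        p = len(theta)
        trPD = self.model.deriv_stack() @ P.ravel()
        U = np.empty((len(self.y), p))
        for k, D in enumerate(self.model.derivs):
            U[:, k] = D @ Py
        score = -0.5 * (trPD - U.T @ Py)
        AI = 0.5 * (U.T @ (P @ U))
        return ll, score, AI, trPD, Py


# ---------------------------------------------------------------------------
# rotated (eigenbasis) path for two-kernel variants
# ---------------------------------------------------------------------------

# parameter -> (trait-block index pair, kernel) for GREML / MVGREML
_KRON_MAP = {
    "GREML": {"ky00": ((0, 0), "g"), "my00": ((0, 0), "r")},
    "MVGREML": {
        "ky00": ((0, 0), "g"),
        "kyc0": ((0, 1), "g"),
        "vbeta": ((1, 1), "g"),
        "my00": ((0, 0), "r"),
        "myc0": ((0, 1), "r"),
        "veps": ((1, 1), "r"),
    },
}


class _KronEngine:
    """Score/AI for V = Bg (x) A + Br (x) I in the eigenbasis of A.

    Observations are reshaped to (n, t) blocks; after rotating by the
    eigenvectors U of A, V is block diagonal with per-individual blocks
    V_i = w_i Bg + Br, and the fixed-effect correction of P is low rank, so
    every REML quantity costs O(n t^3).
    """

    def __init__(self, spec: ModelSpec, A: GRM, y_obs: np.ndarray, X: np.ndarray):
        self.spec = spec
        self.map = _KRON_MAP[spec.variant]
        w, U = A.eig()
        n = A.n
        self.w = w
        t = 2 if spec.bivariate else 1
        self.t = t
        self.yt = np.stack([U.T @ y_obs[k * n : (k + 1) * n] for k in range(t)], axis=1)
        q = X.shape[1]
        self.Xt = np.stack(
            [U.T @ X[k * n : (k + 1) * n, :] for k in range(t)], axis=1
        )  # (n, t, q)
        self.q = q
        self.n = n

    def _blocks(self, theta):
        t = self.t
        Bg = np.zeros((t, t))
        Br = np.zeros((t, t))
        for val, name in zip(theta, self.spec.params):
            (i, j), kern = self.map[name]
            tgt = Bg if kern == "g" else Br
            tgt[i, j] += val
            if i != j:
                tgt[j, i] += val
        return Bg, Br

    def _Dblocks(self):
        out = []
        t = self.t
        for name in self.spec.params:
            (i, j), kern = self.map[name]
            E = np.zeros((t, t))
            E[i, j] = E[j, i] = 1.0
            out.append((E, kern))
        return out

    def _common(self, theta):
        Bg, Br = self._blocks(theta)
        Vb = self.w[:, None, None] * Bg + Br  # (n, t, t)
        if self.t == 1:
            if (Vb[:, 0, 0] <= 0).any():
                return None
            Vi = 1.0 / Vb
            logdetV = float(np.log(Vb[:, 0, 0]).sum())
        else:
            det = Vb[:, 0, 0] * Vb[:, 1, 1] - Vb[:, 0, 1] ** 2
            if (det <= 0).any() or (Vb[:, 0, 0] <= 0).any():
                return None
            Vi = np.empty_like(Vb)
            Vi[:, 0, 0] = Vb[:, 1, 1] / det
            Vi[:, 1, 1] = Vb[:, 0, 0] / det
            Vi[:, 0, 1] = Vi[:, 1, 0] = -Vb[:, 0, 1] / det
            logdetV = float(np.log(det).sum())
        ViY = np.einsum("nij,nj->ni", Vi, self.yt)
        ViX = np.einsum("nij,njq->niq", Vi, self.Xt)
        XtViX = np.einsum("ntq,ntr->qr", self.Xt, ViX)
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        C = np.linalg.inv(XtViX)
        b = np.einsum("ntq,nt->q", self.Xt, ViY)
        Py = ViY - np.einsum("niq,q->ni", ViX, C @ b)
        yPy = float(np.einsum("nt,nt->", self.yt, Py))
        ll = -0.5 * (logdetV + logdetX + yPy)
        return ll, Vi, ViX, C, Py

    def loglik(self, theta):
        common = self._common(theta)
        return None if common is None else common[0]

    def _apply_P(self, Vi, ViX, C, u):
        Viu = np.einsum("nij,nj->ni", Vi, u)
        t = np.einsum("ntq,nt->q", self.Xt, Viu)
        return Viu - np.einsum("niq,q->ni", ViX, C @ t)

    def derivatives(self, theta):
        common = self._common(theta)
        if common is None:
            return None
        ll, Vi, ViX, C, Py = common
        p = self.spec.n_params
        score = np.empty(p)
        trPD = np.empty(p)
        us = []
        for k, (E, kern) in enumerate(self._Dblocks()):
            scale = self.w if kern == "g" else np.ones(self.n)
            # tr(V^-1 D) - tr(C X'V^-1 D V^-1 X)
            tr1 = float(np.einsum("n,nij,ji->", scale, Vi, E))
            G = np.einsum("niq,ij,n,njr->qr", ViX, E, scale, ViX)
            trPD[k] = tr1 - float(np.trace(C @ G))
            u = scale[:, None] * np.einsum("ij,nj->ni", E, Py)
            us.append(u)
            score[k] = -0.5 * (trPD[k] - float(np.einsum("nt,nt->", Py, u)))
        AI = np.empty((p, p))
        for k in range(p):
            Pu = self._apply_P(Vi, ViX, C, us[k])
            for l in range(k, p):
                AI[k, l] = AI[l, k] = 0.5 * float(np.einsum("nt,nt->", us[l], Pu))
        return ll, score, AI, trPD, Py


# ---------------------------------------------------------------------------
# public evaluation / fitting interface
# ---------------------------------------------------------------------------


def _design(spec: ModelSpec, n: int, X: np.ndarray | None) -> np.ndarray:
    """Default fixed effects: an intercept per trait; user columns appended."""
    if spec.bivariate:
        base = np.zeros((2 * n, 2))
        base[:n, 0] = 1.0
        base[n:, 1] = 1.0
    else:
        base = np.ones((n, 1))
    if X is None:
        return base
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != base.shape[0]:
        X = X.T
    return np.column_stack([base, X])


def reml_loglik(
    spec: ModelSpec,
    theta: np.ndarray | dict,
    y_obs: np.ndarray,
    X: np.ndarray | None,
    A: np.ndarray | GRM,
    c: np.ndarray | None,
    groups: np.ndarray | None = None,
    group_values: np.ndarray | None = None,
) -> float:
    """Restricted log-likelihood at a parameter point (dense evaluation)."""
    Av = A.values if isinstance(A, GRM) else np.asarray(A)
    model = build_covariance(spec, Av, c, groups=groups, group_values=group_values)
    if isinstance(theta, dict):
        theta = np.array([float(theta.get(p, 0.0)) for p in spec.params])
    y_obs = np.asarray(y_obs, dtype=float)
    Xd = _design(spec, Av.shape[0], X)
    ll = _loglik_dense(model.V(np.asarray(theta, dtype=float)), y_obs, Xd)[0]
    if ll is None:
        raise sla.LinAlgError("covariance not positive definite at theta")
    return ll


def _start_values(spec: ModelSpec, y: np.ndarray, c: np.ndarray | None) -> np.ndarray:
    """Equal split of phenotypic variance across the base variances."""
    vy = float(np.var(y))
    vc = float(np.var(c)) if c is not None else 1.0
    cyc = float(np.cov(y, c)[0, 1]) if c is not None else 0.0
    start = {
        "ky00": vy / 2,
        "my00": vy / 2,
        "vbeta": vc / 2,
        "veps": vc / 2,
        "kyc0": cyc / 2,
        "myc0": cyc / 2,
    }
    theta = np.array([start.get(p, 0.0) for p in spec.params])
    n_eff = max(1, sum(p.startswith("ky00_e") for p in spec.params))
    for i, p in enumerate(spec.params):
        if p.startswith("res_g"):
            theta[i] = vy / 2
        elif p.startswith("ky00_e"):
            theta[i] = vy / (2 * n_eff)
    return theta


def fit(
    spec: ModelSpec,
    data: dict,
    options: RemlOptions | None = None,
    start: dict[str, float] | None = None,
    engine: str | None = None,
) -> FitResult:
    """Maximise the restricted likelihood of ``spec`` on ``data``.

    ``data`` holds ``y`` (trait), ``A`` (GRM or array), and optionally ``c``
    (covariate), ``X`` (extra fixed-effect columns), ``groups`` and
    ``group_values`` for the stratified variants.  Never raises on
    non-convergence; inspect ``FitResult.converged``.
    """
    opts = options or RemlOptions()
    y = np.asarray(data["y"], dtype=float)
    A = data.get("A")
    if A is None and data.get("effects"):
        A = data["effects"][0][0]
    Agrm = A if isinstance(A, GRM) else GRM(np.asarray(A), [str(i) for i in range(len(y))], 0)
    c = None if data.get("c") is None else np.asarray(data["c"], dtype=float)
    n = len(y)
    if n < opts.min_n:
        raise ValueError(f"need at least {opts.min_n} individuals, got {n}")
    y_obs = np.concatenate([y, c]) if spec.bivariate else y
    X = _design(spec, n, data.get("X"))

    use_kron = engine != "dense" and spec.variant in _KRON_MAP
    if use_kron:
        eng = _KronEngine(spec, Agrm, y_obs, X)
    else:
        model = build_covariance(
            spec, Agrm.values, c, groups=data.get("groups"),
            group_values=data.get("group_values"), effects=data.get("effects"),
        )
        eng = _DenseEngine(model, y_obs, X)

    theta = _start_values(spec, y, c)
    em_steps = opts.em_steps
    if start:
        for i, p in enumerate(spec.params):
            if p in start:
                theta[i] = start[p]
        em_steps = 0  # warm-started fits go straight to AI updates
    nonneg = spec.nonneg_mask()
    scale = float(np.var(y))
    floor = 1e-8 * scale
    theta[nonneg] = np.maximum(theta[nonneg], floor)

    ll = eng.loglik(theta)
    if ll is None:
        # fall back to a safely PD starting point
        theta = _start_values(spec, y, c)
        theta[nonneg] = np.maximum(theta[nonneg], floor)
        ll = eng.loglik(theta)
    converged = False
    n_iter = 0
    AI = None
    for it in range(opts.max_iter):
        n_iter = it + 1
        der = eng.derivatives(theta)
        if der is None:
            break
        ll, score, AI, trPD, _ = der
        if it < em_steps:
            # EM-style update for pure variance parameters: robust, slow
            delta = np.zeros_like(theta)
            nobs = len(y_obs)
            for k in range(len(theta)):
                yPDPy = 2.0 * score[k] + trPD[k]
                new = (theta[k] ** 2 * yPDPy + theta[k] * nobs - theta[k] ** 2 * trPD[k]) / nobs
                if nonneg[k]:
                    delta[k] = new - theta[k]
                else:
                    delta[k] = 0.0
            if not np.any(delta):
                it_em = False
            else:
                it_em = True
        else:
            it_em = False
        ridge = opts.ridge * max(np.trace(AI) / len(theta), 1.0)

        def _ai_step(pin: np.ndarray) -> np.ndarray:
            free = ~pin
            d = np.zeros_like(theta)
            try:
                sub = AI[np.ix_(free, free)]
                d[free] = np.linalg.solve(
                    sub + ridge * np.eye(int(free.sum())), score[free]
                )
            except np.linalg.LinAlgError:
                d[free] = score[free] / max(np.trace(AI), 1.0)
            return d

        def _project(prop: np.ndarray) -> np.ndarray:
            prop = prop.copy()
            prop[nonneg] = np.maximum(prop[nonneg], floor)
            return prop

        if not it_em:
            # active-set AI step: parameters held at their bound with the
            # score pushing outward are frozen and the system re-solved
            pinned = nonneg & (theta <= floor * 1.01) & (score < 0)
            delta = _ai_step(pinned)
            # when the full step would cross a bound, a second candidate pins
            # the crossing parameters at the floor and re-solves the rest
            # (avoids slow crawls along a boundary)
            crossing = nonneg & (theta + delta < floor) & ~pinned
            if crossing.any():
                delta2 = _ai_step(pinned | crossing)
                delta2[crossing] = floor - theta[crossing]
                p1, p2 = _project(theta + delta), _project(theta + delta2)
                l1, l2 = eng.loglik(p1), eng.loglik(p2)
                if (l2 is not None) and (l1 is None or l2 >= l1):
                    delta = delta2
        step = 1.0
        accepted = False
        for _ in range(opts.max_halvings):
            prop = _project(theta + step * delta)
            ll_new = eng.loglik(prop)
            if ll_new is not None and ll_new >= ll - 1e-10:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            converged = True  # no uphill step found: at (constrained) optimum
            break
        dpar = np.max(np.abs(prop - theta) / (np.abs(theta) + 1.0))
        dll = ll_new - ll
        theta, ll = prop, ll_new
        logger.debug(
            "%s iter %d: logL %.6f (dll %.2e, step %.3g)",
            spec.variant, n_iter, ll, dll, step,
        )
        if not it_em and (abs(dll) < opts.tol_loglik or dpar < opts.tol_param):
            converged = True
            break

    params = dict(zip(spec.params, (float(t) for t in theta)))
    boundary = {
        p: bool(nonneg[i] and theta[i] <= max(floor * 2, 1e-12))
        for i, p in enumerate(spec.params)
    }
    se: dict[str, float] = {}
    if AI is not None:
        try:
            cov = np.linalg.inv(AI)
            for i, p in enumerate(spec.params):
                se[p] = float(np.sqrt(max(cov[i, i], 0.0))) if not boundary[p] else float("nan")
        except np.linalg.LinAlgError:
            pass
    ll_final = eng.loglik(theta)
    if ll_final is None:
        ll_final = ll if ll is not None else float("nan")
    return FitResult(
        spec=spec,
        params=params,
        se=se,
        loglik=float(ll_final),
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
    )


def lrt(fit0: FitResult, fit1: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested REML fits on plain chi-square df."""
    if not fit0.spec.nested_in(fit1.spec):
        raise ValueError(
            f"{fit0.spec.variant} is not nested in {fit1.spec.variant}"
        )
    df = fit1.spec.n_params - fit0.spec.n_params
    stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(stat, df, min(max(p, 0.0), 1.0) if stat > 0 else 1.0,
                     valid=fit0.converged and fit1.converged)
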