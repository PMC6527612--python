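"""Independent brute-force oracles, written before (and apart from) the engine.

Everything here is deliberately naive: explicit per-pair loops and textbook
formulas, used only to check the structured implementations.
"""

import numpy as np
from scipy.linalg import null_space


def grm_bruteforce(counts: np.ndarray) -> np.ndarray:
    """Element-wise per-pair GRM: (1/m) sum_j w_ij w_kj, sample frequencies."""
    n, m = counts.shape
    p = counts.mean(axis=0) / 2.0
    w = np.empty((n, m))
    for j in range(m):
        w[:, j] = (counts[:, j] - 2 * p[j]) / np.sqrt(2 * p[j] * (1 - p[j]))
    A = np.empty((n, n))
    for i in range(n):
        for k in range(n):
            A[i, k] = sum(w[i, j] * w[k, j] for j in range(m)) / m
    return A


def joint_covariance_bruteforce(params: dict, A: np.ndarray, c: np.ndarray,
                                bivariate: bool) -> np.ndarray:
    """Per-pair assembly of cov(y_i,y_j), cov(y_i,c_j), cov(c_i,c_j).

    y_i = a0_i + a1_i c_i + t0_i + t1_i c_i,  c_i = beta_i + eps_i, with
    cov(a._i, a._j) proportional to A_ij and residual coefficients iid.
    """
    g = lambda k: float(params.get(k, 0.0))
    n = len(c)
    K = np.array([[g("ky00"), g("ky01")], [g("ky01"), g("ky11")]])
    M = np.array([[g("my00"), g("my01")], [g("my01"), g("my11")]])
    kyc = np.array([g("kyc0"), g("kyc1")])
    myc = np.array([g("myc0"), g("myc1")])
    size = 2 * n if bivariate else n
    V = np.zeros((size, size))
    for i in range(n):
        for j in range(n):
            phi_i = np.array([1.0, c[i]])
            phi_j = np.array([1.0, c[j]])
            vyy = A[i, j] * (phi_i @ K @ phi_j)
            if i == j:
                vyy += phi_i @ M @ phi_j
            V[i, j] = vyy
            if bivariate:
                vyc = A[i, j] * (phi_i @ kyc)
                if i == j:
                    vyc += phi_i @ myc
                V[i, n + j] = vyc
                V[n + j, i] = vyc
                vcc = A[i, j] * g("vbeta")
                if i == j:
                    vcc += g("veps")
                V[n + i, n + j] = vcc
    return V


def reml_loglik_oracle(V: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Restricted likelihood through error contrasts: B'y ~ N(0, B'VB).

    With an orthonormal null-space basis B of X', this equals the engine's
    -(1/2)[log|V| + log|X'V^-1 X| + y'Py] after the constant -(1/2)log|X'X|.
    """
    B = null_space(X.T)
    W = B.T @ V @ B
    z = B.T @ y
    sign, logdet = np.linalg.slogdet(W)
    assert sign > 0
    quad = z @ np.linalg.solve(W, z)
    _, logdetXX = np.linalg.slogdet(X.T @ X)
    return -0.5 * (logdet + quad + logdetXX)
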