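"""Generative simulation of trait/covariate pairs under GCCI and RCCI models.

The data-generating model (interaction order 1) is

    y_i = a0_i + a1_i * c_i + t0_i + t1_i * c_i,      c_i = beta_i + eps_i,

with the three genetic coefficient vectors (a0, beta, a1) jointly normal with
covariance  Sigma_g (x) A  (A the genomic relationship matrix) and the three
residual vectors (t0, eps, t1) with covariance  Sigma_r (x) I.  The covariate
enters the product term on its raw simulated scale (variance
var(beta) + var(eps) = 2 under the shipped designs), which is what makes the
interaction-share bookkeeping var(a1)/var(y) come out at 10% for
var(a1) = 0.25 and 25% for var(a1) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CoefCovariance
from .genotypes import GRM

__all__ = [
    "SimulationDesign",
    "SimulatedData",
    "PRESETS",
    "draw_correlated_effects",
    "simulate_gcci",
    "simulate_rcci",
    "simulate_full",
]


def _check_psd(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3) or not np.allclose(S, S.T):
        raise ValueError(f"{name} must be a symmetric 3x3 matrix")
    w = np.linalg.eigvalsh(S)
    if w.min() < -1e-10 * max(np.trace(S), 1.0):
        raise ValueError(f"{name} is not positive semidefinite (eigenvalues {w})")
    return S


@dataclass
class SimulationDesign:
    """Covariance over genetic (a0, beta, a1) and residual (t0, eps, t1) triples."""

    genetic: np.ndarray
    residual: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.genetic = _check_psd(self.genetic, "genetic covariance")
        self.residual = _check_psd(self.residual, "residual covariance")

    def truth(self) -> CoefCovariance:
        g, r = self.genetic, self.residual
        return CoefCovariance(
            K_y=[[g[0, 0], g[0, 2]], [g[0, 2], g[2, 2]]],
            M_y=[[r[0, 0], r[0, 2]], [r[0, 2], r[2, 2]]],
            K_yc=[g[0, 1], g[1, 2]],
            M_yc=[r[0, 1], r[1, 2]],
            var_beta=g[1, 1],
            var_eps=r[1, 1],
        )


@dataclass
class SimulatedData:
    y: np.ndarray
    c: np.ndarray
    truth: CoefCovariance
    components: dict[str, np.ndarray] = field(default_factory=dict)
    c_components: dict[str, np.ndarray] = field(default_factory=dict)
    design: SimulationDesign | None = None


def _sqrt3(S: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(S)
    return U * np.sqrt(np.clip(w, 0.0, None))


def draw_correlated_effects(
    A: GRM | np.ndarray | None,
    Sigma_g: np.ndarray,
    Sigma_r: np.ndarray,
    seed: int | np.random.Generator = 0,
    A_sqrt: np.ndarray | None = None,
    n: int | None = None,
) -> dict[str, np.ndarray]:
    """Draw (a0, beta, a1) ~ N(0, Sigma_g (x) A) and (t0, eps, t1) ~ N(0, Sigma_r (x) I).

    A's matrix square root is taken by eigendecomposition with negative
    eigenvalues clipped at zero (sample GRMs are near- but not exactly PSD);
    pass ``A_sqrt`` to reuse a precomputed factor across replicates.
    ``A=None`` means unrelated individuals (A = I); give ``n`` in that case.
    """
    Sigma_g = _check_psd(Sigma_g, "Sigma_g")
    Sigma_r = _check_psd(Sigma_r, "Sigma_r")
    rng = np.random.default_rng(seed)
    if A_sqrt is None and A is not None:
        A_sqrt = A.sqrt() if isinstance(A, GRM) else _sqrtm_psd(np.asarray(A))
    if A_sqrt is not None:
        n = A_sqrt.shape[0]
        gen = A_sqrt @ rng.standard_normal((n, 3)) @ _sqrt3(Sigma_g).T
    elif n is not None:
        gen = rng.standard_normal((n, 3)) @ _sqrt3(Sigma_g).T
    else:
        raise ValueError("give A, A_sqrt, or n")
    res = rng.standard_normal((n, 3)) @ _sqrt3(Sigma_r).T
    return {
        "a0": gen[:, 0], "beta": gen[:, 1], "a1": gen[:, 2],
        "t0": res[:, 0], "eps": res[:, 1], "t1": res[:, 2],
    }


def _sqrtm_psd(A: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(A)
    return U * np.sqrt(np.clip(w, 0.0, None))


def simulate_full(
    A: GRM | np.ndarray | None,
    design: SimulationDesign,
    seed: int | np.random.Generator = 0,
    A_sqrt: np.ndarray | None = None,
    n: int | None = None,
) -> SimulatedData:
    """General simulation: y = a0 + a1*c + t0 + t1*c with both triples free."""
    eff = draw_correlated_effects(A, design.genetic, design.residual, seed, A_sqrt, n=n)
    c = eff["beta"] + eff["eps"]
    parts = {
        "a0": eff["a0"],
        "a1c": eff["a1"] * c,
        "t0": eff["t0"],
        "t1c": eff["t1"] * c,
    }
    y = parts["a0"] + parts["a1c"] + parts["t0"] + parts["t1c"]
    return SimulatedData(
        y=y, c=c, truth=design.truth(), components=parts,
        c_components={"beta": eff["beta"], "eps": eff["eps"]}, design=design,
    )


def simulate_gcci(
    A: GRM | np.ndarray,
    var_alpha1: float,
    cov_a0a1: float = 0.05,
    cov_a0b: float = 0.0,
    re_cov: float = 0.0,
    seed: int | np.random.Generator = 0,
    A_sqrt: np.ndarray | None = None,
    n: int | None = None,
) -> SimulatedData:
    """Genotype-covariate correlation/interaction design.

    Genetic covariance over (a0, beta, a1) is
    [[1, cov_a0b, cov_a0a1], [cov_a0b, 1, 0], [cov_a0a1, 0, var_alpha1]];
    residual covariance over (e, eps) is [[1, re_cov], [re_cov, 1]] with no
    residual interaction.
    """
    design = SimulationDesign(
        genetic=[[1.0, cov_a0b, cov_a0a1], [cov_a0b, 1.0, 0.0], [cov_a0a1, 0.0, var_alpha1]],
        residual=[[1.0, re_cov, 0.0], [re_cov, 1.0, 0.0], [0.0, 0.0, 0.0]],
        name="gcci",
    )
    return simulate_full(A, design, seed, A_sqrt, n=n)


def simulate_rcci(
    A: GRM | np.ndarray,
    var_tau1: float,
    cov_t0t1: float = 0.05,
    cov_a0b: float = 0.0,
    cov_t0eps: float = 0.0,
    seed: int | np.random.Generator = 0,
    A_sqrt: np.ndarray | None = None,
    n: int | None = None,
) -> SimulatedData:
    """Residual-covariate correlation/interaction design: y = a0 + t0 + t1*c."""
    design = SimulationDesign(
        genetic=[[1.0, cov_a0b, 0.0], [cov_a0b, 1.0, 0.0], [0.0, 0.0, 0.0]],
        residual=[[1.0, cov_t0eps, cov_t0t1], [cov_t0eps, 1.0, 0.0], [cov_t0t1, 0.0, var_tau1]],
        name="rcci",
    )
    return simulate_full(A, design, seed, A_sqrt, n=n)


# Named designs of the simulation studies.  All have var(a0)=var(beta)=
# var(e)=var(eps)=1 so that var(c)=2 and the interaction share of var(y) is
# var(a1)/var(y).
PRESETS: dict[str, SimulationDesign] = {
    # independent genetic effects, no interaction: the null for the
    # G-C interaction type-I-error study
    "null_independent": SimulationDesign(
        genetic=np.diag([1.0, 1.0, 0.0]),
        residual=np.diag([1.0, 1.0, 0.0]),
        name="null_independent",
    ),
    # var(a1)=0.25, cov(a0,a1)=0.05: the power / 10%-interaction-share design
    "gc_interaction": SimulationDesign(
        genetic=[[1.0, 0.0, 0.05], [0.0, 1.0, 0.0], [0.05, 0.0, 0.25]],
        residual=np.diag([1.0, 1.0, 0.0]),
        name="gc_interaction",
    ),
    # genetic correlation 0.5 and residual correlation 0.3 but no
    # interaction: the spurious-signal null for the univariate model
    "gc_correlation_null": SimulationDesign(
        genetic=[[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 0.0]],
        residual=[[1.0, 0.3, 0.0], [0.3, 1.0, 0.0], [0.0, 0.0, 0.0]],
        name="gc_correlation_null",
    ),
}


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Per-replicate seed convention, recorded in experiment output."""
    return int(base_seed) + int(replicate)
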