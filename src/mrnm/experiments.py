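"""Simulation studies (type-I error, power, inflation) and workflow utilities.

The experiment drivers tie together the simulator and the REML engine: each
replicate simulates a trait/covariate pair over a fixed GRM, fits a nested
H0/H1 model pair, and records the likelihood-ratio p-value.  Summaries follow
the conventions of the simulation studies this package reproduces: rejection
proportions at alpha = 0.05, the median-based inflation factor lambda, and
mean variance-component estimates with Monte Carlo standard errors.

The workflow utilities (confounder pre-adjustment, covariate stratification,
rank-based inverse normal transform, Fisher's method) mirror the real-data
analysis pipeline of the reaction-norm framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import make_model
from .genotypes import GRM
from .reml import FitResult, RemlOptions, fit, lrt
from .simulate import (
    PRESETS,
    SimulatedData,
    SimulationDesign,
    replicate_seed,
    simulate_full,
    simulate_gcci,
    simulate_rcci,
)

__all__ = [
    "ExperimentResult",
    "transform_p_to_z",
    "lambda_median",
    "fisher_meta",
    "rint",
    "stratify_covariate",
    "adjust_for_confounders",
    "run_interaction_test",
    "type_i_error_experiment",
    "power_experiment",
    "inflation_experiment",
    "residual_variance_difference_test",
    "METHODS",
]

ALPHA = 0.05
#: z threshold displayed alongside inverse-normal-transformed p-values
Z_THRESHOLD = 1.65

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


# ---------------------------------------------------------------------------
# summary statistics and transforms
# ---------------------------------------------------------------------------


def transform_p_to_z(p):
    """Upper-tail standard normal quantile of a p-value (p=0.05 -> 1.645)."""
    return stats.norm.isf(p)


def lambda_median(pvals) -> float:
    """Ratio of observed to expected median chi-square(1) test statistic."""
    pvals = np.asarray(pvals, dtype=float)
    obs = stats.chi2.isf(np.median(pvals), 1)
    return float(obs / _CHI2_1_MEDIAN)


def fisher_meta(pvals) -> float:
    """Fisher's method: -2 sum(ln p) against chi-square with 2k df."""
    pvals = np.asarray(pvals, dtype=float)
    stat = -2.0 * np.log(pvals).sum()
    return float(stats.chi2.sf(stat, 2 * len(pvals)))


def rint(y) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset (r-3/8)/(n+1/4)."""
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(y) + 0.25))


def stratify_covariate(
    c, n_groups: int = 4, breakpoints=None
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a covariate into discrete groups (quartiles by default).

    Returns integer labels (0..G-1, ordered by covariate level) and the group
    representative values (mean covariate within each group).  Explicit
    ``breakpoints`` are right-inclusive cut points, so ``breakpoints=[0]`` on
    a covariate with zeros puts the zeros into their own bottom group.
    """
    c = np.asarray(c, dtype=float)
    if breakpoints is not None:
        edges = np.asarray(breakpoints, dtype=float)
        labels = np.searchsorted(edges, c, side="left")
    else:
        qs = np.quantile(c, np.linspace(0, 1, n_groups + 1)[1:-1])
        if len(np.unique(qs)) < len(qs) or np.ptp(c) == 0:
            if np.ptp(c) == 0:
                warnings.warn("covariate is constant; single stratum returned")
                return np.zeros(len(c), dtype=int), np.array([c[0] if len(c) else 0.0])
        labels = np.searchsorted(qs, c, side="right")
    uniq = np.unique(labels)
    remap = {g: i for i, g in enumerate(uniq)}
    labels = np.array([remap[g] for g in labels])
    reps = np.array([c[labels == i].mean() for i in range(len(uniq))])
    return labels, reps


def adjust_for_confounders(y, X_conf=None) -> np.ndarray:
    """Least-squares residuals of y on the confounders plus an intercept."""
    y = np.asarray(y, dtype=float)
    if X_conf is None or (hasattr(X_conf, "size") and np.asarray(X_conf).size == 0):
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), np.atleast_2d(np.asarray(X_conf, float).T).T])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# nested model pairs
# ---------------------------------------------------------------------------

#: named H0/H1 pairs used throughout the simulation studies
METHODS = ("rnm", "rr_greml", "gci_greml", "mrnm")


def _standardize(c: np.ndarray) -> np.ndarray:
    return (c - c.mean()) / c.std()


def run_interaction_test(
    A: GRM,
    sim: SimulatedData,
    method: str,
    n_groups: int = 4,
    standardize: bool = True,
    options: RemlOptions | None = None,
) -> dict:
    """Fit one nested H0/H1 pair on simulated data and return the LRT.

    Methods: ``rnm`` (GREML vs univariate reaction norm), ``rr_greml``
    (stratified random regression with per-group residual variances),
    ``gci_greml`` (same-group interaction component, homogeneous residual),
    ``mrnm`` (bivariate GREML vs multivariate reaction norm).  The alternative
    fit is warm-started from the null fit, which both speeds convergence and
    guarantees logL(H1) >= logL(H0).
    """
    opts = options or RemlOptions()
    c = _standardize(sim.c) if standardize else np.asarray(sim.c, dtype=float)
    y = np.asarray(sim.y, dtype=float)

    if method == "rnm":
        data0 = {"y": y, "c": c, "A": A}
        fit0 = fit(make_model("GREML"), data0, opts)
        fit1 = fit(make_model("RNM_GC"), data0, opts, start=fit0.params)
    elif method == "mrnm":
        data0 = {"y": y, "c": c, "A": A}
        fit0 = fit(make_model("MVGREML"), data0, opts)
        fit1 = fit(make_model("MRNM_GC"), data0, opts, start=fit0.params)
    elif method in ("rr_greml", "gci_greml"):
        labels, reps = stratify_covariate(c, n_groups=n_groups)
        gvals = reps[labels]
        data0 = {"y": y, "c": c, "A": A, "groups": labels, "group_values": gvals}
        if method == "rr_greml":
            fit0 = fit(make_model("RR_GREML", groups=n_groups, rr_order=0), data0, opts)
            fit1 = fit(
                make_model("RR_GREML", groups=n_groups, rr_order=1),
                data0, opts, start=fit0.params,
            )
        else:
            fit0 = fit(make_model("GREML"), data0, opts)
            fit1 = fit(make_model("GCI_GREML", groups=n_groups), data0, opts,
                       start=fit0.params)
    else:
        raise ValueError(f"unknown method {method!r}")
    res = lrt(fit0, fit1)
    return {"p": res.p_value, "lrt": res, "fit0": fit0, "fit1": fit1}


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Per-replicate records and summary of one simulation experiment."""

    method: str
    records: pd.DataFrame
    alpha: float = ALPHA
    n_excluded: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def pvals(self) -> np.ndarray:
        return self.records["p"].to_numpy()

    @property
    def rejection_rate(self) -> float:
        return float((self.pvals < self.alpha).mean())

    @property
    def lambda_gc(self) -> float:
        return lambda_median(self.pvals)

    def mean_estimates(self) -> pd.Series:
        cols = [c for c in self.records.columns if c.startswith("est_")]
        return self.records[cols].mean()

    def mc_se(self) -> pd.Series:
        cols = [c for c in self.records.columns if c.startswith("est_")]
        return self.records[cols].std(ddof=1) / np.sqrt(len(self.records))


def _simulate_design(A, design, seed, A_sqrt):
    if isinstance(design, str):
        design = PRESETS[design]
    return simulate_full(A, design, seed, A_sqrt=A_sqrt)


def interaction_experiment(
    design: SimulationDesign | str,
    n_reps: int,
    A: GRM,
    methods=("rnm",),
    seed: int = 0,
    standardize: bool = True,
    n_groups: int = 4,
    options: RemlOptions | None = None,
) -> dict[str, ExperimentResult]:
    """Simulate replicates under ``design`` and LRT-test each method pair.

    Non-converged replicates are excluded from rejection proportions and the
    exclusion count is reported per method.
    """
    A_sqrt = A.sqrt()
    rows: dict[str, list] = {m: [] for m in methods}
    excluded = {m: 0 for m in methods}
    for rep in range(n_reps):
        sim = _simulate_design(A, design, replicate_seed(seed, rep), A_sqrt)
        for m in methods:
            out = run_interaction_test(
                A, sim, m, n_groups=n_groups, standardize=standardize, options=options
            )
            if not out["lrt"].valid:
                excluded[m] += 1
                continue
            rec = {"rep": rep, "p": out["p"], "stat": out["lrt"].statistic}
            for k, v in out["fit1"].params.items():
                rec[f"est_{k}"] = v
            rows[m].append(rec)
    return {
        m: ExperimentResult(m, pd.DataFrame(rows[m]), n_excluded=excluded[m])
        for m in methods
    }


def type_i_error_experiment(
    preset: SimulationDesign | str,
    n_reps: int,
    A: GRM,
    methods=("rnm",),
    seed: int = 0,
    **kw,
) -> dict[str, ExperimentResult]:
    """Rejection proportion at alpha=0.05 under a no-interaction design."""
    design = PRESETS[preset] if isinstance(preset, str) else preset
    if design.genetic[2, 2] != 0 or design.residual[2, 2] != 0:
        raise ValueError("type-I-error design must have zero interaction variance")
    return interaction_experiment(design, n_reps, A, methods, seed, **kw)


def power_experiment(
    preset: SimulationDesign | str,
    n_reps: int,
    A: GRM,
    methods=("rnm",),
    seed: int = 0,
    **kw,
) -> dict[str, ExperimentResult]:
    """Rejection proportion at alpha=0.05 under an interaction design."""
    return interaction_experiment(preset, n_reps, A, methods, seed, **kw)


def inflation_experiment(
    grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_reps: int = 100,
    A: GRM | None = None,
    seed: int = 0,
    kind: str = "gc",
    options: RemlOptions | None = None,
    fit_rnm: bool = True,
) -> pd.DataFrame:
    """Mean residual-variance estimates from additive GREML vs the reaction norm.

    For each interaction-variance grid point, data are simulated with the
    interaction component present (``kind='gc'``: y = a0 + a1*c + e;
    ``kind='rc'``: y = a0 + t0 + t1*c) and the residual variance is estimated
    by a plain additive GREML (y = a0 + e) and, when ``fit_rnm``, by the
    matching reaction-norm model.  True residual variance is 1, so the GREML
    column divided by 1 is the fold-inflation.
    """
    opts = options or RemlOptions()
    A_sqrt = A.sqrt()
    out = []
    variant = "RNM_GC" if kind == "gc" else "RNM_RC"
    for gi, v in enumerate(grid):
        greml_res, rnm_res = [], []
        for rep in range(n_reps):
            s = replicate_seed(seed, gi * n_reps + rep)
            # the slope/intercept covariance of 0.05 is only PSD-consistent
            # with a positive interaction variance
            cov01 = 0.05 if v > 0 else 0.0
            if kind == "gc":
                sim = simulate_gcci(A, var_alpha1=v, cov_a0a1=cov01, seed=s, A_sqrt=A_sqrt)
            else:
                sim = simulate_rcci(A, var_tau1=v, cov_t0t1=cov01, seed=s, A_sqrt=A_sqrt)
            c = _standardize(sim.c)
            data = {"y": sim.y, "c": c, "A": A}
            f0 = fit(make_model("GREML"), data, opts)
            if f0.converged:
                greml_res.append(f0.params["my00"])
            if fit_rnm:
                f1 = fit(make_model(variant), data, opts, start=f0.params)
                if f1.converged:
                    rnm_res.append(f1.params["my00"])
        row = {
            "var_interaction": v,
            "greml_residual_mean": float(np.mean(greml_res)),
            "greml_residual_ci95": 1.96 * float(np.std(greml_res, ddof=1)) / np.sqrt(len(greml_res)),
            "n_greml": len(greml_res),
        }
        if fit_rnm:
            row.update(
                rnm_residual_mean=float(np.mean(rnm_res)),
                rnm_residual_ci95=1.96 * float(np.std(rnm_res, ddof=1)) / np.sqrt(len(rnm_res)),
                n_rnm=len(rnm_res),
            )
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# residual-variance difference test
# ---------------------------------------------------------------------------


def residual_variance_difference_test(
    fit_greml: FitResult,
    fit_rnm: FitResult,
    data: dict,
    n_jackknife_groups: int = 50,
    seed: int = 0,
    options: RemlOptions | None = None,
) -> tuple[float, float, float]:
    """Wald test of (RNM residual variance) - (GREML residual variance).

    The standard error comes from a delete-a-group jackknife over individuals:
    both models are refitted with each of ``n_jackknife_groups`` random groups
    removed.  Returns (difference, SE, two-tailed p).
    """
    opts = options or RemlOptions()
    diff = fit_rnm.params["my00"] - fit_greml.params["my00"]
    y = np.asarray(data["y"], float)
    c = np.asarray(data["c"], float)
    A = data["A"]
    Av = A.values if isinstance(A, GRM) else np.asarray(A)
    n = len(y)
    rng = np.random.default_rng(seed)
    assign = rng.permutation(n) % n_jackknife_groups
    spec_rnm = fit_rnm.spec
    pseudo = []
    for g in range(n_jackknife_groups):
        keep = assign != g
        sub = GRM(Av[np.ix_(keep, keep)], [str(i) for i in np.where(keep)[0]], 0)
        d = {"y": y[keep], "c": c[keep], "A": sub}
        f0 = fit(make_model("GREML"), d, opts, start=fit_greml.params, engine="dense")
        f1 = fit(spec_rnm, d, opts, start=fit_rnm.params, engine="dense")
        pseudo.append(f1.params["my00"] - f0.params["my00"])
    pseudo = np.asarray(pseudo)
    g = n_jackknife_groups
    se = float(np.sqrt((g - 1) / g * ((pseudo - pseudo.mean()) ** 2).sum()))
    p = float(2.0 * stats.norm.sf(abs(diff) / se)) if se > 0 else float("nan")
    return float(diff), se, p
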