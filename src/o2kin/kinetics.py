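"""Mono-exponential VO2 on-kinetics: model, Gauss-Newton fit, QC.

At walk onset, oxygen uptake rises from its resting level y1 towards a
steady state y2 in an approximately mono-exponential fashion,

    VO2(t) = y2 - (y2 - y1) * exp(-t / tau),

with time constant tau > 0.  The short cardiodynamic delay (phase I) is not
modelled: the three-parameter asymptotic model is stabler than an
over-parameterised delayed one, at the cost of a possible slight upward bias
in tau.  With no delay term, the mean response time (MRT) — the time to
reach 63% (1 - 1/e) of the rest-to-steady-state rise — equals tau.

Fitting is nonlinear least squares via the standard Gauss-Newton algorithm
with step halving.  Goodness of fit is assessed with Neill's lack-of-fit
test, an F-type test that substitutes clusters of neighbouring design points
for exact replicates, and curves are classified against the two failure
patterns seen in field recordings: no plateau within the walk (steadily
rising VO2, typically from increasing walking speed) and marked variability
after the plateau (pauses / variable pace).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .preprocess import WindowedSeries

__all__ = [
    "KineticsFit",
    "QCResult",
    "DegenerateFitError",
    "LackOfFitNotComputable",
    "model_vo2",
    "fit_monoexponential",
    "fit_kinetics",
    "neill_lack_of_fit",
    "classify_qc",
    "adjust_pvalues",
]


class DegenerateFitError(RuntimeError):
    """The fitted rise is non-positive (y2 <= y1): indices are undefined."""


class LackOfFitNotComputable(RuntimeError):
    """Neill's test cannot be computed (too few clusters or no pure error)."""


def model_vo2(t, y1: float, y2: float, tau: float):
    """Mono-exponential on-kinetics model ``y2 - (y2 - y1) * exp(-t/tau)``.

    ``t`` is time since exercise onset, in the same unit as ``tau``.
    The value is y1 at t=0, approaches y2 as t grows, and is strictly
    increasing whenever y2 > y1.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    out = y2 - (y2 - y1) * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


@dataclass
class KineticsFit:
    """Least-squares estimates of (y1, y2, tau) with diagnostics.

    ``tau_min`` is always in minutes; ``tau`` is in the unit of the time
    axis the fit ran on (``time_unit``).
    """

    y1: float
    y2: float
    tau: float
    time_unit: str  # "min" or "s"
    residuals: np.ndarray
    ssr: float
    iterations: int
    converged: bool
    se: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def tau_min(self) -> float:
        return self.tau / 60.0 if self.time_unit == "s" else self.tau

    @property
    def delta_vo2(self) -> float:
        return self.y2 - self.y1

    def predict(self, t):
        return model_vo2(t, self.y1, self.y2, self.tau)

    def to_json(self, **extra) -> str:
        d = {
            "y1_mlmin": self.y1,
            "y2_mlmin": self.y2,
            "tau_min": self.tau_min,
            "ssr": self.ssr,
            "iterations": self.iterations,
            "converged": self.converged,
            "se": list(self.se),
        }
        d.update(extra)
        return json.dumps(d, indent=2)


def _gauss_newton(t, y, beta0, tol=1e-8, max_iter=50, max_halvings=30):
    """Gauss-Newton with step halving for the mono-exponential model.

    Returns (beta, residuals, ssr, iterations, converged).  Steps that raise
    the SSR, or push tau non-positive, are halved; convergence is a relative
    SSR change below ``tol``.
    """
    beta = np.array(beta0, dtype=float)
    if beta[2] <= 0:
        beta[2] = 0.5 * (t[-1] - t[0]) if t[-1] > t[0] else 1.0
    resid = y - model_vo2(t, *beta)
    ssr = float(resid @ resid)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        y1, y2, tau = beta
        e = np.exp(-t / tau)
        # Jacobian of the model wrt (y1, y2, tau)
        J = np.column_stack([e, 1.0 - e, -(y2 - y1) * t * e / tau**2])
        step, *_ = np.linalg.lstsq(J, resid, rcond=None)
        lam = 1.0
        accepted = False
        for _ in range(max_halvings):
            cand = beta + lam * step
            if cand[2] > 0:
                r_new = y - model_vo2(t, *cand)
                ssr_new = float(r_new @ r_new)
                if ssr_new <= ssr:
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            break
        rel_change = (ssr - ssr_new) / ssr if ssr > 0 else 0.0
        beta, resid, ssr = cand, r_new, ssr_new
        if rel_change < tol:
            converged = True
            break
    return beta, resid, ssr, it, converged


def fit_monoexponential(
    t: np.ndarray,
    y: np.ndarray,
    init: Optional[Sequence[float]] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    time_unit: str = "min",
) -> KineticsFit:
    """Fit ``y2 - (y2-y1)exp(-t/tau)`` to (t, y) by Gauss-Newton.

    Default initialisation: y1 = first observation, y2 = mean of the points
    in the final two minutes (final third when the unit is unknown), tau =
    time to half rise divided by ln 2.  Non-convergence returns a fit with
    ``converged=False``; a fitted rise <= 0 raises
    :class:`DegenerateFitError`.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit three parameters")
    if init is None:
        y1_0 = y[0]
        tail = 2.0 if time_unit == "min" else 120.0
        tail_mask = t >= t[-1] - tail
        y2_0 = float(np.mean(y[tail_mask])) if tail_mask.any() else float(y[-1])
        half = y1_0 + 0.5 * (y2_0 - y1_0)
        above = np.nonzero(y >= half)[0] if y2_0 > y1_0 else np.array([], int)
        t_half = t[above[0]] if len(above) else 0.5 * (t[0] + t[-1])
        tau_0 = max(t_half, 1e-3 * max(t[-1], 1.0)) / np.log(2)
        init = (y1_0, y2_0, tau_0)
    beta, resid, ssr, it, converged = _gauss_newton(
        t, y, init, tol=tol, max_iter=max_iter
    )
    y1, y2, tau = (float(b) for b in beta)
    if converged and y2 <= y1:
        raise DegenerateFitError(
            f"fitted rise is non-positive (y2={y2:.1f} <= y1={y1:.1f})"
        )
    # standard errors from the Jacobian at the solution
    se = (np.nan, np.nan, np.nan)
    dof = len(t) - 3
    if converged and dof > 0:
        e = np.exp(-t / tau)
        J = np.column_stack([e, 1.0 - e, -(y2 - y1) * t * e / tau**2])
        try:
            cov = np.linalg.inv(J.T @ J) * (ssr / dof)
            se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(cov), 0, None)))
        except np.linalg.LinAlgError:
            pass
    return KineticsFit(
        y1=y1, y2=y2, tau=tau, time_unit=time_unit,
        residuals=resid, ssr=ssr, iterations=it, converged=converged,
        se=se, t=t, y=y,
    )


def fit_kinetics(
    w: WindowedSeries,
    init: Optional[Sequence[float]] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> KineticsFit:
    """Fit the on-kinetics model to a windowed walk-phase VO2 series.

    Windows are unweighted (homoscedastic errors assumed).  Time is
    converted to minutes since walk onset, so ``tau`` is in minutes.
    """
    if len(w) < 5:
        raise ValueError("need at least 5 windows")
    t_min = w.midpoint_s / 60.0
    return fit_monoexponential(
        t_min, w.vo2_mlmin, init=init, tol=tol, max_iter=max_iter, time_unit="min"
    )


def _pair_clusters(n: int) -> np.ndarray:
    """Default Neill clustering: consecutive non-overlapping pairs.

    With odd n the final cluster holds three points, so every cluster keeps
    at least two members.
    """
    g = np.arange(n) // 2
    if n % 2 == 1 and n >= 3:
        g[-1] = g[-2]
    return g


def neill_lack_of_fit(
    fit: KineticsFit,
    w: Optional[WindowedSeries] = None,
    grouping: Optional[Sequence[int]] = None,
) -> tuple[float, float]:
    """Neill's lack-of-fit test for the fitted on-kinetics curve.

    Nearby design points, grouped into clusters (default: consecutive
    pairs of windows), act as pseudo-replicates.  Within-cluster scatter
    estimates pure error; the excess of the fit's residual sum of squares
    over pure error, per lack-of-fit degree of freedom, is compared to the
    pure-error mean square with an F reference distribution.  Degrees of
    freedom: lack of fit m - p (m clusters, p = 3 parameters), pure error
    n - m.

    Returns ``(F statistic, p value)``.  Raises
    :class:`LackOfFitNotComputable` when fewer than two clusters have two
    members, when m <= p, or when the pure-error sum of squares is zero.
    """
    if not fit.converged:
        raise ValueError("lack-of-fit test requires a converged fit")
    resid = np.asarray(fit.residuals, dtype=float)
    n = len(resid)
    g = np.asarray(grouping if grouping is not None else _pair_clusters(n))
    if len(g) != n:
        raise ValueError("grouping length must match number of windows")
    clusters = np.unique(g)
    sizes = np.array([np.count_nonzero(g == c) for c in clusters])
    if np.count_nonzero(sizes >= 2) < 2:
        raise LackOfFitNotComputable("need at least 2 clusters with >= 2 windows")
    m = len(clusters)
    p = 3
    df_lof, df_pe = m - p, n - m
    if df_lof <= 0 or df_pe <= 0:
        raise LackOfFitNotComputable("not enough clusters for lack-of-fit df")
    ss_pe = 0.0
    for c in clusters:
        r = resid[g == c]
        ss_pe += float(np.sum((r - r.mean()) ** 2))
    ss_tot = float(resid @ resid)
    ss_lof = max(ss_tot - ss_pe, 0.0)
    # effectively-zero pure error (data generated exactly from the model)
    scale = float(np.mean(np.abs(fit.y))) if len(fit.y) else 1.0
    if ss_pe <= n * (1e-9 * max(scale, 1.0)) ** 2:
        raise LackOfFitNotComputable("zero pure-error sum of squares")
    F = (ss_lof / df_lof) / (ss_pe / df_pe)
    pval = float(stats.f.sf(F, df_lof, df_pe))
    return float(F), pval


def adjust_pvalues(pvals: Sequence[float], method: str = "holm") -> np.ndarray:
    """Multiplicity-adjust a collection of p-values (Holm by default,
    'fdr_bh' for Benjamini-Hochberg)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method=method)[1]


@dataclass
class QCResult:
    """Curve-quality classification for one session.

    Exactly one status: ``acceptable``, ``no_plateau`` (VO2 still rising at
    walk end), ``variable_plateau`` (marked post-plateau variability) or
    ``not_converged``.  A significant Neill test flags the fit but does not
    by itself exclude it.
    """

    status: str
    neill_statistic: float = np.nan
    neill_p: float = np.nan
    neill_p_adjusted: float = np.nan
    drift_slope: float = np.nan  # ml/min per min, final 2 min of windows
    drift_p: float = np.nan
    post_plateau_cv: float = np.nan
    neill_flag: bool = False

    @property
    def acceptable(self) -> bool:
        return self.status == "acceptable"


def classify_qc(
    fit: KineticsFit,
    w: WindowedSeries,
    cohort_pvalues: Optional[Sequence[float]] = None,
    drift_slope_threshold: float = 50.0,
    plateau_cv_threshold: float = 0.075,
    adjust_method: str = "holm",
) -> QCResult:
    """Classify a fitted curve against the two exclusion patterns.

    ``no_plateau``: the estimated 3*tau exceeds the walk duration (steady
    state never approached), or a straight line through the final two
    minutes of window means rises faster than ``drift_slope_threshold``
    (ml/min per min) with slope p < 0.05.  ``variable_plateau``: the CV of
    window means after t = 3*tau exceeds ``plateau_cv_threshold``.
    Otherwise ``acceptable``.

    When the cohort's raw Neill p-values are supplied (this fit's raw p
    among them), a multiplicity-adjusted p (Holm by default) is attached and
    the fit is flagged when adjusted p < 0.05 — flagged, not excluded.
    """
    if not fit.converged:
        return QCResult(status="not_converged")
    t_min = w.midpoint_s / 60.0
    v = w.vo2_mlmin
    walk_min = (w.midpoint_s[-1] + w.width_s / 2.0) / 60.0

    # late-phase drift: OLS slope over the final 2 min of windows
    drift_slope = drift_p = np.nan
    late = t_min >= walk_min - 2.0
    if np.count_nonzero(late) >= 3:
        res = stats.linregress(t_min[late], v[late])
        drift_slope, drift_p = float(res.slope), float(res.pvalue)

    # post-plateau variability: CV of window means after 3*tau
    post_cv = np.nan
    post = t_min >= 3.0 * fit.tau_min
    if np.count_nonzero(post) >= 3 and np.mean(v[post]) > 0:
        post_cv = float(np.std(v[post], ddof=1) / np.mean(v[post]))

    try:
        neill_F, neill_p = neill_lack_of_fit(fit, w)
    except LackOfFitNotComputable:
        neill_F = neill_p = np.nan
    neill_p_adj = np.nan
    neill_flag = False
    if cohort_pvalues is not None and np.isfinite(neill_p):
        pvals = np.asarray(cohort_pvalues, dtype=float)
        adj = adjust_pvalues(pvals, method=adjust_method)
        # attach the adjusted value for this fit's own raw p
        i = int(np.argmin(np.abs(pvals - neill_p)))
        neill_p_adj = float(adj[i])
        neill_flag = neill_p_adj < 0.05

    no_plateau = 3.0 * fit.tau_min > walk_min or (
        np.isfinite(drift_slope)
        and drift_slope > drift_slope_threshold
        and drift_p < 0.05
    )
    if no_plateau:
        status = "no_plateau"
    elif np.isfinite(post_cv) and post_cv > plateau_cv_threshold:
        status = "variable_plateau"
    else:
        status = "acceptable"
    return QCResult(
        status=status,
        neill_statistic=neill_F,
        neill_p=neill_p,
        neill_p_adjusted=neill_p_adj,
        drift_slope=drift_slope,
        drift_p=drift_p,
        post_plateau_cv=post_cv,
        neill_flag=neill_flag,
    )


def plot_fit(fit: KineticsFit, w: WindowedSeries, ax=None):
    """Diagnostic plot: windowed points, fitted curve, O2-deficit shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t_min = w.midpoint_s / 60.0
    ax.plot(t_min, w.vo2_mlmin, "o", ms=4, color="0.3", label="20 s window means")
    tt = np.linspace(0, t_min[-1], 200)
    yy = fit.predict(tt)
    ax.plot(tt, yy, "r-", label="fitted mono-exponential")
    ax.fill_between(tt, yy, fit.y2, alpha=0.2, color="tab:blue", label="O2 deficit")
    ax.set_xlabel("time since walk onset (min)")
    ax.set_ylabel("VO2 (ml/min)")
    ax.legend(frameon=False)
    return ax
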