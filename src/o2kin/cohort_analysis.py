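"""Cohort-level statistics: group comparisons, associations, survival.

The per-subject indices feed four analyses: a Shapiro-Wilk normality gate
(liberal rejection at p < 0.25, so mild non-normality is surfaced rather
than hidden), one-way linear-model (ANOVA F) comparisons of an index across
disease groups with uncorrected pairwise contrasts, univariate OLS
regressions of exercise-capacity measures on wMRT (predictor rescaled by
1e3 so slopes land on the conventional reporting scale), and a
median-dichotomized survival analysis: Kaplan-Meier curves per wMRT arm and
a Cox proportional-hazards model whose Wald test carries the hypothesis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalityDecision",
    "GroupComparison",
    "AssociationResult",
    "SurvivalResult",
    "normality_gate",
    "compare_groups",
    "associate",
    "survival_analysis",
    "read_cohort_table",
    "write_cohort_table",
]

#: Columns required of a cohort table.
COHORT_COLUMNS = (
    "subject_id",
    "group",
    "cardiac",
    "mrt_min",
    "vo2_ss_mlmin",
    "vo2_rest_mlmin",
    "wmrt_min2_ml",
    "distance_m",
    "followup_months",
    "event",
)

#: wMRT is of order 1e-3 min^2/ml; regressions rescale it by this factor so
#: slope magnitudes are on the conventional reporting scale.
WMRT_SCALE = 1e3


def read_cohort_table(source) -> pd.DataFrame:
    df = pd.read_csv(source)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (df["followup_months"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def write_cohort_table(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, index=False)


@dataclass
class NormalityDecision:
    statistic: float
    p: float
    parametric: bool  # p >= cutoff: no evidence against normality
    cutoff: float = 0.25


def normality_gate(values, cutoff: float = 0.25) -> NormalityDecision:
    """Shapiro-Wilk gate with a deliberately liberal cutoff (default 0.25).

    ``parametric=False`` flags the variable as non-parametric; group
    comparisons still run on the linear-model path, carrying the flag.
    Constant or too-short samples are not computable (ValueError).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("normality gate needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("normality gate not computable for a constant sample")
    W, p = stats.shapiro(x)
    return NormalityDecision(float(W), float(p), parametric=p >= cutoff,
                             cutoff=cutoff)


@dataclass
class GroupComparison:
    index: str
    f_statistic: float
    p: float
    group_means: dict
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, p
    normality: Optional[NormalityDecision] = None


def compare_groups(
    cohort: pd.DataFrame,
    index: str = "wmrt_min2_ml",
    check_normality: bool = True,
) -> GroupComparison:
    """One-way linear-model (ANOVA F) comparison of an index across groups,
    with uncorrected pairwise contrasts from the pooled residual variance."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = cohort[["group", index]].dropna().rename(columns={index: "y"})
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("group comparison needs at least 2 groups")
    if (df.groupby("group").size() < 2).any():
        raise ValueError("every group needs at least 2 subjects")
    model = smf.ols("y ~ C(group)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    F = float(anova["F"].iloc[0])
    p = float(anova["PR(>F)"].iloc[0])
    means = df.groupby("group")["y"].mean().to_dict()
    ns = df.groupby("group").size().to_dict()
    s2 = model.mse_resid
    dof = model.df_resid
    rows = []
    gl = sorted(groups)
    for i, a in enumerate(gl):
        for b in gl[i + 1:]:
            diff = means[a] - means[b]
            se = np.sqrt(s2 * (1 / ns[a] + 1 / ns[b]))
            tstat = diff / se
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "diff": diff,
                    "p": float(2 * stats.t.sf(abs(tstat), dof)),
                }
            )
    normality = None
    if check_normality:
        try:
            normality = normality_gate(df["y"].to_numpy())
        except ValueError:
            normality = None
    return GroupComparison(
        index=index, f_statistic=F, p=p, group_means=means,
        pairwise=pd.DataFrame(rows), normality=normality,
    )


@dataclass
class AssociationResult:
    outcome: str
    group: str
    beta: float  # per unit of wMRT * 1e3
    r_squared: float
    p: float
    n: int


def associate(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str = "wmrt_min2_ml",
    group: Optional[str] = None,
    predictor_scale: float = WMRT_SCALE,
) -> AssociationResult:
    """Univariate OLS of ``outcome`` on wMRT (rescaled by 1e3) in one group
    (or the whole cohort when ``group`` is None)."""
    import statsmodels.api as sm

    df = cohort if group is None else cohort[cohort["group"] == group]
    df = df[[predictor, outcome]].dropna()
    if len(df) < 3:
        raise ValueError("association needs n >= 3")
    x = df[predictor].to_numpy(dtype=float) * predictor_scale
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(
        outcome=outcome,
        group=group or "all",
        beta=float(model.params[1]),
        r_squared=float(model.rsquared),
        p=float(model.pvalues[1]),
        n=len(df),
    )


@dataclass
class SurvivalResult:
    stratum: str
    median_wmrt: float
    km: dict  # arm -> DataFrame(time, survival, at_risk)
    hazard_ratio: float = np.nan  # high vs low wMRT
    wald_p: float = np.nan
    cox_skipped: str = ""
    n_low: int = 0
    n_high: int = 0


def survival_analysis(
    cohort: pd.DataFrame,
    stratum: str = "cardiac",
    covariate_mode: str = "dichotomized",
) -> SurvivalResult:
    """Median-wMRT-dichotomized survival analysis within one stratum.

    The stratum ('cardiac' or 'non_cardiac') is split at its median wMRT,
    ties going to the low arm; Kaplan-Meier curves are estimated per arm
    and a Cox model with the binary high-vs-low covariate (or continuous
    rescaled wMRT with ``covariate_mode='continuous'``) yields the hazard
    ratio and Wald p.  With no events, the Cox step is skipped with a
    notice and KM curves are still returned.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    if stratum == "cardiac":
        df = cohort[cohort["cardiac"].astype(bool)]
    elif stratum == "non_cardiac":
        df = cohort[~cohort["cardiac"].astype(bool)]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    df = df[["wmrt_min2_ml", "followup_months", "event"]].dropna()
    if len(df) < 4:
        raise ValueError("survival analysis needs >= 4 subjects in stratum")
    median = float(df["wmrt_min2_ml"].median())
    high = (df["wmrt_min2_ml"] > median).to_numpy()  # ties -> low arm

    km = {}
    for arm, mask in (("low", ~high), ("high", high)):
        if not mask.any():  # all ties -> everyone in the low arm
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(df["followup_months"][mask], df["event"][mask], label=arm)
        sf = kmf.survival_function_
        km[arm] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf[arm].to_numpy(dtype=float),
                "at_risk": kmf.event_table["at_risk"].reindex(sf.index)
                .to_numpy(dtype=float),
            }
        )

    result = SurvivalResult(
        stratum=stratum, median_wmrt=median, km=km,
        n_low=int((~high).sum()), n_high=int(high.sum()),
    )
    if df["event"].sum() < 1:
        result.cox_skipped = "no events in stratum; Cox model skipped"
        return result
    cox_df = pd.DataFrame(
        {
            "T": df["followup_months"].to_numpy(dtype=float),
            "E": df["event"].to_numpy(dtype=int),
        }
    )
    if covariate_mode == "dichotomized":
        cox_df["x"] = high.astype(float)
    elif covariate_mode == "continuous":
        cox_df["x"] = df["wmrt_min2_ml"].to_numpy(dtype=float) * WMRT_SCALE
    else:
        raise ValueError(f"unknown covariate_mode {covariate_mode!r}")
    if cox_df["x"].nunique() < 2:
        result.cox_skipped = "covariate constant within stratum; Cox skipped"
        return result
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col="T", event_col="E")
    result.hazard_ratio = float(np.exp(cph.params_["x"]))
    result.wald_p = float(cph.summary.loc["x", "p"])
    return result


def plot_km(result: SurvivalResult, ax=None):
    """Kaplan-Meier step plot for the two wMRT arms of a stratum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for arm, color in (("low", "tab:blue"), ("high", "tab:red")):
        d = result.km[arm]
        ax.step(d["time"], d["survival"], where="post",
                label=f"{arm} wMRT (n={getattr(result, 'n_' + arm)})",
                color=color)
    ax.set_xlabel("follow-up (months)")
    ax.set_ylabel("event-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"{result.stratum}: split at median wMRT "
                 f"{result.median_wmrt * 1e3:.2f}e-3")
    return ax
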