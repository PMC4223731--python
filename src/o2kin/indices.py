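"""Physiological indices derived from a fitted on-kinetics curve.

With no phase-I delay in the model, the mean response time (MRT) — the
time to reach 63% (1 - 1/e) of the rest-to-steady-state VO2 rise — equals
the fitted time constant tau.  The oxygen deficit is the area between an
instantaneous step to the steady state and the observed asymptotic rise,
which for the mono-exponential equals tau * (VO2ss - VO2rest).  The
work-rate-corrected index wMRT divides MRT by the rise (VO2ss - VO2rest),
the proxy for work rate in a self-paced walk, giving units of min^2/ml.
The respiratory exchange ratio (RER = VCO2/VO2) over the final two minutes
and the ATS maximal-effort criteria complete the per-subject summary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Protocol

import numpy as np

from .kinetics import DegenerateFitError, KineticsFit
from .preprocess import BreathSeries

__all__ = [
    "SubjectIndices",
    "PredictedValueProvider",
    "DefaultPredictedValues",
    "compute_mrt",
    "compute_o2_deficit",
    "compute_wmrt",
    "compute_rer",
    "effort_criteria",
    "subject_indices",
]


def compute_mrt(fit: KineticsFit) -> float:
    """Mean response time in minutes: the fitted time constant tau.

    Always returned in minutes, whatever time unit the fit used.
    """
    if not fit.converged:
        raise ValueError("MRT requires a converged fit")
    return fit.tau_min


def compute_o2_deficit(fit: KineticsFit) -> float:
    """Oxygen deficit (ml): tau * (y2 - y1).

    The closed form of the area between an instantaneous step to the upper
    limit and the mono-exponential rise, integrated over [0, inf).
    """
    if not fit.converged:
        raise ValueError("O2 deficit requires a converged fit")
    if fit.delta_vo2 < 0:
        raise DegenerateFitError("O2 deficit undefined for a non-positive rise")
    return fit.tau_min * fit.delta_vo2


def compute_wmrt(mrt_min: float, vo2_ss: float, vo2_rest: float) -> float:
    """Work-rate-corrected mean response time, min^2/ml.

    wMRT = MRT / (VO2ss - VO2rest); e.g. 1 min over a 1000 ml/min rise is
    1.0e-3 min^2/ml.  A non-positive rise leaves the index undefined.
    """
    delta = vo2_ss - vo2_rest
    if delta <= 0:
        raise DegenerateFitError(
            f"wMRT undefined: VO2ss - VO2rest = {delta:.1f} <= 0"
        )
    return mrt_min / delta


def compute_rer(series: BreathSeries, tail_min: float = 2.0) -> float:
    """Mean respiratory exchange ratio VCO2/VO2 over the walk's final
    ``tail_min`` minutes.  Breaths with VO2 <= 0 are excluded with a
    warning."""
    walk = series.phase("walk")
    if len(walk) == 0:
        raise ValueError("no walk phase present")
    if "vco2_mlmin" not in walk.columns or walk["vco2_mlmin"].isna().all():
        raise ValueError("VCO2 missing")
    t = walk["time_s"].to_numpy(dtype=float)
    tail = walk.loc[t >= series.walk_end_s - tail_min * 60.0]
    vo2 = tail["vo2_mlmin"].to_numpy(dtype=float)
    vco2 = tail["vco2_mlmin"].to_numpy(dtype=float)
    ok = vo2 > 0
    if not ok.all():
        warnings.warn(
            f"{np.count_nonzero(~ok)} breath(s) with VO2 <= 0 excluded from RER",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("no usable breaths for RER")
    return float(np.mean(vco2[ok] / vo2[ok]))


class PredictedValueProvider(Protocol):
    """Reference-value equations behind the effort criteria.

    The exact published reference equations vary by lab; any provider with
    these three methods can be plugged in.
    """

    def predicted_hr_max(self, age: float, sex: str) -> float: ...
    def predicted_vo2_max(self, age: float, sex: str, height_cm: float,
                          weight_kg: float) -> float: ...
    def ventilatory_capacity(self, fev1_l: float) -> float: ...


class DefaultPredictedValues:
    """Widely used defaults, documented and swappable.

    HRmax = 220 - age; ventilatory capacity (MVV, l/min) = 35 * FEV1;
    predicted VO2max (ml/min) from the Wasserman/Hansen cycle equations
    (men: weight*(50.72 - 0.372*age); women: (weight + 43)*(22.78 -
    0.17*age)).
    """

    def predicted_hr_max(self, age: float, sex: str = "") -> float:
        return 220.0 - age

    def predicted_vo2_max(self, age: float, sex: str, height_cm: float,
                          weight_kg: float) -> float:
        if str(sex).lower().startswith("f"):
            return (weight_kg + 43.0) * (22.78 - 0.17 * age)
        return weight_kg * (50.72 - 0.372 * age)

    def ventilatory_capacity(self, fev1_l: float) -> float:
        return 35.0 * fev1_l


def effort_criteria(
    metadata: dict,
    provider: Optional[PredictedValueProvider] = None,
) -> dict:
    """ATS maximal-effort flags from measured values and reference equations.

    Criteria (strict inequalities, taken literally): (1) measured HRmax
    > 90% of predicted; (2) VO2peak > 84% of the predicted maximum;
    (3) ventilatory reserve < 11 l/min or < 15% of capacity.  Missing
    metadata leaves the corresponding flag ``None`` (unknown); the
    ``maximal_effort`` disjunction is computed over the known flags.

    ``metadata`` keys: age, sex, height_cm, weight_kg, fev1_l, hr_max_bpm,
    vo2_peak_mlmin, ve_peak_lmin (peak minute ventilation).
    """
    provider = provider or DefaultPredictedValues()

    def _get(*keys):
        vals = [metadata.get(k) for k in keys]
        return vals if all(v is not None and not (isinstance(v, float) and np.isnan(v)) for v in vals) else None

    hr_flag = vo2_flag = vent_flag = None
    got = _get("hr_max_bpm", "age")
    if got:
        hr_max, age = got
        hr_flag = hr_max > 0.90 * provider.predicted_hr_max(age, metadata.get("sex", ""))
    got = _get("vo2_peak_mlmin", "age", "sex", "height_cm", "weight_kg")
    if got:
        vo2_peak, age, sex, height, weight = got
        vo2_flag = vo2_peak > 0.84 * provider.predicted_vo2_max(age, sex, height, weight)
    got = _get("ve_peak_lmin", "fev1_l")
    if got:
        ve_peak, fev1 = got
        cap = provider.ventilatory_capacity(fev1)
        reserve = cap - ve_peak
        vent_flag = reserve < 11.0 or (cap > 0 and reserve / cap < 0.15)
    known = [f for f in (hr_flag, vo2_flag, vent_flag) if f is not None]
    return {
        "hr_max_gt_90pct": hr_flag,
        "vo2peak_gt_84pct": vo2_flag,
        "vent_reserve_low": vent_flag,
        "maximal_effort": any(known) if known else None,
    }


@dataclass
class SubjectIndices:
    """Per-subject physiological summary of one walk test."""

    mrt_min: float
    o2_deficit_ml: float
    wmrt_min2_ml: float
    vo2_ss_mlmin: float
    vo2_rest_mlmin: float
    delta_vo2_mlmin: float
    rer: float = np.nan
    distance_m: float = np.nan
    hr_max_gt_90pct: Optional[bool] = None
    vo2peak_gt_84pct: Optional[bool] = None
    vent_reserve_low: Optional[bool] = None
    maximal_effort: Optional[bool] = None

    def to_dict(self) -> dict:
        return asdict(self)


def subject_indices(
    fit: KineticsFit,
    series: Optional[BreathSeries] = None,
    metadata: Optional[dict] = None,
    provider: Optional[PredictedValueProvider] = None,
) -> SubjectIndices:
    """Assemble all indices for one subject from a converged fit.

    VO2ss is the fitted upper limit y2 and VO2rest the fitted lower limit
    y1 (not window means), so the algebraic identities O2def = MRT * rise
    and wMRT = MRT / rise hold exactly.
    """
    mrt = compute_mrt(fit)
    o2def = compute_o2_deficit(fit)
    wmrt = compute_wmrt(mrt, fit.y2, fit.y1)
    rer = np.nan
    if series is not None:
        rer = compute_rer(series)
    flags = effort_criteria(metadata or {}, provider)
    return SubjectIndices(
        mrt_min=mrt,
        o2_deficit_ml=o2def,
        wmrt_min2_ml=wmrt,
        vo2_ss_mlmin=fit.y2,
        vo2_rest_mlmin=fit.y1,
        delta_vo2_mlmin=fit.delta_vo2,
        rer=rer,
        distance_m=(metadata or {}).get("distance_m", np.nan),
        **flags,
    )
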