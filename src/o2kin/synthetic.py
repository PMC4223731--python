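"""Synthetic breath-by-breath 6MWT sessions and cohorts.

No raw walk-test recordings are publicly deposited for this kind of study,
so every downstream stage is exercised against simulated data with the
statistical structure the analysis assumes: a seated rest phase, a
six-minute walk whose VO2 rises mono-exponentially (with an optional short
cardiodynamic delay), a recovery phase, per-breath Gaussian noise, and
gamma-distributed inter-breath intervals.  Two failure modes reproduce the
patterns that force real exclusions — a walk without a VO2 plateau
(steadily increasing pace) and marked post-plateau variability (pauses).
Cohort simulation draws per-group MRT / VO2ss from published group
means/SDs and attaches follow-up times from an exponential hazard whose
dependence on wMRT is a per-group knob (positive for the cardiac group,
zero elsewhere).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import BREATH_COLUMNS, BreathSeries

__all__ = [
    "KineticsGroundTruth",
    "ProtocolSpec",
    "FailureModeSpec",
    "GroupPreset",
    "DEFAULT_PRESETS",
    "simulate_breath_series",
    "simulate_failure_mode",
    "simulate_cohort",
]


class ParameterError(ValueError):
    """A simulation parameter violates its physiological constraint."""


@dataclass(frozen=True)
class KineticsGroundTruth:
    """True kinetics of one simulated subject.

    vo2_rest / vo2_ss in ml/min, tau in minutes, phase-I delay in seconds
    (0 = no cardiodynamic delay, the analysis model's assumption),
    per-breath additive noise SD in ml/min.
    """

    vo2_rest: float
    vo2_ss: float
    tau: float
    delay: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.vo2_rest > 0:
            raise ParameterError("vo2_rest must be > 0")
        if not self.vo2_ss > self.vo2_rest:
            raise ParameterError("vo2_ss must exceed vo2_rest")
        if not self.tau > 0:
            raise ParameterError("tau must be > 0")
        if self.delay < 0:
            raise ParameterError("delay must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def delta_vo2(self) -> float:
        return self.vo2_ss - self.vo2_rest


@dataclass(frozen=True)
class ProtocolSpec:
    """Session timing and breath-frequency structure.

    ``rest_duration_min=None`` draws uniformly from 3-5 min (seated rest
    until stable VO2); the walk is fixed at 6 min.  Breath timing is a
    gamma renewal process with mean interval 60/mean_resp_rate seconds and
    the given coefficient of variation.
    """

    rest_duration_min: Optional[float] = None
    walk_duration_min: float = 6.0
    recovery_duration_min: float = 2.0
    mean_resp_rate: float = 22.0  # breaths/min
    resp_rate_cv: float = 0.25
    rer_target: float = 0.86

    def __post_init__(self) -> None:
        if self.rest_duration_min is not None and self.rest_duration_min <= 0:
            raise ParameterError("rest_duration_min must be > 0")
        for name in ("walk_duration_min", "recovery_duration_min",
                     "mean_resp_rate", "resp_rate_cv", "rer_target"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class FailureModeSpec:
    """A curve-quality failure pattern.

    ``no_plateau``: add a positive linear VO2 drift (``drift_slope`` ml/min
    per min of walking) over the whole walk — the signature of a steadily
    increasing pace.  ``variable_plateau``: superimpose square-wave VO2 dips
    (walking pauses) after the plateau is reached (t > 2*tau);
    ``pause_starts_s`` are seconds since walk onset, each pause lasting
    ``pause_duration_s`` with depth ``dip_fraction`` of the rest-to-steady
    rise.
    """

    mode: str
    drift_slope: float = 100.0  # ml/min per min, no_plateau
    pause_starts_s: tuple[float, ...] = (180.0, 280.0)
    pause_duration_s: float = 20.0
    dip_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("no_plateau", "variable_plateau"):
            raise ParameterError(f"unknown failure mode {self.mode!r}")
        if self.mode == "no_plateau" and self.drift_slope < 0:
            raise ParameterError("drift_slope must be >= 0")
        if self.mode == "variable_plateau":
            if self.pause_duration_s <= 0 or not (0 < self.dip_fraction <= 1):
                raise ParameterError("invalid pause schedule")


def _breath_times(total_s: float, protocol: ProtocolSpec, rng: np.random.Generator):
    """Gamma renewal process of breath times over [0, total_s)."""
    mean_ibi = 60.0 / protocol.mean_resp_rate
    cv = protocol.resp_rate_cv
    shape = 1.0 / cv**2
    scale = mean_ibi / shape
    n_max = int(total_s / mean_ibi * 2) + 50
    ibis = rng.gamma(shape, scale, size=n_max)
    times = np.cumsum(ibis)
    return times[times < total_s]


def _session_vo2(t_s, truth, protocol, rest_s, drift_slope=0.0):
    """Noise-free VO2 at absolute session times (seconds)."""
    walk_end = rest_s + protocol.walk_duration_min * 60.0
    vo2 = np.full_like(t_s, truth.vo2_rest, dtype=float)
    walking = (t_s >= rest_s) & (t_s < walk_end)
    tw = t_s[walking] - rest_s  # seconds since onset
    te = np.maximum(tw - truth.delay, 0.0) / 60.0  # effective minutes
    vo2[walking] = truth.vo2_ss - truth.delta_vo2 * np.exp(-te / truth.tau)
    vo2[walking] += drift_slope * tw / 60.0
    rec = t_s >= walk_end
    if rec.any():
        v_end = truth.vo2_ss - truth.delta_vo2 * np.exp(
            -max(protocol.walk_duration_min * 60.0 - truth.delay, 0.0)
            / 60.0 / truth.tau
        ) + drift_slope * protocol.walk_duration_min
        tr = (t_s[rec] - walk_end) / 60.0
        vo2[rec] = truth.vo2_rest + (v_end - truth.vo2_rest) * np.exp(-tr / truth.tau)
    return vo2


def simulate_breath_series(
    truth: KineticsGroundTruth,
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int = 0,
    subject_id: str = "",
    _failure: Optional[FailureModeSpec] = None,
) -> BreathSeries:
    """Simulate one rest -> walk -> recovery session breath by breath.

    During the walk, noise-free VO2 follows
    ``vo2_ss - (vo2_ss - vo2_rest) * exp(-max(t - delay, 0)/tau)`` with t
    counted from walk onset; rest breaths sit at ``vo2_rest``; recovery
    decays back towards rest.  Per-breath Gaussian noise (SD
    ``truth.noise_sd``) is added, VCO2 = rer_target * VO2, heart rate ramps
    with the same time constant, and SpO2 is constant plus noise.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rest_min = protocol.rest_duration_min
    if rest_min is None:
        rest_min = float(rng.uniform(3.0, 5.0))
    rest_s = rest_min * 60.0
    total_s = rest_s + (protocol.walk_duration_min + protocol.recovery_duration_min) * 60.0
    t = _breath_times(total_s, protocol, rng)

    drift = 0.0
    if _failure is not None and _failure.mode == "no_plateau":
        drift = _failure.drift_slope
    vo2 = _session_vo2(t, truth, protocol, rest_s, drift_slope=drift)
    if _failure is not None and _failure.mode == "variable_plateau":
        tw = t - rest_s
        onset = max(2.0 * truth.tau * 60.0, 0.0)
        dip = _failure.dip_fraction * truth.delta_vo2
        for start in _failure.pause_starts_s:
            if start < onset:
                continue
            in_pause = (tw >= start) & (tw < start + _failure.pause_duration_s)
            walking = (t >= rest_s) & (t < rest_s + protocol.walk_duration_min * 60.0)
            vo2[in_pause & walking] -= dip
    vo2 = vo2 + rng.normal(0.0, truth.noise_sd, size=len(t))

    # ancillary channels: plumbing around the kinetics, not analysis targets
    hr_rest, hr_peak = 72.0, 120.0
    frac = (vo2 - truth.vo2_rest) / truth.delta_vo2
    hr = hr_rest + (hr_peak - hr_rest) * np.clip(frac, 0.0, 1.5)
    spo2 = np.clip(96.0 + rng.normal(0.0, 0.5, size=len(t)), 85.0, 100.0)
    rr_inst = np.full(len(t), protocol.mean_resp_rate)
    ve_l_min = vo2 / 1000.0 * 28.0  # rough ventilatory equivalent for O2
    vt = ve_l_min / rr_inst

    df = pd.DataFrame(
        {
            "time_s": t,
            "vo2_mlmin": vo2,
            "vco2_mlmin": protocol.rer_target * vo2,
            "hr_bpm": hr,
            "spo2_pct": spo2,
            "vt_l": vt,
            "rr_brpm": rr_inst,
        }
    )[list(BREATH_COLUMNS)]
    return BreathSeries(
        data=df,
        rest_start_s=0.0,
        walk_start_s=rest_s,
        walk_end_s=rest_s + protocol.walk_duration_min * 60.0,
        subject_id=subject_id,
    )


def simulate_failure_mode(
    base: KineticsGroundTruth,
    spec: FailureModeSpec,
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int = 0,
    subject_id: str = "",
) -> BreathSeries:
    """Simulate a session exhibiting one of the exclusion patterns.

    With ``drift_slope=0`` the no-plateau series degenerates to the clean
    series under the same seed (same breath times and noise draw).
    """
    return simulate_breath_series(
        base, protocol, seed=seed, subject_id=subject_id, _failure=spec
    )


# -- cohort simulation -------------------------------------------------------

@dataclass(frozen=True)
class GroupPreset:
    """Per-group sampling distributions and outcome model.

    Means/SDs are group summaries on the scale the field reports them:
    MRT in min, VO2ss in ml/min, walking distance in m, follow-up in
    months.  ``hazard_link`` is the log-hazard increase per SD of wMRT
    (zero for the pulmonary groups, positive for congestive heart failure,
    where slowed O2 kinetics carry prognostic weight);
    ``baseline_event_rate`` is the approximate probability of death or
    hospitalisation before censoring.
    """

    label: str
    n: int
    mrt_mean: float
    mrt_sd: float
    vo2ss_mean: float
    vo2ss_sd: float
    distance_mean: float
    distance_sd: float
    followup_mean_months: float
    followup_sd_months: float
    hazard_link: float = 0.0
    baseline_event_rate: float = 0.45
    vo2_rest_mean: float = 300.0
    vo2_rest_sd: float = 40.0
    cardiac: bool = False


#: Default group presets (healthy controls and four disease groups) with
#: the published cohort's group means/SDs.
DEFAULT_PRESETS: tuple[GroupPreset, ...] = (
    GroupPreset("Healthy", 16, 1.13, 0.28, 2376, 630, 720, 83, 38, 6,
                hazard_link=0.0, baseline_event_rate=0.05),
    GroupPreset("COPD", 84, 1.06, 0.28, 1031, 264, 357, 110, 16, 13,
                hazard_link=0.0, baseline_event_rate=0.45),
    GroupPreset("Restrictive", 39, 1.08, 0.32, 1144, 299, 381, 111, 21, 16,
                hazard_link=0.0, baseline_event_rate=0.51),
    GroupPreset("PAH", 54, 1.07, 0.30, 961, 263, 339, 120, 16, 14,
                hazard_link=0.0, baseline_event_rate=0.52),
    GroupPreset("CHF", 27, 0.92, 0.34, 1184, 342, 341, 91, 14, 12,
                hazard_link=0.6, baseline_event_rate=0.52, cardiac=True),
)

#: Truncation bounds avoiding degenerate wMRT draws.
MRT_MIN = 0.2       # min
DELTA_VO2_MIN = 100.0  # ml/min
MAX_RESAMPLES = 1000


def _truncated_normal(rng, mean, sd, lower, size):
    """Draw-and-reject truncated normal; counts rejected draws."""
    out = np.empty(size)
    n_resampled = 0
    for i in range(size):
        for _ in range(MAX_RESAMPLES):
            x = rng.normal(mean, sd)
            if x >= lower:
                out[i] = x
                break
            n_resampled += 1
        else:
            raise ParameterError(
                f"could not draw value >= {lower} from N({mean}, {sd})"
            )
    return out, n_resampled


def simulate_cohort(
    presets: Sequence[GroupPreset] = DEFAULT_PRESETS,
    seed: int = 0,
    generate_series: bool = False,
    protocol: ProtocolSpec = ProtocolSpec(),
    noise_frac: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a whole cohort: per-subject indices, outcomes, ground truth.

    Per subject, MRT and VO2ss are drawn from truncated normals at the
    preset's mean/SD (MRT >= 0.2 min; the implied rise VO2ss - VO2rest is
    re-drawn until >= 100 ml/min, resamples counted).  Follow-up event times
    come from an exponential hazard with log-hazard = per-group baseline +
    hazard_link * standardized wMRT, censored at the drawn follow-up
    duration.  Returns ``(cohort DataFrame, info dict)``; with
    ``generate_series=True`` the info dict maps subject id ->
    :class:`BreathSeries` simulated from that subject's ground truth (noise
    SD = ``noise_frac`` of the rise).
    """
    rng = np.random.default_rng(seed)
    rows = []
    series: dict[str, BreathSeries] = {}
    n_resampled_total = 0
    for preset in presets:
        if preset.n < 2:
            raise ParameterError(f"preset {preset.label}: need n >= 2")
        mrt, r1 = _truncated_normal(rng, preset.mrt_mean, preset.mrt_sd,
                                    MRT_MIN, preset.n)
        n_resampled_total += r1
        vo2ss = np.empty(preset.n)
        vo2rest = np.empty(preset.n)
        for i in range(preset.n):
            for _ in range(MAX_RESAMPLES):
                ss = rng.normal(preset.vo2ss_mean, preset.vo2ss_sd)
                rest = max(rng.normal(preset.vo2_rest_mean, preset.vo2_rest_sd),
                           50.0)
                if ss - rest >= DELTA_VO2_MIN:
                    vo2ss[i], vo2rest[i] = ss, rest
                    break
                n_resampled_total += 1
            else:
                raise ParameterError(
                    f"preset {preset.label}: cannot draw rise >= {DELTA_VO2_MIN}"
                )
        delta = vo2ss - vo2rest
        wmrt = mrt / delta
        distance = np.maximum(
            rng.normal(preset.distance_mean, preset.distance_sd, preset.n), 50.0
        )
        followup = np.maximum(
            rng.normal(preset.followup_mean_months, preset.followup_sd_months,
                       preset.n),
            1.0,
        )
        # exponential event-time model on the months scale
        z = (wmrt - wmrt.mean()) / (wmrt.std(ddof=0) or 1.0)
        base_rate = -np.log(max(1.0 - preset.baseline_event_rate, 1e-6)) / max(
            preset.followup_mean_months, 1.0
        )
        lam = base_rate * np.exp(preset.hazard_link * z)
        t_event = rng.exponential(1.0 / lam)
        event = (t_event <= followup).astype(int)
        time = np.minimum(t_event, followup)
        for i in range(preset.n):
            sid = f"{preset.label}-{i:03d}"
            rows.append(
                {
                    "subject_id": sid,
                    "group": preset.label,
                    "cardiac": preset.cardiac,
                    "mrt_min": mrt[i],
                    "vo2_rest_mlmin": vo2rest[i],
                    "vo2_ss_mlmin": vo2ss[i],
                    "delta_vo2_mlmin": delta[i],
                    "wmrt_min2_ml": wmrt[i],
                    "o2_deficit_ml": mrt[i] * delta[i],
                    "distance_m": distance[i],
                    "followup_months": time[i],
                    "event": int(event[i]),
                }
            )
            if generate_series:
                truth = KineticsGroundTruth(
                    vo2_rest=vo2rest[i],
                    vo2_ss=vo2ss[i],
                    tau=mrt[i],
                    noise_sd=noise_frac * delta[i],
                )
                series[sid] = simulate_breath_series(
                    truth, protocol,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject_id=sid,
                )
    cohort = pd.DataFrame(rows)
    info = {"n_resampled": n_resampled_total, "series": series}
    return cohort, info
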