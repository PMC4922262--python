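"""Protocol-specific metabolic estimators.

* MMR from swim trials: the uptake at the highest speed with at least one
  completed full cycle.
* MMR from chase / circular-chamber trials: the steepest 1-min sliding
  window immediately after (chase) or during (circle) the exercise bout.
* SMR: mean of the lowest 10% of post-recovery window values, or
  extrapolation of the speed-uptake power curve to zero speed.
* Ucrit: Brett's interpolation between the last completed and the failed
  speed increment, with a solid-blocking speed correction for the fraction
  of the tunnel cross-section the fish occupies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .mo2_engine import BackgroundModel, Mo2Entry, Mo2Series, steepest_window_mo2
from .trace_model import ChamberSpec, FishRecord, OxygenTrace, Protocol

__all__ = [
    "UcritInputs",
    "BlockingSpec",
    "MetricEstimate",
    "MetabolicSummary",
    "mmr_swim",
    "mmr_postexercise",
    "smr_lowest_fraction",
    "smr_extrapolate",
    "ucrit",
    "blocking_correction",
    "aerobic_scope",
    "shape_factor_from_geometry",
    "CHASE_SEARCH_SPAN_S",
    "CIRCLE_SEARCH_SPAN_MAX_S",
    "DEFAULT_RECOVERY_CUTOFF_S",
]

#: Post-exercise search spans (s): chase uses the first 5 min of measuring;
#: the circular chamber allows the first 5-7 min (configurable upper end).
CHASE_SEARCH_SPAN_S = (0.0, 300.0)
CIRCLE_SEARCH_SPAN_MAX_S = 420.0

#: Default start of the SMR-eligible recovery tail: 6 h after exercise (the
#: lower bound of the 6-12 h settling period).
DEFAULT_RECOVERY_CUTOFF_S = 6 * 3600.0

#: Minimum number of post-recovery windows for a lowest-fraction SMR: with
#: fewer than 10 windows the "lowest 10%" degenerates to a single-window
#: minimum dominated by noise.
MIN_SMR_WINDOWS = 10


@dataclass(frozen=True)
class UcritInputs:
    """Inputs to Brett's critical-swimming-speed interpolation.

    ``u_last``: speed of the last fully completed increment; ``u_i``:
    increment size (same units); ``t_s``: time swum into the failed
    increment; ``t_i_s``: time allotted per increment (default 24 min).
    """

    u_last: float
    u_i: float
    t_s: float
    t_i_s: float = 1440.0

    def __post_init__(self) -> None:
        if self.u_last < 0:
            raise ValueError("u_last must be >= 0")
        if self.u_i <= 0:
            raise ValueError("u_i must be > 0")
        if self.t_i_s <= 0:
            raise ValueError("t_i_s must be > 0")
        if self.t_s < 0:
            raise ValueError("t_s must be >= 0")
        if self.t_s > self.t_i_s:
            raise ValueError(
                "t_s exceeds t_i_s: the failed increment was completed; "
                "check increment labelling"
            )


@dataclass(frozen=True)
class BlockingSpec:
    """Solid-blocking correction geometry for a swim tunnel.

    The fractional speed error is eps = tau0 * lambda * (A_fish/A_tunnel)^1.5
    where tau0 is a dimensionless factor for the body cross-section shape
    (0.8 for streamlined fish) and lambda a fineness-type shape factor.
    """

    fish_area_m2: float
    tunnel_area_m2: float
    shape_factor_lambda: float
    dial_tau0: float = 0.8

    def __post_init__(self) -> None:
        if self.fish_area_m2 <= 0 or self.tunnel_area_m2 <= 0:
            raise ValueError("areas must be > 0")
        if self.fish_area_m2 >= self.tunnel_area_m2:
            raise ValueError("fish area must be smaller than tunnel area")
        if self.shape_factor_lambda <= 0 or self.dial_tau0 <= 0:
            raise ValueError("shape factors must be > 0")

    @property
    def epsilon(self) -> float:
        return self.dial_tau0 * self.shape_factor_lambda * \
            (self.fish_area_m2 / self.tunnel_area_m2) ** 1.5


def shape_factor_from_geometry(standard_length_m: float, fish_area_m2: float) -> float:
    """Fineness-type shape factor: length over equivalent circular diameter."""
    if standard_length_m <= 0 or fish_area_m2 <= 0:
        raise ValueError("length and area must be > 0")
    d_eq = 2.0 * math.sqrt(fish_area_m2 / math.pi)
    return standard_length_m / d_eq


@dataclass(frozen=True)
class MetricEstimate:
    """One estimated metric with provenance and diagnostics."""

    value: float
    kind: str                       # "mmr" | "smr" | "aerobic_scope" | ...
    source: str                     # e.g. "swim_top_speed", "rest_lowest10"
    window: Optional[Tuple[float, float]] = None
    diagnostics: Dict[str, float] = field(default_factory=dict)
    flags: Tuple[str, ...] = ()


@dataclass
class MetabolicSummary:
    """Per fish x method metabolic summary: the unit of statistical comparison."""

    fish_id: str
    species: str
    swim_mode: str
    method: Protocol
    mmr: Optional[float] = None
    smr: Optional[float] = None
    smr_source: str = ""
    aerobic_scope: Optional[float] = None
    ucrit_abs_cm_s: Optional[float] = None
    ucrit_rel_bl_s: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mmr is not None and self.smr is not None and self.aerobic_scope is not None:
            if self.aerobic_scope < 0 and "negative_scope" not in self.flags:
                self.flags.append("negative_scope")


# ---------------------------------------------------------------------------
# MMR


def _window_speed(speed_by_window: Dict[float, float], start: float) -> Optional[float]:
    if start in speed_by_window:
        return speed_by_window[start]
    for key, spd in speed_by_window.items():
        if abs(key - start) < 1e-6:
            return spd
    return None


def mmr_swim(
    series: Mo2Series,
    speed_by_window: Dict[float, float],
    completed_cycles: Dict[float, int],
    use_max: bool = True,
) -> MetricEstimate:
    """MMR from a swim trial: uptake at the top speed with >= 1 full cycle.

    Among speeds with at least one completed measure/flush cycle, the
    highest speed is selected and its MMR taken as the maximum (default) or
    mean window value over that speed's completed cycles. Windows beyond
    the completed cycles at that speed (a partial fatigue window) are
    excluded.
    """
    eligible = sorted(s for s, n in completed_cycles.items() if n >= 1)
    if not eligible:
        raise ValueError(
            "no swimming speed has a completed full cycle; the trial is too "
            "short to estimate MMR — review the protocol schedule"
        )
    top = eligible[-1]
    candidates = [
        e for e in series.entries
        if _window_speed(speed_by_window, e.window[0]) == top
    ]
    candidates = candidates[: completed_cycles[top]]
    if not candidates:
        raise ValueError(f"no measurement windows found at top speed {top}")
    values = [e.mo2 for e in candidates]
    value = max(values) if use_max else float(np.mean(values))
    best = candidates[int(np.argmax(values))] if use_max else candidates[0]
    flags = tuple(f for e in candidates for f in e.flags)
    return MetricEstimate(
        value=value, kind="mmr", source="swim_top_speed", window=best.window,
        diagnostics={"top_speed_bl_s": top, "n_windows": len(candidates),
                     "r2": best.r2},
        flags=flags,
    )


def mmr_postexercise(
    trace: OxygenTrace,
    protocol: Protocol,
    fish: FishRecord,
    chamber: ChamberSpec,
    background: Optional[BackgroundModel] = None,
    search_span: Optional[Tuple[float, float]] = None,
    window_len_s: float = 60.0,
    stride_s: float = 2.0,
) -> MetricEstimate:
    """MMR from a chase or circular-chamber trial: steepest 1-min window.

    The chase search span is the first 5 min of measuring; the circular
    chamber span defaults to the first 5 min and may be widened to 7 min.
    """
    if protocol == Protocol.CHASE:
        span = search_span or CHASE_SEARCH_SPAN_S
    elif protocol == Protocol.CIRCLE:
        span = search_span or (0.0, 300.0)
        if span[1] > CIRCLE_SEARCH_SPAN_MAX_S:
            raise ValueError("circle search span must end within the first 7 min")
    else:
        raise ValueError("post-exercise MMR applies to chase or circle protocols")
    entry, window = steepest_window_mo2(
        trace, span, fish, chamber, background,
        window_len_s=window_len_s, stride_s=stride_s,
    )
    return MetricEstimate(
        value=entry.mo2, kind="mmr", source=f"{protocol.value}_steepest_1min",
        window=window,
        diagnostics={"r2": entry.r2, "saturation_min": entry.saturation_min,
                     "span_end_s": span[1]},
        flags=entry.flags,
    )


# ---------------------------------------------------------------------------
# SMR


def smr_lowest_fraction(
    series: Mo2Series,
    recovery_cutoff_s: float = DEFAULT_RECOVERY_CUTOFF_S,
    fraction: float = 0.10,
) -> MetricEstimate:
    """SMR as the mean of the lowest ``fraction`` of post-recovery windows.

    Windows starting at or after ``recovery_cutoff_s`` are eligible;
    k = ceil(fraction * n) values (at least one) are averaged. Requires at
    least 10 eligible windows so the lowest decile is a real average rather
    than a single noisy minimum.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    eligible = [e for e in series.entries if e.window[0] >= recovery_cutoff_s]
    if len(eligible) < MIN_SMR_WINDOWS:
        raise ValueError(
            f"only {len(eligible)} windows start after the recovery cutoff "
            f"({recovery_cutoff_s:.0f} s); need >= {MIN_SMR_WINDOWS}. "
            "Record a longer post-recovery trace or lower the cutoff."
        )
    values = np.array([e.mo2 for e in eligible])
    k = max(1, math.ceil(fraction * len(values)))
    lowest = np.sort(values)[:k]
    flags = tuple(f for e in eligible for f in e.flags if f == "saturation_below_80pct")
    return MetricEstimate(
        value=float(lowest.mean()), kind="smr", source="lowest_fraction",
        diagnostics={"n_eligible": len(values), "k": k, "fraction": fraction,
                     "cutoff_s": recovery_cutoff_s},
        flags=flags,
    )


def _power_model(u, a, b, c):
    return a + b * np.power(u, c)


def smr_extrapolate(
    series: Mo2Series,
    speed_by_window: Dict[float, float],
) -> MetricEstimate:
    """SMR by extrapolating the speed-uptake power curve to zero speed.

    Fits MO2(U) = a + b * U^c (c >= 1) by nonlinear least squares over all
    windows with a known speed; the intercept a estimates SMR. Requires at
    least three distinct speeds.
    """
    pairs = [
        (spd, e.mo2)
        for e in series.entries
        if (spd := _window_speed(speed_by_window, e.window[0])) is not None
    ]
    if len({round(p[0], 9) for p in pairs}) < 3:
        raise ValueError("speed-uptake extrapolation needs >= 3 distinct speeds")
    u = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    a0 = max(float(y.min()) * 0.8, 1e-6)
    b0 = max((float(y.max()) - a0) / max(float(u.max()) ** 2, 1e-9), 1e-9)
    try:
        popt, pcov = curve_fit(
            _power_model, u, y, p0=[a0, b0, 2.0],
            bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"speed-uptake power fit did not converge: {exc}") from exc
    resid = y - _power_model(u, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    a_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return MetricEstimate(
        value=float(popt[0]), kind="smr", source="extrapolated",
        diagnostics={"b": float(popt[1]), "c": float(popt[2]), "r2": r2,
                     "a_se": a_se, "n_points": len(u)},
    )


# ---------------------------------------------------------------------------
# Ucrit, blocking, scope


def ucrit(inputs: UcritInputs) -> float:
    """Brett's critical swimming speed: U_last + U_i * (t / t_i)."""
    return inputs.u_last + inputs.u_i * (inputs.t_s / inputs.t_i_s)


def blocking_correction(speed: float, spec: BlockingSpec) -> Tuple[float, float, bool]:
    """Correct a tunnel speed for solid blocking by the fish's body.

    Returns (corrected speed, epsilon, warn) where warn is True when the
    correction exceeds the 5% ceiling expected of a well-matched
    fish/tunnel pairing (boundary inclusive: exactly 5% does not warn).
    """
    eps = spec.epsilon
    return speed * (1.0 + eps), eps, eps > 0.05


def aerobic_scope(mmr_value: float, smr_value: float) -> Tuple[float, Tuple[str, ...]]:
    """Absolute aerobic scope MMR - SMR; negative results are flagged."""
    scope = mmr_value - smr_value
    flags = ("negative_scope",) if scope < 0 else ()
    return scope, flags
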