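"""Per-window oxygen-uptake estimation from labelled traces.

The chain is: segment the trace into sealed measurement windows, fit an
ordinary-least-squares line to the O2 decline in each window, convert the
slope to a whole-animal uptake via the effective chamber volume, subtract
linearly interpolated background (microbial) respiration, and normalise by
body mass:

    MO2 = S * V_resp / M        (x 3600 for per-hour units)

where S is the O2 decline slope (mg O2 L^-1 s^-1, positive when O2 falls),
V_resp the respirometer volume minus the fish volume (L) and M the fish
mass (kg). MO2 is reported in mg O2 kg^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .trace_model import ChamberSpec, CycleSchedule, FishRecord, OxygenTrace, Phase, Protocol

__all__ = [
    "SlopeEstimate",
    "BackgroundModel",
    "Mo2Entry",
    "Mo2Series",
    "segment_windows",
    "fit_slope",
    "compute_mo2",
    "steepest_window_mo2",
    "process_trace",
]

#: Minimum duration (s) for a partial trailing measurement window to be kept.
MIN_PARTIAL_WINDOW_S = 60.0

#: Air-saturation fraction below which a window is flagged as hypoxic risk.
SATURATION_FLOOR = 0.80


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS fit of O2 decline over one measurement window.

    ``S`` is the magnitude of the decline (positive when O2 falls).
    """

    window: Tuple[float, float]
    S: float                 # mg O2 / L / s
    intercept: float         # mg O2 / L at t = 0
    r2: float
    n_points: int


@dataclass(frozen=True)
class BackgroundModel:
    """Background (empty-chamber) O2 uptake, linear in time.

    Measured before and after the trial; interpolated linearly to each
    window's midpoint. Rates are whole-chamber, mg O2 per hour.
    """

    rate_pre_mg_h: float = 0.0
    rate_post_mg_h: float = 0.0
    t_pre_s: float = 0.0
    t_post_s: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_pre_mg_h < 0 or self.rate_post_mg_h < 0:
            raise ValueError("background rates must be >= 0")
        if self.t_post_s <= self.t_pre_s:
            raise ValueError("t_post_s must exceed t_pre_s")

    def rate_at(self, t_s: float) -> float:
        """Linearly interpolated whole-chamber rate (mg/h), floored at 0."""
        frac = (t_s - self.t_pre_s) / (self.t_post_s - self.t_pre_s)
        rate = self.rate_pre_mg_h + frac * (self.rate_post_mg_h - self.rate_pre_mg_h)
        return max(rate, 0.0)


@dataclass(frozen=True)
class Mo2Entry:
    """One window's mass-specific oxygen uptake with diagnostics."""

    window: Tuple[float, float]
    mo2: float                    # mg O2 / kg / h
    r2: float
    background_fraction: float    # background / gross uptake
    saturation_min: float         # min O2 in window as fraction of sat_conc
    flags: Tuple[str, ...] = ()


@dataclass
class Mo2Series:
    """Time-ordered per-window MO2 estimates for one fish and protocol."""

    fish_id: str
    protocol: Protocol
    entries: List[Mo2Entry]
    v_resp_l: float

    def __post_init__(self) -> None:
        if self.v_resp_l <= 0:
            raise ValueError("v_resp_l must be > 0")
        starts = [e.window[0] for e in self.entries]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("entries must be time-ordered")

    @property
    def values(self) -> np.ndarray:
        return np.array([e.mo2 for e in self.entries], dtype=float)

    @property
    def window_starts(self) -> np.ndarray:
        return np.array([e.window[0] for e in self.entries], dtype=float)


def segment_windows(
    trace: OxygenTrace,
    schedule: Optional[CycleSchedule] = None,
    trim_lead_s: float = 0.0,
) -> List[Tuple[float, float]]:
    """Locate sealed measurement windows in a trace.

    Uses per-sample phase labels when present, otherwise derives them from
    ``schedule``. ``trim_lead_s`` discards that many seconds at each window
    start (mixing stabilisation). Partial trailing windows are kept only if
    at least 60 s long. Returns half-open ``(start, end)`` pairs.
    """
    if trim_lead_s < 0:
        raise ValueError("trim_lead_s must be >= 0")
    phases = trace.phase
    if phases is None:
        if schedule is None:
            raise ValueError("trace has no phase labels and no schedule was given")
        phases = schedule.phase_at(trace.time_s)
    t = trace.time_s
    is_measure = np.asarray([p == Phase.MEASURE.value for p in phases], dtype=bool)
    if not is_measure.any():
        trace.warnings.append("no measurement phase found")
        return []
    # contiguous runs of measurement samples
    edges = np.diff(is_measure.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if is_measure[0]:
        starts.insert(0, 0)
    if is_measure[-1]:
        ends.append(len(t))
    dt = float(np.median(np.diff(t))) if t.size > 1 else 2.0
    full_len = None
    if schedule is not None:
        full_len = schedule.measure_s
    windows: List[Tuple[float, float]] = []
    for i0, i1 in zip(starts, ends):
        start = t[i0] + trim_lead_s
        end = t[i1 - 1] + dt  # half-open: one sample interval past the last
        if end - start <= 0:
            continue
        duration = end - start
        is_partial = full_len is not None and duration < (full_len - trim_lead_s) - dt
        if is_partial and duration < MIN_PARTIAL_WINDOW_S:
            continue
        if full_len is None and duration < MIN_PARTIAL_WINDOW_S:
            continue
        windows.append((float(start), float(end)))
    return windows


def fit_slope(trace: OxygenTrace, window: Tuple[float, float]) -> SlopeEstimate:
    """OLS regression of O2 concentration on time within a window.

    ``S`` is the negated raw slope, so that a declining trace yields a
    positive S. Requires at least 3 samples and non-degenerate times.
    """
    sl = trace.window_slice(*window)
    t = trace.time_s[sl]
    y = trace.o2_mg_l[sl]
    if t.size < 3:
        raise ValueError(f"window {window} has {t.size} samples; need >= 3")
    tc = t - t.mean()
    sxx = float(np.dot(tc, tc))
    if sxx == 0.0:
        raise ValueError(f"window {window} has zero time variance")
    slope = float(np.dot(tc, y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    return SlopeEstimate(window=window, S=-slope, intercept=intercept, r2=r2, n_points=int(t.size))


def compute_mo2(
    slope: SlopeEstimate,
    fish: FishRecord,
    chamber: ChamberSpec,
    background: Optional[BackgroundModel] = None,
    saturation_min: float = 1.0,
) -> Mo2Entry:
    """Convert a window slope into background-corrected, mass-specific MO2.

    Gross whole-animal uptake is ``S * V_resp`` (mg/s); the background rate
    interpolated to the window midpoint is subtracted; the result is scaled
    to mg O2 kg^-1 h^-1. A negative corrected uptake is clamped to zero and
    flagged (it indicates background noise exceeding the signal, not a
    physiological oxygen release).
    """
    v_resp = chamber.v_resp_l(fish)
    gross_mg_s = slope.S * v_resp
    flags: List[str] = []
    bg_mg_s = 0.0
    if background is not None:
        midpoint = 0.5 * (slope.window[0] + slope.window[1])
        bg_mg_s = background.rate_at(midpoint) / 3600.0
    net_mg_s = gross_mg_s - bg_mg_s
    if net_mg_s < 0:
        net_mg_s = 0.0
        flags.append("negative_uptake_clamped")
    if gross_mg_s > 0:
        background_fraction = bg_mg_s / gross_mg_s
    else:
        background_fraction = 0.0 if bg_mg_s == 0 else float("inf")
    if saturation_min < SATURATION_FLOOR:
        flags.append("saturation_below_80pct")
    mo2 = net_mg_s * 3600.0 / fish.mass_kg
    return Mo2Entry(
        window=slope.window,
        mo2=mo2,
        r2=slope.r2,
        background_fraction=background_fraction,
        saturation_min=saturation_min,
        flags=tuple(flags),
    )


def _window_saturation_min(trace: OxygenTrace, window: Tuple[float, float]) -> float:
    sl = trace.window_slice(*window)
    if sl.stop <= sl.start:
        return 1.0
    return float(trace.o2_mg_l[sl].min() / trace.sat_conc_mg_l)


def steepest_window_mo2(
    trace: OxygenTrace,
    search_span: Tuple[float, float],
    fish: FishRecord,
    chamber: ChamberSpec,
    background: Optional[BackgroundModel] = None,
    window_len_s: float = 60.0,
    stride_s: float = 2.0,
) -> Tuple[Mo2Entry, Tuple[float, float]]:
    """Maximum-uptake sliding-window estimate (post-exercise MMR).

    Slides a ``window_len_s`` window at ``stride_s`` steps across the search
    span, fits each by OLS and returns the window with the steepest decline
    (largest S), ties broken by earliest start. The default stride equals
    the 2-s sampling interval, i.e. exhaustive at sample resolution.
    """
    span_start, span_end = search_span
    if span_end - span_start < window_len_s:
        raise ValueError(
            f"search span {search_span} shorter than window length {window_len_s}"
        )
    best: Optional[SlopeEstimate] = None
    start = span_start
    # include the final flush-right window even if the stride overshoots
    starts = list(np.arange(span_start, span_end - window_len_s + 1e-9, stride_s))
    last = span_end - window_len_s
    if not starts or last - starts[-1] > 1e-9:
        starts.append(last)
    for start in starts:
        window = (float(start), float(start + window_len_s))
        sl = trace.window_slice(*window)
        if sl.stop - sl.start < 3:
            continue
        est = fit_slope(trace, window)
        if best is None or est.S > best.S + 1e-15:
            best = est
    if best is None:
        raise ValueError(f"no fittable window inside span {search_span}")
    entry = compute_mo2(
        best, fish, chamber, background, saturation_min=_window_saturation_min(trace, best.window)
    )
    return entry, best.window


def process_trace(
    trace: OxygenTrace,
    fish: FishRecord,
    chamber: ChamberSpec,
    background: Optional[BackgroundModel] = None,
    schedule: Optional[CycleSchedule] = None,
    trim_lead_s: float = 0.0,
) -> Mo2Series:
    """Full trace -> per-window MO2 series (segment, fit, convert, audit)."""
    windows = segment_windows(trace, schedule=schedule, trim_lead_s=trim_lead_s)
    entries: List[Mo2Entry] = []
    for window in windows:
        sl = trace.window_slice(*window)
        if sl.stop - sl.start < 3:
            continue
        est = fit_slope(trace, window)
        entries.append(
            compute_mo2(
                est, fish, chamber, background,
                saturation_min=_window_saturation_min(trace, window),
            )
        )
    return Mo2Series(
        fish_id=trace.fish_id,
        protocol=trace.protocol,
        entries=entries,
        v_resp_l=chamber.v_resp_l(fish),
    )
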