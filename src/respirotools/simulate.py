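"""Synthetic oxygen-trace generator with known ground-truth physiology.

Every downstream stage (window segmentation, slope fitting, MMR/SMR/Ucrit
estimators, the statistical method comparison) is testable against traces
generated here, because each simulated fish carries its true standard and
maximal metabolic rates, critical swimming speed, and the expected
per-window mean oxygen uptake.

Generative model
----------------
Within a sealed measurement window the chamber O2 concentration declines as

    dC/dt = -(m(t) * M + B(t)) / (3600 * V_resp)

with m the mass-specific uptake (mg O2 kg^-1 h^-1), M the fish mass (kg),
B a linear-in-time whole-chamber background rate (mg O2 h^-1) and V_resp
the effective volume (L). The decline is integrated analytically per
segment, so noise-free traces satisfy mass balance to machine precision.

Protocol-specific uptake:

* swim: m(U) = SMR + (MMR - SMR) * ((U - U0)/(Ucrit - U0))^c for speeds U
  above the habituation speed U0, clamped at MMR; the trial terminates
  partway through the speed increment containing the true Ucrit.
* chase: m(t) = SMR + A * exp(-t / tau) from the end of exercise, where
  A = attenuation * (MMR - SMR) is the peak excess post-exercise uptake.
* circle: m ramps over ~60 s to SMR + attenuation * (MMR - SMR), holds for
  the exercise period (measured continuously, no flush), then decays as in
  the chase protocol.

Short protocols express only a fraction (the ``method_attenuation``) of the
fish's true metabolic span — the mechanism by which chase and circular
chamber protocols can understate MMR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import MetabolicSummary
from .trace_model import (
    ChamberSpec,
    CycleSchedule,
    FishRecord,
    OxygenTrace,
    Phase,
    Protocol,
    SwimSchedule,
    DEFAULT_SAT_CONC_MG_L,
    NOMINAL_DT_S,
)

__all__ = [
    "FishPhysiology",
    "SensorModel",
    "SimTruth",
    "SpeciesDesign",
    "STUDY_DESIGN",
    "simulate_swim_trial",
    "simulate_chase_trial",
    "simulate_circle_trial",
    "simulate_cohort",
    "simulate_method_effect_cohort",
]

#: Default method attenuation: fraction of the metabolic span (MMR - SMR)
#: expressed as peak excess uptake under each protocol. The swim protocol
#: drives the fish to its true maximum; the short protocols express less.
#: Chase/circle defaults are calibrated so that cohort-level model-predicted
#: MMR differences land near 20% (swim vs chase) and 25% (swim vs circle)
#: for the default species designs, accounting for the 1-min window mean of
#: the post-exercise exponential (see docs/methods.md for the derivation).
DEFAULT_ATTENUATION = {"swim": 1.0, "chase": 0.85, "circle": 0.77}


@dataclass(frozen=True)
class FishPhysiology:
    """Ground-truth metabolic parameters of one simulated fish.

    Rates in mg O2 kg^-1 h^-1; speeds in body lengths per second; the EPOC
    decay constant ``epoc_tau_s`` in seconds. ``activity_sigma`` is the
    half-normal scale (as a fraction of SMR) of the spontaneous per-cycle
    activity added on top of the deterministic uptake.
    """

    smr_true: float
    mmr_true: float
    ucrit_true_bl_s: float
    speed_exponent_c: float = 2.0
    epoc_tau_s: float = 900.0
    method_attenuation: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    activity_sigma: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.smr_true < self.mmr_true):
            raise ValueError("require 0 < smr_true < mmr_true")
        if self.speed_exponent_c < 1:
            raise ValueError("speed_exponent_c must be >= 1")
        for k, a in self.method_attenuation.items():
            if not (0 < a <= 1):
                raise ValueError(f"attenuation for {k!r} must be in (0, 1]")
        if self.activity_sigma < 0:
            raise ValueError("activity_sigma must be >= 0")

    @property
    def span(self) -> float:
        """Metabolic span MMR - SMR (the absolute aerobic scope)."""
        return self.mmr_true - self.smr_true


@dataclass(frozen=True)
class SensorModel:
    """Optode noise, background respiration and flush kinetics.

    ``noise_sd`` is i.i.d. Gaussian per 2-s sample (mg O2/L). Background is
    whole-chamber microbial uptake, linear in time:
    B(t) = background_rate_0 + background_slope * t/3600 (mg O2/h).
    """

    noise_sd: float = 0.002
    background_rate_0: float = 0.0
    background_slope: float = 0.0  # mg O2 h^-1 per hour of trial
    flush_mode: str = "instant"    # "instant" or "exponential"
    flush_rate_per_s: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_rate_0 < 0:
            raise ValueError("background_rate_0 must be >= 0")
        if self.flush_mode not in ("instant", "exponential"):
            raise ValueError("flush_mode must be 'instant' or 'exponential'")

    def background_at(self, t_s: float) -> float:
        return max(self.background_rate_0 + self.background_slope * t_s / 3600.0, 0.0)


@dataclass
class SimTruth:
    """Everything the simulator knows that an experimenter would not."""

    fish_id: str
    protocol: Protocol
    smr_true: float
    mmr_true: float
    attenuation: float
    peak_excess_target: float           # attenuation * (MMR - SMR)
    windows: List[dict]                 # start, end, mean_m, constant, speed
    speed_by_window: Dict[float, float] = field(default_factory=dict)
    completed_cycles: Dict[float, int] = field(default_factory=dict)
    ucrit_true_bl_s: Optional[float] = None
    fatigue_time_s: Optional[float] = None
    last_completed_speed_bl_s: Optional[float] = None
    failed_speed_bl_s: Optional[float] = None
    summary: Optional[MetabolicSummary] = None

    def window_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows)


# ---------------------------------------------------------------------------
# trace assembly


class _TraceBuilder:
    """Accumulates analytic segments into a sampled trace on the 2-s grid."""

    def __init__(self, sat: float, mass_kg: float, v_resp_l: float,
                 sensor: SensorModel, dt: float = NOMINAL_DT_S):
        self.sat = sat
        self.mass = mass_kg
        self.v = v_resp_l
        self.sensor = sensor
        self.dt = dt
        self.t0 = 0.0           # current segment start
        self.c0 = sat           # clean O2 at segment start
        self.times: List[np.ndarray] = []
        self.o2: List[np.ndarray] = []
        self.phases: List[np.ndarray] = []
        self.windows: List[dict] = []

    def _grid(self, t0: float, t1: float) -> np.ndarray:
        k0 = math.ceil(t0 / self.dt - 1e-9)
        k1 = math.ceil(t1 / self.dt - 1e-9)
        return np.arange(k0, k1) * self.dt

    def _background_integral(self, t0: float, t: np.ndarray) -> np.ndarray:
        """Integral of B (mg/h) over [t0, t], in mg*s/h."""
        b0 = self.sensor.background_rate_0
        b1 = self.sensor.background_slope
        return b0 * (t - t0) + b1 * (t * t - t0 * t0) / 7200.0

    def add_measure(self, duration: float, m_integral, mean_m: float,
                    constant: bool, label: Phase = Phase.MEASURE,
                    speed: Optional[float] = None) -> None:
        """Sealed segment: O2 declines per the analytic uptake integral.

        ``m_integral(tau)`` must return the integral of m over the first
        ``tau`` seconds of the segment (units mg O2 kg^-1 h^-1 * s).
        """
        t1 = self.t0 + duration
        t = self._grid(self.t0, t1)
        tau = t - self.t0
        removed = self.mass * m_integral(tau) + self._background_integral(self.t0, t)
        c = self.c0 - removed / (3600.0 * self.v)
        self.times.append(t)
        self.o2.append(c)
        self.phases.append(np.full(t.size, label.value, dtype=object))
        end_removed = self.mass * m_integral(np.array([duration]))[0] + \
            self._background_integral(self.t0, np.array([t1]))[0]
        c_end = self.c0 - end_removed / (3600.0 * self.v)
        self.windows.append(dict(
            start=self.t0, end=t1, mean_m=mean_m, constant=constant,
            speed=speed, o2_min_clean=float(c_end), phase=label.value,
        ))
        self.t0, self.c0 = t1, float(c_end)

    def add_flush(self, duration: float, label: Phase = Phase.FLUSH) -> None:
        t1 = self.t0 + duration
        t = self._grid(self.t0, t1)
        if self.sensor.flush_mode == "instant":
            c = np.full(t.size, self.sat)
            c_end = self.sat
        else:
            k = self.sensor.flush_rate_per_s
            c = self.sat - (self.sat - self.c0) * np.exp(-k * (t - self.t0))
            c_end = float(self.sat - (self.sat - self.c0) * math.exp(-k * duration))
        self.times.append(t)
        self.o2.append(c)
        self.phases.append(np.full(t.size, label.value, dtype=object))
        self.t0, self.c0 = t1, c_end

    def build(self, fish_id: str, protocol: Protocol,
              rng: np.random.Generator) -> OxygenTrace:
        t = np.concatenate(self.times)
        c = np.concatenate(self.o2)
        phase = np.concatenate(self.phases)
        if self.sensor.noise_sd > 0:
            c = c + rng.normal(0.0, self.sensor.noise_sd, size=c.size)
        trace = OxygenTrace(
            fish_id=fish_id, protocol=protocol, time_s=t, o2_mg_l=c,
            phase=phase, sat_conc_mg_l=self.sat,
        )
        low = [w for w in self.windows
               if w["phase"] == Phase.MEASURE.value
               and w["o2_min_clean"] < 0.80 * self.sat]
        if low:
            trace.warnings.append(
                f"{len(low)} measurement window(s) fell below 80% air saturation"
            )
        return trace


def _const_integral(m: float):
    return lambda tau: m * tau


def _exp_integral(base: float, amp: float, tau_decay: float, t_offset: float):
    """Integral of base + amp*exp(-(t_offset + tau)/tau_decay) over [0, tau]."""
    if not math.isfinite(tau_decay):
        return _const_integral(base + amp)
    e0 = math.exp(-t_offset / tau_decay)
    return lambda tau: base * tau + amp * tau_decay * (e0 - np.exp(-(t_offset + tau) / tau_decay))


def _linear_integral(m0: float, m1: float, duration: float):
    return lambda tau: m0 * tau + (m1 - m0) * tau ** 2 / (2.0 * duration)


def _exp_mean(base: float, amp: float, tau_decay: float, t_offset: float,
              duration: float) -> float:
    if not math.isfinite(tau_decay):
        return base + amp
    return base + amp * tau_decay / duration * (
        math.exp(-t_offset / tau_decay) - math.exp(-(t_offset + duration) / tau_decay)
    )


def _activity(phys: FishPhysiology, rng: np.random.Generator) -> float:
    """Spontaneous per-cycle activity increment (half-normal, >= 0)."""
    if phys.activity_sigma == 0:
        return 0.0
    return abs(rng.normal(0.0, phys.activity_sigma)) * phys.smr_true


# ---------------------------------------------------------------------------
# protocol simulators


def _speed_uptake(phys: FishPhysiology, speed: float, u0: float) -> float:
    """Deterministic uptake at swimming speed ``speed`` (BL/s)."""
    norm = (speed - u0) / (phys.ucrit_true_bl_s - u0)
    norm = min(max(norm, 0.0), 1.0)
    return phys.smr_true + phys.span * norm ** phys.speed_exponent_c


def simulate_swim_trial(
    fish: FishRecord,
    phys: FishPhysiology,
    chamber: ChamberSpec,
    schedule: Optional[SwimSchedule] = None,
    cycles: Optional[CycleSchedule] = None,
    sensor: Optional[SensorModel] = None,
    seed: int = 0,
    sat_conc_mg_l: float = DEFAULT_SAT_CONC_MG_L,
) -> Tuple[OxygenTrace, SimTruth]:
    """Incremental-speed swim-tunnel trial terminating at the true Ucrit.

    Habituation cycles at the habituation speed, a flushed ramp, then
    0.5 BL/s speed steps of three measure/flush cycles each. The fish
    fatigues ``t = (Ucrit - U_last) / U_i * t_i`` seconds into the increment
    containing its true Ucrit, so Brett's interpolation applied to the
    recorded fatigue time recovers Ucrit exactly.
    """
    schedule = schedule or SwimSchedule()
    cycles = cycles or CycleSchedule()
    sensor = sensor or SensorModel()
    schedule.validate_against(cycles)
    if chamber.protocol != Protocol.SWIM:
        raise ValueError("simulate_swim_trial requires a swim chamber")
    if phys.ucrit_true_bl_s <= schedule.start_speed_bl_s:
        raise ValueError("ucrit_true must exceed the protocol start speed")

    rng = np.random.default_rng(seed)
    builder = _TraceBuilder(sat_conc_mg_l, fish.mass_kg, chamber.v_resp_l(fish), sensor)
    u0 = schedule.habituation_speed_bl_s

    n_hab = max(int(round(schedule.habituation_s / cycles.cycle_s)), 1)
    for _ in range(n_hab):
        m = phys.smr_true + _activity(phys, rng)
        builder.add_measure(cycles.measure_s, _const_integral(m), m, True,
                            label=Phase.HABITUATION, speed=u0)
        builder.add_flush(cycles.flush_s, label=Phase.HABITUATION)
    builder.add_flush(schedule.ramp_s, label=Phase.RAMP)  # flushed while ramping

    # every grid speed strictly below the true Ucrit is fully completed
    # (Brett: Ucrit = U_last + U_i * t/t_i with 0 < t <= t_i); the fish
    # fatigues partway through the next increment
    u_i = schedule.increment_bl_s
    completed = []
    s = schedule.start_speed_bl_s
    while s < phys.ucrit_true_bl_s - 1e-12:
        completed.append(round(s, 9))
        s += u_i
    if not completed:
        raise ValueError("ucrit_true must exceed the protocol start speed")
    last_completed = completed[-1]
    failed_speed = round(last_completed + u_i, 9)
    fatigue_t = (phys.ucrit_true_bl_s - last_completed) / u_i * schedule.time_per_speed_s

    speed_by_window: Dict[float, float] = {}
    completed_cycles: Dict[float, int] = {}
    for spd in completed:
        m_base = _speed_uptake(phys, spd, u0)
        for _ in range(schedule.cycles_per_speed):
            m = m_base + _activity(phys, rng)
            start = builder.t0
            builder.add_measure(cycles.measure_s, _const_integral(m), m, True, speed=spd)
            speed_by_window[start] = spd
            builder.add_flush(cycles.flush_s)
        completed_cycles[spd] = schedule.cycles_per_speed

    # fatigue increment at the failed speed (uptake clamped at MMR)
    m_base = _speed_uptake(phys, failed_speed, u0)
    n_full = int(fatigue_t // cycles.cycle_s)
    n_full = min(n_full, schedule.cycles_per_speed)
    for _ in range(n_full):
        m = m_base + _activity(phys, rng)
        start = builder.t0
        builder.add_measure(cycles.measure_s, _const_integral(m), m, True, speed=failed_speed)
        speed_by_window[start] = failed_speed
        builder.add_flush(cycles.flush_s)
    completed_cycles[failed_speed] = n_full
    rem = fatigue_t - n_full * cycles.cycle_s
    dt = NOMINAL_DT_S
    if rem >= dt and n_full < schedule.cycles_per_speed:
        meas = math.floor(min(rem, cycles.measure_s) / dt) * dt
        if meas >= dt:
            m = m_base + _activity(phys, rng)
            start = builder.t0
            builder.add_measure(meas, _const_integral(m), m, True, speed=failed_speed)
            speed_by_window[start] = failed_speed

    trace = builder.build(fish.fish_id, Protocol.SWIM, rng)
    att = phys.method_attenuation.get("swim", 1.0)
    ucrit_abs_cm_s = phys.ucrit_true_bl_s * fish.standard_length_m * 100.0
    summary = MetabolicSummary(
        fish_id=fish.fish_id, species=fish.species, swim_mode=fish.swim_mode,
        method=Protocol.SWIM, mmr=phys.mmr_true, smr=phys.smr_true,
        smr_source="true", aerobic_scope=phys.span,
        ucrit_abs_cm_s=ucrit_abs_cm_s, ucrit_rel_bl_s=phys.ucrit_true_bl_s,
    )
    truth = SimTruth(
        fish_id=fish.fish_id, protocol=Protocol.SWIM,
        smr_true=phys.smr_true, mmr_true=phys.mmr_true,
        attenuation=att, peak_excess_target=att * phys.span,
        windows=builder.windows, speed_by_window=speed_by_window,
        completed_cycles=completed_cycles,
        ucrit_true_bl_s=phys.ucrit_true_bl_s, fatigue_time_s=fatigue_t,
        last_completed_speed_bl_s=last_completed, failed_speed_bl_s=failed_speed,
        summary=summary,
    )
    return trace, truth


def _recovery_cycles(builder: _TraceBuilder, phys: FishPhysiology,
                     cycles: CycleSchedule, duration_s: float,
                     amp: float, tau: float, t_exercise_end: float,
                     rng: np.random.Generator) -> None:
    """Repeated measure/flush cycles riding the EPOC decay down to SMR."""
    while builder.t0 + cycles.cycle_s <= duration_s + 1e-9:
        offset = builder.t0 - t_exercise_end
        act = _activity(phys, rng)
        integral = _exp_integral(phys.smr_true + act, amp, tau, offset)
        mean_m = _exp_mean(phys.smr_true + act, amp, tau, offset, cycles.measure_s)
        constant = not math.isfinite(tau) or amp == 0
        builder.add_measure(cycles.measure_s, integral, mean_m, constant)
        builder.add_flush(cycles.flush_s)


def simulate_chase_trial(
    fish: FishRecord,
    phys: FishPhysiology,
    chamber: ChamberSpec,
    cycles: Optional[CycleSchedule] = None,
    sensor: Optional[SensorModel] = None,
    delay_s: float = 10.0,
    seed: int = 0,
    duration_s: float = 28800.0,
    sat_conc_mg_l: float = DEFAULT_SAT_CONC_MG_L,
) -> Tuple[OxygenTrace, SimTruth]:
    """Exhaustive chase + air exposure, then resting-chamber recovery.

    Trace time 0 is the start of measurement, ``delay_s`` seconds (handling
    time, at most 10 s) after the end of exercise. Uptake decays from
    SMR + attenuation*(MMR - SMR) toward SMR with time constant
    ``phys.epoc_tau_s``; the trace runs long enough (default 8 h) that the
    post-recovery tail supports the lowest-10% SMR estimate.
    """
    cycles = cycles or CycleSchedule()
    sensor = sensor or SensorModel()
    if chamber.protocol not in (Protocol.REST, Protocol.CHASE):
        raise ValueError("simulate_chase_trial requires a resting chamber")
    if not (0.0 <= delay_s <= 10.0):
        raise ValueError("delay_s must be within [0, 10] s")

    rng = np.random.default_rng(seed)
    builder = _TraceBuilder(sat_conc_mg_l, fish.mass_kg, chamber.v_resp_l(fish), sensor)
    att = phys.method_attenuation.get("chase", 1.0)
    amp = att * phys.span
    tau = phys.epoc_tau_s
    _recovery_cycles(builder, phys, cycles, duration_s, amp, tau, -delay_s, rng)
    trace = builder.build(fish.fish_id, Protocol.CHASE, rng)
    summary = MetabolicSummary(
        fish_id=fish.fish_id, species=fish.species, swim_mode=fish.swim_mode,
        method=Protocol.CHASE, mmr=phys.smr_true + amp, smr=phys.smr_true,
        smr_source="true", aerobic_scope=amp,
    )
    truth = SimTruth(
        fish_id=fish.fish_id, protocol=Protocol.CHASE,
        smr_true=phys.smr_true, mmr_true=phys.mmr_true,
        attenuation=att, peak_excess_target=amp,
        windows=builder.windows, summary=summary,
    )
    return trace, truth


def simulate_circle_trial(
    fish: FishRecord,
    phys: FishPhysiology,
    chamber: ChamberSpec,
    cycles: Optional[CycleSchedule] = None,
    sensor: Optional[SensorModel] = None,
    exercise_s: float = 360.0,
    seed: int = 0,
    ramp_s: float = 60.0,
    duration_s: float = 28800.0,
    sat_conc_mg_l: float = DEFAULT_SAT_CONC_MG_L,
) -> Tuple[OxygenTrace, SimTruth]:
    """Circular-chamber trial: ramped vortex exercise, then resting cycles.

    During exercise the chamber is sealed and measured continuously (no
    flush is possible until the fish fatigues — the protocol's structural
    weakness); uptake ramps linearly over ``ramp_s`` to the plateau
    SMR + attenuation*(MMR - SMR) and holds. Afterwards: flush, then
    measure/flush cycles riding the EPOC decay down to SMR.
    """
    cycles = cycles or CycleSchedule()
    sensor = sensor or SensorModel()
    if chamber.protocol != Protocol.CIRCLE:
        raise ValueError("simulate_circle_trial requires a circular chamber")
    if not (300.0 <= exercise_s <= 420.0):
        raise ValueError("exercise_s must be within [300, 420] s")
    if ramp_s >= exercise_s:
        raise ValueError("ramp_s must be shorter than exercise_s")

    rng = np.random.default_rng(seed)
    builder = _TraceBuilder(sat_conc_mg_l, fish.mass_kg, chamber.v_resp_l(fish), sensor)
    att = phys.method_attenuation.get("circle", 1.0)
    plateau = phys.smr_true + att * phys.span

    builder.add_measure(ramp_s, _linear_integral(phys.smr_true, plateau, ramp_s),
                        0.5 * (phys.smr_true + plateau), False)
    builder.add_measure(exercise_s - ramp_s, _const_integral(plateau), plateau, True)
    builder.add_flush(cycles.flush_s)
    _recovery_cycles(builder, phys, cycles, duration_s, plateau - phys.smr_true,
                     phys.epoc_tau_s, exercise_s, rng)
    trace = builder.build(fish.fish_id, Protocol.CIRCLE, rng)
    summary = MetabolicSummary(
        fish_id=fish.fish_id, species=fish.species, swim_mode=fish.swim_mode,
        method=Protocol.CIRCLE, mmr=plateau, smr=phys.smr_true,
        smr_source="true", aerobic_scope=plateau - phys.smr_true,
    )
    truth = SimTruth(
        fish_id=fish.fish_id, protocol=Protocol.CIRCLE,
        smr_true=phys.smr_true, mmr_true=phys.mmr_true,
        attenuation=att, peak_excess_target=att * phys.span,
        windows=builder.windows, summary=summary,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class SpeciesDesign:
    """Between-fish parameter distributions for one species.

    Means and coefficients of variation parameterise log-normal draws
    (positivity guaranteed). Defaults mirror a four-species reef-fish
    repeated-measures design with two body-caudal-fin (BCF) and two
    median-paired-fin (MPF) swimmers.
    """

    species: str
    swim_mode: str
    n: int
    mass_mean_kg: float
    mass_cv: float
    length_mean_m: float
    length_cv: float
    smr_mean: float
    smr_cv: float
    mmr_mean: float
    mmr_cv: float
    ucrit_rel_mean_bl_s: float
    ucrit_cv: float


#: Four-species design matching the study system: species means from the
#: published group means (Table values), between-fish CVs from SEM * sqrt(n).
STUDY_DESIGN: Tuple[SpeciesDesign, ...] = (
    SpeciesDesign("Pterocaesio marri", "BCF", 5, 0.00989, 0.188, 0.0852, 0.134,
                  223.3, 0.40, 1794.3, 0.42, 10.10, 0.23),
    SpeciesDesign("Caesio teres", "BCF", 11, 0.01507, 0.296, 0.0822, 0.082,
                  167.7, 0.62, 1299.4, 0.15, 10.13, 0.098),
    SpeciesDesign("Acanthochromis polyacanthus", "MPF", 11, 0.01688, 0.200, 0.0742, 0.065,
                  143.0, 0.61, 1150.7, 0.32, 8.43, 0.075),
    SpeciesDesign("Chromis atripectoralis", "MPF", 10, 0.00810, 0.186, 0.0625, 0.035,
                  221.0, 0.51, 1768.0, 0.20, 12.10, 0.13),
)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw_fish(design: SpeciesDesign, idx: int, rng: np.random.Generator,
               min_ucrit: float) -> Tuple[FishRecord, FishPhysiology]:
    fish_id = f"{''.join(w[0] for w in design.species.split())}_{idx:02d}"
    mass = _lognormal(rng, design.mass_mean_kg, design.mass_cv)
    length = _lognormal(rng, design.length_mean_m, design.length_cv)
    for _ in range(100):
        smr = _lognormal(rng, design.smr_mean, design.smr_cv)
        mmr = _lognormal(rng, design.mmr_mean, design.mmr_cv)
        if smr < mmr:
            break
    else:  # pragma: no cover - essentially impossible with sane designs
        smr, mmr = design.smr_mean, design.mmr_mean
    for _ in range(100):
        ucrit = _lognormal(rng, design.ucrit_rel_mean_bl_s, design.ucrit_cv)
        if ucrit > min_ucrit:
            break
    else:  # pragma: no cover
        ucrit = max(design.ucrit_rel_mean_bl_s, min_ucrit + 0.5)
    fish = FishRecord(fish_id=fish_id, species=design.species,
                      swim_mode=design.swim_mode, mass_kg=mass,
                      standard_length_m=length)
    phys = FishPhysiology(smr_true=smr, mmr_true=mmr, ucrit_true_bl_s=ucrit)
    return fish, phys


def simulate_cohort(
    design: Sequence[SpeciesDesign] = STUDY_DESIGN,
    n_per_species: Optional[object] = None,
    seed: int = 0,
    sensor: Optional[SensorModel] = None,
    protocols: Sequence[Protocol] = (Protocol.SWIM, Protocol.CHASE, Protocol.CIRCLE),
    mask: Optional[Dict[str, Sequence[Protocol]]] = None,
    swim_schedule: Optional[SwimSchedule] = None,
    cycles: Optional[CycleSchedule] = None,
    chase_duration_s: float = 28800.0,
    circle_duration_s: float = 28800.0,
) -> Tuple[Dict[Tuple[str, Protocol], OxygenTrace], pd.DataFrame,
           Dict[Tuple[str, Protocol], SimTruth], Dict[str, Tuple[FishRecord, FishPhysiology]]]:
    """Draw a cohort of fish and run each through the requested protocols.

    Returns (traces, metadata table, ground-truth table, fish registry).
    Trial order is randomised per fish (recorded in metadata); ``mask`` maps
    fish_id -> protocols to skip, emulating fish that did not complete all
    methods. ``n_per_species`` overrides each design's sample size (an int
    applies to all species; a sequence must match the design length).
    """
    design = list(design)
    if not design:
        raise ValueError("design must list at least one species")
    if n_per_species is not None:
        if isinstance(n_per_species, int):
            ns = [n_per_species] * len(design)
        else:
            ns = list(n_per_species)
            if len(ns) != len(design):
                raise ValueError("n_per_species length must match design length")
        if any(n < 1 for n in ns):
            raise ValueError("n_per_species must be >= 1")
        design = [replace(d, n=n) for d, n in zip(design, ns)]
    sensor = sensor or SensorModel()
    swim_schedule = swim_schedule or SwimSchedule()
    cycles = cycles or CycleSchedule()
    mask = mask or {}
    rng = np.random.default_rng(seed)

    traces: Dict[Tuple[str, Protocol], OxygenTrace] = {}
    truths: Dict[Tuple[str, Protocol], SimTruth] = {}
    registry: Dict[str, Tuple[FishRecord, FishPhysiology]] = {}
    meta_rows = []
    for sp in design:
        for i in range(sp.n):
            fish, phys = _draw_fish(sp, i, rng, swim_schedule.start_speed_bl_s + 0.25)
            registry[fish.fish_id] = (fish, phys)
            order = list(protocols)
            rng.shuffle(order)
            skipped = set(mask.get(fish.fish_id, ()))
            for proto in order:
                if proto in skipped:
                    continue
                trial_seed = int(rng.integers(0, 2**31 - 1))
                if proto == Protocol.SWIM:
                    tr, truth = simulate_swim_trial(
                        fish, phys, ChamberSpec.default(Protocol.SWIM),
                        schedule=swim_schedule, cycles=cycles, sensor=sensor,
                        seed=trial_seed)
                elif proto == Protocol.CHASE:
                    tr, truth = simulate_chase_trial(
                        fish, phys, ChamberSpec.default(Protocol.REST),
                        cycles=cycles, sensor=sensor, seed=trial_seed,
                        duration_s=chase_duration_s)
                elif proto == Protocol.CIRCLE:
                    tr, truth = simulate_circle_trial(
                        fish, phys, ChamberSpec.default(Protocol.CIRCLE),
                        cycles=cycles, sensor=sensor, seed=trial_seed,
                        duration_s=circle_duration_s)
                else:
                    raise ValueError(f"unsupported protocol {proto}")
                traces[(fish.fish_id, proto)] = tr
                truths[(fish.fish_id, proto)] = truth
            meta_rows.append(dict(
                fish_id=fish.fish_id, species=fish.species,
                swim_mode=fish.swim_mode, mass_kg=fish.mass_kg,
                standard_length_m=fish.standard_length_m,
                smr_true=phys.smr_true, mmr_true=phys.mmr_true,
                ucrit_true_bl_s=phys.ucrit_true_bl_s,
                trial_order=">".join(p.value for p in order if p not in skipped),
            ))
    metadata = pd.DataFrame(meta_rows)
    return traces, metadata, truths, registry


def simulate_method_effect_cohort(
    n_per_species: int = 20,
    ratios: Optional[Dict[str, float]] = None,
    design: Sequence[SpeciesDesign] = STUDY_DESIGN,
    between_cv: float = 0.2,
    method_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Summary-level repeated-measures cohort for the statistical stage.

    Draws per-fish MMR as species_mean * lognormal fish effect, and each
    method's observed value as fish_mmr * ratio_method * lognormal noise.
    On the log scale this is exactly the random-intercept mixed model the
    comparison stage fits, so the true method log-ratios are known and
    confidence-interval coverage can be audited cheaply.
    """
    if ratios is None:
        ratios = {"swim": 1.0, "chase": 1.0 / 1.2, "circle": 1.0 / 1.25}
    rng = np.random.default_rng(seed)
    sig_b = math.sqrt(math.log(1 + between_cv ** 2))
    sig_m = math.sqrt(math.log(1 + method_cv ** 2))
    rows = []
    for sp in design:
        for i in range(n_per_species):
            fish_id = f"{''.join(w[0] for w in sp.species.split())}_{i:02d}"
            fish_eff = rng.lognormal(-0.5 * sig_b ** 2, sig_b)
            base = sp.mmr_mean * fish_eff
            for method, ratio in ratios.items():
                noise = rng.lognormal(-0.5 * sig_m ** 2, sig_m)
                rows.append(dict(
                    fish_id=fish_id, species=sp.species, swim_mode=sp.swim_mode,
                    method=method, value=base * ratio * noise,
                ))
    return pd.DataFrame(rows)
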