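"""Core domain types for intermittent-flow respirometry data.

The raw signal is a time-stamped dissolved-oxygen trace recorded inside a
sealed (measurement) or flushed chamber. Everything downstream — per-cycle
oxygen-uptake slopes, MMR/SMR/aerobic-scope estimates, the statistical
method comparison — consumes the types defined here.

Conventions
-----------
* Time is 0-based seconds from trial start; every window is half-open
  ``[start, end)``.
* Oxygen concentration is mg O2 per litre; mass in kg; lengths in metres.
* Trace CSVs are comma-separated, dot-decimal, UTF-8, with a mandatory
  header (``time_s, o2_mg_per_l[, temp_c][, phase]``). No dialect sniffing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Protocol",
    "CycleSchedule",
    "SwimSchedule",
    "FishRecord",
    "ChamberSpec",
    "OxygenTrace",
    "TraceFormatError",
    "TraceValidationError",
    "DEFAULT_SAT_CONC_MG_L",
    "NOMINAL_DT_S",
    "read_trace",
    "write_results",
    "read_results",
]

#: Default 100% air-saturation O2 concentration (mg/L) for warm seawater
#: (~28.5 degC, salinity ~35). A configuration constant, not a solubility
#: model: override per trial when temperature/salinity differ.
DEFAULT_SAT_CONC_MG_L = 6.2

#: Nominal sampling interval of the optode logger (0.5 Hz).
NOMINAL_DT_S = 2.0


class Protocol(str, enum.Enum):
    """Experimental protocol a trace belongs to."""

    SWIM = "swim"        # incremental-speed swim tunnel (Ucrit protocol)
    CHASE = "chase"      # exhaustive chase + air exposure, then resting chamber
    CIRCLE = "circle"    # circular chamber with stir-bar vortex
    REST = "rest"        # resting respirometry only


class Phase(str, enum.Enum):
    """Per-sample phase of the intermittent-flow cycle."""

    MEASURE = "measure"
    FLUSH = "flush"
    RAMP = "ramp"
    HABITUATION = "habituation"


class TraceFormatError(ValueError):
    """Raised when a trace file does not conform to the CSV contract."""


class TraceValidationError(ValueError):
    """Raised when trace contents violate a domain invariant."""


@dataclass(frozen=True)
class CycleSchedule:
    """Intermittent-flow cycle: a sealed measurement period then a flush.

    Defaults are the standard 8-min cycle: 5 min measurement followed by a
    3 min flush that restores full air saturation.
    """

    measure_s: float = 300.0
    flush_s: float = 180.0
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.measure_s <= 0:
            raise ValueError("measure_s must be > 0")
        if self.flush_s < 0:
            raise ValueError("flush_s must be >= 0")
        if self.start_offset_s < 0:
            raise ValueError("start_offset_s must be >= 0")

    @property
    def cycle_s(self) -> float:
        return self.measure_s + self.flush_s

    def phase_at(self, time_s: np.ndarray) -> np.ndarray:
        """Phase label for each time point (habituation before the offset)."""
        t = np.asarray(time_s, dtype=float)
        rel = t - self.start_offset_s
        within = np.mod(rel, self.cycle_s)
        out = np.where(within < self.measure_s, Phase.MEASURE.value, Phase.FLUSH.value)
        out = np.where(rel < 0, Phase.HABITUATION.value, out)
        return out.astype(object)


@dataclass(frozen=True)
class SwimSchedule:
    """Incremental swim-tunnel protocol schedule.

    Speeds are in body lengths per second (BL/s). The defaults follow the
    standard critical-swimming-speed protocol for fast steady swimmers:
    habituation at 0.5 BL/s, a 4-min ramp to 4 BL/s, then 0.5 BL/s
    increments held for three 8-min cycles (24 min) each.
    """

    habituation_speed_bl_s: float = 0.5
    start_speed_bl_s: float = 4.0
    increment_bl_s: float = 0.5
    cycles_per_speed: int = 3
    time_per_speed_s: float = 1440.0
    ramp_s: float = 240.0
    habituation_s: float = 14400.0  # 4 h, the lower bound of typical practice

    def __post_init__(self) -> None:
        for name in (
            "habituation_speed_bl_s",
            "start_speed_bl_s",
            "increment_bl_s",
            "time_per_speed_s",
            "ramp_s",
            "habituation_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cycles_per_speed < 1:
            raise ValueError("cycles_per_speed must be >= 1")

    def validate_against(self, cycles: CycleSchedule) -> None:
        expected = self.cycles_per_speed * cycles.cycle_s
        if abs(self.time_per_speed_s - expected) > 1e-9:
            raise ValueError(
                "time_per_speed_s must equal cycles_per_speed * cycle length "
                f"({self.time_per_speed_s} != {expected})"
            )


@dataclass(frozen=True)
class FishRecord:
    """One animal: identity, taxon, locomotory mode and body dimensions.

    ``body_volume_l`` defaults to mass x 1.0 L/kg (fish are approximately
    neutrally buoyant, density ~ that of water); override when displacement
    was measured. It is subtracted from the chamber volume to obtain the
    effective respirometer volume.
    """

    fish_id: str
    species: str
    swim_mode: str  # "BCF" (body-caudal fin) or "MPF" (median-paired fin)
    mass_kg: float
    standard_length_m: float
    body_volume_l: Optional[float] = None
    cross_section_area_m2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be > 0")
        if self.standard_length_m <= 0:
            raise ValueError("standard_length_m must be > 0")
        if self.swim_mode not in ("BCF", "MPF"):
            raise ValueError("swim_mode must be 'BCF' or 'MPF'")
        if self.body_volume_l is None:
            object.__setattr__(self, "body_volume_l", self.mass_kg * 1.0)
        if self.body_volume_l <= 0:
            raise ValueError("body_volume_l must be > 0")


@dataclass(frozen=True)
class ChamberSpec:
    """A respirometry chamber: protocol type and gross volume.

    Default volumes per protocol (litres): swim tunnel 4.8, resting chamber
    1.615, circular chamber 2.654.
    """

    protocol: Protocol
    volume_l: float
    working_section_m: Optional[tuple] = None  # (width, length, depth), swim only
    tunnel_cross_section_area_m2: Optional[float] = None

    DEFAULT_VOLUMES = {
        Protocol.SWIM: 4.8,
        Protocol.REST: 1.615,
        Protocol.CHASE: 1.615,
        Protocol.CIRCLE: 2.654,
    }

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValueError("volume_l must be > 0")

    @classmethod
    def default(cls, protocol: Protocol) -> "ChamberSpec":
        if protocol == Protocol.SWIM:
            return cls(
                protocol,
                cls.DEFAULT_VOLUMES[protocol],
                working_section_m=(0.07, 0.36, 0.07),
                tunnel_cross_section_area_m2=0.07 * 0.07,
            )
        return cls(protocol, cls.DEFAULT_VOLUMES[protocol])

    def v_resp_l(self, fish: FishRecord) -> float:
        """Effective respirometer volume: chamber minus fish volume."""
        v = self.volume_l - float(fish.body_volume_l)
        if v <= 0:
            raise ValueError(
                f"non-positive effective volume for fish {fish.fish_id!r} in "
                f"{self.protocol.value} chamber ({self.volume_l} L)"
            )
        return v


@dataclass
class OxygenTrace:
    """A sampled dissolved-oxygen time series with per-sample phase labels.

    Invariants: time strictly increasing, all concentrations positive,
    positive saturation concentration. The nominal sampling interval is 2 s
    (0.5 Hz); gaps are allowed but flagged in :attr:`warnings`.
    """

    fish_id: str
    protocol: Protocol
    time_s: np.ndarray
    o2_mg_l: np.ndarray
    sat_conc_mg_l: float = DEFAULT_SAT_CONC_MG_L
    temp_c: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_mg_l = np.asarray(self.o2_mg_l, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.o2_mg_l.shape:
            raise TraceValidationError("time and O2 arrays must be 1-D and equal length")
        if self.time_s.size:
            dt = np.diff(self.time_s)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise TraceValidationError(
                    f"time must be strictly increasing; first violation at index {int(bad[0]) + 1}"
                )
            if np.any(dt > 1.5 * NOMINAL_DT_S):
                self.warnings.append("sampling gaps exceed nominal 2 s interval")
        if np.any(self.o2_mg_l <= 0):
            raise TraceValidationError("O2 concentrations must be > 0")
        if self.sat_conc_mg_l <= 0:
            raise TraceValidationError("sat_conc_mg_l must be > 0")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.shape != self.time_s.shape:
                raise TraceValidationError("phase labels must match sample count")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    def derive_phases(self, schedule: CycleSchedule) -> None:
        """Label every sample from an intermittent-flow cycle schedule."""
        self.phase = schedule.phase_at(self.time_s)

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Index slice of samples with start_s <= t < end_s."""
        i0 = int(np.searchsorted(self.time_s, start_s, side="left"))
        i1 = int(np.searchsorted(self.time_s, end_s, side="left"))
        return slice(i0, i1)


# ---------------------------------------------------------------------------
# Readers / writers


_REQUIRED_COLS = ("time_s", "o2_mg_per_l")


def read_trace(
    path,
    schedule: Optional[CycleSchedule] = None,
    fish_id: str = "",
    protocol: Protocol = Protocol.REST,
    sat_conc_mg_l: float = DEFAULT_SAT_CONC_MG_L,
) -> OxygenTrace:
    """Read an oxygen trace CSV into a validated :class:`OxygenTrace`.

    The file must carry a header with ``time_s`` and ``o2_mg_per_l`` columns;
    ``temp_c`` and ``phase`` are optional. If ``phase`` is absent and a
    ``schedule`` is supplied, phase labels are derived from it. Malformed
    (non-numeric) rows are reported with 1-based file line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required column(s) {missing}")

    numeric = {}
    for col in ("time_s", "o2_mg_per_l") + (("temp_c",) if "temp_c" in df.columns else ()):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 0-base
            raise TraceFormatError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        if vals.isna().any():
            lines = [int(i) + 2 for i in df.index[vals.isna()][:5]]
            raise TraceFormatError(f"{path}: empty values in column {col!r} at line(s) {lines}")
        numeric[col] = vals.to_numpy(dtype=float)

    phase = None
    if "phase" in df.columns:
        labels = df["phase"].astype(str).to_numpy(dtype=object)
        valid = {p.value for p in Phase}
        bad = [lbl for lbl in np.unique(labels) if lbl not in valid]
        if bad:
            raise TraceFormatError(f"{path}: unknown phase label(s) {bad}")
        phase = labels

    trace = OxygenTrace(
        fish_id=fish_id or path.stem,
        protocol=protocol,
        time_s=numeric["time_s"],
        o2_mg_l=numeric["o2_mg_per_l"],
        temp_c=numeric.get("temp_c"),
        phase=phase,
        sat_conc_mg_l=sat_conc_mg_l,
    )
    if trace.phase is None and schedule is not None:
        trace.derive_phases(schedule)
    return trace


def write_trace(trace: OxygenTrace, path) -> None:
    """Write a trace back to the canonical CSV layout."""
    cols = {"time_s": trace.time_s, "o2_mg_per_l": trace.o2_mg_l}
    if trace.temp_c is not None:
        cols["temp_c"] = trace.temp_c
    if trace.phase is not None:
        cols["phase"] = trace.phase
    pd.DataFrame(cols).to_csv(path, index=False)


_RESULT_COLS = [
    "fish_id",
    "species",
    "swim_mode",
    "method",
    "metric",
    "value",
    "unit",
    "flags",
]

_METRIC_UNITS = {
    "mmr": "mg_o2_kg_h",
    "smr": "mg_o2_kg_h",
    "aerobic_scope": "mg_o2_kg_h",
    "ucrit_abs": "cm_s",
    "ucrit_rel": "bl_s",
}


def write_results(records: Sequence, path) -> None:
    """Write MetabolicSummary records as a tidy CSV.

    One row per fish x method x metric; only metrics present on each record
    are emitted. Round-trippable with :func:`read_results`.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty results table")
    rows = []
    for rec in records:
        base = dict(
            fish_id=rec.fish_id,
            species=rec.species,
            swim_mode=rec.swim_mode,
            method=rec.method.value if isinstance(rec.method, Protocol) else rec.method,
            flags=";".join(rec.flags),
        )
        for metric in _METRIC_UNITS:
            value = getattr(rec, metric, None)
            if value is not None:
                rows.append(
                    {**base, "metric": metric, "value": float(value), "unit": _METRIC_UNITS[metric]}
                )
    try:
        pd.DataFrame(rows, columns=_RESULT_COLS).to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    """Read a tidy results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"flags": str})
    missing = [c for c in _RESULT_COLS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: results table missing column(s) {missing}")
    df["value"] = pd.to_numeric(df["value"])
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read a per-fish metadata CSV (fish_id, species, swim_mode, mass_kg, ...)."""
    df = pd.read_csv(path)
    required = ["fish_id", "species", "swim_mode", "mass_kg", "standard_length_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: metadata missing column(s) {missing}")
    return df


def fish_from_row(row) -> FishRecord:
    """Build a FishRecord from one metadata table row."""
    return FishRecord(
        fish_id=str(row["fish_id"]),
        species=str(row["species"]),
        swim_mode=str(row["swim_mode"]),
        mass_kg=float(row["mass_kg"]),
        standard_length_m=float(row["standard_length_m"]),
        body_volume_l=float(row["body_volume_l"]) if "body_volume_l" in row and not pd.isna(row["body_volume_l"]) else None,
    )
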