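"""End-to-end orchestration: simulate (or ingest) -> process -> metrics -> compare.

`RunConfig` is a fully serialisable description of one run (schedules,
sensor model, estimator options, comparison options, seed, output paths);
`run_pipeline` executes the four stages, writes every artifact as CSV/JSON
next to a resolved copy of the config, and returns a manifest with SHA-256
checksums so that repeated runs with the same seed can be verified
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import compare as compare_mod
from . import metrics as metrics_mod
from .mo2_engine import BackgroundModel, Mo2Series, process_trace
from .simulate import (
    STUDY_DESIGN,
    SensorModel,
    SimTruth,
    SpeciesDesign,
    simulate_cohort,
)
from .trace_model import (
    ChamberSpec,
    CycleSchedule,
    FishRecord,
    OxygenTrace,
    Protocol,
    SwimSchedule,
    write_results,
    write_trace,
)

__all__ = ["RunConfig", "run_pipeline", "summarize_trial", "demo_config"]

log = logging.getLogger("respirotools.pipeline")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML round-trippable)."""

    seed: int = 0
    out_dir: str = "runs/demo"
    # cohort
    n_per_species: Optional[int] = None
    species: Optional[List[dict]] = None  # overrides the default design
    # cycle / swim schedules
    measure_s: float = 300.0
    flush_s: float = 180.0
    habituation_s: float = 14400.0
    ramp_s: float = 240.0
    start_speed_bl_s: float = 4.0
    increment_bl_s: float = 0.5
    cycles_per_speed: int = 3
    # sensor
    noise_sd: float = 0.002
    background_rate_0: float = 0.0
    background_slope: float = 0.0
    flush_mode: str = "instant"
    # trial durations
    chase_duration_s: float = 28800.0
    circle_duration_s: float = 28800.0
    # estimator options
    smr_fraction: float = 0.10
    recovery_cutoff_s: float = 21600.0
    circle_span_end_s: float = 300.0
    trim_lead_s: float = 0.0
    mmr_swim_use_max: bool = True
    # comparison options
    alpha: float = 0.05
    adjustment: str = "single-step"
    log_transform: bool = False

    def validate(self) -> None:
        if self.measure_s <= 0 or self.flush_s < 0:
            raise ValueError("invalid cycle schedule in config")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.recovery_cutoff_s < 0 or not (0 < self.smr_fraction <= 1):
            raise ValueError("invalid SMR estimator options")
        if not (300.0 <= self.circle_span_end_s <= 420.0):
            raise ValueError("circle_span_end_s must lie within [300, 420] s")
        if self.species is not None:
            for sp in self.species:
                for key in ("species", "swim_mode", "n", "mass_mean_kg",
                            "length_mean_m", "smr_mean", "mmr_mean",
                            "ucrit_rel_mean_bl_s"):
                    if key not in sp:
                        raise ValueError(f"species entry missing {key!r}")
        # instantiating the schedules runs their own invariant checks
        self.cycle_schedule()
        self.swim_schedule()
        self.sensor_model()

    def cycle_schedule(self) -> CycleSchedule:
        return CycleSchedule(measure_s=self.measure_s, flush_s=self.flush_s)

    def swim_schedule(self) -> SwimSchedule:
        return SwimSchedule(
            start_speed_bl_s=self.start_speed_bl_s,
            increment_bl_s=self.increment_bl_s,
            cycles_per_speed=self.cycles_per_speed,
            time_per_speed_s=self.cycles_per_speed * (self.measure_s + self.flush_s),
            ramp_s=self.ramp_s,
            habituation_s=self.habituation_s,
        )

    def sensor_model(self) -> SensorModel:
        return SensorModel(
            noise_sd=self.noise_sd,
            background_rate_0=self.background_rate_0,
            background_slope=self.background_slope,
            flush_mode=self.flush_mode,
        )

    def design(self) -> Tuple[SpeciesDesign, ...]:
        if self.species is None:
            return STUDY_DESIGN
        defaults = dict(mass_cv=0.2, length_cv=0.08, smr_cv=0.3, mmr_cv=0.25,
                        ucrit_cv=0.12)
        out = []
        for sp in self.species:
            kw = {**defaults, **sp}
            out.append(SpeciesDesign(
                species=kw["species"], swim_mode=kw["swim_mode"], n=int(kw["n"]),
                mass_mean_kg=kw["mass_mean_kg"], mass_cv=kw["mass_cv"],
                length_mean_m=kw["length_mean_m"], length_cv=kw["length_cv"],
                smr_mean=kw["smr_mean"], smr_cv=kw["smr_cv"],
                mmr_mean=kw["mmr_mean"], mmr_cv=kw["mmr_cv"],
                ucrit_rel_mean_bl_s=kw["ucrit_rel_mean_bl_s"],
                ucrit_cv=kw["ucrit_cv"],
            ))
        return tuple(out)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def demo_config() -> RunConfig:
    """A small three-species demonstration run (minutes, not hours)."""
    cfg = RunConfig(
        out_dir="runs/demo",
        n_per_species=6,
        habituation_s=960.0,
        chase_duration_s=12000.0,
        circle_duration_s=12000.0,
        recovery_cutoff_s=6000.0,
    )
    cfg.species = [
        dict(species=sp.species, swim_mode=sp.swim_mode, n=6,
             mass_mean_kg=sp.mass_mean_kg, mass_cv=sp.mass_cv,
             length_mean_m=sp.length_mean_m, length_cv=sp.length_cv,
             smr_mean=sp.smr_mean, smr_cv=sp.smr_cv,
             mmr_mean=sp.mmr_mean, mmr_cv=sp.mmr_cv,
             ucrit_rel_mean_bl_s=sp.ucrit_rel_mean_bl_s, ucrit_cv=sp.ucrit_cv)
        for sp in STUDY_DESIGN[:3]
    ]
    return cfg


def _background_for(trace: OxygenTrace, cfg: RunConfig) -> Optional[BackgroundModel]:
    """Pre/post background measurements implied by the configured drift."""
    if cfg.background_rate_0 == 0 and cfg.background_slope == 0:
        return None
    t_end = float(trace.time_s[-1]) if trace.n_samples else 1.0
    sensor = cfg.sensor_model()
    return BackgroundModel(
        rate_pre_mg_h=sensor.background_at(0.0),
        rate_post_mg_h=sensor.background_at(t_end),
        t_pre_s=0.0, t_post_s=t_end,
    )


def summarize_trial(
    trace: OxygenTrace,
    fish: FishRecord,
    truth: SimTruth,
    cfg: RunConfig,
) -> metrics_mod.MetabolicSummary:
    """Run the estimator chain appropriate to one trial's protocol."""
    proto = trace.protocol
    chamber = ChamberSpec.default(
        Protocol.REST if proto == Protocol.CHASE else proto
    )
    background = _background_for(trace, cfg)
    series = process_trace(trace, fish, chamber, background,
                           trim_lead_s=cfg.trim_lead_s)
    summary = metrics_mod.MetabolicSummary(
        fish_id=fish.fish_id, species=fish.species, swim_mode=fish.swim_mode,
        method=proto,
    )
    if proto == Protocol.SWIM:
        est = metrics_mod.mmr_swim(series, truth.speed_by_window,
                                   truth.completed_cycles,
                                   use_max=cfg.mmr_swim_use_max)
        summary.mmr = est.value
        summary.flags += list(est.flags)
        rel = metrics_mod.ucrit(metrics_mod.UcritInputs(
            u_last=truth.last_completed_speed_bl_s,
            u_i=cfg.increment_bl_s,
            t_s=truth.fatigue_time_s,
            t_i_s=cfg.cycles_per_speed * (cfg.measure_s + cfg.flush_s),
        ))
        summary.ucrit_rel_bl_s = rel
        summary.ucrit_abs_cm_s = rel * fish.standard_length_m * 100.0
    else:
        span = None
        if proto == Protocol.CIRCLE:
            span = (0.0, cfg.circle_span_end_s)
        est = metrics_mod.mmr_postexercise(trace, proto, fish, chamber,
                                           background, search_span=span)
        smr_est = metrics_mod.smr_lowest_fraction(
            series, recovery_cutoff_s=cfg.recovery_cutoff_s,
            fraction=cfg.smr_fraction)
        summary.mmr = est.value
        summary.smr = smr_est.value
        summary.smr_source = (
            "rest_lowest10" if proto == Protocol.CHASE else "circle_lowest10"
        )
        scope, scope_flags = metrics_mod.aerobic_scope(est.value, smr_est.value)
        summary.aerobic_scope = scope
        summary.flags += list(est.flags) + list(smr_est.flags) + list(scope_flags)
    return summary


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Execute simulate -> process -> metrics -> compare; return the manifest.

    Artifacts under ``config.out_dir``: per-trial trace CSVs, the per-fish
    metadata and ground-truth table, per-window MO2 series, the metabolic
    summary table, and a JSON comparison report. A resolved copy of the
    config and a checksum manifest are written alongside; runs with the
    same config and seed are byte-identical.
    """
    config.validate()
    out = Path(config.out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    traces, metadata, truths, registry = simulate_cohort(
        design=config.design(),
        n_per_species=config.n_per_species,
        seed=config.seed,
        sensor=config.sensor_model(),
        swim_schedule=config.swim_schedule(),
        cycles=config.cycle_schedule(),
        chase_duration_s=config.chase_duration_s,
        circle_duration_s=config.circle_duration_s,
    )
    metadata.to_csv(out / "metadata.csv", index=False, float_format="%.12g")

    summaries: List[metrics_mod.MetabolicSummary] = []
    series_rows = []
    for (fish_id, proto), trace in traces.items():
        fish, _ = registry[fish_id]
        write_trace(trace, out / "traces" / f"{fish_id}_{proto.value}.csv")
        try:
            summary = summarize_trial(trace, fish, truths[(fish_id, proto)], config)
        except ValueError as exc:
            raise RuntimeError(
                f"metrics stage failed for fish {fish_id!r} ({proto.value}): {exc}"
            ) from exc
        summaries.append(summary)
        chamber = ChamberSpec.default(
            Protocol.REST if proto == Protocol.CHASE else proto)
        series = process_trace(trace, fish, chamber,
                               _background_for(trace, config),
                               trim_lead_s=config.trim_lead_s)
        for e in series.entries:
            series_rows.append(dict(
                fish_id=fish_id, method=proto.value,
                window_start=e.window[0], window_end=e.window[1], mo2=e.mo2,
                r2=e.r2, background_fraction=e.background_fraction,
                saturation_min=e.saturation_min, flags=";".join(e.flags),
            ))
        log.info("fish %s %s: %d windows", fish_id, proto.value,
                 len(series.entries))
    pd.DataFrame(series_rows).to_csv(out / "mo2_series.csv", index=False,
                                     float_format="%.12g")
    write_results(summaries, out / "summaries.csv")

    frame = compare_mod.summaries_to_frame(summaries)
    report: Dict[str, object] = {}
    mmr_res = compare_mod.fit_comparison(
        frame, compare_mod.ComparisonSpec(
            response="mmr", alpha=config.alpha,
            adjustment=config.adjustment, log_transform=config.log_transform))
    report["mmr"] = _result_to_dict(mmr_res)
    smr_frame = frame.dropna(subset=["smr"])
    if smr_frame["method"].nunique() >= 2:
        smr_res = compare_mod.fit_comparison(
            smr_frame, compare_mod.ComparisonSpec(
                response="smr", alpha=config.alpha,
                adjustment=config.adjustment,
                log_transform=config.log_transform))
        report["smr"] = _result_to_dict(smr_res)
    ucrit_frame = frame.dropna(subset=["ucrit_abs"])
    if ucrit_frame["species"].nunique() >= 2:
        uc = compare_mod.fit_ucrit_lm(ucrit_frame, response="ucrit_abs",
                                      alpha=config.alpha)
        report["ucrit_abs"] = _result_to_dict(uc)
    (out / "comparison.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _result_to_dict(res: compare_mod.ComparisonResult) -> dict:
    d = dict(
        response=res.response, engine=res.engine, log_scale=res.log_scale,
        interaction_removed=res.interaction_removed,
        fixed_effect_tests=res.fixed_effect_tests,
        contrasts=[{**c, "pair": list(c["pair"])} for c in res.contrasts],
        predictions=res.predictions.to_dict(orient="records"),
        n_obs=res.n_obs, n_groups=res.n_groups, notes=res.notes,
    )
    if res.interaction_test is not None:
        d["interaction_test"] = res.interaction_test
    if res.letters is not None:
        d["letters"] = res.letters
    pairs = [tuple(c["pair"]) for c in res.contrasts]
    pct = {}
    for pair in pairs:
        try:
            overall, (lo, hi) = compare_mod.percent_difference(res, pair)
            pct["_vs_".join(pair)] = dict(percent=overall, species_min=lo,
                                          species_max=hi)
        except (ValueError, KeyError):
            continue
    d["percent_differences"] = pct
    return d
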