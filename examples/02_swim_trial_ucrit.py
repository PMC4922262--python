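"""Swim-tunnel trial: incremental speeds, MMR at the top speed, Brett Ucrit.

The fish swims 0.5 BL/s increments (three 8-min cycles each) until fatigue.
MMR is the uptake at the highest speed with at least one completed cycle;
the critical swimming speed interpolates between the last completed and the
failed increment. A solid-blocking correction adjusts tunnel speeds for the
body's share of the working cross-section.
"""

import math

from respirotools import (
    BlockingSpec,
    ChamberSpec,
    FishPhysiology,
    FishRecord,
    Protocol,
    UcritInputs,
    blocking_correction,
    mmr_swim,
    process_trace,
    simulate_swim_trial,
    ucrit,
)
from respirotools.metrics import shape_factor_from_geometry

fish = FishRecord(fish_id="demo", species="Pterocaesio marri", swim_mode="BCF",
                  mass_kg=0.0099, standard_length_m=0.0852)
phys = FishPhysiology(smr_true=223.0, mmr_true=1794.0, ucrit_true_bl_s=10.1)
chamber = ChamberSpec.default(Protocol.SWIM)

trace, truth = simulate_swim_trial(fish, phys, chamber, seed=2)
series = process_trace(trace, fish, chamber)

est = mmr_swim(series, truth.speed_by_window, truth.completed_cycles)
print(f"completed speeds: "
      f"{sorted(s for s, n in truth.completed_cycles.items() if n >= 1)}")
print(f"MMR_swim = {est.value:.1f} mg O2/kg/h at "
      f"{est.diagnostics['top_speed_bl_s']} BL/s (true MMR {phys.mmr_true})")

u = ucrit(UcritInputs(u_last=truth.last_completed_speed_bl_s, u_i=0.5,
                      t_s=truth.fatigue_time_s, t_i_s=1440.0))
print(f"Ucrit = {u:.2f} BL/s = {u * fish.standard_length_m * 100:.1f} cm/s "
      f"(fish fatigued {truth.fatigue_time_s:.0f} s into the "
      f"{truth.failed_speed_bl_s} BL/s increment)")

# blocking correction for a fish occupying ~3% of the 7x7 cm section
depth, width = 0.28 * fish.standard_length_m, 0.13 * fish.standard_length_m
area = math.pi * depth * width / 4.0
spec = BlockingSpec(area, 0.07 * 0.07,
                    shape_factor_from_geometry(fish.standard_length_m, area))
corrected, eps, warn = blocking_correction(u * fish.standard_length_m * 100,
                                           spec)
print(f"solid-blocking correction: eps = {eps*100:.1f}% -> corrected Ucrit "
      f"{corrected:.1f} cm/s (warning above 5%: {warn})")
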