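"""Detect a chloride-unbinding event and its exit direction.

Simulates an ion that stays 4-6 Å from the inner-gate tyrosine for
150 ns and then leaves toward the extracellular side, computes the
nearest-ion distance series, smooths it with a 20-ns moving average, and
calls the unbinding event at the 12 Å threshold.
"""

from clcmech import synthetic as syn
from clcmech.ions import (assign_direction, detect_unbinding,
                          min_distance_series, occupancy_fraction,
                          smooth_series)

fx = syn.make_ion_walk(duration_ns=300.0, exit_time_ns=150.0,
                       direction="extracellular", seed=42)
series = smooth_series(min_distance_series(fx.trajectory, fx.config),
                       window_ns=20.0)
events = detect_unbinding(series, threshold=12.0,
                          ion_id=int(fx.trajectory.topology.ion_ids()[0]))

print(f"{len(events)} unbinding event(s) detected")
for ev in events:
    direction = assign_direction(fx.trajectory, ev, fx.membrane,
                                 fx.pathway_sites)
    print(f"  smoothed distance crossed 12 A at {ev.crossing_time_ns:.1f} ns "
          f"(programmed exit: 150 ns), ion left {direction}ly")
print(f"unbound fraction of frames: {occupancy_fraction(series, 12.0):.2f}")
print("A smoothed distance above 12 A means no chloride occupies the "
      "anion-binding sites; the fraction above threshold is the unbound "
      "occupancy.")
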