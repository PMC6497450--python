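"""Segment a raw tick-level intake stream into drinks and bouts.

Builds a one-day synthetic scale stream (with three injected balance
artifacts and a water channel as distractors), merges ticks into drinks
with the 5 s rule, removes 1 s / 0.2 mL artifacts, and groups drinks into
bouts at the 300 s lapse.
"""

import numpy as np

from drinksim import (
    SimulationConfig,
    emit_raw_stream,
    filter_artifacts,
    merge_events,
    population_mean_parameters,
    sample_parameters,
    segment_bouts,
)

params = population_mean_parameters()
water = sample_parameters(np.random.default_rng(1))
records, truth = emit_raw_stream(
    params, SimulationConfig(n_days=1, seed=42), n_artifacts=3, water_params=water
)
print(f"raw stream: {len(records)} scale readings (both fluids)")

ethanol = [r for r in records if r.fluid == "ethanol"]
drinks = merge_events(ethanol)
drinks, n_removed = filter_artifacts(drinks)
bouts = segment_bouts(drinks)

print(f"ethanol drinks after merging: {len(drinks)} ({n_removed} artifacts removed)")
print(f"bouts: {len(bouts)}; ground truth had {len(truth.true_bouts)}")
print("first three drinks (start s, duration s, volume mL, rate mL/s):")
for d in drinks[:3]:
    print(f"  {d.start:9.1f}  {d.duration:6.1f}  {d.volume:6.2f}  {d.rate:5.3f}")
# Each line is one merged consumption episode; rate = volume / duration
# decides its low/medium/high class against the 0.6 / 1.1 mL/s cut-offs.
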