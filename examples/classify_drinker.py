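"""Classify simulated drinking into LD / BD / HD / VHD categories.

Builds two contrasting profiles — a sparse low-rate "sipper" and a dense
high-rate "gulper" — simulates 180 open-access days for each, and applies
the intake-threshold category rules to the daily g/kg series.
"""

import dataclasses

from drinksim import (
    SimulationConfig,
    WaitingTime,
    classify_series,
    population_mean_parameters,
    simulate_series,
)

base = population_mean_parameters(weight_kg=8.5)
sipper = dataclasses.replace(
    base, p_low=1.0, p_medium=0.0, p_high=0.0, p_bout=0.1,
    inter_bout_gap=WaitingTime("exponential", 1.0, 8000.0, offset_s=300.0),
)
gulper = dataclasses.replace(
    base, p_low=0.0, p_medium=0.0, p_high=1.0, p_bout=0.5,
    bout_length=WaitingTime("exponential", 1.0, 341.84),
    inter_bout_gap=WaitingTime("exponential", 1.0, 2000.0, offset_s=300.0),
)

for name, params in (("sipper", sipper), ("gulper", gulper)):
    series = simulate_series(params, SimulationConfig(n_days=180, seed=11))
    label = classify_series(series)
    ev = label.evidence
    print(f"{name}: {label.category} ({label.collapsed})  "
          f"ADEI {ev['adei_g_per_kg']:.2f} g/kg; "
          f"days > 2/3/4 g/kg: {ev['frac_days_over_2']:.0%} / "
          f"{ev['frac_days_over_3']:.0%} / {ev['frac_days_over_4']:.0%}")
# The category rules quantify over the daily dose series: VHD needs mean
# intake above 3 g/kg plus >10% of days over 4 g/kg; HD >20% of days over
# 3 g/kg; BD >55% of days over 2 g/kg; everything else is LD.
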