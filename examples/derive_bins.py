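"""Derive rate-class bin edges from a pooled drink-rate sample.

Draws a trimodal rate sample (modes at the cohort medians), finds the
density valleys that separate low / medium / high drinking, and compares
them to the shipped defaults (0.6 and 1.1 mL/s).
"""

import numpy as np

from drinksim import DEFAULT_BINS, derive_rate_bins

rng = np.random.default_rng(13)
comps = rng.choice(3, size=5000, p=[0.45, 0.35, 0.20])
rates = rng.normal(np.array([0.383, 0.798, 1.376])[comps], 0.06)
rates = rates[rates > 0]

bins = derive_rate_bins(rates)
print(f"derived cut-offs: {bins.cut_low_med:.3f} / {bins.cut_med_high:.3f} mL/s "
      f"(defaults {DEFAULT_BINS.cut_low_med} / {DEFAULT_BINS.cut_med_high})")
print(f"bin medians: low {bins.median_low:.3f}, medium {bins.median_medium:.3f}, "
      f"high {bins.median_high:.3f} mL/s")
print("fallback used:", bins.fallback)
# The cut-offs sit in the valleys of the smoothed rate density; the medians
# are what the simulator emits as noise-free drink rates for each state.
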