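"""Fit the MilkBot curve to one lactation and derive its yield traits.

Builds a noisy test-day series from known parameters, fits it back, and
prints the recovered parameters next to the truth plus the derived traits:
M305 (cumulative 305-day yield), t_peak (day of peak) and peak yield.
"""

import numpy as np

from lactgwas.milkbot import MilkBotParams, derived_traits, evaluate, fit_lactation

truth = MilkBotParams(scale_a=35.57, ramp_b=30.60, offset_c=0.0, decay_d=0.00142)
rng = np.random.default_rng(1)
dim = np.arange(5, 306, 30, dtype=float)          # monthly milk recording
milk = evaluate(truth, dim) + rng.normal(0, 1.5, dim.size)

fit = fit_lactation(dim, milk)
d = derived_traits(fit.params)

print(f"{'parameter':<12}{'true':>10}{'fitted':>10}")
for name, t, f in zip(("scale a", "ramp b", "offset c", "decay d"),
                      truth.as_array(), fit.params.as_array()):
    print(f"{name:<12}{t:>10.4f}{f:>10.4f}")
print(f"\nM305       = {d.m305:8.1f} kg   (total yield to day 305)")
print(f"t_peak     = {d.t_peak:8.1f} d    (day of peak lactation)")
print(f"peak yield = {d.peak_yield:8.2f} kg/d")
# With 1.5 kg test-day noise and 11 records the scale and decay recover
# closely; ramp and offset are the weakly identified pair.
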