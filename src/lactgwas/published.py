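"""Published Holstein reference values used as inputs and worked examples.

Variance components (AI-REML, European Holstein field data) for 305-day milk yield
and the MilkBot lactation-curve traits, for primiparous (single-record
animal model: additive + residual) and multiparous cows (repeatability
model: additive + permanent environmental + residual), plus the percentages
of additive genetic variance explained by the three associated 50-SNP
windows on BTA14.  Decay components are on the conventional x1000 display
scale.  These constants parameterize worked examples, simulation truth and
consistency checks; nothing here is estimated by this package.
"""

from __future__ import annotations

import pandas as pd

# trait -> (sigma_a2, sigma_e2); primiparous single-record model
PRIMIPAROUS_COMPONENTS = {
    "m305": (526_630.0, 892_670.0),
    "scale": (7.58, 17.19),
    "ramp": (0.0056, 0.0408),
    "decay": (0.02228, 0.09256),
    "t_peak": (14.39, 69.86),
    "peak_yield": (6.36, 11.99),
}

# trait -> (sigma_a2, sigma_p2, sigma_e2); multiparous repeatability model
MULTIPAROUS_COMPONENTS = {
    "m305": (685_000.0, 414_700.0, 1_498_600.0),
    "scale": (12.42, 4.85, 42.92),
    "ramp": (0.3021, 0.0145, 5.6433),
    "decay": (0.07120, 0.01143, 0.27119),
    "t_peak": (7.04, 1.43, 46.08),
    "peak_yield": (9.08, 4.58, 26.23),
}

# Reported point estimates (rounded to 2 d.p. in the source report)
PRIMIPAROUS_H2 = {
    "m305": 0.37, "peak_yield": 0.34, "t_peak": 0.17,
    "ramp": 0.12, "scale": 0.30, "decay": 0.19,
}
MULTIPAROUS_H2 = {
    "m305": 0.26, "peak_yield": 0.23, "t_peak": 0.13,
    "ramp": 0.05, "scale": 0.21, "decay": 0.20,
}
MULTIPAROUS_REPEATABILITY = {
    "m305": 0.42, "peak_yield": 0.34, "t_peak": 0.15,
    "ramp": 0.05, "scale": 0.29, "decay": 0.24,
}

# Primiparous curve-trait means (scale kg/day, ramp days, decay x1000, offset
# treated as 0) used as simulation defaults and worked-example parameters.
PRIMIPAROUS_MEANS = {"scale": 35.57, "ramp": 30.60, "decay_x1000": 1.42, "offset": 0.0}

# Percent additive genetic variance of the three BTA14 candidate windows
# (primiparous), per trait; window bp spans on the UMD3.1 assembly.
BTA14_WINDOWS = pd.DataFrame([
    {"start_bp": 1_480_260, "end_bp": 1_683_767, "m305": 1.21, "peak_yield": 1.04,
     "t_peak": 0.47, "ramp": 0.37, "scale": 0.81, "decay": 0.57},
    {"start_bp": 1_855_090, "end_bp": 2_118_405, "m305": 1.09, "peak_yield": 0.94,
     "t_peak": 0.38, "ramp": 0.28, "scale": 0.73, "decay": 0.44},
    {"start_bp": 2_676_321, "end_bp": 2_940_147, "m305": 0.94, "peak_yield": 0.82,
     "t_peak": 0.55, "ramp": 0.37, "scale": 0.64, "decay": 0.50},
])

# Order in which the six traits are conventionally reported
TRAIT_ORDER = ["m305", "peak_yield", "t_peak", "ramp", "scale", "decay"]
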