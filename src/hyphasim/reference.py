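"""Packaged reference values for calibration-style analyses.

``BRANCHING_PATTERNS`` holds the three branching-frequency parameter sets
compared in the branching-pattern analysis: set ``II`` is the standard
calibrated parameterisation (long apical distance, short interbranch
distance, as measured at the 10 h point of the growth curve); ``I`` is a
literature-style *less frequent* pattern (longer apical and interbranch
distances); ``III`` a *frequent* pattern (shorter distances).  The ``I``
and ``III`` length statistics are representative values in the range
reported for Streptomyces branching studies, packaged here so the
comparison is runnable out of the box; users with their own measurements
should override them via the config file.

``EARLY_GROWTH_REFERENCE`` is a synthetic stand-in for an experimental
summary of early (4 h) hyphal growth: mean ± sd of the maximum network
diameter and of the tip count over a population of young networks.  It was
generated once from a large seeded ensemble of the calibrated model
(α = β = 10) and frozen, and exists so the α/β calibration sweep has a
packaged comparison target; replace it with real measurements for any
scientific use.
"""

from __future__ import annotations

from .params import GrowthParams

__all__ = ["BRANCHING_PATTERNS", "EARLY_GROWTH_REFERENCE"]

BRANCHING_PATTERNS: dict[str, GrowthParams] = {
    # less frequent branching: long apical + interbranch distances
    "I": GrowthParams(l1=57.0, l1_sd=17.0, l2=11.5, l2_sd=6.0),
    # standard calibrated parameters
    "II": GrowthParams(),
    # frequent branching: short apical + interbranch distances
    "III": GrowthParams(l1=16.0, l1_sd=5.0, l2=4.5, l2_sd=2.0),
}

# synthetic early-growth reference (see module docstring): the means are
# the 200-seed ensemble means of the calibrated model at 4 h; the sds are
# set at biological population scale (CV ≈ 45-50%, comparable to the
# coefficient of variation measured for pellet areas), since the reference
# plays the role of a spread of real young networks, not of a simulation
# ensemble
EARLY_GROWTH_REFERENCE: dict[str, float] = {
    "diameter_mean": 35.2,
    "diameter_sd": 15.0,
    "tips_mean": 6.4,
    "tips_sd": 3.2,
}
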