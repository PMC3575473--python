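"""Branching frequency, the hyphal growth unit, and antibiotic yield (~40 s).

Three branching parameter sets are compared: less frequent (I), the
standard calibrated pattern (II), and frequent (III).  More frequent
branching always lowers the hyphal growth unit, but the antibiotic-
producing area peaks for the standard pattern — branching too much
starves the pellet, branching too little leaves it fully aerobic.
"""

import hyphasim as hs

settings = hs.RunSettings(t_end=24.0)
_, substrate, thresholds, _ = hs.default_params()

results = {
    name: [hs.run(g, substrate, thresholds, settings, seed=s) for s in (1, 2)]
    for name, g in hs.BRANCHING_PATTERNS.items()
}
table = hs.branching_pattern_report(results)
print(table.to_string(float_format=lambda v: f"{v:.3g}"))

# hgu_mean falls monotonically from set I to III; producing_area_mean is
# largest for the calibrated set II, showing that apical and interbranch
# lengths jointly tune where secondary metabolism happens.
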