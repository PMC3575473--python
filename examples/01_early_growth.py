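"""Early, substrate-unlimited network growth (runs in ~1 s).

Two germ tubes emerge from a spore at the origin and elongate by the
stochastic velocity process, branching sub-apically as their lengths pass
the experimentally derived branching-length distribution.  Over the first
4 h this produces a young network of a handful of tips.
"""

import hyphasim as hs

res = hs.run(settings=hs.RunSettings(t_end=4.0), seed=1, field_free=True)
m = res.metrics.iloc[-1]

print(f"tips after 4 h:        {int(m['n_tips_total'])}")
print(f"max network diameter:  {m['max_diameter']:.1f} um")
print(f"total hyphal length:   {m['total_length']:.1f} um")
print(f"hyphal growth unit:    {m['hgu']:.1f} um/tip")

# The diameter reflects how far the two original tips wandered from the
# spore; the hyphal growth unit (total length / tips) measures how densely
# the young mycelium branches: each new tip appears after roughly one
# apical + one interbranch length of growth.
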