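"""Count nematode-trap structures against a background of ordinary hyphae.

Traps are dense compact clusters (here: overlapping rings) that differ
from single hyphae purely in size and elongation, so trap counting is the
component pipeline run with trap-scale gates.  The example also shows
what a mis-calibrated (spore-scale) gate does.
"""

from mycovision import count_traps, presets, synthetic

scene = synthetic.generate_trap_scene(n_traps=10, background_hyphae=15, seed=23)
good = presets.trap_scene_params()
print(f"planted traps:      {scene.n_planted['trap']}")
print(f"detected (trap-scale gates): {count_traps(scene.image, good).n_spores}")

bad = good.replace(b1=0.4, b2=0.3, min_area=5, elongation_max=1.0)
print(f"detected (mis-calibrated):   {count_traps(scene.image, bad).n_spores}")

# With gates at trap scale the count is exact; dropping the thresholds and
# gates to spore scale admits hyphal fragments and the count no longer
# reflects the planted traps -- calibration is what separates the two.
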