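"""Count conidia in a brightfield droplet image and extrapolate to a dish.

Builds a synthetic droplet scene with a known number of planted spores
plus hyphal-fragment and dust distractors, counts them with the shared
segmentation pipeline, and extrapolates the droplet count to the full
suspension the way a plate-level conidiation assay would.
"""

from mycovision import count_spores, percent_error, presets, synthetic
from mycovision.spores import droplet_to_dish

scene = synthetic.generate_spore_scene(
    n_spores=120, n_distractors=10, noise_sigma=0.05, seed=42
)
params = presets.spore_scene_params()
result = count_spores(scene.image, params, image_name="droplet_042")

planted = scene.n_planted["spore"]
print(f"planted spores:  {planted}")
print(f"detected spores: {result.n_spores}")
print(f"percent error:   {percent_error(result.n_spores, planted):+.1f}%")
# a 5 ul droplet imaged from a 1 ml harvested suspension
print(f"extrapolated to the dish: {droplet_to_dish(result.n_spores, 5, 1000)} conidia")

# The detected count should match the planted count exactly at this noise
# level: distractors are rejected by the area gate (dust) and the
# elongation gate (hyphal fragments).  The dish-level figure scales the
# droplet count by the volume ratio (x200 here).
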