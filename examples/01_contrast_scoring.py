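"""Score the conspicuousness of a rendered specimen against leaf backgrounds.

Renders a synthetic two-patch beetle (dark pronotum, orange-red elytra) on a
leaf-green background with mild sensor noise, samples five 31x31-pixel
replicate windows per body part, and reports the internal contrast (IC-dE,
bright vs dark body part) and the external contrast (EC-dE) of the bright
part against all six leaf backgrounds. Larger dE = more conspicuous.
"""

from mimevo.color import delta_e_76, sample_patch
from mimevo.synth import ImageRecipe, SimulationRecipe, default_backgrounds, render_specimen

recipe = SimulationRecipe(seed=1, image=ImageRecipe(noise_sigma=0.01))
render = render_specimen(recipe)

bright = sample_patch(render.image, render.centres["bright"], render.window).mean
dark = sample_patch(render.image, render.centres["dark"], render.window).mean

ic = delta_e_76(bright, dark)
ic_true = delta_e_76(render.truth_lab["bright"], render.truth_lab["dark"])
print(f"IC-dE (bright vs dark part): {ic:.2f}  (noiseless truth {ic_true:.2f})")

print("EC-dE of the bright part against each leaf background:")
for (leaf, side), bg in sorted(default_backgrounds().items()):
    print(f"  {leaf}/{side:6s}: {delta_e_76(bright, bg):7.2f}")
print("The bright part is most conspicuous on the darkest leaf surface;")
print("the IC exceeding most EC values mirrors bicoloured warning signals.")
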