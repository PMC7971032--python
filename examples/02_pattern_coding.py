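"""Code specimen colouration descriptors into pattern categories.

Builds a few structured descriptors, assigns each its fine 19-way category
and the coarse six-state code used for ancestral reconstruction, and counts
the pattern richness of the little assemblage.
"""

from mimevo.patterns import (
    ColourationDescriptor,
    classify_nineteen,
    classify_six,
    pattern_richness,
)

specimens = [
    ColourationDescriptor("s1", "black", (("whole", "black"),), "uniform", 1),
    ColourationDescriptor("s2", "black", (("whole", "red"),), "pronotum_vs_elytra", 2),
    ColourationDescriptor(
        "s3", "black", (("basal", "yellow"), ("apical", "black")), "bicoloured_elytra", 2
    ),
    ColourationDescriptor("s4", "black", (("fascia", "orange"),), "fasciate", 2),
    ColourationDescriptor("s5", "metallic", (("whole", "metallic"),), "uniform", 1),
]

cats = []
for d in specimens:
    c19 = classify_nineteen(d)
    c6 = classify_six(d)
    cats.append(c19)
    print(f"{d.specimen_id}: {c19.label:32s} -> state {c6.state} ({c6.label})")

print(f"pattern richness of this assemblage: {pattern_richness(cats)}")
print("Each distinct category counts once; state 6 pools the rare forms.")
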