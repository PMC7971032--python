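"""Controlled vocabulary of the 19 descriptive colour-pattern categories.

The 19-way scheme is assembled from pattern descriptions of aposematic
net-winged beetles (uniform forms, bicoloured forms, mottled forms, and a set
of rare named colour combinations). The exact composition of the original
19-category scheme was never published as a list, so this registry is
PROVISIONAL and deliberately kept in one editable file: amend the entries to
match your own material. Everything downstream (classification, richness
counts, the 19→6 projection) reads the vocabulary from here.

``OVERFLOW_LABEL`` is the open catch-all for aberrant patterns that fit no
closed category; overflow records carry a free-text description and each
distinct description counts as its own pattern in richness tallies.
"""

# label -> six-state projection (see mimevo.patterns.PatternState6)
CATEGORY_TO_STATE6 = {
    "uniform black": 1,
    "uniform yellow": 1,
    "uniform orange": 1,
    "uniform red": 1,
    "metallic": 6,
    "pronotum-elytra bicolour": 2,
    "bicoloured elytra (bright base)": 3,
    "bicoloured elytra (reversed)": 3,
    "fasciate": 4,
    "striate": 5,
    "punctate": 6,
    "tricoloured": 6,
    "reticulate": 6,
    "green": 6,
    "green-black": 6,
    "black-amethyst": 6,
    "red-blue": 6,
    "red-green": 6,
    "red pronotum + metallic elytra": 6,
}

CATEGORIES_19 = tuple(CATEGORY_TO_STATE6)

OVERFLOW_LABEL = "non-categorized"

assert len(CATEGORIES_19) == 19, "registry must hold exactly 19 closed categories"
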