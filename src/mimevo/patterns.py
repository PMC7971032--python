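"""Categorical coding of dorsal colour patterns.

Two codings are provided. The fine 19-category descriptive scheme (plus an
open "non-categorized" overflow) records what a specimen looks like; the
coarse six-state scheme is the trait actually reconstructed on the phylogeny:

1. uniform dorsum (black, yellow, orange or red)
2. contrasting pronotum vs elytra (a dark and a bright body part)
3. bicoloured elytra (dark and bright elytral parts)
4. fasciate elytra
5. striate elytra
6. non-categorized (metallic, reticulate, punctate, tricoloured, green,
   rare colour combinations, aberrant forms)

Each specimen is coded independently — intraspecific polymorphism shows up as
different codes for different specimens of one species, and sexually
dimorphic sexes fall in the same six-state class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .pattern_registry import CATEGORIES_19, CATEGORY_TO_STATE6, OVERFLOW_LABEL

__all__ = [
    "ColourationDescriptor",
    "PatternState6",
    "PatternCategory19",
    "classify_six",
    "classify_nineteen",
    "map_19_to_6",
    "pattern_richness",
    "STATE6_LABELS",
    "read_descriptors",
    "write_trait_file",
]

COLOUR_CLASSES = ("black", "red", "orange", "yellow", "metallic", "green", "other")
BRIGHT_COLOURS = frozenset({"red", "orange", "yellow"})
DARK_COLOURS = frozenset({"black"})
ARRANGEMENTS = (
    "uniform",
    "pronotum_vs_elytra",
    "bicoloured_elytra",
    "fasciate",
    "striate",
    "punctate",
    "reticulate",
    "tricoloured",
    "other",
)
ELYTRA_ZONES = (
    "whole",
    "basal",
    "apical",
    "humeral",
    "sutural",
    "fascia",
    "stria",
    "puncta",
    "reticulum-costae",
    "reticulum-cells",
)
ELYTRA_SHAPES = ("normal", "posteriorly_widened", "globuliform")

STATE6_LABELS = {
    1: "uniform dorsum",
    2: "pronotum vs elytra contrast",
    3: "bicoloured elytra",
    4: "fasciate",
    5: "striate",
    6: "non-categorized",
}


@dataclass(frozen=True)
class ColourationDescriptor:
    """Structured description of one specimen's dorsal colouration."""

    specimen_id: str
    pronotum_colour: str
    elytra_zones: tuple  # ordered ((zone, colour_class), ...)
    arrangement: str
    n_distinct_dorsal_colours: int
    elytra_shape: str = "normal"

    def __post_init__(self):
        if self.pronotum_colour not in COLOUR_CLASSES:
            raise ValueError(f"unknown colour class {self.pronotum_colour!r}")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.elytra_shape not in ELYTRA_SHAPES:
            raise ValueError(f"unknown elytra shape {self.elytra_shape!r}")
        for zone, colour in self.elytra_zones:
            if zone not in ELYTRA_ZONES:
                raise ValueError(f"unknown elytra zone {zone!r}")
            if colour not in COLOUR_CLASSES:
                raise ValueError(f"unknown colour class {colour!r}")
        if self.n_distinct_dorsal_colours < 1:
            raise ValueError("n_distinct_dorsal_colours must be >= 1")
        if self.arrangement == "uniform" and self.n_distinct_dorsal_colours != 1:
            raise ValueError("a uniform dorsum has exactly one colour")

    @property
    def elytra_colours(self) -> tuple:
        return tuple(colour for _, colour in self.elytra_zones)


@dataclass(frozen=True)
class PatternState6:
    """One of the six coarse pattern states used for reconstruction."""

    state: int

    def __post_init__(self):
        if self.state not in STATE6_LABELS:
            raise ValueError(f"state must be in 1..6, got {self.state}")

    @property
    def label(self) -> str:
        return STATE6_LABELS[self.state]


@dataclass(frozen=True)
class PatternCategory19:
    """A label from the 19-entry vocabulary, or the overflow label."""

    label: str
    description: str = ""

    def __post_init__(self):
        if self.label not in CATEGORIES_19 and self.label != OVERFLOW_LABEL:
            raise ValueError(f"label {self.label!r} not in the registry")
        if self.label == OVERFLOW_LABEL and not self.description:
            raise ValueError("overflow records need a free-text description")

    @property
    def is_overflow(self) -> bool:
        return self.label == OVERFLOW_LABEL


def _dark_bright_pair(c1: str, c2: str) -> bool:
    """True when the two colours realise a dark/bright body-part contrast."""
    return (c1 in DARK_COLOURS and c2 in BRIGHT_COLOURS) or (
        c1 in BRIGHT_COLOURS and c2 in DARK_COLOURS
    )


def classify_six(d: ColourationDescriptor) -> PatternState6:
    """Total, deterministic projection of a descriptor onto the six states.

    State 1 is reserved for uniform black/yellow/orange/red dorsa; states 2
    and 3 require a genuine dark-vs-bright contrast between the respective
    parts. Everything else — metallic, green or otherwise unusual uniform
    colours, punctate, reticulate, tricoloured, rare combinations — is
    state 6.
    """
    a = d.arrangement
    if a == "uniform":
        colours = set(d.elytra_colours) | {d.pronotum_colour}
        if colours <= (BRIGHT_COLOURS | DARK_COLOURS):
            return PatternState6(1)
        return PatternState6(6)
    if a == "pronotum_vs_elytra":
        elytra = d.elytra_colours[0] if d.elytra_colours else "other"
        if _dark_bright_pair(d.pronotum_colour, elytra):
            return PatternState6(2)
        return PatternState6(6)
    if a == "bicoloured_elytra":
        cols = d.elytra_colours
        if len(cols) >= 2 and _dark_bright_pair(cols[0], cols[1]):
            return PatternState6(3)
        return PatternState6(6)
    if a == "fasciate":
        return PatternState6(4)
    if a == "striate":
        return PatternState6(5)
    return PatternState6(6)


def classify_nineteen(d: ColourationDescriptor) -> PatternCategory19:
    """Assign one 19-way category; unmatched descriptors overflow.

    The rules mirror classify_six and refine it: uniform dorsa split by
    colour, bicoloured elytra split by whether the basal part is the bright
    one, and the named rare combinations get their own labels.
    """
    a = d.arrangement
    pron = d.pronotum_colour
    ely = d.elytra_colours
    dorsal = set(ely) | {pron}

    if a == "uniform":
        if dorsal <= (BRIGHT_COLOURS | DARK_COLOURS):
            return PatternCategory19(f"uniform {pron}")
        if dorsal == {"metallic"}:
            return PatternCategory19("metallic")
        if dorsal == {"green"}:
            return PatternCategory19("green")
        return PatternCategory19(OVERFLOW_LABEL, f"uniform {pron} dorsum")
    if a == "pronotum_vs_elytra":
        ecol = ely[0] if ely else "other"
        if _dark_bright_pair(pron, ecol):
            return PatternCategory19("pronotum-elytra bicolour")
        if pron == "red" and ecol == "metallic":
            return PatternCategory19("red pronotum + metallic elytra")
        return _combination_or_overflow(d, dorsal)
    if a == "bicoloured_elytra":
        if len(ely) >= 2 and _dark_bright_pair(ely[0], ely[1]):
            if ely[0] in BRIGHT_COLOURS:
                return PatternCategory19("bicoloured elytra (bright base)")
            return PatternCategory19("bicoloured elytra (reversed)")
        return _combination_or_overflow(d, dorsal)
    if a == "fasciate":
        return PatternCategory19("fasciate")
    if a == "striate":
        return PatternCategory19("striate")
    if a == "punctate":
        return PatternCategory19("punctate")
    if a == "reticulate":
        return PatternCategory19("reticulate")
    if a == "tricoloured":
        return PatternCategory19("tricoloured")
    return _combination_or_overflow(d, dorsal)


def _combination_or_overflow(d: ColourationDescriptor, dorsal: set) -> PatternCategory19:
    if dorsal == {"green", "black"}:
        return PatternCategory19("green-black")
    if dorsal == {"red", "green"}:
        return PatternCategory19("red-green")
    desc = (
        f"{d.arrangement} arrangement, colours "
        + "/".join(sorted(dorsal))
        + f", {d.n_distinct_dorsal_colours} dorsal colours"
    )
    return PatternCategory19(OVERFLOW_LABEL, desc)


def map_19_to_6(c: PatternCategory19) -> PatternState6:
    """Project a 19-way category (or overflow) onto the six-state coding."""
    if c.is_overflow:
        return PatternState6(6)
    return PatternState6(CATEGORY_TO_STATE6[c.label])


def pattern_richness(labels: Iterable[PatternCategory19]) -> int:
    """Number of distinct patterns in a set of records.

    Closed categories count once each; every distinct overflow description is
    its own pattern (aberrant patterns are individually described, so two
    different descriptions are two patterns).
    """
    closed = set()
    overflow = set()
    for c in labels:
        if c.is_overflow:
            overflow.add(c.description)
        else:
            closed.add(c.label)
    return len(closed) + len(overflow)


# ---------------------------------------------------------------------------
# I/O


def read_descriptors(path) -> list:
    """Read one-row-per-specimen descriptors from CSV.

    Columns: specimen_id, pronotum_colour, elytra_zones (semicolon-joined
    ``zone:colour`` pairs), arrangement, n_distinct_dorsal_colours,
    elytra_shape.
    """
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        zones = tuple(
            tuple(item.split(":")) for item in str(row.elytra_zones).split(";") if item
        )
        out.append(
            ColourationDescriptor(
                specimen_id=str(row.specimen_id),
                pronotum_colour=row.pronotum_colour,
                elytra_zones=zones,
                arrangement=row.arrangement,
                n_distinct_dorsal_colours=int(row.n_distinct_dorsal_colours),
                elytra_shape=getattr(row, "elytra_shape", "normal"),
            )
        )
    return out


def write_trait_file(path, states: dict) -> None:
    """Write a (taxon, state) trait CSV consumable by the Mk machinery."""
    pd.DataFrame(
        {"taxon": list(states), "state": [int(s) for s in states.values()]}
    ).to_csv(path, index=False)
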