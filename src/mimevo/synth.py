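"""Synthetic study generator: trees, traits, specimen images, regional tables.

Every input the analysis pipeline consumes can be generated here with known
ground truth, so each stage is testable without any external data. All
generators are pure functions of a :class:`SimulationRecipe` (seed
included); a JSON-serialisable metadata dict accompanies every artifact so
fixtures are regenerable.

Default sizes are chosen as desk-scale study conditions: 200-tip
birth–death trees scaled to height 1 (so simulated trees are already in
relative time units), a 6-state equal-rates trait, 256×256 two-patch
specimen renders on leaf-coloured backgrounds, and 12-region diversity
tables.
"""

from __future__ import annotations

import random as _random
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np

from .color import BackgroundSet, LabColour, lab_array_from_srgb
from .diversity import RegionalRecord
from .mk import MkModel, simulate_history
from .trees import Phylogeny

__all__ = [
    "TreeRecipe",
    "TraitRecipe",
    "ImageRecipe",
    "RegionalRecipe",
    "SimulationRecipe",
    "gen_tree",
    "gen_trait",
    "render_specimen",
    "gen_regional_table",
    "default_backgrounds",
]


@dataclass(frozen=True)
class TreeRecipe:
    birth_rate: float = 1.0
    death_rate: float = 0.5
    n_tips: int = 200


@dataclass(frozen=True)
class TraitRecipe:
    k: int = 6
    structure: str = "equal_rates"
    rate: float = 0.5
    root_prior: Optional[tuple] = None


# six leaf backgrounds: three leaves x {upper, bottom}, sRGB in [0,1];
# greens of differing lightness emulate the range of real leaf surfaces
DEFAULT_BACKGROUND_SRGB = {
    ("leaf1", "upper"): (0.13, 0.35, 0.11),
    ("leaf1", "bottom"): (0.55, 0.72, 0.45),
    ("leaf2", "upper"): (0.06, 0.22, 0.08),
    ("leaf2", "bottom"): (0.35, 0.50, 0.30),
    ("leaf3", "upper"): (0.45, 0.65, 0.25),
    ("leaf3", "bottom"): (0.70, 0.80, 0.55),
}


@dataclass(frozen=True)
class ImageRecipe:
    bright_srgb: tuple = (0.85, 0.30, 0.05)   # orange-red elytral colour
    dark_srgb: tuple = (0.08, 0.06, 0.06)     # near-black pronotum
    background_key: tuple = ("leaf1", "upper")
    noise_sigma: float = 0.01
    size: int = 256
    window: int = 31
    n_replicates: int = 5


@dataclass(frozen=True)
class RegionalRecipe:
    n_regions: int = 12
    target_correlation: float = 0.6
    species_range: tuple = (20, 1300)
    tribes_range: tuple = (2, 18)
    pattern_base: float = 3.0
    pattern_slope: float = 0.012


@dataclass(frozen=True)
class SimulationRecipe:
    seed: int = 0
    tree: TreeRecipe = field(default_factory=TreeRecipe)
    trait: TraitRecipe = field(default_factory=TraitRecipe)
    image: ImageRecipe = field(default_factory=ImageRecipe)
    regional: RegionalRecipe = field(default_factory=RegionalRecipe)

    def metadata(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Trees


def gen_tree(recipe: SimulationRecipe) -> Phylogeny:
    """Birth–death tree conditioned on the tip count, scaled to height 1.

    Extinct lineages are pruned, so the returned tree is ultrametric; the
    height-1 scaling means node ages are already relative time units.
    """
    tr = recipe.tree
    if tr.n_tips < 2:
        raise ValueError("need at least 2 tips")
    if tr.death_rate < 0 or tr.birth_rate <= tr.death_rate:
        raise ValueError("need birth > death >= 0")
    if tr.n_tips == 2:  # degenerate case: the only shape is a cherry
        return Phylogeny.from_newick("(T0001:1,T0002:1);")
    rng = _random.Random(int(recipe.seed))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=tr.birth_rate,
        death_rate=tr.death_rate,
        num_extant_tips=tr.n_tips,
        rng=rng,
        is_retain_extinct_tips=False,
    )
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1:04d}"
    phylo = Phylogeny(tree)
    return phylo.to_rtu()  # height-1 rescale (tree is ultrametric by construction)


# ---------------------------------------------------------------------------
# Traits


def gen_trait(tree: Phylogeny, recipe: SimulationRecipe):
    """Simulate a trait with its true change history.

    Returns ``(trait_map, changes, model, root_state)``; changes list every simulated
    substitution as (child node index, time along branch, from, to) so
    origin-detection can be scored against the truth.
    """
    tr = recipe.trait
    if tr.structure != "equal_rates":
        raise NotImplementedError("only equal-rates traits are generated")
    model = MkModel.equal_rates(tr.k, tr.rate, root_prior=tr.root_prior)
    traits, changes, root_state = simulate_history(
        tree, model, seed=np.random.SeedSequence([int(recipe.seed), 1])
    )
    return traits, changes, model, root_state


# ---------------------------------------------------------------------------
# Specimen rendering


def default_backgrounds() -> BackgroundSet:
    """The six default leaf backgrounds as Lab colours."""
    entries = {}
    for key, srgb in DEFAULT_BACKGROUND_SRGB.items():
        lab = lab_array_from_srgb(np.array(srgb))
        entries[key] = LabColour(float(lab[0]), float(lab[1]), float(lab[2]))
    return BackgroundSet(entries=entries)


@dataclass
class SpecimenRender:
    """A rendered two-patch specimen with its ground truth."""

    image: np.ndarray                      # float sRGB in [0,1], (H, W, 3)
    truth_lab: Dict[str, LabColour]        # noiseless Lab of each patch + bg
    centres: Dict[str, List[tuple]]        # legal replicate window centres
    window: int
    metadata: dict


def render_specimen(recipe: SimulationRecipe) -> SpecimenRender:
    """Render a two-patch "specimen" over a leaf-coloured background.

    The pronotum occupies the upper third of a central body rectangle and
    the elytra the lower two thirds; additive Gaussian channel noise with
    the recipe's sigma is applied in sRGB. The noiseless Lab of every patch
    and ``n_replicates`` window centres per patch (windows fully inside
    their patch) are emitted as ground truth.
    """
    im = recipe.image
    size = im.size
    half = im.window // 2
    body_w = size // 3
    body_h = (2 * size) // 3
    r0 = (size - body_h) // 2
    c0 = (size - body_w) // 2
    pron_h = body_h // 3
    # patch interiors must host a window plus jitter room
    if pron_h < im.window + 8 or (body_h - pron_h) < im.window + 8:
        raise ValueError("image too small for the requested window layout")

    bg_srgb = np.array(DEFAULT_BACKGROUND_SRGB[im.background_key])
    img = np.empty((size, size, 3))
    img[:] = bg_srgb
    img[r0 : r0 + pron_h, c0 : c0 + body_w] = np.array(im.dark_srgb)
    img[r0 + pron_h : r0 + body_h, c0 : c0 + body_w] = np.array(im.bright_srgb)

    rng = np.random.default_rng(np.random.SeedSequence([int(recipe.seed), 2]))
    if im.noise_sigma > 0:
        img = img + rng.normal(0.0, im.noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)

    def centres_in(ra, rb, ca, cb, n):
        rows = rng.integers(ra + half, rb - half, size=n)
        cols = rng.integers(ca + half, cb - half, size=n)
        return [(int(r), int(c)) for r, c in zip(rows, cols)]

    centres = {
        "dark": centres_in(r0, r0 + pron_h, c0, c0 + body_w, im.n_replicates),
        "bright": centres_in(r0 + pron_h, r0 + body_h, c0, c0 + body_w, im.n_replicates),
        "background": centres_in(0, r0 - 2, 0, size, im.n_replicates),
    }
    for part, (ra, rb, ca, cb) in {
        "dark": (r0, r0 + pron_h, c0, c0 + body_w),
        "bright": (r0 + pron_h, r0 + body_h, c0, c0 + body_w),
        "background": (0, r0 - 2, 0, size),
    }.items():
        for r, c in centres[part]:
            if r - half < ra or r + half >= rb or c - half < ca or c + half >= cb:
                raise ValueError(f"window at ({r},{c}) would leave the {part} patch")

    def lab_of(srgb):
        arr = lab_array_from_srgb(np.asarray(srgb, dtype=float))
        return LabColour(float(arr[0]), float(arr[1]), float(arr[2]))

    truth = {
        "bright": lab_of(im.bright_srgb),
        "dark": lab_of(im.dark_srgb),
        "background": lab_of(bg_srgb),
    }
    meta = {"seed": int(recipe.seed), "image": asdict(im)}
    return SpecimenRender(
        image=img, truth_lab=truth, centres=centres, window=im.window, metadata=meta
    )


def write_specimen_png(render: SpecimenRender, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(render.image, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Regional tables


def gen_regional_table(recipe: SimulationRecipe):
    """Regional diversity table with a controllable species↔pattern link.

    Species counts are log-uniform over the configured range; pattern counts
    follow a linear response with Gaussian noise whose spread is solved from
    the target correlation; tribe counts are drawn independently (pattern
    richness decoupled from phylogenetic diversity, the situation the real
    regional data suggest). Returns ``(records, truth)``; the truth dict
    records the generating parameters and the achieved correlation. An
    unattainable target triggers a warning, not a failure.
    """
    import warnings

    rg = recipe.regional
    if rg.n_regions < 3:
        raise ValueError("need at least 3 regions")
    if not (-1.0 <= rg.target_correlation <= 1.0):
        raise ValueError("target correlation must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(recipe.seed), 3]))
    lo, hi = rg.species_range
    species = np.exp(rng.uniform(np.log(lo), np.log(hi), size=rg.n_regions))
    b = rg.pattern_slope if rg.target_correlation >= 0 else -rg.pattern_slope
    rho = abs(rg.target_correlation)
    signal = b * species
    if rho >= 1.0 - 1e-12:
        sigma = 0.0
    elif rho <= 1e-12:
        b, signal = 0.0, np.zeros_like(species)
        sigma = 2.0
    else:
        sigma = abs(b) * species.std(ddof=1) * np.sqrt(1.0 / rho**2 - 1.0)
    noise = rng.normal(0.0, sigma, size=rg.n_regions) if sigma > 0 else 0.0
    patterns = np.maximum(np.rint(rg.pattern_base + signal + noise), 0).astype(int)
    tribes = rng.integers(rg.tribes_range[0], rg.tribes_range[1] + 1, size=rg.n_regions)
    records = [
        RegionalRecord(
            region=f"region{i + 1:02d}", n_tribes=int(tribes[i]),
            n_species=int(round(species[i])), n_patterns=int(patterns[i]),
        )
        for i in range(rg.n_regions)
    ]
    achieved = float(np.corrcoef([r.n_species for r in records],
                                 [r.n_patterns for r in records])[0, 1])
    if rho > 1e-12 and abs(achieved - rg.target_correlation) > 0.5:
        warnings.warn(
            f"achieved species-pattern correlation {achieved:.2f} far from "
            f"target {rg.target_correlation:.2f}"
        )
    truth = {
        "seed": int(recipe.seed), "slope": b, "base": rg.pattern_base,
        "noise_sigma": float(np.ravel([sigma])[0]),
        "target_correlation": rg.target_correlation,
        "achieved_correlation": achieved,
    }
    return records, truth
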