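"""Device RGB → CIE La*b* conversion and ΔE76 contrast scoring.

Conspicuousness of a warning signal is quantified here in the colour spectrum
visible to humans: specimen and background patch colours are expressed in the
CIE 1976 La*b* space and compared with the Euclidean colour distance ΔE76.
Two contrast classes are distinguished:

* external contrast (EC-ΔE) — a body part against a leaf background, computed
  separately for the upper and bottom leaf surfaces;
* internal contrast (IC-ΔE) — the bright versus the dark part of the dorsum of
  a bicoloured specimen (undefined for uniformly coloured animals).

All conversions assume the sRGB primaries with D65 illuminant and the 2°
standard observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RGBColour",
    "LabColour",
    "PatchSample",
    "BackgroundSet",
    "ContrastProfile",
    "CalibrationTransform",
    "srgb_to_lab",
    "delta_e_76",
    "sample_patch",
    "external_contrast",
    "internal_contrast",
    "fit_calibration",
    "jitter_centres",
]

# sRGB (IEC 61966-2.1) linear RGB -> XYZ, D65 white.
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# D65, 2 deg observer reference white, taken as the matrix row sums so that
# RGB (1,1,1) maps exactly to L=100, a=b=0 (the row sums match the published
# (0.95047, 1, 1.08883) values to 1e-7).
_WHITE_D65 = _M_RGB2XYZ.sum(axis=1)

_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # 1 / (3 * (6/29)^2)


@dataclass(frozen=True)
class RGBColour:
    """A device RGB colour with channels in [0, 1] and an explicit space tag."""

    r: float
    g: float
    b: float
    colour_space: str = "sRGB_gamma"  # or "linear_RGB"

    def __post_init__(self):
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"channel {name}={v} outside [0, 1]")
        if self.colour_space not in ("sRGB_gamma", "linear_RGB"):
            raise ValueError(f"unknown colour space tag {self.colour_space!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


@dataclass(frozen=True)
class LabColour:
    """A point in CIE 1976 La*b* space (L in [0, 100])."""

    L: float
    a: float
    b: float

    def __post_init__(self):
        if not (-1e-9 <= self.L <= 100.0 + 1e-9):
            raise ValueError(f"L={self.L} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


def _srgb_inverse_companding(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _lab_from_linear_rgb_array(rgb_lin: np.ndarray) -> np.ndarray:
    """Vectorised linear RGB (..., 3) -> Lab (..., 3)."""
    xyz = rgb_lin @ _M_RGB2XYZ.T
    fxyz = _f(xyz / _WHITE_D65)
    L = 116.0 * fxyz[..., 1] - 16.0
    a = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    b = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_array_from_srgb(rgb: np.ndarray, companded: bool = True) -> np.ndarray:
    """Convert an (..., 3) array of sRGB values in [0, 1] to La*b*.

    ``companded=True`` applies the standard sRGB inverse companding first;
    ``False`` treats the input as linear RGB.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must have length 3")
    if rgb.min() < -1e-12 or rgb.max() > 1.0 + 1e-12:
        raise ValueError("RGB channels must lie in [0, 1]")
    lin = _srgb_inverse_companding(rgb) if companded else rgb
    return _lab_from_linear_rgb_array(lin)


def srgb_to_lab(colour: RGBColour, white_point: str = "D65_2deg") -> LabColour:
    """Convert one RGB colour to CIE 1976 La*b*.

    The white point is fixed to D65 with the 2° observer (the sRGB standard);
    other white points are not supported.
    """
    if white_point != "D65_2deg":
        raise ValueError("only the D65 2-degree white point is supported")
    lab = lab_array_from_srgb(
        colour.as_array(), companded=(colour.colour_space == "sRGB_gamma")
    )
    return LabColour(float(np.clip(lab[0], 0.0, 100.0)), float(lab[1]), float(lab[2]))


def delta_e_76(c1: LabColour, c2: LabColour) -> float:
    """CIE 1976 colour distance: Euclidean distance in La*b* space."""
    return float(np.linalg.norm(c1.as_array() - c2.as_array()))


# ---------------------------------------------------------------------------
# Patch sampling


@dataclass(frozen=True)
class PatchSample:
    """Mean La*b* of an image region, estimated from replicate windows.

    Each replicate is the per-pixel Lab average of one ``window`` × ``window``
    square; ``mean`` averages the replicate means (replication emulates the
    practice of sampling a body part at several points).
    """

    centres: tuple
    window: int
    replicate_means: tuple
    mean: LabColour


def _image_to_unit_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    if image.dtype == np.uint16:
        return image.astype(float) / 65535.0
    image = image.astype(float)
    if image.min() < -1e-12 or image.max() > 1.0 + 1e-12:
        raise ValueError("float images must already be scaled to [0, 1]")
    return image


def sample_patch(
    image: np.ndarray,
    centres: Sequence[tuple],
    window: int = 31,
) -> PatchSample:
    """Sample replicate windows from an RGB image and average in Lab space.

    Parameters
    ----------
    image
        (H, W, 3) raster; uint8/uint16 are rescaled by the type maximum,
        floats must already lie in [0, 1]. Values are sRGB-companded.
    centres
        Replicate centre pixels as 0-based (row, col) pairs (five by default
        in the sampling design this emulates).
    window
        Odd side length of each square replicate window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    img = _image_to_unit_float(image)
    h, w = img.shape[:2]
    half = window // 2
    reps = []
    for centre in centres:
        r, c = int(centre[0]), int(centre[1])
        if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
            raise ValueError(
                f"window of side {window} at centre ({r}, {c}) is clipped by "
                f"the image border ({h}x{w})"
            )
        block = img[r - half : r + half + 1, c - half : c + half + 1, :]
        lab = lab_array_from_srgb(block).reshape(-1, 3).mean(axis=0)
        reps.append(LabColour(float(lab[0]), float(lab[1]), float(lab[2])))
    mean = np.mean([rep.as_array() for rep in reps], axis=0)
    return PatchSample(
        centres=tuple((int(r), int(c)) for r, c in centres),
        window=window,
        replicate_means=tuple(reps),
        mean=LabColour(float(mean[0]), float(mean[1]), float(mean[2])),
    )


def jitter_centres(
    seed_point: tuple,
    n: int,
    max_offset: int,
    rng: np.random.Generator,
) -> list:
    """Jitter a seed pixel uniformly within ±max_offset to place replicates."""
    r0, c0 = seed_point
    offs = rng.integers(-max_offset, max_offset + 1, size=(n, 2))
    return [(int(r0 + dr), int(c0 + dc)) for dr, dc in offs]


# ---------------------------------------------------------------------------
# Contrast profiles


@dataclass(frozen=True)
class BackgroundSet:
    """Leaf background colours keyed by (leaf_id, side in {upper, bottom}).

    The measurement design this emulates uses three leaves × two sides = six
    backgrounds, but any non-empty set is accepted.
    """

    entries: Mapping[tuple, LabColour]

    def __post_init__(self):
        for key in self.entries:
            leaf_id, side = key
            if side not in ("upper", "bottom"):
                raise ValueError(f"side must be 'upper' or 'bottom', got {side!r}")

    def __len__(self):
        return len(self.entries)

    def items(self):
        return self.entries.items()


@dataclass
class ContrastProfile:
    """EC/IC contrast scores for one specimen.

    ``ec_upper`` and ``ec_bottom`` map (part, leaf_id) → ΔE76 against the
    upper-/bottom-side backgrounds; ``ic`` is the bright–dark internal
    contrast, ``None`` for uniformly coloured specimens.
    """

    specimen_id: str
    ec_upper: dict = field(default_factory=dict)
    ec_bottom: dict = field(default_factory=dict)
    ic: float | None = None


def external_contrast(
    bright: LabColour | None,
    dark: LabColour | None,
    backgrounds: BackgroundSet,
    specimen_id: str = "",
) -> ContrastProfile:
    """ΔE76 of each present body part against every background entry."""
    if bright is None and dark is None:
        raise ValueError("at least one of bright/dark must be present")
    if len(backgrounds) == 0:
        raise ValueError("background set is empty")
    profile = ContrastProfile(specimen_id=specimen_id)
    parts = [(p, c) for p, c in (("bright", bright), ("dark", dark)) if c is not None]
    for (leaf_id, side), bg in backgrounds.items():
        target = profile.ec_upper if side == "upper" else profile.ec_bottom
        for part, colour in parts:
            target[(part, leaf_id)] = delta_e_76(colour, bg)
    return profile


def internal_contrast(bright: LabColour, dark: LabColour) -> float:
    """Internal contrast (IC-ΔE) between the bright and dark dorsal parts."""
    if bright is None or dark is None:
        raise ValueError("internal contrast is undefined for uniform specimens")
    return delta_e_76(bright, dark)


# ---------------------------------------------------------------------------
# Linear calibration


@dataclass(frozen=True)
class CalibrationTransform:
    """Affine map on linear RGB fitted from measured/reference patch pairs."""

    matrix: np.ndarray
    offset: np.ndarray
    fit_residual: float

    def apply(self, rgb: np.ndarray) -> np.ndarray:
        rgb = np.asarray(rgb, dtype=float)
        return rgb @ self.matrix.T + self.offset


def fit_calibration(
    measured: Iterable[RGBColour],
    reference: Iterable[RGBColour],
) -> CalibrationTransform:
    """Least-squares affine calibration in linear RGB.

    Fits reference ≈ matrix @ measured + offset over ≥4 patch pairs and
    reports the RMS residual. Both colour lists must be tagged linear_RGB.
    """
    meas = list(measured)
    ref = list(reference)
    if len(meas) != len(ref):
        raise ValueError("measured and reference lists differ in length")
    if len(meas) < 4:
        raise ValueError("calibration needs at least 4 patch pairs")
    for c in meas + ref:
        if c.colour_space != "linear_RGB":
            raise ValueError("calibration colours must be in linear RGB")
    X = np.array([c.as_array() for c in meas])
    Y = np.array([c.as_array() for c in ref])
    design = np.hstack([X, np.ones((len(meas), 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("rank-deficient calibration design")
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    resid = Y - (X @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationTransform(matrix=matrix, offset=offset, fit_residual=rms)
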