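"""Sublingual-vein (SV) colour and morphology quantification.

Colour: per-pixel sRGB → CIELAB conversion (decompanding → XYZ → Lab
against a configurable reference white, D65 by default) and region means
over a segmentation mask, yielding the SV-L / SV-a / SV-b features
(lightness, red–green axis, yellow–blue axis).

Morphology: image measurements arrive in pixels and are converted to mm
with the instrument's experimentally determined scale of 1/177.171
mm per pixel.  Grades follow the clinical criteria:

* trunk length — mean of the left/right trunk lengths (a1, a2) relative
  to the sublingual-caruncle-to-tongue-tip distance b; grade 2 when the
  ratio is approximately 3/5 (within a configurable tolerance), grade 1
  below, grade 3 above;
* width — W1 below 3 mm, W2 in [3, 4] mm, W3 above 4 mm;
* tortuosity — expert-coded: two primary raters, with a third
  gold-standard rater adjudicating only on disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color as skcolor

__all__ = [
    "PIXELS_PER_MM",
    "RaterSet",
    "SVRecord",
    "rgb_to_lab",
    "mean_sv_color",
    "pixels_to_mm",
    "trunk_length_grade",
    "width_grade",
    "adjudicate_tortuosity",
]

PIXELS_PER_MM = 177.171
TORTUOSITY_GRADES = ("T1", "T2", "T3")


def rgb_to_lab(r: float, g: float, b: float, white: str = "D65") -> tuple[float, float, float]:
    """Convert one 8-bit sRGB triplet to CIELAB.

    ``white`` selects the reference white for the XYZ → Lab stage
    ("D65" or "D50").  Pure white maps to (100, 0, 0), black to (0, 0, 0),
    and every grey to a = b = 0.
    """
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0 <= v <= 255:
            raise ValueError(f"channel {name}={v} outside 0–255")
    arr = np.array([[[r, g, b]]], dtype=float) / 255.0
    lab = skcolor.rgb2lab(arr, illuminant=white)
    return tuple(float(v) for v in lab[0, 0])


def mean_sv_color(
    image: np.ndarray | str | Path,
    mask: np.ndarray | str | Path,
    white: str = "D65",
) -> tuple[float, float, float]:
    """Mean Lab triplet (SV-L, SV-a, SV-b) over a masked pixel region.

    ``image`` is an H×W×3 8-bit RGB array or a PNG path; ``mask`` is a
    boolean/0-1 array (or single-channel PNG) of the same height/width.
    Conversion is per pixel, then channel means are taken.
    """
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        image = iio.imread(image)
    if isinstance(mask, (str, Path)):
        import imageio.v3 as iio

        mask = iio.imread(mask)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be H×W×3 RGB")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty mask: no SV pixels selected")
    lab = skcolor.rgb2lab(image[..., :3].astype(float) / 255.0, illuminant=white)
    mean = lab[mask].mean(axis=0)
    return tuple(float(v) for v in mean)


def pixels_to_mm(px: float, pixels_per_mm: float = PIXELS_PER_MM) -> float:
    """Convert a pixel measurement to mm (mm = px / 177.171 by default)."""
    if px < 0:
        raise ValueError("pixel length must be non-negative")
    return px / pixels_per_mm


def trunk_length_grade(a1: float, a2: float, b_len: float, tol: float = 0.02) -> str:
    """Trunk-length grade from the mean trunk length relative to 3/5·b.

    ``tol`` is the half-width of the "approximately 3/5" band on the
    ratio (a1+a2)/(2·b); symmetric in a1 and a2.
    """
    if b_len <= 0:
        raise ValueError("caruncle-to-tip length b must be positive")
    if a1 < 0 or a2 < 0:
        raise ValueError("trunk lengths must be non-negative")
    ratio = (a1 + a2) / 2.0 / b_len
    if abs(ratio - 0.6) <= tol:
        return "L2"
    return "L1" if ratio < 0.6 else "L3"


def width_grade(width_mm: float) -> str:
    """Width grade: W1 < 3 mm, W2 in [3, 4] mm, W3 > 4 mm."""
    if width_mm < 0:
        raise ValueError("width must be non-negative")
    if width_mm < 3.0:
        return "W1"
    return "W2" if width_mm <= 4.0 else "W3"


@dataclass(frozen=True)
class RaterSet:
    """Tortuosity grades from the two primary raters plus the optional
    gold-standard third rater (required whenever the first two disagree)."""

    rater1: str
    rater2: str
    rater3: str | None = None

    def __post_init__(self) -> None:
        for g in (self.rater1, self.rater2) + ((self.rater3,) if self.rater3 else ()):
            if g not in TORTUOSITY_GRADES:
                raise ValueError(f"unknown tortuosity grade {g!r}")


def adjudicate_tortuosity(raters: RaterSet) -> str:
    """Consensus tortuosity grade: rater agreement, else the third rater."""
    if raters.rater1 == raters.rater2:
        return raters.rater1
    if raters.rater3 is None:
        raise ValueError("raters disagree and no third-rater grade is available")
    return raters.rater3


@dataclass
class SVRecord:
    """One subject's quantified SV features (colour in Lab, lengths in mm)."""

    sv_l: float
    sv_a: float
    sv_b: float
    a1: float
    a2: float
    b_len: float
    width_mm: float
    tortuosity: str
    trunk_grade: str = ""
    width_grade: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.sv_l <= 100:
            raise ValueError("SV-L must lie in [0, 100]")
        if min(self.a1, self.a2, self.b_len, self.width_mm) < 0:
            raise ValueError("lengths must be non-negative")
        if not self.trunk_grade:
            self.trunk_grade = trunk_length_grade(self.a1, self.a2, self.b_len)
        if not self.width_grade:
            self.width_grade = width_grade(self.width_mm)
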