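"""Six-point pheomelanin color scale.

Coat pheomelanin intensity in dogs ranges from cream/white (e.g. Samoyed)
to deep red (e.g. Irish Setter).  Phenotyping uses an ordinal 1..n scale
whose levels are color swatches interpolated between a small set of anchor
colors (cream, tan, red).  This module builds that scale, maps an observed
RGB color to its nearest swatch, and z-standardizes phenotype vectors for
the analyses that operate on a normalized scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColorScale",
    "DEFAULT_ANCHORS",
    "assign_intensity",
    "build_color_scale",
    "destandardize_phenotype",
    "hex_to_rgb",
    "rgb_to_hex",
    "standardize_phenotype",
]

#: Cream, tan and red anchor shades spanning canine pheomelanin intensity.
DEFAULT_ANCHORS = ("#FFFEF9", "#D3A467", "#93471A")

_HEX_RE = re.compile(r"\A#?([0-9A-Fa-f]{6})\Z")


def hex_to_rgb(color: str) -> tuple[int, int, int]:
    """Parse ``#RRGGBB`` (leading ``#`` optional) into an (R, G, B) tuple."""
    m = _HEX_RE.match(color.strip())
    if m is None:
        raise ValueError(f"invalid hex color: {color!r}")
    h = m.group(1)
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))


def rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    """Format an (R, G, B) tuple as uppercase ``#RRGGBB``."""
    r, g, b = (int(c) for c in rgb)
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError(f"RGB channel out of range: {rgb}")
    return f"#{r:02X}{g:02X}{b:02X}"


def _round_half_away(x: float) -> int:
    """Round half away from zero (190.6 -> 191, 0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ColorScale:
    """Ordered color swatches with ordinal values ``1..n``.

    ``anchors`` are the colors the scale was interpolated between; the first
    and last swatch always coincide with the first and last anchor.
    """

    anchors: tuple[str, ...]
    swatches: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.swatches[0] != self.anchors[0] or self.swatches[-1] != self.anchors[-1]:
            raise ValueError("scale endpoints must equal the first/last anchor")

    @property
    def n(self) -> int:
        return len(self.swatches)

    def swatch_rgb(self) -> np.ndarray:
        """(n, 3) float array of swatch RGB values."""
        return np.array([hex_to_rgb(s) for s in self.swatches], dtype=float)


def build_color_scale(anchors=DEFAULT_ANCHORS, n: int = 6) -> ColorScale:
    """Interpolate ``n`` equally spaced swatches through the anchor colors.

    Anchors are placed at equally spaced positions in [0, 1]; each RGB
    channel is interpolated piecewise-linearly between consecutive anchors;
    the scale samples the interpolant at ``n`` equally spaced positions and
    rounds each channel half away from zero.  With the default cream/tan/red
    anchors and ``n=6`` this yields the canonical six-point swatch set
    #FFFEF9, #EDDABF, #DCB684, #C69158, #AD6C39, #93471A.
    """
    anchors = tuple(anchors)
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchor colors")
    if n < 2:
        raise ValueError("need at least 2 swatches")
    anchor_rgb = np.array([hex_to_rgb(a) for a in anchors], dtype=float)
    positions = np.linspace(0.0, 1.0, len(anchors))
    samples = np.linspace(0.0, 1.0, n)
    swatches = []
    for t in samples:
        channels = tuple(
            _round_half_away(float(np.interp(t, positions, anchor_rgb[:, c])))
            for c in range(3)
        )
        swatches.append(rgb_to_hex(channels))
    # canonicalize anchors to uppercase-# form so endpoint invariant is textual
    canon = tuple(rgb_to_hex(hex_to_rgb(a)) for a in anchors)
    return ColorScale(anchors=canon, swatches=tuple(swatches))


def assign_intensity(rgb, scale: ColorScale) -> int:
    """Ordinal (1-based) of the swatch nearest to ``rgb`` in Euclidean RGB space.

    Ties go to the lower ordinal.  This is the computational stand-in for a
    human rater matching a coat patch against the printed swatch strip.
    """
    if isinstance(rgb, str):
        rgb = hex_to_rgb(rgb)
    target = np.asarray(rgb, dtype=float)
    if target.shape != (3,):
        raise ValueError("rgb must be a 3-channel color")
    d2 = ((scale.swatch_rgb() - target) ** 2).sum(axis=1)
    return int(np.argmin(d2)) + 1  # argmin takes the first (lowest) on ties


def standardize_phenotype(values) -> tuple[np.ndarray, float, float]:
    """Z-score a phenotype vector: returns ``(z, mean, sd)``.

    Uses the population standard deviation (ddof=0).  A constant vector has
    no scale and raises ``ValueError``.
    """
    v = np.asarray(values, dtype=float)
    mu = float(v.mean())
    sd = float(v.std(ddof=0))
    if sd == 0.0:
        raise ValueError("cannot standardize a constant phenotype vector")
    return (v - mu) / sd, mu, sd


def destandardize_phenotype(z, mean: float, sd: float) -> np.ndarray:
    """Inverse of :func:`standardize_phenotype`."""
    return np.asarray(z, dtype=float) * sd + mean
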