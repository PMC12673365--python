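"""Color representations and the CIEDE2000 perceptual color difference.

Every statistic in the pipeline ultimately consumes one of three spaces:

* sRGB 8-bit — what an online color picker delivers;
* HSL — hue/saturation/lightness, the observables the correlation analysis
  uses (hue in degrees, s and l in [0, 1]);
* CIELAB (D65, 2° observer) — the approximately perceptually uniform space
  in which CIEDE2000 is defined.

Picker colors are assumed sRGB under D65, the web default. The ΔE metric is
the full CIEDE2000 formula with unit parametric factors (kL = kC = kH = 1),
including the chroma-dependent G correction, the hue weighting function T and
the blue-region rotation term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColorRGB",
    "ColorHSL",
    "ColorLab",
    "rgb_to_hsl",
    "hsl_to_rgb",
    "srgb_to_lab",
    "rgb_to_hex",
    "hex_to_rgb",
    "delta_e_ciede2000",
]

# sRGB -> XYZ (D65) matrix, IEC 61966-2-1
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_D65 = np.array([0.95047, 1.00000, 1.08883])


@dataclass(frozen=True)
class ColorRGB:
    """8-bit sRGB triple as delivered by a color selection field."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"channel {name}={v} outside 0..255")


@dataclass(frozen=True)
class ColorHSL:
    """Hue (degrees, wraps mod 360), saturation and lightness in [0, 1].

    Achromatic colors (s == 0) have no defined hue; ``hue_defined`` is False
    and ``h`` is set to 0.0 by convention but must not enter statistics.
    """

    h: float
    s: float
    l: float
    hue_defined: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", float(self.h) % 360.0)
        object.__setattr__(self, "s", min(1.0, max(0.0, float(self.s))))
        object.__setattr__(self, "l", min(1.0, max(0.0, float(self.l))))
        if self.s == 0.0:
            object.__setattr__(self, "hue_defined", False)
            object.__setattr__(self, "h", 0.0)


@dataclass(frozen=True)
class ColorLab:
    """CIELAB coordinates: L in [0, 100]; a, b opponent axes."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.L <= 100.0 + 1e-9):
            raise ValueError(f"L={self.L} outside [0, 100]")


def rgb_to_hsl(c: ColorRGB) -> ColorHSL:
    """Standard sRGB -> HSL mapping (hexcone model)."""
    r, g, b = c.r / 255.0, c.g / 255.0, c.b / 255.0
    mx, mn = max(r, g, b), min(r, g, b)
    l = (mx + mn) / 2.0
    if mx == mn:
        return ColorHSL(0.0, 0.0, l, hue_defined=False)
    d = mx - mn
    s = d / (2.0 - mx - mn) if l > 0.5 else d / (mx + mn)
    if mx == r:
        h = ((g - b) / d) % 6.0
    elif mx == g:
        h = (b - r) / d + 2.0
    else:
        h = (r - g) / d + 4.0
    return ColorHSL(60.0 * h, s, l)


def hsl_to_rgb(c: ColorHSL) -> ColorRGB:
    """Inverse of :func:`rgb_to_hsl`; round-trips within 1/255 per channel."""
    if c.s == 0.0:
        v = int(round(c.l * 255.0))
        return ColorRGB(v, v, v)
    q = c.l * (1.0 + c.s) if c.l < 0.5 else c.l + c.s - c.l * c.s
    p = 2.0 * c.l - q

    def hue2rgb(t: float) -> float:
        t %= 1.0
        if t < 1 / 6:
            return p + (q - p) * 6.0 * t
        if t < 1 / 2:
            return q
        if t < 2 / 3:
            return p + (q - p) * (2 / 3 - t) * 6.0
        return p

    h = c.h / 360.0
    return ColorRGB(
        int(round(255.0 * hue2rgb(h + 1 / 3))),
        int(round(255.0 * hue2rgb(h))),
        int(round(255.0 * hue2rgb(h - 1 / 3))),
    )


def _srgb_decode(u: np.ndarray) -> np.ndarray:
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def srgb_to_lab(c: ColorRGB) -> ColorLab:
    """sRGB (gamma per IEC 61966-2-1) -> XYZ (D65) -> CIELAB."""
    rgb = np.array([c.r, c.g, c.b], dtype=float) / 255.0
    xyz = _M_RGB2XYZ @ _srgb_decode(rgb)
    t = xyz / _WHITE_D65
    eps = (6.0 / 29.0) ** 3
    f = np.where(t > eps, np.cbrt(t), t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
    L = 116.0 * f[1] - 16.0
    return ColorLab(float(np.clip(L, 0.0, 100.0)), float(500.0 * (f[0] - f[1])), float(200.0 * (f[1] - f[2])))


def lab_to_srgb(lab: ColorLab, clamp: bool = True) -> ColorRGB:
    """CIELAB -> sRGB. Out-of-gamut values are clamped channel-wise."""
    fy = (lab.L + 16.0) / 116.0
    fx = fy + lab.a / 500.0
    fz = fy - lab.b / 200.0
    delta = 6.0 / 29.0

    def finv(u: float) -> float:
        return u**3 if u > delta else 3.0 * delta**2 * (u - 4.0 / 29.0)

    xyz = _WHITE_D65 * np.array([finv(fx), finv(fy), finv(fz)])
    rgb_lin = np.linalg.solve(_M_RGB2XYZ, xyz)
    rgb = np.where(
        rgb_lin <= 0.0031308, 12.92 * rgb_lin, 1.055 * np.clip(rgb_lin, 0.0, None) ** (1 / 2.4) - 0.055
    )
    if not clamp and (rgb.min() < -1e-6 or rgb.max() > 1.0 + 1e-6):
        raise ValueError("Lab color outside sRGB gamut")
    rgb = np.clip(rgb, 0.0, 1.0)
    return ColorRGB(*(int(round(255.0 * v)) for v in rgb))


def rgb_to_hex(c: ColorRGB) -> str:
    return f"#{c.r:02X}{c.g:02X}{c.b:02X}"


def hex_to_rgb(s: str) -> ColorRGB:
    s = s.lstrip("#")
    if len(s) != 6:
        raise ValueError(f"not a #RRGGBB hex color: {s!r}")
    return ColorRGB(int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))


def delta_e_ciede2000(c1: ColorLab, c2: ColorLab) -> float:
    """CIEDE2000 color difference with kL = kC = kH = 1.

    Symmetric in its arguments; 0 exactly iff the inputs are identical. A
    just-noticeable difference is ~1 ΔE; the consistency scoring treats
    ≥16 ΔE as "no longer the same color".
    """
    L1, a1, b1 = c1.L, c1.a, c1.b
    L2, a2, b2 = c2.L, c2.a, c2.b

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - math.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    h1p = math.degrees(math.atan2(b1, a1p)) % 360.0 if (a1p != 0.0 or b1 != 0.0) else 0.0
    h2p = math.degrees(math.atan2(b2, a2p)) % 360.0 if (a2p != 0.0 or b2 != 0.0) else 0.0

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180.0:
            dhp -= 360.0
        elif dhp < -180.0:
            dhp += 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbp = h1p + h2p
    else:
        hsum = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hbp = 0.5 * hsum
        elif hsum < 360.0:
            hbp = 0.5 * (hsum + 360.0)
        else:
            hbp = 0.5 * (hsum - 360.0)

    T = (
        1.0
        - 0.17 * math.cos(math.radians(hbp - 30.0))
        + 0.24 * math.cos(math.radians(2.0 * hbp))
        + 0.32 * math.cos(math.radians(3.0 * hbp + 6.0))
        - 0.20 * math.cos(math.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * math.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cbp7 = Cbp**7
    RC = 2.0 * math.sqrt(cbp7 / (cbp7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / math.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -math.sin(math.radians(2.0 * dtheta)) * RC

    return math.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
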