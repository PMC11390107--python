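"""Color-space conversions, the CIEDE2000 color difference, and
severity-parameterized deuteranopia simulation.

The simulation uses the Machado et al. physiologically-based transfer
matrices for deutan color-vision deficiency, published at severity steps of
0.1 between 0 (normal trichromacy, identity) and 1 (complete deuteranopia).
Intermediate severities are linearly interpolated between adjacent steps,
which is the convention of the R ``colorspace`` simulation tools.

By default the matrix is applied to gamma-encoded sRGB channel values,
matching the operational behavior of the simulation packages common in
figure-accessibility work; applying it to linearized RGB is available via
``linear_rgb=True``.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from skimage.color import rgb2lab

if TYPE_CHECKING:  # pragma: no cover
    from .image import RasterImage

__all__ = [
    "DEUTAN_SEVERITY_STEP_MATRICES",
    "srgb_to_lab",
    "delta_e_2000",
    "deutan_matrix",
    "apply_deutan",
    "simulate_deutan",
    "is_achromatic",
    "srgb_to_linear",
    "linear_to_srgb",
]

#: Machado et al. deuteranomaly matrices, severity 0.0 to 1.0 in 0.1 steps.
#: Row-stochastic (each row sums to 1), so grays map to grays.
DEUTAN_SEVERITY_STEP_MATRICES: np.ndarray = np.array(
    [
        [[1.000000, 0.000000, -0.000000],
         [0.000000, 1.000000, 0.000000],
         [-0.000000, -0.000000, 1.000000]],
        [[0.866435, 0.177704, -0.044139],
         [0.049567, 0.939063, 0.011370],
         [-0.003453, 0.007233, 0.996220]],
        [[0.760729, 0.319078, -0.079807],
         [0.090568, 0.889315, 0.020117],
         [-0.006027, 0.013325, 0.992702]],
        [[0.675425, 0.433850, -0.109275],
         [0.125303, 0.847755, 0.026942],
         [-0.007950, 0.018572, 0.989378]],
        [[0.605511, 0.528560, -0.134071],
         [0.155318, 0.812366, 0.032316],
         [-0.009376, 0.023176, 0.986200]],
        [[0.547494, 0.607765, -0.155259],
         [0.181692, 0.781742, 0.036566],
         [-0.010410, 0.027275, 0.983136]],
        [[0.498864, 0.674741, -0.173604],
         [0.205199, 0.754872, 0.039929],
         [-0.011131, 0.030969, 0.980162]],
        [[0.457771, 0.731899, -0.189670],
         [0.226409, 0.731012, 0.042579],
         [-0.011595, 0.034333, 0.977261]],
        [[0.422823, 0.781057, -0.203881],
         [0.245752, 0.709602, 0.044646],
         [-0.011843, 0.037423, 0.974421]],
        [[0.392952, 0.823610, -0.216562],
         [0.263559, 0.690210, 0.046232],
         [-0.011910, 0.040281, 0.971630]],
        [[0.367322, 0.860646, -0.227968],
         [0.280085, 0.672501, 0.047413],
         [-0.011820, 0.042940, 0.968881]],
    ],
    dtype=np.float64,
)


def srgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert gamma-encoded sRGB (unit range) to CIE L*a*b*.

    D65 white point, 2 degree observer, via linearized sRGB -> XYZ -> Lab.
    Accepts any array whose last axis has length 3.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must have length 3 (R, G, B)")
    return rgb2lab(rgb)


def srgb_to_linear(c: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer function (gamma decode)."""
    c = np.asarray(c, dtype=np.float64)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(c: np.ndarray) -> np.ndarray:
    """Inverse sRGB transfer function (gamma encode)."""
    c = np.asarray(c, dtype=np.float64)
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, c * 12.92, 1.055 * c ** (1 / 2.4) - 0.055)


def delta_e_2000(
    lab1: np.ndarray,
    lab2: np.ndarray,
    kL: float = 1.0,
    kC: float = 1.0,
    kH: float = 1.0,
) -> np.ndarray | float:
    """CIEDE2000 color difference between Lab colors.

    Symmetric, zero iff the inputs are identical, and not a true metric
    (the triangle inequality can fail).  Parametric weights default to 1.
    Broadcasts over leading axes; the last axis is (L*, a*, b*).
    """
    lab1 = np.asarray(lab1, dtype=np.float64)
    lab2 = np.asarray(lab2, dtype=np.float64)
    scalar = lab1.ndim == 1 and lab2.ndim == 1
    L1, a1, b1 = np.moveaxis(np.atleast_2d(lab1), -1, 0)
    L2, a2, b2 = np.moveaxis(np.atleast_2d(lab2), -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0.0, 0.0, h1p)
    h2p = np.where(C2p == 0.0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    rad = np.radians
    T = (
        1.0
        - 0.17 * np.cos(rad(hbp - 30.0))
        + 0.24 * np.cos(rad(2.0 * hbp))
        + 0.32 * np.cos(rad(3.0 * hbp + 6.0))
        - 0.20 * np.cos(rad(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cbp7 = Cbp**7
    RC = 2.0 * np.sqrt(cbp7 / (cbp7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(rad(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    dE = np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
    return float(dE[0]) if scalar else dE.reshape(np.broadcast(lab1[..., 0], lab2[..., 0]).shape)


def deutan_matrix(severity: float) -> np.ndarray:
    """Deutan simulation matrix at the given severity in [0, 1].

    Severities between the published 0.1 steps are linearly interpolated
    between the two adjacent matrices.  Severity 0 is the identity.
    """
    severity = float(severity)
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    pos = severity * 10.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, 10)
    frac = pos - lo
    return (1.0 - frac) * DEUTAN_SEVERITY_STEP_MATRICES[lo] + frac * DEUTAN_SEVERITY_STEP_MATRICES[hi]


def apply_deutan(rgb: np.ndarray, severity: float, linear_rgb: bool = False) -> np.ndarray:
    """Apply the deutan matrix to an array of sRGB colors (unit range).

    ``linear_rgb=False`` (default) multiplies the gamma-encoded values
    directly; ``True`` decodes to linear RGB first and re-encodes after.
    Out-of-gamut results are clipped to [0, 1].
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    m = deutan_matrix(severity)
    if linear_rgb:
        out = linear_to_srgb(srgb_to_linear(rgb) @ m.T)
    else:
        out = rgb @ m.T
    return np.clip(out, 0.0, 1.0)


def simulate_deutan(img: "RasterImage", severity: float = 0.8, linear_rgb: bool = False) -> "RasterImage":
    """Simulate deuteranopia on an image; output has the input's dimensions."""
    from .image import RasterImage

    if img.pixels.size == 0:
        raise ValueError("cannot simulate an empty image")
    out = apply_deutan(img.pixels, severity, linear_rgb=linear_rgb)
    return RasterImage(
        pixels=out.astype(np.float32),
        source_id=f"{img.source_id}|deutan{severity:g}",
    )


def is_achromatic(rgb: np.ndarray, spread_tol: float = 10.0) -> np.ndarray | bool:
    """True where a color is black/white/gray: max pairwise channel
    difference at most ``spread_tol``, expressed in 8-bit units."""
    if spread_tol < 0:
        raise ValueError("spread_tol must be non-negative")
    rgb = np.asarray(rgb, dtype=np.float64)
    scalar = rgb.ndim == 1
    v = np.atleast_2d(rgb) * 255.0
    spread = v.max(axis=-1) - v.min(axis=-1)
    out = spread <= spread_tol
    return bool(out[0]) if scalar else out
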