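"""Minimal transmissive-light colorimetry: spectra -> CIE XYZ -> sRGB.

Used to render multi-band transmittance cubes into displayable sRGB
images under CIE standard illuminant D65.  The CIE 1931 2-degree
color-matching functions are evaluated from the published multi-lobe
Gaussian fits (Wyman, Sloan & Shirley, JCGT 2013), which reproduce the
tabulated observer to within about one percent; the D65 spectral power
distribution is linearly interpolated from the standard 10 nm table.
Rendering is normalized so that unit transmittance maps exactly to the
display white point, which makes the output invariant to uniform
rescaling of incident and transmitted intensities.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cie_1931_cmf",
    "d65_spd",
    "XYZ_TO_LINEAR_SRGB",
    "srgb_encode",
    "transmittance_to_srgb",
]

# CIE standard illuminant D65, relative spectral power, 380-780 nm @ 10 nm.
_D65_WL = np.arange(380.0, 781.0, 10.0)
_D65_SPD = np.array([
    49.98, 54.65, 82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81,
    114.86, 115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41,
    104.05, 100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29,
    83.70, 80.03, 80.21, 82.28, 78.28, 69.72, 71.61, 74.35, 61.60,
    69.89, 75.09, 63.59, 46.42, 66.81, 63.38,
])

# Rec. 709 primaries / D65 white, the standard sRGB matrix.
XYZ_TO_LINEAR_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def _lobe(wl: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    """Piecewise Gaussian with separate left/right widths."""
    s = np.where(wl < mu, s1, s2)
    return np.exp(-0.5 * ((wl - mu) / s) ** 2)


def cie_1931_cmf(wavelengths_nm: np.ndarray) -> np.ndarray:
    """CIE 1931 2-degree color-matching functions, shape (len(wl), 3)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = (
        1.056 * _lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _lobe(wl, 530.9, 16.3, 31.1)
    z = 1.217 * _lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _lobe(wl, 459.0, 26.0, 13.8)
    return np.clip(np.stack([x, y, z], axis=-1), 0.0, None)


def d65_spd(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Relative D65 spectral power at the given wavelengths (nm)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.min() < _D65_WL[0] or wl.max() > _D65_WL[-1]:
        raise ValueError(
            f"wavelengths must lie within [{_D65_WL[0]:.0f}, {_D65_WL[-1]:.0f}] nm"
        )
    return np.interp(wl, _D65_WL, _D65_SPD)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Standard sRGB transfer function on linear values in [0, 1]."""
    linear = np.clip(linear, 0.0, 1.0)
    lo = 12.92 * linear
    hi = 1.055 * np.power(np.maximum(linear, 1e-12), 1.0 / 2.4) - 0.055
    return np.where(linear <= 0.0031308, lo, hi)


def transmittance_to_srgb(transmittance: np.ndarray, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Render per-band transmittance to sRGB in [0, 1].

    Parameters
    ----------
    transmittance : (M, n) array of spectral transmittance values.
    wavelengths_nm : (M,) strictly increasing band centers.

    Returns
    -------
    (3, n) array of gamma-encoded sRGB values in [0, 1].  Unit
    transmittance maps exactly to (1, 1, 1): the linear RGB of every
    pixel is divided channelwise by the linear RGB of the illuminant.
    """
    t = np.asarray(transmittance, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if t.ndim != 2 or t.shape[0] != wl.size:
        raise ValueError("transmittance must be (M, n) matching wavelengths")
    if wl.size < 2:
        raise ValueError("at least 2 spectral bands are required")
    weights = d65_spd(wl)[:, None] * cie_1931_cmf(wl)  # (M, 3)
    xyz = weights.T @ t  # (3, n)
    linear = XYZ_TO_LINEAR_SRGB @ xyz
    white = XYZ_TO_LINEAR_SRGB @ weights.sum(axis=0)
    if np.any(white <= 0):
        raise ValueError("degenerate wavelength support: white point non-positive")
    linear /= white[:, None]
    return srgb_encode(linear)
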