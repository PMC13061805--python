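"""Evaluation metrics and MS/RGB abundance calibration.

RGB and multispectral unmixing express dye amount on different scales
(their stain matrices are normalized over different channel counts), so
quantitative comparison needs a per-dye calibration factor.  On a
single-stain sample the per-pixel abundance reduces to a one-variable
least-squares fit against the dye's coefficient vector, and the
calibration coefficient p is the least-squares scale between the RGB
and MS abundance vectors.  Reference values (robust per-dye maxima)
map abundances into [0, 1] for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .unmix import AbundanceMap

__all__ = [
    "CalibrationCoefficients",
    "ReferenceValues",
    "single_stain_abundance",
    "calibration_coefficient",
    "reference_values",
    "normalize_abundance",
    "sre_db",
    "rmse",
]


@dataclass
class CalibrationCoefficients:
    """Per-dye scale factors p mapping RGB abundances onto the MS scale."""

    p: np.ndarray
    dye_names: tuple[str, ...] = ("EY", "H", "LG", "OG")

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        if not np.all(np.isfinite(self.p)):
            raise ValueError("calibration coefficients must be finite")


@dataclass
class ReferenceValues:
    """Per-dye robust maxima q used to normalize abundances to [0, 1]."""

    q: np.ndarray
    percentile: float = 99.0
    dye_names: tuple[str, ...] = ("EY", "H", "LG", "OG")

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        if np.any(self.q <= 0):
            raise ValueError("reference values must be strictly positive")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def single_stain_abundance(Y_single: np.ndarray, coeff: np.ndarray) -> np.ndarray:
    """Per-pixel abundance of a single-stain sample.

    With one dye present, y_j = coeff * s_j; the least-squares scalar is
    s_j = (coeff . y_j) / (coeff . coeff).
    """
    coeff = np.asarray(coeff, dtype=float).ravel()
    denom = float(coeff @ coeff)
    if denom == 0:
        raise ValueError("coefficient vector must be nonzero")
    Y = np.asarray(Y_single, dtype=float)
    if Y.shape[0] != coeff.size:
        raise ValueError("channel count mismatch")
    return coeff @ Y / denom


def calibration_coefficient(s_rgb: np.ndarray, s_ms: np.ndarray) -> float:
    """Least-squares scale p minimizing sum (p * s_rgb - s_ms)^2."""
    s_rgb = np.asarray(s_rgb, dtype=float).ravel()
    s_ms = np.asarray(s_ms, dtype=float).ravel()
    if s_rgb.size != s_ms.size:
        raise ValueError("abundance vectors must have the same length")
    denom = float(s_rgb @ s_rgb)
    if denom == 0:
        raise ValueError("RGB abundance vector is identically zero")
    return float(s_rgb @ s_ms / denom)


def reference_values(X: AbundanceMap, percentile: float = 99.0) -> ReferenceValues:
    """Robust per-dye maxima: the given percentile of each dye's abundances.

    Uses the linear-interpolation percentile convention.  A degenerate
    all-zero dye is floored at machine epsilon with a warning.
    """
    if X.n_pixels == 0:
        raise ValueError("empty abundance map")
    q = np.percentile(X.values, percentile, axis=1, method="linear")
    if np.any(q <= 0):
        warnings.warn(
            "degenerate dye with nonpositive reference; flooring at machine epsilon",
            stacklevel=2,
        )
        q = np.maximum(q, np.finfo(float).eps)
    return ReferenceValues(q=q, percentile=percentile, dye_names=X.dye_names)


def normalize_abundance(
    X: AbundanceMap, ref: ReferenceValues, clip: bool = True
) -> AbundanceMap:
    """Divide each dye row by its reference value; clip into [0, 1].

    Pass ``clip=False`` to retrieve the unclipped map for quantitative
    work.
    """
    if np.any(ref.q <= 0):
        raise ValueError("reference values must be strictly positive")
    values = X.values / ref.q[:, None]
    if clip:
        values = np.clip(values, 0.0, 1.0)
    return replace(X, values=values)


def sre_db(X_gt: np.ndarray, X_hat: np.ndarray) -> float:
    """Signal-to-reconstruction error 10 log10(||X_gt||^2 / ||X_gt - X_hat||^2) in dB.

    Returns ``math.inf`` for an exact reconstruction.
    """
    X_gt = np.asarray(X_gt, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X_gt.shape != X_hat.shape:
        raise ValueError("shape mismatch")
    signal = float(np.sum(X_gt**2))
    if signal == 0:
        raise ValueError("ground truth is identically zero")
    err = float(np.sum((X_gt - X_hat) ** 2))
    if err == 0:
        return math.inf
    return 10.0 * math.log10(signal / err)


def rmse(X_gt: np.ndarray, X_hat: np.ndarray) -> float:
    """Root mean square error over all matrix elements."""
    X_gt = np.asarray(X_gt, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X_gt.shape != X_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.sum((X_gt - X_hat) ** 2) / X_gt.size))
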