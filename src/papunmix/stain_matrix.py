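"""Stain (absorption coefficient) matrices measured from single-stain slides.

Each dye's absorption vector is the mean optical density over
well-stained regions of interest cropped from slides stained with that
dye alone.  Columns are normalized to unit element sum so every dye
contributes on a comparable scale; abundance units are therefore
"total OD deposited per pixel" for that dye.

The RGB matrix A is 3 x r with the fixed dye order [EY, H, LG, OG]
(Eosin Y, hematoxylin, Light Green SF, Orange G); the multispectral
matrix E is M x R over the cube's wavelength grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DYES",
    "StainMatrix",
    "MSStainMatrix",
    "measure_dye_vector",
    "normalize_columns",
    "save_stain_matrix",
    "load_stain_matrix",
]

DEFAULT_DYES = ("EY", "H", "LG", "OG")
_COLUMN_SUM_TOL = 1e-6


def _check_columns(coefficients: np.ndarray, tol: float = 1e-9) -> None:
    if np.any(coefficients < 0):
        raise ValueError("stain coefficients must be nonnegative")
    sums = coefficients.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError(f"columns must sum to 1, got sums {sums}")


@dataclass
class StainMatrix:
    """3 x r matrix of per-dye RGB absorption coefficients, unit column sums."""

    coefficients: np.ndarray
    dye_names: tuple[str, ...] = DEFAULT_DYES

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.dye_names = tuple(self.dye_names)
        if self.coefficients.ndim != 2 or self.coefficients.shape[0] != 3:
            raise ValueError(f"expected (3, r), got {self.coefficients.shape}")
        if self.coefficients.shape[1] != len(self.dye_names):
            raise ValueError("dye_names must match number of columns")
        if self.coefficients.shape[1] < 1:
            raise ValueError("need at least one dye")
        _check_columns(self.coefficients)

    @property
    def n_dyes(self) -> int:
        return self.coefficients.shape[1]

    def dye_index(self, name: str) -> int:
        return self.dye_names.index(name)

    def column(self, name: str) -> np.ndarray:
        return self.coefficients[:, self.dye_index(name)]


@dataclass
class MSStainMatrix:
    """M x R matrix of per-dye spectral absorption coefficients."""

    coefficients: np.ndarray
    dye_names: tuple[str, ...] = DEFAULT_DYES
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.dye_names = tuple(self.dye_names)
        if self.coefficients.ndim != 2:
            raise ValueError("expected a 2-D coefficient matrix")
        if self.coefficients.shape[1] != len(self.dye_names):
            raise ValueError("dye_names must match number of columns")
        _check_columns(self.coefficients)
        if self.wavelengths_nm is not None:
            self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float).ravel()
            if self.wavelengths_nm.size != self.coefficients.shape[0]:
                raise ValueError("wavelengths must match row count")

    @property
    def n_bands(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_dyes(self) -> int:
        return self.coefficients.shape[1]

    def dye_index(self, name: str) -> int:
        return self.dye_names.index(name)


def measure_dye_vector(od_rois: list[np.ndarray]) -> np.ndarray:
    """Mean OD vector of a dye over all pixels of all single-stain ROIs.

    Each ROI is a (channels, n_i) OD matrix; the mean is taken over the
    concatenated pixels, so ROIs are weighted by their pixel count.
    """
    if not od_rois:
        raise ValueError("at least one ROI is required")
    mats = [np.atleast_2d(np.asarray(r, dtype=float)) for r in od_rois]
    channels = mats[0].shape[0]
    for m in mats:
        if m.shape[0] != channels:
            raise ValueError("all ROIs must have the same channel count")
        if m.shape[1] == 0:
            raise ValueError("empty ROI")
        if not np.all(np.isfinite(m)):
            raise ValueError("OD values must be finite")
    stacked = np.concatenate(mats, axis=1)
    mean = stacked.mean(axis=1)
    if np.allclose(mean, 0.0):
        raise ValueError("all-zero mean OD: dye not detected in the ROIs")
    return mean


def normalize_columns(
    raw: np.ndarray,
    dye_names: tuple[str, ...] = DEFAULT_DYES,
    wavelengths_nm: np.ndarray | None = None,
) -> StainMatrix | MSStainMatrix:
    """Normalize raw per-dye absorption vectors to unit column sums.

    ``raw`` is (channels, r); 3 channels produce a :class:`StainMatrix`,
    anything else an :class:`MSStainMatrix`.  Negative components (which
    can arise from incident-light misestimation) are clipped to zero
    with a warning before normalization.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a (channels, r) matrix of raw vectors")
    if np.any(raw < 0):
        warnings.warn("negative absorption components clipped to 0", stacklevel=2)
        raw = np.clip(raw, 0.0, None)
    sums = raw.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError(f"every column must have a positive sum, got {sums}")
    coefficients = raw / sums
    if raw.shape[0] == 3 and wavelengths_nm is None:
        return StainMatrix(coefficients=coefficients, dye_names=dye_names)
    return MSStainMatrix(
        coefficients=coefficients, dye_names=dye_names, wavelengths_nm=wavelengths_nm
    )


def save_stain_matrix(matrix: StainMatrix | MSStainMatrix, path: str | Path) -> None:
    """Write a stain matrix as CSV (``channel,EY,H,LG,OG``) or JSON.

    Coefficients are stored at full double precision so the round trip
    is lossless.
    """
    path = Path(path)
    if isinstance(matrix, StainMatrix):
        channels = ["R", "G", "B"]
    elif matrix.wavelengths_nm is not None:
        channels = [f"{w:g}" for w in matrix.wavelengths_nm]
    else:
        channels = [f"band{i}" for i in range(matrix.n_bands)]
    if path.suffix.lower() == ".json":
        payload = {
            "dye_names": list(matrix.dye_names),
            "channels": channels,
            "coefficients": [[repr(float(v)) for v in row] for row in matrix.coefficients],
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    df = pd.DataFrame(
        matrix.coefficients, columns=list(matrix.dye_names),
        index=pd.Index(channels, name="channel"),
    )
    df.to_csv(path, float_format="%.17g")


def load_stain_matrix(path: str | Path) -> StainMatrix | MSStainMatrix:
    """Read a stain matrix written by :func:`save_stain_matrix`.

    Column sums are validated to within 1e-6 and renormalized exactly;
    a larger violation is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        names = tuple(payload["dye_names"])
        channels = payload["channels"]
        coefficients = np.array(
            [[float(v) for v in row] for row in payload["coefficients"]]
        )
    else:
        df = pd.read_csv(path, index_col="channel")
        names = tuple(df.columns)
        channels = [str(c) for c in df.index]
        coefficients = df.to_numpy(dtype=float)
    sums = coefficients.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > _COLUMN_SUM_TOL):
        raise ValueError(f"stored columns do not sum to 1 (sums {sums})")
    coefficients = coefficients / sums  # remove round-off from the text format
    wavelengths = None
    try:
        wavelengths = np.array([float(c) for c in channels])
    except ValueError:
        pass
    if coefficients.shape[0] == 3 and channels[:3] == ["R", "G", "B"]:
        return StainMatrix(coefficients=coefficients, dye_names=names)
    return MSStainMatrix(
        coefficients=coefficients, dye_names=names, wavelengths_nm=wavelengths
    )
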