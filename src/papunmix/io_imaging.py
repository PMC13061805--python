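"""Raster / spectral-cube I/O and optical-density conversion.

Brightfield micrographs record transmitted light: a pixel's decadic
optical density (OD, absorbance) in channel i is

    y_i = log10(I_0,i / l_i)

where I_0 is the incident light measured on bare glass and l the
transmitted intensity.  Under the Beer-Lambert model OD is linear in
dye amount, so all unmixing happens in OD space.  This module converts
between intensity and OD, estimates the incident light from glass
pixels, reads/writes the supported raster formats, and renders
multi-band spectral cubes to sRGB for display.

Conventions
-----------
* OD is nonnegative: pixels brighter than the incident estimate are
  clipped to OD 0 (the abundance model forbids emission).
* Transmitted intensities are floored at ``I_0 * 10**(-od_max)`` before
  the log so that zero-valued pixels map to the finite ceiling
  ``od_max`` (default 3.0).
* Rasters are linearized row-major; every (channels x n) matrix in the
  package shares that pixel order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .colorimetry import transmittance_to_srgb

__all__ = [
    "RGBImage",
    "ODImage",
    "SpectralCube",
    "read_raster",
    "write_rgb",
    "write_abundance_stack",
    "read_abundance_stack",
    "estimate_incident_light",
    "rgb_to_od",
    "od_to_rgb",
    "cube_to_od",
    "spectral_to_srgb",
]

DEFAULT_OD_MAX = 3.0


@dataclass
class RGBImage:
    """Three-channel brightfield image in device intensity units.

    ``pixels`` is a ``(height, width, 3)`` float array; ``incident_light``
    optionally carries the per-channel incident intensity I_0.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    incident_light: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.incident_light is not None:
            self.incident_light = np.asarray(self.incident_light, dtype=float).reshape(3)
            if np.any(self.incident_light <= 0):
                raise ValueError("incident_light must be strictly positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class ODImage:
    """Optical densities as a (3, n) matrix over a row-major raster."""

    values: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError(f"expected (3, n) values, got {self.values.shape}")
        if self.values.shape[1] != self.height * self.width:
            raise ValueError("n must equal height * width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OD values must be finite")
        if np.any(self.values < 0):
            raise ValueError("OD values must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def as_raster(self) -> np.ndarray:
        """Return the (height, width, 3) view of the OD data."""
        return self.values.T.reshape(self.height, self.width, 3)


@dataclass
class SpectralCube:
    """M-band transmitted-intensity cube with wavelength metadata."""

    bands: np.ndarray  # (M, height, width)
    wavelengths_nm: np.ndarray  # (M,), strictly increasing
    incident_spectrum: np.ndarray  # (M,), strictly positive
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float).ravel()
        self.incident_spectrum = np.asarray(self.incident_spectrum, dtype=float).ravel()
        if self.bands.ndim != 3:
            raise ValueError(f"expected (M, H, W) bands, got {self.bands.shape}")
        m = self.bands.shape[0]
        if m < 2:
            raise ValueError("a spectral cube needs at least 2 bands")
        if self.wavelengths_nm.size != m or self.incident_spectrum.size != m:
            raise ValueError("wavelengths/incident spectrum must match band count")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.incident_spectrum <= 0):
            raise ValueError("incident spectrum must be strictly positive")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def height(self) -> int:
        return self.bands.shape[1]

    @property
    def width(self) -> int:
        return self.bands.shape[2]


def _bit_depth_of(arr: np.ndarray) -> int:
    return 16 if arr.dtype == np.uint16 else 8


def read_raster(path: str | Path) -> RGBImage | SpectralCube:
    """Read a PNG/TIFF RGB image or a multi-page TIFF spectral cube.

    A cube is recognized by a sidecar JSON next to the TIFF
    (``<stem>.json``) with ``{"wavelengths_nm": [...],
    "incident_spectrum": [...]}``; the incident spectrum is optional and
    is otherwise estimated per band from glass pixels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".json")
    if path.suffix.lower() in (".tif", ".tiff") and sidecar.exists():
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ValueError(f"expected a stack of single-channel pages, got {pages.shape}")
        meta = json.loads(sidecar.read_text())
        wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
        if wavelengths.size != pages.shape[0]:
            raise ValueError(
                f"sidecar lists {wavelengths.size} wavelengths for {pages.shape[0]} pages"
            )
        if "incident_spectrum" in meta and meta["incident_spectrum"] is not None:
            incident = np.asarray(meta["incident_spectrum"], dtype=float)
        else:
            incident = np.array([_glass_level(b) for b in pages.astype(float)])
        return SpectralCube(
            bands=pages.astype(float),
            wavelengths_nm=wavelengths,
            incident_spectrum=incident,
            bit_depth=_bit_depth_of(pages),
        )
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {arr.shape}")
    return RGBImage(pixels=arr.astype(float), bit_depth=_bit_depth_of(arr))


def write_rgb(path: str | Path, image: RGBImage) -> None:
    """Write an RGBImage as PNG or TIFF at its declared bit depth."""
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    arr = np.clip(np.rint(image.pixels), 0, image.max_value).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_abundance_stack(
    path: str | Path, values: np.ndarray, height: int, width: int,
    dye_names: list[str], metadata: dict | None = None,
) -> None:
    """Write an (r, n) abundance matrix as a float32 multi-page TIFF.

    One page per dye in row order, plus a JSON sidecar carrying the dye
    names and any extra provenance mapping.
    """
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    pages = values.reshape(len(dye_names), height, width)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {"dye_names": list(dye_names), "height": height, "width": width}
    if metadata:
        meta.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_abundance_stack(path: str | Path) -> tuple[np.ndarray, int, int, list[str]]:
    """Inverse of :func:`write_abundance_stack`; returns (values, h, w, names)."""
    path = Path(path)
    pages = tifffile.imread(path).astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = list(meta["dye_names"])
    else:
        names = [f"dye{i}" for i in range(pages.shape[0])]
    h, w = pages.shape[1], pages.shape[2]
    return pages.reshape(pages.shape[0], h * w), h, w, names


def _glass_level(channel: np.ndarray, quantile: float = 99.0) -> float:
    """Robust bright-plateau level of a single channel (see below)."""
    flat = channel.ravel()
    thresh = np.percentile(flat, quantile)
    mask = flat >= thresh
    return float(flat[mask].mean())


def estimate_incident_light(
    image: RGBImage,
    mode: str = "auto",
    roi: tuple[int, int, int, int] | None = None,
    value: np.ndarray | None = None,
    quantile: float = 99.0,
) -> np.ndarray:
    """Estimate the per-channel incident light I_0 from glass pixels.

    Modes
    -----
    auto
        Glass mask = pixels whose *minimum* channel exceeds the given
        percentile (default 99th) of the per-pixel minimum channel;
        I_0 = per-channel mean over the mask.  Using the minimum channel
        keeps saturated single-channel pixels inside stained regions out
        of the mask.
    roi
        Per-channel mean over an (x, y, width, height) rectangle.
    explicit
        Pass a strictly positive 3-vector through unchanged.
    """
    if mode == "explicit":
        if value is None:
            raise ValueError("explicit mode requires a value")
        out = np.asarray(value, dtype=float).reshape(3)
        if np.any(out <= 0):
            raise ValueError("explicit incident light must be strictly positive")
        return out
    if mode == "roi":
        if roi is None:
            raise ValueError("roi mode requires a rectangle (x, y, w, h)")
        x, y, w, h = roi
        patch = image.pixels[y : y + h, x : x + w]
        if patch.size == 0:
            raise ValueError("ROI is empty or outside the raster")
        out = patch.reshape(-1, 3).mean(axis=0)
    elif mode == "auto":
        min_channel = image.pixels.min(axis=2)
        thresh = np.percentile(min_channel, quantile)
        mask = min_channel >= thresh
        if not np.any(mask):
            raise ValueError("no candidate glass pixels found")
        out = image.pixels[mask].mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(out <= 0):
        raise ValueError("estimated incident light is not strictly positive")
    return out


def rgb_to_od(
    image: RGBImage,
    incident: np.ndarray | None = None,
    od_max: float = DEFAULT_OD_MAX,
) -> ODImage:
    """Convert intensities to optical density, y = log10(I_0 / l).

    Transmitted intensities are floored at ``I_0 * 10**(-od_max)`` so the
    output is finite, and negative OD (pixel brighter than I_0) is
    clipped to zero.
    """
    if incident is None:
        incident = image.incident_light
        if incident is None:
            incident = estimate_incident_light(image, mode="auto")
    incident = np.asarray(incident, dtype=float).reshape(3)
    if np.any(incident <= 0):
        raise ValueError("incident light must be strictly positive")
    flat = image.pixels.reshape(-1, 3).T  # (3, n)
    floor = incident[:, None] * 10.0 ** (-od_max)
    od = np.log10(incident[:, None] / np.maximum(flat, floor))
    od = np.clip(od, 0.0, od_max)
    return ODImage(values=od, height=image.height, width=image.width)


def od_to_rgb(
    od: ODImage,
    incident: np.ndarray,
    bit_depth: int = 8,
    quantize: bool = False,
) -> RGBImage:
    """Invert :func:`rgb_to_od`: l = I_0 * 10**(-y).

    With ``quantize=False`` the round trip through ``rgb_to_od`` is exact
    (to floating point) whenever no flooring/clipping was triggered.
    """
    incident = np.asarray(incident, dtype=float).reshape(3)
    if np.any(incident <= 0):
        raise ValueError("incident light must be strictly positive")
    intensities = incident[:, None] * 10.0 ** (-od.values)
    pixels = intensities.T.reshape(od.height, od.width, 3)
    if quantize:
        pixels = np.clip(np.rint(pixels), 0, 2**bit_depth - 1)
    return RGBImage(pixels=pixels, bit_depth=bit_depth, incident_light=incident)


def cube_to_od(cube: SpectralCube, od_max: float = DEFAULT_OD_MAX) -> np.ndarray:
    """Per-band decadic OD of a spectral cube as an (M, n) matrix.

    Same flooring/clipping policy as :func:`rgb_to_od`.
    """
    flat = cube.bands.reshape(cube.n_bands, -1)
    incident = cube.incident_spectrum[:, None]
    floor = incident * 10.0 ** (-od_max)
    od = np.log10(incident / np.maximum(flat, floor))
    return np.clip(od, 0.0, od_max)


def spectral_to_srgb(cube: SpectralCube, bit_depth: int = 8) -> RGBImage:
    """Render a spectral cube to sRGB under illuminant D65.

    Transmittance I_T/I_I is weighted by the D65 spectrum and the CIE
    1931 2-degree observer at the cube's band centers; the result is
    white-point normalized (unit transmittance maps to full scale),
    converted through the standard sRGB matrix, gamma encoded, and
    scaled to the requested bit depth.
    """
    transmittance = cube.bands.reshape(cube.n_bands, -1) / cube.incident_spectrum[:, None]
    srgb = transmittance_to_srgb(transmittance, cube.wavelengths_nm)  # (3, n) in [0,1]
    scale = 2**bit_depth - 1
    pixels = np.rint(srgb * scale).T.reshape(cube.height, cube.width, 3)
    return RGBImage(
        pixels=pixels,
        bit_depth=bit_depth,
        incident_light=np.full(3, float(scale)),
    )
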