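"""Seeded synthetic Papanicolaou-like phantoms.

The generator builds scenes that embody the three priors the solver
exploits: abundances are nonnegative; hematoxylin is confined to
nucleus disks (with an optional small bleed into cytoplasm); and
cytoplasmic dye fields vary smoothly within each cell, so abundance
maps are piecewise smooth.  Scenes are rendered to RGB through the
Beer-Lambert law with a bundled stain matrix, with optional additive
Gaussian sensor noise (intensity domain) and quantization, and
optionally to a 14-band spectral cube for the multispectral
ground-truth path.

Every cell carries at most two cytoplasmic dyes and nuclei carry
hematoxylin only, so each region has at most three active dyes — the
regime in which the regularized four-dye problem is identifiable from
three channels.  Default abundances are order one ("total OD per
pixel" units of a unit-column-sum stain matrix), peaking around 2 for
hematoxylin in nuclei, which keeps the brightest-to-darkest intensity
range of a 16-bit render well inside the OD ceiling.

The bundled stain matrices are synthetic: they reproduce the
qualitative structure of measured Papanicolaou coefficients (a
hematoxylin column strongest in red OD, strongly overlapping Eosin Y
and Orange G columns, a distinct Light Green column) without claiming
any measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_imaging import RGBImage, SpectralCube
from .stain_matrix import DEFAULT_DYES, MSStainMatrix, StainMatrix, normalize_columns
from .unmix import AbundanceMap

__all__ = [
    "PhantomConfig",
    "Phantom",
    "bundled_stain_matrix",
    "generate_scene",
    "render_rgb",
    "render_ms_cube",
    "make_phantom",
]

# Synthetic RGB absorption coefficients (columns EY, H, LG, OG; unit sums).
_PAP_RGB = np.array([
    [0.10, 0.55, 0.45, 0.15],
    [0.65, 0.30, 0.10, 0.55],
    [0.25, 0.15, 0.45, 0.30],
])

_MS_WAVELENGTHS = np.linspace(440.0, 720.0, 14)  # 14 bands spanning 440-720 nm


def bundled_stain_matrix(name: str) -> StainMatrix | MSStainMatrix:
    """Fixed synthetic stain matrices for phantoms and examples.

    ``papanicolaou_rgb`` is 3 x 4; ``papanicolaou_ms`` is a 14-band spectral
    matrix spanning 440-720 nm built from smooth absorption
    lobes with the same qualitative dye overlaps.
    """
    if name == "papanicolaou_rgb":
        return StainMatrix(coefficients=_PAP_RGB.copy(), dye_names=DEFAULT_DYES)
    if name == "papanicolaou_ms":
        wl = _MS_WAVELENGTHS
        def lobe(mu, sigma, amp=1.0):
            return amp * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
        raw = np.stack(
            [
                lobe(520.0, 32.0),                      # EY: green absorber (pink dye)
                lobe(600.0, 65.0) + lobe(520.0, 30.0, 0.25),  # H: broad red/green
                lobe(630.0, 40.0) + lobe(450.0, 35.0, 0.55),  # LG: red+blue absorber
                lobe(488.0, 38.0),                      # OG: blue-green, overlaps EY
            ],
            axis=1,
        )
        return normalize_columns(raw, dye_names=DEFAULT_DYES, wavelengths_nm=wl)
    raise ValueError(f"unknown bundled stain matrix {name!r}")


@dataclass
class PhantomConfig:
    """Scene and rendering parameters of the phantom generator.

    dye_levels are the peak abundances (EY, H, LG, OG); noise_sd is the
    additive Gaussian sensor noise in device intensity units of the
    chosen bit depth; h_bleed is the cytoplasmic hematoxylin level as a
    fraction of the nuclear level (0 disables it).
    """

    height: int = 64
    width: int = 64
    n_cells: int = 6
    nucleus_area_fraction: float = 0.1
    dye_levels: tuple[float, float, float, float] = (1.2, 2.0, 1.0, 0.8)
    h_bleed: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0
    render_ms: bool = False
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.height < 4 or self.width < 4:
            raise ValueError("raster must be at least 4 x 4")
        if not 0 < self.nucleus_area_fraction < 0.5:
            raise ValueError("nucleus_area_fraction must lie in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.h_bleed <= 0.02:
            raise ValueError("h_bleed must lie in [0, 0.02]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def incident_light(self) -> np.ndarray:
        scale = 2**self.bit_depth - 1
        return scale * np.array([0.95, 0.93, 0.91])


@dataclass
class Phantom:
    """A generated scene: ground truth, stain matrix, renders, masks."""

    truth: AbundanceMap
    stain_matrix: StainMatrix
    clean_rgb: RGBImage
    noisy_rgb: RGBImage
    masks: dict[str, np.ndarray]
    config: PhantomConfig
    ms_cube: SpectralCube | None = None
    ms_stain_matrix: MSStainMatrix | None = None


def _smooth_field(shape, rng, base: float = 0.7, amplitude: float = 0.3) -> np.ndarray:
    """Strictly positive low-frequency field in [base-amplitude, base+amplitude]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    fy, fx = rng.uniform(0.5, 1.5, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wave = np.sin(2 * np.pi * fy * yy / h + phase[0]) * np.cos(
        2 * np.pi * fx * xx / w + phase[1]
    )
    return base + amplitude * wave


def generate_scene(config: PhantomConfig) -> tuple[AbundanceMap, dict[str, np.ndarray]]:
    """Place non-overlapping elliptical cells with hematoxylin nuclei.

    Returns the ground-truth abundance map and boolean masks
    (``background``, ``cytoplasm``, ``nuclei``).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w]
    X = np.zeros((4, h, w))
    cytoplasm = np.zeros((h, w), dtype=bool)
    nuclei = np.zeros((h, w), dtype=bool)

    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 300 * max(config.n_cells, 1)
    n_placed = 0
    min_dim = min(h, w)
    while n_placed < config.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells "
                f"in a {h}x{w} raster after {max_attempts} attempts"
            )
        attempts += 1
        a = rng.uniform(0.10, 0.16) * min_dim  # semi-axes
        b = rng.uniform(0.08, 0.13) * min_dim
        cy = rng.uniform(a, h - a)
        cx = rng.uniform(a, w - a)
        r_out = max(a, b)
        if any(
            np.hypot(cy - py, cx - px) < r_out + pr + 1.0 for py, px, pr in placed
        ):
            continue
        placed.append((cy, cx, r_out))
        n_placed += 1

        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        cell = (u / a) ** 2 + (v / b) ** 2 <= 1.0

        r_nuc = np.sqrt(config.nucleus_area_fraction * a * b)
        off = rng.uniform(-0.2, 0.2, size=2) * min(a, b)
        nucleus = np.hypot(yy - (cy + off[0]), xx - (cx + off[1])) <= r_nuc
        nucleus &= cell
        cyto = cell & ~nucleus

        # Cytoplasmic dye sets are restricted to combinations whose *absent*
        # dyes pin the pixel uniquely under nonnegativity: with the bundled
        # stain matrix the null vector of A has signs (-, +, -, +) over
        # (EY, H, LG, OG), so the zero set must contain components of both
        # signs.  EY+LG together (H and OG absent) is the one ambiguous
        # pair and is excluded.
        options = [(0, 3), (2, 3), (0,), (2,), (3,)]  # rows: EY=0, LG=2, OG=3
        dye_idx = options[rng.choice(len(options), p=[0.3, 0.3, 0.15, 0.15, 0.1])]
        for d in dye_idx:
            level = config.dye_levels[d]
            field = level * _smooth_field((h, w), rng)
            X[d][cyto] = field[cyto]

        h_level = config.dye_levels[1]
        profile = h_level * _smooth_field((h, w), rng, base=0.8, amplitude=0.2)
        X[1][nucleus] = profile[nucleus]
        if config.h_bleed > 0:
            X[1][cyto] = config.h_bleed * h_level

        cytoplasm |= cyto
        nuclei |= nucleus

    truth = AbundanceMap(
        values=X.reshape(4, -1), height=h, width=w, dye_names=DEFAULT_DYES
    )
    masks = {
        "background": ~(cytoplasm | nuclei),
        "cytoplasm": cytoplasm,
        "nuclei": nuclei,
    }
    return truth, masks


def render_rgb(
    truth: AbundanceMap,
    A: StainMatrix,
    incident: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    bit_depth: int = 16,
) -> tuple[RGBImage, RGBImage]:
    """Beer-Lambert render of a scene: returns (clean, noisy) images.

    Intensity = I_0 * 10**(-A X); noise is additive Gaussian in the
    intensity (sensor) domain; both outputs are clipped to the valid
    range and quantized to the bit depth.
    """
    incident = np.asarray(incident, dtype=float).reshape(3)
    od = A.coefficients @ truth.values  # (3, n)
    intensity = incident[:, None] * 10.0 ** (-od)
    max_value = 2**bit_depth - 1

    def finalize(arr: np.ndarray) -> RGBImage:
        pixels = np.clip(np.rint(arr), 0, max_value).T.reshape(
            truth.height, truth.width, 3
        )
        return RGBImage(pixels=pixels, bit_depth=bit_depth, incident_light=incident)

    clean = finalize(intensity)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = finalize(intensity + rng.normal(0.0, noise_sd, size=intensity.shape))
    else:
        noisy = finalize(intensity)
    return clean, noisy


def render_ms_cube(
    truth: AbundanceMap,
    E: MSStainMatrix,
    incident_level: float = 0.93,
    bit_depth: int = 16,
) -> SpectralCube:
    """Render the scene through the spectral stain matrix to an M-band cube."""
    scale = 2**bit_depth - 1
    incident = np.full(E.n_bands, incident_level * scale)
    od = E.coefficients @ truth.values  # (M, n)
    bands = (incident[:, None] * 10.0 ** (-od)).reshape(
        E.n_bands, truth.height, truth.width
    )
    return SpectralCube(
        bands=np.rint(bands),
        wavelengths_nm=E.wavelengths_nm,
        incident_spectrum=incident,
        bit_depth=bit_depth,
    )


def make_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Generate a full phantom: scene, RGB renders, optional MS cube."""
    if config is None:
        config = PhantomConfig()
    truth, masks = generate_scene(config)
    A = bundled_stain_matrix("papanicolaou_rgb")
    clean, noisy = render_rgb(
        truth,
        A,
        config.incident_light,
        noise_sd=config.noise_sd,
        seed=config.seed + 1,  # independent of the scene stream
        bit_depth=config.bit_depth,
    )
    ms_cube = None
    ms_matrix = None
    if config.render_ms:
        ms_matrix = bundled_stain_matrix("papanicolaou_ms")
        ms_cube = render_ms_cube(truth, ms_matrix, bit_depth=config.bit_depth)
    return Phantom(
        truth=truth,
        stain_matrix=A,
        clean_rgb=clean,
        noisy_rgb=noisy,
        masks=masks,
        config=config,
        ms_cube=ms_cube,
        ms_stain_matrix=ms_matrix,
    )
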