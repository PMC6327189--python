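"""Synthetic phantoms with known ground truth, and detection metrics.

The 2D phantom is a grid of continuous density waves: two orthogonal cosine
waves of a given period are summed, negative values are clipped to zero, and
the sum is halved so the maximum is exactly 1; the grid patch is embedded
centrally in a larger zero background and i.i.d. Gaussian noise is added
over the whole frame.  Detection can then be scored against the exact signal
support: empirical FDR (false detections / detections) and recall.

The 3D phantom embeds soft-edged spherical blobs in a noise volume, keeping
the outer shell of the box pure noise so the solvent-window machinery works
end to end; a strong-core / weak-periphery variant exercises the local SNR
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .volume_io import DensityMap

__all__ = [
    "GridPhantom",
    "SphereSpec",
    "TwoRegionPhantom",
    "make_grid",
    "add_noise",
    "snr",
    "power_spectrum",
    "empirical_fdr",
    "recall",
    "make_volume_phantom",
    "make_two_region_phantom",
]


@dataclass
class GridPhantom:
    """A synthetic image/volume with exact ground truth.

    ``image`` is the noiseless signal in [0, 1]; ``truth_mask`` is True
    exactly where image > 0; ``noisy`` (present after :func:`add_noise`) is
    image plus i.i.d. Gaussian noise of variance ``noise_variance``.
    """

    image: np.ndarray
    truth_mask: np.ndarray
    noisy: np.ndarray | None = None
    noise_variance: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
        if self.truth_mask.shape != self.image.shape:
            raise ValueError("truth mask must match image shape")

    def as_density_map(self, voxel_size: float = 1.0) -> DensityMap:
        """The noisy lattice (or the clean one if noise was never added)."""
        values = self.noisy if self.noisy is not None else self.image
        return DensityMap(values, (voxel_size,) * values.ndim)


def make_grid(
    image_size: int = 400, grid_size: int = 200, period: float = 5.0
) -> GridPhantom:
    """Noiseless cosine-grid phantom.

    The grid patch value at (x, y) is 0.5 * max(cos(2*pi*x/period) +
    cos(2*pi*y/period), 0): the summed waves are clipped at zero and halved,
    so the maximum is exactly 1.  The patch is embedded centred in a zero
    frame of ``image_size`` pixels per side.
    """
    if grid_size > image_size:
        raise ValueError("grid_size must not exceed image_size")
    if period < 2:
        raise ValueError(f"period {period} px is below the 2 px sampling limit")
    x = np.arange(grid_size)
    wave = np.cos(2.0 * np.pi * x / period)
    patch = 0.5 * np.maximum(wave[:, None] + wave[None, :], 0.0)
    image = np.zeros((image_size, image_size))
    start = (image_size - grid_size) // 2
    image[start : start + grid_size, start : start + grid_size] = patch
    return GridPhantom(image, image > 0)


def add_noise(phantom: GridPhantom, variance: float, seed: int) -> GridPhantom:
    """Add i.i.d. Gaussian noise of mean 0 and the given variance everywhere.

    The background stays pure noise (the signal support is untouched by
    construction), which is what makes solvent-side noise estimation valid.
    Deterministic for a given seed.
    """
    if not variance > 0:
        raise ValueError(f"noise variance must be > 0, got {variance}")
    rng = np.random.default_rng(seed)
    noisy = phantom.image + rng.normal(0.0, np.sqrt(variance), phantom.image.shape)
    return replace(phantom, noisy=noisy, noise_variance=float(variance), seed=seed)


def snr(phantom: GridPhantom) -> float:
    """Signal-to-noise ratio: var(noiseless image over the full frame) / var(noise)."""
    if not phantom.noise_variance > 0:
        raise ValueError("phantom has no noise; add_noise first")
    return float(np.var(phantom.image)) / phantom.noise_variance


def power_spectrum(image: np.ndarray) -> np.ndarray:
    """Squared modulus of the DFT, zero-frequency centred (diagnostic)."""
    return np.abs(np.fft.fftshift(np.fft.fftn(np.asarray(image, dtype=float)))) ** 2


def empirical_fdr(detections: np.ndarray, truth: np.ndarray) -> float:
    """Observed false-discovery fraction: false detections / all detections.

    Returns 0 when nothing is detected (no detections means no false
    discoveries).
    """
    detections = np.asarray(detections, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detections.shape != truth.shape:
        raise ValueError("detections and truth must be congruent")
    n_det = int(np.count_nonzero(detections))
    if n_det == 0:
        return 0.0
    n_false = int(np.count_nonzero(detections & ~truth))
    return n_false / n_det


def recall(detections: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of true-signal voxels detected."""
    detections = np.asarray(detections, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detections.shape != truth.shape:
        raise ValueError("detections and truth must be congruent")
    n_truth = int(np.count_nonzero(truth))
    if n_truth == 0:
        raise ValueError("empty truth mask")
    return int(np.count_nonzero(detections & truth)) / n_truth


@dataclass(frozen=True)
class SphereSpec:
    """A soft-edged spherical blob.

    ``center`` is in voxels relative to the box centre; amplitude is the
    plateau value (map gray units); the profile falls from the plateau to 0
    over ``edge`` voxels as a raised cosine, so the blob is nearly
    band-limited and behaves well under low-pass filtration.
    """

    center: tuple[float, float, float]
    radius: float
    amplitude: float
    edge: float = 3.0


def make_volume_phantom(
    size: int,
    spheres: Sequence[SphereSpec],
    noise_variance: float,
    seed: int,
    clear_shell: int | None = None,
) -> GridPhantom:
    """3D phantom: soft spherical blobs in a pure-noise box.

    ``clear_shell`` is the thickness (voxels) of the outer shell that must
    stay signal-free so background windows sample pure noise; it defaults to
    the extent of the default window placement (1.5 x the clamped default
    window edge).  Signal reaching into the shell is an error, not a warning
    — it would silently bias the noise estimate.
    """
    if not noise_variance > 0:
        raise ValueError(f"noise variance must be > 0, got {noise_variance}")
    from .noise_model import DEFAULT_WINDOW_EDGE

    if clear_shell is None:
        edge = min(DEFAULT_WINDOW_EDGE, size // 4)
        clear_shell = (3 * edge) // 2

    coords = np.arange(size) - size / 2.0
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)
    image = np.zeros((size, size, size))
    for sphere in spheres:
        cx, cy, cz = sphere.center
        r = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2)
        ramp = np.clip((r - sphere.radius) / max(sphere.edge, 1e-12), 0.0, 1.0)
        profile = sphere.amplitude * 0.5 * (1.0 + np.cos(np.pi * ramp))
        profile[r > sphere.radius + sphere.edge] = 0.0
        image = np.maximum(image, profile)

    truth = image > 0
    if clear_shell > 0:
        interior = np.zeros_like(truth)
        s = slice(clear_shell, size - clear_shell)
        interior[s, s, s] = True
        if np.any(truth & ~interior):
            raise ValueError(
                f"signal reaches into the outer {clear_shell}-voxel shell "
                "reserved for background windows"
            )
    rng = np.random.default_rng(seed)
    noisy = image + rng.normal(0.0, np.sqrt(noise_variance), image.shape)
    return GridPhantom(image, truth, noisy, float(noise_variance), seed)


@dataclass
class TwoRegionPhantom:
    """A strong-core / weak-periphery phantom with its local-resolution field.

    Emulates a reconstruction whose rigid core is resolved to high resolution
    while flexible peripheral features are weaker and only resolved coarsely:
    the core blob has a high amplitude, the peripheral blobs a low one, and
    ``locres`` assigns a fine resolution to the core region and a coarse one
    everywhere else (periphery and solvent alike).  ``periphery_mask`` marks
    the true-signal voxels outside the core support, the region where local
    SNR adjustment should gain statistical power.
    """

    phantom: GridPhantom
    locres: np.ndarray
    core_mask: np.ndarray
    periphery_mask: np.ndarray


def make_two_region_phantom(
    size: int = 96,
    noise_variance: float = 0.01,
    seed: int = 0,
    core_amplitude_sd: float = 8.0,
    periphery_amplitude_sd: float = 3.5,
    fine_resolution: float = 3.0,
    coarse_resolution: float = 6.0,
) -> TwoRegionPhantom:
    """Build the two-region volume used to validate local SNR adjustment.

    Amplitudes are specified in units of the noise standard deviation.  The
    core is a soft sphere at the box centre; six weak peripheral blobs sit on
    the +-x/+-y/+-z axes, clear of the solvent-window shell.  The peripheral
    blobs are smooth (raised-cosine profile) and their spatial scale (about
    11 voxels across) is resolvable at the coarse resolution, so the coarse
    low-pass keeps most of their amplitude while removing most of the noise
    power — the regime in which local SNR adjustment is meaningful.
    """
    sd = float(np.sqrt(noise_variance))
    core_r, core_edge = 8.0, 3.0
    periph_r, periph_edge, periph_offset = 3.0, 2.5, 12.0
    spheres = [SphereSpec((0.0, 0.0, 0.0), core_r, core_amplitude_sd * sd, core_edge)]
    for axis in range(3):
        for sign in (-1.0, 1.0):
            center = [0.0, 0.0, 0.0]
            center[axis] = sign * periph_offset
            spheres.append(
                SphereSpec(tuple(center), periph_r,
                           periphery_amplitude_sd * sd, periph_edge)
            )
    phantom = make_volume_phantom(size, spheres, noise_variance, seed)

    coords = np.arange(size) - size / 2.0
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)
    dist = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    core_support = core_r + core_edge
    core_mask = phantom.truth_mask & (dist <= core_support)
    periphery_mask = phantom.truth_mask & (dist > core_support)
    # fine resolution in the rigid core, coarse everywhere else (weak
    # peripheral blobs and solvent alike)
    locres = np.full((size, size, size), coarse_resolution)
    locres[dist <= core_support + 2.0] = fine_resolution
    return TwoRegionPhantom(phantom, locres, core_mask, periphery_mask)
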