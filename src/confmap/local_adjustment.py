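"""Local SNR adjustment by resolution-dependent low-pass filtration.

When resolution varies strongly across a map (flexible periphery, rigid
core), a single global noise variance under-states the significance of
smooth peripheral features.  The remedy: low-pass filter each voxel to its
own local resolution, and test it against the variance of background noise
that has been passed through the *same* filter.  Filtration is done with a
finite bank of Fourier filters, one per resolution bin; the per-bin noise
variance is measured in the original background windows of the identically
filtered volume, so signal and null always share the same Fourier support.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateNoiseError
from .fdr_control import P_FLOOR, PValueMap
from .noise_model import BackgroundWindows, NoiseModel, _extract
from .volume_io import DensityMap

__all__ = [
    "LocalResolutionMap",
    "LocalNoiseModel",
    "ResolutionBins",
    "bin_resolutions",
    "lowpass",
    "local_filter",
    "local_noise",
    "pvalues_local",
    "DEFAULT_BIN_STEP",
    "DEFAULT_FILTER_EDGE",
]

logger = logging.getLogger(__name__)

#: Width of a resolution bin (Å) for discretising the local-resolution field.
DEFAULT_BIN_STEP = 0.5
#: Width of the raised-cosine filter edge, in Fourier pixels.
DEFAULT_FILTER_EDGE = 3.0


@dataclass
class LocalResolutionMap:
    """Per-voxel resolution estimates (Å) on the same lattice as the map.

    Values below the Nyquist limit (2 x the largest voxel dimension) are
    clamped up with a warning — no reconstruction can be more resolved than
    its sampling.  Missing/zero/non-finite values are assigned the worst
    (largest) finite resolution present, the conservative choice.
    """

    values: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=float)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        nyquist = 2.0 * max(self.voxel_size)
        bad = ~np.isfinite(values) | (values <= 0)
        if np.any(bad):
            worst = float(np.max(values[~bad])) if np.any(~bad) else nyquist
            warnings.warn(
                f"{int(bad.sum())} missing/invalid local-resolution values "
                f"assigned the worst bin ({worst:.2f} A)",
                stacklevel=2,
            )
            values[bad] = worst
        below = values < nyquist
        if np.any(below):
            warnings.warn(
                f"{int(below.sum())} local-resolution values below Nyquist "
                f"({nyquist:.2f} A) clamped up",
                stacklevel=2,
            )
            values[below] = nyquist
        self.values = values

    @classmethod
    def from_map(cls, locres_map: DensityMap) -> "LocalResolutionMap":
        return cls(locres_map.values, locres_map.voxel_size)


@dataclass
class ResolutionBins:
    """Discretisation of a local-resolution field into a filter bank.

    ``resolutions`` lists the bin resolutions (Å, ascending = sharpest
    first); ``index`` assigns each voxel the bin whose resolution is >= its
    own local value, so no voxel is ever filtered more sharply than measured.
    """

    resolutions: np.ndarray
    index: np.ndarray

    def __len__(self) -> int:
        return self.resolutions.size


@dataclass
class LocalNoiseModel:
    """Per-voxel noise sigma matched to the local filtration.

    ``mean`` is the global (unfiltered) background mean; ``sigma`` gives each
    voxel the standard deviation of background noise filtered to that voxel's
    resolution bin.  ``bin_table`` maps bin resolution (Å) to the pair
    (cutoff frequency in 1/Å, filtered-background variance).
    """

    sigma: np.ndarray
    mean: float
    bin_table: dict[float, tuple[float, float]]

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
            raise DegenerateNoiseError("all local sigma values must be finite and > 0")

    @classmethod
    def from_sigma_map(cls, sigma_map: DensityMap, mean: float) -> "LocalNoiseModel":
        """Adopt an externally computed per-voxel sigma volume (e.g. from
        model-based amplitude scaling) as a drop-in local noise model."""
        return cls(sigma_map.values, float(mean), {})


def bin_resolutions(
    locres: LocalResolutionMap, step: float = DEFAULT_BIN_STEP
) -> ResolutionBins:
    """Discretise local resolutions into bins of width ``step`` Å.

    Bins start at the sharpest resolution present and cover the full range;
    each voxel is rounded *up* (towards worse resolution) to its bin.
    """
    if not step > 0:
        raise ValueError(f"bin step must be > 0, got {step}")
    values = locres.values
    if values.size == 0:
        raise ValueError("empty local-resolution map")
    r_min = float(values.min())
    r_max = float(values.max())
    # half-open intervals [r_min + k*step, r_min + (k+1)*step); a bin's
    # resolution is the worst value among its members, so nothing is ever
    # filtered sharper than measured and a uniform field keeps its own value
    raw_index = np.floor((values - r_min) / step + 1e-9).astype(int)
    occupied = np.unique(raw_index)
    remap = np.full(int(raw_index.max()) + 1, -1, dtype=int)
    remap[occupied] = np.arange(occupied.size)
    index = remap[raw_index]
    resolutions = np.array(
        [float(values[raw_index == k].max()) for k in occupied]
    )
    logger.info(
        "local resolution %.2f-%.2f A discretised into %d bin(s) of %.2f A",
        r_min,
        r_max,
        resolutions.size,
        step,
    )
    return ResolutionBins(resolutions, index)


def _radial_frequency(dims: tuple[int, ...], voxel_size: tuple[float, ...]):
    axes = [np.fft.fftfreq(n, d=vs) for n, vs in zip(dims, voxel_size)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(sum(g ** 2 for g in grids))


def lowpass(
    density_map: DensityMap,
    resolution: float,
    edge_width: float = DEFAULT_FILTER_EDGE,
) -> DensityMap:
    """Fourier low-pass at ``resolution`` Å with a raised-cosine edge.

    The transfer function is 1 below the cutoff frequency 1/resolution and
    falls to 0 over ``edge_width`` Fourier pixels as 0.5*(1 + cos).  A cutoff
    at or beyond the Nyquist frequency is an all-pass: the map is returned
    unchanged (a spherical mask at Nyquist would clip the corner frequencies
    of the lattice, which carry real sampled content).
    """
    nyquist_resolution = 2.0 * max(density_map.voxel_size)
    if resolution < nyquist_resolution - 1e-9:
        raise ValueError(
            f"resolution {resolution} A is below Nyquist ({nyquist_resolution} A)"
        )
    nyquist_freq = 0.5 / max(density_map.voxel_size)
    cutoff = 1.0 / resolution
    if cutoff >= nyquist_freq - 1e-12:
        return density_map.with_values(density_map.values.copy())

    r = _radial_frequency(density_map.dims, density_map.voxel_size)
    # one Fourier pixel = the frequency step of the grid (mean over axes)
    df = float(
        np.mean([1.0 / (n * vs) for n, vs in
                 zip(density_map.dims, density_map.voxel_size)])
    )
    edge = edge_width * df
    if edge > 0:
        ramp = np.clip((r - cutoff) / edge, 0.0, 1.0)
        mask = 0.5 * (1.0 + np.cos(np.pi * ramp))
    else:
        mask = (r <= cutoff).astype(float)
    spectrum = np.fft.fftn(density_map.values)
    filtered = np.fft.ifftn(spectrum * mask).real
    return density_map.with_values(filtered)


def mask_power_fraction(
    dims: tuple[int, ...],
    voxel_size: tuple[float, ...],
    resolution: float,
    edge_width: float = DEFAULT_FILTER_EDGE,
) -> float:
    """Mean squared transfer of the low-pass mask (Parseval factor).

    White noise of variance v filtered at ``resolution`` has variance
    approximately v * mask_power_fraction(...); used as an independent check
    on the filtered-background variance.
    """
    nyquist_freq = 0.5 / max(voxel_size)
    cutoff = 1.0 / resolution
    if cutoff >= nyquist_freq - 1e-12:
        return 1.0
    r = _radial_frequency(dims, voxel_size)
    df = float(np.mean([1.0 / (n * vs) for n, vs in zip(dims, voxel_size)]))
    edge = edge_width * df
    if edge > 0:
        ramp = np.clip((r - cutoff) / edge, 0.0, 1.0)
        mask = 0.5 * (1.0 + np.cos(np.pi * ramp))
    else:
        mask = (r <= cutoff).astype(float)
    return float(np.mean(mask ** 2))


def local_filter(
    density_map: DensityMap,
    locres: LocalResolutionMap,
    step: float = DEFAULT_BIN_STEP,
    edge_width: float = DEFAULT_FILTER_EDGE,
) -> DensityMap:
    """Per-voxel low-pass filtration to each voxel's local resolution bin.

    The volume is filtered once per bin and every voxel takes its value from
    the volume filtered at its own bin; with a uniform local-resolution field
    this reduces exactly to a single global low-pass.
    """
    if locres.values.shape != density_map.dims:
        raise ValueError(
            f"local-resolution lattice {locres.values.shape} does not match "
            f"map dims {density_map.dims}"
        )
    bins = bin_resolutions(locres, step)
    out = np.empty_like(density_map.values, dtype=float)
    for b, resolution in enumerate(bins.resolutions):
        members = bins.index == b
        if not np.any(members):
            continue
        filtered = lowpass(density_map, float(resolution), edge_width)
        out[members] = filtered.values[members]
    return density_map.with_values(out)


def local_noise(
    windows: BackgroundWindows,
    density_map: DensityMap,
    locres: LocalResolutionMap,
    step: float = DEFAULT_BIN_STEP,
    edge_width: float = DEFAULT_FILTER_EDGE,
) -> LocalNoiseModel:
    """Per-voxel noise sigma from identically filtered background windows.

    For each resolution bin the whole map is filtered at the bin's cutoff and
    the background variance is re-estimated inside the original solvent
    windows of the filtered volume (filtering the full map rather than the
    windows in isolation keeps the Fourier support consistent and avoids
    window edge artifacts).  The mean is taken from the unfiltered
    background, where it is estimated without filter bias.
    """
    min_edge = min(e for _, e in windows.windows)
    if min_edge < 10:
        raise DegenerateNoiseError(
            f"background windows of edge {min_edge} are too small for filtered "
            "variance estimation (need edge >= 10)"
        )
    if locres.values.shape != density_map.dims:
        raise ValueError("local-resolution lattice does not match map dims")
    mean = float(np.mean(windows.pooled_values))
    bins = bin_resolutions(locres, step)
    sigma = np.empty(density_map.dims, dtype=float)
    bin_table: dict[float, tuple[float, float]] = {}
    for b, resolution in enumerate(bins.resolutions):
        members = bins.index == b
        if not np.any(members):
            continue
        filtered = lowpass(density_map, float(resolution), edge_width)
        pooled = np.concatenate(
            [_extract(filtered.values, c, e).ravel() for c, e in windows.windows]
        )
        variance = float(np.var(pooled, ddof=1))
        if variance <= 0:
            raise DegenerateNoiseError(
                f"degenerate filtered background variance in the "
                f"{resolution:.2f} A bin"
            )
        sigma[members] = np.sqrt(variance)
        bin_table[float(resolution)] = (1.0 / float(resolution), variance)
        logger.info(
            "bin %.2f A: filtered background variance %.6g (%d voxels)",
            resolution,
            variance,
            int(members.sum()),
        )
    return LocalNoiseModel(sigma, mean, bin_table)


def pvalues_local(
    filtered_map: DensityMap, local: LocalNoiseModel
) -> PValueMap:
    """One-sided Gaussian p-values with each voxel's own noise sigma.

    p = 1 - Phi((x - mean) / sigma_voxel); feeds the BY adjustment exactly
    like the global p-value lattice.
    """
    from scipy.special import ndtr

    if local.sigma.shape != filtered_map.dims:
        raise ValueError("sigma lattice does not match map dims")
    z = (filtered_map.values - local.mean) / local.sigma
    p = ndtr(-z)
    return PValueMap(np.clip(p, P_FLOOR, 1.0))
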