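"""Background (solvent) noise estimation from windows outside the particle.

The null distribution of voxel values is estimated from a small number of
cubic windows placed in the solvent region of the box — by default four
windows in the outer shell along the central axes, or anywhere the user
specifies for off-centre particles and subtomogram averages, where the
solvent region must be picked with care.  From the pooled window values we
take a Gaussian null (sample mean and unbiased variance) or, when the
background is visibly non-Gaussian, an empirical upper-tail function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateNoiseError, WindowPlacementError
from .volume_io import DensityMap

__all__ = [
    "BackgroundWindows",
    "NoiseModel",
    "place_default_windows",
    "place_manual_window",
    "combine_windows",
    "estimate_noise",
    "scale_noise",
    "DEFAULT_WINDOW_EDGE",
]

logger = logging.getLogger(__name__)

#: Default window edge length in voxels, the centre of the 10-30 voxel range
#: over which background variance estimates are stable in practice.
DEFAULT_WINDOW_EDGE = 20


@dataclass
class BackgroundWindows:
    """A set of non-overlapping cubic solvent windows and their pooled values.

    ``windows`` holds ``(corner, edge)`` pairs, the corner being the 0-based
    index of the window's low corner and ``edge`` its side length in voxels.
    """

    windows: list[tuple[tuple[int, ...], int]]
    pooled_values: np.ndarray

    def __post_init__(self) -> None:
        self.pooled_values = np.asarray(self.pooled_values, dtype=float).ravel()
        expected = sum(edge ** len(corner) for corner, edge in self.windows)
        if self.pooled_values.size != expected:
            raise WindowPlacementError(
                f"pooled value count {self.pooled_values.size} does not match "
                f"window volumes ({expected})"
            )

    @property
    def n_values(self) -> int:
        return self.pooled_values.size


@dataclass(frozen=True)
class NoiseModel:
    """Null distribution of background voxel values.

    ``mean`` and ``variance`` are in map gray units (squared for variance).
    In empirical mode ``background_sorted`` holds the sorted pooled values,
    and :meth:`tail` evaluates the empirical upper-tail fraction with a +1
    continuity correction so no p-value is ever exactly 0.
    """

    mean: float
    variance: float
    background_sorted: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.variance):
            raise DegenerateNoiseError("non-finite noise estimates")
        if self.variance <= 0:
            raise DegenerateNoiseError(
                f"background variance must be > 0, got {self.variance}"
            )

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def is_empirical(self) -> bool:
        return self.background_sorted is not None

    def tail(self, x: np.ndarray) -> np.ndarray:
        """Empirical upper-tail fraction P(background >= x), continuity-corrected.

        Returns ``(1 + #{b_i >= x}) / (n + 1)``, which is non-increasing in x,
        equals 1 below the background minimum (up to the correction) and
        ``1/(n+1)`` — never 0 — above the background maximum.
        """
        if self.background_sorted is None:
            raise DegenerateNoiseError(
                "noise model has no empirical tail; estimate with mode='empirical'"
            )
        b = self.background_sorted
        n = b.size
        n_ge = n - np.searchsorted(b, np.asarray(x, dtype=float), side="left")
        return (1.0 + n_ge) / (n + 1.0)


def _check_window(dims: tuple[int, ...], corner: Sequence[int], edge: int) -> None:
    if edge < 1:
        raise WindowPlacementError(f"window edge must be >= 1 voxel, got {edge}")
    if len(corner) != len(dims):
        raise WindowPlacementError(
            f"corner {tuple(corner)} does not match map dimensionality {len(dims)}"
        )
    for c, d in zip(corner, dims):
        if c < 0 or c + edge > d:
            raise WindowPlacementError(
                f"window corner={tuple(corner)} edge={edge} exceeds map dims {dims}"
            )


def _overlap(a: tuple[tuple[int, ...], int], b: tuple[tuple[int, ...], int]) -> bool:
    (ca, ea), (cb, eb) = a, b
    return all(ca[i] < cb[i] + eb and cb[i] < ca[i] + ea for i in range(len(ca)))


def _extract(values: np.ndarray, corner: Sequence[int], edge: int) -> np.ndarray:
    slices = tuple(slice(c, c + edge) for c in corner)
    return values[slices]


def place_default_windows(
    density_map: DensityMap, edge: int | None = None
) -> BackgroundWindows:
    """Place four solvent windows in the outer shell along the central axes.

    One window per -x, +x, -y, +y face, each centred on the central axis
    perpendicular to that face with its centre one edge length in from the
    face, so the windows sit in the solvent shell of a centred particle.
    If ``edge`` is None the default of 20 voxels is used, clamped down so
    that 4*edge fits in the smallest map dimension.

    The exact geometry is a documented convention of this package (window
    placement in the solvent is not unique); placements are logged, and
    off-centre particles should use :func:`place_manual_window` instead.
    """
    dims = density_map.dims
    min_dim = min(dims)
    if edge is None:
        edge = min(DEFAULT_WINDOW_EDGE, min_dim // 4)
        if edge < DEFAULT_WINDOW_EDGE:
            logger.warning(
                "window edge clamped to %d voxels to fit a %s box", edge, dims
            )
    if edge < 1 or 4 * edge > min_dim:
        raise WindowPlacementError(
            f"window edge {edge} does not fit: need 4*edge <= min(dims)={min_dim}; "
            "specify windows manually for off-centre particles"
        )

    centre = [d // 2 for d in dims]
    placements: list[tuple[tuple[int, ...], int]] = []
    for axis in (0, 1):
        for face in (0, 1):
            window_centre = list(centre)
            window_centre[axis] = edge if face == 0 else dims[axis] - edge
            corner = tuple(int(c - edge // 2) for c in window_centre)
            # keep fully inside for odd edges near the far face
            corner = tuple(
                int(np.clip(c, 0, dims[i] - edge)) for i, c in enumerate(corner)
            )
            placements.append((corner, edge))

    for i, a in enumerate(placements):
        for b in placements[i + 1 :]:
            if _overlap(a, b):  # pragma: no cover - prevented by 4*edge check
                raise WindowPlacementError(f"windows overlap: {a} and {b}")
    pooled = np.concatenate(
        [_extract(density_map.values, c, e).ravel() for c, e in placements]
    )
    logger.info(
        "placed %d background windows (edge %d): %s",
        len(placements),
        edge,
        [c for c, _ in placements],
    )
    return BackgroundWindows(placements, pooled)


def place_manual_window(
    density_map: DensityMap, corner: Sequence[int], edge: int
) -> BackgroundWindows:
    """A single user-specified cubic window (for off-centre particles)."""
    _check_window(density_map.dims, corner, edge)
    corner = tuple(int(c) for c in corner)
    pooled = _extract(density_map.values, corner, edge).ravel()
    logger.info("manual background window corner=%s edge=%d", corner, edge)
    return BackgroundWindows([(corner, edge)], pooled)


def combine_windows(*window_sets: BackgroundWindows) -> BackgroundWindows:
    """Pool several window sets, enforcing pairwise non-overlap."""
    placements = [w for ws in window_sets for w in ws.windows]
    for i, a in enumerate(placements):
        for b in placements[i + 1 :]:
            if _overlap(a, b):
                raise WindowPlacementError(f"windows overlap: {a} and {b}")
    pooled = np.concatenate([ws.pooled_values for ws in window_sets])
    return BackgroundWindows(placements, pooled)


def estimate_noise(
    windows: BackgroundWindows, mode: str = "gaussian"
) -> NoiseModel:
    """Estimate the null distribution from pooled background values.

    Gaussian mode: sample mean and unbiased (n-1) sample variance.
    Empirical mode: additionally retains the sorted pooled values to evaluate
    the continuity-corrected empirical upper tail.
    """
    values = windows.pooled_values
    if values.size < 2:
        raise DegenerateNoiseError(
            f"need >= 2 background values for a variance, got {values.size}"
        )
    if mode not in ("gaussian", "empirical"):
        raise ValueError(f"mode must be 'gaussian' or 'empirical', got {mode!r}")
    mean = float(np.mean(values))
    variance = float(np.var(values, ddof=1))
    if variance == 0.0:
        raise DegenerateNoiseError("constant background window (zero variance)")
    background = np.sort(values) if mode == "empirical" else None
    logger.info(
        "background noise: mean=%.6g variance=%.6g (n=%d, mode=%s)",
        mean,
        variance,
        values.size,
        mode,
    )
    return NoiseModel(mean, variance, background)


def scale_noise(model: NoiseModel, factor: float) -> NoiseModel:
    """Multiply the noise variance by ``factor`` (mean unchanged).

    Used for robustness analysis: overestimating the variance (factor > 1)
    can only make detection more conservative.
    """
    if not factor > 0:
        raise ValueError(f"variance scale factor must be > 0, got {factor}")
    if factor != 1.0:
        logger.warning("scaling background variance by %g", factor)
    return replace(model, variance=model.variance * factor)
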