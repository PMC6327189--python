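"""Per-voxel hypothesis testing and FDR control for density maps.

Every voxel value x is tested one-sidedly against the background null
(interpretable cryo-EM density is positive signal), giving a p-value
p = P(noise >= x).  The p-values are then adjusted with the
Benjamini-Yekutieli (BY) step-up procedure, which controls the false
discovery rate under arbitrary dependence between voxels:

    q_(i) = min(1, min_{j >= i} m * c(m) * p_(j) / j),   c(m) = sum_{k=1}^m 1/k

with m the total number of voxels tested.  The confidence map is the
complement PPV = 1 - q; thresholding it at 0.99 keeps exactly the voxels
whose q <= 0.01, i.e. an expected false discovery fraction of at most 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import ndtr

from .errors import DegenerateNoiseError
from .noise_model import NoiseModel
from .volume_io import AtomicCoordinates, DensityMap

__all__ = [
    "PValueMap",
    "ConfidenceMap",
    "pvalues_gaussian",
    "pvalues_empirical",
    "adjust_by",
    "confidence_map",
    "threshold",
    "percent_voxels_detected",
    "atom_inclusion_fraction",
    "sigma_threshold",
]

# p-values are floored at the smallest positive normal float: a p of exactly 0
# would break the rank semantics of the step-up pass.
P_FLOOR = float(np.finfo(np.float64).tiny)


@dataclass
class PValueMap:
    """Per-voxel one-sided p-values on the same lattice as the source map."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValueError("empty p-value lattice")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ValueError("p-values must lie in (0, 1]")


@dataclass
class ConfidenceMap:
    """Per-voxel positive predictive values, PPV = 1 - q.

    Thresholding at PPV >= 1 - alpha keeps the voxels significant at FDR
    alpha.  q-values are strictly positive, but for extremely significant
    voxels (q below machine epsilon) the complement rounds to exactly 1.0 in
    floating point, so stored values lie in [0, 1].  ``noise_provenance``
    records how the null was obtained so a run can be audited.
    """

    values: np.ndarray
    fdr_method: str = "BY"
    noise_provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("confidence values must lie in [0, 1]")


def pvalues_gaussian(density_map: DensityMap, noise: NoiseModel) -> PValueMap:
    """Upper-tail Gaussian p-values: p = 1 - Phi((x - mean) / sd).

    A voxel exactly at the background mean gets p = 0.5; values far below
    the mean approach 1; the upper tail is floored at the smallest positive
    normal float rather than underflowing to 0.
    """
    if noise.variance <= 0:  # NoiseModel already guarantees this; belt-and-braces
        raise DegenerateNoiseError("noise variance must be positive")
    z = (density_map.values - noise.mean) / noise.sd
    p = ndtr(-z)  # upper tail = Phi(-z)
    return PValueMap(np.clip(p, P_FLOOR, 1.0))


def pvalues_empirical(density_map: DensityMap, noise: NoiseModel) -> PValueMap:
    """Empirical upper-tail p-values from the pooled background values.

    Uses the continuity-corrected tail (1 + #{b >= x}) / (n + 1), so p is 1
    below the background minimum and 1/(n+1) (never 0) above its maximum.
    """
    p = noise.tail(density_map.values)
    return PValueMap(p)


def adjust_by(pvalues: PValueMap) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (q-values).

    m counts every voxel in the lattice (background windows included), the
    conservative choice.  Ties are handled by a stable sort, the step-up
    minimum is a reversed running minimum over m*c(m)*p_(j)/j, and the result
    is clipped to [0, 1] and scattered back to the original lattice.
    """
    flat = pvalues.values.ravel()
    m = flat.size
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    order = np.argsort(flat, kind="stable")
    raw = flat[order] * (m * c_m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty(m, dtype=np.float64)
    q[order] = q_sorted
    return q.reshape(pvalues.values.shape)


def confidence_map(
    qvalues: np.ndarray, noise_provenance: dict[str, Any] | None = None
) -> ConfidenceMap:
    """PPV = 1 - q per voxel, with provenance carried along."""
    qvalues = np.asarray(qvalues, dtype=np.float64)
    if np.any(qvalues < 0) or np.any(qvalues > 1):
        raise ValueError("q-values must lie in [0, 1]")
    return ConfidenceMap(1.0 - qvalues, "BY", noise_provenance or {})


def threshold(conf: ConfidenceMap, fdr: float = 0.01) -> np.ndarray:
    """Binary detection lattice: voxel detected iff PPV >= 1 - fdr.

    Equivalent to q <= fdr.  The default of 1% FDR is the recommended
    working threshold for map interpretation.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must lie in (0, 1), got {fdr}")
    return conf.values >= 1.0 - fdr


def percent_voxels_detected(detections: np.ndarray) -> float:
    """Detected voxels as a percentage of all voxels in the lattice."""
    detections = np.asarray(detections, dtype=bool)
    return 100.0 * float(np.count_nonzero(detections)) / detections.size


def atom_inclusion_fraction(
    detections: np.ndarray,
    density_map: DensityMap,
    atoms: AtomicCoordinates,
) -> float:
    """Fraction of atoms whose containing voxel is detected.

    Atoms are mapped to voxels by the voxel-centre convention; atoms outside
    the box are excluded from the denominator (their count is recoverable by
    comparing ``len(atoms)`` with the in-box total).
    """
    if len(atoms) == 0:
        raise ValueError("empty atomic model")
    detections = np.asarray(detections, dtype=bool)
    idx = density_map.voxel_of(atoms.positions)
    dims = np.asarray(density_map.dims)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    if not np.any(inside):
        raise ValueError("all atoms fall outside the map box")
    idx_in = idx[inside]
    hits = detections[tuple(idx_in.T)]
    return float(np.mean(hits))


def sigma_threshold(
    density_map: DensityMap, noise: NoiseModel, k: float
) -> np.ndarray:
    """Conventional sigma thresholding: detected iff x >= mean + k*sd.

    The baseline contouring practice that confidence maps are compared
    against; it performs no multiple-testing correction.
    """
    if noise.variance <= 0:
        raise DegenerateNoiseError("noise variance must be positive")
    return density_map.values >= noise.mean + k * noise.sd
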