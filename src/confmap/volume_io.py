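"""Reading and writing volumetric maps (MRC2014/CCP4) and atomic coordinates (PDB).

The in-memory representation is :class:`DensityMap`: a dense scalar lattice
with a physical voxel size and origin, both in ångström.  Axis convention:
``values[i, j, k]`` indexes x, y, z in that order; on load, files whose
headers permute the axis order (MAPC/MAPR/MAPS) are normalised to this
convention so downstream math never sees deposition quirks.

Coordinate convention: voxel indices are 0-based and a voxel's physical
centre is ``origin + (index + 0.5) * voxel_size``.  This is used consistently
when atomic positions are mapped into the lattice.

File I/O is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    CoordinateParseError,
    EmptyModelError,
    MapFormatError,
    NonFiniteMapError,
)

__all__ = [
    "DensityMap",
    "AtomicCoordinates",
    "read_map",
    "write_map",
    "read_atomic_coordinates",
]


@dataclass
class DensityMap:
    """A 2D or 3D scalar lattice with physical metadata.

    Parameters
    ----------
    values : ndarray
        Voxel values, axis order x, y(, z).  Must be finite.
    voxel_size : tuple of float
        Å per voxel along each axis; all components > 0.
    origin : tuple of float
        Physical position (Å) of the lattice start (corner of voxel 0).
    """

    values: np.ndarray
    voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0)
    origin: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise MapFormatError(
                f"density lattice must be 2D or 3D, got {self.values.ndim}D"
            )
        if any(d < 1 for d in self.values.shape):
            raise MapFormatError(f"all dims must be >= 1, got {self.values.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)[: self.values.ndim]
        self.origin = tuple(float(v) for v in self.origin)[: self.values.ndim]
        if len(self.voxel_size) != self.values.ndim:
            raise MapFormatError("voxel_size must have one component per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise MapFormatError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            n_bad = int(np.size(self.values) - np.sum(np.isfinite(self.values)))
            raise NonFiniteMapError(
                f"map contains {n_bad} non-finite voxel value(s); refusing to "
                "proceed (they would corrupt background variance estimates)"
            )

    @property
    def dims(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def with_values(self, values: np.ndarray) -> "DensityMap":
        """A copy of this map carrying ``values`` on the same lattice."""
        return DensityMap(values, self.voxel_size, self.origin)

    def voxel_of(self, position: np.ndarray) -> np.ndarray:
        """Map physical positions (Å) to containing voxel indices.

        Under the voxel-centre convention the voxel containing physical
        point ``p`` along an axis is ``floor((p - origin) / voxel_size)``.
        Indices may fall outside the lattice; callers check bounds.
        """
        pos = np.atleast_2d(np.asarray(position, dtype=float))
        vs = np.asarray(self.voxel_size)
        org = np.asarray(self.origin)
        return np.floor((pos - org) / vs).astype(int)


@dataclass
class AtomicCoordinates:
    """Atomic positions in Å (model frame) with informational element labels."""

    positions: np.ndarray  # (n, 3)
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.positions.shape[0]


def read_map(path: os.PathLike | str) -> DensityMap:
    """Read an MRC2014/CCP4 map, normalising the axis order to x, y, z.

    The voxel size is taken from the unit cell and sampling, the origin from
    the ORIGIN header words (falling back to NXSTART offsets for CCP4-style
    files).  Maps containing non-finite values are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MapFormatError(f"no such file: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(path)
        # reorder axes per MAPC/MAPR/MAPS without resampling
        ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read {path} as MRC/CCP4: {exc}") from exc

    values = np.array(ccp4.grid, copy=True)
    spacing = tuple(float(s) for s in ccp4.grid.spacing)
    origin = tuple(float(ccp4.header_float(w)) for w in (50, 51, 52))
    if all(o == 0.0 for o in origin):
        nstart = [ccp4.header_i32(w) for w in (5, 6, 7)]
        origin = tuple(n * s for n, s in zip(nstart, spacing))
    if not np.all(np.isfinite(values)):
        n_bad = int(values.size - np.sum(np.isfinite(values)))
        raise NonFiniteMapError(f"{path}: {n_bad} non-finite voxel value(s)")
    return DensityMap(values, spacing, origin)


def write_map(density_map: DensityMap, path: os.PathLike | str) -> None:
    """Write a map as MRC2014 mode-2 (float32) with correct header metadata.

    2D lattices are written as single-section volumes.  Confidence maps are
    plain float volumes in [0, 1], so any standard viewer can contour them.
    """
    values = density_map.values
    voxel_size = density_map.voxel_size
    origin = density_map.origin
    if values.ndim == 2:
        values = values[:, :, np.newaxis]
        voxel_size = (*voxel_size, voxel_size[-1])
        origin = (*origin, 0.0)

    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(values, dtype=np.float32))
    nx, ny, nz = values.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * voxel_size[0], ny * voxel_size[1], nz * voxel_size[2], 90.0, 90.0, 90.0
    )
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(os.fspath(path))


def read_atomic_coordinates(path: os.PathLike | str) -> AtomicCoordinates:
    """Read all ATOM and HETATM positions (Å) from a PDB file.

    Coordinate fields are validated up front so that a malformed record is
    reported with its line number instead of being silently repaired.
    """
    path = os.fspath(path)
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi]
                    try:
                        float(fld)
                    except ValueError:
                        raise CoordinateParseError(
                            f"{path}:{line_no}: unparseable coordinate "
                            f"field {fld!r}"
                        ) from None
    structure = gemmi.read_pdb(path)
    positions: list[tuple[float, float, float]] = []
    elements: list[str] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    positions.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    elements.append(atom.element.name)
    if not positions:
        raise EmptyModelError(f"{path}: no ATOM/HETATM records")
    return AtomicCoordinates(np.asarray(positions), elements)
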