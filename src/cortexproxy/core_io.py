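"""Volume/time-series containers and NIfTI + tabular I/O.

Axis convention (fixed throughout the package): axis 0 runs left->right,
axis 1 posterior->anterior, axis 2 inferior->superior (RAS+). Voxel indices
are 0-based and a voxel's position in mm is ``index * voxel_size_mm`` at the
voxel center. Images whose affine is a pure permutation/flip of this
orientation are reoriented on load; oblique affines are rejected rather than
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "BoldRun",
    "FormatError",
    "ConfigurationError",
    "InputError",
    "read_volume",
    "write_volume",
    "read_bold",
    "write_bold",
    "read_motion",
    "write_motion",
]


class FormatError(ValueError):
    """A file does not satisfy the on-disk format contract."""


class ConfigurationError(ValueError):
    """A required parameter is missing or out of range."""


class InputError(ValueError):
    """An in-memory input violates an operation's precondition."""


@dataclass
class VolumeGrid:
    """A 3-D scalar/boolean/integer lattice with per-axis voxel size in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Boolean arrays represent masks; non-negative integer
        arrays represent label atlases (0 = background).
    voxel_size_mm : tuple of 3 floats
        Edge length of a voxel along each axis, strictly positive.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError(f"VolumeGrid requires 3-D data, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or not all(np.isfinite(v) and v > 0 for v in vs):
            raise FormatError(f"voxel sizes must be 3 positive finite reals, got {vs}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_bool(self) -> "VolumeGrid":
        return VolumeGrid(self.data.astype(bool), self.voxel_size_mm)


@dataclass
class BoldRun:
    """One resting-state run: a 4-D (space x time) lattice.

    ``data`` has shape (nx, ny, nz, T) with T >= 2; ``tr_s`` is the repetition
    time in seconds. Non-finite values are rejected at construction.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InputError(f"BoldRun requires 4-D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise InputError("BoldRun requires T >= 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("BoldRun data contains non-finite values")
        if not (np.isfinite(self.tr_s) and self.tr_s > 0):
            raise ConfigurationError(f"repetition time must be positive, got {self.tr_s}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if not all(np.isfinite(v) and v > 0 for v in vs):
            raise FormatError(f"voxel sizes must be positive, got {vs}")
        self.voxel_size_mm = vs

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def T(self) -> int:
        return self.data.shape[3]


def _check_not_oblique(affine: np.ndarray) -> None:
    """Reject affines that are not a permutation/flip of the grid axes.

    Each column of the rotation block must have exactly one entry that is
    non-negligible relative to the column norm; anything else would require
    resampling, which is out of scope.
    """
    rot = np.asarray(affine)[:3, :3]
    for j in range(3):
        col = np.abs(rot[:, j])
        norm = col.max()
        if norm == 0 or not np.isfinite(norm):
            raise FormatError("degenerate affine column")
        if np.sum(col > 1e-3 * norm) != 1:
            raise FormatError(
                "oblique affine: volume is not axis-aligned and resampling is not supported"
            )


def _load_canonical(path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    _check_not_oblique(img.affine)
    return nib.as_closest_canonical(img)


def read_volume(path) -> VolumeGrid:
    """Read a 3-D NIfTI volume and canonicalize its orientation.

    Returns a :class:`VolumeGrid` whose data axes follow the package
    convention (axis 2 inferior->superior) regardless of how the file was
    stored, provided the affine is axis-aligned.
    """
    img = _load_canonical(path)
    if img.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got ndim={img.ndim}: {path}")
    zooms = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise FormatError(f"volume contains non-finite values: {path}")
    return VolumeGrid(data, tuple(float(z) for z in zooms))


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1 with a diagonal RAS affine."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def read_bold(path, tr_s: float | None = None) -> BoldRun:
    """Read a 4-D NIfTI run.

    The repetition time is taken from the header's 4th zoom; pass ``tr_s`` to
    override. A missing/zero header TR without an override raises
    :class:`ConfigurationError`.
    """
    img = _load_canonical(path)
    if img.ndim != 4:
        raise FormatError(f"expected a 4-D run, got ndim={img.ndim}: {path}")
    zooms = img.header.get_zooms()
    if tr_s is None:
        header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not np.isfinite(header_tr) or header_tr <= 0:
            raise ConfigurationError(
                f"no repetition time in header of {path}; pass tr_s explicitly"
            )
        tr_s = header_tr
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return BoldRun(data, tuple(float(z) for z in zooms[:3]), float(tr_s))


def write_bold(run: BoldRun, path) -> None:
    affine = np.diag(list(run.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(run.voxel_size_mm) + (run.tr_s,))
    nib.save(img, str(path))


def read_motion(path, t_expected: int | None = None) -> np.ndarray:
    """Read a whitespace-delimited motion-parameter table (T rows x 6 cols)."""
    table = np.loadtxt(str(path), dtype=np.float64, ndmin=2)
    if table.ndim != 2 or table.shape[1] != 6:
        raise FormatError(
            f"motion table must have 6 columns, got shape {table.shape}: {path}"
        )
    if not np.all(np.isfinite(table)):
        raise FormatError(f"motion table contains non-finite values: {path}")
    if t_expected is not None and table.shape[0] != t_expected:
        raise FormatError(
            f"motion table has {table.shape[0]} rows, expected {t_expected}: {path}"
        )
    return table


def write_motion(table: np.ndarray, path) -> None:
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[1] != 6:
        raise InputError(f"motion table must be T x 6, got {table.shape}")
    np.savetxt(str(path), table, fmt="%.10g")
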