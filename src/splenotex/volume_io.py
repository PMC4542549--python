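"""Image-volume containers and I/O.

Defines the axis convention used throughout the package: volumes are numpy
arrays indexed ``(z, y, x)`` — slice, row, column — so the voxel at index
``(0, 0, 0)`` is the first pixel of the first page of a multi-page TIFF.
``x`` is the column direction, ``y`` the row direction, ``z`` the slice
(depth) direction. Voxels are assumed isotropic; anisotropic input is
rejected because displacement vectors mix x and z components, which only
makes sense on an isotropic grid.

ROI indexing is 0-based and half-open everywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

RAW_FLOAT = "raw-float"
QUANTISED_8BIT = "quantised-8bit"

_LOSSY_EXTENSIONS = {".jpg", ".jpeg"}


@dataclass
class ImageVolume:
    """A 2-D or 3-D scalar image with an isotropic voxel size.

    Parameters
    ----------
    values
        Array indexed ``(z, y, x)`` (3-D) or ``(y, x)`` (2-D).
    dtype_role
        ``"raw-float"`` for reconstruction-space attenuation values or
        ``"quantised-8bit"`` for images scaled to integers in [0, 255].
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    provenance
        Free-text processing history; appended to by each operation.
    """

    values: np.ndarray
    dtype_role: str = RAW_FLOAT
    voxel_size_um: float = 26.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D data, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.dtype_role not in (RAW_FLOAT, QUANTISED_8BIT):
            raise ValueError(f"unknown dtype_role {self.dtype_role!r}")
        if self.dtype_role == QUANTISED_8BIT:
            v = self.values
            if not np.issubdtype(v.dtype, np.integer):
                raise ValueError("quantised-8bit volume must have integer dtype")
            if v.size and (v.min() < 0 or v.max() > 255):
                raise ValueError("quantised-8bit values must lie in [0, 255]")
            self.values = v.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (e.g. (26 um)^3 = 1.7576e-5 mm^3)."""
        return (self.voxel_size_um * 1e-3) ** 3

    def with_values(self, values: np.ndarray, *, dtype_role: str | None = None,
                    note: str = "") -> "ImageVolume":
        """Return a copy carrying new values and an appended provenance note."""
        prov = self.provenance
        if note:
            prov = f"{prov}; {note}" if prov else note
        return ImageVolume(values, dtype_role=dtype_role or self.dtype_role,
                           voxel_size_um=self.voxel_size_um, provenance=prov)


@dataclass(frozen=True)
class ROISpec:
    """A rectangular region of interest, 0-based and half-open.

    ``origin`` and ``shape`` are given in ``(x, y, z)`` order, matching how
    ROI dimensions are quoted (e.g. 200 x 200 x 30 means nx=200, ny=200,
    nz=30); the extracted array is indexed ``(z, y, x)``.
    """

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("origin and shape must be (x, y, z) triples")
        if any(o < 0 for o in self.origin):
            raise ValueError("origin components must be >= 0")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape components must be >= 1")

    def slices(self) -> tuple[slice, slice, slice]:
        """(z, y, x) slices for indexing a volume array."""
        (x0, y0, z0), (nx, ny, nz) = self.origin, self.shape
        return slice(z0, z0 + nz), slice(y0, y0 + ny), slice(x0, x0 + nx)


# ---------------------------------------------------------------------------
# Reading and writing


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "directory"
    ext = path.suffix.lower()
    if ext in (".tif", ".tiff"):
        return "tiff"
    if ext == ".nii" or path.name.lower().endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer volume format from {path}")


def read_volume(path: str | os.PathLike, format: str | None = None,
                voxel_size_um: float | None = None) -> ImageVolume:
    """Read an image volume from TIFF, NIfTI-1, or a directory of 2-D images.

    Directory input is stacked in lexicographic filename order, one file per
    z slice. JPEG slices are accepted but flagged as lossy in provenance.
    For NIfTI the voxel size is taken from the header unless overridden;
    anisotropic headers raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)

    if fmt == "tiff":
        import tifffile

        values = tifffile.imread(path)
        prov = f"read TIFF {path.name}"
    elif fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D NIfTI, got ndim={data.ndim}")
        # NIfTI stores (x, y, z); transpose to (z, y, x)
        values = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-4):
            raise ValueError(f"anisotropic voxels {zooms} are not supported")
        if voxel_size_um is None:
            voxel_size_um = float(zooms[0]) * 1000.0  # header zooms in mm
        prov = f"read NIfTI {path.name}"
    elif fmt == "directory":
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.is_file() and not p.name.startswith("."))
        if not files:
            raise ValueError(f"no image files in {path}")
        slices = []
        lossy = False
        shape0 = None
        for f in files:
            arr = iio.imread(f)
            if arr.ndim == 3:  # RGB(A) -> luma-free grey by channel mean
                arr = arr.mean(axis=-1)
            if shape0 is None:
                shape0 = arr.shape
            elif arr.shape != shape0:
                raise ValueError(
                    f"slice {f.name} has shape {arr.shape}, expected {shape0}")
            if f.suffix.lower() in _LOSSY_EXTENSIONS:
                lossy = True
            slices.append(arr)
        values = np.stack(slices, axis=0)
        prov = f"read {len(files)} slices from {path.name}"
        if lossy:
            prov += " (JPEG input: lossy, intensities may be quantised)"
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if np.issubdtype(values.dtype, np.unsignedinteger) and values.dtype.itemsize == 1:
        role = QUANTISED_8BIT
    else:
        role = RAW_FLOAT
        values = values.astype(np.float32, copy=False)
    return ImageVolume(values, dtype_role=role,
                       voxel_size_um=voxel_size_um if voxel_size_um else 26.0,
                       provenance=prov)


def write_volume(volume: ImageVolume, path: str | os.PathLike,
                 format: str | None = None) -> None:
    """Write a volume as multi-page TIFF (8-bit or 32-bit float) or NIfTI-1."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        import tifffile

        if volume.dtype_role == QUANTISED_8BIT:
            data = volume.values.astype(np.uint8)
        else:
            data = volume.values.astype(np.float32)
        tifffile.imwrite(path, data, photometric="minisblack")
    elif fmt == "nifti":
        import nibabel as nib

        data = np.transpose(np.atleast_3d(volume.values), (2, 1, 0))
        mm = volume.voxel_size_um * 1e-3
        img = nib.Nifti1Image(np.ascontiguousarray(data), np.diag([mm, mm, mm, 1.0]))
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported write format {fmt!r}")


def save_table(records: Iterable[Mapping], path: str | os.PathLike,
               fieldnames: Sequence[str] | None = None) -> None:
    """Write homogeneous records as CSV with a header row.

    An empty record list writes a header-only CSV; for that case the column
    names must be supplied via ``fieldnames``.
    """
    import pandas as pd

    records = list(records)
    if records:
        df = pd.DataFrame.from_records(records)
        if fieldnames is not None:
            df = df[list(fieldnames)]
    else:
        if fieldnames is None:
            raise ValueError("fieldnames required to write an empty table")
        df = pd.DataFrame(columns=list(fieldnames))
    df.to_csv(path, index=False)
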