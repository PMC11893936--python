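"""Voxel-grid containers, discrete vector calculus, and volume I/O.

The segmentation model lives on a regular 3-D voxel grid with physical
spacing.  Arrays are indexed ``(x, y, z)``, 0-based; world coordinates are
``origin + index * spacing``.  The x axis is the rotation axis of the
parametric left-ventricle model (see :mod:`cmflv.lv_model`).

The total-variation machinery needs a gradient/divergence pair that are
exact negative adjoints of each other: forward differences with Neumann
(zero-flux) boundaries for the gradient, backward differences for the
divergence — the standard discretization for Chambolle-type schemes.

Supported formats: Interfile (ASCII ``key := value`` header + raw binary),
NIfTI-1 (via nibabel) and DICOM series (read-only, via pydicom).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridError",
    "FormatError",
    "Volume",
    "LabelField",
    "BinaryMask",
    "VectorField",
    "gradient",
    "divergence",
    "read_volume",
    "write_volume",
]


class GridError(ValueError):
    """Mismatched or invalid voxel grids."""


class FormatError(ValueError):
    """Unreadable or inconsistent volume file."""


def _as_3d(a, name: str, min_dim: int = 1) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 3:
        raise GridError(f"{name} must be 3-D, got shape {a.shape}")
    if any(s < min_dim for s in a.shape):
        raise GridError(f"{name} needs all dims >= {min_dim}, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GridError(f"{name} contains non-finite values")
    return a


@dataclass
class Volume:
    """Scalar 3-D activity field (counts or Bq/mL) on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Non-negative voxel values.
    spacing : tuple of float
        Voxel size (dx, dy, dz) in mm; all positive.
    origin : tuple of float
        World position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = _as_3d(self.data, "Volume.data")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be 3 positive reals, got {self.spacing}")
        if len(self.origin) != 3:
            raise GridError("origin must have 3 components")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def like(self, data) -> "Volume":
        """New Volume with the same grid geometry but different data."""
        return Volume(data, self.spacing, self.origin)


@dataclass
class LabelField:
    """Relaxed label lambda(x) in [0, 1] on a voxel grid."""

    lam: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.lam = _as_3d(self.lam, "LabelField.lam")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.lam.min() < -1e-12 or self.lam.max() > 1 + 1e-12:
            raise GridError("label values must lie in [0, 1]")
        np.clip(self.lam, 0.0, 1.0, out=self.lam)


@dataclass
class BinaryMask:
    """Hard {0, 1} labeling on a voxel grid."""

    mask: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise GridError(f"mask must be 3-D, got shape {m.shape}")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise GridError("mask values must be exactly 0 or 1")
        self.mask = m.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class VectorField:
    """Spatial flow p(x) with one component array per axis."""

    px: np.ndarray
    py: np.ndarray
    pz: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.px = _as_3d(self.px, "VectorField.px")
        self.py = _as_3d(self.py, "VectorField.py")
        self.pz = _as_3d(self.pz, "VectorField.pz")
        if not (self.px.shape == self.py.shape == self.pz.shape):
            raise GridError("vector components must share one grid")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.px.shape

    @classmethod
    def zeros(cls, shape, spacing=(1.0, 1.0, 1.0)) -> "VectorField":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape), spacing)

    def norm(self) -> np.ndarray:
        """Pointwise Euclidean norm |p(x)|."""
        return np.sqrt(self.px**2 + self.py**2 + self.pz**2)


# ---------------------------------------------------------------------------
# Discrete vector calculus
# ---------------------------------------------------------------------------

def _forward_diff(a: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Forward difference with zero-flux across the last face."""
    d = np.zeros_like(a)
    if a.shape[axis] < 2:
        return d
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    d[tuple(sl_lo)] = (a[tuple(sl_hi)] - a[tuple(sl_lo)]) / h
    return d


def gradient(lam: LabelField) -> VectorField:
    """Forward-difference gradient of a label field, scaled by spacing.

    Neumann boundary: the difference across the last face along each axis
    is zero, so constant fields have exactly zero gradient.
    """
    a = lam.lam
    hx, hy, hz = lam.spacing
    return VectorField(
        _forward_diff(a, 0, hx),
        _forward_diff(a, 1, hy),
        _forward_diff(a, 2, hz),
        lam.spacing,
    )


def _backward_diff(comp: np.ndarray, axis: int, h: float) -> np.ndarray:
    # Negative adjoint of _forward_diff: interior backward differences with
    # the boundary rows that make <grad u, p> + <u, div p> vanish identically.
    if comp.shape[axis] < 2:
        # singleton axis: its gradient is identically zero, so its adjoint is too
        return np.zeros_like(comp)
    d = np.empty_like(comp)
    first = [slice(None)] * 3
    last = [slice(None)] * 3
    inner = [slice(None)] * 3
    shifted = [slice(None)] * 3
    first[axis] = 0
    last[axis] = -1
    inner[axis] = slice(1, -1)
    shifted[axis] = slice(0, -2)
    d[tuple(first)] = comp[tuple(first)] / h
    d[tuple(inner)] = (comp[tuple(inner)] - comp[tuple(shifted)]) / h
    prev_last = [slice(None)] * 3
    prev_last[axis] = -2
    d[tuple(last)] = -comp[tuple(prev_last)] / h
    return d


def divergence(p: VectorField) -> np.ndarray:
    """Backward-difference divergence, the exact negative adjoint of
    :func:`gradient` under the Neumann convention."""
    hx, hy, hz = p.spacing
    return (
        _backward_diff(p.px, 0, hx)
        + _backward_diff(p.py, 1, hy)
        + _backward_diff(p.pz, 2, hz)
    )


# ---------------------------------------------------------------------------
# Interfile dialect
# ---------------------------------------------------------------------------

_NUMBER_FORMATS = {
    ("unsigned integer", 2): np.dtype("<u2"),
    ("unsigned integer", 4): np.dtype("<u4"),
    ("signed integer", 2): np.dtype("<i2"),
    ("signed integer", 4): np.dtype("<i4"),
    ("short float", 4): np.dtype("<f4"),
    ("float", 4): np.dtype("<f4"),
    ("float", 8): np.dtype("<f8"),
    ("long float", 8): np.dtype("<f8"),
}

_MANDATORY_KEYS = (
    "matrix size [1]",
    "matrix size [2]",
    "matrix size [3]",
    "scaling factor (mm/pixel) [1]",
    "scaling factor (mm/pixel) [2]",
    "scaling factor (mm/pixel) [3]",
    "number format",
    "name of data file",
)


def _parse_interfile_header(path: str) -> dict:
    keys = {}
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line or ":=" not in line:
                continue
            key, _, val = line.partition(":=")
            key = key.lstrip("!").strip().lower()
            keys[key] = val.strip()
    for k in _MANDATORY_KEYS:
        if k not in keys:
            raise FormatError(f"Interfile header missing mandatory key '{k}'")
    return keys


def _read_interfile(path: str) -> Volume:
    keys = _parse_interfile_header(path)
    try:
        shape = tuple(int(keys[f"matrix size [{i}]"]) for i in (1, 2, 3))
        spacing = tuple(
            float(keys[f"scaling factor (mm/pixel) [{i}]"]) for i in (1, 2, 3)
        )
    except ValueError as exc:
        raise FormatError(f"non-numeric Interfile geometry: {exc}") from exc
    nbytes = int(keys.get("number of bytes per pixel", 4))
    fmt = keys["number format"].lower()
    byte_order = keys.get("imagedata byte order", "littleendian").lower()
    dtype = _NUMBER_FORMATS.get((fmt, nbytes))
    if dtype is None:
        raise FormatError(f"unsupported Interfile number format '{fmt}'/{nbytes}B")
    if byte_order.startswith("big"):
        dtype = dtype.newbyteorder(">")
    offset = int(keys.get("data offset in bytes", 0))
    datafile = os.path.join(os.path.dirname(path), keys["name of data file"])
    n = int(np.prod(shape))
    raw = np.fromfile(datafile, dtype=dtype, count=n, offset=offset)
    if raw.size != n:
        raise FormatError(
            f"Interfile data file holds {raw.size} voxels, header promises {n}"
        )
    if not np.all(np.isfinite(raw.astype(np.float64))):
        raise FormatError("non-numeric voxel data in Interfile payload")
    origin = tuple(
        float(keys.get(f"first pixel offset (mm) [{i}]", 0.0)) for i in (1, 2, 3)
    )
    # x varies fastest on disk
    data = raw.reshape(shape, order="F").astype(np.float64)
    return Volume(data, spacing, origin)


def _write_interfile(vol: Volume, path: str) -> None:
    base = os.path.splitext(os.path.basename(path))[0]
    datafile = base + ".img"
    data = vol.data.astype("<f4")
    with open(path, "w", encoding="ascii") as fh:
        fh.write("!INTERFILE :=\n")
        fh.write(f"name of data file := {datafile}\n")
        fh.write("number format := short float\n")
        fh.write("number of bytes per pixel := 4\n")
        fh.write("imagedata byte order := LITTLEENDIAN\n")
        fh.write("data offset in bytes := 0\n")
        for i, (n, s, o) in enumerate(
            zip(vol.shape, vol.spacing, vol.origin), start=1
        ):
            fh.write(f"matrix size [{i}] := {n}\n")
            fh.write(f"scaling factor (mm/pixel) [{i}] := {s!r}\n")
            fh.write(f"first pixel offset (mm) [{i}] := {o!r}\n")
        fh.write("!END OF INTERFILE :=\n")
    data.T.reshape(-1).tofile(os.path.join(os.path.dirname(path), datafile))


# ---------------------------------------------------------------------------
# NIfTI / DICOM
# ---------------------------------------------------------------------------

def _read_nifti(path: str) -> Volume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3-D NIfTI, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), tuple(map(float, zooms)), origin)


def _write_nifti(vol: Volume, path: str) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), path)


def _read_dicom_series(path: str) -> Volume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    if not files:
        raise FormatError(f"no DICOM files in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception as exc:  # unreadable member file
            raise FormatError(f"cannot parse DICOM file {f}: {exc}") from exc
    slices.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    arrs = [ds.pixel_array.astype(np.float64) for ds in slices]
    ds0 = slices[0]
    ps = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    dz = float(
        getattr(ds0, "SpacingBetweenSlices", getattr(ds0, "SliceThickness", 1.0))
    )
    # slice stack along z; pixel rows/cols -> (x, y)
    data = np.stack(arrs, axis=-1).transpose(1, 0, 2)
    pos = getattr(ds0, "ImagePositionPatient", (0.0, 0.0, 0.0))
    return Volume(data, (float(ps[1]), float(ps[0]), dz), tuple(float(v) for v in pos))


_FORMATS = ("interfile", "nifti", "dicom_series")


def _guess_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom_series"
    if re.search(r"\.nii(\.gz)?$", path):
        return "nifti"
    return "interfile"


def read_volume(path: str, format: str | None = None) -> Volume:
    """Read a 3-D volume with spacing from Interfile, NIfTI-1 or a DICOM dir."""
    fmt = format or _guess_format(path)
    if fmt == "interfile":
        return _read_interfile(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format '{fmt}'; expected one of {_FORMATS}")


def write_volume(vol: Volume, path: str, format: str | None = None,
                 overwrite: bool = False) -> None:
    """Write a volume (NIfTI-1 default, Interfile supported; no DICOM writing)."""
    fmt = format or ("interfile" if path.endswith((".hdr", ".hv")) else "nifti")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "interfile":
        _write_interfile(vol, path)
    else:
        raise FormatError(f"unknown or unwritable format '{fmt}'")
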