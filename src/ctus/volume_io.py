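"""Volume and image I/O.

The :class:`CTVolume` container is shared by every stage of the simulator:
the phantom generator emits one, the vesselness filter consumes and produces
them, and slice extraction reads one.  Physical convention: voxel indices are
0-based and voxel-centered, so the physical position of voxel ``(i, j, k)`` is
``origin + index * spacing`` (mm).

Supported on-disk formats:

* NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel,
* MetaImage (``.mhd`` / ``.mha``) via SimpleITK,
* headerless raw (``.raw``) with a ``<path>.hdr`` key=value sidecar,
* 8-bit grayscale PNG / PGM for rendered ultrasound frames via Pillow.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "CTVolume",
    "UltrasoundImage",
    "FormatError",
    "read_volume",
    "write_volume",
    "write_image",
    "read_image",
]

VALID_UNIT_TAGS = ("HU", "raw", "unknown")


class FormatError(ValueError):
    """A file's structure contradicts its declared format."""


@dataclass
class CTVolume:
    """A 3D scalar field with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities, Hounsfield units or raw scanner units.
    spacing : tuple of 3 floats
        Physical size of one voxel per axis, mm.  Strictly positive.
    origin : tuple of 3 floats
        Physical coordinate of voxel (0, 0, 0), mm.
    unit_tag : {"HU", "raw", "unknown"}
        Declared intensity calibration.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    unit_tag: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        if self.unit_tag not in VALID_UNIT_TAGS:
            raise ValueError(f"unit_tag must be one of {VALID_UNIT_TAGS}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains NaN or infinite voxels")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def world_extent(self) -> np.ndarray:
        """Physical coordinates of the last voxel center per axis (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(
            self.spacing
        )

    def copy_with(self, data: np.ndarray, unit_tag: Optional[str] = None) -> "CTVolume":
        """Same geometry, new voxel data."""
        return CTVolume(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            unit_tag=self.unit_tag if unit_tag is None else unit_tag,
        )


@dataclass
class UltrasoundImage:
    """Final rendered B-mode frame: 8-bit pixels plus sector geometry.

    ``pixels`` is row-major with the apex at the top; ``mask`` marks pixels
    inside the sector; every pixel outside the mask is exactly 0.
    ``origin`` / ``pitch`` place the raster in slice coordinates (mm).
    """

    pixels: np.ndarray
    geometry: object = None
    mask: Optional[np.ndarray] = None
    origin: tuple = (0.0, 0.0)
    pitch: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("image pixels must be 2D")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels")
            if np.any(self.pixels[~self.mask] != 0):
                raise ValueError("pixels outside the sector mask must be 0")


# ---------------------------------------------------------------------------
# volume readers / writers
# ---------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".hdr"


def _sniff_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint.lower()
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mhd", ".mha")):
        return "metaimage"
    if name.endswith(".raw"):
        return "raw"
    raise FormatError(f"cannot infer volume format from file name: {path}")


def read_volume(path, format_hint: Optional[str] = None) -> CTVolume:
    """Read a CT volume from NIfTI, MetaImage or raw+sidecar.

    Raises ``IOError`` for missing/unreadable files and :class:`FormatError`
    when the file contents contradict the declared format (e.g. a raw file
    whose byte count does not match the sidecar's dims and dtype).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    fmt = _sniff_format(path, format_hint)
    if fmt == "nifti":
        vol = _read_nifti(path)
    elif fmt == "metaimage":
        vol = _read_metaimage(path)
    elif fmt == "raw":
        vol = _read_raw(path)
    else:
        raise FormatError(f"unknown format hint {format_hint!r}")
    if np.issubdtype(vol.data.dtype, np.floating) and not np.all(
        np.isfinite(vol.data)
    ):  # pragma: no cover - CTVolume also rejects
        raise FormatError(f"volume {path} contains NaN voxels")
    return vol


def write_volume(volume: CTVolume, path) -> None:
    """Write a volume so that :func:`read_volume` round-trips it exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    fmt = _sniff_format(path, None)
    try:
        if fmt == "nifti":
            _write_nifti(volume, path)
        elif fmt == "metaimage":
            _write_metaimage(volume, path)
        else:
            _write_raw(volume, path)
    except PermissionError as exc:
        raise IOError(f"cannot write volume to {path}: {exc}") from exc


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode("ascii", "ignore")
    unit_tag = "HU" if "units=HU" in descrip else "raw"
    return CTVolume(data, tuple(float(z) for z in zooms), origin, unit_tag)


def _write_nifti(volume: CTVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    if volume.unit_tag == "HU":
        img.header["descrip"] = b"units=HU"
    nib.save(img, str(path))


def _read_metaimage(path: Path) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    unit_tag = "raw"
    if img.HasMetaDataKey("IntensityUnits") and img.GetMetaData(
        "IntensityUnits"
    ) == "HU":
        unit_tag = "HU"
    return CTVolume(data, img.GetSpacing(), img.GetOrigin(), unit_tag)


def _write_metaimage(volume: CTVolume, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    if volume.unit_tag == "HU":
        img.SetMetaData("IntensityUnits", "HU")
    sitk.WriteImage(img, str(path))


def _read_raw(path: Path) -> CTVolume:
    sidecar = Path(str(path) + _SIDECAR_SUFFIX)
    if not sidecar.exists():
        raise IOError(f"raw volume sidecar not found: {sidecar}")
    meta = {}
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        meta[key.strip().lower()] = value.strip()
    try:
        dims = tuple(int(v) for v in meta["dims"].split())
        spacing = tuple(float(v) for v in meta["spacing"].split())
        dtype = np.dtype(meta["dtype"])
    except KeyError as exc:
        raise FormatError(f"raw sidecar {sidecar} missing key {exc}") from exc
    endian = meta.get("endianness", "little")
    dtype = dtype.newbyteorder("<" if endian == "little" else ">")
    origin = tuple(float(v) for v in meta.get("origin", "0 0 0").split())
    unit_tag = meta.get("units", "raw")
    if unit_tag not in VALID_UNIT_TAGS:
        unit_tag = "raw"
    raw = path.read_bytes()
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(raw) != expected:
        raise FormatError(
            f"raw file {path}: got {len(raw)} bytes, sidecar implies {expected} "
            f"(dims={dims}, dtype={dtype})"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(dims)
    return CTVolume(data, spacing, origin, unit_tag)


def _write_raw(volume: CTVolume, path: Path) -> None:
    data = np.ascontiguousarray(volume.data)
    dtype = data.dtype.newbyteorder("<")
    path.write_bytes(data.astype(dtype, copy=False).tobytes())
    sidecar = Path(str(path) + _SIDECAR_SUFFIX)
    sidecar.write_text(
        "dims = {} {} {}\n".format(*data.shape)
        + "spacing = {} {} {}\n".format(*volume.spacing)
        + "origin = {} {} {}\n".format(*volume.origin)
        + f"dtype = {data.dtype.name}\n"
        + "endianness = little\n"
        + f"units = {volume.unit_tag}\n"
    )


# ---------------------------------------------------------------------------
# image writer
# ---------------------------------------------------------------------------


def write_image(image: UltrasoundImage, path) -> None:
    """Write an 8-bit grayscale PNG or PGM (chosen by extension); lossless."""
    from PIL import Image

    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    pixels = image.pixels
    if image.mask is not None:
        pixels = np.where(image.mask, pixels, 0).astype(np.uint8)
    # image rows are the first axis already; Pillow expects (rows, cols)
    pil = Image.fromarray(pixels, mode="L")
    try:
        if path.suffix.lower() == ".pgm":
            pil.save(str(path), format="PPM")
        else:
            pil.save(str(path), format="PNG")
    except PermissionError as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def read_image(path) -> np.ndarray:
    """Read back an 8-bit grayscale image as a uint8 array."""
    from PIL import Image

    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    with Image.open(str(path)) as pil:
        return np.asarray(pil.convert("L"), dtype=np.uint8)
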