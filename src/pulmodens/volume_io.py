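"""Volumetric I/O, Hounsfield calibration and pre-filtering.

Micro-CT scanners deliver reconstructed chest volumes as stacks of
unsigned 16-bit cross-sections.  This module reads and writes those
volumes (NIfTI, MetaImage, multi-page TIFF, or raw 16-bit with a JSON
sidecar), converts scanner grey levels to CT numbers (Hounsfield units,
HU) with a two-point air/water calibration, and applies the cubic
median pre-filter that precedes every densitometric analysis.

Axis convention is ``(z, y, x)`` — slice, row, column — throughout the
package, with 0-based voxel indexing.  Voxel spacing is isotropic and
expressed in micrometres (µm); murine chest protocols typically
reconstruct at 50 µm.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("pulmodens")

#: Default isotropic voxel spacing assumed when a file carries none (µm).
DEFAULT_SPACING_UM = 50.0

#: CT numbers are stored clipped to the conventional 12-bit HU window.
HU_MIN = -1024.0
HU_MAX = 3071.0

_FORMATS = ("nifti", "metaimage", "tiff_stack", "raw")


class VolumeIOError(IOError):
    """Raised when a volume file cannot be read or written."""


class CalibrationError(ValueError):
    """Raised for invalid grey→HU calibration references."""


@dataclass
class RawVolume:
    """Reconstructed scanner output: unsigned 16-bit grey values.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx), dtype uint16
        Grey values in ``[0, 65535]``.
    spacing_um : float
        Isotropic voxel edge length in µm, > 0.
    """

    voxels: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("RawVolume requires a 3-D lattice with all dims >= 1")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")
        if self.voxels.dtype != np.uint16:
            vmin, vmax = self.voxels.min(), self.voxels.max()
            if vmin < 0 or vmax > 65535:
                raise ValueError("grey values must lie in [0, 65535]")
            self.voxels = self.voxels.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class CTVolume:
    """Calibrated CT volume in Hounsfield units.

    ``voxels`` is float32 (finer than 1 HU resolution), clipped to
    ``[-1024, +3071]``.  ``provenance`` records calibration references
    and any filtering applied, for auditability.
    """

    voxels: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("CTVolume requires a 3-D lattice with all dims >= 1")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")
        np.clip(self.voxels, HU_MIN, HU_MAX, out=self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _guess_format(path: str) -> str:
    p = path.lower()
    if p.endswith((".nii", ".nii.gz")):
        return "nifti"
    if p.endswith((".mhd", ".mha")):
        return "metaimage"
    if p.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if p.endswith(".raw"):
        return "raw"
    raise VolumeIOError(f"cannot infer volume format from path {path!r}")


def _read_array(path: str, fmt: str) -> tuple[np.ndarray, float | None]:
    """Return ``(voxels_zyx, spacing_um or None)`` for a file."""
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj)
        if arr.ndim != 3:
            raise VolumeIOError(f"NIfTI file {path!r} is not 3-D")
        # NIfTI stores (x, y, z); flip to our (z, y, x) convention.
        arr = np.transpose(arr, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = float(zooms[0]) * 1000.0 if zooms and zooms[0] > 0 else None
        return arr, spacing
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        arr = sitk.GetArrayFromImage(img)  # already (z, y, x)
        if arr.ndim != 3:
            raise VolumeIOError(f"MetaImage file {path!r} is not 3-D")
        sp = img.GetSpacing()  # (x, y, z) in mm
        spacing = float(sp[0]) * 1000.0 if sp and sp[0] > 0 else None
        return arr, spacing
    if fmt == "tiff_stack":
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise VolumeIOError(f"TIFF stack {path!r} is not 3-D")
        return arr, None
    if fmt == "raw":
        sidecar = os.path.splitext(path)[0] + ".json"
        if not os.path.exists(sidecar):
            raise VolumeIOError(f"raw volume {path!r} lacks its JSON sidecar {sidecar!r}")
        with open(sidecar) as fh:
            meta = json.load(fh)
        try:
            dims = tuple(int(d) for d in meta["dims"])
        except KeyError as exc:
            raise VolumeIOError(f"sidecar {sidecar!r} misses 'dims'") from exc
        endian = meta.get("endianness", "little")
        dtype = np.dtype("<u2" if endian == "little" else ">u2")
        data = np.fromfile(path, dtype=dtype)
        if data.size != int(np.prod(dims)):
            raise VolumeIOError(
                f"raw file {path!r}: expected {int(np.prod(dims))} voxels, got {data.size}"
            )
        spacing = float(meta["spacing_um"]) if "spacing_um" in meta else None
        return data.reshape(dims).astype(np.uint16), spacing
    raise VolumeIOError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def read_volume(path: str, format: str | None = None) -> RawVolume:
    """Read a 16-bit volumetric image into a :class:`RawVolume`.

    Parameters
    ----------
    path : str
        Input file.  For ``raw`` a JSON sidecar ``<stem>.json`` with keys
        ``dims``, ``spacing_um`` and optionally ``endianness`` is required.
    format : {'nifti', 'metaimage', 'tiff_stack', 'raw'}, optional
        Format hint; inferred from the extension when omitted.

    Notes
    -----
    When the file carries no voxel spacing, 50 µm is assumed and a
    warning is logged.
    """
    if not os.path.exists(path):
        raise VolumeIOError(f"no such volume file: {path!r}")
    fmt = format or _guess_format(path)
    if fmt not in _FORMATS:
        raise VolumeIOError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    try:
        arr, spacing = _read_array(path, fmt)
    except VolumeIOError:
        raise
    except Exception as exc:  # file truncated / parser failure
        raise VolumeIOError(f"could not read {fmt} volume {path!r}: {exc}") from exc
    if spacing is None:
        logger.warning(
            "volume %s carries no voxel spacing; assuming %.0f um", path, DEFAULT_SPACING_UM
        )
        spacing = DEFAULT_SPACING_UM
    return RawVolume(voxels=arr, spacing_um=spacing)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_volume(volume, path: str, format: str | None = None) -> str:
    """Write a volume (or label map) to disk; round-trips bit-faithfully.

    Accepts :class:`RawVolume`, :class:`CTVolume`, a segmentation map with
    ``labels``/``spacing_um`` attributes, or a bare ndarray.  HU volumes
    are written as float32 (NIfTI/MetaImage) and are not writable as raw
    or TIFF uint16 stacks; label maps are written as 8-bit.
    """
    if hasattr(volume, "voxels"):
        arr = volume.voxels
        spacing = volume.spacing_um
    elif hasattr(volume, "labels"):
        arr = np.asarray(volume.labels, dtype=np.uint8)
        spacing = volume.spacing_um
    else:
        arr = np.asarray(volume)
        spacing = DEFAULT_SPACING_UM
    fmt = format or _guess_format(path)
    if fmt not in _FORMATS:
        raise VolumeIOError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    mm = spacing / 1000.0
    try:
        if fmt == "nifti":
            import nibabel as nib

            affine = np.diag([mm, mm, mm, 1.0])
            img = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine)
            img.header.set_zooms((mm, mm, mm))
            nib.save(img, path)
        elif fmt == "metaimage":
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(arr)
            img.SetSpacing((mm, mm, mm))
            sitk.WriteImage(img, path)
        elif fmt == "tiff_stack":
            import tifffile

            tifffile.imwrite(path, arr)
        elif fmt == "raw":
            if not np.issubdtype(arr.dtype, np.integer):
                raise VolumeIOError("raw format stores unsigned 16-bit integers only")
            arr16 = arr.astype("<u2")
            arr16.tofile(path)
            sidecar = os.path.splitext(path)[0] + ".json"
            with open(sidecar, "w") as fh:
                json.dump(
                    {"dims": list(arr.shape), "spacing_um": spacing, "endianness": "little"},
                    fh,
                )
    except VolumeIOError:
        raise
    except Exception as exc:
        raise VolumeIOError(f"could not write {fmt} volume to {path!r}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Calibration and pre-filtering
# ---------------------------------------------------------------------------

def calibrate_hu(
    raw: RawVolume,
    air_grey: float | None = None,
    water_grey: float | None = None,
    *,
    precalibrated: bool = False,
    hu_offset: float = -1000.0,
) -> CTVolume:
    """Convert grey levels to Hounsfield units.

    The two-point scheme maps the mean grey of an air reference region to
    −1000 HU and the mean grey of a water reference to 0 HU, linearly::

        HU(g) = 1000 * (g - water_grey) / (water_grey - air_grey)

    Parameters
    ----------
    raw : RawVolume
    air_grey, water_grey : float
        Reference grey levels; ``air_grey < water_grey`` required.
    precalibrated : bool
        If true, the grey values are already HU shifted by ``-hu_offset``
        (scanner-side calibration stored in unsigned form); the volume is
        passed through with only the offset applied.
    """
    if precalibrated:
        hu = raw.voxels.astype(np.float32) + np.float32(hu_offset)
        prov = [{"calibration": "pass-through", "hu_offset": hu_offset}]
        return CTVolume(voxels=hu, spacing_um=raw.spacing_um, provenance=prov)
    if air_grey is None or water_grey is None:
        raise CalibrationError("air_grey and water_grey are required unless precalibrated")
    if not air_grey < water_grey:
        raise CalibrationError(
            f"air reference grey ({air_grey}) must be below water reference grey ({water_grey})"
        )
    scale = 1000.0 / (water_grey - air_grey)
    hu = (raw.voxels.astype(np.float32) - np.float32(water_grey)) * np.float32(scale)
    prov = [{"calibration": "two-point", "air_grey": air_grey, "water_grey": water_grey}]
    return CTVolume(voxels=hu, spacing_um=raw.spacing_um, provenance=prov)


def median_filter(ct: CTVolume, kernel_edge: int = 5) -> CTVolume:
    """Cubic median pre-filter (default 5 × 5 × 5 neighbourhood).

    Borders are handled by edge replication so no out-of-range values are
    introduced.  ``kernel_edge`` must be odd; 1 is the identity.
    """
    if kernel_edge < 1 or kernel_edge % 2 == 0:
        raise ValueError(f"kernel_edge must be odd and >= 1, got {kernel_edge}")
    if kernel_edge == 1:
        return CTVolume(
            voxels=ct.voxels.copy(),
            spacing_um=ct.spacing_um,
            provenance=list(ct.provenance),
        )
    from scipy import ndimage

    filtered = ndimage.median_filter(ct.voxels, size=kernel_edge, mode="nearest")
    prov = list(ct.provenance) + [{"median_filter_kernel": kernel_edge}]
    return CTVolume(voxels=filtered, spacing_um=ct.spacing_um, provenance=prov)
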