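"""The OCT volume container and its disk formats (multi-page TIFF / NIfTI).

Array convention: ``intensities[b, z, a]`` with ``b`` the B-scan (slow raster)
index, ``z`` the depth index (0 = anteriormost / top of the B-scan) and ``a``
the A-scan (fast raster) index.  Intensities are floats in [0, 1].  Physical
calibration is carried as mm-per-pixel metadata; Bennett magnification scaling
is applied to the transverse calibration only (never by resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid with physical calibration and eye metadata.

    Parameters
    ----------
    intensities
        ``(n_bscans, depth_px, n_ascans)`` float array in [0, 1].
    transverse_mm_per_px
        Nominal (device) en-face pitch, identical for the B- and A-scan axes.
    axial_mm_per_px
        Depth pitch.
    axial_length_mm
        The eye's axial length; drives Bennett magnification scaling.
    orientation
        ``"left"`` or ``"right"``: for a left eye the A-scan index increases
        from temporal to nasal (and the reverse for a right eye).  Used by the
        asymmetric temporal/nasal window of the 0-degree curvature radius.
    """

    intensities: np.ndarray
    transverse_mm_per_px: float
    axial_mm_per_px: float
    axial_length_mm: float = 24.0
    orientation: str = "left"
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (bscan, depth, ascan) array")
        if self.transverse_mm_per_px <= 0 or self.axial_mm_per_px <= 0:
            raise ValueError("calibration pitches must be positive")
        if self.orientation not in ("left", "right"):
            raise ValueError("orientation must be 'left' or 'right'")

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def depth_px(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def bscan(self, b: int) -> np.ndarray:
        """The ``(depth_px, n_ascans)`` intensity grid of B-scan ``b``."""
        return self.intensities[b]

    def with_intensities(self, intensities: np.ndarray) -> "OCTVolume":
        """A copy of this volume carrying new intensities, same calibration."""
        out = replace(self, intensities=np.asarray(intensities, dtype=np.float64))
        return out


def save_volume(vol: OCTVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (``.tif``) or NIfTI (``.nii``/``.nii.gz``).

    TIFF pages are B-scans; calibration/metadata travel in the TIFF description
    or the NIfTI header zooms plus an extension-free sidecar convention is not
    needed because both formats carry the pitches.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32), affine=np.eye(4))
        img.header.set_zooms(
            (vol.transverse_mm_per_px, vol.axial_mm_per_px, vol.transverse_mm_per_px)
        )
        nib.save(img, str(path))
    else:
        meta = {
            "transverse_mm_per_px": vol.transverse_mm_per_px,
            "axial_mm_per_px": vol.axial_mm_per_px,
            "axial_length_mm": vol.axial_length_mm,
            "orientation": vol.orientation,
        }
        tifffile.imwrite(
            str(path),
            np.asarray(vol.intensities, dtype=np.float32),
            metadata=meta,
        )


def load_volume(
    path: str | Path,
    transverse_mm_per_px: float | None = None,
    axial_mm_per_px: float | None = None,
    axial_length_mm: float = 24.0,
    orientation: str = "left",
) -> OCTVolume:
    """Read a volume written by :func:`save_volume`.

    Calibration stored in the file wins; explicit arguments fill gaps (NIfTI
    does not store axial length or orientation).
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()
        return OCTVolume(
            data,
            transverse_mm_per_px=transverse_mm_per_px or float(zooms[0]),
            axial_mm_per_px=axial_mm_per_px or float(zooms[1]),
            axial_length_mm=axial_length_mm,
            orientation=orientation,
        )
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(np.float64)
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return OCTVolume(
        data,
        transverse_mm_per_px=float(meta.get("transverse_mm_per_px", transverse_mm_per_px or 1.0)),
        axial_mm_per_px=float(meta.get("axial_mm_per_px", axial_mm_per_px or 1.0)),
        axial_length_mm=float(meta.get("axial_length_mm", axial_length_mm)),
        orientation=str(meta.get("orientation", orientation)),
    )
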