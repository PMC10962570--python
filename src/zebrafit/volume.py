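"""Masked 4D signal volumes (NIfTI in, NIfTI out)."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import DimensionError, ProtocolError, SchemeValidationError
from .scheme import AcquisitionScheme

__all__ = ["VolumeSeries", "load_volume_series"]

log = logging.getLogger(__name__)

#: Default acquisition resolution, mm (isotropic).
DEFAULT_VOXEL_SIZE_MM = (3.0, 3.0, 3.0)


@dataclass
class VolumeSeries:
    """A 4D diffusion-relaxometry series restricted to an organ mask.

    signal : (x, y, z, m) non-negative array, one volume per measurement
    mask : (x, y, z) boolean array, nonzero = organ
    voxel_size : mm per axis
    scheme : the acquisition scheme; its length must equal the 4th
        signal dimension
    affine : voxel-to-world matrix carried through to output maps
    """

    signal: np.ndarray
    mask: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple = DEFAULT_VOXEL_SIZE_MM
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.mask = np.asarray(self.mask) != 0
        if self.signal.ndim != 4:
            raise DimensionError(
                f"signal must be 4D (x, y, z, measurement), got shape "
                f"{self.signal.shape}"
            )
        if self.mask.shape != self.signal.shape[:3]:
            raise DimensionError(
                f"mask shape {self.mask.shape} does not match image spatial "
                f"shape {self.signal.shape[:3]}"
            )
        if self.signal.shape[3] != len(self.scheme):
            raise ProtocolError(
                f"image has {self.signal.shape[3]} measurements but the "
                f"scheme has {len(self.scheme)}"
            )
        if not self.mask.any():
            raise SchemeValidationError("mask contains no voxels")
        in_mask = self.signal[self.mask]
        if not np.all(np.isfinite(in_mask)):
            raise SchemeValidationError("non-finite in-mask signal values")

    @property
    def spatial_shape(self) -> tuple:
        return self.signal.shape[:3]

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_signals(self) -> np.ndarray:
        """(n_mask_voxels, n_measurements) signal matrix, C-order voxels."""
        return self.signal[self.mask]


def load_volume_series(image_path: str | os.PathLike,
                       mask_path: str | os.PathLike,
                       scheme: AcquisitionScheme) -> VolumeSeries:
    """Load a 4D NIfTI series plus a 3D binary mask against a scheme.

    The mask is cast to binary (nonzero = in-mask).  Voxels with any
    non-finite in-mask measurement are removed from the mask with a
    logged count rather than failing the whole series.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) != 0
    if data.ndim != 4:
        raise DimensionError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    if mask.ndim != 3:
        raise DimensionError(f"{mask_path}: expected a 3D mask, got {mask.ndim}D")
    if mask.shape != data.shape[:3]:
        raise DimensionError(
            f"mask shape {mask.shape} does not match image spatial shape "
            f"{data.shape[:3]}"
        )
    if data.shape[3] != len(scheme):
        raise ProtocolError(
            f"{image_path}: 4th dimension is {data.shape[3]} but the scheme "
            f"has {len(scheme)} measurements"
        )
    bad = mask & ~np.all(np.isfinite(data), axis=3)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("removed %d voxel(s) with non-finite signal from the mask",
                    n_bad)
        mask = mask & ~bad
    zooms = img.header.get_zooms()[:3]
    return VolumeSeries(signal=data, mask=mask, scheme=scheme,
                        voxel_size=tuple(float(z) for z in zooms),
                        affine=np.asarray(img.affine, dtype=float))
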