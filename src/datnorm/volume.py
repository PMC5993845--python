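"""3-D SPECT count volumes and NIfTI-1 I/O.

The in-memory unit of quantification is :class:`SpectVolume`: a 3-D float
array in RAS+ axis order (axis 0 = left-to-right, axis 1 =
posterior-to-anterior, axis 2 = inferior-to-superior) with voxel spacing in
millimetres.  Files are read and written as NIfTI-1 through nibabel; any
input orientation is normalized to RAS+ on read so that left/right labels
downstream are consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import VolumeFormatError

__all__ = ["SpectVolume", "read_volume", "write_volume"]


@dataclass
class SpectVolume:
    """A 3-D voxel count grid with spacing in mm, RAS+ axis order.

    ``meta`` carries optional provenance from the simulator (ground-truth
    compartment masks, background concentration, seeds); it is never
    required by the quantifier and is not serialized into NIfTI.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"invalid voxel spacing {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "SpectVolume":
        return SpectVolume(self.data.copy(), self.spacing, dict(self.meta))

    def affine(self) -> np.ndarray:
        """RAS+ affine with the grid center at the world origin."""
        aff = np.diag([*self.spacing, 1.0])
        center = (np.array(self.shape) - 1) / 2.0
        aff[:3, 3] = -center * np.array(self.spacing)
        return aff


def write_volume(volume: SpectVolume, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI-1, RAS+."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> SpectVolume:
    """Read a NIfTI-1 volume, reorienting to RAS+.

    Raises
    ------
    FileNotFoundError
        If the path does not exist (message includes the path).
    VolumeFormatError
        For 4-D or otherwise non-spatial files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D spatial volume, got shape {shape}")
    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj).astype(np.float64)
    zooms = canonical.header.get_zooms()[:3]
    return SpectVolume(data, tuple(float(z) for z in zooms))
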