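"""Digital anthropomorphic striatal phantom.

A physical striatal phantom has two fillable striatal compartments inside a
head-shaped background compartment; filling them at known activity
concentrations establishes a ground-truth specific binding ratio (SBR).
With a spatially uniform background the true SBR of a hemisphere is exactly

    SBR_true = striatal_conc / background_conc - 1,

i.e. the nominal filling ratio minus one.  This module builds the digital
twin: a parametric compartment specification (:class:`PhantomSpec`) and a
rasterizer that produces noiseless :class:`~datnorm.volume.SpectVolume`
grids on which each striatal hemisphere encloses the nominal 11.2 mL to
better than half a voxel.

The striatal compartments are mirrored ellipsoids (the exact compartment
shape is immaterial for an oversized-VOI SBR estimator); the background is
a head-sized ellipsoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidRatioError, RasterizationError
from .volume import SpectVolume

__all__ = [
    "PhantomSpec",
    "build_phantom_spec",
    "rasterize_phantom",
    "DEFAULT_RATIO_PAIRS",
    "filling_sequence",
]

#: Nominal filling series: (right ratio, left ratio) per acquisition.
#: High-normal/low pairing, mid pairing, and a uniform (null-binding) fill.
DEFAULT_RATIO_PAIRS: tuple[tuple[float, float], ...] = ((8.0, 4.0), (6.0, 3.0), (1.0, 1.0))

_BASE_STRIATAL_SEMI_AXES = (10.0, 22.0, 12.154)  # mm; encloses ~11.2 mL


@dataclass(frozen=True)
class PhantomSpec:
    """Compartment geometry and activity concentrations of a striatal phantom.

    Concentrations are in kBq/mL; lengths in mm; the per-hemisphere striatal
    volume defaults to the 11.2 mL standard striatal volume.
    """

    striatal_conc_right: float
    striatal_conc_left: float
    background_conc: float
    striatal_volume_ml: float = 11.2
    head_semi_axes: tuple[float, float, float] = (80.0, 95.0, 70.0)
    striatal_center_right: tuple[float, float, float] = (25.0, 10.0, 0.0)
    striatal_center_left: tuple[float, float, float] = (-25.0, 10.0, 0.0)
    striatal_semi_axes: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.striatal_semi_axes is None:
            # scale the base shape so the analytic volume matches striatal_volume_ml
            base = _BASE_STRIATAL_SEMI_AXES
            base_vol_ml = 4.0 / 3.0 * math.pi * base[0] * base[1] * base[2] / 1000.0
            s = (self.striatal_volume_ml / base_vol_ml) ** (1.0 / 3.0)
            object.__setattr__(self, "striatal_semi_axes", tuple(a * s for a in base))
        for name in ("striatal_conc_right", "striatal_conc_left", "background_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.striatal_conc_right < self.background_conc or self.striatal_conc_left < self.background_conc:
            raise InvalidRatioError("striatal concentration below background (ratio < 1)")
        if self.striatal_volume_ml <= 0:
            raise ValueError("striatal_volume_ml must be > 0")
        self._check_geometry()

    def _check_geometry(self) -> None:
        a = np.asarray(self.striatal_semi_axes)
        for center in (self.striatal_center_right, self.striatal_center_left):
            c = np.asarray(center)
            if np.any(np.abs(c) + a >= np.asarray(self.head_semi_axes)):
                raise ValueError("striatal compartment not strictly inside the head")
        # disjoint: bounding boxes along x must not overlap
        rx = self.striatal_center_right[0] - a[0]
        lx = self.striatal_center_left[0] + a[0]
        if lx >= rx:
            raise ValueError("striatal compartments overlap across the midline")

    @property
    def ratio_right(self) -> float:
        return self.striatal_conc_right / self.background_conc

    @property
    def ratio_left(self) -> float:
        return self.striatal_conc_left / self.background_conc

    @property
    def true_sbr_right(self) -> float:
        """Ground-truth SBR of the right hemisphere (ratio - 1)."""
        return self.ratio_right - 1.0

    @property
    def true_sbr_left(self) -> float:
        return self.ratio_left - 1.0

    def with_background_scaled(self, factor: float) -> "PhantomSpec":
        """New spec with background concentration scaled, striata untouched.

        Mirrors the physical refilling step in which raising the background
        by 33% turns an 8:1/4:1 fill into ~6:1/~3:1.
        """
        if factor <= 0:
            raise ValueError("factor must be > 0")
        return replace(self, background_conc=self.background_conc * factor)


def build_phantom_spec(
    target_ratio_right: float,
    target_ratio_left: float,
    background_conc: float,
    **kwargs,
) -> PhantomSpec:
    """Build a phantom spec from nominal striatum:background ratios.

    Striatal concentrations are ratio x background; the ground-truth SBR per
    hemisphere is ratio - 1.
    """
    if target_ratio_right < 1 or target_ratio_left < 1:
        raise InvalidRatioError(
            f"filling ratios must be >= 1, got ({target_ratio_right}, {target_ratio_left})"
        )
    if background_conc <= 0:
        raise ValueError(f"background_conc must be > 0, got {background_conc}")
    return PhantomSpec(
        striatal_conc_right=target_ratio_right * background_conc,
        striatal_conc_left=target_ratio_left * background_conc,
        background_conc=background_conc,
        **kwargs,
    )


def filling_sequence(background_conc: float = 5.0) -> list[PhantomSpec]:
    """The three-fill experimental sequence of a phantom session.

    1. uniform fill (null binding);
    2. striata refilled to nominal 8:1 (right) and 4:1 (left);
    3. background raised by 33% with striata untouched, giving ~6:1 / ~3:1.
    """
    uniform = build_phantom_spec(1.0, 1.0, background_conc)
    high = build_phantom_spec(8.0, 4.0, background_conc)
    low = high.with_background_scaled(1.33)
    return [uniform, high, low]


def _hemisphere_mask(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    target_volume_mm3: float,
    voxel_volume_mm3: float,
    tol: float,
) -> np.ndarray:
    """Boolean mask of one striatal compartment, volume-matched to target.

    Voxels are ranked by normalized ellipsoidal radius and the smallest-k
    taken so the digitized volume differs from the target by at most half a
    voxel; this keeps the region an (isotropically scaled) ellipsoid level
    set while absorbing voxel-center discretization error.
    """
    x, y, z = coords
    r2 = (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    )
    k = int(round(target_volume_mm3 / voxel_volume_mm3))
    flat = r2.ravel()
    if k < 1 or k > flat.size:
        raise RasterizationError("striatal compartment not representable at this voxel size")
    idx = np.argpartition(flat, k - 1)[:k]
    # sanity: the selected level set must stay close to the nominal ellipsoid
    achieved = k * voxel_volume_mm3
    if abs(achieved - target_volume_mm3) / target_volume_mm3 > tol:
        raise RasterizationError(
            f"digitized striatal volume {achieved:.1f} mm^3 deviates from "
            f"{target_volume_mm3:.1f} mm^3 by more than {tol:.0%}"
        )
    mask = np.zeros(flat.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(r2.shape)


def rasterize_phantom(
    spec: PhantomSpec,
    voxel_size: float,
    volume_tol: float = 0.02,
) -> SpectVolume:
    """Rasterize a phantom spec to a noiseless count volume.

    The returned volume's ``meta`` records the spec, the ground-truth
    compartment masks and centers (voxel indices), and the background
    concentration — the simulator-side ground truth used by tests and by
    the scanner model's bias injection.
    """
    if not (1.0 <= voxel_size <= 4.0):
        raise ValueError(f"voxel_size must be in [1.0, 4.0] mm, got {voxel_size}")
    spacing = (voxel_size, voxel_size, voxel_size)
    pad = voxel_size
    half_extent = np.asarray(spec.head_semi_axes) + pad
    shape = tuple(int(np.ceil(2 * h / voxel_size)) | 1 for h in half_extent)  # odd dims: center voxel
    center_vox = (np.array(shape) - 1) / 2.0
    axes = [
        (np.arange(shape[i]) - center_vox[i]) * voxel_size for i in range(3)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)

    head = (
        (x / spec.head_semi_axes[0]) ** 2
        + (y / spec.head_semi_axes[1]) ** 2
        + (z / spec.head_semi_axes[2]) ** 2
    ) <= 1.0

    xb, yb, zb = np.broadcast_arrays(x, y, z)
    coords = (xb, yb, zb)
    target_mm3 = spec.striatal_volume_ml * 1000.0
    voxvol = voxel_size**3
    mask_r = _hemisphere_mask(coords, spec.striatal_center_right, spec.striatal_semi_axes, target_mm3, voxvol, volume_tol)
    mask_l = _hemisphere_mask(coords, spec.striatal_center_left, spec.striatal_semi_axes, target_mm3, voxvol, volume_tol)
    if np.any(mask_r & mask_l) or np.any(mask_r & ~head) or np.any(mask_l & ~head):
        raise RasterizationError("striatal compartments overlap or extend outside the head")

    data = np.zeros(shape, dtype=np.float64)
    data[head] = spec.background_conc
    data[mask_r] = spec.striatal_conc_right
    data[mask_l] = spec.striatal_conc_left

    def _centroid(mask: np.ndarray) -> tuple[float, float, float]:
        ijk = np.argwhere(mask)
        return tuple(float(v) for v in ijk.mean(axis=0))

    meta = {
        "spec": spec,
        "background_conc": spec.background_conc,
        "striatal_mask_right": mask_r,
        "striatal_mask_left": mask_l,
        "center_right_vox": _centroid(mask_r),
        "center_left_vox": _centroid(mask_l),
        "true_sbr_right": spec.true_sbr_right,
        "true_sbr_left": spec.true_sbr_left,
        "striatal_volume_ml": spec.striatal_volume_ml,
    }
    return SpectVolume(data, spacing, meta)
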