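"""Reporter-concentration measurement in the upper region of the masked dome.

The quantified region lies between the (curvature-inflated) paraboloid
surface and a transversal plane at an axial distance of 20 or 50 μm from
the apex, the plane cut perpendicular to the paraboloid axis.  The measure
is the concentration of fluorescence intensity: total voxel intensity
divided by total voxel volume.  For display the concentration is divided
by 1000 (``reported_concentration``).

Diffuse-reporter profiles (SOC1:GFP-style) are optionally smoothed with a
Gaussian filter (σ = 2.5 px by default) restricted to the paraboloid
interior; the filter is mask-weighted so edge voxels are not diluted by the
zeroed exterior.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .paraboloid import Paraboloid3D, axial_depth, interior_mask
from .stack_io import IsotropicStack

__all__ = ["MaskRegion", "FluorMeasure", "upper_region", "smooth_in_region",
           "concentration", "SOC1_SMOOTHING_SIGMA"]

#: default smoothing for diffuse GFP-fusion profiles (pixels)
SOC1_SMOOTHING_SIGMA = 2.5


@dataclass
class MaskRegion:
    """The set of voxels quantified: paraboloid interior down to a depth."""

    mask: np.ndarray  # boolean (Z, Y, X)
    depth_um: float
    voxel_size_um: float
    paraboloid: Paraboloid3D

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.voxel_size_um**3


@dataclass
class FluorMeasure:
    """Total intensity, volume, and their ratio (the concentration proxy)."""

    total_intensity: float
    volume_um3: float
    depth_um: float
    smoothing_sigma_px: float | None = None

    @property
    def concentration(self) -> float:
        return self.total_intensity / self.volume_um3

    @property
    def reported_concentration(self) -> float:
        """Concentration divided by 1000 (display convention)."""
        return self.concentration / 1000.0

    def to_row(self, sample_id: str = "", channel: str = "") -> dict:
        return {
            "sample_id": sample_id,
            "channel": channel,
            "depth_um": self.depth_um,
            "total_intensity": self.total_intensity,
            "volume_um3": self.volume_um3,
            "concentration": self.concentration,
            "reported_concentration": self.reported_concentration,
            "smoothing_sigma_px": self.smoothing_sigma_px,
        }


def upper_region(p: Paraboloid3D, shape_zyx, voxel_size_um: float,
                 depth_um: float) -> MaskRegion:
    """Interior voxels within ``depth_um`` of the apex along the dome axis."""
    if depth_um <= 0:
        raise ValueError("depth must be positive")
    inside = interior_mask(p, shape_zyx, voxel_size_um)
    zeta = axial_depth(p, shape_zyx, voxel_size_um)
    mask = inside & (zeta <= depth_um)
    if not mask.any():
        raise ValueError("upper region contains no voxels within the grid")
    return MaskRegion(mask, float(depth_um), float(voxel_size_um), p)


def smooth_in_region(stack: IsotropicStack, p: Paraboloid3D, channel,
                     sigma_px: float = SOC1_SMOOTHING_SIGMA) -> IsotropicStack:
    """Gaussian-smooth one channel inside the paraboloid only.

    Uses a mask-weighted (renormalised) filter: inside voxels receive
    ``G*(I·M) / G*M``, outside voxels are untouched.  A constant region
    therefore stays constant right up to the mask boundary.
    """
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    idx = stack.channel_index(channel)
    mask = interior_mask(p, stack.shape_zyx, stack.voxel_size_xy)
    m = mask.astype(float)
    img = stack.data[idx].astype(float)
    num = gaussian_filter(img * m, sigma_px)
    den = gaussian_filter(m, sigma_px)
    smoothed = np.where(mask, num / np.maximum(den, 1e-12), img)
    data = stack.data.astype(float, copy=True)
    data[idx] = np.clip(smoothed, 0, None)
    return dataclasses.replace(stack, data=data)


def concentration(stack: IsotropicStack, region: MaskRegion, channel,
                  smoothing_sigma_px: float | None = None) -> FluorMeasure:
    """Concentration of fluorescence intensity in the region.

    ``total_intensity`` is the sum of voxel intensities over the region;
    ``volume`` the voxel count times the (isotropic) per-voxel volume.
    Raw anisotropic stacks are refused: resample first.
    """
    if not isinstance(stack, IsotropicStack):
        raise TypeError("concentration requires an IsotropicStack; resample first")
    if region.voxel_count == 0:
        raise ValueError("empty region")
    if smoothing_sigma_px is not None:
        stack = smooth_in_region(stack, region.paraboloid, channel,
                                 smoothing_sigma_px)
    grid = stack.channel(channel)
    total = float(grid[region.mask].sum())
    return FluorMeasure(total, region.volume_um3, region.depth_um,
                        smoothing_sigma_px)
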