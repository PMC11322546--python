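"""Reading, writing and resampling of multi-channel confocal z-stacks.

Conventions used throughout the package:

* grids are indexed ``(channel, z, y, x)``; ``z = 0`` is the top (apex-side)
  slice and z increases into the tissue;
* coordinates are voxel-centered: index ``i`` on an axis with spacing ``s``
  sits at physical position ``i * s`` micrometres (0-based);
* all physical lengths are micrometres.

Stacks are stored as ImageJ-style hyperstack TIFFs so the files open with
correct voxel sizes in Fiji.  Tables are plain CSV with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.interpolate import CubicSpline

__all__ = [
    "VoxelStack",
    "IsotropicStack",
    "read_stack",
    "write_stack",
    "resample_isotropic",
    "write_table",
    "read_table",
    "MORPH_COLUMNS",
    "FLUOR_COLUMNS",
]

#: column schema for morphometric record tables
MORPH_COLUMNS = [
    "genotype",
    "timepoint_d",
    "height_um",
    "width_um",
    "area_um2",
    "primordium_identity",
    "experiment_id",
]

#: column schema for fluorescence-measure tables
FLUOR_COLUMNS = [
    "sample_id",
    "channel",
    "depth_um",
    "total_intensity",
    "volume_um3",
    "concentration",
    "reported_concentration",
    "smoothing_sigma_px",
]


@dataclass
class VoxelStack:
    """A multi-channel 3D intensity grid with anisotropic voxel sizes.

    Parameters
    ----------
    data : ndarray, shape (C, Z, Y, X)
        Non-negative intensities, one grid per channel.
    voxel_size_xy : float
        In-plane pixel size in micrometres.
    voxel_size_z : float
        Slice spacing (z step) in micrometres.
    channel_names : list of str
        One label per channel.
    """

    data: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) grid, got shape {self.data.shape}")
        if self.voxel_size_xy <= 0 or self.voxel_size_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and self.data.size:
            if float(self.data.min()) < 0:
                raise ValueError("negative intensities in stack")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(f"unknown channel {channel!r}; have {self.channel_names}")
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the (Z, Y, X) grid of one channel."""
        return self.data[self.channel_index(channel)]


@dataclass
class IsotropicStack(VoxelStack):
    """A :class:`VoxelStack` resampled to a single voxel size on all axes."""

    provenance: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isclose(self.voxel_size_xy, self.voxel_size_z):
            raise ValueError("IsotropicStack requires equal xy and z voxel sizes")

    @property
    def voxel_size(self) -> float:
        return self.voxel_size_xy

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size**3)


def write_stack(stack: VoxelStack, path) -> None:
    """Write a stack as an ImageJ hyperstack TIFF with voxel-size metadata.

    Integer and float32 grids round-trip bit-exactly; float64 data is stored
    as float32 (TIFF/ImageJ limitation).
    """
    data = stack.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    # ImageJ hyperstack axis order is (Z, C, Y, X)
    arr = np.ascontiguousarray(np.moveaxis(data, 0, 1))
    info = json.dumps({"channel_names": stack.channel_names})
    tifffile.imwrite(
        path,
        arr,
        imagej=True,
        resolution=(1.0 / stack.voxel_size_xy, 1.0 / stack.voxel_size_xy),
        metadata={
            "axes": "ZCYX",
            "spacing": stack.voxel_size_z,
            "unit": "um",
            "Info": info,
        },
    )


def read_stack(path, voxel_sizes: tuple[float, float] | None = None) -> VoxelStack:
    """Read a (multi-channel) z-stack TIFF.

    Parameters
    ----------
    voxel_sizes : (xy, z) in μm, optional
        Overrides the file metadata.  Required when the file carries no
        resolution tags.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        meta = tif.imagej_metadata or {}
        page = tif.pages[0]
        xres = page.tags.get("XResolution")

    # normalise axes to (C, Z, Y, X)
    axes = axes.replace("S", "C").replace("Q", "C")
    if set(axes) - set("CZYX"):
        raise ValueError(f"unsupported TIFF axes {axes!r}")
    for missing in set("CZYX") - set(axes):
        arr = arr[None]
        axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    arr = np.transpose(arr, order)

    if voxel_sizes is not None:
        sxy, sz = voxel_sizes
    else:
        if xres is None or "spacing" not in meta:
            raise ValueError(
                "voxel sizes unknown: file lacks resolution/spacing metadata "
                "and no override was given"
            )
        num, den = xres.value
        sxy = den / num
        sz = float(meta["spacing"])

    names: list[str] = []
    if meta.get("Info"):
        try:
            names = json.loads(meta["Info"]).get("channel_names", [])
        except (json.JSONDecodeError, AttributeError):
            names = []

    if np.issubdtype(arr.dtype, np.floating) and arr.size and float(arr.min()) < 0:
        raise ValueError("negative intensities after decoding")
    return VoxelStack(arr, float(sxy), float(sz), list(names))


def resample_isotropic(stack: VoxelStack) -> IsotropicStack:
    """Resample a stack to isotropic voxels by cubic interpolation along z.

    The number of slices is increased so the new slice spacing equals the
    in-plane pixel size; xy planes are untouched.  Interpolation is an
    interpolating cubic spline per (y, x) column (not-a-knot ends, so
    polynomials of degree ≤ 3 along z are reproduced exactly); negative
    overshoot is clipped to 0.
    """
    sxy, sz = stack.voxel_size_xy, stack.voxel_size_z
    if sz < sxy * (1 - 1e-9):
        raise ValueError(
            f"voxel_size_z ({sz}) < voxel_size_xy ({sxy}): refusing to "
            "downsample along z (inverted anisotropy)"
        )
    if np.isclose(sz, sxy):
        return IsotropicStack(
            stack.data.copy(), sxy, sxy, list(stack.channel_names),
            provenance="already isotropic (identity)",
        )

    nz = stack.data.shape[1]
    z_old = np.arange(nz) * sz
    n_new = int(np.floor(z_old[-1] / sxy + 1e-9)) + 1
    z_new = np.arange(n_new) * sxy
    if nz >= 4:
        spline = CubicSpline(z_old, stack.data, axis=1)
        out = spline(z_new)
    else:  # too few slices for a cubic spline; fall back to linear
        out = np.stack(
            [
                np.stack(
                    [np.interp(z_new, z_old, stack.data[c, :, j, i]) for i in range(stack.data.shape[3])],
                    axis=-1,
                )
                for c in range(stack.data.shape[0])
                for j in range(stack.data.shape[2])
            ]
        ).reshape(stack.data.shape[0], stack.data.shape[2], n_new, stack.data.shape[3])
        out = np.moveaxis(out, 1, 2)
    out = np.clip(out, 0, None)
    return IsotropicStack(
        out, sxy, sxy, list(stack.channel_names),
        provenance=f"cubic z-resample {sz}->{sxy} um ({nz}->{n_new} slices)",
    )


def write_table(records: pd.DataFrame, path, schema: list[str] | None = None) -> None:
    """Write a tidy table as UTF-8 CSV, optionally enforcing a column schema."""
    df = pd.DataFrame(records)
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"table missing required columns: {missing}")
        df = df[schema + [c for c in df.columns if c not in schema]]
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
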