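"""Expression-domain geometry from half-maximum isoclines.

Nuclear-localised transcriptional reporters (WUS::3xVENUS-NLS marking the
organizing center, CLV3::mCHERRY-NLS the central zone) are quantified from
orthogonal sum projections of a cropped sub-stack: the level set at a
fraction (default one half) of the projection maximum is extracted with
sub-pixel precision and an ellipse is fitted to it; the ellipse axis closer
to the image vertical is reported as the domain height, the other as its
width.  Axis lengths are *full* lengths (2 × semi-axes), so that the
peripheral-zone width, (meristem width − WUS width) / 2, is geometrically
meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

from .paraboloid import ProjectionImage

__all__ = [
    "CropRect",
    "DomainEllipse",
    "DomainWidths",
    "crop_substack",
    "orthogonal_projections",
    "isocline_ellipse",
    "domain_dimensions",
    "periphery_metrics",
]


@dataclass
class CropRect:
    """Rectangular xy region (voxel indices, half-open) containing the SAM."""

    x0: int
    x1: int
    y0: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty crop rectangle")


@dataclass
class DomainEllipse:
    """Isocline ellipse of one expression domain in one side view."""

    center_um: tuple[float, float]  # (lateral, depth)
    height_um: float  # full axis closer to the image vertical
    width_um: float  # full axis closer to the image horizontal
    orientation_deg: float  # of the height axis w.r.t. vertical
    fraction: float
    plane: str

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0:
            raise ValueError("ellipse axes must be positive")
        if not 0 < self.fraction < 1:
            raise ValueError("threshold fraction must be in (0, 1)")


@dataclass
class DomainWidths:
    """Meristem/OC widths and derived peripheral-zone metrics (all μm)."""

    meristem_width_um: float
    oc_width_um: float
    periphery_um: float
    pz_oc_ratio: float
    cz_height_um: float | None = None
    cz_width_um: float | None = None


def crop_substack(stack, rect: CropRect):
    """Crop the stack to the rectangle in xy, keeping all z slices."""
    nz, ny, nx = stack.shape_zyx
    if not (0 <= rect.x0 < rect.x1 <= nx and 0 <= rect.y0 < rect.y1 <= ny):
        raise ValueError(f"crop rectangle {rect} outside grid {(ny, nx)}")
    data = stack.data[:, :, rect.y0:rect.y1, rect.x0:rect.x1].copy()
    return dataclasses.replace(stack, data=data)


def orthogonal_projections(stack, channel) -> tuple[ProjectionImage, ProjectionImage]:
    """Full-axis sum projections of one channel in both side views.

    Returns (xz, yz): xz sums over y, yz sums over x; rows are z (depth),
    columns the remaining lateral axis.
    """
    grid = stack.channel(channel)
    if grid.size == 0:
        raise ValueError("empty substack")
    xz = ProjectionImage(grid.sum(axis=1), "xz", stack.voxel_size_xy)
    yz = ProjectionImage(grid.sum(axis=2), "yz", stack.voxel_size_xy)
    return xz, yz


def _moment_ellipse(region: np.ndarray):
    """Equivalent (second-moment) ellipse of a binary region: fallback fit."""
    props = measure.regionprops(region.astype(np.uint8))
    if not props:
        raise ValueError("threshold region empty")
    p = props[0]
    cy, cx = p.centroid
    # regionprops orientation: angle of major axis from the row (vertical) axis
    return (cx, cy, p.axis_major_length / 2, p.axis_minor_length / 2, p.orientation)


def isocline_ellipse(projection: ProjectionImage, fraction: float = 0.5,
                     smooth_sigma_px: float = 1.0) -> DomainEllipse:
    """Fit an ellipse to the isocline at ``fraction`` of the projection max.

    The projection is lightly smoothed (σ = 1 px by default) before taking
    the maximum, the contour is extracted at sub-pixel precision by
    marching squares, and a direct least-squares ellipse is fitted to the
    contour points (second-moment fallback when fewer than 6 points).  A
    threshold region touching the image border is an error, not a silent
    fit.  Axis lengths are full lengths in μm.
    """
    img = projection.image.astype(float)
    if smooth_sigma_px > 0:
        img = gaussian_filter(img, smooth_sigma_px)
    mx = img.max()
    if mx <= 0:
        raise ValueError("projection has no positive signal")
    level = fraction * mx

    above = img > level
    border = np.zeros_like(above)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if (above & border).any():
        raise ValueError(
            "threshold region touches the image border; domain not fully "
            "contained in the crop"
        )

    contours = measure.find_contours(img, level)
    if not contours:
        raise ValueError("no isocline found at the requested level")
    peak = np.unravel_index(np.argmax(img), img.shape)
    # keep the contour enclosing the global maximum (largest if ambiguous)
    def encloses_peak(c):
        path = measure.points_in_poly([peak], c)
        return bool(path[0])

    enclosing = [c for c in contours if encloses_peak(c)]
    contour = max(enclosing or contours, key=len)

    px = projection.pixel_size_um
    if len(contour) >= 6:
        # EllipseModel expects (x, y); contour rows are (row=z, col=lateral)
        pts = contour[:, ::-1]
        model = measure.EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed on the isocline contour")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:
        xc, yc, a, b, theta = _moment_ellipse(above)
        theta = np.pi / 2 - theta  # to angle-from-x-axis convention

    # axis a has direction (cos θ, sin θ) in (x=lateral, y=depth) coordinates;
    # the more vertical axis (|sin| ≥ |cos|) is the height
    if abs(np.sin(theta)) >= abs(np.cos(theta)):
        height, width = 2 * a * px, 2 * b * px
        orient = np.rad2deg(np.arctan2(np.cos(theta), np.sin(theta)))
    else:
        height, width = 2 * b * px, 2 * a * px
        orient = np.rad2deg(np.arctan2(-np.sin(theta), np.cos(theta)))
    return DomainEllipse((xc * px, yc * px), float(height), float(width),
                         float(orient), fraction, projection.plane)


def domain_dimensions(e_xz: DomainEllipse, e_yz: DomainEllipse
                      ) -> tuple[float, float]:
    """Combine the two side views: mean height and mean width (μm)."""
    return (0.5 * (e_xz.height_um + e_yz.height_um),
            0.5 * (e_xz.width_um + e_yz.width_um))


def periphery_metrics(meristem_width_um: float, oc_width_um: float,
                      cz_height_um: float | None = None,
                      cz_width_um: float | None = None) -> DomainWidths:
    """Peripheral-zone width and PZ/OC ratio.

    ``periphery = (meristem width − OC width) / 2``; the OC (WUS domain)
    width delimits the peripheral region because it aligns with where
    primordia initiate.
    """
    if oc_width_um < 0 or meristem_width_um < oc_width_um:
        raise ValueError("need meristem_width ≥ oc_width ≥ 0")
    periphery = (meristem_width_um - oc_width_um) / 2.0
    if oc_width_um == 0:
        raise ValueError("PZ/OC ratio undefined for zero OC width")
    return DomainWidths(meristem_width_um, oc_width_um, periphery,
                        periphery / oc_width_um, cz_height_um, cz_width_um)
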