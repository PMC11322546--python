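"""Paraboloid mask construction for the meristem dome.

The SAM surface is modelled, in a frame tilted by an angle θ about the y
axis, as the elliptic paraboloid

    ζ = ξ² / c₁² + η² / c₂²

with apex at (x₀, y₀, z₀) and ζ pointing into the tissue (increasing z at
θ = 0).  The two denominators come from parabolas fitted independently to
the dome outline in the xz and yz side-view projections of the cell-wall
channel: c₁² = 1/a_xz and c₂² = 1/a_yz, with z₀ the mean of the two apex
depths.  When the lateral (yz) view is truncated by the acquisition, only
the xz curvature is used (c₂² = c₁²).

Voxels above the surface (outside the dome) are zeroed by the mask; a voxel
belongs to the interior iff its centre satisfies the paraboloid inequality.
Before quantification the curvature is inflated, a′ = a/α with α the image
resolution in μm (α < 1), which shrinks the mask away from the dome flanks
and excludes signal from boundary regions and primordia.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Parabola2D",
    "Paraboloid3D",
    "ProjectionImage",
    "rot2",
    "sum_projection",
    "fit_parabola",
    "build_paraboloid",
    "inflate_curvature",
    "interior_mask",
    "axial_depth",
    "apply_mask",
]


def rot2(theta_deg: float) -> np.ndarray:
    """2D rotation matrix [[c, -s], [s, c]] for an angle in degrees.

    Applied to (u, w) offsets it tilts the parabola axis by ``theta_deg``
    away from the image vertical; the same matrix (acting on the (x, z)
    components) defines the 3D tilt about the y axis.
    """
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass
class Parabola2D:
    """A parabola fitted to a dome outline in one side-view projection.

    ``w = w0 + a (u - u0)²`` in the frame rotated by ``theta_deg``; the apex
    ``(u0_um, w0_um)`` is reported in the unrotated projection coordinates
    (u lateral, w depth, both μm).
    """

    u0_um: float
    w0_um: float
    a: float  # curvature, μm⁻¹
    theta_deg: float
    rss: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("parabola curvature must be positive (dome opens downward)")

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Outline points (u', w') in unrotated coordinates for offsets u."""
        offsets = rot2(self.theta_deg) @ np.stack([u, self.a * np.asarray(u) ** 2])
        return offsets[0] + self.u0_um, offsets[1] + self.w0_um


@dataclass
class Paraboloid3D:
    """The 3D dome mask geometry."""

    apex_um: tuple[float, float, float]  # (x0, y0, z0)
    c1_sq: float  # μm², xz-view denominator
    c2_sq: float  # μm², yz-view denominator
    theta_deg: float = 0.0
    lateral_complete: bool = True

    def __post_init__(self) -> None:
        if self.c1_sq <= 0 or self.c2_sq <= 0:
            raise ValueError("paraboloid denominators must be positive")
        if not self.lateral_complete and not np.isclose(self.c2_sq, self.c1_sq):
            raise ValueError("with lateral_complete=False, c2_sq must equal c1_sq")

    def to_dict(self) -> dict:
        return {
            "apex_um": list(map(float, self.apex_um)),
            "c1_sq": float(self.c1_sq),
            "c2_sq": float(self.c2_sq),
            "theta_deg": float(self.theta_deg),
            "lateral_complete": bool(self.lateral_complete),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Paraboloid3D":
        return cls(
            tuple(d["apex_um"]), d["c1_sq"], d["c2_sq"],
            d.get("theta_deg", 0.0), d.get("lateral_complete", True),
        )


@dataclass
class ProjectionImage:
    """A 2D side-view sum projection, rows = z (depth), cols = lateral axis."""

    image: np.ndarray
    plane: str  # "xz" (y collapsed) or "yz" (x collapsed)
    pixel_size_um: float
    slice_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.plane not in ("xz", "yz"):
            raise ValueError(f"plane must be 'xz' or 'yz', got {self.plane!r}")


def sum_projection(stack, channel, plane: str, slice_interval: tuple[int, int] | None = None
                   ) -> ProjectionImage:
    """Sum-project the cell-wall signal of a slice interval onto a side view.

    Parameters
    ----------
    stack : IsotropicStack
    plane : "xz" or "yz"
        Which side view to produce; "xz" collapses the y axis.
    slice_interval : (z_start, z_stop), half-open, optional
        Slices to include.  Defaults to the top quartile of the stack (the
        interval containing the apex); override to taste.
    """
    grid = stack.channel(channel)
    nz = grid.shape[0]
    if slice_interval is None:
        slice_interval = (0, max(1, nz // 4))
    z0, z1 = slice_interval
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or out-of-bounds slice interval {slice_interval}")
    sub = grid[z0:z1]
    axis = 1 if plane == "xz" else 2  # collapse y for xz, x for yz
    img = sub.sum(axis=axis)
    # pad back to full z height so row index == z index of the stack
    full = np.zeros((nz, img.shape[1]), dtype=img.dtype)
    full[z0:z1] = img
    return ProjectionImage(full, plane, stack.voxel_size_xy, (z0, z1))


def _fit_at_theta(pts: np.ndarray, theta: float) -> tuple[float, np.ndarray]:
    """Least-squares quadratic fit of the points rotated into frame θ.

    Returns (rss, coeffs) with coeffs = (c2, c1, c0) of w' = c2 u'² + c1 u' + c0.
    """
    q = rot2(theta).T @ pts.T  # (2, n)
    u, w = q
    coeffs, res, *_ = np.polynomial.polynomial.polyfit(u, w, 2, full=True)
    pred = np.polynomial.polynomial.polyval(u, coeffs)
    rss = float(np.sum((w - pred) ** 2))
    return rss, coeffs[::-1]  # (c2, c1, c0)


def fit_parabola(points, theta_range: tuple[float, float] = (-20.0, 20.0),
                 coarse_step_deg: float = 1.0, refine_tol_deg: float = 1e-3
                 ) -> Parabola2D:
    """Fit a parabola to outline points, searching over the tilt angle.

    For each candidate orientation θ the points are rotated by −θ and a
    quadratic ``w' = w0' + a (u' − u0')²`` is fitted by least squares; the θ
    minimising the residual sum of squares wins (coarse grid over
    ``theta_range`` followed by bounded refinement).  The apex is reported in
    the unrotated coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (u, w) μm coordinates")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 outline points to fit a parabola")
    # collinearity check: rank of centred points
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise ValueError("outline points are collinear; cannot fit a parabola")

    lo, hi = theta_range
    thetas = np.arange(lo, hi + 0.5 * coarse_step_deg, coarse_step_deg)
    rss_grid = np.array([_fit_at_theta(pts, t)[0] for t in thetas])
    best = int(np.argmin(rss_grid))

    a_lo = thetas[max(best - 1, 0)]
    a_hi = thetas[min(best + 1, len(thetas) - 1)]
    if a_hi > a_lo:
        res = minimize_scalar(
            lambda t: _fit_at_theta(pts, t)[0],
            bounds=(a_lo, a_hi), method="bounded",
            options={"xatol": refine_tol_deg},
        )
        theta_hat = float(res.x)
    else:
        theta_hat = float(thetas[best])

    rss, (c2, c1, c0) = _fit_at_theta(pts, theta_hat)
    if c2 <= 0:
        # fall back: scan for any orientation giving an upward-opening fit
        ok = [(t, _fit_at_theta(pts, t)) for t in thetas]
        ok = [(t, r, co) for t, (r, co) in ok if co[0] > 0]
        if not ok:
            raise ValueError("all candidate fits degenerate (non-positive curvature)")
        theta_hat, rss, (c2, c1, c0) = min(ok, key=lambda x: x[1])

    u0p = -c1 / (2 * c2)
    w0p = c0 - c1**2 / (4 * c2)
    apex = rot2(theta_hat) @ np.array([u0p, w0p])
    w = (rot2(theta_hat).T @ pts.T)[1]
    tss = float(np.sum((w - w.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return Parabola2D(float(apex[0]), float(apex[1]), float(c2), theta_hat, rss, r2)


def build_paraboloid(p_xz: Parabola2D, p_yz: Parabola2D | None = None,
                     lateral_complete: bool = True, y0_um: float | None = None
                     ) -> Paraboloid3D:
    """Assemble the 3D paraboloid from the orthogonal parabola fits.

    ``c₁² = 1/a_xz`` and ``c₂² = 1/a_yz``; the apex depth z₀ is the mean of
    the two parabola apices.  When ``lateral_complete`` is False (the yz view
    is truncated) the xz curvature is reused, ``c₂² = c₁²``; a yz parabola,
    if supplied, still contributes its apex, otherwise ``y0_um`` is required.
    """
    if lateral_complete and p_yz is None:
        raise ValueError("lateral_complete=True requires the yz parabola")
    c1_sq = 1.0 / p_xz.a
    if lateral_complete:
        c2_sq = 1.0 / p_yz.a
    else:
        c2_sq = c1_sq
    if p_yz is not None:
        z0 = 0.5 * (p_xz.w0_um + p_yz.w0_um)
        y0 = p_yz.u0_um
    else:
        if y0_um is None:
            raise ValueError("without a yz parabola, y0_um must be given")
        z0 = p_xz.w0_um
        y0 = y0_um
    return Paraboloid3D((p_xz.u0_um, y0, z0), c1_sq, c2_sq,
                        p_xz.theta_deg, lateral_complete)


def inflate_curvature(p: Paraboloid3D, alpha: float) -> Paraboloid3D:
    """Increase the mask curvature, a′ = a/α (α the image resolution, μm).

    With 0 < α < 1 the paraboloid narrows, excluding dome-boundary and
    primordium signal from the mask.  Apex and tilt are unchanged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1) (the image resolution in μm)")
    return Paraboloid3D(p.apex_um, p.c1_sq * alpha, p.c2_sq * alpha,
                        p.theta_deg, p.lateral_complete)


def _rotated_coords(p: Paraboloid3D, shape_zyx, voxel_size: float):
    """(ξ, η, ζ) coordinates of every voxel centre in the paraboloid frame."""
    nz, ny, nx = shape_zyx
    x0, y0, z0 = p.apex_um
    z = np.arange(nz)[:, None, None] * voxel_size - z0
    y = np.arange(ny)[None, :, None] * voxel_size - y0
    x = np.arange(nx)[None, None, :] * voxel_size - x0
    t = np.deg2rad(p.theta_deg)
    c, s = np.cos(t), np.sin(t)
    xi = c * x + s * z
    zeta = -s * x + c * z
    return xi, y, zeta


def interior_mask(p: Paraboloid3D, shape_zyx, voxel_size: float) -> np.ndarray:
    """Boolean (Z, Y, X) mask of voxels inside the paraboloid.

    A voxel is interior iff its centre satisfies
    ``ζ ≥ ξ²/c₁² + η²/c₂²`` in the tilted frame.
    """
    xi, eta, zeta = _rotated_coords(p, shape_zyx, voxel_size)
    return zeta >= xi**2 / p.c1_sq + eta**2 / p.c2_sq


def axial_depth(p: Paraboloid3D, shape_zyx, voxel_size: float) -> np.ndarray:
    """ζ (μm along the paraboloid axis, ≥0 below the apex) per voxel centre."""
    _, _, zeta = _rotated_coords(p, shape_zyx, voxel_size)
    return np.broadcast_to(zeta, shape_zyx) + np.zeros(shape_zyx)


def apply_mask(stack, p: Paraboloid3D, channel):
    """Zero every voxel of ``channel`` outside the paraboloid.

    Returns a new stack of the same type; other channels are untouched.
    Emits a warning (and an all-zero channel) when no voxel is interior.
    """
    idx = stack.channel_index(channel)
    mask = interior_mask(p, stack.shape_zyx, stack.voxel_size_xy)
    if not mask.any():
        warnings.warn("paraboloid has no interior voxel within the grid; "
                      "channel masked to all zeros", stacklevel=2)
    data = stack.data.copy()
    data[idx] = np.where(mask, data[idx], 0)
    return dataclasses.replace(stack, data=data)
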