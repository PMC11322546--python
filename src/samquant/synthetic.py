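"""Synthetic confocal stacks, outlines, cell tables and cohort timecourses.

Every generator is a pure function of (spec, seed) and returns, next to the
artificial data, a *manifest* holding the complete ground truth, so each
downstream estimator (apex position, curvatures, tilt, reporter
concentration, domain size, morphometrics) can be scored without real
microscopy data.

The dome is a tilted elliptic paraboloid surface ζ = a₁ξ² + a₂η² in the
frame rotated by θ about the y axis.  Channel 0 carries a Gaussian shell of
cell-wall signal around that surface; further channels emulate reporters:

* ``uniform-interior`` — diffuse protein fusions (SOC1:GFP / AP2:VENUS
  style): a constant concentration everywhere below the surface;
* ``graded`` — the same with a linear depth gradient;
* ``nuclear-gaussian`` — transcriptional reporters confined to a domain
  (WUS/CLV3 style): a 3D Gaussian intensity blob inside the tissue.

Noise follows the standard confocal approximation: Poisson statistics on
the signal (with a gain, i.e. intensity units per detected photon) plus
additive Gaussian read noise, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paraboloid import rot2
from .stack_io import MORPH_COLUMNS, VoxelStack

__all__ = [
    "DomeSpec",
    "ReporterSpec",
    "CohortSpec",
    "make_dome_stack",
    "make_outline_points",
    "make_cell_table",
    "make_timecourse",
    "default_cohort",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_VOXEL_XY",
    "DEFAULT_VOXEL_Z",
]

# default acquisition geometry: anisotropic voxels with the 0.4 μm z step
DEFAULT_GRID_SHAPE = (96, 128, 128)  # (z, y, x)
DEFAULT_VOXEL_XY = 0.2
DEFAULT_VOXEL_Z = 0.4


@dataclass
class DomeSpec:
    """Geometry of the synthetic meristem dome."""

    apex_um: tuple[float, float, float] = (12.8, 12.8, 4.0)  # (x0, y0, z0)
    a1: float = 0.05  # μm⁻¹, curvature in the xz view
    a2: float = 0.05  # μm⁻¹, curvature in the yz view
    tilt_deg: float = 0.0  # rotation of the dome axis about y
    wall_thickness_um: float = 0.8
    wall_amplitude: float = 400.0
    n_primordia: int = 0
    primordium_offset_um: float = 10.0  # lateral distance of bumps from apex
    primordium_amplitude: float = 300.0
    primordium_sigma_um: float = 1.5  # bump size; compact support (3σ cut-off)

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("dome curvatures must be positive")
        if self.wall_thickness_um <= 0:
            raise ValueError("wall thickness must be positive")
        if abs(self.tilt_deg) >= 45:
            raise ValueError("|tilt| must be below 45 degrees")


@dataclass
class ReporterSpec:
    """One synthetic reporter channel."""

    mode: str = "uniform-interior"  # or "graded", "nuclear-gaussian"
    value: float = 100.0  # concentration (a.u./voxel) or Gaussian amplitude
    background: float = 0.0
    center_um: tuple[float, float, float] | None = None  # nuclear-gaussian
    sigma_um: tuple[float, float, float] = (4.0, 4.0, 4.0)
    grad_per_um: float = 0.0  # depth gradient for "graded"
    poisson_gain: float = 0.0  # 0 disables shot noise
    read_noise_sd: float = 0.0
    name: str = "reporter"

    def __post_init__(self) -> None:
        if self.mode not in ("uniform-interior", "graded", "nuclear-gaussian"):
            raise ValueError(f"unknown reporter mode {self.mode!r}")
        if self.value < 0 or self.background < 0:
            raise ValueError("amplitudes must be non-negative")
        if any(s <= 0 for s in self.sigma_um):
            raise ValueError("Gaussian sigmas must be positive")


def _dome_frame(dome: DomeSpec, shape_zyx, sxy: float, sz: float):
    nz, ny, nx = shape_zyx
    x0, y0, z0 = dome.apex_um
    z = np.arange(nz)[:, None, None] * sz - z0
    y = np.arange(ny)[None, :, None] * sxy - y0
    x = np.arange(nx)[None, None, :] * sxy - x0
    t = np.deg2rad(dome.tilt_deg)
    c, s = np.cos(t), np.sin(t)
    xi = c * x + s * z
    zeta = -s * x + c * z
    return xi, y, zeta


def make_dome_stack(dome: DomeSpec, reporters: list[ReporterSpec], *,
                    shape_zyx=DEFAULT_GRID_SHAPE,
                    voxel_size_xy: float = DEFAULT_VOXEL_XY,
                    voxel_size_z: float = DEFAULT_VOXEL_Z,
                    seed: int) -> tuple[VoxelStack, dict]:
    """Render a dome stack: wall-shell channel 0 plus one channel per reporter.

    Returns the stack and a manifest with the full ground truth (geometry,
    per-channel noiseless totals, interior voxel count).
    """
    nz, ny, nx = shape_zyx
    if nz * ny * nx == 0:
        raise ValueError("zero-size grid")
    x0, y0, z0 = dome.apex_um
    extent = (nx - 1) * voxel_size_xy, (ny - 1) * voxel_size_xy, (nz - 1) * voxel_size_z
    if not (0 <= x0 <= extent[0] and 0 <= y0 <= extent[1] and 0 <= z0 <= extent[2]):
        raise ValueError("dome apex lies outside the grid")

    rng = np.random.default_rng(seed)
    xi, eta, zeta = _dome_frame(dome, shape_zyx, voxel_size_xy, voxel_size_z)
    residual = zeta - (dome.a1 * xi**2 + dome.a2 * eta**2)
    interior = residual >= 0

    wall = dome.wall_amplitude * np.exp(
        -(residual**2) / (2 * dome.wall_thickness_um**2)
    )
    primordia = []
    if dome.n_primordia:
        angles = np.linspace(0, 2 * np.pi, dome.n_primordia, endpoint=False)
        for ang in angles:
            px = x0 + dome.primordium_offset_um * np.cos(ang)
            py = y0 + dome.primordium_offset_um * np.sin(ang)
            # drop the bump onto the (untilted) surface depth at that offset
            pz = z0 + dome.a1 * (px - x0) ** 2 + dome.a2 * (py - y0) ** 2
            zc = np.arange(nz)[:, None, None] * voxel_size_z
            yc = np.arange(ny)[None, :, None] * voxel_size_xy
            xc = np.arange(nx)[None, None, :] * voxel_size_xy
            d2 = (xc - px) ** 2 + (yc - py) ** 2 + (zc - pz) ** 2
            sig = dome.primordium_sigma_um
            bump = dome.primordium_amplitude * np.exp(-d2 / (2 * sig**2))
            wall = wall + np.where(d2 <= (3 * sig) ** 2, bump, 0.0)
            primordia.append({"center_um": [float(px), float(py), float(pz)]})

    channels = [wall]
    names = ["wall"]
    truth_channels = []
    for rep in reporters:
        if rep.mode == "uniform-interior":
            clean = np.where(interior, rep.value, 0.0) + rep.background
        elif rep.mode == "graded":
            depth = np.clip(zeta, 0, None)
            clean = np.where(interior, rep.value * (1 + rep.grad_per_um * depth), 0.0)
            clean = np.clip(clean, 0, None) + rep.background
        else:  # nuclear-gaussian
            cx, cy, cz = rep.center_um if rep.center_um is not None else dome.apex_um
            sx, sy, szg = rep.sigma_um
            zc = np.arange(nz)[:, None, None] * voxel_size_z
            yc = np.arange(ny)[None, :, None] * voxel_size_xy
            xc = np.arange(nx)[None, None, :] * voxel_size_xy
            g = rep.value * np.exp(
                -((xc - cx) ** 2) / (2 * sx**2)
                - ((yc - cy) ** 2) / (2 * sy**2)
                - ((zc - cz) ** 2) / (2 * szg**2)
            )
            clean = np.where(interior, g, 0.0) + rep.background
        noisy = clean
        if rep.poisson_gain > 0:
            noisy = rng.poisson(clean / rep.poisson_gain) * rep.poisson_gain
        if rep.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, rep.read_noise_sd, clean.shape)
        noisy = np.clip(noisy, 0, None)
        channels.append(noisy.astype(float))
        names.append(rep.name)
        truth_channels.append(
            {
                "name": rep.name,
                "mode": rep.mode,
                "value": rep.value,
                "background": rep.background,
                "center_um": list(rep.center_um) if rep.center_um else None,
                "sigma_um": list(rep.sigma_um),
                "noiseless_total": float(clean.sum()),
                "noiseless_interior_mean": float(clean[interior].mean())
                if interior.any()
                else 0.0,
            }
        )

    stack = VoxelStack(np.stack(channels), voxel_size_xy, voxel_size_z, names)
    manifest = {
        "seed": int(seed),
        "grid": {"shape_zyx": list(shape_zyx), "voxel_size_xy": voxel_size_xy,
                 "voxel_size_z": voxel_size_z},
        "dome": {
            "apex_um": list(dome.apex_um),
            "a1": dome.a1,
            "a2": dome.a2,
            "c1_sq": 1.0 / dome.a1,
            "c2_sq": 1.0 / dome.a2,
            "tilt_deg": dome.tilt_deg,
            "wall_thickness_um": dome.wall_thickness_um,
            "primordia": primordia,
        },
        "interior_voxel_count": int(interior.sum()),
        "channels": truth_channels,
    }
    return stack, manifest


def make_outline_points(apex_um: tuple[float, float], a: float, theta_deg: float,
                        n: int, noise_sd_um: float, seed: int,
                        u_range_um: float = 10.0) -> np.ndarray:
    """Sample noisy points on a rotated parabola (the drawn dome outline).

    Points are ``apex + R(θ)·(u, a u²)`` for u uniform on ±``u_range_um``,
    with isotropic Gaussian jitter of ``noise_sd_um``.  Returns (n, 2) μm.
    """
    if n < 3:
        raise ValueError("need at least 3 outline points")
    rng = np.random.default_rng(seed)
    u = np.linspace(-u_range_um, u_range_um, n)
    offsets = rot2(theta_deg) @ np.stack([u, a * u**2])
    pts = offsets.T + np.asarray(apex_um)
    if noise_sd_um > 0:
        pts = pts + rng.normal(0.0, noise_sd_um, pts.shape)
    return pts


def make_cell_table(n_cells: int, *, median_area_um2: float = 25.0,
                    sigma_log: float = 0.3, meristem_fraction: float = 1.0,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Stand-in for an external segmentation export: per-cell areas + membership.

    Areas are lognormal; ``meristem_fraction`` of the cells are flagged as
    belonging to the meristem (the externally derived negative-Gaussian-
    curvature boundary).  The manifest records the true total meristem area.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    if sigma_log > 0:
        areas = median_area_um2 * np.exp(rng.normal(0.0, sigma_log, n_cells))
    else:
        areas = np.full(n_cells, float(median_area_um2))
    n_members = int(round(meristem_fraction * n_cells))
    member = np.zeros(n_cells, dtype=bool)
    member[rng.choice(n_cells, size=n_members, replace=False)] = True
    df = pd.DataFrame({"cell_id": np.arange(n_cells), "area_um2": areas,
                       "meristem_member": member})
    manifest = {
        "total_meristem_area_um2": float(areas[member].sum()),
        "member_count": int(n_members),
    }
    return df, manifest


@dataclass
class CohortSpec:
    """Design of a synthetic morphometric timecourse.

    ``medians`` maps genotype -> timepoint (days) -> dict with keys
    ``height_um``, ``width_um``, ``area_um2``; ``identities`` maps genotype ->
    timepoint -> list of (identity, probability) for the primordium type
    visible at the SAM flanks.
    """

    medians: dict
    identities: dict = field(default_factory=dict)
    sigma_log: float = 0.12  # lognormal dispersion (≈12% CV), typical plant-to-plant scatter
    n_per_group: int = 8
    n_experiments: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for g, tps in self.medians.items():
            for t, m in tps.items():
                if min(m.values()) <= 0:
                    raise ValueError(f"non-positive median for {g} at {t}")
        for g, tps in self.identities.items():
            for t, mix in tps.items():
                if abs(sum(p for _, p in mix) - 1) > 1e-9:
                    raise ValueError("identity mixture probabilities must sum to 1")


def default_cohort(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort emulating the long-day floral-transition timecourse.

    Wild-type medians rise 2-fold in height and 1.5-fold in width from day
    10 to the day-14 peak; the AP2-deficient genotype stalls after day 12,
    ending 50% shorter and 25% narrower than wild type at the peak.
    """
    medians = {
        "wildtype": {
            10: {"height_um": 35.0, "width_um": 64.0, "area_um2": 4500.0},
            12: {"height_um": 50.0, "width_um": 78.0, "area_um2": 6200.0},
            14: {"height_um": 70.0, "width_um": 96.0, "area_um2": 9000.0},
        },
        "ap2": {
            10: {"height_um": 35.0, "width_um": 64.0, "area_um2": 4500.0},
            12: {"height_um": 40.0, "width_um": 70.0, "area_um2": 5200.0},
            14: {"height_um": 35.0, "width_um": 72.0, "area_um2": 5400.0},
        },
    }
    identities = {
        "wildtype": {
            10: [("vegetative", 1.0)],
            12: [("vegetative", 0.5), ("cauline", 0.5)],
            14: [("cauline", 0.9), ("floral", 0.1)],
        },
        "ap2": {
            10: [("vegetative", 1.0)],
            12: [("cauline", 0.5), ("floral", 0.5)],
            14: [("floral", 1.0)],
        },
    }
    kwargs = dict(medians=medians, identities=identities, seed=seed)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def make_timecourse(cohort: CohortSpec) -> pd.DataFrame:
    """Draw a morphometric record table from the cohort design.

    Each plant's height/width/area are lognormal around the specified
    medians (so the *population* median equals the spec value exactly);
    reproducible under the cohort seed.
    """
    rng = np.random.default_rng(cohort.seed)
    rows = []
    for e in range(cohort.n_experiments):
        exp_id = f"exp{e + 1}"
        for genotype, tps in cohort.medians.items():
            for tp, med in sorted(tps.items()):
                mix = cohort.identities.get(genotype, {}).get(tp, [("vegetative", 1.0)])
                labels = [m[0] for m in mix]
                probs = [m[1] for m in mix]
                for _ in range(cohort.n_per_group):
                    f = (
                        np.exp(rng.normal(0.0, cohort.sigma_log, 3))
                        if cohort.sigma_log > 0
                        else np.ones(3)
                    )
                    rows.append(
                        {
                            "genotype": genotype,
                            "timepoint_d": tp,
                            "height_um": med["height_um"] * f[0],
                            "width_um": med["width_um"] * f[1],
                            "area_um2": med.get("area_um2", np.nan) * f[2],
                            "primordium_identity": rng.choice(labels, p=probs),
                            "experiment_id": exp_id,
                        }
                    )
    return pd.DataFrame(rows, columns=MORPH_COLUMNS)
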