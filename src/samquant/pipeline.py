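"""End-to-end reproducible runs: simulate → resample → mask → quantify → stats.

A :class:`RunConfig` declares every knob of a run (grid, dome geometry,
mask parameters, quantification depths, cohort design, seed).  The run
writes its outputs under one directory and finishes with a JSON manifest
listing every file plus a hash of the configuration, sufficient to re-run.
Identical config + seed produces byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fluor, morphometry, paraboloid, stats, synthetic
from .stack_io import FLUOR_COLUMNS, MORPH_COLUMNS, resample_isotropic, write_stack, write_table

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "ConfigError"]

log = logging.getLogger("samquant")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int
    outdir: str = "samquant_run"
    # synthetic stack
    grid_shape_zyx: tuple[int, int, int] = (64, 96, 96)
    voxel_size_xy: float = 0.25
    voxel_size_z: float = 0.5
    dome_apex_um: tuple[float, float, float] = (11.875, 11.875, 3.0)
    dome_a1: float = 0.05
    dome_a2: float = 0.055
    dome_tilt_deg: float = 5.0
    reporter_value: float = 100.0
    reporter_mode: str = "uniform-interior"
    poisson_gain: float = 1.0
    # outline / mask
    outline_points: int = 60
    outline_noise_um: float = 0.1
    theta_range: tuple[float, float] = (-20.0, 20.0)
    alpha: float = 0.9
    # quantification
    depths_um: tuple[float, ...] = (20.0, 50.0)
    smoothing_sigma_px: float | None = None
    # cohort / stats
    cohort_n_per_group: int = 8
    cohort_n_experiments: int = 6
    cohort_sigma_log: float = 0.12
    reference_genotype: str = "wildtype"
    alpha_level: float = 0.05

    def validate(self) -> None:
        if not all(s > 0 for s in self.grid_shape_zyx):
            raise ConfigError("grid shape must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha (mask inflation) must lie in (0, 1)")
        if any(d <= 0 for d in self.depths_um):
            raise ConfigError("quantification depths must be positive")
        if self.cohort_n_per_group < 1 or self.cohort_n_experiments < 1:
            raise ConfigError("cohort sizes must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # lists, plain types

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigError("config must set a seed")
        kwargs = dict(d)
        for key in ("grid_shape_zyx", "dome_apex_um", "theta_range", "depths_um"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str) -> Path:
        p = outdir / name
        outputs.append(name)
        return p

    rng_seed = int(config.seed)

    # --- simulate -------------------------------------------------------
    @_stage("simulate")
    def simulate():
        dome = synthetic.DomeSpec(config.dome_apex_um, config.dome_a1,
                                  config.dome_a2, config.dome_tilt_deg)
        reporter = synthetic.ReporterSpec(
            mode=config.reporter_mode, value=config.reporter_value,
            poisson_gain=config.poisson_gain, name="reporter")
        stack, manifest = synthetic.make_dome_stack(
            dome, [reporter], shape_zyx=config.grid_shape_zyx,
            voxel_size_xy=config.voxel_size_xy,
            voxel_size_z=config.voxel_size_z, seed=rng_seed)
        write_stack(stack, emit("dome_stack.tif"))
        with open(emit("dome_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return dome, stack, manifest

    dome, stack, dome_manifest = simulate()

    # --- resample -------------------------------------------------------
    iso = _stage("resample")(resample_isotropic)(stack)

    # --- fit-mask -------------------------------------------------------
    @_stage("fit-mask")
    def fit_mask():
        x0, y0, z0 = dome.apex_um
        pts_xz = synthetic.make_outline_points(
            (x0, z0), dome.a1, dome.tilt_deg, config.outline_points,
            config.outline_noise_um, rng_seed + 1)
        pts_yz = synthetic.make_outline_points(
            (y0, z0), dome.a2, 0.0, config.outline_points,
            config.outline_noise_um, rng_seed + 2)
        p_xz = paraboloid.fit_parabola(pts_xz, config.theta_range)
        p_yz = paraboloid.fit_parabola(pts_yz, config.theta_range)
        shape3d = paraboloid.build_paraboloid(p_xz, p_yz, lateral_complete=True)
        inflated = paraboloid.inflate_curvature(shape3d, config.alpha)
        with open(emit("paraboloid.json"), "w") as fh:
            json.dump({"fitted": shape3d.to_dict(),
                       "inflated": inflated.to_dict(),
                       "alpha": config.alpha}, fh, indent=2, sort_keys=True)
        return inflated

    shape3d = fit_mask()

    # --- quantify -------------------------------------------------------
    @_stage("quantify")
    def quantify():
        masked = paraboloid.apply_mask(iso, shape3d, "reporter")
        rows = []
        for depth in config.depths_um:
            region = fluor.upper_region(shape3d, masked.shape_zyx,
                                        masked.voxel_size, depth)
            meas = fluor.concentration(masked, region, "reporter",
                                       config.smoothing_sigma_px)
            rows.append(meas.to_row(sample_id="dome_stack", channel="reporter"))
        df = pd.DataFrame(rows)
        write_table(df, emit("fluor_measures.csv"), FLUOR_COLUMNS)
        return df

    fluor_df = quantify()

    # --- cohort ---------------------------------------------------------
    @_stage("cohort")
    def cohort_stage():
        spec = synthetic.default_cohort(
            seed=rng_seed + 10, n_per_group=config.cohort_n_per_group,
            n_experiments=config.cohort_n_experiments,
            sigma_log=config.cohort_sigma_log)
        records = synthetic.make_timecourse(spec)
        write_table(records, emit("morph_records.csv"), MORPH_COLUMNS)
        return records

    records = cohort_stage()

    # --- stats ----------------------------------------------------------
    @_stage("stats")
    def stats_stage():
        ref = config.reference_genotype
        genos = [g for g in records["genotype"].unique() if g != ref]
        peak = morphometry.max_height_timepoint(records, ref)
        rows = []
        for measure in ("height_um", "width_um"):
            for g in genos:
                for tp in sorted(records["timepoint_d"].unique()):
                    cmp_ = stats.compare_genotypes(records, measure, tp, ref, g,
                                                   config.alpha_level)
                    rows.append({
                        "measure": measure, "genotype": g, "timepoint_d": tp,
                        "test": cmp_.test, "statistic": cmp_.statistic,
                        "p_value": cmp_.p_value,
                        "significant": cmp_.significant,
                        "n1": cmp_.n1, "n2": cmp_.n2,
                    })
        write_table(pd.DataFrame(rows), emit("genotype_comparisons.csv"))

        t0 = min(records["timepoint_d"].unique())
        folds = pd.DataFrame([
            {
                "genotype": g, "measure": m, "t0": t0, "t1": peak,
                "fold_change": stats.fold_change(records, m, t0, peak, g),
            }
            for g in records["genotype"].unique()
            for m in ("height_um", "width_um")
        ])
        write_table(folds, emit("fold_changes.csv"))

        letter_rows = []
        for g in records["genotype"].unique():
            disp = stats.compare_timepoints(records, "height_um", g,
                                            config.alpha_level)
            for tp in disp.groups:
                letter_rows.append({
                    "genotype": g, "timepoint_d": tp,
                    "letters": disp.letters[tp],
                    "anova_F": disp.anova_F, "anova_p": disp.anova_p,
                })
        write_table(pd.DataFrame(letter_rows), emit("timepoint_letters.csv"))

        norm = stats.normalize_by_reference(
            records[records["timepoint_d"] == peak], ref, "height_um")
        write_table(norm, emit("normalized_heights.csv"))
        return folds

    folds = stats_stage()

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": rng_seed,
        "outputs": outputs,
        "summary": {
            "reported_concentrations": fluor_df["reported_concentration"].tolist(),
            "fold_changes": folds.to_dict("records"),
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
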