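"""End-to-end orchestration: geometry -> flow -> analysis -> filtration.

A single :class:`RunConfig` (built in Python or loaded from YAML) names the
input geometry (an image stack, a synthetic weave, or a named analytic
fixture), the solver and particle-sweep settings, and an output directory.
:func:`run_pipeline` executes the stages in order and writes the grid, the
Darcy/impedance summary, the filtration curve CSV and a JSON report with
every number the run produced (units included).  Runs are deterministic
for a fixed seed.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import flow_analysis, particles
from .fabric import FIXTURE_NAMES, FabricSpec, generate_fixture, \
    generate_plain_weave
from .grid import VoxelGrid, save_grid
from .imaging import ImagePipelineParams, crop_region, load_stack, preprocess
from .lbm import LBMParams, run_lbm
from .scales import FLOW_SPEED_MODERATE, build_units

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class ParticleSweep:
    diameters_um: tuple = (1.0, 1.5, 2.0, 5.0, 10.0, 20.0)
    modes: tuple = ("inertial", "tracer")
    n_samp: int = 1600
    u_face_m_per_s: float = FLOW_SPEED_MODERATE
    max_steps: int = 1_000_000


@dataclass
class RunConfig:
    """One fully-specified pipeline run.

    Exactly one of ``stack_path``, ``fabric`` or ``fixture`` selects the
    input geometry.
    """

    stack_path: str | None = None
    fabric: FabricSpec | None = None
    fixture: dict | None = None            # {"name": ..., "shape": ..., ...}
    image_params: ImagePipelineParams = field(default_factory=ImagePipelineParams)
    crop_box: tuple | None = None          # (x0, y0, nx, ny)
    lbm: LBMParams = field(default_factory=LBMParams)
    sweep: ParticleSweep = field(default_factory=ParticleSweep)
    voxel_pitch_um: float | None = None    # required for stacks w/o sidecar
    output_dir: str = "weavefilter_out"
    rng_seed: int = 0
    run_particles: bool = True

    def __post_init__(self) -> None:
        sources = [self.stack_path is not None, self.fabric is not None,
                   self.fixture is not None]
        if sum(sources) != 1:
            raise ConfigError("exactly one input source must be given")


def config_from_yaml(path: str | Path) -> RunConfig:
    """Build a validated RunConfig from a YAML file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {"stack_path", "fabric", "fixture", "image_params", "crop_box",
             "lbm", "sweep", "voxel_pitch_um", "output_dir", "rng_seed",
             "run_particles"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    try:
        if "fabric" in raw:
            kwargs["fabric"] = FabricSpec(**raw["fabric"])
        if "fixture" in raw:
            fx = dict(raw["fixture"])
            if fx.get("name") not in FIXTURE_NAMES:
                raise ConfigError(f"fixture name must be one of {FIXTURE_NAMES}")
            fx["shape"] = tuple(fx["shape"])
            kwargs["fixture"] = fx
        if "image_params" in raw:
            kwargs["image_params"] = ImagePipelineParams(**raw["image_params"])
        if "lbm" in raw:
            kwargs["lbm"] = LBMParams(**raw["lbm"])
        if "sweep" in raw:
            sw = dict(raw["sweep"])
            for key in ("diameters_um", "modes"):
                if key in sw:
                    sw[key] = tuple(sw[key])
            kwargs["sweep"] = ParticleSweep(**sw)
        for key in ("stack_path", "crop_box", "voxel_pitch_um", "output_dir",
                    "rng_seed", "run_particles"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "crop_box" \
                    else raw[key]
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(**kwargs)


def _build_geometry(config: RunConfig) -> VoxelGrid:
    if config.fabric is not None:
        spec = config.fabric
        if spec.rng_seed != config.rng_seed:
            from dataclasses import replace
            spec = replace(spec, rng_seed=config.rng_seed)
        return generate_plain_weave(spec)
    if config.fixture is not None:
        fx = dict(config.fixture)
        name = fx.pop("name")
        return generate_fixture(name, **fx)
    stack = load_stack(config.stack_path, config.voxel_pitch_um)
    grid = preprocess(stack, config.image_params)
    if config.crop_box is not None:
        grid = crop_region(grid, *config.crop_box)
    return grid


def run_pipeline(config: RunConfig) -> dict:
    """Execute geometry -> LBM -> Darcy analysis -> filtration sweep.

    Returns the report dictionary (also written to ``report.json`` in the
    output directory, alongside ``grid.tif``, ``filtration.csv``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": config.rng_seed, "stages": {}}

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:   # tag the failing stage
            raise StageError(stage, exc) from exc
        report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s: %.2fs", stage, time.perf_counter() - t0)
        return result

    grid = timed("geometry", lambda: _build_geometry(config))
    save_grid(grid, out / "grid.tif")
    report["geometry"] = {
        "shape": list(grid.shape),
        "voxel_pitch_um": grid.voxel_pitch,
        "fabric_z_range": list(grid.fabric_z_range),
        "solid_fraction_in_fabric": grid.solid_fraction(),
    }

    fld = timed("flow", lambda: run_lbm(grid, config.lbm))
    report["flow"] = {
        "converged": fld.converged,
        "steps": fld.steps_run,
        "mean_uz_lb": fld.mean_uz(),
    }

    units = build_units(grid.voxel_pitch, nu_lb=config.lbm.nu_lb)
    darcy = timed("analysis", lambda: flow_analysis.darcy_summary(fld, units=units))
    imp = flow_analysis.impedance(darcy.k_um2, grid.fabric_thickness_um) \
        if darcy.k_um2 > 0 else float("inf")
    u_cm = config.sweep.u_face_m_per_s * 100.0
    report["darcy"] = {
        "Q_lb": darcy.q_lb,
        "U_darcy_lb": darcy.u_darcy_lb,
        "k_lb": darcy.k_lb,
        "k_um2": darcy.k_um2,
        "delta_p_lb": darcy.delta_p_lb,
        "L_F_um": grid.fabric_thickness_um,
        "reynolds": darcy.reynolds,
        "impedance_Pa_s_per_cm": imp,
        "pressure_drop_Pa_at_U": (imp * u_cm if np.isfinite(imp) else
                                  float("inf")),
        "U_face_cm_per_s": u_cm,
        "units": {"Q_lb": "lattice^3/step", "k_um2": "um^2",
                  "impedance_Pa_s_per_cm": "Pa s cm^-1",
                  "pressure_drop_Pa_at_U": "Pa"},
    }

    if config.run_particles and darcy.u_darcy_lb > 0:
        scaled = flow_analysis.rescale_flow(fld, config.sweep.u_face_m_per_s,
                                            units)
        result = timed("filtration", lambda: particles.run_filtration_curve(
            scaled, config.sweep.diameters_um, config.sweep.modes,
            config.sweep.n_samp, config.sweep.u_face_m_per_s,
            max_steps=config.sweep.max_steps))
        rows = []
        for mode in config.sweep.modes:
            for i, d in enumerate(result.diameters_um):
                c = result.counts[mode][i]
                rows.append({"diameter_um": d, "mode": mode,
                             "efficiency": result.efficiency[mode][i],
                             "n_collided": c[0], "n_penetrated": c[1],
                             "n_unresolved": c[2]})
        with open(out / "filtration.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
        report["filtration"] = {
            "n_samp": result.n_samp,
            "diameters_um": list(result.diameters_um),
            "efficiency": {m: list(map(float, result.efficiency[m]))
                           for m in config.sweep.modes},
            "units": {"diameters_um": "um", "efficiency": "fraction in [0,1]"},
        }
        fom = {}
        for m in config.sweep.modes:
            fom[m] = [flow_analysis.figure_of_merit(min(e, 1.0 - 1e-12), imp)
                      if np.isfinite(imp) else 0.0
                      for e in result.efficiency[m]]
        report["figure_of_merit_cm_per_Pa_s"] = fom

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
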