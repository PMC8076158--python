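"""End-to-end analysis pipeline: movie -> structure functions -> diffusion.

`run_pipeline` ties the stages together into a reproducible, seeded run that
writes every table alongside a provenance record (configuration echo +
package version + seed).  Any stage failure aborts with a stage-labelled
error so partial outputs are identifiable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as _io
from .ddm import ImageSequence, structure_function
from .fitmodels import StructureFunctionFit
from .sgmap import sg_structure_function
from .simulate import SimulationConfig, generate_movie
from . import tracking as _tracking

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``input_path`` points at an existing TIFF stack, or
    ``simulation`` holds a SimulationConfig and the movie is generated.
    ``analyses`` is any subset of {"ddm", "sgddm", "track"} or ["all"].
    """

    out_dir: str
    input_path: str | None = None
    simulation: SimulationConfig | None = None
    pixel_size: float | None = None  # µm/px, required with input_path
    dt: float | None = None  # s, required with input_path
    analyses: tuple[str, ...] = ("all",)
    fit_model: str = "double"
    q_max: float | None = None  # analysis band and fit-range cap, µm^-1
    max_pairs: int = 300
    subtract_background: bool = False
    max_disp_px: float = 3.0
    min_separation_px: int = 9
    roi_halfwidth: int = 12
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_path is None and self.simulation is None:
            raise ValueError("either input_path or simulation must be given")
        if self.input_path is not None:
            if not Path(self.input_path).exists():
                raise ValueError(f"input path {self.input_path} does not exist")
            if not (self.pixel_size and self.pixel_size > 0):
                raise ValueError("pixel_size must be positive when reading a stack")
            if not (self.dt and self.dt > 0):
                raise ValueError("dt must be positive when reading a stack")

    @property
    def wants(self) -> set[str]:
        if "all" in self.analyses:
            return {"ddm", "sgddm", "track"}
        return set(self.analyses)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = _io.read_config(path)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "image_shape" in sim:
                sim["image_shape"] = tuple(sim["image_shape"])
            sim = SimulationConfig(**sim)
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["analyses"] = list(self.analyses)
        return d


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("input")
def _load(config: RunConfig) -> ImageSequence:
    if config.input_path is not None:
        return _io.read_stack(config.input_path, config.pixel_size, config.dt)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    seq, traj = generate_movie(sim)
    out = Path(config.out_dir)
    traj.to_dataframe().to_csv(out / "ground_truth.csv", index=False)
    return seq


@_stage("ddm")
def _run_ddm(seq, config, out):
    table = structure_function(seq, max_pairs=config.max_pairs, q_max=config.q_max)
    _io.write_structure_table(out / "ddm_structure_function.csv", table)
    res = StructureFunctionFit(table, model="single", q_max=config.q_max).fit()
    res.params.to_csv(out / "ddm_fits.csv")
    bundle = {"table": table, "fits": res}
    try:
        bundle["D_T"] = res.translational_diffusion()
    except ValueError as exc:
        bundle["D_T_error"] = str(exc)
    return bundle


@_stage("sgddm")
def _run_sg(seq, config, out):
    table = sg_structure_function(
        seq,
        max_pairs=config.max_pairs,
        subtract_background=config.subtract_background,
        q_max=config.q_max,
    )
    _io.write_structure_table(out / "sgddm_structure_function.csv", table)
    res = StructureFunctionFit(table, model=config.fit_model, q_max=config.q_max).fit()
    res.params.to_csv(out / "sgddm_fits.csv")
    bundle = {"table": table, "fits": res}
    try:
        bundle["D_T"] = res.translational_diffusion()
    except ValueError as exc:
        bundle["D_T_error"] = str(exc)
    if config.fit_model == "double":
        try:
            bundle["D_R"] = res.rotational_diffusion()
        except ValueError as exc:
            bundle["D_R_error"] = str(exc)
    return bundle


@_stage("track")
def _run_track(seq, config, out):
    dets = [
        detdf.assign(frame=i)
        for i, detdf in enumerate(
            _tracking.detect_particles(f, min_separation=config.min_separation_px)
            for f in seq.frames
        )
    ]
    linked = _tracking.link(pd.concat(dets, ignore_index=True), max_disp=config.max_disp_px)
    traj = _tracking.measure_trajectories(seq, linked, roi_halfwidth=config.roi_halfwidth)
    traj.to_csv(out / "trajectories.csv", index=False)
    msd_curve, msd_fit = _tracking.msd(traj, seq.dt)
    msd_curve.to_csv(out / "msd.csv", index=False)
    bundle = {"trajectories": traj, "msd": msd_fit}
    try:
        ang_curve, ang_fit = _tracking.angular_msd(traj, seq.dt)
        ang_curve.to_csv(out / "angular_msd.csv", index=False)
        bundle["angular_msd"] = ang_fit
    except ValueError as exc:
        bundle["angular_msd"] = {"error": str(exc)}
    try:
        c_curve, c_fit = _tracking.aspect_ratio_autocorrelation(traj, seq.dt)
        c_curve.to_csv(out / "aspect_autocorrelation.csv", index=False)
        bundle["aspect_autocorrelation"] = c_fit
    except ValueError as exc:
        bundle["aspect_autocorrelation"] = {"error": str(exc)}
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses; returns the result bundle.

    Deterministic given the seed.  Writes structure functions, fit tables,
    trajectory tables, a diffusion summary and a provenance record into
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_config_echo(
        out / "run.yaml",
        {"config": config.to_dict(), "version": __version__, "seed": config.seed},
    )
    seq = _load(config)
    bundle: dict = {"sequence": seq}
    summary: dict = {"seed": config.seed, "version": __version__}
    if "ddm" in config.wants:
        r = _run_ddm(seq, config, out)
        bundle["ddm"] = r
        if "D_T" in r:
            summary["DDM"] = {"D_T": r["D_T"].D_T, "D_T_se": r["D_T"].D_T_se,
                              "q_max": r["D_T"].q_max_used}
        else:
            summary["DDM"] = {"error": r["D_T_error"]}
    if "sgddm" in config.wants:
        r = _run_sg(seq, config, out)
        bundle["sgddm"] = r
        summary["SG-DDM"] = {}
        if "D_T" in r:
            summary["SG-DDM"].update({"D_T": r["D_T"].D_T, "D_T_se": r["D_T"].D_T_se})
        else:
            summary["SG-DDM"]["error"] = r["D_T_error"]
        if "D_R" in r:
            summary["SG-DDM"].update({"D_R": r["D_R"].D_R, "D_R_se": r["D_R"].D_R_se})
    if "track" in config.wants:
        r = _run_track(seq, config, out)
        bundle["track"] = r
        summary["SPT"] = {"D_T": r["msd"]["D_T"]}
        if "D_R" in r.get("angular_msd", {}):
            summary["SPT"]["D_R_angular"] = r["angular_msd"]["D_R"]
        if "D_R" in r.get("aspect_autocorrelation", {}):
            summary["SPT"]["D_R_aspect"] = r["aspect_autocorrelation"]["D_R"]
            summary["SPT"]["gamma"] = r["aspect_autocorrelation"]["gamma"]
    _io.write_config_echo(out / "summary.yaml", _pyify(summary))
    bundle["summary"] = summary
    return bundle


def _pyify(obj):
    """Recursively convert numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
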