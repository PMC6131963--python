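"""One-config pipeline tying the stages together.

A single TOML file (or in-memory dict) describes geometry, material, load,
schedule and analysis toggles; :func:`run_pipeline` executes
geometry -> solve -> optimise -> analyses -> reports, writing VTK fields,
CSV tables, an STL surface and a JSON manifest with checksums of every
output.  Re-running an identical config yields bit-identical CSV/VTK
outputs (the pipeline is deterministic).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as budget_mod
from . import fem, io, stress, topopt
from .geometry import PadGeometryParams, RecessSpec, build_design_domain
from .morphometry import fixture_frame
from .peel import PeelConfig, kendall_peel_force, septum_loadcase_comparison

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_fields"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run (all published defaults)."""

    geometry: dict = field(default_factory=dict)
    resolution: tuple[int, int, int] = (30, 20, 9)
    material: dict = field(default_factory=lambda: {"E_MPa": 20.0, "nu": 0.33,
                                                    "sigma_t_MPa": 20.0})
    load: dict = field(default_factory=lambda: {"total_force_N": 3.815e-3,
                                                "face": "proximal",
                                                "direction": (-1.0, 0.0, 0.0)})
    schedule: dict = field(default_factory=lambda: {"total_reduction": 0.60,
                                                    "step": 0.025,
                                                    "inner_iters_max": 30,
                                                    "convergence_tol": 0.01})
    optimiser: dict = field(default_factory=lambda: {"penalty_p": 3.0,
                                                     "filter_radius_voxels": 1.5,
                                                     "freeze_ventral": True,
                                                     "threshold": 0.5})
    analysis: dict = field(default_factory=lambda: {"optimise": True,
                                                    "trajectories": True,
                                                    "contrasts": True,
                                                    "ridge_profile": True,
                                                    "budget": True,
                                                    "peel": True})
    peel: dict = field(default_factory=lambda: {"attachment_frac": 0.25,
                                                "inclination_deg": 70.0})
    budget: dict = field(default_factory=lambda: {"demands": [1.27, 3.815e-3]})
    output_dir: str = "frogpad_run"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(io.load_toml(path))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for key in ("geometry", "material", "load", "schedule", "optimiser",
                    "analysis", "peel", "budget"):
            if key in raw:
                getattr(cfg, key).update(raw[key])
        if "resolution" in raw:
            r = raw["resolution"]
            cfg.resolution = tuple(int(v) for v in (r["nx"], r["ny"], r["nz"])) \
                if isinstance(r, dict) else tuple(int(v) for v in r)
        if "output" in raw and "directory" in raw["output"]:
            cfg.output_dir = raw["output"]["directory"]
        return cfg

    # -- resolved objects -------------------------------------------------
    def pad_params(self) -> PadGeometryParams:
        g = dict(self.geometry)
        recess = RecessSpec(
            shape=g.pop("recess_shape", "quarter_cylinder"),
            radius_mm=g.pop("recess_radius_mm", None),
        )
        return PadGeometryParams(recess=recess, **g)

    def fem_material(self) -> fem.Material:
        return fem.Material(**self.material)

    def load_case(self) -> fem.LoadCase:
        d = np.asarray(self.load["direction"], dtype=float)
        d = d / np.linalg.norm(d)
        f = tuple(d * self.load["total_force_N"])
        return fem.LoadCase(tractions=(fem.FaceTraction(face=self.load["face"], force_N=f),))

    def opt_schedule(self) -> topopt.OptimisationSchedule:
        return topopt.OptimisationSchedule(**self.schedule)

    def to_dict(self) -> dict:
        return asdict(self)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fields(domain, fields: dict, path: str | Path) -> Path:
    """Write density plus solved fields of a domain as one VTK file.

    ``fields`` may contain a DisplacementField under "displacement" and a
    StressField under "stress"; cell arrays density, von_mises, sigma1..3
    and the point displacement vector are emitted.
    """
    cell = {"density": domain.density}
    point = {}
    if "stress" in fields:
        sf = fields["stress"]
        cell["von_mises"] = sf.von_mises
        pv = sf.principal_values
        cell["sigma1"] = pv[..., 0]
        cell["sigma2"] = pv[..., 1]
        cell["sigma3"] = pv[..., 2]
    if "displacement" in fields:
        point["displacement"] = fields["displacement"].values
    return io.write_vtk(path, domain, cell_data=cell, point_data=point or None)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest (also written).

    Any stage error aborts the run with a partial manifest (marked failed)
    written to the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}, "status": "running"}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    def stage_done(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
        log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    try:
        # geometry ---------------------------------------------------------
        t0 = time.perf_counter()
        params = config.pad_params()
        domain = build_design_domain(params, config.resolution)
        fixture = fixture_frame()
        fixture_path = out / "morphometry.csv"
        fixture.to_csv(fixture_path, index=False)
        record("morphometry", fixture_path)
        record("geometry_vtk", io.write_vtk(out / "geometry.vtk", domain,
                                            cell_data={"density": domain.density}))
        stage_done("geometry", t0, void_fraction=domain.void_fraction())

        # solve (non-optimised) -------------------------------------------
        t0 = time.perf_counter()
        material = config.fem_material()
        load_case = config.load_case()
        u = fem.solve(domain, material, load_case)
        sf = fem.recover_stress(domain, material, u)
        record("solve_vtk", write_fields(domain, {"displacement": u, "stress": sf},
                                         out / "solve.vtk"))
        stage_done("solve", t0, compliance_Nmm=u.compliance_Nmm, residual=u.residual)

        toggles = config.analysis
        opt_result = None
        if toggles.get("optimise", True):
            t0 = time.perf_counter()
            opt = config.optimiser
            opt_result = topopt.optimise(
                domain, material, load_case, config.opt_schedule(),
                penalty_p=opt["penalty_p"],
                filter_radius_voxels=opt["filter_radius_voxels"],
                freeze_ventral=opt["freeze_ventral"],
            )
            hist = pd.DataFrame({
                "stage": np.arange(1, opt_result.n_stages + 1),
                "volume_fraction": opt_result.volume_fraction,
                "compliance": opt_result.compliance_Nmm,
            })
            hist_path = out / "compliance_history.csv"
            hist.to_csv(hist_path, index=False)
            record("compliance_history", hist_path)
            u_opt = fem.solve(opt_result.domain, material, load_case,
                              opt["penalty_p"])
            sf_opt = fem.recover_stress(opt_result.domain, material, u_opt,
                                        opt["penalty_p"])
            record("optimised_vtk", write_fields(
                opt_result.domain, {"displacement": u_opt, "stress": sf_opt},
                out / "optimised.vtk"))
            record("optimised_stl", io.write_stl(out / "optimised.stl",
                                                 opt_result.domain,
                                                 threshold=opt["threshold"]))
            stage_done("optimise", t0,
                       final_volume_fraction=opt_result.final_volume_fraction,
                       stages=opt_result.n_stages)

        if toggles.get("trajectories", True):
            t0 = time.perf_counter()
            trajs = stress.trace_trajectories(sf, domain)
            record("trajectories", io.write_trajectories_csv(out / "trajectories.csv", trajs))
            stage_done("trajectories", t0, n=len(trajs))

        if toggles.get("contrasts", True):
            t0 = time.perf_counter()
            rep = stress.von_mises_contrasts(sf, domain)
            summary = {
                "inter_row_mean_MPa": rep.inter_row_mean,
                "intra_row_mean_MPa": rep.intra_row_mean,
                "ratio": rep.ratio,
                "quartile_means_MPa": list(rep.quartile_means),
            }
            path = out / "von_mises_contrasts.json"
            path.write_text(json.dumps(summary, indent=2) + "\n")
            record("contrasts", path)
            stage_done("contrasts", t0, ratio=rep.ratio)

        if toggles.get("ridge_profile", True) and opt_result is not None:
            t0 = time.perf_counter()
            prof = stress.ridge_profile(opt_result.domain)
            df = pd.DataFrame({"y_mm": prof.y_mm, "density": prof.profile})
            path = out / "ridge_profile.csv"
            df.to_csv(path, index=False)
            record("ridge_profile", path)
            stage_done("ridge_profile", t0,
                       troughs=list(map(float, prof.trough_y)),
                       ridges=list(map(float, prof.ridge_y)))

        if toggles.get("budget", True):
            t0 = time.perf_counter()
            demands = {f"demand_{i}": d for i, d in enumerate(config.budget["demands"])}
            budgets = budget_mod.budget_report(reference_loads=demands)
            path = out / "load_budget.csv"
            budget_mod.budget_frame(budgets).to_csv(path, index=False)
            record("budget", path)
            stage_done("budget", t0)

        if toggles.get("peel", True):
            t0 = time.perf_counter()
            rep = septum_loadcase_comparison(
                domain, material,
                force_N=config.load["total_force_N"],
                attachment_frac=config.peel["attachment_frac"],
                inclination_deg=config.peel["inclination_deg"],
            )
            angles = np.arange(10.0, 181.0, 10.0)
            forces = [
                kendall_peel_force(PeelConfig(
                    width_b_mm=domain.params.width_mm,
                    thickness_d_mm=domain.params.height_mm,
                    E_MPa=material.E_MPa,
                    R_Jm2=config.peel.get("R_Jm2", 50.0),
                    theta_deg=a)) for a in angles
            ]
            summary = {
                "septum_max_tensile_MPa": rep.septum.max_tensile_MPa,
                "septum_max_location_mm": rep.septum.max_tensile_location_mm,
                "septum_mean_tensile_MPa": rep.septum.mean_tensile_MPa,
                "proximal_mean_tensile_MPa": rep.proximal_pull.mean_tensile_MPa,
                "mean_tensile_ratio": rep.mean_tensile_ratio,
                "kendall_theta_deg": list(angles),
                "kendall_force_N": forces,
            }
            path = out / "peel_report.json"
            path.write_text(json.dumps(summary, indent=2) + "\n")
            record("peel", path)
            stage_done("peel", t0)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
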