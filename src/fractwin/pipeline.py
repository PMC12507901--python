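"""End-to-end orchestration: phantom -> calibration -> segmentation -> mesh
-> materials -> FE solve -> mechanobiological assessment, per weight-bearing
level, as a configured, logged, reproducible run.

A run compares the configured weight-bearing levels (20 kg partial load,
50% body weight, full) on one construct: the stiffness is assembled and
factorized once and each level only re-weights the three unit-load
solutions. All randomness derives from the single run seed, so identical
(config, seed) pairs produce byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fem import BoundaryCondition, LinearGaitSolver, LoadCase
from .gait import ReferenceDatabase, WeightBearingLevel, build_reference, scale_to_patient
from .healing import HealingAssessment, HealingWindowConfig, assess, default_window
from .imaging import SegmentationConfig, calibrate_density, rod_masks_from_layout, segment_adaptive
from .inp import write_inp
from .materials import MaterialModel, map_materials
from .meshing import MeshConfig, build_mesh
from .phantom import PhantomSpec, SyntheticCurveSpec, generate_gait_curve, generate_phantom_volume
from .vtkio import write_vtu

log = logging.getLogger("fractwin")

__all__ = ["RunConfig", "PipelineRun", "run"]

_ALL_LEVELS = (WeightBearingLevel.PWB_20KG, WeightBearingLevel.PWB_50PCT, WeightBearingLevel.FULL)


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    materials: MaterialModel = field(default_factory=MaterialModel)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    window: HealingWindowConfig = field(default_factory=default_window)
    levels: tuple[WeightBearingLevel, ...] = _ALL_LEVELS
    patient_mass: float = 70.0  # kg
    n_reference_subjects: int = 22
    curve_noise_sd: float = 5.0  # %BW
    n_curve_samples: int = 101
    unfavorable_limit: float = 0.0
    gravity: float = 9.81
    seed: int = 0
    out_dir: str = "fractwin_out"
    write_fields: bool = True  # VTU at the peak-load sample per level
    use_cache: bool = True

    def __post_init__(self) -> None:
        self.levels = tuple(WeightBearingLevel(lv) for lv in self.levels)
        if not self.levels:
            raise ValueError("at least one weight-bearing level must be configured")
        if self.patient_mass <= 0:
            raise ValueError("patient mass must be positive")
        if self.n_reference_subjects < 1:
            raise ValueError("need at least one reference subject")
        if not isinstance(self.window, HealingWindowConfig):
            self.window = HealingWindowConfig.from_dict(self.window)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = self.window.to_dict()
        d["levels"] = [lv.value for lv in self.levels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("phantom", PhantomSpec),
            ("materials", MaterialModel),
            ("segmentation", SegmentationConfig),
            ("mesh", MeshConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: _tupled(v) for k, v in d[key].items()})
        if "window" in d and isinstance(d["window"], dict):
            d["window"] = HealingWindowConfig.from_dict(d["window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (I/O knobs excluded)."""
        d = self.to_dict()
        for key in ("out_dir", "write_fields", "use_cache"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, *tags: int) -> int:
        """Derive a deterministic sub-seed (< 2^31) from the run seed."""
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, *tags])
        return int(ss.generate_state(1)[0] % (2**31))


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


@dataclass
class PipelineRun:
    """Outputs of :func:`run`."""

    config: RunConfig
    calibration: object
    mesh: object
    materials: object
    reference: ReferenceDatabase
    load_cases: dict[WeightBearingLevel, LoadCase]
    results: dict[WeightBearingLevel, object]
    assessments: dict[WeightBearingLevel, HealingAssessment]
    report: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %-12s started", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("phantom")
def _phantom_stage(config: RunConfig):
    spec = replace(config.phantom, seed=config.stage_seed(1))
    return generate_phantom_volume(spec), spec


@_stage("calibrate")
def _calibrate_stage(config: RunConfig, volume):
    rods = rod_masks_from_layout(volume)
    return calibrate_density(volume, rods, volume.meta["rod_densities_mg_cm3"])


@_stage("segment")
def _segment_stage(config: RunConfig, volume, calibration):
    return segment_adaptive(volume, calibration, config.segmentation)


@_stage("mesh")
def _mesh_stage(config: RunConfig, masks):
    return build_mesh(masks.labels, masks.spacing, config.mesh)


@_stage("materials")
def _materials_stage(config: RunConfig, mesh, volume, calibration):
    return map_materials(mesh, volume, calibration, config.materials)


@_stage("loading")
def _loading_stage(config: RunConfig):
    curves = {}
    for li, level in enumerate(config.levels):
        curves[level] = [
            generate_gait_curve(
                SyntheticCurveSpec.for_level(
                    level,
                    seed=config.stage_seed(2, li, si),
                    noise_sd=config.curve_noise_sd,
                    n_samples=config.n_curve_samples,
                )
            )
            for si in range(config.n_reference_subjects)
        ]
    db = build_reference(curves, n_grid=config.n_curve_samples)
    loads = {
        level: scale_to_patient(db, level, config.patient_mass, g=config.gravity)
        for level in config.levels
    }
    return db, loads


def run(config: RunConfig, out_dir: str | Path | None = None) -> PipelineRun:
    """Execute all stages and write reports under the output directory.

    Writes per level: the load-case CSV, healing-class-fraction CSV, an
    assessment JSON and (optionally) a VTU of the fields at the peak-load
    sample; plus the shared input deck, calibration report, a machine report
    (report.json), a human summary (report.md) and a run manifest.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (volume, labels), phantom_spec = _phantom_stage(config)
    calibration = _calibrate_stage(config, volume)
    mesh, materials = _cached_geometry(config, out, volume, calibration)
    reference, load_cases = _loading_stage(config)

    bc = BoundaryCondition()
    solver = LinearGaitSolver(mesh, materials, bc)
    results = {level: solver.result(load_cases[level]) for level in config.levels}
    assessments = {
        level: assess(
            results[level],
            mesh,
            config.window,
            yield_strength=config.materials.implant_yield,
            unfavorable_limit=config.unfavorable_limit,
        )
        for level in config.levels
    }

    report = _build_report(config, calibration, mesh, load_cases, results, assessments)
    _write_outputs(config, out, calibration, mesh, materials, bc, load_cases,
                   results, assessments, report)
    return PipelineRun(
        config=config,
        calibration=calibration,
        mesh=mesh,
        materials=materials,
        reference=reference,
        load_cases=load_cases,
        results=results,
        assessments=assessments,
        report=report,
    )


def _cached_geometry(config: RunConfig, out: Path, volume, calibration):
    """Mesh + materials, cached on disk keyed by the config hash so the FE
    stage can be iterated without re-segmenting/re-meshing."""
    cache_dir = out / ".cache" / config.config_hash()
    mesh_npz = cache_dir / "geometry.npz"
    if config.use_cache and mesh_npz.exists():
        from .materials import ElementMaterials
        from .meshing import TetMesh

        log.info("geometry cache hit: %s", cache_dir)
        d = np.load(mesh_npz, allow_pickle=False)
        mesh = TetMesh(
            d["nodes"], d["elements"], d["region"],
            {"distal": d["distal"], "proximal": d["proximal"]},
            element_voxel=d["element_voxel"],
        )
        mats = ElementMaterials(E=d["E"], nu=d["nu"], region=d["region"])
        return mesh, mats

    masks = _segment_stage(config, volume, calibration)
    mesh = _mesh_stage(config, masks)
    mats = _materials_stage(config, mesh, volume, calibration)
    if config.use_cache:
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.savez(
            mesh_npz,
            nodes=mesh.nodes,
            elements=mesh.elements,
            region=mesh.region,
            distal=mesh.node_sets["distal"],
            proximal=mesh.node_sets["proximal"],
            element_voxel=mesh.element_voxel,
            E=mats.E,
            nu=mats.nu,
        )
    return mesh, mats


def _build_report(config, calibration, mesh, load_cases, results, assessments) -> dict:
    levels = {}
    for level in config.levels:
        lc = load_cases[level]
        a = assessments[level]
        rf = results[level].reaction_trace()
        peak_idx = int(np.argmax(np.linalg.norm(lc.forces, axis=1)))
        levels[level.value] = {
            "peak_force_N": {
                "Fx": float(np.abs(lc.forces[:, 0]).max()),
                "Fy": float(np.abs(lc.forces[:, 1]).max()),
                "Fz": float(np.abs(lc.forces[:, 2]).max()),
                "magnitude": lc.peak_force_magnitude(),
                "sample": peak_idx,
            },
            "equilibrium_residual": float(
                np.abs(rf + lc.forces).max() / max(np.abs(lc.forces).max(), 1e-30)
            ),
            "peak_gap_octahedral_shear_strain": a.peak_gap_gamma_oct,
            "worst_unfavorable_fraction": a.worst_unfavorable_fraction,
            "peak_implant_von_mises_MPa": a.peak_implant_von_mises,
            "stable": a.stable,
            "healing_ok": a.healing_ok,
        }
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "patient_mass_kg": config.patient_mass,
        "calibration": {
            "slope_mg_cm3_per_hu": calibration.slope,
            "intercept_mg_cm3": calibration.intercept,
            "rmse_mg_cm3": calibration.rmse,
        },
        "mesh": {"n_nodes": int(mesh.n_nodes), "n_elements": int(mesh.n_elements)},
        "yield_strength_MPa": config.materials.implant_yield,
        "levels": levels,
    }


def _write_outputs(config, out: Path, calibration, mesh, materials, bc, load_cases,
                   results, assessments, report) -> None:
    calibration.to_json(out / "calibration.json")
    (out / "model.inp").write_text(
        write_inp(mesh, materials, bc, load_cases[config.levels[0]])
    )
    for level in config.levels:
        tag = level.value.lower()
        load_cases[level].to_csv(out / f"loadcase_{tag}.csv")
        assessments[level].to_json(out / f"assessment_{tag}.json")
        assessments[level].fractions_to_csv(out / f"class_fractions_{tag}.csv")
        if config.write_fields:
            _write_level_vtu(out / f"fields_{tag}.vtu", mesh, materials,
                             results[level], assessments[level], config)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.md").write_text(_markdown_summary(report))
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"fractwin": __version__, "numpy": np.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def _write_level_vtu(path, mesh, materials, result, assessment, config) -> None:
    """Fields at the sample of peak applied force magnitude."""
    i = int(np.argmax(np.linalg.norm(result.applied, axis=1)))
    from .fem import voigt_to_tensor
    from .healing import octahedral_shear, volumetric_strain

    tensors = voigt_to_tensor(result.strain_voigt(i))
    gamma = octahedral_shear(tensors)
    vol = volumetric_strain(tensors)
    healing_class = np.full(mesh.n_elements, -1, dtype=np.int64)
    healing_class[assessment.gap_elements] = assessment.classes[i]
    write_vtu(
        path,
        mesh,
        point_data={"displacement": result.displacement(i)},
        cell_data={
            "region": mesh.region,
            "E": materials.E,
            "von_mises": result.von_mises_field(i),
            "octahedral_shear_strain": gamma,
            "volumetric_strain": vol,
            "healing_class": healing_class,
        },
    )


def _markdown_summary(report: dict) -> str:
    lines = [
        "# Weight-bearing assessment",
        "",
        f"- config hash: `{report['config_hash']}`, seed {report['seed']}",
        f"- patient mass: {report['patient_mass_kg']} kg",
        f"- calibration: rho = {report['calibration']['slope_mg_cm3_per_hu']:.4g}*HU + "
        f"{report['calibration']['intercept_mg_cm3']:.4g} mg/cm3 "
        f"(RMSE {report['calibration']['rmse_mg_cm3']:.3g})",
        f"- mesh: {report['mesh']['n_elements']} elements / {report['mesh']['n_nodes']} nodes",
        "",
        "| level | peak |F| (N) | peak gap gamma_oct | unfavorable fraction | "
        "peak implant VM (MPa) | stable | healing |",
        "|---|---|---|---|---|---|---|",
    ]
    for level, d in report["levels"].items():
        vm = d["peak_implant_von_mises_MPa"]
        lines.append(
            f"| {level} | {d['peak_force_N']['magnitude']:.1f} | "
            f"{d['peak_gap_octahedral_shear_strain']:.3e} | "
            f"{d['worst_unfavorable_fraction']:.3f} | "
            f"{vm if vm is None else f'{vm:.1f}'} | {d['stable']} | {d['healing_ok']} |"
        )
    lines.append("")
    lines.append(
        f"Stability compares peak implant von Mises stress with the "
        f"{report['yield_strength_MPa']} MPa yield strength."
    )
    return "\n".join(lines) + "\n"
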