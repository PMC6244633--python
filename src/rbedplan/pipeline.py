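"""End-to-end treatment-planning pipeline: phantom → dose → RBED → stats.

A single YAML-configurable run builds (or loads) the phantom, simulates
the calibrated 2 Gy fraction for the NP-doped and undoped phantoms,
produces RBED grids for the conventional and the three radiosensitisation
scenarios, and writes DVH/RVH CSVs plus a JSON report with provenance.
Identical configuration reproduces bit-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .dose import (
    BeamSpec,
    EngineOptions,
    calibrate_to_min_region_dose,
    dose_difference_report,
    opposed_pair,
    simulate_fraction,
)
from .dvh import cumulative_histogram, region_stats_table
from .phantom import (
    DEFAULT_REGIONS,
    RegionSpec,
    ShapePrimitive,
    VoxelPhantom,
    _merge,
    DEFAULT_CONFIG,
    build_default_phantom,
    export_phantom,
    import_phantom,
    tumour_centre,
    voxelize,
)
from .physics import AttenuationTable, EnergySpectrum
from .radiobio import (
    TissueResponseMap,
    equivalent_exposure_scaling,
    get_scenario,
    rbed_from_concentration,
    rbed_map,
    scenario_names,
)

logger = logging.getLogger(__name__)

RESPONDING_MATERIAL = "breast_tissue"


def default_response_map(phantom: VoxelPhantom) -> TissueResponseMap:
    """Breast-tissue regions respond to the AuNP agent; all others are
    mapped as identity (zero radiosensitisation increase)."""
    return TissueResponseMap(
        {lab: spec.material == RESPONDING_MATERIAL for lab, spec in phantom.regions.items()}
    )


@dataclass
class PlanConfig:
    """Pipeline configuration (all fields have working defaults)."""

    phantom: dict = field(default_factory=dict)
    phantom_path: str | None = None
    beam: dict = field(default_factory=dict)
    spectrum_path: str | None = None
    scenario: str = "maximum"
    engine: dict = field(default_factory=dict)
    prescription: dict = field(default_factory=dict)
    target_regions: list[str] = field(
        default_factory=lambda: ["tumour_inner", "tumour_wall"]
    )
    output_dir: str = "rbedplan_out"
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in scenario_names():
            raise ValueError(
                f"scenario must be one of {scenario_names()}, got {self.scenario!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlanConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def engine_options(self) -> EngineOptions:
        return EngineOptions(**self.engine)

    def fraction_dose_gy(self) -> float:
        return float(self.prescription.get("fraction_dose_gy", 2.0))


@dataclass
class RunReport:
    """Numerical summary of one pipeline run."""

    regions: list[str]
    dose_stats: dict
    rbed_stats: dict
    dose_difference: dict
    calibration: dict
    equivalent_exposure: dict
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text()))


def _save_grid(grid: np.ndarray, phantom: VoxelPhantom, path: Path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(phantom.spacing)
    aff[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(grid.astype(np.float32), aff), path)


def _target_labels(phantom: VoxelPhantom, names: list[str]) -> list[int]:
    return [phantom.label_by_name(n) for n in names]


def run_pipeline(config: PlanConfig) -> RunReport:
    """Execute every stage and write artifacts under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    def stage(name):
        logger.info("stage %-14s t=%.1fs", name, time.perf_counter() - t_start)

    stage("phantom")
    try:
        if config.phantom_path:
            phantom = import_phantom(config.phantom_path)
        else:
            phantom = build_default_phantom(config.phantom)
    except Exception:
        logger.exception("stage 'phantom' failed")
        raise
    export_phantom(phantom, out / "phantom.nii.gz")
    undoped = phantom.with_concentrations(0.0)

    spectrum = (
        EnergySpectrum.from_csv(config.spectrum_path)
        if config.spectrum_path
        else EnergySpectrum.bundled_6mv()
    )
    table = AttenuationTable.bundled()
    iso = config.beam.get("isocentre") or list(tumour_centre(config.phantom))
    plan = opposed_pair(
        iso,
        diameter_mm=config.beam.get("diameter_mm", 30.0),
        angle_deg=config.beam.get("angle_deg", 20.0),
        weight=config.beam.get("weight", 1.0),
    )
    opts = config.engine_options()
    targets = _target_labels(phantom, config.target_regions)

    stage("dose")
    try:
        raw_doped = simulate_fraction(phantom, plan, spectrum, table, opts)
        raw_undoped = simulate_fraction(undoped, plan, spectrum, table, opts)
        target = config.fraction_dose_gy()
        f_doped, dose_doped = calibrate_to_min_region_dose(raw_doped, phantom, targets, target)
        f_undoped, dose_undoped = calibrate_to_min_region_dose(
            raw_undoped, phantom, targets, target
        )
    except Exception:
        logger.exception("stage 'dose' failed")
        raise
    _save_grid(dose_doped, phantom, out / "dose_doped.nii.gz")
    _save_grid(dose_undoped, phantom, out / "dose_undoped.nii.gz")
    diff = dose_difference_report(dose_doped, dose_undoped, phantom, opts.dose_floor_fraction)

    stage("rbed")
    tmap = default_response_map(phantom)
    rbed_grids: dict[str, np.ndarray] = {}
    try:
        for name in scenario_names():
            scen = get_scenario(name)
            dose_grid = dose_undoped if name == "conventional" else dose_doped
            rbed_grids[name] = rbed_map(dose_grid, phantom, tmap, scen)
            _save_grid(rbed_grids[name], phantom, out / f"rbed_{name}.nii.gz")
    except Exception:
        logger.exception("stage 'rbed' failed")
        raise

    # Jensen-direction note (logged, not enforced): RBED is concave in
    # dose, so a region's mean RBED should not exceed the RBED of its
    # mean dose.
    try:
        breast_lab = phantom.label_by_name("breast")
        bmask = phantom.labels == breast_lab
        if bmask.any():
            conc_b = phantom.regions[breast_lab].concentration
            for name in scenario_names():
                if name == "conventional":
                    continue
                mean_rbed = float(rbed_grids[name][bmask].mean())
                rbed_of_mean = float(
                    rbed_from_concentration(
                        float(dose_doped[bmask].mean()), conc_b, get_scenario(name)
                    )
                )
                logger.info(
                    "breast Jensen check [%s]: mean RBED %.4f %s RBED(mean dose) %.4f",
                    name,
                    mean_rbed,
                    "<=" if mean_rbed <= rbed_of_mean else ">",
                    rbed_of_mean,
                )
    except KeyError:
        pass

    stage("statistics")
    unions = {"whole_tumour": targets} if len(targets) > 1 else {}
    dose_stats = {
        "doped": region_stats_table(dose_doped, phantom, unions),
        "undoped": region_stats_table(dose_undoped, phantom, unions),
    }
    rbed_stats = {
        name: region_stats_table(grid, phantom, unions)
        for name, grid in rbed_grids.items()
    }
    for lab, spec in phantom.regions.items():
        if lab == 0 or not (phantom.labels == lab).any():
            continue
        cumulative_histogram(dose_doped, phantom, lab).to_csv(
            out / f"dvh_{spec.name}.csv"
        )
        for name, grid in rbed_grids.items():
            cumulative_histogram(grid, phantom, lab).to_csv(
                out / f"rvh_{name}_{spec.name}.csv"
            )

    eq_exposure = {}
    tmask = phantom.mask(targets)
    conc = np.zeros(phantom.shape)
    for lab in targets:
        conc[phantom.labels == lab] = phantom.regions[lab].concentration
    for name in scenario_names():
        if name == "conventional":
            continue
        eq_exposure[name] = equivalent_exposure_scaling(
            dose_doped[tmask], conc[tmask], get_scenario(name)
        )

    named_diff = {phantom.regions[lab].name: d for lab, d in diff.items()}
    report = RunReport(
        regions=[s.name for s in phantom.regions.values() if s.label != 0],
        dose_stats=dose_stats,
        rbed_stats=rbed_stats,
        dose_difference=named_diff,
        calibration={
            "target_gy": config.fraction_dose_gy(),
            "factor_doped": f_doped,
            "factor_undoped": f_undoped,
        },
        equivalent_exposure=eq_exposure,
        provenance={
            "config_hash": config.config_hash(),
            "rbedplan_version": __version__,
            "seed": config.seed,
            "scenario": config.scenario,
        },
    )
    report.to_json(out / "report.json")
    stage("done")
    return report


def compare_runs(report_a: RunReport, report_b: RunReport) -> dict:
    """Per-region relative differences of dose and RBED statistics."""
    if report_a.regions != report_b.regions:
        raise ValueError("reports cover different region tables")

    def rel(a: float, b: float) -> float:
        return abs(a - b) / abs(a) if a != 0 else abs(b - a)

    out: dict = {"dose": {}, "rbed": {}}
    for arm in report_a.dose_stats:
        out["dose"][arm] = {
            reg: {k: rel(va[k], vb[k]) for k in va}
            for reg, (va, vb) in _paired(report_a.dose_stats[arm], report_b.dose_stats[arm])
        }
    for scen in report_a.rbed_stats:
        out["rbed"][scen] = {
            reg: {k: rel(va[k], vb[k]) for k in va}
            for reg, (va, vb) in _paired(report_a.rbed_stats[scen], report_b.rbed_stats[scen])
        }
    return out


def _paired(a: dict, b: dict):
    for reg in a:
        if reg in b:
            yield reg, (a[reg], b[reg])


# -- desk-scale fixtures --------------------------------------------------

FIXTURE_KINDS = ("slab", "sphere-in-box", "mini-default")


def generate_fixture(kind: str, outdir: str | Path, **params) -> Path:
    """Write a small phantom + plan config usable by every stage.

    Kinds: ``slab`` (homogeneous water box, one beam), ``sphere-in-box``
    (two-compartment doped sphere in a breast-tissue cube, concentrations
    25/250/500 μg/ml), ``mini-default`` (the default anatomy scaled by
    0.5 on a ≤ 64³ grid). Deterministic given identical parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "slab":
        size = params.get("size_mm", 60.0)
        spacing = params.get("spacing_mm", 2.0)
        half = size / 2
        labels, origin = voxelize([], spacing, [[-half, half]] * 3)
        labels[:] = 1
        # Central in-beam core: the calibration region (the slab corners
        # receive only scatter tails, so a whole-slab minimum is not a
        # usable prescription point).
        core = ShapePrimitive(
            "sphere", (0.0, 0.0, 0.0), {"radius": 8.0}, label=2, priority=2
        )
        xs = [origin[i] + (np.arange(labels.shape[i]) + 0.5) * spacing for i in range(3)]
        labels[core.contains(*xs)] = 2
        phantom = VoxelPhantom(
            labels,
            (spacing,) * 3,
            origin,
            {
                0: RegionSpec(0, "background", "vacuum", 0.0),
                1: RegionSpec(1, "water_slab", "water", 0.0),
                2: RegionSpec(2, "core", "water", 0.0),
            },
        )
        plan_cfg = {
            "phantom_path": str(outdir / "phantom.nii.gz"),
            "beam": {"isocentre": [0.0, 0.0, 0.0], "angle_deg": 0.0, "diameter_mm": 30.0},
            "target_regions": ["core"],
        }
    elif kind == "sphere-in-box":
        size = params.get("size_mm", 40.0)
        spacing = params.get("spacing_mm", 1.0)
        half = size / 2
        shapes = [
            ShapePrimitive(
                "spherical-shell",
                (0.0, 0.0, 0.0),
                {"outer_radius": 10.0, "inner_radius": 8.0},
                label=9,
                priority=2,
            ),
            ShapePrimitive("sphere", (0.0, 0.0, 0.0), {"radius": 8.0}, label=8, priority=3),
        ]
        labels, origin = voxelize(shapes, spacing, [[-half, half]] * 3, background_label=7)
        phantom = VoxelPhantom(
            labels,
            (spacing,) * 3,
            origin,
            {
                7: RegionSpec(7, "breast", "breast_tissue", 25.0),
                8: RegionSpec(8, "tumour_inner", "breast_tissue", 250.0),
                9: RegionSpec(9, "tumour_wall", "breast_tissue", 500.0),
            },
        )
        plan_cfg = {
            "phantom_path": str(outdir / "phantom.nii.gz"),
            "beam": {"isocentre": [0.0, 0.0, 0.0], "angle_deg": 20.0},
            "target_regions": ["tumour_inner", "tumour_wall"],
        }
    elif kind == "mini-default":
        scale = params.get("scale", 0.5)
        spacing = params.get("spacing_mm", 2.5)
        cfg = _scaled_default_config(scale, spacing)
        phantom = build_default_phantom(cfg)
        plan_cfg = {
            "phantom_path": str(outdir / "phantom.nii.gz"),
            "beam": {
                "isocentre": [float(v) for v in tumour_centre(cfg)],
                "diameter_mm": 30.0 * scale,
            },
            "target_regions": ["tumour_inner", "tumour_wall"],
        }
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")

    export_phantom(phantom, outdir / "phantom.nii.gz")
    plan_path = outdir / "plan.yaml"
    plan_cfg["output_dir"] = str(outdir / "run")
    plan_path.write_text(yaml.safe_dump(plan_cfg, sort_keys=True))
    return plan_path


def _scale_lengths(obj, scale: float):
    if isinstance(obj, dict):
        return {k: v if k in ("count", "n_vertebrae") else _scale_lengths(v, scale) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_scale_lengths(v, scale) for v in obj]
    if isinstance(obj, (int, float)):
        return obj * scale
    return obj


def _scaled_default_config(scale: float, spacing: float) -> dict:
    cfg = _merge(DEFAULT_CONFIG, {})
    angles = {
        ("heart", "skew_deg"): cfg["heart"]["skew_deg"],
        ("breast", "angle_deg"): cfg["breast"]["angle_deg"],
    }
    cfg = _scale_lengths(cfg, scale)
    for (sec, key), val in angles.items():
        cfg[sec][key] = val
    cfg["spacing_mm"] = spacing
    return cfg
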