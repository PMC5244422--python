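"""End-to-end scenario orchestration and the comparative report.

Three named scenarios mirror the clinical design: ``normal`` (dilated
arterial opening, low-resistance waveform), ``iugr`` (undilated opening,
high-resistance waveform) and ``iugr_pe`` (undilated opening, notched
waveform). Only the opening type and the inlet waveform differ between the
scenarios on matched grids -- everything else (fluid, villous packing seeds,
solver settings) is shared, so cross-scenario ratios isolate the effect of
spiral-artery remodeling failure.

Waveform calibration: peak-systolic velocity and shape are fixed per profile
(similar systolic peaks across scenarios); the end-diastolic level is solved
in closed form so that the cycle-mean spiral-artery flow equals the study
conditions 0.031 / 0.027 / 0.017 ml/s for normal / IUGR / IUGR-PE.

The first heart cycle is a washout from rest; metrics are evaluated on
snapshots of the final cycle only. Reports carry the source study's headline
factors purely as orientation annotations -- they describe a different
(histology-derived, 3-D) geometry and are never assertion targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import metrics as M
from .geometry import (
    GridSpec,
    MorphologicalStage,
    SpiralArterySpec,
    VillousSpec,
    build_stage,
    save_stage_vtk,
)
from .solver import FlowField, FluidProperties, SolveReport, SolverConfig, solve_unsteady
from .waveform import (
    FlowWaveform,
    VelocityWaveform,
    VesselGeometryConstants,
    WaveformParams,
    cycle_mean,
    flow_to_inlet_velocity,
    params_for_cycle_mean,
    partition_to_spiral_artery,
    synthesize_uterine_waveform,
    velocity_to_flow,
)

log = logging.getLogger(__name__)

SCENARIO_NAMES = ("normal", "iugr", "iugr_pe")

#: Per-scenario waveform profile and driving condition (cycle-mean spiral flow).
SCENARIO_PROFILES: dict[str, dict] = {
    "normal": {"psv": 60.0, "systolic_fraction": 0.35, "notch_depth": 0.0,
               "q_sa_mean_ml_s": 0.031},
    "iugr": {"psv": 65.0, "systolic_fraction": 0.30, "notch_depth": 0.0,
             "q_sa_mean_ml_s": 0.027},
    "iugr_pe": {"psv": 65.0, "systolic_fraction": 0.30, "notch_depth": 0.5,
                "q_sa_mean_ml_s": 0.017},
}

#: Reference factors printed by the source study (proprietary 3-D geometry);
#: reported alongside computed ratios for orientation only, never asserted.
REFERENCE_ANNOTATIONS = {
    "jet_peak_factor_iugr": "5x vs normal (source study, 3-D geometry)",
    "jet_peak_factor_iugr_pe": "4x vs normal (source study, 3-D geometry)",
    "dp_total_factor_iugr": "1.12x vs normal (source study)",
    "dp_total_factor_iugr_pe": "1.53x vs normal (source study)",
    "dp_opening_steepness_factor_iugr": "20x vs normal (source study)",
    "dp_opening_steepness_factor_iugr_pe": "14x vs normal (source study)",
    "ivs_pressure_factor_iugr": "2.16x vs normal (source study)",
    "ivs_pressure_factor_iugr_pe": "1.58x vs normal (source study)",
    "shunted_pct_iugr": "17.6% (source study)",
    "shunted_pct_iugr_pe": "13.7% (source study)",
}

#: Planar stage presets: (extent_x_um, extent_z_um, nx, nz).
#: 2400 um arterial (spiralized) zone + 2000 um proximal IVS.
STAGE_PRESETS = {
    "desk": (3000.0, 4400.0, 300, 440),     # 10 um voxels
    "coarse": (3000.0, 4400.0, 75, 110),    # 40 um voxels; minutes-scale runs
    "tiny": (3000.0, 4400.0, 40, 55),       # 75/80 um voxels; smoke runs
}


class ScenarioConfigError(ValueError):
    pass


class GridMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    preset: str = "coarse"
    period_s: float = 0.8
    n_cycles: int = 3
    waveform_dt_s: float = 1e-3
    ivs_height_um: float = 2000.0
    artery: SpiralArterySpec | None = None
    villi: VillousSpec = VillousSpec(target_porosity=0.5, rng_seed=12)
    vessels: VesselGeometryConstants = VesselGeometryConstants()
    fluid: FluidProperties = FluidProperties()
    solver: SolverConfig = field(default_factory=SolverConfig)
    n_store_per_cycle: int = 32
    stage_seed: int = 7
    write_vtk: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ScenarioConfigError(f"unknown scenario {self.name!r}")
        if self.preset not in STAGE_PRESETS:
            raise ScenarioConfigError(f"unknown preset {self.preset!r}")
        want = "dilated" if self.name == "normal" else "undilated"
        if self.artery is not None and self.artery.opening != want:
            raise ScenarioConfigError(
                f"scenario {self.name!r} requires a {want} opening, got "
                f"{self.artery.opening!r}"
            )
        if self.n_cycles < 2:
            raise ScenarioConfigError("n_cycles >= 2 (first cycle is washout)")

    def resolved_artery(self) -> SpiralArterySpec:
        if self.artery is not None:
            return self.artery
        opening = "dilated" if self.name == "normal" else "undilated"
        return SpiralArterySpec(opening=opening, rng_seed=self.stage_seed)


def scenario_stage(cfg: ScenarioConfig) -> MorphologicalStage:
    ex, ez, nx, nz = STAGE_PRESETS[cfg.preset]
    hy = ex / nx
    grid = GridSpec((ex, hy, ez), (nx, 1, nz))
    return build_stage(grid, cfg.resolved_artery(), cfg.villi,
                       ivs_height_um=cfg.ivs_height_um)


def scenario_waveforms(cfg: ScenarioConfig) -> tuple[VelocityWaveform, FlowWaveform]:
    """Uterine-artery velocity trace and the spiral-artery inlet flow."""
    prof = SCENARIO_PROFILES[cfg.name]
    area = np.pi * (cfg.vessels.d_au_mm / 2) ** 2
    # target uterine-artery mean velocity (cm/s): q_sa_mean * n/2 arteries,
    # ml/s -> mm^3/s (x1000), / area, mm/s -> cm/s (/10)
    target_mean = prof["q_sa_mean_ml_s"] * (cfg.vessels.n_spiral / 2) * 1000 / area / 10
    base = WaveformParams(
        psv=prof["psv"], edv=prof["psv"] / 2, period=cfg.period_s,
        systolic_fraction=prof["systolic_fraction"], notch_depth=prof["notch_depth"],
        n_cycles=cfg.n_cycles, dt=cfg.waveform_dt_s,
    )
    params = params_for_cycle_mean(target_mean, base)
    v_au = synthesize_uterine_waveform(params)
    q_au = velocity_to_flow(v_au, cfg.vessels.d_au_mm)
    q_sa = partition_to_spiral_artery(q_au, q_au, cfg.vessels.n_spiral)
    return v_au, q_sa


@dataclass
class ScenarioBundle:
    cfg: ScenarioConfig
    stage: MorphologicalStage
    fields: list[FlowField]          # final-cycle snapshots
    peak_field: FlowField
    report: SolveReport
    metrics: dict
    uterine_waveform: VelocityWaveform
    inlet_flow: FlowWaveform


def run_scenario(cfg: ScenarioConfig, outdir: str | Path | None = None) -> ScenarioBundle:
    """Build the stage, derive the inlet waveform, solve the pulsatile flow,
    and evaluate all headline metrics on the final heart cycle."""
    log.info("scenario %s: building stage (%s preset)", cfg.name, cfg.preset)
    stage = scenario_stage(cfg)
    v_au, q_sa = scenario_waveforms(cfg)
    T = cfg.period_s
    t_end = cfg.n_cycles * T
    store = list(np.linspace((cfg.n_cycles - 1) * T, t_end,
                             cfg.n_store_per_cycle + 1))[1:]
    scfg = replace(cfg.solver, t_end=t_end) if cfg.solver.t_end is None else cfg.solver
    log.info("scenario %s: solving %d cycles of %.2f s", cfg.name, cfg.n_cycles, T)
    # planar (slab) stages cannot carry the physical 3-D flux; they are driven
    # by the physical inlet *velocity* waveform. Full 3-D stages are driven by
    # the flow waveform (plug scaled so the face-integrated flux matches).
    if stage.two_d:
        inlet = flow_to_inlet_velocity(q_sa, cfg.vessels.d_inlet_mm)
    else:
        inlet = q_sa
    fields, report = solve_unsteady(stage, inlet, cfg.fluid, scfg, store_times=store)
    cycle_fields = [f for f in fields if f.t > (cfg.n_cycles - 1) * T - 1e-9]

    jet = M.jet_metrics(cycle_fields, stage)
    ivs = M._ivs_mask(stage)
    i_pk = int(np.argmax([f.cell_speed()[ivs].max() for f in cycle_fields]))
    peak = cycle_fields[i_pk]
    # headline shunt: particle paths released throughout the systolic filling
    # phase and advected through the stored cycle -- the erythrocyte's-eye
    # statistic. Frozen-field streamlines are kept as a diagnostic: on planar
    # solenoidal snapshots they are stream-function contours and cannot enter
    # closed vortices, so their shunt fraction is not meaningful in 2-D.
    fractions = M.systolic_shunt_fraction(
        cycle_fields, stage, cycle_start_s=(cfg.n_cycles - 1) * T, period_s=T,
        cfg=M.StreamlineConfig(n_seeds=201))
    streamlines = M.trace_streamlines(peak, stage)
    frozen_fracs = M.vortex_fraction(streamlines)
    wss = M.wall_shear_stress(peak, stage, cfg.fluid.mu)
    info = M._opening_info(stage)
    center = np.array(info["center_mm"])
    # the villous surfaces the entry jet strikes: first shell past the
    # obstacle-free clearance zone
    r_jet = (info["clearance_mm"] or 0.7) + 0.3
    near = np.linalg.norm(wss.positions_mm - center[None, :], axis=1) <= r_jet
    vill_near = (wss.region == "villous") & near
    wss_villous_jet_max = float(wss.tau_pa[vill_near].max()) if vill_near.any() else 0.0
    pdec = M.pressure_drop_decomposition(peak, stage)
    cons = M.conservation_summary(report, scfg.poisson_tol)
    p_ivs_mean = float(peak.p[ivs].mean()) / M.MMHG_PA
    recirc_peak = M.recirculation_fraction(peak, stage)

    row = {
        "scenario": cfg.name,
        "q_sa_cycle_mean_ml_s": cycle_mean(q_sa),
        "jet_peak_velocity_cm_s": jet.peak_velocity_cm_s,
        "jet_onset_time_s": (None if jet.onset_time_s is None
                             else jet.onset_time_s - (cfg.n_cycles - 1) * T),
        "jet_penetration_mm": jet.penetration_depth_mm,
        "shunted_pct": fractions["shunted_pct"],
        "reached_top_pct": fractions["reached_top_pct"],
        "stalled_pct": fractions["stalled_pct"],
        "shunted_pct_streamlines_frozen": frozen_fracs["shunted_pct"],
        "recirc_fraction_peak_pct": recirc_peak,
        "wss_villous_max_pa": wss.summary.get("villous", {}).get("max_pa", 0.0),
        "wss_villous_jet_region_max_pa": wss_villous_jet_max,
        "wss_villous_mean_pa": wss.summary.get("villous", {}).get("mean_pa", 0.0),
        "wss_artery_max_pa": wss.summary.get("artery", {}).get("max_pa", 0.0),
        "dp_total_mmhg": pdec.dp_total_mmhg,
        "dp_artery_mmhg": pdec.dp_artery_mmhg,
        "dp_opening_mmhg": pdec.dp_opening_mmhg,
        "dp_ivs_mmhg": pdec.dp_ivs_mmhg,
        "dp_opening_steepness_mmhg_per_mm": pdec.opening_steepness_mmhg_per_mm,
        "ivs_mean_pressure_mmhg": p_ivs_mean,
        "max_divergence": cons["max_divergence"],
        "max_flux_imbalance": cons["max_flux_imbalance"],
        "porosity": stage.provenance.get("realized_porosity"),
        "opening_diameter_um": stage.provenance.get("realized_opening_diameter_um"),
    }
    bundle = ScenarioBundle(cfg, stage, cycle_fields, peak, report, row, v_au, q_sa)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _metrics_csv_text(rows: list[dict]) -> str:
    cols = list(rows[0].keys())
    lines = [",".join(cols)]
    for r in rows:
        lines.append(",".join("" if r[c] is None else repr(r[c]) if isinstance(r[c], float)
                              else str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"


def _write_bundle(b: ScenarioBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "metrics.csv").write_text(_metrics_csv_text([b.metrics]))
    detail = {
        "config": _cfg_dict(b.cfg),
        "metrics": b.metrics,
        "solve_report": b.report.to_dict(),
        "stage_provenance": b.stage.provenance,
    }
    (outdir / "detail.json").write_text(json.dumps(detail, indent=2, default=float))
    with open(outdir / "run.log.jsonl", "w") as fh:
        for i, t in enumerate(b.report.t[:: max(1, len(b.report.t) // 200)]):
            fh.write(json.dumps({"t": t}) + "\n")
    if b.cfg.write_vtk:
        from .vtkio import write_streamlines, write_structured_points

        save_stage_vtk(b.stage, outdir / "stage.vtk")
        write_structured_points(
            outdir / "peak_field.vtk",
            spacing_mm=b.stage.grid.spacing_mm,
            cell_arrays={"pressure_pa": b.peak_field.p},
            vector_arrays={"velocity_mm_s": b.peak_field.cell_velocity()},
        )
        sl = M.trace_streamlines(b.peak_field, b.stage)
        write_streamlines(outdir / "streamlines.vtk", sl)
        M.isobar_export(b.peak_field, b.stage, outdir / "isobars.vtk")


def _cfg_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    d["artery"] = asdict(cfg.resolved_artery())
    return d


@dataclass
class ComparativeReport:
    rows: list[dict]
    ratios: dict
    ordering_checks: dict
    reference_annotations: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.rows, "ratios": self.ratios,
             "ordering_checks": self.ordering_checks,
             "reference_annotations": self.reference_annotations,
             "provenance": self.provenance},
            indent=2, default=float,
        )

    def to_markdown(self) -> str:
        cols = ["scenario", "jet_peak_velocity_cm_s", "shunted_pct",
                "wss_villous_max_pa", "dp_total_mmhg",
                "dp_opening_steepness_mmhg_per_mm", "ivs_mean_pressure_mmhg"]
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "---|" * len(cols)]
        for r in self.rows:
            lines.append("| " + " | ".join(
                f"{r[c]:.4g}" if isinstance(r[c], float) else str(r[c]) for c in cols) + " |")
        lines.append("")
        lines.append("Ratios vs normal: " + json.dumps(self.ratios, default=float))
        lines.append("")
        lines.append("Source-study orientation values (different geometry; not targets):")
        for k, v in self.reference_annotations.items():
            lines.append(f"- {k}: {v}")
        return "\n".join(lines)


def compare_scenarios(bundles: list[ScenarioBundle]) -> ComparativeReport:
    """Cross-scenario ratio table with normal as the denominator, plus the
    qualitative ordering checks (pathological >= normal where remodeling
    failure should raise the metric)."""
    if len(bundles) < 2:
        raise ValueError("need at least two scenario bundles to compare")
    shapes = {b.stage.grid.shape for b in bundles}
    spacings = {b.stage.grid.spacing_um for b in bundles}
    if len(shapes) > 1 or len(spacings) > 1:
        raise GridMismatchError(
            f"bundles are on mismatched grids: shapes={shapes}, spacings={spacings}; "
            "rerun the scenarios with a common preset"
        )
    ref_i = next((i for i, b in enumerate(bundles) if b.cfg.name == "normal"), 0)
    ref = bundles[ref_i]
    ratios: dict[str, dict] = {}
    checks: dict[str, dict] = {}
    for i, b in enumerate(bundles):
        if i == ref_i:
            continue
        key = b.cfg.name if b.cfg.name not in ratios else f"{b.cfg.name}_{i}"
        r, m = ref.metrics, b.metrics

        def ratio(key):
            denom = r[key]
            return m[key] / denom if denom not in (0, None) else None

        ratios[key] = {
            "jet_peak_velocity": ratio("jet_peak_velocity_cm_s"),
            "dp_total": ratio("dp_total_mmhg"),
            "dp_opening_steepness": ratio("dp_opening_steepness_mmhg_per_mm"),
            "ivs_mean_pressure": ratio("ivs_mean_pressure_mmhg"),
            "wss_villous_max": ratio("wss_villous_max_pa"),
            "wss_villous_jet_region_max": ratio("wss_villous_jet_region_max_pa"),
            "shunted_pct_minus_normal": m["shunted_pct"] - r["shunted_pct"],
        }
        checks[key] = {
            "jet_peak_ge_normal": m["jet_peak_velocity_cm_s"] >= r["jet_peak_velocity_cm_s"],
            "wss_villous_max_ge_normal": (
                m["wss_villous_jet_region_max_pa"] >= r["wss_villous_jet_region_max_pa"]
            ),
            "dp_opening_steeper_than_normal": (
                m["dp_opening_steepness_mmhg_per_mm"] >= r["dp_opening_steepness_mmhg_per_mm"]
            ),
        }
    return ComparativeReport(
        rows=[b.metrics for b in bundles],
        ratios=ratios,
        ordering_checks=checks,
        reference_annotations=dict(REFERENCE_ANNOTATIONS),
        provenance={
            "configs": {b.cfg.name: _cfg_dict(b.cfg) for b in bundles},
            "grid_shape": list(shapes)[0],
            "spacing_um": list(spacings)[0],
        },
    )


def run_all_scenarios(
    preset: str = "coarse",
    n_cycles: int = 2,
    outdir: str | Path | None = None,
    **overrides,
) -> tuple[list[ScenarioBundle], ComparativeReport]:
    """Convenience driver: the three scenarios on a matched grid + comparison."""
    bundles = []
    for name in SCENARIO_NAMES:
        cfg = ScenarioConfig(name=name, preset=preset, n_cycles=n_cycles, **overrides)
        sub = None if outdir is None else Path(outdir) / name
        bundles.append(run_scenario(cfg, sub))
    report = compare_scenarios(bundles)
    if outdir is not None:
        Path(outdir, "report.json").write_text(report.to_json())
        Path(outdir, "report.md").write_text(report.to_markdown())
        rows_csv = _metrics_csv_text([b.metrics for b in bundles])
        Path(outdir, "metrics.csv").write_text(rows_csv)
    return bundles, report
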