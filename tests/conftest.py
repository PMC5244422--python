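"""Shared fixtures: the three pulsatile scenario runs, the Poiseuille
benchmark solutions, and the critical-flow bisections are computed once per
session and shared across test modules."""

import numpy as np
import pytest

from ivs_hemoflow.geometry import (
    GridSpec,
    SpiralArterySpec,
    VillousSpec,
    build_stage,
    channel_stage_2d,
    straight_tube_stage,
)
from ivs_hemoflow.metrics import critical_flow_threshold
from ivs_hemoflow.pipeline import ScenarioConfig, run_scenario
from ivs_hemoflow.solver import FluidProperties, SolverConfig, solve_steady

COARSE_GRID = GridSpec((3000.0, 40.0, 4400.0), (75, 1, 110))
VILLI = VillousSpec(target_porosity=0.5, rng_seed=12)
FLUID = FluidProperties()


@pytest.fixture(scope="session")
def scenario_bundles():
    """The three named scenarios on the matched coarse planar grid, 2 cycles
    (first cycle washout, metrics on the second)."""
    return {
        name: run_scenario(ScenarioConfig(name=name, preset="coarse", n_cycles=2))
        for name in ("normal", "iugr", "iugr_pe")
    }


@pytest.fixture(scope="session")
def undilated_stage():
    return build_stage(COARSE_GRID, SpiralArterySpec(opening="undilated", rng_seed=7), VILLI)


@pytest.fixture(scope="session")
def dilated_stage():
    return build_stage(COARSE_GRID, SpiralArterySpec(opening="dilated", rng_seed=7), VILLI)


@pytest.fixture(scope="session")
def channel_solution():
    """Steady pressure-driven flow in a 20-cells-across planar channel at
    mean speed 10 mm/s (creeping regime; entrance length negligible)."""
    stage = channel_stage_2d(gap_mm=0.4, length_mm=1.2, n_across=20)
    q = 10.0 * 0.4 * stage.grid.spacing_mm[1] / 1000.0  # U * gap * slab depth, ml/s
    field, report = solve_steady(stage, q, FLUID, SolverConfig(steady_tol=1e-8))
    return stage, field, report


@pytest.fixture(scope="session")
def tube_solution():
    """Steady flow through a voxelized straight tube, R = 0.17 mm, L = 10 mm,
    Q = 0.031 ml/s, 14 voxels across the lumen (coarse axial spacing; the
    developed profile is axially smooth)."""
    stage = straight_tube_stage(radius_mm=0.17, length_mm=10.0, n_across=14, hz_mm=0.125)
    field, report = solve_steady(stage, 0.031, FLUID, SolverConfig(steady_tol=5e-7))
    return stage, field, report


@pytest.fixture(scope="session")
def qstar_results(undilated_stage, dilated_stage):
    out = {
        "undilated": critical_flow_threshold(undilated_stage, FLUID),
        "dilated": critical_flow_threshold(dilated_stage, FLUID),
    }
    out["undilated_refined"] = critical_flow_threshold(
        undilated_stage, FLUID, tol_ml_s=1e-3
    )
    return out
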