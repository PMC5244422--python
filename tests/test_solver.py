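"""Navier-Stokes solver verification: null forcing, Poiseuille channel,
Taylor-Green decay and temporal order, energy stability, Stokes linearity,
Picard mode, and the fused-kernel/numpy predictor agreement."""

import numpy as np
import pytest

from ivs_hemoflow.geometry import channel_stage_2d, closed_box_stage
from ivs_hemoflow.solver import (
    FluidProperties,
    MACSolver,
    SolveReport,
    SolverConfig,
    SolverError,
    solve_steady,
    solve_unsteady,
    taylor_green_step_error,
)
from ivs_hemoflow.waveform import VelocityWaveform, WaveformParams, synthesize_uterine_waveform

FLUID = FluidProperties()


def test_fluid_properties_units():
    assert FLUID.nu == pytest.approx(6e-3 / 1.055e-3)
    with pytest.raises(ValueError):
        FluidProperties(mu=-1.0)


def test_null_forcing_stays_at_rest():
    stage = channel_stage_2d(gap_mm=0.4, length_mm=0.8, n_across=10)
    t = np.arange(100) * 1e-3
    zero = VelocityWaveform(t, np.zeros_like(t), period=0.1)
    fields, report = solve_unsteady(stage, zero, FLUID, SolverConfig(t_end=0.005))
    f = fields[-1]
    assert np.all(f.u == 0) and np.all(f.w == 0)
    assert np.all(f.p == 0)


def test_channel_profile_matches_poiseuille(channel_solution):
    """Developed profile within 3% Linf of w(x) = (3/2) U (1 - (x/h)^2)."""
    stage, field, report = channel_solution
    assert report.converged
    nx, ny, nz = stage.grid.shape
    k = int(0.8 * nz)
    prof = field.w[1:-1, 0, k]
    xs = stage.centers_mm(0)[1:-1]
    gap, x0 = 0.4, stage.grid.spacing_mm[0]
    U = prof.mean()
    exact = 1.5 * U * (1 - ((xs - (x0 + gap / 2)) / (gap / 2)) ** 2)
    assert np.abs(prof - exact).max() / np.abs(exact).max() < 0.03


def test_channel_spatial_convergence_under_refinement():
    """Linf profile error decreases with resolution (order >= 1 on plane walls)."""
    errs = []
    for n_across in (10, 20):
        stage = channel_stage_2d(gap_mm=0.4, length_mm=0.8, n_across=n_across)
        q = 10.0 * 0.4 * stage.grid.spacing_mm[1] / 1000.0
        field, _ = solve_steady(stage, q, FLUID, SolverConfig(steady_tol=1e-8))
        nz = stage.grid.shape[2]
        prof = field.w[1:-1, 0, int(0.8 * nz)]
        xs = stage.centers_mm(0)[1:-1]
        gap, x0 = 0.4, stage.grid.spacing_mm[0]
        U = prof.mean()
        exact = 1.5 * U * (1 - ((xs - (x0 + gap / 2)) / (gap / 2)) ** 2)
        errs.append(np.abs(prof - exact).max() / np.abs(exact).max())
    assert errs[1] < errs[0]
    assert np.log2(errs[0] / errs[1]) >= 1.0


def test_mass_conservation_every_step(channel_solution):
    _, _, report = channel_solution
    assert max(report.max_div) < 1e-7
    assert report.flux_imbalance().max() < 1e-3


def test_taylor_green_energy_decay_within_2pct():
    r = taylor_green_step_error(n=64, nu=0.01, dt=2e-3)
    assert r["energy_rel_error"] < 0.02


def test_taylor_green_temporal_order_at_least_first():
    """Self-convergence against a small-dt reference on the same grid."""
    ref = taylor_green_step_error(n=48, nu=0.01, dt=1.25e-4)
    errs = []
    for dt in (4e-3, 2e-3, 1e-3):
        r = taylor_green_step_error(n=48, nu=0.01, dt=dt)
        errs.append(float(np.sqrt(((r["u"] - ref["u"]) ** 2).mean()
                                  + ((r["v"] - ref["v"]) ** 2).mean())))
    orders = [np.log2(a / b) for a, b in zip(errs, errs[1:])]
    assert min(orders) >= 1.0


def test_energy_decays_with_zero_inflow():
    """Closed cavity, initial swirl: kinetic energy is non-increasing."""
    stage = closed_box_stage(n=24, size_mm=1.0)
    solver = MACSolver(stage, FLUID, SolverConfig())
    state = solver.zero_state()
    xs = np.arange(25) / 24
    state.u[:, 0, :] = 10 * np.sin(np.pi * xs)[:, None] * np.cos(
        np.pi * (np.arange(24) + 0.5) / 24)[None, :]
    state.w[:, 0, :] = -10 * np.cos(np.pi * (np.arange(24) + 0.5) / 24)[:, None] * np.sin(
        np.pi * np.arange(25) / 24)[None, :]
    report = SolveReport()
    ke = []
    for _ in range(60):
        dt_a, dt_v = solver.stable_dt(state.u, state.v, state.w)
        state = solver.step(state, min(1e-4, dt_a, dt_v), 0.0, report)
        ke.append(float((state.u**2).sum() + (state.w**2).sum()))
    assert all(b <= a * (1 + 1e-12) for a, b in zip(ke, ke[1:]))


def test_stokes_linearity_doubling_flux_doubles_pressure_drop():
    stage = channel_stage_2d(gap_mm=0.4, length_mm=0.8, n_across=10)
    cfg = SolverConfig(steady_tol=1e-9, advection_scheme="none")
    dp = []
    for q in (4e-5, 8e-5):
        f, _ = solve_steady(stage, q, FLUID, cfg)
        dp.append(f.p[:, 0, 0][stage.labels[:, 0, 0] == 1].mean())
    assert dp[1] == pytest.approx(2 * dp[0], rel=1e-4)


def test_picard_mode_reaches_nonlinear_tolerance():
    stage = channel_stage_2d(gap_mm=0.4, length_mm=0.8, n_across=10)
    cfg = SolverConfig(t_end=2e-3, advection_implicit=True, nonlinear_tol=1e-5)
    t = np.arange(100) * 1e-3
    inlet = VelocityWaveform(t, np.full_like(t, 1.0), period=0.1)  # 1 cm/s
    fields, report = solve_unsteady(stage, inlet, FLUID, cfg)
    assert max(report.picard_residual) <= 1e-5
    assert max(report.picard_iters) >= 1


def test_cfl_violation_without_substepping_is_rejected():
    stage = channel_stage_2d(gap_mm=0.4, length_mm=0.8, n_across=10)
    cfg = SolverConfig(dt=5e-2, adaptive_dt=False, t_end=1.0)
    t = np.arange(100) * 1e-2
    inlet = VelocityWaveform(t, np.full_like(t, 50.0), period=1.0)
    with pytest.raises(SolverError, match="CFL"):
        solve_unsteady(stage, inlet, FLUID, cfg)


def test_numba_kernel_matches_numpy_reference(scenario_bundles):
    """The fused predictor kernel reproduces the vectorised numpy predictor to
    round-off on a developed pulsatile scenario state."""
    b = scenario_bundles["iugr"]
    solver = MACSolver(b.stage, b.cfg.fluid, b.cfg.solver)
    f = b.peak_field
    for scheme in ("upwind1", "central2", "none"):
        fast = solver.predict(f.u, f.v, f.w, 1e-5, scheme, use_kernel=True)
        ref = solver.predict(f.u, f.v, f.w, 1e-5, scheme, use_kernel=False)
        scale = max(np.abs(f.w).max(), 1.0)
        for a, r in zip(fast, ref):
            assert np.abs(a - r).max() < 1e-10 * scale


def test_checkpoint_roundtrip_and_resume(tmp_path, channel_solution):
    from ivs_hemoflow.solver import load_checkpoint, save_checkpoint

    stage, field, report = channel_solution
    p = tmp_path / "chk.h5"
    save_checkpoint(field, p, report)
    back = load_checkpoint(p)
    assert back.t == field.t
    assert np.array_equal(back.w, field.w)
    # resuming a converged steady state converges immediately
    f2, rep2 = solve_steady(stage, 10.0 * 0.4 * stage.grid.spacing_mm[1] / 1000.0,
                            FLUID, SolverConfig(steady_tol=1e-8), initial=back)
    assert rep2.converged
    assert rep2.n_steps <= 50
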