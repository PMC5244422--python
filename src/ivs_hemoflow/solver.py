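"""Unsteady incompressible Navier-Stokes on the voxelized stage.

Discretization: staggered (MAC) finite volumes on the stage's voxel grid with
an incremental pressure-projection scheme. Velocity components live on cell
faces, pressure at cell centres. Solid voxels impose no-slip through the mask:
normal velocities on fluid-solid faces are held at zero and tangential
velocities are mirrored (ghost value -u) across the wall plane, giving
first-order stair-step boundary accuracy.

Boundary conditions follow the physical stage: prescribed plug inflow over the
inlet patch (scaled so the face-integrated flux matches the spiral-artery flow
waveform), no-slip on artery walls / villous surfaces / the basal bottom, slip
(zero normal velocity, zero tangential shear) on the lateral sides of the
intervillous space, and zero-traction outflow at the top (p = 0 with zero
normal gradient of tangential velocity).

Unit system is mm-g-s: 1 g.mm^-1.s^-2 == 1 Pa, so pressures are stored in Pa
without scale factors and converted to mmHg only at I/O (1 mmHg = 133.322 Pa).
Blood is Newtonian with mu = 6e-3 g/(mm.s) and rho = 1.055e-3 g/mm^3
(nu ~ 5.69 mm^2/s).

Time integration is explicit (upwind or central advection, explicit diffusion)
with adaptive sub-stepping under both the advective CFL limit and the
diffusive stability limit; an optional Picard mode iterates the advective term
to a nonlinear-residual tolerance (default 1e-5) for an implicit-in-advection
step. The pressure Poisson problem is solved with a cached sparse LU
factorization, so the discrete divergence of every accepted step is at the
level of the direct-solver round-off and global in/out flux balance is exact
to accumulator precision.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels as _K
from .geometry import Label, MorphologicalStage
from .waveform import FlowWaveform, VelocityWaveform

MMHG_PA = 133.322  # 1 mmHg in Pa (g.mm^-1.s^-2)


class SolverError(RuntimeError):
    """Solver failure (NaN, non-convergence, CFL violation without sub-stepping)."""

    def __init__(self, message: str, last_good: "FlowField | None" = None):
        super().__init__(message)
        self.last_good = last_good


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model in mm-g-s units.

    mu: dynamic viscosity (g.mm^-1.s^-1 = mPa.s in SI reading); rho: density
    (g/mm^3). ``printed_source_values`` keeps the source's verbatim constants
    ("kinematic viscosity of 6 mPas", rho = 1.055e-6 g/mm^3) for provenance;
    the working values below are the dimensionally consistent reading.
    """

    mu: float = 6e-3
    rho: float = 1.055e-3
    printed_source_values: tuple = (("kinematic_viscosity", "6 mPas"),
                                    ("density_g_mm3", 1.055e-6))

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (mm^2/s)."""
        return self.mu / self.rho


@dataclass
class SolverConfig:
    dt: float = 1e-4              # ceiling time step (s)
    t_end: float | None = None    # defaults to the inlet waveform span
    nonlinear_tol: float = 1e-5   # Picard residual tolerance (implicit advection mode)
    max_picard_iters: int = 25
    poisson_tol: float = 1e-7     # accepted max |div u| (1/s) per cell
    cfl_cap: float = 0.4
    visc_safety: float = 0.45     # fraction of the explicit diffusion limit
    advection_scheme: str = "upwind1"  # upwind1 | central2 | none
    advection_implicit: bool = False
    adaptive_dt: bool = True
    store_dt: float | None = None  # snapshot interval (s); None -> final only
    steady_tol: float = 1e-6       # relative velocity change per step at steadiness
    steady_patience: int = 10
    max_steps: int = 2_000_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("nonlinear_tol", "poisson_tol", "steady_tol"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.advection_scheme not in ("upwind1", "central2", "none"):
            raise ValueError("advection_scheme must be upwind1, central2 or none")


@dataclass
class FlowField:
    """Velocity (mm/s) on staggered faces and cell pressure (Pa) at time t (s)."""

    u: np.ndarray  # (nx+1, ny, nz)
    v: np.ndarray  # (nx, ny+1, nz)
    w: np.ndarray  # (nx, ny, nz+1)
    p: np.ndarray  # (nx, ny, nz)
    t: float

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(), self.w.copy(), self.p.copy(), self.t)

    def cell_velocity(self) -> np.ndarray:
        """Cell-centred velocity vectors, shape (nx, ny, nz, 3)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return np.stack([uc, vc, wc], axis=-1)

    def cell_speed(self) -> np.ndarray:
        return np.linalg.norm(self.cell_velocity(), axis=-1)

    def p_mmhg(self) -> np.ndarray:
        return self.p / MMHG_PA


@dataclass
class SolveReport:
    t: list = field(default_factory=list)
    dt: list = field(default_factory=list)
    max_div: list = field(default_factory=list)
    flux_in: list = field(default_factory=list)
    flux_out: list = field(default_factory=list)
    cfl: list = field(default_factory=list)
    picard_iters: list = field(default_factory=list)
    picard_residual: list = field(default_factory=list)
    wall_clock_s: float = 0.0
    n_steps: int = 0
    converged: bool | None = None
    convergence_certificate: dict = field(default_factory=dict)

    def flux_imbalance(self) -> np.ndarray:
        qin = np.asarray(self.flux_in)
        qout = np.asarray(self.flux_out)
        scale = np.maximum(np.abs(qin), 1e-12)
        return np.abs(qin - qout) / scale

    def to_dict(self) -> dict:
        return {
            "n_steps": self.n_steps,
            "wall_clock_s": self.wall_clock_s,
            "max_div_overall": float(np.max(self.max_div)) if self.max_div else 0.0,
            "max_flux_imbalance": float(np.max(self.flux_imbalance())) if self.t else 0.0,
            "max_cfl": float(np.max(self.cfl)) if self.cfl else 0.0,
            "converged": self.converged,
            "convergence_certificate": self.convergence_certificate,
        }


def _shift(F: np.ndarray, axis: int, d: int) -> np.ndarray:
    """Neighbour values along ``axis`` displaced by ``d``; out-of-range -> 0."""
    out = np.zeros_like(F)
    src = [slice(None)] * F.ndim
    dst = [slice(None)] * F.ndim
    if d == 1:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = F[tuple(src)]
    return out


class MACSolver:
    """Precomputed masks, ghost conventions and the cached Poisson factorization
    for one stage + fluid + config combination."""

    def __init__(self, stage: MorphologicalStage, fluid: FluidProperties, cfg: SolverConfig):
        self.stage = stage
        self.fluid = fluid
        self.cfg = cfg
        nx, ny, nz = stage.grid.shape
        self.shape = (nx, ny, nz)
        self.h = stage.grid.spacing_mm
        labels = stage.labels
        fl = stage.fluid_mask()
        self.fl = fl

        self.u_act = np.zeros((nx + 1, ny, nz), bool)
        self.u_act[1:nx] = fl[:-1] & fl[1:]
        self.v_act = np.zeros((nx, ny + 1, nz), bool)
        self.v_act[:, 1:ny] = fl[:, :-1] & fl[:, 1:]
        self.w_act = np.zeros((nx, ny, nz + 1), bool)
        self.w_act[:, :, 1:nz] = fl[:, :, :-1] & fl[:, :, 1:]

        self.inlet_faces = labels[:, :, 0] == int(Label.INLET)
        self.outlet_faces = labels[:, :, -1] == int(Label.TOP_OUTLET)
        hx, hy, hz = self.h
        self.inlet_area = float(self.inlet_faces.sum()) * hx * hy
        self._build_poisson()

        # tangential ghost signs: -1 mirrors no-slip walls; +1 at slip sides
        # (lateral domain boundaries) and the zero-gradient top.
        self._s = {}
        for comp, shape_c in (("u", self.u_act.shape), ("v", self.v_act.shape),
                              ("w", self.w_act.shape)):
            for ax in range(3):
                sp_ = -np.ones(shape_c)
                sm_ = -np.ones(shape_c)
                last = [slice(None)] * 3
                last[ax] = -1
                first = [slice(None)] * 3
                first[ax] = 0
                if (comp, ax) in (("u", 1), ("v", 0), ("w", 0), ("w", 1)):
                    sp_[tuple(last)] = 1.0   # lateral slip, both sides
                    sm_[tuple(first)] = 1.0
                if ax == 2 and comp in ("u", "v"):
                    sp_[tuple(last)] = 1.0   # top outflow: zero tangential gradient
                self._s[comp, ax, +1] = sp_
                self._s[comp, ax, -1] = sm_

    # -- pressure Poisson ---------------------------------------------------
    def _build_poisson(self) -> None:
        nx, ny, nz = self.shape
        hx, hy, hz = self.h
        fl = self.fl
        idx = -np.ones(self.shape, np.int64)
        n = int(fl.sum())
        if n == 0:
            raise SolverError("stage has no fluid cells")
        idx[fl] = np.arange(n)
        diag = np.zeros(n)
        rows, cols, vals = [], [], []
        for ax, h in ((0, hx), (1, hy), (2, hz)):
            t = 1.0 / h**2
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            both = fl[tuple(sl_lo)] & fl[tuple(sl_hi)]
            a = idx[tuple(sl_lo)][both]
            b = idx[tuple(sl_hi)][both]
            rows += [a, b]
            cols += [b, a]
            vals += [np.full(a.size, -t), np.full(a.size, -t)]
            np.add.at(diag, a, t)
            np.add.at(diag, b, t)
        out_ids = idx[:, :, -1][self.outlet_faces]
        self._has_outlet = out_ids.size > 0
        if self._has_outlet:
            np.add.at(diag, out_ids, 2.0 / hz**2)  # ghost p = -p across the top face
        else:
            diag[0] += 1.0  # closed domain: weakly pin the pressure level
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        )
        self._lu = spla.splu(A)
        self._idx = idx
        self._n_fluid = n

    def divergence(self, u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
        hx, hy, hz = self.h
        div = (
            (u[1:] - u[:-1]) / hx
            + (v[:, 1:] - v[:, :-1]) / hy
            + (w[:, :, 1:] - w[:, :, :-1]) / hz
        )
        div[~self.fl] = 0.0
        return div

    def project(self, u, v, w, dt):
        """Make the predictor field discretely divergence-free; returns p (Pa)."""
        rho = self.fluid.rho
        hx, hy, hz = self.h
        # assembled matrix is -L (positive definite); L p = (rho/dt) div u*
        rhs = -(rho / dt) * self.divergence(u, v, w)[self.fl]
        p = self._lu.solve(rhs)
        p3 = np.zeros(self.shape)
        p3[self.fl] = p
        gx = (p3[1:] - p3[:-1]) / hx
        u[1:-1] -= (dt / rho) * np.where(self.u_act[1:-1], gx, 0.0)
        gy = (p3[:, 1:] - p3[:, :-1]) / hy
        v[:, 1:-1] -= (dt / rho) * np.where(self.v_act[:, 1:-1], gy, 0.0)
        gz = (p3[:, :, 1:] - p3[:, :, :-1]) / hz
        w[:, :, 1:-1] -= (dt / rho) * np.where(self.w_act[:, :, 1:-1], gz, 0.0)
        if self._has_outlet:
            w[:, :, -1] += np.where(self.outlet_faces, (dt / rho) * 2.0 * p3[:, :, -1] / hz, 0.0)
        return p3

    # -- momentum predictor -------------------------------------------------
    def _tang(self, F, comp, ax, d, act):
        nb = _shift(F, ax, d)
        ex = _shift(act, ax, d)
        return np.where(ex, nb, self._s[comp, ax, d] * F)

    def _rhs_component(self, F, act, comp, norm_ax, adv_vels, scheme):
        """-(a.grad)F + nu lap F on the faces of one velocity component."""
        nu = self.fluid.nu
        h = self.h
        Fp_n = _shift(F, norm_ax, +1)
        Fm_n = _shift(F, norm_ax, -1)
        nbrs = {}
        for ax in range(3):
            if ax == norm_ax:
                nbrs[ax] = (Fm_n, Fp_n)
            else:
                nbrs[ax] = (self._tang(F, comp, ax, -1, act), self._tang(F, comp, ax, +1, act))
        lap = sum(
            (nbrs[ax][0] - 2 * F + nbrs[ax][1]) / h[ax] ** 2 for ax in range(3)
        )
        rhs = nu * lap
        if scheme != "none":
            adv = np.zeros_like(F)
            for ax in range(3):
                a = adv_vels[ax]
                Fm, Fp = nbrs[ax]
                if scheme == "upwind1":
                    dF = np.where(a > 0, (F - Fm) / h[ax], (Fp - F) / h[ax])
                else:  # central2
                    dF = (Fp - Fm) / (2 * h[ax])
                adv += a * dF
            rhs = rhs - adv
        return rhs

    def _adv_fields(self, u, v, w):
        nx, ny, nz = self.shape
        vb_u = np.zeros_like(u)
        vb_u[1:nx] = 0.25 * (v[: nx - 1, :-1] + v[: nx - 1, 1:] + v[1:nx, :-1] + v[1:nx, 1:])
        wb_u = np.zeros_like(u)
        wb_u[1:nx] = 0.25 * (
            w[: nx - 1, :, :-1] + w[: nx - 1, :, 1:] + w[1:nx, :, :-1] + w[1:nx, :, 1:]
        )
        ub_v = np.zeros_like(v)
        ub_v[:, 1:ny] = 0.25 * (
            u[:-1, : ny - 1] + u[1:, : ny - 1] + u[:-1, 1:ny] + u[1:, 1:ny]
        )
        wb_v = np.zeros_like(v)
        wb_v[:, 1:ny] = 0.25 * (
            w[:, : ny - 1, :-1] + w[:, : ny - 1, 1:] + w[:, 1:ny, :-1] + w[:, 1:ny, 1:]
        )
        ub_w = np.zeros_like(w)
        ub_w[:, :, 1:nz] = 0.25 * (
            u[:-1, :, : nz - 1] + u[1:, :, : nz - 1] + u[:-1, :, 1:nz] + u[1:, :, 1:nz]
        )
        vb_w = np.zeros_like(w)
        vb_w[:, :, 1:nz] = 0.25 * (
            v[:, :-1, : nz - 1] + v[:, 1:, : nz - 1] + v[:, :-1, 1:nz] + v[:, 1:, 1:nz]
        )
        return (vb_u, wb_u), (ub_v, wb_v), (ub_w, vb_w)

    def predict(self, u, v, w, dt, scheme, use_kernel: bool = True):
        """One explicit predictor evaluation; returns (u*, v*, w*) with BCs applied.

        The fused numba kernel and the vectorised numpy path implement the
        same discretization; the numpy path is the reference."""
        if use_kernel and _K.HAVE_NUMBA:
            us, vs, ws = u.copy(), v.copy(), w.copy()
            code = {"none": 0, "upwind1": 1, "central2": 2}[scheme]
            hx, hy, hz = self.h
            _K.predict_kernel(u, v, w, self.u_act, self.v_act, self.w_act,
                              hx, hy, hz, self.fluid.nu, dt, code, us, vs, ws)
            return us, vs, ws
        (vb_u, wb_u), (ub_v, wb_v), (ub_w, vb_w) = self._adv_fields(u, v, w)
        ru = self._rhs_component(u, self.u_act, "u", 0, (u, vb_u, wb_u), scheme)
        rv = self._rhs_component(v, self.v_act, "v", 1, (ub_v, v, wb_v), scheme)
        rw = self._rhs_component(w, self.w_act, "w", 2, (ub_w, vb_w, w), scheme)
        us = np.where(self.u_act, u + dt * ru, u)
        vs = np.where(self.v_act, v + dt * rv, v)
        ws = np.where(self.w_act, w + dt * rw, w)
        return us, vs, ws

    def apply_inflow_outflow(self, w_arr, w_in: float) -> None:
        w_arr[:, :, 0] = np.where(self.inlet_faces, w_in, 0.0)
        if self._has_outlet:
            w_arr[:, :, -1] = np.where(self.outlet_faces, w_arr[:, :, -2], 0.0)

    def stable_dt(self, u, v, w) -> tuple[float, float]:
        hx, hy, hz = self.h
        umax = max(np.abs(u).max(), 1e-12)
        vmax = max(np.abs(v).max(), 1e-12)
        wmax = max(np.abs(w).max(), 1e-12)
        dt_adv = self.cfg.cfl_cap * min(hx / umax, hy / vmax, hz / wmax)
        # collapsed axes (single cell, slip-slip) carry no diffusion
        nx, ny, nz = self.shape
        inv = sum(1.0 / h**2 for h, n in ((hx, nx), (hy, ny), (hz, nz)) if n > 1)
        dt_visc = self.cfg.visc_safety * 0.5 / (self.fluid.nu * inv)
        return dt_adv, dt_visc

    def step(self, state: FlowField, dt: float, w_in: float, report: SolveReport) -> FlowField:
        cfg = self.cfg
        u, v, w = state.u, state.v, state.w
        self.apply_inflow_outflow(w, w_in)
        scheme = cfg.advection_scheme
        us, vs, ws = self.predict(u, v, w, dt, scheme)
        iters, res = 1, 0.0
        if cfg.advection_implicit and scheme != "none":
            scale = max(np.abs(u).max(), np.abs(v).max(), np.abs(w).max(), 1e-12)
            for iters in range(2, cfg.max_picard_iters + 1):
                # re-evaluate the advective term at the latest iterate
                (vb_u, wb_u), (ub_v, wb_v), (ub_w, vb_w) = self._adv_fields(us, vs, ws)
                ru = self._rhs_component(us, self.u_act, "u", 0, (us, vb_u, wb_u), scheme)
                rv = self._rhs_component(vs, self.v_act, "v", 1, (ub_v, vs, wb_v), scheme)
                rw = self._rhs_component(ws, self.w_act, "w", 2, (ub_w, vb_w, ws), scheme)
                # diffusion stays evaluated at u^n for stability: subtract its
                # double-count by rebuilding from u^n advected with iterate
                nu_lap_u = self._rhs_component(u, self.u_act, "u", 0, (u, u, u), "none")
                nu_lap_v = self._rhs_component(v, self.v_act, "v", 1, (v, v, v), "none")
                nu_lap_w = self._rhs_component(w, self.w_act, "w", 2, (w, w, w), "none")
                un = np.where(self.u_act, u + dt * (ru - self._rhs_component(us, self.u_act, "u", 0, (us, us, us), "none") + nu_lap_u), u)
                vn = np.where(self.v_act, v + dt * (rv - self._rhs_component(vs, self.v_act, "v", 1, (vs, vs, vs), "none") + nu_lap_v), v)
                wn = np.where(self.w_act, w + dt * (rw - self._rhs_component(ws, self.w_act, "w", 2, (ws, ws, ws), "none") + nu_lap_w), w)
                res = max(
                    np.abs(un - us).max(), np.abs(vn - vs).max(), np.abs(wn - ws).max()
                ) / scale
                us, vs, ws = un, vn, wn
                if res <= cfg.nonlinear_tol:
                    break
            else:
                raise SolverError(
                    f"Picard iteration did not reach nonlinear_tol={cfg.nonlinear_tol} "
                    f"(residual {res:.3e})", last_good=state
                )
        self.apply_inflow_outflow(ws, w_in)
        p3 = self.project(us, vs, ws, dt)
        if not (np.isfinite(us).all() and np.isfinite(vs).all() and np.isfinite(ws).all()):
            raise SolverError("NaN/Inf detected in velocity field", last_good=state)
        new = FlowField(us, vs, ws, p3, state.t + dt)
        hx, hy, hz = self.h
        div = self.divergence(us, vs, ws)
        report.t.append(new.t)
        report.dt.append(dt)
        report.max_div.append(float(np.abs(div).max()))
        report.flux_in.append(float((ws[:, :, 0] * self.inlet_faces).sum() * hx * hy))
        report.flux_out.append(float((ws[:, :, -1] * self.outlet_faces).sum() * hx * hy))
        umax = max(np.abs(us).max() / hx, np.abs(vs).max() / hy, np.abs(ws).max() / hz)
        report.cfl.append(float(umax * dt))
        report.picard_iters.append(iters)
        report.picard_residual.append(res)
        report.n_steps += 1
        return new

    def zero_state(self) -> FlowField:
        nx, ny, nz = self.shape
        return FlowField(
            np.zeros((nx + 1, ny, nz)), np.zeros((nx, ny + 1, nz)),
            np.zeros((nx, ny, nz + 1)), np.zeros((nx, ny, nz)), 0.0,
        )


def _inlet_speed_fn(
    solver: MACSolver, inlet: VelocityWaveform | FlowWaveform | float
) -> Callable[[float], float]:
    """Plug inlet speed (mm/s) as a function of time.

    A FlowWaveform (ml/s) is divided by the voxel-realized inlet patch area so
    the face-integrated flux matches the waveform exactly; a VelocityWaveform
    (cm/s) is applied as-is; a float is a constant flux in ml/s.
    """
    area = solver.inlet_area
    if area <= 0:
        return lambda t: 0.0
    if isinstance(inlet, FlowWaveform):
        return lambda t: float(inlet.at(t)) * 1000.0 / area  # ml/s -> mm^3/s
    if isinstance(inlet, VelocityWaveform):
        return lambda t: float(inlet.at(t)) * 10.0  # cm/s -> mm/s
    q = float(inlet) * 1000.0
    return lambda t: q / area


def solve_unsteady(
    stage: MorphologicalStage,
    inlet: VelocityWaveform | FlowWaveform,
    fluid: FluidProperties = FluidProperties(),
    cfg: SolverConfig = SolverConfig(),
    initial: FlowField | None = None,
    store_times: Sequence[float] | None = None,
) -> tuple[list[FlowField], SolveReport]:
    """March the pulsatile flow problem from rest (or ``initial``) to t_end.

    Snapshots are stored at ``store_times`` (or every ``cfg.store_dt`` s), plus
    the final state. Every accepted step satisfies the divergence and flux
    balance contracts recorded in the report.
    """
    solver = MACSolver(stage, fluid, cfg)
    speed = _inlet_speed_fn(solver, inlet)
    t_end = cfg.t_end
    if t_end is None:
        if isinstance(inlet, (VelocityWaveform, FlowWaveform)):
            t_end = inlet.period * inlet.n_cycles
        else:
            raise ValueError("cfg.t_end required for constant inflow")
    state = initial.copy() if initial is not None else solver.zero_state()
    report = SolveReport()
    fields: list[FlowField] = []
    targets = sorted(store_times) if store_times is not None else None
    if targets is None and cfg.store_dt is not None:
        targets = list(np.arange(cfg.store_dt, t_end - 1e-12, cfg.store_dt))
    next_i = 0
    tic = time.perf_counter()
    while state.t < t_end - 1e-12:
        dt_adv, dt_visc = solver.stable_dt(state.u, state.v, state.w)
        dt = min(cfg.dt, dt_visc, dt_adv if cfg.adaptive_dt else np.inf)
        if not cfg.adaptive_dt and cfg.dt > dt_adv:
            raise SolverError(
                f"CFL violation: dt={cfg.dt:.3e} exceeds advective limit {dt_adv:.3e}; "
                "reduce dt or enable adaptive_dt", last_good=state,
            )
        if targets is not None and next_i < len(targets):
            dt = min(dt, targets[next_i] - state.t)
        dt = min(dt, t_end - state.t)
        if report.n_steps >= cfg.max_steps:
            raise SolverError("max_steps exceeded", last_good=state)
        state = solver.step(state, dt, speed(state.t + dt), report)
        if targets is not None and next_i < len(targets) and state.t >= targets[next_i] - 1e-12:
            fields.append(state.copy())
            next_i += 1
    fields.append(state.copy())
    report.wall_clock_s = time.perf_counter() - tic
    return fields, report


def solve_steady(
    stage: MorphologicalStage,
    q_const_ml_s: float,
    fluid: FluidProperties = FluidProperties(),
    cfg: SolverConfig = SolverConfig(),
    initial: FlowField | None = None,
) -> tuple[FlowField, SolveReport]:
    """Time-march at constant inlet flux until the velocity field is stationary.

    Steadiness: relative max velocity change per step below ``cfg.steady_tol``
    for ``cfg.steady_patience`` consecutive steps. On hitting ``max_steps``
    the report carries a limit-cycle diagnosis (kinetic-energy oscillation
    amplitude over the trailing window) instead of failing silently.
    """
    solver = MACSolver(stage, fluid, cfg)
    speed = _inlet_speed_fn(solver, q_const_ml_s)
    state = initial.copy() if initial is not None else solver.zero_state()
    report = SolveReport()
    calm = 0
    ke_window: list[float] = []
    tic = time.perf_counter()
    while True:
        dt_adv, dt_visc = solver.stable_dt(state.u, state.v, state.w)
        dt = min(cfg.dt, dt_visc, dt_adv if cfg.adaptive_dt else np.inf)
        prev_u, prev_v, prev_w = state.u.copy(), state.v.copy(), state.w.copy()
        state = solver.step(state, dt, speed(0.0), report)
        scale = max(np.abs(state.u).max(), np.abs(state.v).max(),
                    np.abs(state.w).max(), 1e-12)
        change = max(
            np.abs(state.u - prev_u).max(),
            np.abs(state.v - prev_v).max(),
            np.abs(state.w - prev_w).max(),
        ) / scale
        ke = float((state.u**2).sum() + (state.v**2).sum() + (state.w**2).sum())
        ke_window.append(ke)
        if len(ke_window) > 200:
            ke_window.pop(0)
        calm = calm + 1 if change < cfg.steady_tol else 0
        if calm >= cfg.steady_patience:
            report.converged = True
            report.convergence_certificate = {
                "final_relative_change": change, "steps": report.n_steps,
            }
            break
        if report.n_steps >= cfg.max_steps:
            amp = (max(ke_window) - min(ke_window)) / max(max(ke_window), 1e-30)
            report.converged = False
            report.convergence_certificate = {
                "final_relative_change": change,
                "steps": report.n_steps,
                "limit_cycle_ke_amplitude": amp,
                "diagnosis": (
                    "oscillatory flow (limit cycle)" if amp > 10 * cfg.steady_tol
                    else "slow transient; raise max_steps"
                ),
            }
            break
    report.wall_clock_s = time.perf_counter() - tic
    return state, report


def save_checkpoint(field: FlowField, path, report: SolveReport | None = None) -> None:
    """HDF5 checkpoint of one flow state; resume by passing the loaded field
    as ``initial`` to :func:`solve_unsteady` / :func:`solve_steady`."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("u", "v", "w", "p"):
            f.create_dataset(name, data=getattr(field, name), compression="gzip")
        f.attrs["t"] = field.t
        if report is not None:
            f.attrs["n_steps"] = report.n_steps


def load_checkpoint(path) -> FlowField:
    import h5py

    with h5py.File(path, "r") as f:
        return FlowField(f["u"][()], f["v"][()], f["w"][()], f["p"][()],
                         float(f.attrs["t"]))


# ---------------------------------------------------------------------------
# Periodic-box verification harness (Taylor-Green vortex)

def taylor_green_step_error(
    n: int = 64,
    nu: float = 0.01,
    dt: float = 2e-3,
    t_end: float | None = None,
    scheme: str = "central2",
    amplitude: float = 1.0,
) -> dict:
    """Integrate the 2-D Taylor-Green vortex in a periodic unit box.

    Initial condition u = sin(kx) cos(ky), v = -cos(kx) sin(ky) with k = 2*pi;
    the exact solution decays self-similarly with kinetic energy
    E(t) = E(0) exp(-4 nu k^2 t). Returns the measured/analytic energy ratio
    error at t_end (default: one energy-decay time 1/(4 nu k^2)) and the final
    fields for convergence studies. Kinematic formulation (rho = 1).
    """
    k = 2 * np.pi
    if t_end is None:
        t_end = 1.0 / (4 * nu * k**2)
    h = 1.0 / n
    xf = np.arange(n) * h          # u faces at x_i, cell centres y_j+1/2
    yc = (np.arange(n) + 0.5) * h
    X_u, Y_u = np.meshgrid(xf, yc, indexing="ij")
    X_v, Y_v = np.meshgrid(yc, xf, indexing="ij")
    u = amplitude * np.sin(k * X_u) * np.cos(k * Y_u)
    v = -amplitude * np.cos(k * X_v) * np.sin(k * Y_v)

    kx = np.fft.fftfreq(n, d=h) * 2 * np.pi
    eig = (2 * np.cos(kx[:, None] * h) - 2) / h**2 + (2 * np.cos(kx[None, :] * h) - 2) / h**2
    eig[0, 0] = 1.0

    def project(u, v, dt):
        div = (np.roll(u, -1, 0) - u) / h + (np.roll(v, -1, 1) - v) / h
        rhs = np.fft.fft2(div / dt)
        phat = rhs / eig
        phat[0, 0] = 0.0
        p = np.real(np.fft.ifft2(phat))
        u -= dt * (p - np.roll(p, 1, 0)) / h
        v -= dt * (p - np.roll(p, 1, 1)) / h
        return u, v

    def rhs(u, v):
        lap_u = (np.roll(u, -1, 0) + np.roll(u, 1, 0) + np.roll(u, -1, 1) + np.roll(u, 1, 1) - 4 * u) / h**2
        lap_v = (np.roll(v, -1, 0) + np.roll(v, 1, 0) + np.roll(v, -1, 1) + np.roll(v, 1, 1) - 4 * v) / h**2
        vb = 0.25 * (v + np.roll(v, -1, 1) + np.roll(v, 1, 0) + np.roll(np.roll(v, 1, 0), -1, 1))
        ub = 0.25 * (u + np.roll(u, -1, 0) + np.roll(u, 1, 1) + np.roll(np.roll(u, 1, 1), -1, 0))
        if scheme == "central2":
            dudx = (np.roll(u, -1, 0) - np.roll(u, 1, 0)) / (2 * h)
            dudy = (np.roll(u, -1, 1) - np.roll(u, 1, 1)) / (2 * h)
            dvdx = (np.roll(v, -1, 0) - np.roll(v, 1, 0)) / (2 * h)
            dvdy = (np.roll(v, -1, 1) - np.roll(v, 1, 1)) / (2 * h)
        else:  # upwind1
            dudx = np.where(u > 0, (u - np.roll(u, 1, 0)) / h, (np.roll(u, -1, 0) - u) / h)
            dudy = np.where(vb > 0, (u - np.roll(u, 1, 1)) / h, (np.roll(u, -1, 1) - u) / h)
            dvdx = np.where(ub > 0, (v - np.roll(v, 1, 0)) / h, (np.roll(v, -1, 0) - v) / h)
            dvdy = np.where(v > 0, (v - np.roll(v, 1, 1)) / h, (np.roll(v, -1, 1) - v) / h)
        au = u * dudx + vb * dudy
        av = ub * dvdx + v * dvdy
        return nu * lap_u - au, nu * lap_v - av

    t = 0.0
    e0 = float((u**2).sum() + (v**2).sum())
    while t < t_end - 1e-14:
        step = min(dt, t_end - t)
        ru, rv = rhs(u, v)
        u = u + step * ru
        v = v + step * rv
        u, v = project(u, v, step)
        t += step
    e = float((u**2).sum() + (v**2).sum())
    ratio = e / e0
    exact = np.exp(-4 * nu * k**2 * t_end)
    decay = np.exp(-2 * nu * k**2 * t_end)
    ue = amplitude * np.sin(k * X_u) * np.cos(k * Y_u) * decay
    ve = -amplitude * np.cos(k * X_v) * np.sin(k * Y_v) * decay
    l2 = float(np.sqrt(((u - ue) ** 2 + (v - ve) ** 2).mean()))
    return {
        "energy_ratio": ratio,
        "energy_ratio_exact": float(exact),
        "energy_rel_error": abs(ratio - exact) / exact,
        "velocity_l2_error": l2,
        "t_end": t_end,
        "u": u,
        "v": v,
    }
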