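"""Hemodynamic metrics on solved fields: wall shear stress, segmented pressure
drops, streamline classification and vortex-shunt fraction, jet metrics,
iso-pressure contours, and the critical-flow threshold.

Wall shear stress is evaluated per wall-adjacent face. Where the stage
carries analytic wall primitives (all synthetic stages do), the tangential
velocity gradient is measured along the true surface normal with a
second-order one-sided two-probe formula (samples at delta and 2*delta from
the surface, delta = 2 voxel spacings by default): this removes the ~4/pi
staircase bias of naive per-face estimates. Faces are weighted by their
Cauchy-projected area |n_face . n_true| in region summaries. Without
primitives a first-order staircase estimate (mu * |u_t| / (h/2)) is used.

Streamlines integrate dx/ds = u/|u| (4th-order Runge-Kutta on the frozen
field) from seeds covering the arterial opening cross-section, and are
classified reached_top / recirculated / stalled. Unsteady pathlines through a
stored snapshot series are available as an alternative tracer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from .geometry import Label, MorphologicalStage
from .solver import (
    MMHG_PA,
    FlowField,
    FluidProperties,
    SolveReport,
    SolverConfig,
    solve_steady,
)

JET_ONSET_THRESHOLD_CM_S = 70.0  # default jet-onset speed threshold (configurable)


class MetricsError(ValueError):
    pass


class BracketError(RuntimeError):
    """The criterion is already true at the lower bracket end; no valid bisection."""


# ---------------------------------------------------------------------------
# velocity interpolation on the staggered grid

def velocity_interpolator(f: FlowField, stage: MorphologicalStage):
    """Linear interpolation of the staggered velocity at arbitrary points (mm)."""
    hx, hy, hz = stage.grid.spacing_mm

    def interp(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        cu = np.vstack([x / hx, y / hy - 0.5, z / hz - 0.5])
        cv = np.vstack([x / hx - 0.5, y / hy, z / hz - 0.5])
        cw = np.vstack([x / hx - 0.5, y / hy - 0.5, z / hz])
        return np.stack(
            [
                map_coordinates(f.u, cu, order=1, mode="nearest"),
                map_coordinates(f.v, cv, order=1, mode="nearest"),
                map_coordinates(f.w, cw, order=1, mode="nearest"),
            ],
            axis=1,
        )

    return interp


# ---------------------------------------------------------------------------
# stage bookkeeping shared by several metrics

def _opening_info(stage: MorphologicalStage) -> dict:
    """Mouth plane height, centre and realized diameter, from labels/provenance."""
    labels = stage.labels
    hx, hy, hz = stage.grid.spacing_mm
    ks = np.flatnonzero((labels == int(Label.OPENING)).any(axis=(0, 1)))
    if ks.size == 0:
        raise MetricsError("stage has no OPENING region")
    k_top = int(ks.max())
    k_lo = int(ks.min())
    mouth = np.isin(labels[:, :, k_top], (int(Label.OPENING),))
    ii, jj = np.nonzero(mouth)
    cx = (ii.mean() + 0.5) * hx
    cy = (jj.mean() + 0.5) * hy
    prov = stage.provenance
    if "realized_opening_diameter_um" in prov:
        d_open = prov["realized_opening_diameter_um"] / 1000.0
    elif stage.two_d:
        d_open = mouth.sum() * hx
    else:
        d_open = 2 * math.sqrt(mouth.sum() * hx * hy / math.pi)
    # scenario-independent reference length for streamline budgets: the
    # arterial lumen diameter (the opening diameter varies 3-5x with dilation)
    ref_d = d_open
    if isinstance(prov.get("artery"), dict) and "lumen_diameter_um" in prov["artery"]:
        ref_d = prov["artery"]["lumen_diameter_um"] / 1000.0
    clearance = None
    if isinstance(prov.get("villi"), dict) and "clearance_radius_um" in prov["villi"]:
        clearance = prov["villi"]["clearance_radius_um"] / 1000.0
    return {
        "k_top": k_top,
        "k_lo": k_lo,
        "z_plane_mm": (k_top + 1) * hz,
        "center_mm": (cx, cy, (k_top + 1) * hz),
        "diameter_mm": d_open,
        "ref_diameter_mm": ref_d,
        "clearance_mm": clearance,
        "length_mm": (k_top - k_lo + 1) * hz,
    }


def _ivs_mask(stage: MorphologicalStage) -> np.ndarray:
    return np.isin(stage.labels, (int(Label.IVS_FLUID), int(Label.TOP_OUTLET)))


# ---------------------------------------------------------------------------
# wall shear stress

@dataclass
class WSSField:
    positions_mm: np.ndarray   # (n, 3) wall-face centres
    normals: np.ndarray        # (n, 3) outward-of-solid normals (into fluid)
    tau_pa: np.ndarray         # (n,) shear stress magnitude
    weights: np.ndarray        # (n,) Cauchy-projected area weights
    region: np.ndarray         # (n,) 'villous' | 'artery'
    summary: dict = field(default_factory=dict)


def wall_shear_stress(
    f: FlowField,
    stage: MorphologicalStage,
    mu: float | None = None,
    probe_factor: float = 2.0,
) -> WSSField:
    """Wall shear stress at every fluid face adjacent to solid voxels."""
    if f.p.shape != stage.grid.shape:
        raise MetricsError("field and stage are on different grids")
    if mu is None:
        mu = FluidProperties().mu
    labels = stage.labels
    fl = stage.fluid_mask()
    hx, hy, hz = stage.grid.spacing_mm
    h = (hx, hy, hz)
    xs = stage.centers_mm(0)
    ys = stage.centers_mm(1)
    zs = stage.centers_mm(2)
    interp = velocity_interpolator(f, stage)

    pos_l, nrm_l, tau_l, wt_l, reg_l = [], [], [], [], []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 0, 1), (0, 0, -1)]
    if not stage.two_d:
        offsets += [(0, 1, 0), (0, -1, 0)]
    have_prims = bool(stage.wall_primitives)
    cell_vel = f.cell_velocity()
    for off in offsets:
        ax = int(np.nonzero(off)[0][0])
        d = off[ax]
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if d == 1:
            src[ax] = slice(1, None)
            dst[ax] = slice(None, -1)
        else:
            src[ax] = slice(None, -1)
            dst[ax] = slice(1, None)
        nb_lab = np.full(labels.shape, -1, dtype=np.int16)
        nb_lab[tuple(dst)] = labels[tuple(src)]
        wall_face = fl & np.isin(nb_lab, (int(Label.WALL), int(Label.VILLOUS_SOLID)))
        if not wall_face.any():
            continue
        ii, jj, kk = np.nonzero(wall_face)
        centers = np.stack([xs[ii], ys[jj], zs[kk]], axis=1)
        face_pos = centers.copy()
        face_pos[:, ax] += d * h[ax] / 2.0
        region = np.where(nb_lab[ii, jj, kk] == int(Label.VILLOUS_SOLID), "villous", "artery")
        if have_prims:
            delta = probe_factor * h[ax]
            d_signed, n_true = stage.nearest_wall(face_pos, step_mm=0.25 * min(hx, hz))
            foot = face_pos - d_signed[:, None] * n_true
            p1 = foot + delta * n_true
            p2 = foot + 2 * delta * n_true
            u1 = interp(p1)
            u2 = interp(p2)
            g = (4 * u1 - u2) / (2 * delta)
            g_t = g - (np.sum(g * n_true, axis=1))[:, None] * n_true
            tau = mu * np.linalg.norm(g_t, axis=1)
            e_ax = np.zeros(3)
            e_ax[ax] = 1.0
            wts = np.abs(n_true @ e_ax)
        else:
            uc = cell_vel[ii, jj, kk]
            n_true = np.zeros((len(ii), 3))
            n_true[:, ax] = -d  # into fluid
            u_t = uc - (np.sum(uc * n_true, axis=1))[:, None] * n_true
            tau = mu * np.linalg.norm(u_t, axis=1) / (h[ax] / 2.0)
            wts = np.ones(len(ii))
        pos_l.append(face_pos)
        nrm_l.append(n_true)
        tau_l.append(tau)
        wt_l.append(wts)
        reg_l.append(region)

    if not pos_l:
        raise MetricsError("stage has no wall-adjacent fluid faces")
    positions = np.concatenate(pos_l)
    normals = np.concatenate(nrm_l)
    tau = np.concatenate(tau_l)
    wts = np.concatenate(wt_l)
    region = np.concatenate(reg_l)
    summary = {}
    for reg in ("villous", "artery"):
        m = region == reg
        if not m.any():
            continue
        wsum = wts[m].sum()
        summary[reg] = {
            "max_pa": float(tau[m].max()),
            "mean_pa": float((tau[m] * wts[m]).sum() / wsum),
            "p99_pa": float(np.percentile(tau[m], 99)),
            "n_faces": int(m.sum()),
        }
    return WSSField(positions, normals, tau, wts, region, summary)


# ---------------------------------------------------------------------------
# pressure decomposition

@dataclass
class PressureDecomposition:
    dp_artery_mmhg: float
    dp_opening_mmhg: float
    dp_ivs_mmhg: float
    dp_total_mmhg: float
    opening_steepness_mmhg_per_mm: float
    cut_planes_k: dict

    def __post_init__(self) -> None:
        resid = abs(self.dp_artery_mmhg + self.dp_opening_mmhg + self.dp_ivs_mmhg
                    - self.dp_total_mmhg)
        if resid > 1e-6:
            raise MetricsError(f"pressure decomposition not additive (residual {resid})")


def pressure_drop_decomposition(f: FlowField, stage: MorphologicalStage) -> PressureDecomposition:
    """Area-averaged pressures on three cut planes: artery inlet, opening
    entry, IVS entry; drops per segment telescope exactly to the total
    (reference p = 0 at the top outlet)."""
    if f.p.shape != stage.grid.shape:
        raise MetricsError("field and stage are on different grids")
    info = _opening_info(stage)
    labels = stage.labels
    artery_set = (int(Label.INLET), int(Label.ARTERY_LUMEN), int(Label.OPENING))

    def layer_mean(k: int, restrict_artery: bool) -> float:
        lay = labels[:, :, k]
        if restrict_artery:
            m = np.isin(lay, artery_set)
        else:
            m = np.isin(lay, [int(l) for l in
                              (Label.INLET, Label.ARTERY_LUMEN, Label.OPENING,
                               Label.IVS_FLUID, Label.TOP_OUTLET)])
        if not m.any():
            raise MetricsError(f"cut plane k={k} intersects solid-only cells")
        return float(f.p[:, :, k][m].mean())

    p_in = layer_mean(0, True)
    p_open = layer_mean(info["k_lo"], True)
    k_ivs = min(info["k_top"] + 1, stage.grid.shape[2] - 1)
    p_ivs = layer_mean(k_ivs, False)
    dp_a = (p_in - p_open) / MMHG_PA
    dp_o = (p_open - p_ivs) / MMHG_PA
    dp_i = p_ivs / MMHG_PA
    return PressureDecomposition(
        dp_artery_mmhg=dp_a,
        dp_opening_mmhg=dp_o,
        dp_ivs_mmhg=dp_i,
        dp_total_mmhg=dp_a + dp_o + dp_i,
        opening_steepness_mmhg_per_mm=dp_o / info["length_mm"],
        cut_planes_k={"inlet": 0, "opening": info["k_lo"], "ivs": k_ivs},
    )


# ---------------------------------------------------------------------------
# streamlines

@dataclass
class StreamlineConfig:
    n_seeds: int = 101
    eps_u: float = 1e-2          # mm/s; slower seeds/points count as stalled
    max_arc_diams: float = 50.0  # arc-length budget in lumen diameters
    confine_mm: float | None = None  # vortex-confinement radius; None -> the
    #                                  stage's obstacle-free clearance zone
    confine_diams: float = 3.0   # fallback (in lumen diameters) without provenance
    ds_factor: float = 0.5       # step as fraction of min spacing
    store_stride: int = 8


@dataclass
class StreamlineSet:
    seeds_mm: np.ndarray
    paths: list
    classes: np.ndarray  # 'reached_top' | 'recirculated' | 'stalled'
    meta: dict = field(default_factory=dict)


def _seed_points(stage: MorphologicalStage, n_seeds: int) -> np.ndarray:
    info = _opening_info(stage)
    labels = stage.labels
    hx, hy, hz = stage.grid.spacing_mm
    mouth = labels[:, :, info["k_top"]] == int(Label.OPENING)
    ii, jj = np.nonzero(mouth)
    z = info["z_plane_mm"] + 0.25 * hz
    if stage.two_d:
        x_lo = (ii.min() + 0.1) * hx
        x_hi = (ii.max() + 0.9) * hx
        xs = np.linspace(x_lo, x_hi, n_seeds)
        y = stage.centers_mm(1)[0]
        return np.stack([xs, np.full(n_seeds, y), np.full(n_seeds, z)], axis=1)
    m = max(2, int(math.ceil(math.sqrt(n_seeds * 4 / math.pi))))
    x_lo, x_hi = (ii.min() + 0.1) * hx, (ii.max() + 0.9) * hx
    y_lo, y_hi = (jj.min() + 0.1) * hy, (jj.max() + 0.9) * hy
    gx, gy = np.meshgrid(np.linspace(x_lo, x_hi, m), np.linspace(y_lo, y_hi, m), indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), np.full(m * m, z)], axis=1)
    iv = np.clip((pts[:, 0] / hx).astype(int), 0, mouth.shape[0] - 1)
    jv = np.clip((pts[:, 1] / hy).astype(int), 0, mouth.shape[1] - 1)
    return pts[mouth[iv, jv]]


def trace_streamlines(
    f: FlowField,
    stage: MorphologicalStage,
    cfg: StreamlineConfig = StreamlineConfig(),
) -> StreamlineSet:
    """Integrate streamlines of the frozen field from the opening cross-section.

    Classification: ``reached_top`` on entering the top-outlet layer;
    ``recirculated`` on re-crossing the opening plane downward after rising,
    or on exhausting the arc-length budget while confined within
    ``confine_diams`` opening diameters of the mouth; ``stalled`` when the
    local speed falls below ``eps_u`` (seeds in dead zones are reported
    stalled, never dropped) or when the budget runs out far from the opening.
    """
    info = _opening_info(stage)
    hx, hy, hz = stage.grid.spacing_mm
    interp = velocity_interpolator(f, stage)
    seeds = _seed_points(stage, cfg.n_seeds)
    n = len(seeds)
    pos = seeds.copy()
    z_plane = info["z_plane_mm"]
    z_top = (stage.grid.shape[2] - 0.5) * hz
    center = np.array(info["center_mm"])
    D = info["ref_diameter_mm"]
    ds = cfg.ds_factor * min(hx, hz) if stage.two_d else cfg.ds_factor * min(hx, hy, hz)
    max_steps = int(cfg.max_arc_diams * D / ds) + 1
    status = np.zeros(n, dtype=np.int8)  # 0 active, 1 top, 2 recirc, 3 stalled
    z_max = pos[:, 2].copy()
    paths: list[list[np.ndarray]] = [[seeds[i].copy()] for i in range(n)]

    def unit_vel(p):
        vel = interp(p)
        sp = np.linalg.norm(vel, axis=1)
        return vel / np.maximum(sp, 1e-30)[:, None], sp

    for step in range(max_steps):
        act = status == 0
        if not act.any():
            break
        pa = pos[act]
        k1, sp = unit_vel(pa)
        newly_stalled = sp < cfg.eps_u
        k2, _ = unit_vel(pa + 0.5 * ds * k1)
        k3, _ = unit_vel(pa + 0.5 * ds * k2)
        k4, _ = unit_vel(pa + ds * k3)
        pa_new = pa + (ds / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        idx = np.flatnonzero(act)
        pos[idx] = pa_new
        st = status[idx]
        st[newly_stalled] = 3
        z = pa_new[:, 2]
        z_max[idx] = np.maximum(z_max[idx], z)
        st[(st == 0) & (z >= z_top)] = 1
        rec = (st == 0) & (z < z_plane - 0.5 * hz) & (z_max[idx] > z_plane + hz)
        st[rec] = 2
        status[idx] = st
        if step % cfg.store_stride == 0:
            for m, i in enumerate(idx):
                paths[i].append(pa_new[m].copy())
    # exhausted budget: confined near the opening -> recirculated, else stalled
    act = status == 0
    if act.any():
        confine = cfg.confine_mm
        if confine is None:
            confine = info["clearance_mm"] or cfg.confine_diams * D
        d_center = np.linalg.norm(pos[act] - center[None, :], axis=1)
        status[np.flatnonzero(act)[d_center <= confine]] = 2
        status[status == 0] = 3
    class_names = np.array(["", "reached_top", "recirculated", "stalled"])
    return StreamlineSet(
        seeds_mm=seeds,
        paths=[np.array(p) for p in paths],
        classes=class_names[status],
        meta={"ds_mm": ds, "max_steps": max_steps, "opening": info},
    )


def trace_pathlines(
    fields: Sequence[FlowField],
    stage: MorphologicalStage,
    cfg: StreamlineConfig = StreamlineConfig(),
    t_release: float | None = None,
) -> StreamlineSet:
    """Unsteady particle paths through a stored snapshot series (linear time
    interpolation between snapshots); same seeding and classification grammar
    as :func:`trace_streamlines`."""
    times = np.array([f.t for f in fields])
    if len(fields) < 2:
        raise MetricsError("pathlines need at least two stored snapshots")
    info = _opening_info(stage)
    hx, hy, hz = stage.grid.spacing_mm
    interps = [velocity_interpolator(f, stage) for f in fields]
    seeds = _seed_points(stage, cfg.n_seeds)
    n = len(seeds)
    pos = seeds.copy()
    t0 = float(times[0] if t_release is None else t_release)
    t_end = float(times[-1])
    z_plane = info["z_plane_mm"]
    z_top = (stage.grid.shape[2] - 0.5) * hz
    center = np.array(info["center_mm"])
    D = info["ref_diameter_mm"]
    status = np.zeros(n, dtype=np.int8)
    z_max = pos[:, 2].copy()
    paths: list[list[np.ndarray]] = [[seeds[i].copy()] for i in range(n)]

    def vel_at(p, t):
        j = int(np.clip(np.searchsorted(times, t) - 1, 0, len(times) - 2))
        frac = (t - times[j]) / (times[j + 1] - times[j])
        return (1 - frac) * interps[j](p) + frac * interps[j + 1](p)

    # time step from a CFL-like bound on the fastest snapshot
    vmax = max(max(np.abs(f.u).max(), np.abs(f.v).max(), np.abs(f.w).max())
               for f in fields)
    dt = 0.5 * min(hx, hz) / max(vmax, 1e-9)
    t = t0
    step = 0
    while t < t_end - 1e-12:
        act = status == 0
        if not act.any():
            break
        h_t = min(dt, t_end - t)
        pa = pos[act]
        k1 = vel_at(pa, t)
        sp = np.linalg.norm(k1, axis=1)
        k2 = vel_at(pa + 0.5 * h_t * k1, t + 0.5 * h_t)
        k3 = vel_at(pa + 0.5 * h_t * k2, t + 0.5 * h_t)
        k4 = vel_at(pa + h_t * k3, t + h_t)
        pa_new = pa + (h_t / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        idx = np.flatnonzero(act)
        pos[idx] = pa_new
        st = status[idx]
        st[sp < cfg.eps_u] = 3
        z = pa_new[:, 2]
        z_max[idx] = np.maximum(z_max[idx], z)
        st[(st == 0) & (z >= z_top)] = 1
        st[(st == 0) & (z < z_plane - 0.5 * hz) & (z_max[idx] > z_plane + hz)] = 2
        status[idx] = st
        t += h_t
        step += 1
        if step % cfg.store_stride == 0:
            for m, i in enumerate(idx):
                paths[i].append(pa_new[m].copy())
    act = status == 0
    if act.any():
        confine = cfg.confine_mm
        if confine is None:
            confine = info["clearance_mm"] or cfg.confine_diams * D
        d_center = np.linalg.norm(pos[act] - center[None, :], axis=1)
        status[np.flatnonzero(act)[d_center <= confine]] = 2
        status[status == 0] = 3
    class_names = np.array(["", "reached_top", "recirculated", "stalled"])
    return StreamlineSet(seeds, [np.array(p) for p in paths], class_names[status],
                         meta={"mode": "pathline", "t0": t0, "t_end": t_end})


def systolic_shunt_fraction(
    fields: Sequence[FlowField],
    stage: MorphologicalStage,
    cycle_start_s: float,
    period_s: float,
    release_window_fraction: float = 0.5,
    cfg: StreamlineConfig | None = None,
) -> dict:
    """Aggregate pathline classification for blood entering during systole.

    Particles are released at the opening at every stored snapshot within the
    first ``release_window_fraction`` of the cycle (the systolic filling
    phase) and advected through the remainder of the stored cycle; the
    returned percentages pool all releases. This is the particle-true version
    of the erythrocyte-shunt statistic: material entering while the entry
    vortex grows can be wound into it even though no single frozen snapshot's
    streamlines can cross into a closed planar recirculation zone.
    """
    if cfg is None:
        cfg = StreamlineConfig()
    t_lim = cycle_start_s + release_window_fraction * period_s
    releases = [f.t for f in fields if f.t <= t_lim + 1e-12]
    if not releases:
        releases = [fields[0].t]
    counts = {"reached_top": 0, "recirculated": 0, "stalled": 0}
    n_total = 0
    for t0 in releases:
        sub = [f for f in fields if f.t >= t0 - 1e-12]
        if len(sub) < 2:
            continue
        pl = trace_pathlines(sub, stage, cfg, t_release=t0)
        for cls in ("reached_top", "recirculated", "stalled"):
            counts[cls] += int((pl.classes == cls).sum())
        n_total += len(pl.classes)
    if n_total == 0:
        raise MetricsError("no pathline releases possible within the stored cycle")
    return {
        "reached_top_pct": 100.0 * counts["reached_top"] / n_total,
        "shunted_pct": 100.0 * counts["recirculated"] / n_total,
        "stalled_pct": 100.0 * counts["stalled"] / n_total,
        "n_particles": n_total,
        "n_releases": len(releases),
    }


def vortex_fraction(streamlines: StreamlineSet) -> dict:
    """Percentages of streamlines reaching the top / shunted into recirculation
    / stalled; the three classes partition the set (conserved to 0.1 pp)."""
    n = len(streamlines.classes)
    if n == 0:
        raise MetricsError("empty streamline set")
    out = {
        "reached_top_pct": 100.0 * float((streamlines.classes == "reached_top").sum()) / n,
        "shunted_pct": 100.0 * float((streamlines.classes == "recirculated").sum()) / n,
        "stalled_pct": 100.0 * float((streamlines.classes == "stalled").sum()) / n,
    }
    if abs(sum(out.values()) - 100.0) > 0.1:
        raise MetricsError("streamline class fractions do not sum to 100%")
    return out


# ---------------------------------------------------------------------------
# jet metrics

@dataclass
class JetMetrics:
    peak_velocity_cm_s: float
    onset_time_s: float | None
    penetration_depth_mm: float
    peak_time_s: float


def jet_metrics(
    fields: Sequence[FlowField],
    stage: MorphologicalStage,
    onset_threshold_cm_s: float = JET_ONSET_THRESHOLD_CM_S,
    penetration_fraction: float = 0.5,
    jet_region_mm: float | None = None,
) -> JetMetrics:
    """Peak entry-region IVS speed over the stored cycle, jet onset time, and
    the penetration depth of the jet above the opening at peak systole.

    The peak is evaluated over IVS cells within ``jet_region_mm`` of the
    opening centre (default: the stage's obstacle-free clearance zone) -- the
    proximal entry region where velocity jets form -- so that narrow pore
    throats deep in the villous packing (whose speeds are set by continuity,
    not by the opening) do not mask the opening's effect.

    Penetration depth: greatest height above the opening plane at which the
    local speed still exceeds ``penetration_fraction`` of the opening exit
    speed (both evaluated on the snapshot of peak IVS velocity).
    """
    ivs = _ivs_mask(stage)
    if not ivs.any():
        raise MetricsError("stage has no IVS region")
    info = _opening_info(stage)
    hz = stage.grid.spacing_mm[2]
    if jet_region_mm is None:
        jet_region_mm = info["clearance_mm"]
    if jet_region_mm is not None:
        cx, cy, cz = info["center_mm"]
        X, Y, Z = np.meshgrid(stage.centers_mm(0), stage.centers_mm(1),
                              stage.centers_mm(2), indexing="ij")
        near = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= jet_region_mm**2
        ivs = ivs & near
        if not ivs.any():
            raise MetricsError("no IVS cells inside the jet evaluation region")
    peaks = []
    for f in fields:
        sp = f.cell_speed()
        peaks.append(float(sp[ivs].max()) / 10.0)  # mm/s -> cm/s
    peaks = np.array(peaks)
    i_peak = int(np.argmax(peaks))
    onset = None
    for f, pk in zip(fields, peaks):
        if pk >= onset_threshold_cm_s:
            onset = float(f.t)
            break
    f_pk = fields[i_peak]
    sp = f_pk.cell_speed()
    mouth_layer = stage.labels[:, :, info["k_top"]] == int(Label.OPENING)
    v_exit = float(sp[:, :, info["k_top"]][mouth_layer].mean())
    depth = 0.0
    if v_exit > 0:
        zs = stage.centers_mm(2)
        above = _ivs_mask(stage) & (sp >= penetration_fraction * v_exit)
        ks = np.flatnonzero(above.any(axis=(0, 1)))
        ks = ks[zs[ks] > info["z_plane_mm"]]
        if ks.size:
            depth = float(zs[ks.max()] - info["z_plane_mm"])
    return JetMetrics(
        peak_velocity_cm_s=float(peaks[i_peak]),
        onset_time_s=onset,
        penetration_depth_mm=depth,
        peak_time_s=float(f_pk.t),
    )


def recirculation_fraction(
    f: FlowField,
    stage: MorphologicalStage,
    region_radius_mm: float | None = None,
    w_reverse_mm_s: float = 5.0,
) -> float:
    """Percentage of the entry-pocket area occupied by reversed (downward)
    flow: IVS cells within ``region_radius_mm`` of the opening centre
    (default: the obstacle-free clearance radius) whose vertical velocity is
    below ``-w_reverse_mm_s``.

    This is the field-based vortex detector: an abrupt-expansion vortex beside
    the entry jet reverses a substantial share of the pocket, while an
    attached (well-dilated) diffuser leaves it near zero. It is used as the
    critical-flow criterion because instantaneous streamlines of a solenoidal
    planar field are stream-function level sets and cannot pass from the
    opening into a closed recirculation region, making seed-based shunt
    fractions degenerate on steady planar fields.
    """
    info = _opening_info(stage)
    if region_radius_mm is None:
        region_radius_mm = info["clearance_mm"] or 3.0 * info["ref_diameter_mm"]
    cx, cy, cz = info["center_mm"]
    X, Y, Z = np.meshgrid(stage.centers_mm(0), stage.centers_mm(1),
                          stage.centers_mm(2), indexing="ij")
    pocket = _ivs_mask(stage) & (
        (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= region_radius_mm**2
    )
    if not pocket.any():
        raise MetricsError("no IVS cells inside the vortex detection region")
    wc = 0.5 * (f.w[:, :, :-1] + f.w[:, :, 1:])
    return 100.0 * float(((wc < -w_reverse_mm_s) & pocket).sum()) / float(pocket.sum())


# ---------------------------------------------------------------------------
# critical flow threshold

@dataclass
class CriticalFlow:
    found: bool
    q_star_ml_s: float | None
    bracket: tuple[float, float]
    criterion: dict
    trace: list
    reason: str = ""


#: Physiologic per-spiral-artery steady flows (ml/s): spans the three
#: scenarios' cycle means (0.017-0.031) up to just above the source study's
#: critical value.
DEFAULT_QSTAR_BRACKET = (0.005, 0.04)
DEFAULT_VORTEX_THRESHOLD_PCT = 15.0


def critical_flow_threshold(
    stage: MorphologicalStage,
    fluid: FluidProperties,
    bracket: tuple[float, float] = DEFAULT_QSTAR_BRACKET,
    tol_ml_s: float = 2e-3,
    threshold_pct: float = DEFAULT_VORTEX_THRESHOLD_PCT,
    criterion: str = "reversed_area",
    cfg: SolverConfig | None = None,
    sl_cfg: StreamlineConfig | None = None,
    monotonicity_scan: bool = False,
) -> CriticalFlow:
    """Bisect for the steady inlet flow Q* above which the vortex criterion
    switches on.

    ``criterion`` selects the detector: ``reversed_area`` (default) uses
    :func:`recirculation_fraction` >= ``threshold_pct``; ``shunted_pct`` uses
    the seed-based streamline shunt fraction (meaningful for 3-D stages; see
    :func:`recirculation_fraction` on why it degenerates on planar fields).

    The criterion must be false at the lower bracket end (else BracketError).
    If it never switches on up to the upper end, that is reported as
    ``found=False`` -- the behaviour of a well-dilated opening over the
    physiologic range -- rather than treated as an error. With
    ``monotonicity_scan`` the bracket is first scanned at five points and the
    bisection refuses to run (reporting the scan) if the detector is not
    non-decreasing.
    """
    if cfg is None:
        cfg = SolverConfig(steady_tol=1e-5, store_dt=None)
    if sl_cfg is None:
        sl_cfg = StreamlineConfig()
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    trace: list[tuple[float, float]] = []
    warm: dict = {"field": None}

    # planar stages are driven at the physical inlet velocity equivalent of q
    # (a one-voxel slab cannot carry the 3-D volumetric flux); q keeps its
    # spiral-artery ml/s meaning throughout the bisection.
    def q_effective(q: float) -> float:
        prov = stage.provenance
        if stage.two_d and isinstance(prov.get("artery"), dict):
            d = prov["artery"]["lumen_diameter_um"] / 1000.0
            v_in = q * 1000.0 / (math.pi * (d / 2) ** 2)  # mm/s
            hx, hy, _ = stage.grid.spacing_mm
            area_vox = float((stage.labels[:, :, 0] == int(Label.INLET)).sum()) * hx * hy
            return v_in * area_vox / 1000.0
        return q

    def detector(q: float) -> float:
        f, _rep = solve_steady(stage, q_effective(q), fluid, cfg, initial=warm["field"])
        warm["field"] = f
        if criterion == "reversed_area":
            val = recirculation_fraction(f, stage)
        elif criterion == "shunted_pct":
            val = vortex_fraction(trace_streamlines(f, stage, sl_cfg))["shunted_pct"]
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        trace.append((q, val))
        return val

    crit = {"name": criterion, "threshold_pct": threshold_pct}
    if monotonicity_scan:
        scan = [(q, detector(q)) for q in np.linspace(lo, hi, 5)]
        vals = [v for _, v in scan]
        if any(b < a - 0.5 for a, b in zip(vals, vals[1:])):
            return CriticalFlow(False, None, bracket, crit, trace,
                                reason=f"detector not monotone over bracket: {scan}")
    if detector(lo) >= threshold_pct:
        raise BracketError(
            f"criterion already true at lower bracket q={lo} ml/s "
            f"(detector {trace[-1][1]:.2f}%); trace={trace}"
        )
    if detector(hi) < threshold_pct:
        return CriticalFlow(False, None, bracket, crit, trace,
                            reason="criterion false throughout the bracket")
    a, b = lo, hi
    while b - a > tol_ml_s:
        mid = 0.5 * (a + b)
        if detector(mid) >= threshold_pct:
            b = mid
        else:
            a = mid
    return CriticalFlow(True, b, bracket, crit, trace)


# ---------------------------------------------------------------------------
# iso-pressure export

def isobar_export(
    f: FlowField,
    stage: MorphologicalStage,
    path: str | Path,
    interval_mmhg: float = 0.05,
) -> dict:
    """Contour the pressure field at multiples of ``interval_mmhg`` and write
    VTK polydata (lines in 2-D via marching squares, triangle meshes in 3-D
    via marching cubes). Returns metadata including the levels written."""
    from skimage import measure

    from .vtkio import write_polydata

    p = f.p_mmhg()
    fl = stage.fluid_mask()
    # fill solid cells with their nearest fluid value so contours end at walls
    if (~fl).any() and fl.any():
        _, inds = distance_transform_edt(~fl, return_indices=True)
        p = p[tuple(inds)]
    pmin, pmax = float(p.min()), float(p.max())
    k0 = math.ceil(pmin / interval_mmhg)
    k1 = math.floor(pmax / interval_mmhg)
    levels = [k * interval_mmhg for k in range(k0, k1 + 1)
              if pmin < k * interval_mmhg < pmax]
    hx, hy, hz = stage.grid.spacing_mm
    points: list[np.ndarray] = []
    lines: list[list[int]] = []
    polys: list[list[int]] = []
    level_of: list[float] = []
    if stage.two_d:
        img = p[:, 0, :]
        for lev in levels:
            for cont in measure.find_contours(img, lev):
                base = sum(len(pt) for pt in points)
                xyz = np.stack(
                    [(cont[:, 0] + 0.5) * hx,
                     np.full(len(cont), stage.centers_mm(1)[0]),
                     (cont[:, 1] + 0.5) * hz], axis=1)
                points.append(xyz)
                lines.append(list(range(base, base + len(cont))))
                level_of += [lev] * len(cont)
    else:
        for lev in levels:
            try:
                verts, faces, _, _ = measure.marching_cubes(p, level=lev)
            except (ValueError, RuntimeError):
                continue
            base = sum(len(pt) for pt in points)
            xyz = np.stack([(verts[:, 0] + 0.5) * hx, (verts[:, 1] + 0.5) * hy,
                            (verts[:, 2] + 0.5) * hz], axis=1)
            points.append(xyz)
            polys += [[base + int(a) for a in tri] for tri in faces]
            level_of += [lev] * len(verts)
    pts = np.concatenate(points) if points else np.zeros((0, 3))
    write_polydata(path, pts, lines=lines, polygons=polys,
                   point_scalars={"pressure_mmhg": np.array(level_of)})
    meta = {"interval_mmhg": interval_mmhg, "levels": levels, "path": str(path)}
    Path(str(path) + ".json").write_text(__import__("json").dumps(meta))
    return meta


# ---------------------------------------------------------------------------
# conservation summary (used by the pipeline's invariant reporting)

def conservation_summary(report: SolveReport, poisson_tol: float) -> dict:
    imb = report.flux_imbalance()
    return {
        "max_divergence": float(np.max(report.max_div)) if report.max_div else 0.0,
        "divergence_ok": bool(np.max(report.max_div) <= poisson_tol) if report.max_div else True,
        "max_flux_imbalance": float(np.max(imb)) if imb.size else 0.0,
        "flux_balance_ok": bool(np.max(imb) <= 1e-3) if imb.size else True,
    }
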