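"""Synthetic flow-domain generator: the voxelized "morphological stage".

The stage stands in for a histology-derived reconstruction of a
uteroplacental inflow region: a spiralized artery (helical in 3-D, serpentine
in the planar variant) rises through a solid basal zone and discharges
through its terminal opening -- dilated (funnel-shaped, the remodeled
phenotype) or undilated (straight, the IUGR phenotype) -- into a
villous-obstructed intervillous cuboid. The villous tree is modelled
statistically as a porosity-controlled random packing of spheres (disks in
2-D) with an obstacle-free clearance zone in front of the opening.

Conventions: voxel indices are 0-based; physical coordinates live at voxel
centres; the z axis points from basal (artery inlet, z = 0) to the top
outlet. Specs are given in micrometres; coordinates handed to the solver and
metrics are in millimetres (mm-g-s unit system). Rasterization is a
centre-in-shape test; stair-step boundaries are the accuracy limiter and are
accepted as first-order geometry.

Stages built here additionally carry *analytic wall primitives* (cylindrical
channel, spheres, basal plate, planes) so that downstream wall-shear-stress
evaluation can measure gradients against the true smooth surface rather than
the voxel staircase.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import asdict, dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import ndimage


class Label(IntEnum):
    """Per-voxel region codes of the morphological stage."""

    INLET = 1
    ARTERY_LUMEN = 2
    WALL = 3
    OPENING = 4
    IVS_FLUID = 5
    VILLOUS_SOLID = 6
    TOP_OUTLET = 7
    SIDE_BOUNDARY = 8   # face semantics only (slip); never a voxel label
    BOTTOM_BOUNDARY = 9  # face semantics only (no-slip); never a voxel label


FLUID_LABELS = (Label.INLET, Label.ARTERY_LUMEN, Label.OPENING, Label.IVS_FLUID, Label.TOP_OUTLET)
SOLID_LABELS = (Label.WALL, Label.VILLOUS_SOLID)


class ResolutionError(ValueError):
    """The lumen (or another feature) is not resolved by the voxel grid."""


class PackingError(RuntimeError):
    """Villous packing could not reach the target porosity within budget."""


class TopologyError(RuntimeError):
    """Inlet and top outlet are not connected through fluid voxels."""


class UndefinedPorosityError(ValueError):
    """Porosity is undefined: the stage has no intervillous region."""


@dataclass(frozen=True)
class GridSpec:
    """Physical extent (um) and voxel counts of the stage; spacing derived."""

    extent_um: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_um) or any(n < 1 for n in self.shape):
            raise ValueError("extents must be positive and voxel counts >= 1")

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return tuple(e / n for e, n in zip(self.extent_um, self.shape))

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return tuple(s / 1000.0 for s in self.spacing_um)

    def centers_um(self, axis: int) -> np.ndarray:
        h = self.spacing_um[axis]
        return (np.arange(self.shape[axis]) + 0.5) * h


@dataclass(frozen=True)
class SpiralArterySpec:
    """Spiralized artery: helix radius/pitch/turns, lumen, and opening type.

    ``pitch_um`` is the axial rise per turn; the arterial zone height is
    pitch_um * n_turns (or pitch_um alone for a straight artery, n_turns=0).
    ``opening`` selects the terminal segment: 'dilated' widens linearly from
    the lumen to ``funnel_mouth_diameter_um`` over ``funnel_length_um``;
    'undilated' keeps the lumen diameter to the mouth.
    """

    helix_radius_um: float = 450.0
    pitch_um: float = 2400.0
    n_turns: float = 1.0
    lumen_diameter_um: float = 340.0
    opening: str = "dilated"
    # gentle trumpet: ~5 deg half-angle keeps the diffuser attached at
    # systolic Reynolds numbers (alpha * Re_h well below the Jeffery-Hamel
    # separation range), the hemodynamic point of remodeling
    funnel_mouth_diameter_um: float = 600.0
    funnel_length_um: float = 800.0
    opening_label_length_um: float = 200.0
    end_straight_um: float = 250.0    # vertical inlet segment
    mouth_straight_um: float = 850.0  # vertical terminal segment (covers funnel)
    end_taper_um: float = 450.0       # coil amplitude ramps over this length
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.opening not in ("dilated", "undilated"):
            raise ValueError("opening must be 'dilated' or 'undilated'")
        if self.lumen_diameter_um <= 0 or self.pitch_um <= 0 or self.n_turns < 0:
            raise ValueError("lumen, pitch positive; n_turns >= 0")
        if self.opening == "dilated" and self.funnel_mouth_diameter_um <= self.lumen_diameter_um:
            raise ValueError("dilated opening requires funnel_mouth_diameter > lumen_diameter")

    @property
    def zone_height_um(self) -> float:
        """Height of the arterial (basal) zone below the IVS."""
        return self.pitch_um * (self.n_turns if self.n_turns > 0 else 1.0)

    @property
    def mouth_diameter_um(self) -> float:
        return self.funnel_mouth_diameter_um if self.opening == "dilated" else self.lumen_diameter_um


@dataclass(frozen=True)
class VillousSpec:
    """Statistical villous stand-in: porosity-controlled random sphere/disk packing."""

    target_porosity: float = 0.5
    obstacle_radius_mean_um: float = 150.0
    obstacle_radius_sd_um: float = 40.0
    clearance_radius_um: float = 600.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_porosity <= 1):
            raise ValueError("target_porosity must be in (0, 1]")
        if self.obstacle_radius_mean_um <= 0 or self.obstacle_radius_sd_um < 0:
            raise ValueError("obstacle radii must be positive")


# ---------------------------------------------------------------------------
# Analytic wall primitives (mm): distance from a fluid-side point to the
# nearest true (pre-rasterization) solid surface, and its outward normal.

def _prim_distance(prim: dict, pts: np.ndarray, two_d: bool) -> np.ndarray:
    """Unsigned distance (mm) from fluid points to one primitive's surface.

    Points on the solid side return negative values; callers take the min
    over primitives of the positive part.
    """
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    kind = prim["kind"]
    if kind == "sphere":
        c = prim["center"]
        if two_d:
            d = np.hypot(x - c[0], z - c[2])
        else:
            d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        return d - prim["r"]
    if kind == "channel":
        samples, radii = _channel_samples(prim)
        # the channel is the union of balls of radius r_i swept along the
        # centerline: signed inside-ness = max_i (r_i - |p - s_i|) (the
        # nearest sample alone is wrong when the radius varies, e.g. funnels)
        if two_d:
            pts2 = np.stack([x, z], axis=1)
            smp = samples[:, [0, 2]]
        else:
            pts2 = np.stack([x, y, z], axis=1)
            smp = samples
        out = np.empty(len(pts2))
        chunk = 65536
        for i0 in range(0, len(pts2), chunk):
            block = pts2[i0:i0 + chunk]
            d = np.sqrt(((block[:, None, :] - smp[None, :, :]) ** 2).sum(-1))
            out[i0:i0 + chunk] = (radii[None, :] - d).max(axis=1)
        return out
    if kind == "basal":
        # top surface of the basal plate, with the circular mouth cut out:
        # outside the mouth the surface is the plane z = z0; inside, the
        # nearest plate point is the rim circle (continuous across the rim)
        c = prim["mouth_center"]
        if two_d:
            dh = np.abs(x - c[0])
        else:
            dh = np.hypot(x - c[0], y - c[1])
        inside = np.maximum(prim["mouth_r"] - dh, 0.0)
        return np.where(inside > 0, np.hypot(inside, z - prim["z0"]), z - prim["z0"])
    if kind == "plane":
        # solid on the 'side' of coordinate 'pos' along 'axis'
        coord = pts[:, prim["axis"]]
        return (coord - prim["pos"]) * prim["side"]
    raise ValueError(f"unknown primitive kind {kind!r}")


def _centerline_mm(prim: dict, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coil centerline at height z (mm). The coil amplitude tapers smoothly to
    zero over ``straight_len`` at both ends, so the artery meets the inlet
    plane and the opening with a vertical terminal segment (circular mouth)."""
    cx, cy = prim["center_xy"]
    amp = prim["helix_radius"]
    if amp == 0 or prim["n_turns"] == 0:
        return np.full_like(z, cx), np.full_like(z, cy)
    zt = prim["z_top"]
    zc = np.clip(z, 0.0, zt)
    phase = 2 * math.pi * prim["n_turns"] * (zc - zt) / zt
    l0b = prim.get("straight_len", 0.0)       # bottom (inlet) straight length
    l0t = prim.get("mouth_straight_len", l0b)  # top (mouth) straight length
    l1 = prim.get("taper_len", 0.0)
    if l0b > 0 or l0t > 0 or l1 > 0:
        tb = np.clip((zc - l0b) / max(l1, 1e-12), 0.0, 1.0)
        tt = np.clip((zt - zc - l0t) / max(l1, 1e-12), 0.0, 1.0)
        t = np.minimum(tb, tt)
        env = t * t * (3 - 2 * t)  # smoothstep: zero (straight) within the ends
    else:
        env = 1.0
    if prim["two_d"]:
        return cx + amp * env * np.sin(phase), np.full_like(z, cy)
    return cx + amp * env * np.sin(phase), cy + amp * env * np.cos(phase) - amp * env

def _channel_samples(prim: dict) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled centerline polyline (mm) and per-sample lumen radius.

    The channel solid surface is the envelope of balls of radius r(z) swept
    along the centerline; distances are measured perpendicular to the curve,
    which keeps steep serpentine/helical segments watertight and connected.
    """
    step = prim["r_lumen"] / 4.0
    n = max(16, int(math.ceil(prim["z_top"] / step)) + 1)
    z = np.linspace(0.0, prim["z_top"], n)
    xc, yc = _centerline_mm(prim, z)
    return np.stack([xc, yc, z], axis=1), _radius_profile_mm(prim, z)


def _radius_profile_mm(prim: dict, z: np.ndarray) -> np.ndarray:
    r = np.full_like(z, prim["r_lumen"])
    if prim["r_mouth"] > prim["r_lumen"]:
        z1, lf = prim["z_top"], prim["funnel_length"]
        frac = np.clip((z - (z1 - lf)) / lf, 0.0, 1.0)
        r = prim["r_lumen"] + frac * (prim["r_mouth"] - prim["r_lumen"])
    return r


@dataclass
class MorphologicalStage:
    """Labeled voxel grid defining the flow domain, plus provenance.

    ``labels`` has shape ``grid.shape`` and dtype int8 with values from
    :class:`Label`. ``wall_primitives`` describe the analytic solid surfaces
    (mm) used for near-wall gradient evaluation; ``provenance`` records the
    generating specs, seeds, and realized measurements.
    """

    grid: GridSpec
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)
    wall_primitives: list[dict] = field(default_factory=list)

    @property
    def two_d(self) -> bool:
        return self.grid.shape[1] == 1

    def fluid_mask(self) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in FLUID_LABELS])

    def solid_mask(self) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in SOLID_LABELS])

    def centers_mm(self, axis: int) -> np.ndarray:
        return self.grid.centers_um(axis) / 1000.0

    def _prim_matrix(self, pts: np.ndarray) -> np.ndarray:
        """Signed distances to every primitive's surface, shape (n_prims, n_pts).

        Each primitive's sign convention is positive on its own fluid side,
        so |d| is the distance to that surface near the surface."""
        return np.stack(
            [_prim_distance(p, pts, self.two_d) for p in self.wall_primitives]
        )

    def wall_distance(self, pts_mm: np.ndarray) -> np.ndarray:
        """Distance (mm) from points to the nearest analytic wall surface."""
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        if not self.wall_primitives:
            return np.full(len(pts), np.nan)
        D = np.abs(self._prim_matrix(pts))
        D[~np.isfinite(D)] = np.inf
        return D.min(axis=0)

    def nearest_wall(self, pts_mm: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Signed distance to the nearest wall surface (positive on the fluid
        side) and its into-fluid unit normal (finite-differenced on the
        nearest primitive's signed distance, so it is well-defined *on* the
        surface)."""
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        D = self._prim_matrix(pts)
        A = np.abs(D)
        A[~np.isfinite(A)] = np.inf
        j = A.argmin(axis=0)
        cols = np.arange(len(pts))
        d_signed = D[j, cols]
        grad = np.zeros_like(pts)
        axes = (0, 2) if self.two_d else (0, 1, 2)
        for ax in axes:
            dp = pts.copy()
            dm = pts.copy()
            dp[:, ax] += step_mm
            dm[:, ax] -= step_mm
            grad[:, ax] = (self._prim_matrix(dp)[j, cols]
                           - self._prim_matrix(dm)[j, cols]) / (2 * step_mm)
        norm = np.linalg.norm(grad, axis=1)
        norm[norm == 0] = 1.0
        return d_signed, grad / norm[:, None]


# ---------------------------------------------------------------------------
# Stage construction

def build_stage(
    grid: GridSpec,
    artery: SpiralArterySpec,
    villi: VillousSpec,
    ivs_height_um: float = 2000.0,
) -> MorphologicalStage:
    """Build a voxelized stage from specs (deterministic under fixed seeds).

    Postconditions: inlet patch present and connected; fluid 6-connected from
    inlet to top outlet; realized IVS porosity within +-0.02 of target;
    realized opening diameter within one voxel of spec. Violations raise
    (ResolutionError / PackingError / TopologyError), never silent repair --
    except that isolated pore pockets sealed off by the random packing are
    converted to villous solid and counted in provenance (they cannot carry
    flow and would make the pressure problem singular).
    """
    nx, ny, nz = grid.shape
    hx, hy, hz = grid.spacing_um
    two_d = ny == 1
    in_plane = max(hx, hz) if two_d else max(hx, hy)
    if artery.lumen_diameter_um <= 2 * in_plane:
        raise ResolutionError(
            f"lumen diameter {artery.lumen_diameter_um} um not resolved by >2 voxels "
            f"at spacing {in_plane} um"
        )
    Lx, Ly, Lz = grid.extent_um
    z0 = Lz - ivs_height_um
    if not (0 < z0 < Lz):
        raise ValueError("ivs_height_um must leave a positive arterial zone below the IVS")
    if abs(z0 - artery.zone_height_um) > 0.51 * hz:
        raise ValueError(
            f"arterial zone height from artery spec ({artery.zone_height_um} um) does not "
            f"match grid extent minus IVS height ({z0} um)"
        )

    xs = grid.centers_um(0)
    ys = grid.centers_um(1)
    zs = grid.centers_um(2)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    cx, cy = Lx / 2.0, Ly / 2.0
    amp = artery.helix_radius_um if artery.n_turns > 0 else 0.0
    r_l = artery.lumen_diameter_um / 2.0
    r_m = artery.mouth_diameter_um / 2.0
    if amp + r_m >= min(cx, Lx - cx):
        raise ValueError("helix radius + mouth radius exceed the domain half-width")

    prim_channel = {
        "kind": "channel",
        "center_xy": (cx / 1000.0, cy / 1000.0),
        "helix_radius": amp / 1000.0,
        "n_turns": float(artery.n_turns),
        "z_top": z0 / 1000.0,
        "r_lumen": r_l / 1000.0,
        "r_mouth": r_m / 1000.0,
        "funnel_length": artery.funnel_length_um / 1000.0,
        "straight_len": artery.end_straight_um / 1000.0,
        "mouth_straight_len": artery.mouth_straight_um / 1000.0,
        "taper_len": artery.end_taper_um / 1000.0,
        "two_d": two_d,
    }

    # rasterize the channel by perpendicular distance to the sampled centerline
    k_ivs0 = int(np.searchsorted(zs, z0))
    artery_fluid = np.zeros(grid.shape, dtype=bool)
    if k_ivs0 > 0:
        XX, YY, ZZ = np.meshgrid(xs, ys, zs[:k_ivs0], indexing="ij")
        pts_mm = np.stack([XX.ravel(), YY.ravel(), ZZ.ravel()], axis=1) / 1000.0
        inside = _prim_distance(prim_channel, pts_mm, two_d) > 0
        artery_fluid[:, :, :k_ivs0] = inside.reshape(nx, ny, k_ivs0)

    labels = np.full(grid.shape, int(Label.WALL), dtype=np.int8)
    labels[:, :, zs >= z0] = int(Label.IVS_FLUID)
    labels = np.where(artery_fluid, np.int8(Label.ARTERY_LUMEN), labels)
    l_open = artery.funnel_length_um if artery.opening == "dilated" else artery.opening_label_length_um
    opening_band = artery_fluid & (Z >= z0 - l_open)
    labels = np.where(opening_band, np.int8(Label.OPENING), labels)

    # inlet patch: artery fluid voxels in the bottom layer
    inlet_layer = labels[:, :, 0]
    inlet_mask = np.isin(inlet_layer, (int(Label.ARTERY_LUMEN), int(Label.OPENING)))
    if not inlet_mask.any():
        raise TopologyError("artery does not reach the bottom layer; no inlet patch")
    lab2d, ncomp = ndimage.label(inlet_mask)
    if ncomp != 1:
        raise TopologyError(f"inlet patch is not a single connected component ({ncomp})")
    inlet_layer[inlet_mask] = int(Label.INLET)
    labels[:, :, 0] = inlet_layer

    # mouth centre (um): centerline at the IVS entry plane
    mxy_mm, myy_mm = _centerline_mm(prim_channel, np.array([z0 / 1000.0]))
    mouth_x, mouth_y = float(mxy_mm[0] * 1000.0), float(myy_mm[0] * 1000.0)

    # villous packing: pack to a raw porosity target, seal off pore pockets
    # unreachable from the inlet, and re-pack with a compensated raw target if
    # the sealing pushed the final porosity below the +-0.02 band.
    ivs_sel = zs >= z0
    n_ivs_total = int(nx * ny * ivs_sel.sum())
    zs_ivs = zs[k_ivs0:]
    base_labels = labels
    structure = ndimage.generate_binary_structure(3, 1)

    def _pack(raw_target: float):
        rng = np.random.default_rng(villi.rng_seed)
        obstacles: list[tuple[float, float, float, float]] = []  # (x, y, z, r) um
        solid_ivs = np.zeros((nx, ny, nz - k_ivs0), dtype=bool)
        if raw_target >= 1.0:
            return obstacles, solid_ivs
        if two_d:
            mean_vol = math.pi * villi.obstacle_radius_mean_um**2 * hy
        else:
            mean_vol = 4 / 3 * math.pi * villi.obstacle_radius_mean_um**3
        ivs_vol = Lx * Ly * ivs_height_um
        expected = max(1, math.ceil((1 - raw_target) * ivs_vol / mean_vol)) * 3 + 10
        max_draws = 10 * expected
        fluid_count = n_ivs_total
        draws = 0
        while fluid_count / n_ivs_total > raw_target:
            if draws >= max_draws:
                raise PackingError(
                    f"porosity {fluid_count / n_ivs_total:.3f} still above raw target "
                    f"{raw_target:.3f} after {draws} draws"
                )
            draws += 1
            ox = rng.uniform(0, Lx)
            oy = cy if two_d else rng.uniform(0, Ly)
            oz = rng.uniform(z0, Lz)
            orad = rng.normal(villi.obstacle_radius_mean_um, villi.obstacle_radius_sd_um)
            orad = float(np.clip(orad, 1.2 * in_plane, None))
            if two_d:
                d_mouth = math.hypot(ox - mouth_x, oz - z0)
            else:
                d_mouth = math.sqrt((ox - mouth_x) ** 2 + (oy - mouth_y) ** 2 + (oz - z0) ** 2)
            if d_mouth < villi.clearance_radius_um + orad:
                continue
            i0, i1 = np.searchsorted(xs, [ox - orad, ox + orad])
            j0, j1 = (0, 1) if two_d else np.searchsorted(ys, [oy - orad, oy + orad])
            k0, k1 = np.searchsorted(zs_ivs, [oz - orad, oz + orad])
            if i0 >= i1 or k0 >= k1:
                continue
            if two_d:
                d2 = (xs[i0:i1, None, None] - ox) ** 2 + (zs_ivs[None, None, k0:k1] - oz) ** 2
            else:
                d2 = (
                    (xs[i0:i1, None, None] - ox) ** 2
                    + (ys[None, j0:j1, None] - oy) ** 2
                    + (zs_ivs[None, None, k0:k1] - oz) ** 2
                )
            ball = d2 < orad**2
            newly = ball & ~solid_ivs[i0:i1, j0:j1, k0:k1]
            n_new = int(newly.sum())
            if (fluid_count - n_new) / n_ivs_total < raw_target - 0.02:
                continue  # would overshoot the porosity band; skip this obstacle
            solid_ivs[i0:i1, j0:j1, k0:k1] |= ball
            fluid_count -= n_new
            obstacles.append((ox, oy, oz, orad))
        return obstacles, solid_ivs

    def _seal(labels_in: np.ndarray):
        fluid = np.isin(labels_in, [int(l) for l in FLUID_LABELS])
        comp, _ = ndimage.label(fluid, structure=structure)
        inlet_ids = np.unique(comp[labels_in == int(Label.INLET)])
        inlet_ids = inlet_ids[inlet_ids > 0]
        reach = np.isin(comp, inlet_ids)
        if not (reach[:, :, -1] & fluid[:, :, -1]).any():
            raise TopologyError("no 6-connected fluid path from the inlet to the top outlet")
        orphan = fluid & ~reach
        if orphan.any():
            seal = np.where(np.broadcast_to(Z >= z0, orphan.shape),
                            np.int8(Label.VILLOUS_SOLID), np.int8(Label.WALL))
            labels_in = np.where(orphan, seal, labels_in)
        return labels_in, int(orphan.sum())

    all_obstacles, _ = _pack(villi.target_porosity)

    def _realize(m: int):
        """Labels + realized porosity using the first m packed obstacles."""
        solid_ivs = np.zeros((nx, ny, nz - k_ivs0), dtype=bool)
        for ox, oy, oz, orad in all_obstacles[:m]:
            i0, i1 = np.searchsorted(xs, [ox - orad, ox + orad])
            j0, j1 = (0, 1) if two_d else np.searchsorted(ys, [oy - orad, oy + orad])
            k0, k1 = np.searchsorted(zs_ivs, [oz - orad, oz + orad])
            if two_d:
                d2 = (xs[i0:i1, None, None] - ox) ** 2 + (zs_ivs[None, None, k0:k1] - oz) ** 2
            else:
                d2 = ((xs[i0:i1, None, None] - ox) ** 2
                      + (ys[None, j0:j1, None] - oy) ** 2
                      + (zs_ivs[None, None, k0:k1] - oz) ** 2)
            solid_ivs[i0:i1, j0:j1, k0:k1] |= d2 < orad**2
        full = np.zeros(grid.shape, dtype=bool)
        full[:, :, k_ivs0:] = solid_ivs
        lab = np.where(full, np.int8(Label.VILLOUS_SOLID), base_labels)
        lab, trapped = _seal(lab)
        n_fl = int(np.isin(lab[:, :, k_ivs0:], [int(l) for l in FLUID_LABELS]).sum())
        return lab, trapped, n_fl / n_ivs_total

    # sealing trapped pore pockets lowers porosity below the packed value, so
    # pick the longest obstacle-sequence prefix whose *sealed* porosity stays
    # within the band (sealed porosity is ~non-increasing in prefix length)
    target = villi.target_porosity
    m = len(all_obstacles)
    labels, trapped, realized = _realize(m)
    if realized < target - 0.02:
        lo, hi = 0, m  # invariant: realized(lo) >= target - 0.02 > realized(hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _realize(mid)[2] >= target - 0.02:
                lo = mid
            else:
                hi = mid
        m = lo
        labels, trapped, realized = _realize(m)
    if abs(realized - target) > 0.02:
        raise PackingError(
            f"sealed porosity {realized:.4f} cannot be landed within +-0.02 of "
            f"target {target} (one obstacle plus its sealed pocket jumps the band)"
        )
    obstacles = all_obstacles[:m]

    # top outlet label
    top = labels[:, :, -1]
    top[np.isin(top, (int(Label.IVS_FLUID),))] = int(Label.TOP_OUTLET)
    labels[:, :, -1] = top

    stage = MorphologicalStage(grid=grid, labels=labels)
    stage.wall_primitives = [prim_channel,
                             {"kind": "basal", "z0": z0 / 1000.0,
                              "mouth_center": (mouth_x / 1000.0, mouth_y / 1000.0),
                              "mouth_r": r_m / 1000.0}]
    stage.wall_primitives += [
        {"kind": "sphere", "center": (ox / 1000.0, oy / 1000.0, oz / 1000.0), "r": orad / 1000.0}
        for ox, oy, oz, orad in obstacles
    ]

    por = porosity(stage) if villi.target_porosity < 1.0 or ivs_height_um > 0 else 1.0
    if abs(por - villi.target_porosity) > 0.02:
        raise PackingError(
            f"realized porosity {por:.4f} outside +-0.02 of target {villi.target_porosity}"
        )

    # realized opening diameter at the last arterial layer
    k_mouth = int(np.searchsorted(zs, z0)) - 1
    mouth_mask = np.isin(labels[:, :, k_mouth], (int(Label.OPENING), int(Label.ARTERY_LUMEN)))
    n_mouth = int(mouth_mask.sum())
    if two_d:
        d_real = n_mouth * hx
    else:
        d_real = 2 * math.sqrt(n_mouth * hx * hy / math.pi)
    if abs(d_real - artery.mouth_diameter_um) > max(hx, hy) + 1e-9:
        raise ResolutionError(
            f"realized opening diameter {d_real:.1f} um deviates from spec "
            f"{artery.mouth_diameter_um} um by more than one voxel"
        )

    stage.provenance = {
        "grid": asdict(grid),
        "artery": asdict(artery),
        "villi": asdict(villi),
        "ivs_height_um": ivs_height_um,
        "realized_porosity": por,
        "realized_opening_diameter_um": d_real,
        "mouth_center_um": (mouth_x, mouth_y, z0),
        "n_obstacles": len(obstacles),
        "trapped_pore_voxels_sealed": trapped,
    }
    return stage


def make_2d_slice(
    artery: SpiralArterySpec,
    villi: VillousSpec,
    extent_um: tuple[float, float] = (3000.0, 4400.0),
    shape: tuple[int, int] = (300, 440),
    ivs_height_um: float = 2000.0,
    slab_thickness_um: float | None = None,
) -> MorphologicalStage:
    """Planar (one-voxel-thick) stage: serpentine artery into an obstructed half-plane.

    Same region grammar and invariants as the 3-D builder; the helix becomes
    an in-plane serpentine of the same amplitude and turn count.
    """
    hx = extent_um[0] / shape[0]
    hy = slab_thickness_um if slab_thickness_um is not None else hx
    grid = GridSpec((extent_um[0], hy, extent_um[1]), (shape[0], 1, shape[1]))
    return build_stage(grid, artery, villi, ivs_height_um=ivs_height_um)


def porosity(stage: MorphologicalStage) -> float:
    """Fluid fraction of the IVS: |IVS fluid| / (|IVS fluid| + |villous solid|).

    Top-outlet voxels are IVS fluid that happens to sit in the outflow layer
    and are counted as fluid.
    """
    n_fluid = int(np.isin(stage.labels, (int(Label.IVS_FLUID), int(Label.TOP_OUTLET))).sum())
    n_solid = int((stage.labels == int(Label.VILLOUS_SOLID)).sum())
    if n_fluid + n_solid == 0:
        raise UndefinedPorosityError("stage has no intervillous region")
    return n_fluid / (n_fluid + n_solid)


@dataclass
class ConnectivityReport:
    connected: bool
    path_witness: list[tuple[int, int, int]] | None
    n_fluid: int
    n_reachable: int


def check_connectivity(stage: MorphologicalStage) -> ConnectivityReport:
    """6-connected flood fill from the inlet; witness voxel path when connected."""
    labels = stage.labels
    fluid = stage.fluid_mask()
    shape = labels.shape
    flat_fluid = fluid.ravel()
    parent = np.full(flat_fluid.size, -1, dtype=np.int64)
    visited = np.zeros(flat_fluid.size, dtype=bool)
    seeds = np.flatnonzero((labels == int(Label.INLET)).ravel())
    queue = deque(int(s) for s in seeds)
    visited[seeds] = True
    strides = (shape[1] * shape[2], shape[2], 1)
    goal = -1
    top_flat = np.zeros(flat_fluid.size, dtype=bool)
    top_flat.reshape(shape)[:, :, -1] = labels[:, :, -1] == int(Label.TOP_OUTLET)
    while queue:
        cur = queue.popleft()
        if top_flat[cur]:
            goal = cur
            break
        i, rem = divmod(cur, strides[0])
        j, k = divmod(rem, strides[1])
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            nxt = ni * strides[0] + nj * strides[1] + nk
            if flat_fluid[nxt] and not visited[nxt]:
                visited[nxt] = True
                parent[nxt] = cur
                queue.append(nxt)
    n_fluid = int(flat_fluid.sum())
    n_reach = int(visited.sum())
    if goal < 0:
        return ConnectivityReport(False, None, n_fluid, n_reach)
    path = []
    cur = goal
    while cur >= 0:
        i, rem = divmod(cur, strides[0])
        j, k = divmod(rem, strides[1])
        path.append((int(i), int(j), int(k)))
        cur = int(parent[cur])
    path.reverse()
    return ConnectivityReport(True, path, n_fluid, n_reach)


# ---------------------------------------------------------------------------
# Benchmark stages (straight geometries with exact analytic walls)

def straight_tube_stage(
    radius_mm: float = 0.17,
    length_mm: float = 10.0,
    n_across: int = 14,
    hz_mm: float | None = None,
) -> MorphologicalStage:
    """3-D straight tube along z: inlet at the bottom, outlet at the top.

    The cross-section spacing resolves the diameter with ``n_across`` voxels;
    axial spacing defaults to the in-plane spacing (set ``hz_mm`` coarser for
    long tubes -- fully developed flow is axially smooth).
    """
    h = 2 * radius_mm / n_across
    hz = hz_mm if hz_mm is not None else h
    n_side = n_across + 4
    nz = max(4, int(round(length_mm / hz)))
    grid = GridSpec((n_side * h * 1000, n_side * h * 1000, nz * hz * 1000), (n_side, n_side, nz))
    xs = (np.arange(n_side) + 0.5) * h
    c = n_side * h / 2
    X, Y = np.meshgrid(xs - c, xs - c, indexing="ij")
    disk = X**2 + Y**2 < radius_mm**2
    labels = np.full(grid.shape, int(Label.WALL), dtype=np.int8)
    labels[disk, :] = int(Label.ARTERY_LUMEN)
    labels[:, :, 0][disk] = int(Label.INLET)
    labels[:, :, -1][disk] = int(Label.TOP_OUTLET)
    stage = MorphologicalStage(grid=grid, labels=labels)
    stage.wall_primitives = [{
        "kind": "channel", "center_xy": (c, c), "helix_radius": 0.0, "n_turns": 0.0,
        "z_top": nz * hz, "r_lumen": radius_mm, "r_mouth": radius_mm,
        "funnel_length": 1.0, "two_d": False,
    }]
    area = float(disk.sum()) * h * h
    stage.provenance = {
        "kind": "straight_tube", "radius_mm": radius_mm, "length_mm": nz * hz,
        "effective_radius_mm": math.sqrt(area / math.pi), "n_across": n_across,
        "lumen_area_mm2": area,
    }
    return stage


def channel_stage_2d(
    gap_mm: float = 0.4,
    length_mm: float = 1.2,
    n_across: int = 20,
    wall_cells: int = 1,
) -> MorphologicalStage:
    """Planar straight channel along z with solid side walls (no-slip on both)."""
    h = gap_mm / n_across
    nx = n_across + 2 * wall_cells
    nz = max(4, int(round(length_mm / h)))
    grid = GridSpec((nx * h * 1000, h * 1000, nz * h * 1000), (nx, 1, nz))
    labels = np.full(grid.shape, int(Label.ARTERY_LUMEN), dtype=np.int8)
    labels[:wall_cells] = int(Label.WALL)
    labels[nx - wall_cells:] = int(Label.WALL)
    interior = labels[:, 0, 0] != int(Label.WALL)
    labels[interior, :, 0] = int(Label.INLET)
    labels[interior, :, -1] = int(Label.TOP_OUTLET)
    stage = MorphologicalStage(grid=grid, labels=labels)
    x_lo = wall_cells * h
    x_hi = (nx - wall_cells) * h
    stage.wall_primitives = [
        {"kind": "plane", "axis": 0, "pos": x_lo, "side": 1},
        {"kind": "plane", "axis": 0, "pos": x_hi, "side": -1},
    ]
    stage.provenance = {"kind": "channel_2d", "gap_mm": gap_mm, "length_mm": nz * h,
                        "n_across": n_across}
    return stage


def closed_box_stage(n: int = 32, size_mm: float = 1.0) -> MorphologicalStage:
    """Planar closed cavity (no inlet, no outlet); used for decay/stability checks."""
    h = size_mm / n
    grid = GridSpec((size_mm * 1000, h * 1000, size_mm * 1000), (n, 1, n))
    labels = np.full(grid.shape, int(Label.IVS_FLUID), dtype=np.int8)
    stage = MorphologicalStage(grid=grid, labels=labels)
    stage.provenance = {"kind": "closed_box", "n": n, "size_mm": size_mm}
    return stage


# ---------------------------------------------------------------------------
# I/O

def save_stage_vtk(stage: MorphologicalStage, path: str | Path) -> None:
    """Legacy-ASCII VTK structured points with the integer label array, plus a
    JSON provenance sidecar."""
    from .vtkio import write_structured_points

    path = Path(path)
    write_structured_points(
        path,
        spacing_mm=stage.grid.spacing_mm,
        cell_arrays={"label": stage.labels.astype(np.int32)},
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(stage.provenance, indent=2, default=float)
    )


def save_stage_h5(stage: MorphologicalStage, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=stage.labels, compression="gzip")
        f.attrs["extent_um"] = stage.grid.extent_um
        f.attrs["shape"] = stage.grid.shape
        f.attrs["provenance"] = json.dumps(stage.provenance, default=float)
        f.attrs["wall_primitives"] = json.dumps(stage.wall_primitives, default=float)


def load_stage_h5(path: str | Path) -> MorphologicalStage:
    import h5py

    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        grid = GridSpec(tuple(f.attrs["extent_um"]), tuple(int(n) for n in f.attrs["shape"]))
        prov = json.loads(f.attrs["provenance"])
        prims = json.loads(f.attrs["wall_primitives"])
    for p in prims:  # JSON round-trips tuples as lists
        for k, v in p.items():
            if isinstance(v, list):
                p[k] = tuple(v)
    return MorphologicalStage(grid=grid, labels=labels.astype(np.int8),
                              provenance=prov, wall_primitives=prims)
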