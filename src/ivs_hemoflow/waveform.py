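"""Uterine-artery Doppler waveform synthesis and the conversion chain to the
spiral-artery inlet.

The maternal inflow boundary condition of the intervillous-space (IVS) flow
problem is derived from uterine-artery Doppler velocimetry in four steps:

1. a periodic uterine-artery velocity waveform v(t) [cm/s] (measured trace or
   the synthetic template below);
2. volumetric flow per uterine artery, Q(t) = v(t) * pi (d_AU/2)^2, with the
   standard uterine-artery diameter d_AU = 3.0 mm;
3. equal partition of the summed left+right flow over n = 130 spiral
   arteries, q_SA(t) = (Q_l + Q_r)/n;
4. back-conversion to a plug inlet velocity through the reconstructed
   spiral-artery inlet diameter d_in = 0.34 mm.

Every step is linear in the input velocity, so scaling peak-systolic and
end-diastolic velocity by k scales the spiral-artery cycle-mean flow by k.

The synthetic template is piecewise smooth and C1-periodic: a squared-sine
systolic pulse on a diastolic plateau, with an optional Gaussian post-systolic
dip ("dicrotic notch", the waveform signature of the IUGR/PE profile).
Reverse flow is not modelled; velocities are non-negative everywhere.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VelocityWaveform",
    "FlowWaveform",
    "WaveformParams",
    "VesselGeometryConstants",
    "WaveformConfigError",
    "GridMismatchError",
    "synthesize_uterine_waveform",
    "waveform_value",
    "velocity_to_flow",
    "partition_to_spiral_artery",
    "flow_to_inlet_velocity",
    "cycle_mean",
    "params_for_cycle_mean",
    "read_waveform_csv",
    "write_waveform_csv",
]


class WaveformConfigError(ValueError):
    """Waveform parameters are inconsistent (e.g. notch inside the systolic upstroke)."""


class GridMismatchError(ValueError):
    """Two waveforms do not share a sampling grid; resample explicitly first."""


def _check_grid(t: np.ndarray, period: float, n_cycles: int) -> None:
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time axis must be 1-D with at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time samples must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time samples must be uniform")
    span = t[-1] - t[0] + dt[0]
    if not math.isclose(span, n_cycles * period, rel_tol=1e-6):
        raise ValueError(
            f"samples cover {span:.6g} s, expected n_cycles*period = {n_cycles * period:.6g} s"
        )


@dataclass(frozen=True)
class VelocityWaveform:
    """Periodic velocity time series (cm/s) on a uniform grid.

    ``t`` holds left sample edges: t[0] = 0, t[-1] = n_cycles*period - dt, so
    the samples tile the cycles exactly and the trapezoidal mean over the
    periodic extension equals the plain sample mean.
    """

    t: np.ndarray
    v: np.ndarray
    period: float
    n_cycles: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, float))
        object.__setattr__(self, "v", np.asarray(self.v, float))
        if self.period <= 0 or self.n_cycles < 1:
            raise ValueError("period must be positive, n_cycles >= 1")
        _check_grid(self.t, self.period, self.n_cycles)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have the same shape")
        if np.any(self.v < 0):
            raise ValueError("reverse flow is not modelled: v must be >= 0 everywhere")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def at(self, time: float | np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of v at arbitrary times (s)."""
        tau = np.mod(time, self.period * self.n_cycles)
        tp = np.concatenate([self.t, [self.t[-1] + self.dt]])
        vp = np.concatenate([self.v, [self.v[0]]])
        return np.interp(tau, tp, vp)


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic volumetric flow series (ml/s) on the same grid grammar as velocity."""

    t: np.ndarray
    q: np.ndarray
    period: float
    n_cycles: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, float))
        object.__setattr__(self, "q", np.asarray(self.q, float))
        if self.period <= 0 or self.n_cycles < 1:
            raise ValueError("period must be positive, n_cycles >= 1")
        _check_grid(self.t, self.period, self.n_cycles)
        if self.t.shape != self.q.shape:
            raise ValueError("t and q must have the same shape")
        if np.any(self.q < 0):
            raise ValueError("flow must be >= 0 everywhere")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def at(self, time: float | np.ndarray) -> np.ndarray:
        tau = np.mod(time, self.period * self.n_cycles)
        tp = np.concatenate([self.t, [self.t[-1] + self.dt]])
        qp = np.concatenate([self.q, [self.q[0]]])
        return np.interp(tau, tp, qp)


@dataclass(frozen=True)
class WaveformParams:
    """Shape descriptors of the synthetic uterine-artery waveform.

    psv/edv: peak-systolic and end-diastolic velocity (cm/s); period (s);
    systolic_fraction: fraction of the cycle occupied by the systolic pulse;
    notch_depth: fractional depth of the post-systolic dip relative to the
    local plateau (0 = no notch); notch_time_fraction: cycle position of the
    notch centre; notch_width_fraction: Gaussian sigma as a cycle fraction.
    """

    psv: float
    edv: float
    period: float = 0.8
    systolic_fraction: float = 0.35
    notch_depth: float = 0.0
    notch_time_fraction: float = 0.5
    notch_width_fraction: float = 0.04
    n_cycles: int = 1
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 <= self.edv <= self.psv):
            raise WaveformConfigError("need 0 <= edv <= psv")
        if not (0 <= self.notch_depth < 1):
            raise WaveformConfigError("need 0 <= notch_depth < 1")
        if not (0 < self.systolic_fraction < 1):
            raise WaveformConfigError("need 0 < systolic_fraction < 1")
        if self.period <= 0 or self.dt <= 0 or self.n_cycles < 1:
            raise WaveformConfigError("period, dt positive; n_cycles >= 1")
        if self.notch_depth > 0 and self.notch_time_fraction < self.systolic_fraction:
            raise WaveformConfigError(
                "notch centre lies inside the systolic pulse; "
                f"need notch_time_fraction >= systolic_fraction ({self.systolic_fraction})"
            )


@dataclass(frozen=True)
class VesselGeometryConstants:
    """Vessel constants of the conversion chain.

    d_au_mm: uterine-artery diameter; n_spiral: spiral arteries per placenta;
    d_inlet_mm: reconstructed spiral-artery inlet diameter.
    """

    d_au_mm: float = 3.0
    n_spiral: int = 130
    d_inlet_mm: float = 0.34

    def __post_init__(self) -> None:
        if not (self.d_au_mm > 0 and self.n_spiral > 0 and self.d_inlet_mm > 0):
            raise ValueError("all vessel constants must be positive")


def waveform_value(params: WaveformParams, t: np.ndarray | float) -> np.ndarray:
    """Continuous template v(t) in cm/s (periodic; vectorised).

    Systole [0, sf*T]: edv + (psv-edv)*sin^2(pi t / (sf*T)); diastole: edv
    plateau; optional Gaussian notch dip of depth notch_depth*edv.
    """
    T = params.period
    tau = np.mod(np.asarray(t, float), T)
    ts = params.systolic_fraction * T
    v = np.full_like(tau, params.edv)
    sys = tau < ts
    v = np.where(
        sys, params.edv + (params.psv - params.edv) * np.sin(np.pi * tau / ts) ** 2, v
    )
    if params.notch_depth > 0:
        tn = params.notch_time_fraction * T
        sigma = params.notch_width_fraction * T
        # nearest periodic image so the dip is periodic to machine tolerance
        dtau = tau - tn
        dtau = dtau - T * np.round(dtau / T)
        v = v - params.notch_depth * params.edv * np.exp(-0.5 * (dtau / sigma) ** 2)
    return v


def synthesize_uterine_waveform(params: WaveformParams) -> VelocityWaveform:
    """Sample the template on a uniform grid covering n_cycles periods."""
    n_per = int(round(params.period / params.dt))
    if n_per < 8 or not math.isclose(n_per * params.dt, params.period, rel_tol=1e-9):
        raise WaveformConfigError("dt must divide the period and give >= 8 samples/cycle")
    t = np.arange(n_per * params.n_cycles) * params.dt
    return VelocityWaveform(t, waveform_value(params, t), params.period, params.n_cycles)


def template_cycle_mean(params: WaveformParams) -> float:
    """Closed-form cycle mean of the template (cm/s); Gaussian tails neglected."""
    sf = params.systolic_fraction
    mean = params.edv + (params.psv - params.edv) * sf / 2
    if params.notch_depth > 0:
        mean -= (
            params.notch_depth * params.edv * params.notch_width_fraction * math.sqrt(2 * math.pi)
        )
    return mean


def params_for_cycle_mean(target_mean: float, params: WaveformParams) -> WaveformParams:
    """Solve for edv (closed form) so the template's cycle mean hits ``target_mean``.

    The mean is affine in edv at fixed psv/shape, so no iteration is needed.
    """
    sf = params.systolic_fraction
    notch_mass = (
        params.notch_depth * params.notch_width_fraction * math.sqrt(2 * math.pi)
        if params.notch_depth > 0
        else 0.0
    )
    # mean = edv*(1 - sf/2 - notch_mass) + psv*sf/2
    coeff = 1 - sf / 2 - notch_mass
    edv = (target_mean - params.psv * sf / 2) / coeff
    if not (0 <= edv <= params.psv):
        raise WaveformConfigError(
            f"target mean {target_mean} cm/s not reachable with psv={params.psv}"
        )
    return replace(params, edv=edv)


def velocity_to_flow(w: VelocityWaveform, d_mm: float) -> FlowWaveform:
    """Q(t) = v(t) * pi (d/2)^2; cm/s times mm^2 handled as mm^3/s = 1e-3 ml/s."""
    if d_mm <= 0:
        raise ValueError("diameter must be positive")
    area_mm2 = math.pi * (d_mm / 2) ** 2
    q_mm3_s = (w.v * 10.0) * area_mm2  # cm/s -> mm/s
    return FlowWaveform(w.t.copy(), q_mm3_s / 1000.0, w.period, w.n_cycles)


def partition_to_spiral_artery(
    q_left: FlowWaveform, q_right: FlowWaveform, n: int
) -> FlowWaveform:
    """q_SA(t) = (Q_l(t) + Q_r(t)) / n on a shared sampling grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if (
        q_left.t.shape != q_right.t.shape
        or not np.array_equal(q_left.t, q_right.t)
        or q_left.period != q_right.period
        or q_left.n_cycles != q_right.n_cycles
    ):
        raise GridMismatchError(
            "left/right flow waveforms are on different sampling grids; "
            "resample explicitly before partitioning"
        )
    return FlowWaveform(
        q_left.t.copy(), (q_left.q + q_right.q) / n, q_left.period, q_left.n_cycles
    )


def flow_to_inlet_velocity(q_sa: FlowWaveform, d_inlet_mm: float) -> VelocityWaveform:
    """v_in(t) = q_SA(t) / (pi (d/2)^2), returned in cm/s."""
    if d_inlet_mm <= 0:
        raise ValueError("inlet diameter must be positive")
    area_mm2 = math.pi * (d_inlet_mm / 2) ** 2
    v_cm_s = (q_sa.q * 1000.0) / area_mm2 / 10.0  # ml/s -> mm^3/s -> mm/s -> cm/s
    return VelocityWaveform(q_sa.t.copy(), v_cm_s, q_sa.period, q_sa.n_cycles)


def cycle_mean(q: FlowWaveform | VelocityWaveform) -> float:
    """Trapezoidal time-average over the integer number of periods covered.

    The sample grid tiles the cycles exactly (left edges), so the periodic
    trapezoidal rule reduces to the plain sample mean.
    """
    y = q.q if isinstance(q, FlowWaveform) else q.v
    return float(np.mean(y))


def write_waveform_csv(w: VelocityWaveform, path: str | Path) -> None:
    """Two-column CSV ``t_s,v_cm_s`` plus a JSON sidecar with period/n_cycles."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "v_cm_s"])
        for ti, vi in zip(w.t, w.v):
            writer.writerow([repr(float(ti)), repr(float(vi))])
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"period_s": w.period, "n_cycles": w.n_cycles}))


def read_waveform_csv(
    path: str | Path, period: float | None = None, n_cycles: int | None = None
) -> VelocityWaveform:
    """Read a measured or exported trace; period/n_cycles from args or JSON sidecar."""
    path = Path(path)
    if period is None or n_cycles is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no period/n_cycles given and sidecar {sidecar} not found"
            )
        meta = json.loads(sidecar.read_text())
        period = period if period is not None else float(meta["period_s"])
        n_cycles = n_cycles if n_cycles is not None else int(meta["n_cycles"])
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["t_s", "v_cm_s"]:
            raise ValueError(f"expected header 't_s,v_cm_s', got {header!r}")
        rows = [(float(r[0]), float(r[1])) for r in reader]
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    if np.any(v < 0):
        raise ValueError("imported trace contains reverse flow (v < 0); not modelled")
    return VelocityWaveform(t, v, period, n_cycles)
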