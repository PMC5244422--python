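"""Doppler waveform synthesis and the uterine-artery -> spiral-artery
conversion chain, against closed-form and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ivs_hemoflow.waveform import (
    FlowWaveform,
    GridMismatchError,
    VelocityWaveform,
    WaveformConfigError,
    WaveformParams,
    cycle_mean,
    flow_to_inlet_velocity,
    params_for_cycle_mean,
    partition_to_spiral_artery,
    read_waveform_csv,
    synthesize_uterine_waveform,
    velocity_to_flow,
    waveform_value,
    write_waveform_csv,
)


def test_flat_degenerate_case_is_constant():
    w = synthesize_uterine_waveform(WaveformParams(psv=40.0, edv=40.0))
    assert np.allclose(w.v, 40.0)


def test_template_hits_psv_and_diastolic_plateau():
    w = synthesize_uterine_waveform(WaveformParams(psv=70.0, edv=20.0))
    assert abs(w.v.max() - 70.0) < 0.5
    assert abs(w.v[-1] - 20.0) < 0.5
    assert np.all(w.v >= 0)


def test_notch_strictly_lowers_cycle_mean():
    """Quadrature oracle: the dicrotic notch removes positive area from the
    cycle, lowering mean velocity (and hence mean flow)."""
    base = WaveformParams(psv=70.0, edv=20.0, notch_depth=0.0)
    notched = WaveformParams(psv=70.0, edv=20.0, notch_depth=0.5)
    m0 = quad(lambda t: waveform_value(base, t), 0, base.period, limit=200)[0]
    m1 = quad(lambda t: waveform_value(notched, t), 0, base.period, limit=200)[0]
    assert m1 < m0
    w0 = synthesize_uterine_waveform(base)
    w1 = synthesize_uterine_waveform(notched)
    assert cycle_mean(w1) < cycle_mean(w0)


def test_notch_inside_systolic_upstroke_rejected():
    with pytest.raises(WaveformConfigError):
        WaveformParams(psv=70.0, edv=20.0, notch_depth=0.3, notch_time_fraction=0.1)


def test_velocity_to_flow_closed_form():
    w = synthesize_uterine_waveform(WaveformParams(psv=10.0, edv=10.0))
    q = velocity_to_flow(w, 3.0)
    assert np.allclose(q.q, 0.70686, atol=5e-6)  # pi * 1.5^2 * 100 mm^3/s
    assert np.allclose(velocity_to_flow(
        VelocityWaveform(w.t, np.zeros_like(w.v), w.period), 3.0).q, 0.0)


@given(k=st.floats(0.1, 5.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_conversion_chain_is_linear_in_velocity(k):
    p0 = WaveformParams(psv=60.0, edv=20.0)
    pk = WaveformParams(psv=60.0 * k, edv=20.0 * k)
    q0 = velocity_to_flow(synthesize_uterine_waveform(p0), 3.0)
    qk = velocity_to_flow(synthesize_uterine_waveform(pk), 3.0)
    sa0 = partition_to_spiral_artery(q0, q0, 130)
    sak = partition_to_spiral_artery(qk, qk, 130)
    assert cycle_mean(sak) == pytest.approx(k * cycle_mean(sa0), rel=1e-12)


def test_partition_closed_form_and_conservation():
    w = synthesize_uterine_waveform(WaveformParams(psv=10.0, edv=10.0))
    q = velocity_to_flow(w, 3.0)
    sa = partition_to_spiral_artery(q, q, 130)
    assert np.allclose(sa.q, 0.010875, atol=1e-5)
    # exact conservation by construction
    assert np.all(130 * sa.q == q.q + q.q)
    ident = partition_to_spiral_artery(
        q, FlowWaveform(q.t, np.zeros_like(q.q), q.period), 1)
    assert np.array_equal(ident.q, q.q)


def test_partition_rejects_mismatched_grids():
    w1 = synthesize_uterine_waveform(WaveformParams(psv=10.0, edv=10.0, dt=1e-3))
    w2 = synthesize_uterine_waveform(WaveformParams(psv=10.0, edv=10.0, dt=2e-3))
    with pytest.raises(GridMismatchError):
        partition_to_spiral_artery(velocity_to_flow(w1, 3.0), velocity_to_flow(w2, 3.0), 130)


def test_inlet_velocity_closed_form_and_roundtrip():
    w = synthesize_uterine_waveform(WaveformParams(psv=10.0, edv=10.0))
    q = FlowWaveform(w.t, np.full_like(w.v, 0.031), w.period)
    v_in = flow_to_inlet_velocity(q, 0.34)
    assert np.allclose(v_in.v, 34.1, atol=0.1)
    # inverse pair to machine precision
    back = velocity_to_flow(v_in, 0.34)
    assert np.allclose(back.q, q.q, rtol=1e-14)
    # halving the diameter quadruples the velocity
    v_half = flow_to_inlet_velocity(q, 0.17)
    assert np.allclose(v_half.v, 4 * v_in.v, rtol=1e-12)


def test_cycle_mean_trivial_and_quadrature():
    w = synthesize_uterine_waveform(WaveformParams(psv=30.0, edv=30.0, n_cycles=2))
    assert cycle_mean(w) == pytest.approx(30.0)
    # sinusoid over integer cycles averages to its offset
    t = np.arange(1600) * 1e-3
    v = 20.0 + 5.0 * np.sin(2 * np.pi * t / 0.8)
    assert cycle_mean(VelocityWaveform(t, v, 0.8, 2)) == pytest.approx(20.0, abs=1e-12)
    # template sampled at dt = 1e-3 vs adaptive quadrature
    p = WaveformParams(psv=65.0, edv=15.0, notch_depth=0.4, dt=1e-3)
    exact = quad(lambda x: waveform_value(p, x), 0, p.period, limit=400)[0] / p.period
    sampled = cycle_mean(synthesize_uterine_waveform(p))
    assert sampled == pytest.approx(exact, rel=1e-6)


def test_params_for_cycle_mean_is_exact():
    p = params_for_cycle_mean(28.5, WaveformParams(psv=60.0, edv=30.0))
    got = cycle_mean(synthesize_uterine_waveform(p))
    assert got == pytest.approx(28.5, rel=1e-6)


def test_reverse_flow_rejected():
    t = np.arange(800) * 1e-3
    with pytest.raises(ValueError):
        VelocityWaveform(t, np.full_like(t, -1.0), 0.8)


def test_csv_roundtrip(tmp_path):
    w = synthesize_uterine_waveform(WaveformParams(psv=55.0, edv=18.0, notch_depth=0.3))
    path = tmp_path / "trace.csv"
    write_waveform_csv(w, path)
    back = read_waveform_csv(path)
    assert back.period == w.period
    assert np.allclose(back.v, w.v)
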