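import numpy as np
import pytest

import seqshim as ss
from helpers_oracle import (
    polar_grid_minimum,
    quadrature_scale_bisection,
    random_two_channel_instance,
)
from seqshim.pulse_timing import RFPulse, SequenceTiming, peak_amp_for_flip
from seqshim.sar_model import calibrate
from seqshim.shim_core import (
    ConstraintSet,
    SolverOptions,
    build_constraints,
    flip_metrics,
    solve_min_bias,
    solve_mse,
    solve_quadrature,
)


@pytest.fixture(scope="module")
def cons_default(gauss_pulse, limits, sens, vops):
    pulse = RFPulse(tau=1.7, preset=gauss_pulse.preset)
    timing = SequenceTiming(tr=3.4)
    p_max = peak_amp_for_flip(sens.theta0, pulse)
    cal = calibrate(sens, ss.quadrature_weights(sens.n_channels), p_max)
    return build_constraints(pulse, timing, limits, cal, vops)


def test_amplitude_caps_reproduce_hardware_point(gauss_pulse, limits, sens, vops):
    """With P_peak = 1 kW and A = 2.5 W/μT², the per-channel peak-field
    cap |wⱼ|·p_max is exactly 20 μT, independent of τ."""
    for tau in (0.8, 1.2, 2.5):
        pulse = RFPulse(tau=tau, preset="measured-gaussian")
        timing = SequenceTiming(tr=ss.min_tr(tau))
        p_max = peak_amp_for_flip(sens.theta0, pulse)
        cal = calibrate(sens, ss.quadrature_weights(sens.n_channels), p_max)
        cons = build_constraints(pulse, timing, limits, cal, vops)
        assert cons.amp_peak_cap * p_max == pytest.approx(20.0, rel=1e-9)
        assert cons.amp_peak_cap > 0 and cons.amp_avg_cap > 0
        assert np.isfinite(cons.local_qcap) and cons.local_qcap > 0


def test_sar_cap_scales_with_tr(gauss_pulse, limits, sens, vops):
    """Doubling TR at fixed τ doubles the allowed quadratic form for the
    same SAR limit (SAR ∝ 1/(τ·TR))."""
    pulse = RFPulse(tau=1.5, preset="measured-gaussian")
    p_max = peak_amp_for_flip(sens.theta0, pulse)
    cal = calibrate(sens, ss.quadrature_weights(sens.n_channels), p_max)
    c1 = build_constraints(pulse, SequenceTiming(tr=3.2), limits, cal, vops)
    c2 = build_constraints(pulse, SequenceTiming(tr=6.4), limits, cal, vops)
    assert c2.local_qcap == pytest.approx(2 * c1.local_qcap, rel=1e-12)
    assert c2.wb_qcap == pytest.approx(2 * c1.wb_qcap, rel=1e-12)


def test_single_channel_uniform_identity():
    """One channel with uniform unit sensitivity and generous caps: the
    shim is exactly θ₀/S_θ, zero cost, zero bias."""
    S = ss.ChannelSensitivities(
        s=np.full((6, 1), 1.0 + 0j), roi=np.arange(6)
    ).with_target(np.deg2rad(45))
    cons = ConstraintSet(
        amp_peak_cap=100.0,
        amp_avg_cap=100.0,
        local_matrices=np.ones((1, 1, 1), dtype=complex),
        local_qcap=1e6,
        wholebody=None,
        wb_qcap=1.0,
    )
    sol = solve_mse(S, cons)
    assert sol.w[0] == pytest.approx(1.0 + 0j, abs=1e-7)
    assert sol.objective == pytest.approx(0.0, abs=1e-12)
    assert sol.bias_pct == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("mode", ["mse", "min_bias"])
def test_inner_solver_against_grid_oracle(mode):
    """On seeded 2-channel/12-voxel instances with a tight SAR cap, the
    variable-exchange solution is never worse than the exhaustive
    201×201×201 polar-grid minimum by more than 1% (it is usually
    better, the grid being discrete)."""
    fn = solve_mse if mode == "mse" else solve_min_bias
    for seed in range(3):
        S, cons = random_two_channel_instance(seed)
        sol = fn(S, cons)
        grid = polar_grid_minimum(S, cons, mode)
        assert sol.objective <= grid * 1.01
        assert cons.satisfied(sol.w, rtol=1e-6)


def test_exchange_cost_monotone():
    """The magnitude-LS cost of the running-best iterate never increases
    across variable exchanges."""
    S, cons = random_two_channel_instance(9)
    costs = []
    for k in range(1, 8):
        sol = solve_mse(S, cons, SolverOptions(max_exchange=k, tol=0.0,
                                               phase_restarts=0))
        costs.append(sol.objective)
    assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))


def test_relaxation_monotonicity():
    """Enlarging any cap never increases the optimal inner cost."""
    from dataclasses import replace

    S, cons = random_two_channel_instance(4)
    base = solve_mse(S, cons).objective
    for change in (
        {"amp_peak_cap": cons.amp_peak_cap * 3},
        {"amp_avg_cap": cons.amp_avg_cap * 3},
        {"local_qcap": cons.local_qcap * 3},
        {"wb_qcap": cons.wb_qcap * 3},
    ):
        relaxed = replace(cons, **change)
        assert solve_mse(S, relaxed).objective <= base * (1 + 1e-6)


def test_min_bias_zero_when_caps_generous():
    rng = np.random.default_rng(17)
    s = 1 + 0.4 * (rng.standard_normal((15, 4)) + 1j * rng.standard_normal((15, 4)))
    S = ss.ChannelSensitivities(s=s, roi=np.arange(15)).with_target(np.deg2rad(45))
    cons = ConstraintSet(
        amp_peak_cap=1e3,
        amp_avg_cap=1e3,
        local_matrices=np.eye(4, dtype=complex)[None],
        local_qcap=1e9,
        wholebody=None,
        wb_qcap=1.0,
    )
    sol = solve_min_bias(S, cons)
    assert abs(sol.bias_pct) < 1e-6


def test_min_bias_cap_bound_case():
    """With a binding SAR cap the achieved mean stays below target and at
    least one constraint family is active."""
    S, cons = random_two_channel_instance(21)
    sol = solve_min_bias(S, cons)
    mean_flip = sol.flip_map.mean()
    assert mean_flip < S.theta0
    assert sol.active, "expected an active constraint at a cap-bound optimum"
    # The scaled-quadrature point is feasible, so its bias is a bound.
    quad = solve_quadrature(S, cons)
    assert sol.objective <= quad.objective * (1 + 1e-9)


def test_quadrature_closed_form_matches_bisection():
    for seed in range(6):
        S, cons = random_two_channel_instance(seed + 100)
        wq = ss.quadrature_weights(2)
        sol = solve_quadrature(S, cons)
        d_oracle = quadrature_scale_bisection(S, cons, wq)
        d_closed = np.abs(sol.w[0])
        assert d_closed == pytest.approx(d_oracle, rel=1e-6, abs=1e-9)


def test_mse_beats_scaled_quadrature(sens, cons_default):
    """Quadrature lies inside the feasible set, so the MSE optimum can
    never have a larger magnitude-LS cost than the scaled-quadrature
    point (evaluated under the same Σ(|S_θw|−θ₀)² functional)."""
    quad = solve_quadrature(sens, cons_default)
    mse = solve_mse(sens, cons_default)
    quad_mse_cost = np.sum((np.abs(sens.s_theta @ quad.w) - sens.theta0) ** 2)
    assert mse.objective <= quad_mse_cost * (1 + 1e-9)
    assert cons_default.satisfied(mse.w, rtol=1e-6)


def test_flip_metrics():
    assert flip_metrics(np.full(5, np.pi / 4), np.pi / 4) == (0.0, 0.0)
    bias, cov = flip_metrics(np.array([1.0, 3.0]), 2.0)
    assert bias == 0.0 and cov == pytest.approx(0.5)
    bias, _ = flip_metrics(np.full(3, np.deg2rad(42.75)), np.deg2rad(45.0))
    assert bias == pytest.approx(-5.0, rel=1e-12)
    with pytest.raises(ss.shim_core.UndefinedMetricError):
        flip_metrics(np.zeros(4), 1.0)


def test_infeasible_constraints_typed_result():
    S, cons = random_two_channel_instance(2)
    from dataclasses import replace

    bad = replace(cons, amp_peak_cap=-1.0)
    sol = solve_mse(S, bad)
    assert not sol.feasible
    assert not np.isfinite(sol.objective)
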