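"""Constrained RF shimming: constraint assembly and inner solvers.

Given per-channel transmit sensitivities over an ROI, a target flip angle
θ₀, and hardware/safety limits, the inner problem finds complex shim
weights w subject to, for a given pulse duration τ and repetition time TR:

* per-channel peak-power amplitude caps     |wⱼ| ≤ √(P_peak/A)/p_max,
* per-channel average-power amplitude caps  |wⱼ| ≤ √(P_av/(A·Δ))/p_max,
* local SAR                max_i w*Q_i w · B1⁺_achieved²·Δ ≤ lSAR_max,
* whole-body SAR                 w*Q_wb w · B1⁺_achieved²·Δ ≤ wbSAR_max.

Because p_max, Δ and B1⁺_achieved are functions of (τ, TR), so are all
caps; they must be rebuilt whenever the timing changes.

Two objectives are supported.  The *minimum bias* problem drives the mean
ROI flip angle to target; the *minimum squared error* (MSE) problem fits
the full flip-angle map to the target magnitude.  Both involve |S_θw| and
are non-convex; they are solved as magnitude least squares by the
variable-exchange method: alternate a convex fit with the auxiliary phase
z held fixed, then update z to the phase of the current solution.  The
convex subproblems are solved with SLSQP on the real/imag stacking of w
with analytic gradients, followed by a radial feasibility repair (w = 0
is always feasible, so shrinking toward it restores any residual
constraint violation exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .pulse_timing import RFPulse, SequenceTiming, TimingError, duty_cycle

__all__ = [
    "ChannelSensitivities",
    "HardwareLimits",
    "ConstraintSet",
    "SolverOptions",
    "ShimSolution",
    "UndefinedMetricError",
    "build_constraints",
    "solve_mse",
    "solve_min_bias",
    "solve_quadrature",
    "flip_metrics",
]


class UndefinedMetricError(ValueError):
    """Raised when a flip-angle statistic is undefined (zero mean)."""


@dataclass
class ChannelSensitivities:
    """Per-voxel × per-channel complex transmit sensitivities on an ROI.

    ``s`` is dimensionless (1 = nominal quadrature mean); ``roi`` holds
    flat voxel indices into a grid of shape ``grid_shape``.  ``theta0``
    (rad) scales the sensitivities to flip-angle units: ``s_theta = θ₀·s``.
    """

    s: np.ndarray
    roi: np.ndarray
    grid_shape: tuple[int, int] | None = None
    theta0: float | None = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=complex)
        if self.s.ndim != 2:
            raise ValueError("s must be (n_roi, n_channels)")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("sensitivities must be finite")
        if self.s.shape[0] == 1:
            warnings.warn("single-voxel ROI: statistics will be degenerate")

    @property
    def n_channels(self) -> int:
        return self.s.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.s.shape[0]

    @property
    def s_theta(self) -> np.ndarray:
        if self.theta0 is None:
            raise ValueError("theta0 not set; use with_target() first")
        return self.theta0 * self.s

    def with_target(self, theta0: float) -> "ChannelSensitivities":
        """Return a copy with the target flip angle (rad) attached."""
        if not (0 < theta0 < np.pi):
            raise ValueError(f"theta0 must lie in (0, π) rad, got {theta0}")
        return replace(self, theta0=float(theta0))


@dataclass(frozen=True)
class HardwareLimits:
    """Per-channel power limits, RF-chain gain and regulatory SAR caps.

    Defaults: 1 kW peak / 100 W average forward power per channel,
    A = 2.5 W/μT², and the IEC normal-mode limits of 10 W/kg (10 g local)
    and 2 W/kg (whole body).
    """

    p_peak: float = 1000.0
    p_av: float = 100.0
    A: float = 2.5
    lsar_max: float = 10.0
    wbsar_max: float = 2.0

    def __post_init__(self):
        for name in ("p_peak", "p_av", "A", "lsar_max", "wbsar_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"limit {name} must be positive")


@dataclass(frozen=True)
class ConstraintSet:
    """All shim constraints at one (τ, TR) operating point.

    ``local_matrices`` are the (possibly VOP-compressed) local Q-matrices;
    quadratic caps are expressed on the normalized quadratic form, i.e.
    ``w*Qw ≤ local_qcap``.  ``provenance`` records the timing and
    calibration used so stale sets are detectable.
    """

    amp_peak_cap: float
    amp_avg_cap: float
    local_matrices: np.ndarray
    local_qcap: float
    wholebody: np.ndarray | None
    wb_qcap: float
    provenance: dict = field(default_factory=dict)

    @property
    def amp_cap(self) -> float:
        return min(self.amp_peak_cap, self.amp_avg_cap)

    @property
    def n_channels(self) -> int:
        return self.local_matrices.shape[-1]

    @property
    def feasible(self) -> bool:
        return self.amp_cap > 0 and self.local_qcap > 0 and self.wb_qcap > 0

    def local_q(self, w: np.ndarray) -> np.ndarray:
        return np.einsum("j,vjk,k->v", np.conj(w), self.local_matrices, w).real

    def wb_q(self, w: np.ndarray) -> float:
        if self.wholebody is None:
            return 0.0
        return float(np.real(np.conj(w) @ self.wholebody @ w))

    def margins(self, w: np.ndarray) -> dict[str, tuple[float, float]]:
        """Map family name -> (attained value, cap)."""
        amps = np.abs(w)
        return {
            "peak_power": (float(amps.max()), self.amp_peak_cap),
            "avg_power": (float(amps.max()), self.amp_avg_cap),
            "local_sar": (float(self.local_q(w).max()), self.local_qcap),
            "wholebody_sar": (self.wb_q(w), self.wb_qcap),
        }

    def satisfied(self, w: np.ndarray, rtol: float = 1e-6) -> bool:
        return all(v <= c * (1 + rtol) for v, c in self.margins(w).values())

    def active(self, w: np.ndarray, rtol: float = 1e-3) -> list[str]:
        return [
            name
            for name, (v, c) in self.margins(w).items()
            if v >= c * (1 - rtol)
        ]

    def shrink_to_feasible(self, w: np.ndarray) -> np.ndarray:
        """Scale w toward zero until every constraint holds exactly."""
        s = 1.0
        amax = np.abs(w).max()
        if amax > 0:
            s = min(s, self.amp_cap / amax)
        for val, cap in (
            (self.local_q(w).max(), self.local_qcap),
            (self.wb_q(w), self.wb_qcap),
        ):
            if val > 0:
                s = min(s, np.sqrt(cap / val))
        if s >= 1.0:
            return w
        return w * s * (1 - 1e-12)


def build_constraints(
    pulse: RFPulse,
    timing: SequenceTiming,
    limits: HardwareLimits,
    cal,
    vops,
) -> ConstraintSet:
    """Assemble the constraint set for one (τ, TR) operating point.

    ``cal`` is a :class:`seqshim.sar_model.Calibration`; ``vops`` a VOPSet
    or a full QMatrixSet (its matrices are used for the local constraint
    and its ``wholebody`` for the whole-body constraint).
    """
    if pulse.tau <= 0 or timing.tr <= 0:
        raise TimingError("tau and TR must be positive")
    Delta = duty_cycle(pulse, timing)
    amp_peak = np.sqrt(limits.p_peak / limits.A) / cal.p_max
    amp_avg = np.sqrt(limits.p_av / (limits.A * Delta)) / cal.p_max
    sar_scale = cal.b1_achieved**2 * Delta
    matrices = getattr(vops, "matrices", None)
    if matrices is None:
        matrices = vops.local
    return ConstraintSet(
        amp_peak_cap=float(amp_peak),
        amp_avg_cap=float(amp_avg),
        local_matrices=matrices,
        local_qcap=limits.lsar_max / sar_scale,
        wholebody=vops.wholebody,
        wb_qcap=limits.wbsar_max / sar_scale,
        provenance={
            "tau": pulse.tau,
            "tr": timing.tr,
            "Delta": Delta,
            "p_max": cal.p_max,
            "b1_achieved": cal.b1_achieved,
        },
    )


@dataclass(frozen=True)
class SolverOptions:
    """Variable-exchange and SLSQP settings.

    ``max_exchange`` bounds the number of phase updates; the loop stops
    earlier when the relative cost change drops below ``tol``.
    ``phase_restarts`` adds seeded random-phase re-initializations of z
    and keeps the best local optimum (magnitude least squares is
    non-convex; the quadrature-phase start is usually but not always in
    the best basin).
    """

    max_exchange: int = 20
    tol: float = 1e-4
    slsqp_maxiter: int = 300
    slsqp_ftol: float = 1e-12
    phase_restarts: int = 2
    restart_seed: int = 0


@dataclass
class ShimSolution:
    """Result of one inner shimming solve at fixed (τ, TR)."""

    w: np.ndarray
    objective: float
    bias_pct: float
    cov: float
    flip_map: np.ndarray
    active: list[str]
    phase_ref: np.ndarray | None
    feasible: bool = True
    n_exchanges: int = 0
    mode: str = ""


def flip_metrics(
    flip_map: np.ndarray, theta0: float, roi: np.ndarray | None = None
) -> tuple[float, float]:
    """Flip-angle bias (percent of target) and coefficient of variation.

    ``bias = (mean − θ₀)/θ₀·100``; ``cov = population std / mean`` over
    the ROI.
    """
    vals = np.asarray(flip_map, dtype=float)
    if roi is not None:
        vals = vals[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = vals.mean()
    bias = (mean - theta0) / theta0 * 100.0
    if mean == 0:
        raise UndefinedMetricError("zero mean flip angle: cov undefined")
    return float(bias), float(vals.std() / mean)


def _quad_weights(n: int) -> np.ndarray:
    from .synthetic_em import quadrature_weights

    return quadrature_weights(n)


def _max_quad_scale(cons: ConstraintSet, w_quad: np.ndarray) -> float:
    """Largest d such that d·w_quad satisfies every constraint."""
    d = cons.amp_cap / np.abs(w_quad).max()
    ql = cons.local_q(w_quad).max()
    if ql > 0:
        d = min(d, np.sqrt(cons.local_qcap / ql))
    qw = cons.wb_q(w_quad)
    if qw > 0:
        d = min(d, np.sqrt(cons.wb_qcap / qw))
    return d


def _solve_fixed_phase(
    M: np.ndarray,
    t: np.ndarray,
    cons: ConstraintSet,
    x0: np.ndarray,
    opts: SolverOptions,
) -> np.ndarray:
    """Convex subproblem min ‖Mw − t‖² s.t. constraints, via SLSQP.

    Variables are the real/imag stacking x = [Re w; Im w]; all
    constraints are normalized to unit caps for conditioning.
    """
    n = cons.n_channels
    amp_cap2 = cons.amp_cap**2
    V = cons.local_matrices
    wb = cons.wholebody

    def unpack(x):
        return x[:n] + 1j * x[n:]

    def f(x):
        r = M @ unpack(x) - t
        return float(np.real(np.vdot(r, r)))

    def fgrad(x):
        w = unpack(x)
        g = M.conj().T @ (M @ w - t)
        return 2.0 * np.concatenate([g.real, g.imag])

    def c_amp(x):
        return 1.0 - (x[:n] ** 2 + x[n:] ** 2) / amp_cap2

    def c_amp_jac(x):
        jr = np.zeros((n, 2 * n))
        idx = np.arange(n)
        jr[idx, idx] = -2.0 * x[:n] / amp_cap2
        jr[idx, idx + n] = -2.0 * x[n:] / amp_cap2
        return jr

    def c_sar(x):
        w = unpack(x)
        vals = np.einsum("j,vjk,k->v", w.conj(), V, w).real
        return 1.0 - vals / cons.local_qcap

    def c_sar_jac(x):
        w = unpack(x)
        qw = V @ w  # (n_vop, n)
        return np.concatenate([-2.0 * qw.real, -2.0 * qw.imag], axis=1) / cons.local_qcap

    constraints = [
        {"type": "ineq", "fun": c_amp, "jac": c_amp_jac},
        {"type": "ineq", "fun": c_sar, "jac": c_sar_jac},
    ]
    if wb is not None:

        def c_wb(x):
            w = unpack(x)
            return np.array([1.0 - np.real(np.vdot(w, wb @ w)) / cons.wb_qcap])

        def c_wb_jac(x):
            w = unpack(x)
            qw = wb @ w
            return np.concatenate([-2.0 * qw.real, -2.0 * qw.imag])[None, :] / cons.wb_qcap

        constraints.append({"type": "ineq", "fun": c_wb, "jac": c_wb_jac})

    res = minimize(
        f,
        x0,
        jac=fgrad,
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": opts.slsqp_maxiter, "ftol": opts.slsqp_ftol},
    )
    w = unpack(res.x if np.all(np.isfinite(res.x)) else x0)
    w = cons.shrink_to_feasible(w)
    # Never return worse than the (feasible) starting point.
    w0 = cons.shrink_to_feasible(unpack(x0))
    if f(np.concatenate([w0.real, w0.imag])) < f(np.concatenate([w.real, w.imag])):
        w = w0
    return w


def _finalize(
    S: ChannelSensitivities,
    cons: ConstraintSet,
    w: np.ndarray,
    objective: float,
    z: np.ndarray | None,
    mode: str,
    n_exchanges: int,
) -> ShimSolution:
    flip = np.abs(S.s_theta @ w)
    bias, cov = flip_metrics(flip, S.theta0)
    return ShimSolution(
        w=w,
        objective=float(objective),
        bias_pct=bias,
        cov=cov,
        flip_map=flip,
        active=cons.active(w),
        phase_ref=z,
        n_exchanges=n_exchanges,
        mode=mode,
    )


def _exchange_solve(
    S: ChannelSensitivities,
    cons: ConstraintSet,
    opts: SolverOptions,
    mode: str,
    z0: np.ndarray | None,
) -> ShimSolution:
    """Variable-exchange driver shared by the MSE and minimum-bias solvers."""
    if not cons.feasible:
        n = cons.n_channels
        return ShimSolution(
            w=np.zeros(n, dtype=complex),
            objective=np.inf,
            bias_pct=-100.0,
            cov=np.nan,
            flip_map=np.zeros(S.n_voxels),
            active=[],
            phase_ref=None,
            feasible=False,
            mode=mode,
        )
    St = S.s_theta
    theta0 = S.theta0
    m = S.n_voxels
    w_quad = _quad_weights(cons.n_channels)

    def true_cost(w):
        mags = np.abs(St @ w)
        if mode == "mse":
            return float(np.sum((mags - theta0) ** 2))
        return float((mags.mean() - theta0) ** 2)

    def phase_of(w):
        field = St @ w
        z = np.ones_like(field)
        nz = field != 0
        z[nz] = field[nz] / np.abs(field[nz])
        return z

    def subproblem(z):
        if mode == "mse":
            return St, theta0 * z
        return (z.conj()[None, :] @ St) / m, np.array([theta0])

    # Feasible starting point along the quadrature direction.
    d0 = _max_quad_scale(cons, w_quad)
    quad_field = St @ w_quad
    d_target = theta0 / np.abs(quad_field).mean()
    w_start = min(d_target, d0) * w_quad

    z_inits = [z0 if z0 is not None else phase_of(w_quad)]
    if z0 is None and opts.phase_restarts > 0:
        rng = np.random.default_rng(opts.restart_seed)
        for _ in range(opts.phase_restarts):
            z_inits.append(np.exp(2j * np.pi * rng.random(m)))

    best_w, best_cost, best_z, best_k = w_start, true_cost(w_start), z_inits[0], 0
    for z_init in z_inits:
        z = z_init
        w = w_start
        prev = true_cost(w)
        for k in range(opts.max_exchange):
            M, t = subproblem(z)
            x0 = np.concatenate([w.real, w.imag])
            w = _solve_fixed_phase(M, t, cons, x0, opts)
            cost = true_cost(w)
            if cost < best_cost:
                best_w, best_cost, best_z, best_k = w, cost, z, k + 1
            if prev - cost <= opts.tol * max(prev, 1e-30):
                break
            prev = cost
            z = phase_of(w)
    return _finalize(S, cons, best_w, best_cost, best_z, mode, best_k)


def solve_mse(
    S: ChannelSensitivities,
    cons: ConstraintSet,
    opts: SolverOptions | None = None,
    z0: np.ndarray | None = None,
) -> ShimSolution:
    """Minimum-squared-error shim: fit |S_θw| to θ₀ over the ROI.

    Solved as magnitude least squares by variable exchange; the auxiliary
    phase z starts from the quadrature-mode excitation unless ``z0`` is
    given (pass the phase from a previous solve to reuse it).
    """
    return _exchange_solve(S, cons, opts or SolverOptions(), "mse", z0)


def solve_min_bias(
    S: ChannelSensitivities,
    cons: ConstraintSet,
    opts: SolverOptions | None = None,
    z0: np.ndarray | None = None,
) -> ShimSolution:
    """Minimum-bias shim: drive the mean ROI flip angle to θ₀.

    The projected image phase is removed before averaging, so the
    objective is |mean(S_θw∘z*) − θ₀|²; the flip-angle variance is left
    unconstrained.
    """
    return _exchange_solve(S, cons, opts or SolverOptions(), "min_bias", z0)


def solve_quadrature(S: ChannelSensitivities, cons: ConstraintSet) -> ShimSolution:
    """Optimal scaled-quadrature (single-channel) shim, closed form.

    With w = d·w_quad only the scale d is free, so homogeneity is fixed;
    d is the zero-bias scale θ₀/mean|S_θw_quad| clipped to the largest
    value every cap allows.
    """
    w_quad = _quad_weights(S.n_channels)
    quad_field = S.s_theta @ w_quad
    mu = np.abs(quad_field).mean()
    d_target = S.theta0 / mu
    d_max = _max_quad_scale(cons, w_quad)
    d = min(d_target, d_max)
    w = d * w_quad
    obj = (d * mu - S.theta0) ** 2
    z = quad_field / np.where(np.abs(quad_field) == 0, 1.0, np.abs(quad_field))
    return _finalize(S, cons, w, obj, z, "quadrature", 0)
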