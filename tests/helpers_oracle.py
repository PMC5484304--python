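"""Independent brute-force oracles used by the solver tests.

These deliberately avoid the library's solution paths: the shim oracle is
an exhaustive polar-grid search over per-channel amplitude and relative
phase; the quadrature oracle is a 1-D bisection on the scale factor.
"""

import numpy as np

from seqshim import ChannelSensitivities
from seqshim.shim_core import ConstraintSet


def random_two_channel_instance(seed: int, n_vox: int = 12):
    """Seeded 2-channel / 12-voxel shimming instance with a tight SAR cap."""
    rng = np.random.default_rng(seed)
    n_ch = 2
    s = 1.0 + 0.5 * (
        rng.standard_normal((n_vox, n_ch)) + 1j * rng.standard_normal((n_vox, n_ch))
    )
    S = ChannelSensitivities(s=s, roi=np.arange(n_vox)).with_target(np.deg2rad(45.0))

    def psd(scale=1.0):
        a = rng.standard_normal((n_ch, n_ch)) + 1j * rng.standard_normal((n_ch, n_ch))
        m = a @ a.conj().T
        return scale * m / np.linalg.norm(m, 2)

    local = np.stack([psd() for _ in range(3)])
    cons = ConstraintSet(
        amp_peak_cap=1.5,
        amp_avg_cap=1.2,
        local_matrices=local,
        local_qcap=0.15,
        wholebody=psd(0.3),
        wb_qcap=0.1,
    )
    return S, cons


def polar_grid_minimum(S, cons, mode: str, n_amp: int = 201, n_phase: int = 201):
    """Exhaustive minimum over amplitude×amplitude×relative-phase grid.

    The global phase of w is irrelevant to both magnitude objectives, so
    channel 1 is kept real; feasibility is enforced on the grid before
    taking the minimum.
    """
    St = S.s_theta
    th = S.theta0
    cap = cons.amp_cap
    a = np.linspace(0.0, cap, n_amp)
    A1, A2 = np.meshgrid(a, a, indexing="ij")
    best = np.inf
    mats = list(cons.local_matrices) + (
        [] if cons.wholebody is None else [cons.wholebody]
    )
    caps = [cons.local_qcap] * len(cons.local_matrices) + (
        [] if cons.wholebody is None else [cons.wb_qcap]
    )
    for phi in np.linspace(0.0, 2 * np.pi, n_phase, endpoint=False):
        w2 = np.exp(1j * phi)
        ok = np.ones_like(A1, dtype=bool)
        for q, qcap in zip(mats, caps):
            val = (
                q[0, 0].real * A1**2
                + q[1, 1].real * A2**2
                + 2 * (q[0, 1] * w2).real * A1 * A2
            )
            ok &= val <= qcap
        flip = np.abs(A1[..., None] * St[:, 0] + (A2 * w2)[..., None] * St[:, 1])
        if mode == "mse":
            cost = ((flip - th) ** 2).sum(-1)
        else:
            cost = (flip.mean(-1) - th) ** 2
        m = cost[ok].min() if ok.any() else np.inf
        best = min(best, m)
    return best


def quadrature_scale_bisection(S, cons, w_quad, tol: float = 1e-12):
    """1-D oracle for the scaled-quadrature problem: the optimal d is the
    zero-bias scale clipped to feasibility, found here by bisection on
    the feasibility indicator rather than in closed form."""
    St = S.s_theta

    def feasible(d):
        w = d * w_quad
        if np.abs(w).max() > cons.amp_cap:
            return False
        if cons.local_q(w).max() > cons.local_qcap:
            return False
        return cons.wb_q(w) <= cons.wb_qcap

    d_target = S.theta0 / np.abs(St @ w_quad).mean()
    if feasible(d_target):
        return d_target
    lo, hi = 0.0, d_target
    while hi - lo > tol * max(d_target, 1.0):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo
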