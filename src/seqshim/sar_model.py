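"""SAR evaluation from Q-matrices and virtual observation point compression.

A Q-matrix is a Hermitian positive semidefinite n_ch×n_ch matrix mapping a
shim vector to SAR at one location via ``w*Qw``.  The matrices here are
normalized to the quadrature mode: they give W/kg per unit drive when the
quadrature excitation produces a mean B1⁺ of 1 μT in the slice ROI.
Absolute SAR for a sequence follows by scaling with the square of the
achieved B1⁺ calibration and the power duty cycle:

    SAR = max_i  Re(w* Q_i w) · B1⁺_achieved² · Δ

The full local set (one matrix per voxel) is compressed with the virtual
observation points (VOP) method into a small set that provably never
underestimates the true maximum, at the price of a bounded overestimate
``ε·w*Zw`` where Z is the spectral-norm-dominating member of the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QMatrixSet",
    "VOPSet",
    "Calibration",
    "calibrate",
    "sar",
    "sar_map",
    "compress_vops",
]


@dataclass(frozen=True)
class QMatrixSet:
    """Local (per-voxel) and whole-body Q-matrices.

    ``local``: (n_vox, n_ch, n_ch) Hermitian PSD; ``wholebody``: (n_ch,
    n_ch); ``labels``: flat voxel index of each local matrix in the grid
    of shape ``grid``.
    """

    local: np.ndarray
    wholebody: np.ndarray
    labels: np.ndarray | None = None
    grid: tuple[int, int] | None = None

    def __post_init__(self):
        loc = np.asarray(self.local, dtype=complex)
        herm = np.abs(loc - loc.conj().transpose(0, 2, 1)).max()
        scale = max(np.abs(loc).max(), 1e-300)
        if herm > 1e-12 * scale:
            raise ValueError(f"local Q-matrices not Hermitian (deviation {herm:g})")
        object.__setattr__(self, "local", loc)

    @property
    def n_channels(self) -> int:
        return self.local.shape[-1]

    def __len__(self) -> int:
        return self.local.shape[0]

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        """Per-matrix quadratic forms Re(w*Q_i w) for one shim vector."""
        return np.einsum("j,vjk,k->v", np.conj(w), self.local, w).real


@dataclass(frozen=True)
class VOPSet:
    """Compressed, overestimating subset of a Q-matrix set.

    Each stored matrix already includes the ``ε·Z`` overestimation term,
    so ``max_v w*V_v w ≥ max_i w*Q_i w`` for every shim w, with excess at
    most ``ε·w*Zw``.  ``provenance`` holds the indices of the retained
    (dominating) members in the original set; ``z`` is the dominating
    matrix used for the overestimate bound.
    """

    matrices: np.ndarray
    epsilon: float
    provenance: np.ndarray
    z: np.ndarray
    wholebody: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[-1]

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        return np.einsum("j,vjk,k->v", np.conj(w), self.matrices, w).real


@dataclass(frozen=True)
class Calibration:
    """Scaling between the normalized EM model and scanning conditions.

    ``b1_achieved`` (μT) is the mean quadrature-mode B1⁺ over the slice
    ROI at the pulse peak; ``A`` (W/μT²) the amplitude-to-power gain of
    the RF chain; ``p_max`` (μT) the peak pulse amplitude.
    """

    b1_achieved: float
    A: float
    p_max: float

    def __post_init__(self):
        if self.b1_achieved <= 0 or self.A <= 0 or self.p_max <= 0:
            raise ValueError("calibration values must be positive")


class CalibrationError(ValueError):
    pass


def calibrate(S, w_quad: np.ndarray, p_max: float, A: float = 2.5) -> Calibration:
    """Quadrature-referenced calibration: ``b1_achieved = p_max·mean|S·w_quad|``
    over the ROI, matching the normalized EM model to scanning conditions.

    ``S`` is a ChannelSensitivities object or a (n_roi, n_ch) complex array.
    """
    s = getattr(S, "s", S)
    s = np.asarray(s)
    if s.size == 0:
        raise CalibrationError("empty ROI: cannot calibrate")
    mean_quad = np.abs(s @ w_quad).mean()
    return Calibration(b1_achieved=p_max * mean_quad, A=A, p_max=p_max)


def sar(
    w: np.ndarray,
    qset: QMatrixSet | VOPSet,
    cal: Calibration,
    Delta: float,
) -> tuple[float, float, int]:
    """Maximum local and whole-body SAR (W/kg) for shims ``w``.

    Returns ``(local_max, wholebody, argmax_index)`` where the index
    refers to the matrix attaining the local maximum (a voxel label for a
    full set, a VOP index for a compressed set).
    """
    w = np.asarray(w, dtype=complex)
    if w.shape != (qset.n_channels,):
        raise ValueError(
            f"shim length {w.shape} does not match {qset.n_channels} channels"
        )
    scale = cal.b1_achieved**2 * Delta
    vals = qset.evaluate(w) * scale
    idx = int(np.argmax(vals))
    wb = 0.0
    if qset.wholebody is not None:
        wb = float(np.real(np.conj(w) @ qset.wholebody @ w) * scale)
    return float(vals[idx]), wb, idx


def sar_map(
    w: np.ndarray, qset: QMatrixSet, cal: Calibration, Delta: float
) -> np.ndarray:
    """Per-voxel local SAR (W/kg).  Returns a 2-D map if the set carries
    grid labels, otherwise the flat per-matrix vector."""
    w = np.asarray(w, dtype=complex)
    vals = qset.evaluate(w) * cal.b1_achieved**2 * Delta
    if qset.grid is not None and qset.labels is not None:
        out = np.zeros(qset.grid).ravel()
        out[qset.labels] = vals
        return out.reshape(qset.grid)
    return vals


def _is_psd(mat: np.ndarray, tol_scale: float) -> bool:
    evals = np.linalg.eigvalsh(mat)
    return evals.min() >= -1e-9 * tol_scale


def compress_vops(qset: QMatrixSet, epsilon: float) -> VOPSet:
    """Greedy VOP compression with overestimate bound ``epsilon``.

    Candidates are visited in decreasing spectral-norm order (ties broken
    by original index).  A candidate Q is dominated by an existing VOP
    core V when ``V + ε·Z − Q`` is PSD, Z being the member with the
    largest spectral norm; dominated candidates are dropped, others are
    retained as new cores.  Stored VOP matrices are ``V + ε·Z`` so the
    compressed maximum never underestimates the true maximum.  With
    ``epsilon = 0`` the compression is lossless: only exactly dominated
    matrices are dropped.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be nonnegative, got {epsilon}")
    q = qset.local
    norms = np.linalg.norm(q, ord=2, axis=(1, 2))
    order = np.lexsort((np.arange(len(q)), -norms))
    z = q[order[0]]
    tol_scale = max(norms.max(), 1e-300)
    ez = epsilon * z

    cores: list[np.ndarray] = []
    kept: list[int] = []
    for idx in order:
        cand = q[idx]
        dominated = any(_is_psd(v + ez - cand, tol_scale) for v in cores)
        if not dominated:
            cores.append(cand)
            kept.append(int(idx))
    matrices = np.stack([v + ez for v in cores])
    return VOPSet(
        matrices=matrices,
        epsilon=float(epsilon),
        provenance=np.asarray(kept),
        z=z,
        wholebody=qset.wholebody,
    )
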