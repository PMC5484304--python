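"""RF pulse shape model and bSSFP sequence timing.

An excitation pulse is characterized by its peak amplitude ``p_max`` (μT),
its duration ``tau`` (ms), and two dimensionless shape factors that relate
it to a block (hard) pulse of the same peak amplitude and duration:

* ``delta1`` — relative *duration*: the fraction of the equivalent block
  pulse's area, ``∫p(t)dt / (p_max·τ)``.  It fixes the flip angle at the
  slice center, ``θ = δ₁·p_max·τ·γ``.
* ``delta2`` — relative *energy*: ``∫p(t)²dt / (p_max²·τ)``.  It fixes the
  RF power deposited per repetition and hence the power duty cycle of the
  sequence, ``Δ = δ₂·τ/TR``.

For any physical (nonnegative, peak-normalized) envelope,
``δ₁² ≤ δ₂ ≤ δ₁`` (Cauchy–Schwarz below, boundedness above).

All public interfaces use milliseconds and μT; γ products are evaluated
with the duration converted to seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_1H",
    "PULSE_PRESETS",
    "RFPulse",
    "SequenceTiming",
    "PhysicsConstants",
    "InvalidPulseError",
    "TimingError",
    "ConfigError",
    "shape_factors",
    "peak_amp_for_flip",
    "duty_cycle",
    "min_tr",
    "per_channel_power",
]

#: Gyromagnetic ratio of ¹H in rad·s⁻¹·μT⁻¹.
GAMMA_1H = 267.522

#: Named pulse shapes with stored (delta1, delta2).  "measured-gaussian" is
#: a truncated Gaussian excitation pulse as characterized on a clinical
#: 3 T system; its factors are stored rather than recomputed because the
#: exact truncation/apodization of vendor pulses is not reproducible from
#: the nominal shape alone.
PULSE_PRESETS: dict[str, tuple[float, float]] = {
    "block": (1.0, 1.0),
    "half-sine": (2.0 / np.pi, 0.5),
    "measured-gaussian": (0.53, 0.40),
}


class InvalidPulseError(ValueError):
    """Raised for non-physical pulse envelopes (negative samples, zero peak)."""


class TimingError(ValueError):
    """Raised for inconsistent sequence timing (e.g. TR shorter than the pulse)."""


class ConfigError(ValueError):
    """Raised for out-of-range configuration values."""


@dataclass(frozen=True)
class RFPulse:
    """An RF pulse: either a sampled envelope or a named preset.

    Parameters
    ----------
    tau : float
        Pulse duration in ms.
    waveform : ndarray, optional
        Nonnegative amplitude envelope sampled uniformly over [0, τ],
        normalized to unit peak.  Shape factors are computed from it by
        trapezoidal quadrature.
    preset : str, optional
        Key into :data:`PULSE_PRESETS`; shape factors are the stored values.
    """

    tau: float
    waveform: np.ndarray | None = None
    preset: str | None = None
    _factors: tuple[float, float] = field(init=False, repr=False)

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidPulseError(f"pulse duration must be positive, got {self.tau}")
        if (self.waveform is None) == (self.preset is None):
            raise InvalidPulseError("provide exactly one of waveform or preset")
        if self.preset is not None:
            try:
                d1, d2 = PULSE_PRESETS[self.preset]
            except KeyError:
                raise InvalidPulseError(
                    f"unknown pulse preset {self.preset!r}; "
                    f"known: {sorted(PULSE_PRESETS)}"
                ) from None
        else:
            wf = np.asarray(self.waveform, dtype=float)
            if wf.ndim != 1 or wf.size < 8:
                raise InvalidPulseError("waveform must be 1-D with at least 8 samples")
            if np.any(wf < 0):
                raise InvalidPulseError("waveform samples must be nonnegative")
            peak = wf.max()
            if peak <= 0:
                raise InvalidPulseError("waveform peak must be positive")
            if abs(peak - 1.0) > 1e-9:
                raise InvalidPulseError("waveform must be normalized to unit peak")
            object.__setattr__(self, "waveform", wf)
            # Integrals relative to the unit block pulse on the same grid.
            d1 = float(np.trapezoid(wf, dx=1.0 / (wf.size - 1)))
            d2 = float(np.trapezoid(wf**2, dx=1.0 / (wf.size - 1)))
        object.__setattr__(self, "_factors", (float(d1), float(d2)))

    @property
    def delta1(self) -> float:
        return self._factors[0]

    @property
    def delta2(self) -> float:
        return self._factors[1]


@dataclass(frozen=True)
class SequenceTiming:
    """bSSFP timing: TR, spatial-encoding time, and amplifier gating limit.

    ``t_enc`` (ms) is the time needed within each TR for the spatial
    encoding gradients; ``delta0`` is the RF amplifier gating duty-cycle
    limit (fraction of time the amplifier may be unblanked, irrespective
    of power).
    """

    tr: float
    t_enc: float = 1.7
    delta0: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.delta0 <= 1.0):
            raise ConfigError(f"delta0 must lie in (0, 1], got {self.delta0}")
        if self.tr <= 0 or self.t_enc <= 0:
            raise TimingError("tr and t_enc must be positive")


@dataclass(frozen=True)
class PhysicsConstants:
    """Physical constants; gamma in rad·s⁻¹·μT⁻¹ (defaults to ¹H)."""

    gamma: float = GAMMA_1H

    def __post_init__(self):
        if self.gamma <= 0:
            raise ConfigError("gamma must be positive")


def shape_factors(pulse: RFPulse) -> tuple[float, float]:
    """Return the (delta1, delta2) shape factors of a pulse.

    For sampled envelopes these are the trapezoidal estimates of the
    relative duration and relative energy of the equivalent block pulse;
    presets return their stored values.
    """
    return pulse._factors


def peak_amp_for_flip(
    theta0: float, pulse: RFPulse, gamma: float = GAMMA_1H
) -> float:
    """Peak pulse amplitude p_max (μT) producing flip angle ``theta0`` (rad)
    at unit transmit sensitivity: ``p_max = θ₀ / (δ₁·γ·τ)``.
    """
    if theta0 < 0:
        raise ValueError(f"target flip angle must be nonnegative, got {theta0}")
    tau_s = pulse.tau * 1e-3
    return theta0 / (pulse.delta1 * gamma * tau_s)


def duty_cycle(pulse: RFPulse, timing: SequenceTiming) -> float:
    """Power duty cycle ``Δ = δ₂·τ/TR`` of the sequence (dimensionless)."""
    if timing.tr < pulse.tau:
        raise TimingError(
            f"TR ({timing.tr} ms) shorter than pulse duration ({pulse.tau} ms)"
        )
    return pulse.delta2 * pulse.tau / timing.tr


def min_tr(tau: float, t_enc: float = 1.7, delta0: float = 0.5) -> float:
    """Minimum achievable TR (ms) irrespective of power or SAR.

    The TR must fit the RF pulse plus the encoding gradients
    (``τ + t_enc``) and respect the amplifier gating duty-cycle limit
    (``τ/δ₀``); the minimum is the larger of the two.
    """
    if not (0.0 < delta0 <= 1.0):
        raise ConfigError(f"delta0 must lie in (0, 1], got {delta0}")
    if tau <= 0 or t_enc <= 0:
        raise TimingError("tau and t_enc must be positive")
    return max(tau + t_enc, tau / delta0)


def per_channel_power(
    wj_amplitude: float, p_max: float, A: float, Delta: float
) -> tuple[float, float]:
    """Peak and average forward power (W) demanded on one transmit channel.

    ``A`` (W/μT²) is the gain of the RF chain relating field amplitude at
    the subject to forward power at the amplifier; the channel transmits
    the shimmed waveform ``wj·p(t)`` so peak power is ``A·(|wj|·p_max)²``
    and average power is that times the duty cycle.
    """
    if wj_amplitude < 0 or p_max < 0:
        raise ValueError("amplitudes must be nonnegative")
    if A <= 0:
        raise ValueError("power gain A must be positive")
    peak = A * (wj_amplitude * p_max) ** 2
    return peak, peak * Delta
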