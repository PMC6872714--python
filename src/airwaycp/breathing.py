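"""Sinusoidal tidal-breathing waveform.

Nasal respiration is driven by a volumetric flow rate

    Q(t) = A_t * sin(2 pi t / tau)

with amplitude ``A_t`` and breathing-cycle period ``tau``.  Positive flow is
inspiratory.  The amplitude is calibrated so the inhalation half-cycle moves
exactly one tidal volume:

    integral_0^{tau/2} A_t sin(2 pi t / tau) dt = A_t tau / pi = V_tidal
    =>  A_t = pi * V_tidal / tau

Defaults follow normal resting respiration: 500 ml tidal volume, tau = 5 s
(so that peak inhalation falls at t = 1.25 s), a simulated duration of one
inhalation half-cycle (2.5 s), and a 1 ms time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["BreathingWaveform", "amplitude_from_tidal_volume", "flow_rate"]


def amplitude_from_tidal_volume(tidal_volume_m3: float, cycle_period_s: float) -> float:
    """Flow amplitude A_t = pi * V_tidal / tau [m3/s].

    This is the amplitude for which the half-cycle integral of the sinusoid
    equals the tidal volume.
    """
    if tidal_volume_m3 <= 0:
        raise ParameterError("tidal_volume_m3: must be positive")
    if cycle_period_s <= 0:
        raise ParameterError("cycle_period_s: must be positive")
    return math.pi * tidal_volume_m3 / cycle_period_s


@dataclass(frozen=True)
class BreathingWaveform:
    """Sinusoidal respiration waveform (SI units).

    The calibration identity ``amplitude * tau / pi == tidal_volume`` is
    enforced at construction; use :meth:`from_tidal_volume` rather than
    picking an amplitude by hand.
    """

    amplitude_m3s: float
    cycle_period_s: float
    tidal_volume_m3: float
    duration_s: float
    time_step_s: float = 1e-3

    def __post_init__(self) -> None:
        if self.amplitude_m3s <= 0:
            raise ParameterError("amplitude_m3s: must be positive")
        if self.cycle_period_s <= 0:
            raise ParameterError("cycle_period_s: must be positive")
        if self.time_step_s <= 0:
            raise ParameterError("time_step_s: must be positive")
        if not 0 < self.duration_s <= self.cycle_period_s:
            raise ParameterError("duration_s: must lie in (0, cycle_period_s]")
        expected = amplitude_from_tidal_volume(self.tidal_volume_m3, self.cycle_period_s)
        if not math.isclose(self.amplitude_m3s, expected, rel_tol=1e-9):
            raise ParameterError(
                "amplitude_m3s: inconsistent with tidal volume "
                f"(expected pi*V/tau = {expected:.6e} m3/s)"
            )

    @classmethod
    def from_tidal_volume(
        cls,
        tidal_volume_m3: float = 500e-6,
        cycle_period_s: float = 5.0,
        duration_s: float | None = None,
        time_step_s: float = 1e-3,
    ) -> "BreathingWaveform":
        """Build a calibrated waveform; duration defaults to the inhalation
        half-cycle tau/2."""
        if duration_s is None:
            duration_s = 0.5 * cycle_period_s
        return cls(
            amplitude_m3s=amplitude_from_tidal_volume(tidal_volume_m3, cycle_period_s),
            cycle_period_s=cycle_period_s,
            tidal_volume_m3=tidal_volume_m3,
            duration_s=duration_s,
            time_step_s=time_step_s,
        )

    def _check_time(self, t) -> np.ndarray:
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0) or np.any(arr > self.duration_s * (1 + 1e-12)):
            raise ParameterError(
                f"t: must lie within [0, {self.duration_s}] s (simulated window)"
            )
        return arr

    def flow_rate(self, t):
        """Volumetric flow rate Q(t) = A_t sin(2 pi t / tau) [m3/s]."""
        arr = self._check_time(t)
        q = self.amplitude_m3s * np.sin(2.0 * math.pi * arr / self.cycle_period_s)
        return float(q) if arr.ndim == 0 else q

    def flow_rate_derivative(self, t):
        """Analytic dQ/dt = A_t (2 pi / tau) cos(2 pi t / tau) [m3/s2]."""
        arr = self._check_time(t)
        omega = 2.0 * math.pi / self.cycle_period_s
        dq = self.amplitude_m3s * omega * np.cos(omega * arr)
        return float(dq) if arr.ndim == 0 else dq

    def times(self) -> np.ndarray:
        """Uniform time grid over [0, duration] at the configured step."""
        n = int(round(self.duration_s / self.time_step_s))
        return np.linspace(0.0, self.duration_s, n + 1)

    def sample(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, flow) sampled on :meth:`times`."""
        t = self.times()
        return t, self.flow_rate(t)

    def inspired_volume(self) -> float:
        """Trapezoidal integral of the flow over the simulated window [m3]."""
        t, q = self.sample()
        return float(np.trapezoid(q, t))


def flow_rate(t, waveform: BreathingWaveform):
    """Functional form of :meth:`BreathingWaveform.flow_rate`."""
    return waveform.flow_rate(t)
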