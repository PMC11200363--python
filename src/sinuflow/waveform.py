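"""Pulsatile inlet mass-flow waveform.

The inflow trace is synthesized as a strictly positive two-harmonic Fourier
series around a configurable mean,

    Q(t) = Q_mean * (1 + a1 sin(2 pi t/T + phi1) + a2 sin(4 pi t/T + phi2)),

with T = 0.8 s per cardiac cycle.  Q is a mass flow per unit out-of-plane
depth (kg s^-1 m^-1); dividing by the blood density gives the 2D volumetric
flux used by the fluid solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WaveformParams


@dataclass(frozen=True)
class InletWaveform:
    period: float = 0.8
    mean: float = 1.1025  # kg/(s m)
    a1: float = 0.3
    a2: float = 0.1
    phi1: float = 0.0
    phi2: float = 0.0

    @classmethod
    def from_params(cls, p: WaveformParams) -> "InletWaveform":
        p.validate()
        return cls(period=p.period, mean=p.mean_mass_flow,
                   a1=p.a1, a2=p.a2, phi1=p.phi1, phi2=p.phi2)

    def sample(self, t):
        """Mass flow at time t (scalar or array); periodic and positive."""
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        q = self.mean * (1.0 + self.a1 * np.sin(w * t + self.phi1)
                         + self.a2 * np.sin(2.0 * w * t + self.phi2))
        return q if q.ndim else float(q)

    def peak(self) -> float:
        t = np.linspace(0.0, self.period, 4001)
        return float(np.max(self.sample(t)))

    def trough(self) -> float:
        t = np.linspace(0.0, self.period, 4001)
        return float(np.min(self.sample(t)))


def sample_waveform(w: InletWaveform, t):
    """Module-level alias for :meth:`InletWaveform.sample`."""
    return w.sample(t)


def ramp_factor(t: float, ramp_time: float) -> float:
    """Smooth 0 -> 1 start-up multiplier over ``ramp_time`` seconds."""
    if ramp_time <= 0 or t >= ramp_time:
        return 1.0
    return 0.5 * (1.0 - np.cos(np.pi * t / ramp_time))
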