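"""The iGluSnFR impulse-response kernel.

A single vesicle's glutamate transient is modelled as a double exponential

    h(t) = A * exp(-t / tau_f) * (1 - exp(-t / tau_r)),   t >= 0

with rise time constant ``tau_r`` (~1 ms) and fall time constant ``tau_f``
(~60 ms). These kinetics are approximately invariant across event
amplitudes, so the recorded trace is a linear superposition of scaled,
shifted copies of h — which is what makes Wiener deconvolution an
appropriate event detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Kernel"]


@dataclass(frozen=True)
class Kernel:
    """Double-exponential fluorescence impulse response.

    Parameters
    ----------
    tau_r
        Rise time constant, s. Default 1 ms.
    tau_f
        Fall time constant, s. Default 60 ms. Must exceed ``tau_r``.
    amplitude
        Multiplicative amplitude A (dimensionless for a unit-normalized
        kernel; see :meth:`sample`).
    """

    tau_r: float = 0.001
    tau_f: float = 0.060
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_r > 0:
            raise ValueError("tau_r must be positive")
        if not self.tau_f > self.tau_r:
            raise ValueError("tau_f must exceed tau_r")

    @property
    def t_peak(self) -> float:
        """Time of the kernel maximum: tau_r * ln(1 + tau_f / tau_r)."""
        return self.tau_r * np.log1p(self.tau_f / self.tau_r)

    @property
    def peak_value(self) -> float:
        """Maximum of the un-normalized kernel (A times shape maximum)."""
        return float(self.amplitude * self._shape(np.array([self.t_peak]))[0])

    def _shape(self, t: np.ndarray) -> np.ndarray:
        out = np.exp(-t / self.tau_f) * -np.expm1(-t / self.tau_r)
        return np.where(t < 0, 0.0, out)

    def evaluate(self, t) -> np.ndarray:
        """Kernel value A * e^(-t/tau_f) * (1 - e^(-t/tau_r)); zero for t < 0."""
        t = np.asarray(t, dtype=float)
        return self.amplitude * self._shape(t)

    def sample(
        self, line_rate: float, duration: float | None = None, normalize: str = "peak"
    ) -> np.ndarray:
        """Sample the kernel at a linescan's rate.

        Parameters
        ----------
        line_rate
            Sampling rate in Hz.
        duration
            Length of the sampled support in seconds; defaults to
            ``8 * tau_f``, after which the kernel is < 0.04% of peak.
        normalize
            ``"peak"`` scales the samples so the maximum is 1 (an impulse
            of height a then renders a transient of peak a); ``"none"``
            keeps A as the scale.
        """
        if duration is None:
            duration = 8.0 * self.tau_f
        n = max(int(round(duration * line_rate)), 2)
        t = np.arange(n) / line_rate
        h = self.evaluate(t)
        if normalize == "peak":
            h = h / h.max()
        elif normalize != "none":
            raise ValueError("normalize must be 'peak' or 'none'")
        return h
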