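"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "LinescanRecording",
    "GaussianComponent",
    "SpatialProfile",
    "FluorescenceTrace",
    "EventTrain",
    "QuantalSeries",
]

# FWHM of a Gaussian = 2 sigma sqrt(2 ln 2)
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Active zones wider than this (FWHM, um) risk conflating several release
# sites and are excluded from event analysis.
MAX_ACTIVE_ZONE_FWHM_UM = 1.5


@dataclass
class LinescanRecording:
    """A raw linescan: fluorescence sampled along one spatial line over time.

    ``values`` has shape (n_positions, n_samples); rows are positions along
    the scanned line, columns are line times at ``line_rate`` Hz.
    """

    values: np.ndarray
    line_rate: float
    pixel_size: float
    truth: Any | None = None  # ground-truth QuantalSeries for synthetic data

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("linescan values must be 2-D (position x time)")
        if not np.all(np.isfinite(v)):
            raise ValueError("linescan contains non-finite values")
        if not self.line_rate > 0:
            raise ValueError("line_rate must be positive")
        self.values = v

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.line_rate

    @property
    def positions(self) -> np.ndarray:
        """Position of each pixel along the line, um."""
        return np.arange(self.n_positions) * self.pixel_size


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian point source (putative active zone) in a spatial profile."""

    center: float  # um
    sigma: float  # um
    amplitude: float  # a.u.

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma

    @property
    def excluded(self) -> bool:
        """True when the source is too wide to be a single active zone."""
        return self.fwhm >= MAX_ACTIVE_ZONE_FWHM_UM


@dataclass
class SpatialProfile:
    """Sum-of-Gaussians decomposition of the time-averaged linescan profile."""

    components: list[GaussianComponent]
    offset: float
    residual_rms: float

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c.center)
        for c in self.components:
            if not c.sigma > 0:
                raise ValueError("component sigma must be positive")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def design_matrix(self, positions: np.ndarray) -> np.ndarray:
        """Unit-amplitude component shapes evaluated at ``positions``
        (n_positions x n_components), plus a constant column for the offset."""
        cols = [
            np.exp(-0.5 * ((positions - c.center) / c.sigma) ** 2)
            for c in self.components
        ]
        cols.append(np.ones_like(positions))
        return np.column_stack(cols)


@dataclass
class FluorescenceTrace:
    """Per-component fluorescence time series, before or after ΔF/F0."""

    values: np.ndarray
    line_rate: float
    f0: float | None = None
    bleach_slope: float = 0.0  # a.u. per s, removed trend
    bleach_intercept: float = 0.0
    is_dff: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.line_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.line_rate


@dataclass
class EventTrain:
    """Detected release events: times E and deconvolved amplitudes A."""

    times: np.ndarray
    amplitudes: np.ndarray
    threshold_sd: float
    noise_sd: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be matching 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("event amplitudes must be positive")
        self.times, self.amplitudes = t, a

    def __len__(self) -> int:
        return self.times.size


@dataclass
class QuantalSeries:
    """Release events expressed as integer numbers of quanta (vesicles)."""

    times: np.ndarray
    quanta: np.ndarray
    quantal_amplitude: float | None = None
    polarity: str = "unknown"  # ON | OFF | unknown

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.quanta)
        if t.shape != q.shape or t.ndim != 1:
            raise ValueError("times and quanta must be matching 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        if q.size and (np.any(q < 1) or np.any(q != np.round(q))):
            raise ValueError("quanta must be positive integers")
        if self.polarity not in ("ON", "OFF", "unknown"):
            raise ValueError("polarity must be 'ON', 'OFF' or 'unknown'")
        self.times = t
        self.quanta = q.astype(int)

    def __len__(self) -> int:
        return self.times.size

    @property
    def total_vesicles(self) -> int:
        return int(self.quanta.sum())
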