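"""Synthetic linescan recordings with known ground-truth release.

The study's raw data are not deposited, so this module generates
recordings with the statistical structure the analysis assumes:

* point-source active zones with Gaussian spatial profiles along the line;
* quantal release events whose amplitudes are integer multiples of a
  unitary quantum, with multivesicular release (MVR) drawn from a
  probability vector over quanta-per-event;
* contrast-dependent event rates (linear or Hill-shaped in contrast);
* the double-exponential iGluSnFR kernel (rise ~1 ms, decay ~60 ms);
* additive Gaussian noise and slow linear bleaching.

Every generator is driven by an explicit seed; identical inputs and seed
give bit-identical output. The ground-truth event times and quanta travel
with the rendered recording so that detection and clustering can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from quantalglu.containers import LinescanRecording, QuantalSeries
from quantalglu.kernel import Kernel
from quantalglu.protocol import StimulusProtocol

__all__ = ["ReleaseModel", "ImagingModel", "simulate_release", "render_linescan"]


@dataclass(frozen=True)
class ReleaseModel:
    """Contrast-dependent quantal release statistics of one active zone.

    The event rate at contrast c (percent) is either linear,
    ``base_rate + rate_gain * max(c - contrast_offset, 0)``, or
    Hill-shaped when ``r_max`` is set,
    ``base_rate + r_max * c**hill_n / (c**hill_n + c_half**hill_n)``.

    Parameters
    ----------
    base_rate
        Event rate at zero contrast, events/s (spontaneous release).
    rate_gain
        Linear rate increase, events/s per percent contrast.
    r_max, c_half, hill_n
        Hill-shaped contrast dependence of the event rate; used when
        ``r_max`` is not None, in which case ``rate_gain`` is ignored.
    quantal_amplitude
        ΔF/F0 of a single-vesicle event.
    mvr_weights
        Probability of an event comprising k vesicles, as a mapping
        {k: p_k}; must sum to 1.
    amplitude_cv
        Fractional spread of a single quantum's fluorescence amplitude.
    amplitude_spread
        How the spread of a k-quantum event scales: ``"sqrt_k"`` (SD
        cv*q*sqrt(k), the variance-additivity of k independent vesicles)
        or ``"fixed"`` (SD cv*q regardless of k).
    phase_locked
        If True, events cluster at a preferred phase within each cycle
        instead of being uniform (homogeneous Poisson) over the cycle.
    preferred_phase, phase_concentration
        Centre (fraction of the cycle) and von Mises concentration of the
        phase distribution when ``phase_locked``.
    """

    base_rate: float = 0.0
    rate_gain: float = 0.0
    contrast_offset: float = 0.0
    r_max: float | None = None
    c_half: float = 50.0
    hill_n: float = 2.0
    quantal_amplitude: float = 1.0
    mvr_weights: dict = field(default_factory=lambda: {1: 1.0})
    amplitude_cv: float = 0.0
    amplitude_spread: str = "sqrt_k"
    phase_locked: bool = False
    preferred_phase: float = 0.25
    phase_concentration: float = 4.0

    def __post_init__(self) -> None:
        w = np.array(list(self.mvr_weights.values()), dtype=float)
        k = np.array(list(self.mvr_weights.keys()))
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mvr_weights must be non-negative and sum to 1")
        if np.any(k < 1) or np.any(k != np.round(k)):
            raise ValueError("mvr_weights keys must be positive integers")
        if self.base_rate < 0 or self.rate_gain < 0:
            raise ValueError("rates must be non-negative")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.amplitude_spread not in ("sqrt_k", "fixed"):
            raise ValueError("amplitude_spread must be 'sqrt_k' or 'fixed'")

    def rate(self, contrast) -> np.ndarray:
        """Event rate (events/s) at the given percent contrast(s)."""
        c = np.asarray(contrast, dtype=float)
        if self.r_max is not None:
            cn = np.power(c, self.hill_n)
            r = self.base_rate + self.r_max * cn / (cn + self.c_half**self.hill_n)
        else:
            r = self.base_rate + self.rate_gain * np.clip(c - self.contrast_offset, 0.0, None)
        return r

    def draw_quanta(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ks = np.array(list(self.mvr_weights.keys()), dtype=int)
        ps = np.array(list(self.mvr_weights.values()), dtype=float)
        return rng.choice(ks, size=n, p=ps)


@dataclass(frozen=True)
class ImagingModel:
    """Optical and noise parameters of the simulated linescan.

    ``source_centers``/``source_widths`` place Gaussian point sources
    (active zones) along the scanned line, in um. ``noise_sd`` is additive
    Gaussian noise in ΔF/F0 units; ``bleach_slope`` is the fractional
    baseline loss per second; ``background`` a spatially uniform baseline
    floor as a fraction of ``baseline_F0``.
    """

    n_positions: int = 24
    pixel_size: float = 0.2  # um
    line_rate: float = 1000.0  # Hz
    source_centers: tuple = (2.4,)  # um
    source_widths: tuple = (0.4,)  # Gaussian sigma, um
    noise_sd: float = 0.0  # ΔF/F0 units
    bleach_slope: float = 0.0  # fraction of baseline per s
    baseline_F0: float = 100.0  # a.u.
    background: float = 0.1  # fraction of baseline_F0

    def __post_init__(self) -> None:
        if not self.line_rate > 0:
            raise ValueError("line_rate must be positive")
        if len(self.source_centers) != len(self.source_widths):
            raise ValueError("one width per source center required")
        if any(w <= 0 for w in self.source_widths):
            raise ValueError("source widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n_positions) * self.pixel_size

    def source_profiles(self) -> np.ndarray:
        """Unit-peak Gaussian profile of each source (n_sources x n_positions)."""
        p = self.positions
        return np.stack(
            [
                np.exp(-0.5 * ((p - c) / w) ** 2)
                for c, w in zip(self.source_centers, self.source_widths)
            ]
        )


def simulate_release(
    protocol: StimulusProtocol,
    model: ReleaseModel,
    seed: int,
    min_separation: float = 0.0,
) -> QuantalSeries:
    """Draw a ground-truth quantal release series for a stimulus protocol.

    Event counts per cycle are Poisson with mean
    ``cycle_duration * model.rate(contrast)``; event times are uniform
    within the cycle (homogeneous Poisson) or phase-locked; quanta per
    event are drawn from ``model.mvr_weights``.

    Parameters
    ----------
    min_separation
        If positive, events closer than this (s) to their predecessor are
        dropped, yielding a well-separated train for round-trip tests.
        The realized rate is correspondingly below the nominal rate.
    """
    rng = np.random.default_rng(seed)
    dt = protocol.cycle_duration
    times = []
    for i, c in enumerate(protocol.contrasts):
        lam = dt * float(model.rate(c))
        n = rng.poisson(lam) if lam > 0 else 0
        if n == 0:
            continue
        if model.phase_locked:
            phase = rng.vonmises(
                2 * np.pi * model.preferred_phase - np.pi,
                model.phase_concentration,
                size=n,
            )
            frac = (phase + np.pi) / (2 * np.pi)
        else:
            frac = rng.random(n)
        times.append(i * dt + frac * dt)
    t = np.sort(np.concatenate(times)) if times else np.empty(0)
    # strictly increasing times (ties are measure-zero but seeds are finite)
    if t.size > 1:
        t = t[np.concatenate(([True], np.diff(t) > 0))]
    if min_separation > 0 and t.size > 1:
        keep = [0]
        for i in range(1, t.size):
            if t[i] - t[keep[-1]] >= min_separation:
                keep.append(i)
        t = t[keep]
    q = model.draw_quanta(t.size, rng)
    return QuantalSeries(times=t, quanta=q, quantal_amplitude=model.quantal_amplitude)


def _event_amplitudes(
    truth: QuantalSeries, model: ReleaseModel, rng: np.random.Generator
) -> np.ndarray:
    """Continuous ΔF/F0 peak of each event: k*q jittered by the quantal CV."""
    q = model.quantal_amplitude
    k = truth.quanta.astype(float)
    mean = k * q
    if model.amplitude_cv == 0:
        return mean
    sd = model.amplitude_cv * q * (np.sqrt(k) if model.amplitude_spread == "sqrt_k" else 1.0)
    amp = mean + sd * rng.standard_normal(k.size)
    return np.clip(amp, 0.05 * q, None)


def render_linescan(
    truth: QuantalSeries | list[QuantalSeries],
    kernel: Kernel,
    imaging: ImagingModel,
    duration: float,
    seed: int,
    release_model: ReleaseModel | None = None,
) -> LinescanRecording:
    """Render ground-truth release into a noisy linescan recording.

    The recording is ``baseline * (1 - bleach_slope * t)`` plus, for each
    event, ``amplitude * kernel`` placed at the event time and spread
    spatially by its source Gaussian, plus additive Gaussian noise — all
    scaled by ``baseline_F0`` so event amplitudes are in ΔF/F0 units.

    Parameters
    ----------
    truth
        One :class:`QuantalSeries` per source (a bare series maps to the
        first source).
    duration
        Recording length, s. Events beyond it are rejected.
    release_model
        Supplies the quantal amplitude and its CV for rendering; when
        omitted, events render at ``truth.quantal_amplitude`` exactly.
    """
    series = [truth] if isinstance(truth, QuantalSeries) else list(truth)
    if len(series) > len(imaging.source_centers):
        raise ValueError("more truth series than sources in the imaging model")
    n = int(round(duration * imaging.line_rate))
    for s in series:
        if s.times.size and s.times.max() >= duration:
            raise ValueError(
                f"event at t={s.times.max():.3f}s beyond the {duration:.3f}s recording"
            )

    rng = np.random.default_rng(seed)
    t = np.arange(n) / imaging.line_rate
    profiles = imaging.source_profiles()
    h = kernel.sample(imaging.line_rate, normalize="peak")

    # baseline: sources + uniform background, bleached linearly in time
    spatial_baseline = profiles.sum(axis=0) + imaging.background
    bleach = 1.0 - imaging.bleach_slope * t
    rec = np.outer(spatial_baseline, bleach)

    for src, s in enumerate(series):
        if not len(s):
            continue
        if release_model is not None:
            amps = _event_amplitudes(s, release_model, rng)
        else:
            qa = s.quantal_amplitude if s.quantal_amplitude is not None else 1.0
            amps = s.quanta * qa
        impulses = np.zeros(n)
        idx = np.minimum((s.times * imaging.line_rate).round().astype(int), n - 1)
        np.add.at(impulses, idx, amps)
        dff = fftconvolve(impulses, h)[:n]
        rec += np.outer(profiles[src], dff)

    if imaging.noise_sd > 0:
        rec = rec + imaging.noise_sd * rng.standard_normal(rec.shape)
    rec *= imaging.baseline_F0

    attached = series[0] if len(series) == 1 else series
    return LinescanRecording(
        values=rec,
        line_rate=imaging.line_rate,
        pixel_size=imaging.pixel_size,
        truth=attached,
    )
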