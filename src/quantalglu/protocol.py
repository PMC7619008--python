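"""Stimulus protocols: the contrast delivered on each cycle of a periodic
full-field stimulus.

The protocol is the conditioning variable S of the information analysis:
a sequence of percent-contrast values, one per stimulus cycle, delivered
at a fixed temporal frequency. The canonical design is eleven equiprobable
contrasts spanning C1/2 +/- 10% at 5 Hz (200-ms cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusProtocol", "make_stimulus"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Contrast per cycle of a periodic stimulus.

    Parameters
    ----------
    contrasts
        Percent contrast for each cycle, in presentation order.
    frequency
        Stimulus frequency in Hz; cycle duration is ``1 / frequency``.
    seed
        Seed used to generate the presentation order (bookkeeping only).
    """

    contrasts: np.ndarray
    frequency: float
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.contrasts, dtype=float)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("contrasts must be a non-empty 1-D sequence")
        bad = c[(c < 0) | (c > 100)]
        if bad.size:
            raise ValueError(
                f"contrast {bad[0]:g}% outside the physical range [0, 100]"
            )
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        object.__setattr__(self, "contrasts", c)

    @property
    def cycle_duration(self) -> float:
        """Duration of one stimulus cycle in seconds."""
        return 1.0 / self.frequency

    @property
    def n_cycles(self) -> int:
        return int(self.contrasts.size)

    @property
    def duration(self) -> float:
        """Total protocol duration in seconds."""
        return self.n_cycles * self.cycle_duration

    @property
    def cycle_edges(self) -> np.ndarray:
        """Cycle boundaries in seconds, length ``n_cycles + 1``.

        Cycle ``i`` covers the half-open interval ``[edges[i], edges[i+1])``.
        """
        return np.arange(self.n_cycles + 1) * self.cycle_duration

    def stimulus_marginal(self) -> tuple[np.ndarray, np.ndarray]:
        """Designed marginal p(S): unique contrasts and their probabilities.

        Taken from the protocol design (exactly uniform for a balanced
        design) rather than estimated from data.
        """
        levels, counts = np.unique(self.contrasts, return_counts=True)
        return levels, counts / counts.sum()

    def entropy_bits(self) -> float:
        """Entropy of the stimulus ensemble H(S) in bits per cycle."""
        _, p = self.stimulus_marginal()
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


def make_stimulus(
    contrast_set,
    frequency: float = 5.0,
    repeats: int = 1,
    seed: int = 0,
    randomize: bool = True,
) -> StimulusProtocol:
    """Build a protocol delivering each contrast of ``contrast_set`` an equal
    number of times.

    Parameters
    ----------
    contrast_set
        Distinct percent-contrast values (e.g. eleven values spanning
        C1/2 +/- 10%).
    frequency
        Stimulus frequency in Hz (default 5, i.e. 200-ms cycles).
    repeats
        Number of cycles per contrast.
    seed
        Seed for the pseudo-random presentation order.
    randomize
        If True the cycles are a seeded permutation of the multiset;
        otherwise contrasts are delivered blockwise in sorted order.
    """
    contrast_set = np.asarray(contrast_set, dtype=float)
    if contrast_set.size == 0:
        raise ValueError("contrast_set must be non-empty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    seq = np.repeat(np.sort(contrast_set), repeats)
    if randomize:
        rng = np.random.default_rng(seed)
        seq = rng.permutation(seq)
    return StimulusProtocol(contrasts=seq, frequency=float(frequency), seed=seed)
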