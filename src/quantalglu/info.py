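"""Signal-to-noise ratio and information-theoretic measures.

SNR at one contrast is S^2 / sigma^2, with S the trial-mean vesicle count
per stimulus cycle and sigma^2 the across-trial variance.

Information transmission is measured on the binned quantal response: the
event series is discretized into 20-ms bins (so a bin holds zero events
or one event of integer amplitude), the conditional distribution p(Q|S)
is estimated by empirical frequency for each stimulus contrast, and the
joint/posterior follow by the chain rule. Mutual information is the
plug-in double sum

    I(S;Q) = sum_{s,q} p(s,q) log2[ p(s,q) / (p(s) p(q)) ]

and the specific information of a response symbol q is
I2(S,q) = H(S) - H(S|q), whose p(q)-weighted mean equals I(S;Q).
All logarithms are base 2; 0*log(0) is 0 by continuity. No small-sample
bias correction is applied by default (a shuffle-null diagnostic is
available separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from quantalglu.containers import QuantalSeries
from quantalglu.protocol import StimulusProtocol
from quantalglu.response import CyclewiseCounts

__all__ = [
    "SNRResult",
    "BinnedResponse",
    "InfoDistributions",
    "InfoResult",
    "snr",
    "bin_events",
    "estimate_distributions",
    "mutual_information",
    "specific_information",
    "information_rate",
    "information_report",
    "stimulus_entropy",
    "shuffle_null_information",
]

DEFAULT_BIN_WIDTH = 0.02  # s


# ------------------------------------------------------------------- SNR


@dataclass
class SNRResult:
    """Per-contrast SNR table: columns contrast, S, sigma2, snr, n_trials,
    infinite (flag for zero-variance contrasts)."""

    table: pd.DataFrame
    ddof: int = 1


def snr(counts: CyclewiseCounts, contrast: float | None = None, ddof: int = 1) -> SNRResult:
    """SNR = S^2 / sigma^2 per contrast, across repeated cycles (trials).

    ``ddof=1`` gives the unbiased variance estimator (default). Contrasts
    whose trials are identical have sigma^2 = 0; their SNR is reported as
    infinite with the ``infinite`` flag set rather than raising.
    """
    tab = counts.table
    if contrast is not None:
        tab = tab[tab["contrast"] == contrast]
        if tab.empty:
            raise ValueError(f"no cycles at contrast {contrast:g}%")
    rows = []
    for c, grp in tab.groupby("contrast", sort=True):
        x = grp["vesicles"].to_numpy(float)
        if x.size < 2:
            raise ValueError(f"need >= 2 trials at contrast {c:g}% (got {x.size})")
        S = float(x.mean())
        var = float(x.var(ddof=ddof))
        infinite = var == 0.0
        rows.append(
            {
                "contrast": float(c),
                "S": S,
                "sigma2": var,
                "snr": np.inf if infinite else S**2 / var,
                "n_trials": int(x.size),
                "infinite": infinite,
            }
        )
    return SNRResult(table=pd.DataFrame(rows), ddof=ddof)


# ------------------------------------------------------------------ binning


@dataclass
class BinnedResponse:
    """Quanta per time bin, aligned to stimulus cycles.

    ``q`` holds the integer quanta in each bin (0 for empty bins);
    ``contrast`` the stimulus contrast the bin belongs to. Bins that
    contained two or more events violate the one-event-per-bin premise of
    the 20-ms discretization; their quanta are summed into one symbol and
    their indices recorded in ``violations``.
    """

    q: np.ndarray
    contrast: np.ndarray
    bin_width: float
    bins_per_cycle: int
    violations: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_bins(self) -> int:
        return self.q.size

    @property
    def violation_rate(self) -> float:
        return self.violations.size / self.n_bins if self.n_bins else 0.0


def bin_events(
    series: QuantalSeries,
    protocol: StimulusProtocol,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedResponse:
    """Discretize the quantal series into fixed-width bins within cycles.

    ``bin_width`` must divide the cycle duration exactly (20 ms into a
    200-ms cycle gives 10 bins/cycle). Each bin's symbol is the total
    quanta of events whose time falls in the half-open bin interval.
    """
    cyc = protocol.cycle_duration
    ratio = cyc / bin_width
    if abs(ratio - round(ratio)) > 1e-9:
        divisors = [cyc / k for k in (2, 4, 5, 8, 10, 20)]
        raise ValueError(
            f"bin_width {bin_width:g}s does not divide the {cyc:g}s cycle; "
            f"try one of {', '.join(f'{d:g}' for d in divisors)} s"
        )
    per_cycle = int(round(ratio))
    n_bins = per_cycle * protocol.n_cycles
    if len(series) and series.times.max() >= protocol.duration:
        raise ValueError("series extends beyond the protocol")
    q = np.zeros(n_bins, dtype=int)
    n_events = np.zeros(n_bins, dtype=int)
    if len(series):
        idx = np.minimum((series.times / bin_width).astype(int), n_bins - 1)
        np.add.at(q, idx, series.quanta)
        np.add.at(n_events, idx, 1)
    violations = np.flatnonzero(n_events >= 2)
    contrast = np.repeat(protocol.contrasts, per_cycle)
    return BinnedResponse(
        q=q,
        contrast=contrast,
        bin_width=bin_width,
        bins_per_cycle=per_cycle,
        violations=violations,
    )


# ------------------------------------------------------------ distributions


@dataclass
class InfoDistributions:
    """Empirical stimulus/response distributions of the binned response.

    ``p_q_given_s`` is (n_stimuli x n_symbols), rows normalized;
    ``p_s`` comes from the protocol design (exactly uniform for a balanced
    design), not from data; joint and posterior follow by the chain rule.
    """

    stimuli: np.ndarray  # contrast levels
    symbols: np.ndarray  # quanta-per-bin alphabet
    p_q_given_s: np.ndarray
    p_s: np.ndarray
    p_sq: np.ndarray
    p_q: np.ndarray
    p_s_given_q: np.ndarray

    @classmethod
    def from_conditional(
        cls,
        p_q_given_s: np.ndarray,
        p_s: np.ndarray,
        stimuli: np.ndarray | None = None,
        symbols: np.ndarray | None = None,
    ) -> "InfoDistributions":
        """Build the full set of distributions from p(Q|S) and p(S)."""
        p_q_given_s = np.asarray(p_q_given_s, float)
        p_s = np.asarray(p_s, float)
        p_sq = p_q_given_s * p_s[:, None]
        p_q = p_sq.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_s_given_q = np.where(p_q[None, :] > 0, p_sq / p_q[None, :], 0.0)
        n_s, n_q = p_q_given_s.shape
        return cls(
            stimuli=np.arange(n_s) if stimuli is None else np.asarray(stimuli),
            symbols=np.arange(n_q) if symbols is None else np.asarray(symbols),
            p_q_given_s=p_q_given_s,
            p_s=p_s,
            p_sq=p_sq,
            p_q=p_q,
            p_s_given_q=p_s_given_q,
        )

    def validate(self, atol: float = 1e-9) -> None:
        assert np.allclose(self.p_q_given_s.sum(axis=1), 1.0, atol=atol)
        assert np.isclose(self.p_s.sum(), 1.0, atol=atol)
        assert np.isclose(self.p_sq.sum(), 1.0, atol=atol)
        assert np.allclose(self.p_sq.sum(axis=1), self.p_s, atol=atol)
        assert np.allclose(self.p_sq.sum(axis=0), self.p_q, atol=atol)


def estimate_distributions(
    binned: BinnedResponse, protocol: StimulusProtocol
) -> InfoDistributions:
    """Estimate p(Q|S) by empirical bin frequencies and derive the rest.

    For each stimulus contrast, the count of bins holding q quanta is
    divided by that contrast's total bin count. p(S) is the designed
    stimulus marginal; p(S,Q) = p(Q|S) p(S); p(S|Q) = p(S,Q) / p(Q).
    """
    levels, p_s = protocol.stimulus_marginal()
    symbols = np.arange(int(binned.q.max()) + 1 if binned.q.size else 1)
    p_q_given_s = np.zeros((levels.size, symbols.size))
    for i, s in enumerate(levels):
        mask = binned.contrast == s
        total = int(mask.sum())
        if total == 0:
            raise ValueError(f"stimulus contrast {s:g}% has no bins")
        p_q_given_s[i] = np.bincount(binned.q[mask], minlength=symbols.size) / total
    p_sq = p_q_given_s * p_s[:, None]
    p_q = p_sq.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_s_given_q = np.where(p_q[None, :] > 0, p_sq / p_q[None, :], 0.0)
    return InfoDistributions(
        stimuli=levels,
        symbols=symbols,
        p_q_given_s=p_q_given_s,
        p_s=p_s,
        p_sq=p_sq,
        p_q=p_q,
        p_s_given_q=p_s_given_q,
    )


# ------------------------------------------------------------- information


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2x(np.asarray(p, float)).sum())


def stimulus_entropy(protocol_or_n) -> float:
    """H(S) in bits per cycle: of a protocol, or of n equiprobable stimuli."""
    if isinstance(protocol_or_n, StimulusProtocol):
        return protocol_or_n.entropy_bits()
    return float(np.log2(protocol_or_n))


def mutual_information(dists: InfoDistributions) -> float:
    """Plug-in mutual information I(S;Q) in bits per bin (symmetric)."""
    p_sq = dists.p_sq
    outer = dists.p_s[:, None] * dists.p_q[None, :]
    nz = p_sq > 0
    return float(np.sum(p_sq[nz] * np.log2(p_sq[nz] / outer[nz])))


def specific_information(dists: InfoDistributions) -> pd.DataFrame:
    """I2(S,q) = H(S) - H(S|q) per response symbol with p(q) > 0.

    Individual values may be negative; the p(q)-weighted mean equals the
    mutual information. Symbols never observed (p(q) = 0) are omitted.
    """
    h_s = _entropy(dists.p_s)
    rows = []
    for j, q in enumerate(dists.symbols):
        if dists.p_q[j] <= 0:
            continue
        h_s_given_q = _entropy(dists.p_s_given_q[:, j])
        rows.append(
            {"q": int(q), "p_q": float(dists.p_q[j]), "i2_bits": h_s - h_s_given_q}
        )
    return pd.DataFrame(rows)


def information_rate(bits_per_cycle: float, frequency: float) -> float:
    """Convert information per stimulus cycle into bits per second."""
    if not frequency > 0:
        raise ValueError("frequency must be positive")
    return bits_per_cycle * frequency


# ------------------------------------------------------------- full report


@dataclass
class InfoResult:
    """Information summary of one quantal series under one protocol."""

    h_s_bits: float
    mi_bits_per_bin: float
    bits_per_cycle: float
    bits_per_s: float
    h_s_given_q_bits: float
    specific: pd.DataFrame
    snr: SNRResult | None
    bin_violation_rate: float
    cycle_information: str  # "sum_bins" | "cycle_symbols"


def _cycle_symbol_information(
    series: QuantalSeries, protocol: StimulusProtocol
) -> float:
    """I(S;Q) with Q the total quanta per cycle (the coarse alternative
    reading of per-cycle information)."""
    edges = protocol.cycle_edges
    idx = np.searchsorted(edges, series.times, side="right") - 1
    per_cycle = np.bincount(idx, weights=series.quanta, minlength=protocol.n_cycles)
    fake = BinnedResponse(
        q=per_cycle.astype(int),
        contrast=protocol.contrasts,
        bin_width=protocol.cycle_duration,
        bins_per_cycle=1,
    )
    return mutual_information(estimate_distributions(fake, protocol))


def information_report(
    series: QuantalSeries,
    protocol: StimulusProtocol,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cycle_information: str = "sum_bins",
    counts: CyclewiseCounts | None = None,
) -> InfoResult:
    """Full information summary: entropies, I(S;Q), rate, specific info.

    ``cycle_information`` selects how per-cycle information is obtained:
    ``"sum_bins"`` (default) sums the per-bin information over the bins of
    a cycle (bits/bin x bins/cycle); ``"cycle_symbols"`` computes I on a
    per-cycle total-quanta alphabet instead.
    """
    if cycle_information not in ("sum_bins", "cycle_symbols"):
        raise ValueError("cycle_information must be 'sum_bins' or 'cycle_symbols'")
    binned = bin_events(series, protocol, bin_width)
    dists = estimate_distributions(binned, protocol)
    mi_bin = mutual_information(dists)
    if cycle_information == "sum_bins":
        bits_per_cycle = mi_bin * binned.bins_per_cycle
    else:
        bits_per_cycle = _cycle_symbol_information(series, protocol)
    h_s = _entropy(dists.p_s)
    snr_res = None
    if counts is not None:
        snr_res = snr(counts)
    return InfoResult(
        h_s_bits=h_s,
        mi_bits_per_bin=mi_bin,
        bits_per_cycle=bits_per_cycle,
        bits_per_s=information_rate(bits_per_cycle, protocol.frequency),
        h_s_given_q_bits=h_s - mi_bin,
        specific=specific_information(dists),
        snr=snr_res,
        bin_violation_rate=binned.violation_rate,
        cycle_information=cycle_information,
    )


def shuffle_null_information(
    binned: BinnedResponse,
    protocol: StimulusProtocol,
    n_shuffles: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Small-sample bias diagnostic: I(S;Q) after shuffling bins across
    stimuli, which destroys any true association. The distribution of
    shuffled values estimates the positive plug-in bias at this sample
    size."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = BinnedResponse(
            q=rng.permutation(binned.q),
            contrast=binned.contrast,
            bin_width=binned.bin_width,
            bins_per_cycle=binned.bins_per_cycle,
        )
        out[i] = mutual_information(estimate_distributions(shuffled, protocol))
    return out
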