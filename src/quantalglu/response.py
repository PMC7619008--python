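"""Response measures built on the quantal event series.

From a quantal series and its stimulus protocol this module computes the
study's synaptic response measures: per-cycle vesicle counts, the
contrast-response (CR) function and its Hill fit (half-maximal contrast
C1/2), maximum contrast gain over C1/2 +/- 10%, the factorization of the
vesicle code into event rate x event amplitude, event-amplitude
probability distributions, and frequency-response classification
(low-pass vs band-pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from quantalglu.containers import QuantalSeries
from quantalglu.protocol import StimulusProtocol

__all__ = [
    "CyclewiseCounts",
    "ContrastResponseFit",
    "GainResult",
    "FrequencyResponse",
    "count_per_cycle",
    "fit_hill",
    "contrast_gain",
    "factorize_code",
    "amplitude_distribution",
    "compare_amplitude_distributions",
    "frequency_response",
]


@dataclass
class CyclewiseCounts:
    """Per-cycle release summary: the CR function's raw material.

    ``table`` has one row per stimulus cycle with columns ``contrast``
    (percent), ``events``, ``vesicles`` and ``mean_event_amplitude``
    (quanta/event; NaN for cycles without events). ``event_quanta`` keeps
    the individual event amplitudes of each cycle for distribution-level
    analyses.
    """

    table: pd.DataFrame
    frequency: float
    event_quanta: list[np.ndarray] = field(default_factory=list)

    @property
    def cycle_duration(self) -> float:
        return 1.0 / self.frequency

    def mean_per_contrast(self) -> pd.DataFrame:
        """Mean vesicles/cycle (and release rate, vesicles/s) per contrast."""
        g = self.table.groupby("contrast", sort=True)["vesicles"].agg(
            ["mean", "sem", "count"]
        )
        g = g.rename(columns={"mean": "vesicles_per_cycle", "count": "n_cycles"})
        g["release_rate"] = g["vesicles_per_cycle"] * self.frequency
        return g.reset_index()


@dataclass
class ContrastResponseFit:
    """Hill fit r(c) = r_max * c^n / (c^n + c_half^n) to the CR function."""

    r_max: float
    c_half: float
    hill_n: float
    covariance: np.ndarray
    flagged: bool = False
    flag_reason: str = ""

    @property
    def c_half_se(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def c_half_ci(self, z: float = 1.96) -> tuple[float, float]:
        se = self.c_half_se
        return (self.c_half - z * se, self.c_half + z * se)

    def predict(self, contrast) -> np.ndarray:
        return _hill(np.asarray(contrast, float), self.r_max, self.c_half, self.hill_n)


@dataclass
class GainResult:
    """Maximum contrast gain: slope of relative release rate vs contrast
    over the 20%-wide window centered on C1/2."""

    slope: float
    intercept: float
    window: tuple[float, float]
    normalization_contrast: float
    n_contrasts: int


@dataclass
class FrequencyResponse:
    """Release rate vs stimulus frequency and its low-pass/band-pass label."""

    frequencies: np.ndarray
    rates: np.ndarray
    classification: str
    relative_gain: np.ndarray | None = None


# ---------------------------------------------------------------- counting


def count_per_cycle(
    series: QuantalSeries, protocol: StimulusProtocol
) -> CyclewiseCounts:
    """Assign events to stimulus cycles and tally vesicles per cycle.

    Cycle membership uses half-open intervals [start, end). Events at or
    beyond the end of the protocol are an error (the series and protocol
    must share a time origin).
    """
    edges = protocol.cycle_edges
    orphans = series.times[(series.times < 0) | (series.times >= edges[-1])]
    if orphans.size:
        raise ValueError(
            f"{orphans.size} event(s) outside the protocol, e.g. t={orphans[0]:.4f}s "
            f"(protocol spans [0, {edges[-1]:.4f})s)"
        )
    idx = np.searchsorted(edges, series.times, side="right") - 1
    n = protocol.n_cycles
    events = np.bincount(idx, minlength=n) if len(series) else np.zeros(n, int)
    vesicles = (
        np.bincount(idx, weights=series.quanta, minlength=n).astype(int)
        if len(series)
        else np.zeros(n, int)
    )
    with np.errstate(invalid="ignore"):
        mean_amp = np.where(events > 0, vesicles / np.maximum(events, 1), np.nan)
    per_cycle = [
        series.quanta[idx == i] if len(series) else np.empty(0, int) for i in range(n)
    ]
    table = pd.DataFrame(
        {
            "cycle": np.arange(n),
            "contrast": protocol.contrasts,
            "events": events,
            "vesicles": vesicles,
            "mean_event_amplitude": mean_amp,
        }
    )
    return CyclewiseCounts(table=table, frequency=protocol.frequency, event_quanta=per_cycle)


# ---------------------------------------------------------------- Hill fit

HILL_N_BOUNDS = (0.5, 8.0)
C_HALF_BOUNDS = (1.0, 100.0)


def _hill(c, r_max, c_half, n):
    cn = np.power(np.maximum(c, 0.0), n)
    return r_max * cn / (cn + c_half**n)


def fit_hill(counts: CyclewiseCounts) -> ContrastResponseFit:
    """Fit the mean vesicles-per-cycle vs contrast with a Hill function.

    Points are inverse-variance weighted by the standard error of the
    per-contrast mean (Poisson-like counts are strongly heteroscedastic);
    contrasts without a finite positive SEM fall back to equal weights.
    C1/2 is reported with a standard error from the fit covariance.
    Monotone-decreasing data, non-convergence, or C1/2 pinned at a bound
    yield a *flagged* fit rather than a silent success (the Hill function
    is monotone increasing).
    """
    per = counts.mean_per_contrast()
    if per.shape[0] < 4:
        raise ValueError("need >= 4 distinct contrasts for a Hill fit")
    c = per["contrast"].to_numpy(float)
    r = per["vesicles_per_cycle"].to_numpy(float)
    sem = per["sem"].to_numpy(float)
    ok = np.isfinite(sem) & (sem > 0)
    # a zero-SEM point is maximally precise: give it the smallest observed SEM
    sigma = np.where(ok, sem, sem[ok].min()) if ok.any() else np.ones_like(c)

    flagged, reason = False, ""
    rho = stats.spearmanr(c, r).statistic
    if np.isfinite(rho) and rho < 0:
        flagged, reason = True, "response decreases with contrast (Hill is increasing)"

    r_top = max(r.max(), 1e-9)
    half_idx = int(np.argmin(np.abs(r - 0.5 * r_top)))
    p0 = [r_top, float(np.clip(c[half_idx], *C_HALF_BOUNDS)), 2.0]
    lo = [0.0, C_HALF_BOUNDS[0], HILL_N_BOUNDS[0]]
    hi = [np.inf, C_HALF_BOUNDS[1], HILL_N_BOUNDS[1]]
    try:
        popt, pcov = optimize.curve_fit(
            _hill, c, r, p0=p0, sigma=sigma, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as err:
        return ContrastResponseFit(
            r_max=np.nan,
            c_half=np.nan,
            hill_n=np.nan,
            covariance=np.full((3, 3), np.nan),
            flagged=True,
            flag_reason=f"fit did not converge: {err}",
        )
    if not flagged:
        for val, (b_lo, b_hi), name in (
            (popt[1], C_HALF_BOUNDS, "c_half"),
            (popt[2], HILL_N_BOUNDS, "hill_n"),
        ):
            if np.isclose(val, b_lo, rtol=1e-3) or np.isclose(val, b_hi, rtol=1e-3):
                flagged, reason = True, f"{name}={val:.3g} at a fit bound"
                break
    return ContrastResponseFit(
        r_max=float(popt[0]),
        c_half=float(popt[1]),
        hill_n=float(popt[2]),
        covariance=pcov,
        flagged=flagged,
        flag_reason=reason,
    )


# ------------------------------------------------------------ contrast gain


def contrast_gain(
    counts: CyclewiseCounts, c_half: float, half_width: float = 10.0
) -> GainResult:
    """Maximum contrast gain over the window C1/2 +/- ``half_width``%.

    Release rates at each contrast inside the window are normalized to the
    rate at the window's lowest contrast; the gain is the ordinary
    least-squares slope of relative rate vs contrast (per percent).
    """
    per = counts.mean_per_contrast()
    lo, hi = c_half - half_width, c_half + half_width
    win = per[(per["contrast"] >= lo) & (per["contrast"] <= hi)]
    if win.shape[0] == 0:
        raise ValueError(f"no contrasts inside the gain window [{lo:g}, {hi:g}]%")
    if win.shape[0] < 3:
        raise ValueError(
            f"only {win.shape[0]} contrast(s) inside [{lo:g}, {hi:g}]%; need >= 3"
        )
    c = win["contrast"].to_numpy(float)
    rate = win["release_rate"].to_numpy(float)
    c_norm = float(c.min())
    r0 = float(rate[np.argmin(c)])
    if r0 <= 0:
        raise ValueError(
            f"zero release rate at the normalization contrast {c_norm:g}%"
        )
    rel = rate / r0
    slope, intercept = np.polyfit(c, rel, 1)
    return GainResult(
        slope=float(slope),
        intercept=float(intercept),
        window=(lo, hi),
        normalization_contrast=c_norm,
        n_contrasts=int(win.shape[0]),
    )


# ----------------------------------------------------------- factorization


def factorize_code(counts: CyclewiseCounts) -> pd.DataFrame:
    """Factorize the vesicle code: vesicle rate = event rate x amplitude.

    Per contrast: ``event_rate`` (events/s over all cycles at that
    contrast), ``mean_amplitude`` (quanta/event, averaged over events;
    NaN where no events occurred), and ``vesicle_rate`` as their product —
    an identity, since total vesicles / time = (events / time) x
    (vesicles / event). Relative columns are normalized to the lowest
    contrast with a defined value.
    """
    tab = counts.table
    if tab["contrast"].nunique() < 2:
        raise ValueError("need >= 2 distinct contrasts to factorize the code")
    g = tab.groupby("contrast", sort=True).agg(
        events=("events", "sum"), vesicles=("vesicles", "sum"), n_cycles=("cycle", "count")
    )
    time_per_contrast = g["n_cycles"] * counts.cycle_duration
    out = pd.DataFrame(
        {
            "contrast": g.index.to_numpy(float),
            "event_rate": (g["events"] / time_per_contrast).to_numpy(),
            "mean_amplitude": np.where(
                g["events"] > 0, g["vesicles"] / g["events"].replace(0, np.nan), np.nan
            ),
        }
    )
    out["vesicle_rate"] = out["event_rate"] * out["mean_amplitude"].fillna(0.0)
    ref = out.iloc[0]
    out["relative_event_rate"] = out["event_rate"] / ref["event_rate"]
    out["relative_amplitude"] = out["mean_amplitude"] / ref["mean_amplitude"]
    out["relative_vesicle_rate"] = out["vesicle_rate"] / ref["vesicle_rate"]
    return out


# ---------------------------------------------------- amplitude distribution


def amplitude_distribution(counts: CyclewiseCounts) -> pd.DataFrame:
    """Probability density over event amplitudes, with a no-response bin.

    Symbols are quanta-per-event (1, 2, 3, ...) plus symbol 0 for stimulus
    cycles that elicited no event; the denominator is the number of empty
    cycles plus the number of events, so the density sums to 1.
    """
    quanta = (
        np.concatenate(counts.event_quanta)
        if counts.event_quanta
        else np.empty(0, int)
    )
    n_empty = int((counts.table["events"] == 0).sum())
    max_q = int(quanta.max()) if quanta.size else 0
    symbols = np.arange(max_q + 1)
    tallies = np.zeros(max_q + 1, dtype=int)
    tallies[0] = n_empty
    if quanta.size:
        tallies[1:] = np.bincount(quanta, minlength=max_q + 1)[1:]
    total = tallies.sum()
    prob = tallies / total if total else tallies.astype(float)
    return pd.DataFrame({"quanta": symbols, "count": tallies, "probability": prob})


def compare_amplitude_distributions(a: pd.DataFrame, b: pd.DataFrame):
    """Chi-squared test between two amplitude distributions (on counts)."""
    max_q = int(max(a["quanta"].max(), b["quanta"].max()))

    def _counts(d):
        c = np.zeros(max_q + 1, dtype=int)
        c[d["quanta"].to_numpy(int)] = d["count"].to_numpy(int)
        return c

    table = np.stack([_counts(a), _counts(b)])
    keep = table.sum(axis=0) > 0
    res = stats.chi2_contingency(table[:, keep])
    return float(res.statistic), float(res.pvalue)


# -------------------------------------------------------- frequency response

BANDPASS_MARGIN = 1.2  # interior peak must exceed both endpoints by 20%


def frequency_response(
    series_by_frequency: dict,
    reference: "FrequencyResponse | None" = None,
    margin: float = BANDPASS_MARGIN,
) -> FrequencyResponse:
    """Release rate vs stimulus frequency, classified low-pass or band-pass.

    Parameters
    ----------
    series_by_frequency
        Mapping frequency (Hz) -> ``(QuantalSeries, duration_s)``; the
        rate at each frequency is total vesicles / duration.
    reference
        A control-condition response on the same frequencies; when given,
        ``relative_gain`` holds this condition's rate over the reference's.
    margin
        Band-pass calls require the interior maximum to exceed both
        endpoint rates by this factor.
    """
    if len(series_by_frequency) < 3:
        raise ValueError("need >= 3 stimulus frequencies to classify the response")
    freqs = np.array(sorted(series_by_frequency), dtype=float)
    rates = np.array(
        [
            series_by_frequency[f][0].total_vesicles / series_by_frequency[f][1]
            for f in freqs
        ]
    )
    imax = int(np.argmax(rates))
    interior = 0 < imax < freqs.size - 1
    if interior and rates[imax] >= margin * rates[0] and rates[imax] >= margin * rates[-1]:
        classification = "band-pass"
    else:
        classification = "low-pass"
    rel = None
    if reference is not None:
        if not np.array_equal(reference.frequencies, freqs):
            raise ValueError("reference condition must cover the same frequencies")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = rates / reference.rates
    return FrequencyResponse(
        frequencies=freqs, rates=rates, classification=classification, relative_gain=rel
    )
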