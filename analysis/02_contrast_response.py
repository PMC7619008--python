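"""Contrast-response functions and maximum contrast gain per condition.

Reads the event tables written by 01_simulate_and_decompose.py, fits the
Hill contrast-response function of each condition, and measures the
maximum contrast gain over the C1/2 +/- 10% window. Writes
results/contrast_response.csv and prints the gain ratio between the
afternoon-like and morning-like conditions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from quantalglu.cli import _load_protocol
from quantalglu.io import read_events, table_to_series
from quantalglu.response import contrast_gain, count_per_cycle, fit_hill

RESULTS = Path(__file__).resolve().parent.parent / "results"


def _gain_center(counts) -> float:
    """Centre of the gain window: the contrast of half-maximal measured
    response, interpolated from the CR points. The Hill C1/2 is reported
    alongside but can sit outside the sampled range (or be weakly
    identified) for barely-saturating synapses, so the window itself is
    anchored non-parametrically."""
    per = counts.mean_per_contrast()
    c = per["contrast"].to_numpy()
    r = per["vesicles_per_cycle"].to_numpy()
    return float(np.interp(0.5 * r.max(), r, c))


def main() -> None:
    rows = []
    gains = {}
    for name in ("AM", "PM"):
        series = table_to_series(read_events(RESULTS / name / "events.csv"))
        protocol = _load_protocol(RESULTS / name / "protocol.yaml")
        counts = count_per_cycle(series, protocol)
        fit = fit_hill(counts)
        gain = contrast_gain(counts, _gain_center(counts))
        gains[name] = gain.slope
        rows.append(
            {
                "condition": name,
                "n_events": len(series),
                "r_max_vesicles_per_cycle": fit.r_max,
                "c_half_pct": fit.c_half,
                "hill_n": fit.hill_n,
                "fit_flagged": fit.flagged,
                "gain_slope_per_pct": gain.slope,
                "gain_window_lo": gain.window[0],
                "gain_window_hi": gain.window[1],
            }
        )
        print(
            f"[{name}] C1/2 = {fit.c_half:.1f}%  r_max = {fit.r_max:.2f} ves/cycle  "
            f"gain slope = {gain.slope:.4f} /%"
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "contrast_response.csv", index=False)
    print(f"PM/AM gain ratio: {gains['PM'] / gains['AM']:.2f}")
    print(f"wrote {RESULTS / 'contrast_response.csv'}")


if __name__ == "__main__":
    main()
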