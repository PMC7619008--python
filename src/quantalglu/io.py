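"""Readers and writers for recordings, event tables and configs.

Recordings travel as single-plane TIFF (position x time) or HDF5 (dataset
``linescan`` plus ground truth, attributes ``line_rate_hz`` and
``pixel_size_um``); events as CSV with columns
``time_s, amplitude, quanta, polarity``; configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from quantalglu.containers import LinescanRecording, QuantalSeries

__all__ = [
    "write_linescan",
    "read_linescan",
    "write_events",
    "read_events",
    "events_to_table",
    "table_to_series",
    "read_config",
    "write_config",
]

EVENT_COLUMNS = ["time_s", "amplitude", "quanta", "polarity"]


# ------------------------------------------------------------- recordings


def write_linescan(path, recording: LinescanRecording) -> None:
    """Write a linescan as HDF5 (.h5/.hdf5, with any attached ground truth)
    or single-plane TIFF (.tif/.tiff, pixel data only)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("linescan", data=recording.values)
            f.attrs["line_rate_hz"] = recording.line_rate
            f.attrs["pixel_size_um"] = recording.pixel_size
            truth = recording.truth
            if isinstance(truth, QuantalSeries):
                f.create_dataset("truth_times", data=truth.times)
                f.create_dataset("truth_quanta", data=truth.quanta)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            recording.values.astype(np.float32),
            metadata={
                "line_rate_hz": recording.line_rate,
                "pixel_size_um": recording.pixel_size,
            },
        )
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")


def read_linescan(
    path, line_rate: float | None = None, pixel_size: float | None = None
) -> LinescanRecording:
    """Read a linescan written by :func:`write_linescan`.

    TIFF files do not always carry acquisition metadata; ``line_rate`` and
    ``pixel_size`` override or supply it.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = f["linescan"][()]
            lr = float(f.attrs["line_rate_hz"])
            px = float(f.attrs["pixel_size_um"])
            truth = None
            if "truth_times" in f:
                truth = QuantalSeries(
                    times=f["truth_times"][()], quanta=f["truth_quanta"][()]
                )
        return LinescanRecording(
            values=values,
            line_rate=line_rate or lr,
            pixel_size=pixel_size or px,
            truth=truth,
        )
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        lr = line_rate or float(meta.get("line_rate_hz", 0) or 0)
        px = pixel_size or float(meta.get("pixel_size_um", 0) or 0)
        if not lr or not px:
            raise ValueError("TIFF lacks metadata: pass line_rate and pixel_size")
        return LinescanRecording(values=values, line_rate=lr, pixel_size=px)
    raise ValueError(f"unsupported recording format: {path.suffix}")


# ----------------------------------------------------------------- events


def events_to_table(
    series: QuantalSeries, amplitudes: np.ndarray | None = None
) -> pd.DataFrame:
    """Event table with columns time_s, amplitude, quanta, polarity."""
    amp = (
        amplitudes
        if amplitudes is not None
        else series.quanta * (series.quantal_amplitude or np.nan)
    )
    return pd.DataFrame(
        {
            "time_s": series.times,
            "amplitude": amp,
            "quanta": series.quanta,
            "polarity": series.polarity,
        }
    )


def table_to_series(table: pd.DataFrame) -> QuantalSeries:
    polarity = (
        str(table["polarity"].iloc[0]) if len(table) else "unknown"
    )
    return QuantalSeries(
        times=table["time_s"].to_numpy(float),
        quanta=table["quanta"].to_numpy(int) if len(table) else np.empty(0, int),
        polarity=polarity,
    )


def write_events(path, table: pd.DataFrame) -> None:
    """Write an event table as CSV; write-then-read is the identity."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {', '.join(missing)}")
    # %.17g round-trips float64 exactly through text
    table.loc[:, EVENT_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_events(path) -> pd.DataFrame:
    """Read and validate an event CSV: required columns, numeric rows,
    strictly increasing times. Offending rows are reported by line number
    (header is line 1)."""
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("time_s", "amplitude", "quanta"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}:{line}: malformed value in column '{col}'")
        table[col] = numeric
    t = table["time_s"].to_numpy(float)
    if t.size > 1:
        nonmono = np.flatnonzero(np.diff(t) <= 0)
        if nonmono.size:
            line = int(nonmono[0]) + 3  # second row of the offending pair
            raise ValueError(f"{path}:{line}: event times not strictly increasing")
    table["quanta"] = table["quanta"].astype(int) if len(table) else table["quanta"]
    return table


# ----------------------------------------------------------------- configs


def read_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)
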