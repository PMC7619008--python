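"""Configured end-to-end pipeline: simulate -> detect -> respond -> info.

A single YAML config drives all stages; every stochastic stage takes an
explicit seed; unknown config keys are rejected up front. Each run writes
a manifest recording the config hash, package version and per-output
checksums, so identical configs reproduce identical checksums for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np

import quantalglu
from quantalglu.containers import QuantalSeries
from quantalglu.decompose import decompose_recording
from quantalglu.info import information_report
from quantalglu.io import (
    events_to_table,
    read_config,
    read_linescan,
    write_config,
    write_events,
    write_linescan,
)
from quantalglu.kernel import Kernel
from quantalglu.protocol import StimulusProtocol, make_stimulus
from quantalglu.response import (
    contrast_gain,
    count_per_cycle,
    factorize_code,
    fit_hill,
)
from quantalglu.synthetic import ImagingModel, ReleaseModel, render_linescan, simulate_release

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


_ALLOWED = {
    "": {"condition", "seed", "simulate", "detect", "respond", "info", "input"},
    "simulate": {
        "contrast_set",
        "frequency",
        "repeats",
        "randomize",
        "base_rate",
        "rate_gain",
        "r_max",
        "c_half",
        "hill_n",
        "quantal_amplitude",
        "mvr_weights",
        "amplitude_cv",
        "amplitude_spread",
        "noise_sd",
        "bleach_slope",
        "n_positions",
        "pixel_size",
        "line_rate",
        "source_centers",
        "source_widths",
        "baseline_F0",
    },
    "detect": {
        "tau_r",
        "tau_f",
        "threshold_sd",
        "refractory_ms",
        "noise_power",
        "max_components",
        "quantal_amplitude",
        "spread_fraction",
        "spread_model",
    },
    "respond": {"gain_half_width"},
    "info": {"bin_ms", "cycle_information", "snr_ddof"},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_ALLOWED`` for the schema)."""

    condition: str = "unlabelled"
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    detect: dict = dataclasses.field(default_factory=dict)
    respond: dict = dataclasses.field(default_factory=dict)
    info: dict = dataclasses.field(default_factory=dict)
    input: str | None = None  # existing recording; skips the simulate stage

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _ALLOWED[""]
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for section in ("simulate", "detect", "respond", "info"):
            sec = raw.get(section) or {}
            bad = set(sec) - _ALLOWED[section]
            if bad:
                raise ValueError(
                    f"unknown key(s) in '{section}': {', '.join(sorted(bad))}"
                )
        if "simulate" not in raw and "input" not in raw:
            raise ValueError("config needs either a 'simulate' section or an 'input'")
        if "detect" in raw:
            for key in ("tau_r", "tau_f"):
                if key not in raw["detect"]:
                    raise ValueError(f"detect section must set the kernel '{key}'")
        return cls(
            condition=str(raw.get("condition", "unlabelled")),
            seed=int(raw.get("seed", 0)),
            simulate=dict(raw.get("simulate") or {}),
            detect=dict(raw.get("detect") or {}),
            respond=dict(raw.get("respond") or {}),
            info=dict(raw.get("info") or {}),
            input=raw.get("input"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(read_config(path))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v not in (None, {})}

    @property
    def kernel(self) -> Kernel:
        return Kernel(
            tau_r=float(self.detect.get("tau_r", 0.001)),
            tau_f=float(self.detect.get("tau_f", 0.060)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    package_version: str
    started: str
    finished: str
    outputs: dict  # path -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _protocol_from_config(sim: dict, seed: int) -> StimulusProtocol:
    return make_stimulus(
        sim["contrast_set"],
        frequency=float(sim.get("frequency", 5.0)),
        repeats=int(sim.get("repeats", 1)),
        seed=seed,
        randomize=bool(sim.get("randomize", True)),
    )


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the configured stages in order and write a run manifest.

    Stage order is simulate (optional) -> detect -> respond -> info. A
    failing stage aborts with :class:`StageError` naming the stage;
    outputs of completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    outputs: dict[str, str] = {}

    def _register(path: Path) -> None:
        outputs[path.name] = _sha256(path)

    # ---- simulate ----------------------------------------------------
    stage = "simulate"
    try:
        if config.input is None:
            sim = config.simulate
            protocol = _protocol_from_config(sim, config.seed)
            model = ReleaseModel(
                base_rate=float(sim.get("base_rate", 0.0)),
                rate_gain=float(sim.get("rate_gain", 0.0)),
                r_max=sim.get("r_max"),
                c_half=float(sim.get("c_half", 50.0)),
                hill_n=float(sim.get("hill_n", 2.0)),
                quantal_amplitude=float(sim.get("quantal_amplitude", 1.0)),
                mvr_weights={
                    int(k): float(v)
                    for k, v in dict(sim.get("mvr_weights", {1: 1.0})).items()
                },
                amplitude_cv=float(sim.get("amplitude_cv", 0.0)),
                amplitude_spread=str(sim.get("amplitude_spread", "sqrt_k")),
            )
            imaging = ImagingModel(
                n_positions=int(sim.get("n_positions", 24)),
                pixel_size=float(sim.get("pixel_size", 0.2)),
                line_rate=float(sim.get("line_rate", 1000.0)),
                source_centers=tuple(sim.get("source_centers", (2.4,))),
                source_widths=tuple(sim.get("source_widths", (0.4,))),
                noise_sd=float(sim.get("noise_sd", 0.0)),
                bleach_slope=float(sim.get("bleach_slope", 0.0)),
                baseline_F0=float(sim.get("baseline_F0", 100.0)),
            )
            truth = simulate_release(protocol, model, seed=config.seed + 1)
            recording = render_linescan(
                truth,
                config.kernel,
                imaging,
                duration=protocol.duration,
                seed=config.seed + 2,
                release_model=model,
            )
            rec_path = out / "recording.h5"
            write_linescan(rec_path, recording)
            _register(rec_path)
        else:
            recording = read_linescan(config.input)
            sim = config.simulate
            protocol = _protocol_from_config(sim, config.seed) if sim else None
        proto_path = out / "protocol.yaml"
        if protocol is not None:
            write_config(
                proto_path,
                {
                    "contrasts": [float(c) for c in protocol.contrasts],
                    "frequency": protocol.frequency,
                    "seed": protocol.seed,
                },
            )
            _register(proto_path)
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise StageError(stage, err) from err

    # ---- detect ------------------------------------------------------
    stage = "detect"
    try:
        det = config.detect
        series_list = decompose_recording(
            recording,
            config.kernel,
            max_components=int(det.get("max_components", 3)),
            threshold_sd=float(det.get("threshold_sd", 3.5)),
            refractory=float(det.get("refractory_ms", 5.0)) / 1000.0,
            noise_power=det.get("noise_power", "auto"),
            quantal_amplitude=det.get("quantal_amplitude"),
            spread_fraction=float(det.get("spread_fraction", 0.15)),
            spread_model=str(det.get("spread_model", "sqrt_k")),
        )
        series = series_list[0] if series_list else QuantalSeries(
            times=np.empty(0), quanta=np.empty(0, int)
        )
        ev_path = out / "events.csv"
        write_events(ev_path, events_to_table(series))
        _register(ev_path)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # ---- respond -----------------------------------------------------
    stage = "respond"
    try:
        if protocol is None:
            raise ValueError("respond stage needs a protocol (simulate section)")
        counts = count_per_cycle(series, protocol)
        counts_path = out / "cycle_counts.csv"
        counts.table.to_csv(counts_path, index=False)
        _register(counts_path)
        report: dict = {"condition": config.condition}
        if counts.table["contrast"].nunique() >= 4:
            fit = fit_hill(counts)
            report["hill"] = {
                "r_max": fit.r_max,
                "c_half": fit.c_half,
                "hill_n": fit.hill_n,
                "flagged": fit.flagged,
                "flag_reason": fit.flag_reason,
            }
            if np.isfinite(fit.c_half) and not fit.flagged:
                try:
                    gain = contrast_gain(
                        counts,
                        fit.c_half,
                        half_width=float(config.respond.get("gain_half_width", 10.0)),
                    )
                    report["gain"] = {
                        "slope": gain.slope,
                        "window": list(gain.window),
                        "normalization_contrast": gain.normalization_contrast,
                    }
                except ValueError as gerr:
                    report["gain"] = {"error": str(gerr)}
        if counts.table["contrast"].nunique() >= 2:
            fact = factorize_code(counts)
            fact_path = out / "factorization.csv"
            fact.to_csv(fact_path, index=False)
            _register(fact_path)
        resp_path = out / "respond.json"
        with open(resp_path, "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
        _register(resp_path)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # ---- info --------------------------------------------------------
    stage = "info"
    try:
        inf = config.info
        res = information_report(
            series,
            protocol,
            bin_width=float(inf.get("bin_ms", 20.0)) / 1000.0,
            cycle_information=str(inf.get("cycle_information", "sum_bins")),
            counts=counts,
        )
        info_report = {
            "H_S_bits": res.h_s_bits,
            "I_bits_per_bin": res.mi_bits_per_bin,
            "I_bits_per_cycle": res.bits_per_cycle,
            "I_bits_per_s": res.bits_per_s,
            "bin_violation_rate": res.bin_violation_rate,
            "I2_per_q": res.specific.to_dict(orient="records"),
            "SNR_per_contrast": res.snr.table.replace([np.inf], "inf").to_dict(
                orient="records"
            )
            if res.snr is not None
            else None,
        }
        info_path = out / "info.json"
        with open(info_path, "w") as f:
            json.dump(info_report, f, indent=2, sort_keys=True)
        _register(info_path)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=quantalglu.__version__,
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=outputs,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
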