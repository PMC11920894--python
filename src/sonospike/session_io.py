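"""Session-bundle serialization and run configuration.

A session bundle is a directory of plain-text files:

- ``session.json``  — protocol parameters, seed, package version
- ``triggers.csv``  — trial, onset_s
- ``spikes.csv``    — unit_id, time_s
- ``units.csv``     — unit_id, channel, ground-truth label and spec fields
- ``artifacts.csv`` — start_s, end_s
- ``trace.bin`` + ``trace_meta.json`` — optional raw float32 traces

Times are written in seconds with 6 decimal places; CSVs are UTF-8 with a
header row and '.' decimal separator, a fixed dialect so that identical
configurations produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import StimulusProtocol
from .spikeproc import UnitRecording
from .synthetic import (
    SessionFixture,
    UnitSpec,
    generate_template,
    preset,
    TEMPLATE_SAMPLE_RATE,
)

_TIME_FMT = "%.6f"


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Resolved configuration for an end-to-end pipeline run.

    ``population`` is a list of ``{"preset": name, "count": int,
    "overrides": {...}}`` entries; overrides patch individual UnitSpec
    fields. Every stochastic stage derives its stream from ``seed``.
    """

    seed: int
    protocol: dict = field(default_factory=dict)
    population: list = field(default_factory=list)
    analysis: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    artifact_rate: float = 0.0

    _KNOWN = {"seed", "protocol", "population", "analysis", "classify", "artifact_rate"}
    _ANALYSIS_KEYS = {
        "bin_width", "t_pre", "t_post", "drop_first", "sem_mode",
        "delayed_window", "min_consec", "cv_thresh",
    }
    _CLASSIFY_KEYS = {"ambiguity_thresh", "rate_cutoff"}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigError("config must set an explicit seed")
        bad = set(d.get("analysis", {})) - cls._ANALYSIS_KEYS
        if bad:
            raise ConfigError(f"unknown analysis keys: {sorted(bad)}")
        bad = set(d.get("classify", {})) - cls._CLASSIFY_KEYS
        if bad:
            raise ConfigError(f"unknown classify keys: {sorted(bad)}")
        for entry in d.get("population", []):
            if "preset" not in entry or "count" not in entry:
                raise ConfigError("population entries need 'preset' and 'count'")
        return cls(
            seed=int(d["seed"]),
            protocol=dict(d.get("protocol", {})),
            population=list(d.get("population", [])),
            analysis=dict(d.get("analysis", {})),
            classify=dict(d.get("classify", {})),
            artifact_rate=float(d.get("artifact_rate", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "protocol": self.protocol,
            "population": self.population,
            "analysis": self.analysis,
            "classify": self.classify,
            "artifact_rate": self.artifact_rate,
        }

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def build_protocol(self) -> StimulusProtocol:
        return StimulusProtocol(**self.protocol)

    def build_population(self) -> list[tuple[UnitSpec, int]]:
        from dataclasses import replace

        pop = []
        for entry in self.population:
            spec = preset(entry["preset"])
            overrides = entry.get("overrides", {})
            if overrides:
                if "onset_trunc" in overrides:
                    overrides = dict(overrides)
                    overrides["onset_trunc"] = tuple(overrides["onset_trunc"])
                spec = replace(spec, **overrides)
            pop.append((spec, int(entry["count"])))
        return pop


def _write_csv(df: pd.DataFrame, path: Path, float_cols: list[str]) -> None:
    df = df.copy()
    for c in float_cols:
        df[c] = df[c].map(lambda x: _TIME_FMT % x if pd.notna(x) else "")
    df.to_csv(path, index=False)


def save_session(fixture: SessionFixture, out_dir: str | Path) -> Path:
    """Write a session bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    meta = {
        "package_version": __version__,
        "seed": fixture.seed,
        "protocol": fixture.protocol.to_dict(),
        "n_units": len(fixture.units),
        "duration_s": round(fixture.duration, 6),
        "has_trace": fixture.traces is not None,
    }
    (out / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    _write_csv(
        pd.DataFrame(
            {"trial": np.arange(len(fixture.triggers)), "onset_s": fixture.triggers}
        ),
        out / "triggers.csv",
        ["onset_s"],
    )

    rows = []
    for u in fixture.units:
        for t in u.spike_times:
            rows.append((u.unit_id, t))
    _write_csv(
        pd.DataFrame(rows, columns=["unit_id", "time_s"]),
        out / "spikes.csv",
        ["time_s"],
    )

    urows = []
    for u in fixture.units:
        spec = u.truth.get("spec", {})
        urows.append(
            {
                "unit_id": u.unit_id,
                "channel": u.channel,
                "cell_type": u.truth.get("cell_type", ""),
                "response_kind": u.truth.get("response_kind", ""),
                "onset_s": u.truth.get("onset"),
                "baseline_rate": spec.get("baseline_rate", np.nan),
                "gain": spec.get("gain", np.nan),
                "response_dur": spec.get("response_dur", np.nan),
                "ip_ms": spec.get("ip_dur", np.nan),
                "ahp_ms": spec.get("ahp_dur", np.nan),
                "amp": spec.get("amp", np.nan),
            }
        )
    _write_csv(
        pd.DataFrame(urows),
        out / "units.csv",
        ["onset_s", "baseline_rate", "gain", "response_dur", "ip_ms", "ahp_ms", "amp"],
    )

    _write_csv(
        pd.DataFrame(fixture.artifact_epochs, columns=["start_s", "end_s"]),
        out / "artifacts.csv",
        ["start_s", "end_s"],
    )

    if fixture.traces is not None:
        fixture.traces.astype(np.float32).tofile(out / "trace.bin")
        (out / "trace_meta.json").write_text(
            json.dumps(
                {
                    "sample_rate": fixture.trace_sample_rate,
                    "n_channels": fixture.traces.shape[0],
                    "n_samples": fixture.traces.shape[1],
                    "dtype": "float32",
                },
                indent=2,
            )
        )
    return out


_REQUIRED = {
    "triggers.csv": ["trial", "onset_s"],
    "spikes.csv": ["unit_id", "time_s"],
    "units.csv": ["unit_id", "channel", "cell_type", "response_kind", "onset_s"],
    "artifacts.csv": ["start_s", "end_s"],
}


def load_session(path: str | Path) -> SessionFixture:
    """Load a session bundle written by :func:`save_session`.

    Waveform templates are regenerated from the stored phase durations.
    Extra columns are tolerated; missing required columns raise a schema
    error naming them.
    """
    import warnings

    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    frames: dict[str, pd.DataFrame] = {}
    for fname, cols in _REQUIRED.items():
        df = pd.read_csv(path / fname)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{fname}: missing required columns {missing}")
        extra = [c for c in df.columns if c not in cols and fname != "units.csv"]
        if extra:
            warnings.warn(f"{fname}: ignoring extra columns {extra}")
        frames[fname] = df

    protocol = StimulusProtocol(**meta["protocol"])
    triggers = frames["triggers.csv"]["onset_s"].to_numpy()
    spikes = frames["spikes.csv"]
    udf = pd.read_csv(path / "units.csv")
    duration = float(meta["duration_s"])

    units: list[UnitRecording] = []
    for _, row in udf.iterrows():
        st = spikes.loc[spikes["unit_id"] == row["unit_id"], "time_s"].to_numpy()
        tpl = generate_template(row["ip_ms"], row["ahp_ms"], row["amp"])
        truth = {
            "cell_type": row["cell_type"],
            "response_kind": row["response_kind"],
            "onset": None if pd.isna(row["onset_s"]) else float(row["onset_s"]),
        }
        units.append(
            UnitRecording(
                unit_id=row["unit_id"],
                spike_times=np.sort(st),
                template=tpl,
                sample_rate=TEMPLATE_SAMPLE_RATE,
                duration=duration,
                channel=int(row["channel"]),
                truth=truth,
            )
        )
    epochs = [
        (float(r["start_s"]), float(r["end_s"]))
        for _, r in frames["artifacts.csv"].iterrows()
    ]

    traces = None
    trace_sr = None
    if meta.get("has_trace") and (path / "trace.bin").exists():
        tmeta = json.loads((path / "trace_meta.json").read_text())
        traces = np.fromfile(path / "trace.bin", dtype=np.float32).reshape(
            tmeta["n_channels"], tmeta["n_samples"]
        )
        trace_sr = tmeta["sample_rate"]

    return SessionFixture(
        protocol=protocol,
        triggers=triggers,
        units=units,
        artifact_epochs=epochs,
        seed=int(meta["seed"]),
        traces=traces,
        trace_sample_rate=trace_sr,
    )


def load_nwb_session(path: str | Path):  # pragma: no cover - optional interface
    """Loader contract for NWB sessions.

    An implementation must return ``(spike_times_per_unit, trigger_times,
    templates)`` for a recorded session. No NWB backend ships with this
    package; the synthetic bundle format covers all tested paths, and this
    hook exists so recorded data can be dropped into the same pipeline.
    """
    raise NotImplementedError(
        "no NWB backend is installed; provide a loader returning "
        "(spike_times_per_unit, trigger_times, templates)"
    )
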