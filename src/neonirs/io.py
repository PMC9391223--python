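"""Dataset layout, readers/writers and pipeline configuration.

A study lives in one directory::

    root/
      study.json                  # montage, groups, phases, device, seed
      ground_truth.json           # simulation sidecar (synthetic studies)
      sub-<id>/<phase>/
        intensity.tsv             # time + one column per channel x wavelength
        events.tsv                # BIDS convention: onset, duration, trial_type
        resting.json              # resting-window annotation
      derived/                    # per-stage outputs (features.tsv, reports)

Everything is TSV + JSON so datasets are inspectable and language-neutral;
numeric columns are written at full float precision (%.17g) so round trips
are lossless and re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, make_montage
from .signals import MbllParams, RawRecording, WAVELENGTHS
from .simulate import (EventSchedule, GroundTruth, ScheduledEvent,
                       StudyConfig, StudyData)

__all__ = ["PipelineConfig", "write_raw", "read_raw", "write_events",
           "read_events", "write_study", "read_study_index", "load_config",
           "file_sha256"]

_FMT = "%.17g"


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

_SIM_KEYS = {"n_per_group", "group_sizes", "n_channels", "n_forward",
             "n_backward", "trial_dur", "iti_range", "resting_duration",
             "amp_delta", "lat_delta", "conn_delta", "base_amplitude",
             "null_effects", "quiet_noise"}


@dataclass
class PipelineConfig:
    """All stage parameters (defaults = the analysis' stated values) plus
    the optional simulate directive and the global seed."""

    seed: int = 0
    dataset: str | None = None           # consume an existing study root
    simulate: dict | None = None         # or simulate one (keys in _SIM_KEYS)
    band: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 3
    artifact_fraction: float = 0.2
    spike_sd_threshold: float = 6.0
    spike_window_s: float = 1.0
    saturation_run_length: int = 10
    epoch_window: tuple[float, float] = (-2.0, 20.0)
    amplitude_window: tuple[float, float] = (6.0, 16.0)
    search_window: tuple[float, float] = (0.0, 20.0)
    resting_duration: float = 180.0
    q_star: float = 0.15
    alpha: float = 0.05
    threshold_rule: str = "experimental_T0"
    od_reference: str = "mean"

    def __post_init__(self) -> None:
        if self.dataset is None and self.simulate is None:
            raise ValueError("config needs either 'dataset' or 'simulate'")
        if self.simulate is not None:
            unknown = set(self.simulate) - _SIM_KEYS
            if unknown:
                raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        if not (0 < self.q_star <= 1) or not (0 < self.alpha < 1):
            raise ValueError("q_star and alpha must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("band", "epoch_window", "amplitude_window",
                  "search_window"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def study_config(self) -> StudyConfig:
        sim = dict(self.simulate or {})
        sim.pop("amp_delta", None); sim.pop("lat_delta", None)
        sim.pop("conn_delta", None); sim.pop("base_amplitude", None)
        sim.pop("null_effects", None); sim.pop("quiet_noise", None)
        npg = sim.pop("n_per_group", None)
        if npg is not None:
            sim["group_sizes"] = {g: npg for g in
                                  ("experimental", "active", "passive")}
        if "iti_range" in sim:
            sim["iti_range"] = tuple(sim["iti_range"])
        sim.setdefault("resting_duration", self.resting_duration)
        return StudyConfig(**sim)

    def ground_truth(self, montage: Montage) -> GroundTruth:
        from .simulate import NoiseSpec
        sim = dict(self.simulate or {})
        noise = NoiseSpec.quiet() if sim.get("quiet_noise") else None
        if sim.get("null_effects"):
            return GroundTruth.null(
                noise=noise or NoiseSpec(),
                base_amplitude=sim.get("base_amplitude", 1.0))
        kw = {k: sim[k] for k in ("amp_delta", "lat_delta", "conn_delta",
                                  "base_amplitude") if k in sim}
        return GroundTruth.default(montage, noise=noise, **kw)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return PipelineConfig.from_dict(d)


# --------------------------------------------------------------------------
# Raw recordings
# --------------------------------------------------------------------------

def write_raw(raw: RawRecording, out_dir: str | Path) -> Path:
    """Write one recording's intensity table (lossless)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = raw.n_samples
    cols = {"time": np.arange(n) / raw.sampling_rate}
    for c in range(raw.n_channels):
        for wi, wl in enumerate(WAVELENGTHS):
            cols[f"ch{c + 1:02d}_{wl}"] = raw.intensity[c, wi]
    df = pd.DataFrame(cols)
    path = out_dir / "intensity.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)
    meta = {"sampling_rate": raw.sampling_rate,
            "dynamic_range": list(raw.dynamic_range),
            "subject_id": raw.subject_id, "group": raw.group,
            "phase": raw.phase, "session_kind": raw.session_kind}
    (out_dir / "recording.json").write_text(json.dumps(meta, sort_keys=True,
                                                       indent=1))
    return path


def read_raw(rec_dir: str | Path) -> RawRecording:
    """Read a recording; wavelength columns are normalised to (760, 850)
    order whatever their order on disk."""
    rec_dir = Path(rec_dir)
    tsv = rec_dir / "intensity.tsv"
    if not tsv.exists():
        raise FileNotFoundError(f"missing intensity table: {tsv}")
    meta = json.loads((rec_dir / "recording.json").read_text())
    df = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
    chan_wl = {}
    for col in df.columns:
        if col == "time":
            continue
        name, wl = col.rsplit("_", 1)
        chan_wl.setdefault(int(name[2:]), {})[int(wl)] = col
    cids = sorted(chan_wl)
    arr = np.stack([
        np.stack([df[chan_wl[c][wl]].to_numpy() for wl in WAVELENGTHS])
        for c in cids])
    return RawRecording(arr, meta["sampling_rate"],
                        tuple(meta["dynamic_range"]), meta["subject_id"],
                        meta["group"], meta["phase"], meta["session_kind"])


def write_events(schedule: EventSchedule, out_dir: str | Path) -> Path:
    """BIDS-style events table: onset, duration, trial_type."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "onset": [e.onset for e in schedule.events],
        "duration": [e.duration for e in schedule.events],
        "trial_type": [e.stimulus_type for e in schedule.events],
    })
    path = out_dir / "events.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)
    return path


def read_events(rec_dir: str | Path) -> EventSchedule:
    path = Path(rec_dir) / "events.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing events table: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    events = tuple(
        ScheduledEvent(float(r.onset), float(r.duration), str(r.trial_type), i)
        for i, r in enumerate(df.itertuples()))
    dur = events[-1].onset + events[-1].duration if events else 0.0
    return EventSchedule(events, "test", duration=dur)


# --------------------------------------------------------------------------
# Whole studies
# --------------------------------------------------------------------------

def write_study(study: StudyData, root: str | Path) -> Path:
    """Materialise a simulated study to disk (subject by subject)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    index = []
    for si, pi, raw, sched, annot in study.iter_recordings():
        sid, group = cfg.subjects[si]
        phase = cfg.phases[pi]
        rec_dir = root / f"sub-{sid}" / phase
        write_raw(raw, rec_dir)
        write_events(sched, rec_dir)
        (rec_dir / "resting.json").write_text(
            json.dumps(annot, sort_keys=True))
        index.append({"subject_id": sid, "group": group, "phase": phase,
                      "path": str(rec_dir.relative_to(root))})
    study_meta = {
        "seed": study.seed,
        "n_channels": cfg.n_channels,
        "groups": cfg.group_sizes,
        "phases": list(cfg.phases),
        "sampling_rate": cfg.sampling_rate,
        "distance": cfg.distance,
        "dynamic_range": list(cfg.dynamic_range),
        "i0": cfg.i0,
        "mbll": {"extinction": [list(r) for r in cfg.mbll.extinction],
                 "dpf": list(cfg.mbll.dpf), "log_base": cfg.mbll.log_base},
        "recordings": index,
    }
    (root / "study.json").write_text(json.dumps(study_meta, sort_keys=True,
                                                indent=1))
    (root / "ground_truth.json").write_text(
        json.dumps(study.ground_truth.to_dict(), sort_keys=True, indent=1))
    return root


def read_study_index(root: str | Path) -> dict:
    root = Path(root)
    meta = json.loads((root / "study.json").read_text())
    for rec in meta["recordings"]:
        full = root / rec["path"]
        if not (full / "intensity.tsv").exists():
            raise FileNotFoundError(f"study index references missing "
                                    f"recording: {full}")
    meta["root"] = str(root)
    meta["montage"] = make_montage(meta["n_channels"])
    meta["mbll_params"] = MbllParams(
        tuple(tuple(r) for r in meta["mbll"]["extinction"]),
        tuple(meta["mbll"]["dpf"]), meta["mbll"]["log_base"])
    return meta


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
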