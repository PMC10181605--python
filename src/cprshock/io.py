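"""On-disk formats: columnar signal text, JSON timelines, manifests, checkpoints.

Schema
------
``<poi>.csv``   columns ``time_s, ecg_uV[, impedance_ohm]`` written at full
                float precision (%.17g) so that a write→read round trip is
                lossless.
``<poi>.json``  sidecar with fs, band, t0, label and the event timeline:
                ``cc_episodes`` as ``[[start, stop], ...]`` (half-open,
                seconds, floats), ``aed_analysis_start``,
                ``rhythm_segments`` as ``[[start, stop, label], ...]``,
                ``cc_rate`` and ``extent``.
``manifest.tsv``  one row per period: patient_id, poi_id, split, label.

Model checkpoints are a ``.npz`` of the weight arrays plus a JSON sidecar
carrying the architecture, analysis duration, decision threshold and the
config hash of the run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import ModelSpec, OperatingPoint, ShockClassifier, TrainConfig
from .synth import Dataset
from .types import (
    CprShockError,
    EventTimeline,
    LengthMismatchError,
    MalformedTimelineError,
    PeriodOfInterest,
    RhythmLabel,
    SamplingRateMismatchError,
    SignalRecord,
)

__all__ = [
    "RunConfig",
    "write_record",
    "read_record",
    "write_dataset",
    "read_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


def write_record(basepath, record: SignalRecord, timeline: EventTimeline,
                 label: RhythmLabel) -> None:
    """Write ``<basepath>.csv`` (signals) and ``<basepath>.json`` (timeline)."""
    basepath = Path(basepath)
    n = len(record.ecg)
    t = record.t0 + (np.arange(n) + 1) / record.fs
    cols = {"time_s": t, "ecg_uV": record.ecg}
    if record.impedance is not None:
        cols["impedance_ohm"] = record.impedance
    pd.DataFrame(cols).to_csv(basepath.with_suffix(".csv"), index=False,
                              float_format="%.17g")
    meta = {
        "record_id": record.record_id,
        "fs": record.fs,
        "band": list(record.band),
        "t0": record.t0,
        "label": RhythmLabel(label).value,
        "timeline": {
            "cc_episodes": [[s, e] for s, e in timeline.cc_episodes],
            "aed_analysis_start": timeline.aed_analysis_start,
            "rhythm_segments": [[s, e, lab.value]
                                for (s, e), lab in timeline.rhythm_segments],
            "cc_rate": timeline.cc_rate,
            "extent": list(timeline.extent) if timeline.extent else None,
        },
    }
    basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_record(basepath) -> tuple[SignalRecord, EventTimeline, RhythmLabel]:
    """Read a record written by :func:`write_record`, validating the schema."""
    basepath = Path(basepath)
    try:
        meta = json.loads(basepath.with_suffix(".json").read_text())
    except json.JSONDecodeError as exc:
        raise MalformedTimelineError(f"unparseable timeline JSON: {exc}") from exc
    frame = pd.read_csv(basepath.with_suffix(".csv"), float_precision="round_trip")
    if "time_s" not in frame or "ecg_uV" not in frame:
        raise CprShockError("signal file must carry time_s and ecg_uV columns")
    fs = float(meta["fs"])
    t = frame["time_s"].to_numpy()
    if len(t) > 1:
        step = np.median(np.diff(t))
        if abs(step - 1.0 / fs) > 0.01 / fs:
            raise SamplingRateMismatchError(
                f"time column step {step:.6g} s disagrees with fs={fs} Hz"
            )
    imp = frame["impedance_ohm"].to_numpy() if "impedance_ohm" in frame else None
    tl_meta = meta["timeline"]
    try:
        timeline = EventTimeline(
            cc_episodes=tuple(tuple(iv) for iv in tl_meta["cc_episodes"]),
            aed_analysis_start=float(tl_meta["aed_analysis_start"]),
            rhythm_segments=tuple(((s, e), RhythmLabel(lab))
                                  for s, e, lab in tl_meta["rhythm_segments"]),
            cc_rate=float(tl_meta.get("cc_rate", 110.0)),
            extent=tuple(tl_meta["extent"]) if tl_meta.get("extent") else None,
        )
    except (KeyError, TypeError) as exc:
        raise MalformedTimelineError(f"timeline JSON missing fields: {exc}") from exc
    record = SignalRecord(
        record_id=meta["record_id"], ecg=frame["ecg_uV"].to_numpy(), fs=fs,
        impedance=imp, band=tuple(meta.get("band", (1.0, 30.0))),
        t0=float(meta.get("t0", 0.0)),
    )
    return record, timeline, RhythmLabel(meta["label"])


def write_dataset(dataset: Dataset, outdir) -> Path:
    """Write every period of interest plus ``manifest.tsv``; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for poi_id, poi in dataset.pois.items():
        rec = SignalRecord(record_id=poi_id, ecg=poi.samples, fs=poi.fs, t0=-30.0)
        write_record(outdir / poi_id, rec, poi.timeline, poi.label)
    dataset.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir


def read_dataset(indir) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    pois = {}
    for row in manifest.itertuples():
        rec, timeline, label = read_record(indir / row.poi_id)
        pois[row.poi_id] = PeriodOfInterest(
            source=rec.record_id, samples=rec.ecg, timeline=timeline,
            label=label, fs=rec.fs, poi_id=row.poi_id,
        )
    return Dataset(pois=pois, manifest=manifest)


@dataclass
class RunConfig:
    """Frozen effective configuration of a pipeline run."""

    duration: int = 10
    seed: int = 0
    runs: int = 5
    manifest: Optional[str] = None
    threshold: Optional[float] = None  # None -> selected on validation
    outdir: str = "runs"
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def freeze(self, outdir) -> Path:
        path = Path(outdir) / "run_config.yaml"
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = self.to_dict()
        payload["config_hash"] = self.config_hash
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload.pop("config_hash", None)
        train = payload.pop("train", None)
        cfg = cls(**payload)
        if train:
            cfg.train = TrainConfig(**train)
        return cfg


def save_checkpoint(basepath, classifier: ShockClassifier,
                    operating_point: Optional[OperatingPoint] = None,
                    config_hash: str = "") -> None:
    """Write weights (``.npz``) and an architecture/threshold JSON sidecar."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    weights = classifier.get_weights()
    np.savez(basepath.with_suffix(".npz"),
             **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {
        "duration": classifier.duration,
        "spec": dataclasses.asdict(classifier.spec),
        "n_params": classifier.n_params,
        "config_hash": config_hash,
        "operating_point": dataclasses.asdict(operating_point)
        if operating_point else None,
    }
    basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(basepath) -> tuple[ShockClassifier, Optional[OperatingPoint]]:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    spec_d = meta["spec"]
    spec = ModelSpec(
        kernel_sizes=tuple(spec_d["kernel_sizes"]),
        filters=tuple(spec_d["filters"]),
        pool_size=spec_d["pool_size"], dropout=spec_d["dropout"],
        init_scale=spec_d["init_scale"],
    )
    clf = ShockClassifier(meta["duration"], spec=spec, seed=0)
    with np.load(basepath.with_suffix(".npz")) as npz:
        clf.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
    op = None
    if meta.get("operating_point"):
        op = OperatingPoint(**meta["operating_point"])
    return clf, op
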