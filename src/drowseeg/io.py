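"""File formats: CSV signal files with JSON sidecars, epoch directories
with manifests, feature tables, and report serialization.

A recording is stored as a CSV with one row per sample and one column per
channel (header = channel names, values in uV, 6 decimal places) next to a
JSON sidecar holding sampling rate, subject/session identity, label and
seed provenance.  Output bytes are deterministic for a fixed recording.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from drowseeg.features import CSPModel, FeatureMatrix
from drowseeg.preprocess import Epoch, EpochSet
from drowseeg.synth import LabeledDataset, Recording, SessionProtocol

_FLOAT_FMT = "%.6f"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path, seed: int | None = None) -> Path:
    """Write ``<path>.csv`` (or the given .csv path) plus a JSON sidecar."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ValueError("refusing to write an empty recording")
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "label": rec.label,
        "channel_names": rec.channel_names,
        "n_samples": rec.n_samples,
        "seed": seed,
        "format_version": 1,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a CSV + JSON sidecar pair written by :func:`write_recording`."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"{path} contains NaN values")
    n_meta = len(meta["channel_names"])
    if df.shape[1] != n_meta:
        raise ValueError(
            f"channel count mismatch: CSV has {df.shape[1]} columns, "
            f"sidecar declares {n_meta}"
        )
    return Recording(
        data=df.to_numpy().T,
        sampling_rate=meta["sampling_rate"],
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        label=meta["label"],
        channel_names=list(meta["channel_names"]),
    )


def write_dataset(ds: LabeledDataset, out_dir: str | Path) -> Path:
    """Write every recording of a dataset plus a dataset manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for rec in ds.recordings:
        name = f"{rec.subject_id}_{rec.session_id}.csv"
        write_recording(rec, out_dir / name, seed=ds.seed)
        files.append(name)
    manifest = {
        "protocol": asdict(ds.protocol),
        "seed": ds.seed,
        "recordings": files,
        "format_version": 1,
    }
    (out_dir / "dataset.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def read_dataset(in_dir: str | Path) -> LabeledDataset:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "dataset.json").read_text())
    protocol = SessionProtocol(**manifest["protocol"])
    recordings = [read_recording(in_dir / name) for name in manifest["recordings"]]
    return LabeledDataset(recordings=recordings, protocol=protocol, seed=manifest["seed"])


def write_epochs(es: EpochSet, out_dir: str | Path) -> Path:
    """Serialize an epoch set to a directory of per-epoch CSVs + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, e in enumerate(es.epochs):
        name = f"epoch_{i:05d}.csv"
        pd.DataFrame(e.data.T).to_csv(
            out_dir / name, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )
        entries.append(
            {
                "file": name,
                "label": e.label,
                "subject_id": e.subject_id,
                "session_id": e.session_id,
                "start_offset": e.start_offset,
                "augmented": e.augmented,
            }
        )
    manifest = {
        "sampling_rate": es.sampling_rate,
        "window": es.window,
        "overlap_fraction": es.overlap_fraction,
        "epochs": entries,
        "format_version": 1,
    }
    (out_dir / "epochs.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def read_epochs(in_dir: str | Path) -> EpochSet:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "epochs.json").read_text())
    epochs = []
    for entry in manifest["epochs"]:
        data = pd.read_csv(in_dir / entry["file"]).to_numpy().T
        epochs.append(
            Epoch(
                data=data,
                label=entry["label"],
                subject_id=entry["subject_id"],
                session_id=entry["session_id"],
                start_offset=entry["start_offset"],
                augmented=entry["augmented"],
            )
        )
    return EpochSet(
        epochs=epochs,
        sampling_rate=manifest["sampling_rate"],
        window=manifest["window"],
        overlap_fraction=manifest["overlap_fraction"],
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "label", fm.labels)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    labels = df.pop("label").tolist()
    return FeatureMatrix(
        values=df.to_numpy(), feature_names=list(df.columns), labels=labels
    )


def write_csp_model(model: CSPModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "filters_row_major": model.filters.ravel().tolist(),
        "shape": list(model.filters.shape),
        "eigenvalues": model.eigenvalues.tolist(),
        "n_components": model.n_components,
        "class_order": list(model.class_order),
        "format_version": 1,
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def read_csp_model(path: str | Path) -> CSPModel:
    doc = json.loads(Path(path).read_text())
    return CSPModel(
        filters=np.array(doc["filters_row_major"]).reshape(doc["shape"]),
        eigenvalues=np.array(doc["eigenvalues"]),
        n_components=doc["n_components"],
        class_order=tuple(doc["class_order"]),
    )


def epochset_hash(es: EpochSet) -> str:
    """Stable content hash of an epoch set (data + labels), for manifests."""
    h = hashlib.sha256()
    for e in es.epochs:
        h.update(np.ascontiguousarray(np.round(e.data, 9)).tobytes())
        h.update(e.label.encode())
    return h.hexdigest()
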