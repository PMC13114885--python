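"""Reading and writing the pipeline's file formats.

Behavioral tables and phenotype tables travel as CSV; signals as NPZ
archives with a JSON sidecar carrying the sample rate and phase intervals
(seconds, half-open, time origin at recording start); EDF recordings are
read through MNE when it is installed. Reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehavioralMatrix
from .eegsignal import EEGRecording


def write_behavioral_csv(table: BehavioralMatrix, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_behavioral_csv(path: str | Path, standardized: bool = True
                        ) -> BehavioralMatrix:
    return BehavioralMatrix.from_frame(pd.read_csv(path),
                                       standardized=standardized)


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write samples to ``<path>.npz`` and metadata to ``<path>.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), samples=rec.samples)
    meta = {
        "sample_rate": rec.sample_rate,
        "phase_intervals": {k: list(v) for k, v in rec.phase_intervals.items()},
        "animal_id": rec.animal_id,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def read_recording(path: str | Path) -> EEGRecording:
    """Read an NPZ + JSON-sidecar recording (or a bare .npy/.csv of samples
    with the sidecar)."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if path.suffix == ".npz" or path.with_suffix(".npz").exists():
        arr = np.load(path.with_suffix(".npz"))["samples"]
    elif path.suffix == ".csv":
        arr = np.loadtxt(path)
    else:
        arr = np.load(path)
    return EEGRecording(
        samples=arr,
        sample_rate=float(meta["sample_rate"]),
        phase_intervals={k: tuple(v) for k, v in
                         meta.get("phase_intervals", {}).items()},
        animal_id=meta.get("animal_id", ""),
    )


def read_edf(path: str | Path, channel: str = "EEG",
             phase_intervals: dict | None = None) -> EEGRecording:
    """Read one channel of an EDF file (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install pndeeg[edf])"
                          ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"channel {channel!r} not in {raw.ch_names}")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return EEGRecording(samples=data, sample_rate=float(raw.info["sfreq"]),
                        phase_intervals=phase_intervals or {},
                        animal_id=Path(path).stem)


def write_json_report(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if k != "model"}
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
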