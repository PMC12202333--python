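"""Reading and writing recordings and cohorts.

The interchange format is one two-column CSV (FP1, FP2, microvolts) per
recording plus a ``manifest.csv`` with columns path, subject_id, state, fs.
EDF files can be read through the optional mne dependency (channel labels
matched case-insensitively against FP1/FP2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import CHANNELS, EEGRecording

MANIFEST_COLUMNS = ("path", "subject_id", "state", "fs")


def write_recording_csv(recording: EEGRecording, path) -> None:
    pd.DataFrame({ch: recording.channels[i]
                  for i, ch in enumerate(CHANNELS)}).to_csv(path, index=False)


def read_recording_csv(path, subject_id, state: str, fs: float) -> EEGRecording:
    df = pd.read_csv(path)
    cols = {c.upper(): c for c in df.columns}
    missing = [ch for ch in CHANNELS if ch not in cols]
    if missing:
        raise ValueError(f"{path}: missing channel columns {missing}")
    channels = np.vstack([df[cols[ch]].to_numpy(dtype=float)
                          for ch in CHANNELS])
    return EEGRecording(subject_id=subject_id, state=state, fs=fs,
                        channels=channels)


def read_recording_edf(path, subject_id, state: str) -> EEGRecording:
    """Read FP1/FP2 from an EDF file (requires mne)."""
    try:
        import mne
    except ImportError as err:   # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the optional 'mne' package")\
            from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    name_map = {name.upper().replace(" ", ""): name for name in raw.ch_names}
    picks = []
    for ch in CHANNELS:
        match = next((orig for key, orig in name_map.items() if ch in key),
                     None)
        if match is None:
            raise ValueError(f"{path}: no channel matching {ch}")
        picks.append(match)
    data = raw.get_data(picks=picks) * 1e6    # volts -> microvolts
    return EEGRecording(subject_id=subject_id, state=state,
                        fs=float(raw.info["sfreq"]), channels=data)


def write_cohort(recordings: list[EEGRecording], out_dir) -> Path:
    """Write one CSV per recording plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        name = f"sub{int(rec.subject_id):03d}_{rec.state}.csv"
        write_recording_csv(rec, out_dir / name)
        rows.append({"path": name, "subject_id": rec.subject_id,
                     "state": rec.state, "fs": rec.fs})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest,
                                                              index=False)
    return manifest


def read_cohort(manifest_path) -> list[EEGRecording]:
    """Load all recordings listed in a manifest (CSV or EDF per row)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and
               not (c == "fs" and "fs" in df.columns)]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    recordings = []
    for _, row in df.iterrows():
        path = base / str(row["path"])
        if path.suffix.lower() == ".edf":
            rec = read_recording_edf(path, row["subject_id"], row["state"])
        else:
            rec = read_recording_csv(path, row["subject_id"], row["state"],
                                     float(row["fs"]))
        recordings.append(rec)
    return recordings
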