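"""Core data containers shared across the pipeline.

The unit of acquisition is a two-channel (FP1, FP2) forehead EEG recording;
the unit of classification is a non-overlapping 1-s epoch cut from it.
Feature extraction turns epochs into rows of a :class:`FeatureTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("FP1", "FP2")

#: canonical state labels; fatigue is the positive class throughout
STATE_NORMAL = "normal"
STATE_FATIGUE = "fatigue"
STATES = (STATE_NORMAL, STATE_FATIGUE)

#: columns of a feature-table DataFrame that are metadata, not features
META_COLUMNS = ("subject_id", "state", "label", "epoch_index")


@dataclass
class EEGRecording:
    """One subject/state's continuous two-channel signal.

    ``channels`` is a float array of shape (2, n_samples) in microvolts,
    ordered (FP1, FP2).
    """

    subject_id: int
    state: str
    fs: float
    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 2:
            raise ValueError("channels must have shape (2, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A 1-s two-channel window; ``samples`` has shape (2, fs)."""

    subject_id: int
    state: str
    fs: float
    samples: np.ndarray
    index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise ValueError("samples must have shape (2, fs)")

    def channel(self, name: str) -> np.ndarray:
        return self.samples[CHANNELS.index(name)]


@dataclass
class FeatureTable:
    """Epochs x named features plus label metadata.

    ``df`` holds one row per epoch with the metadata columns of
    :data:`META_COLUMNS` followed by feature columns.  Labels are binary
    (normal=0, fatigue=1).
    """

    df: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = [
                c for c in self.df.columns if c not in META_COLUMNS
            ]
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing metadata columns {missing}")

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def subjects(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def select_features(self, names: list[str]) -> "FeatureTable":
        cols = list(META_COLUMNS) + list(names)
        return FeatureTable(self.df[cols].copy(), list(names))

    def select_rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.df.loc[mask].reset_index(drop=True),
                            list(self.feature_names))

    def channel_subset(self, channels: tuple[str, ...]) -> "FeatureTable":
        """Restrict to features whose name ends in one of the channel suffixes."""
        names = [n for n in self.feature_names
                 if any(n.endswith("_" + ch) for ch in channels)]
        return self.select_features(names)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))


def state_to_label(state: str) -> int:
    if state == STATE_NORMAL:
        return 0
    if state == STATE_FATIGUE:
        return 1
    raise ValueError(f"unknown state label {state!r}; expected one of {STATES}")
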