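"""In-memory containers shared across the pipeline.

The interchange currency between stages is deliberately small: a continuous
:class:`Recording`, a trial-locked :class:`EpochSet`, its windowed
:class:`SegmentSet`, and the :class:`FeatureMatrix` fed to the classifier.
All arrays are float64 microvolts; channel axes carry explicit labels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The three task cues, in canonical display order.
CLASSES = ("REST", "MI-GRASP", "MI-ELBOW")


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One unique label per row of ``data``.
    reference_label : str
        Name of the reference electrode (vertex Cz by convention).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference_label: str = "Cz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("row count does not match channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventList:
    """Cue onsets (sample indices into a recording) with task labels."""

    onsets: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.onsets.shape != self.labels.shape or self.onsets.ndim != 1:
            raise ValueError("onsets and labels must be equal-length 1-D")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown task labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class EpochSet:
    """Trial-locked 3-D array (trials x channels x samples).

    ``window`` records the epoch extent in seconds relative to cue onset.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    window: tuple[float, float]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("trial count does not match labels")
        self.channel_labels = list(self.channel_labels)
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class SegmentSet(EpochSet):
    """Fixed-length analysis windows cut from epochs.

    Each instance inherits the label of its parent trial; ``parent_trial``
    maps every instance back to the epoch it was cut from so that
    cross-validation can keep sibling windows on the same side of a fold.
    """

    parent_trial: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.parent_trial = np.asarray(self.parent_trial, dtype=np.int64)
        if len(self.parent_trial) != self.data.shape[0]:
            raise ValueError("parent_trial must have one entry per instance")


@dataclass
class FeatureMatrix:
    """Instances x named features, plus per-instance labels.

    ``groups`` (optional) carries the parent-trial index of each instance;
    the cross-validation driver uses it to group sibling windows.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("row count does not match labels")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=np.int64)
            if len(self.groups) != self.values.shape[0]:
                raise ValueError("groups must have one entry per row")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        if self.groups is not None:
            df["group"] = self.groups
        return df

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write features as CSV plus an optional JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        groups = df.pop("group").to_numpy() if "group" in df.columns else None
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(float), list(df.columns), labels, groups)
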