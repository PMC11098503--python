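"""Trial-resolved recordings to analysis-ready response matrices.

The recordings arrive as stimuli x repetitions x channels x time-bins
arrays (1 ms bins, stimulus onset partway into the trial).  Analysis
uses a per-region feedforward time window (e.g. 25-125 ms after onset
for V1, later for V4 and IT, tracking response latency down the ventral
stream), averages over the window and over repetitions, and z-scores
each channel with statistics estimated on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionMap",
    "ResponseRecording",
    "ResponseMatrix",
    "build_region_map",
    "average_window",
    "average_repetitions",
    "normalize_channels",
    "sliding_windows",
]


@dataclass
class RegionMap:
    """Channel-to-region assignment plus per-region time windows.

    ``channel_region``/``channel_array`` assign every channel to exactly
    one region and array (contiguous indexing grouped by array);
    ``windows`` holds per-region (start, end) in ms after stimulus
    onset, half-open.
    """

    channel_region: np.ndarray  # (C,) str
    channel_array: np.ndarray  # (C,) int
    windows: dict[str, tuple[float, float]]
    region_names: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channel_region)

    def channels(self, region: str) -> np.ndarray:
        """Indices of the channels recorded in ``region``."""
        if region not in self.region_names:
            raise KeyError(f"unknown region {region!r}")
        return np.flatnonzero(self.channel_region == region)

    def to_frame(self) -> pd.DataFrame:
        """Channel map as a DataFrame (channel, array, region)."""
        return pd.DataFrame(
            {
                "channel": np.arange(self.n_channels),
                "array": self.channel_array,
                "region": self.channel_region,
            }
        )


@dataclass
class ResponseRecording:
    """Stimuli x repetitions x channels x time-bins recording."""

    values: np.ndarray
    onset_ms: int = 100
    bin_ms: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("recording must be 4-D (stim, rep, channel, bin)")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_reps(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def trial_ms(self) -> int:
        return self.values.shape[3] * self.bin_ms


@dataclass
class ResponseMatrix:
    """Stimuli x channels matrix after windowing, averaging and z-scoring."""

    values: np.ndarray
    mean: np.ndarray | None = None  # training-set per-channel mean
    std: np.ndarray | None = None  # training-set per-channel std
    window_note: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("response matrix must be 2-D (stimuli x channels)")


def build_region_map(
    spec: list[tuple[str, int, int]] | tuple[tuple[str, int, int], ...],
    windows: dict[str, tuple[float, float]] | None = None,
) -> RegionMap:
    """Lay out channels contiguously by array, grouped by region.

    ``spec`` lists (region, n_arrays, channels_per_array); the standard
    configuration (V1, 7, 64), (V4, 4, 64), (IT, 4, 64) yields 960
    channels.  ``windows`` gives per-region onset-relative time windows
    in ms.
    """
    spec = list(spec)
    if not spec:
        raise ValueError("region spec must be nonempty")
    names = [name for name, *_ in spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names in spec")
    regions: list[str] = []
    arrays: list[int] = []
    array_id = 0
    for name, n_arrays, per_array in spec:
        if n_arrays < 1 or per_array < 1:
            raise ValueError("array and channel counts must be positive")
        for _ in range(n_arrays):
            regions.extend([name] * per_array)
            arrays.extend([array_id] * per_array)
            array_id += 1
    windows = dict(windows) if windows else {}
    return RegionMap(
        channel_region=np.array(regions),
        channel_array=np.array(arrays),
        windows=windows,
        region_names=tuple(names),
    )


def average_window(
    rec: ResponseRecording, region_map: RegionMap
) -> np.ndarray:
    """Average each channel over its region's time window.

    Windows are half-open [start, end) in ms relative to stimulus onset,
    so a 25-125 ms window spans exactly 100 one-ms bins.  Repetitions
    are preserved; returns (stimuli, reps, channels).
    """
    if rec.bin_ms != 1:
        raise ValueError("windowing assumes 1 ms bins")
    out = np.empty(rec.values.shape[:3])
    for name in region_map.region_names:
        if name not in region_map.windows:
            raise ValueError(f"no time window specified for region {name!r}")
        start, end = region_map.windows[name]
        lo = int(rec.onset_ms + start)
        hi = int(rec.onset_ms + end)
        if not (0 <= lo < hi <= rec.trial_ms):
            raise ValueError(
                f"window [{start}, {end}) for {name!r} outside the recorded trial"
            )
        chans = region_map.channels(name)
        out[:, :, chans] = rec.values[:, :, chans, lo:hi].mean(axis=3)
    return out


def average_repetitions(values: np.ndarray | ResponseRecording) -> np.ndarray:
    """Mean over the repetition axis (axis 1)."""
    arr = values.values if isinstance(values, ResponseRecording) else np.asarray(values)
    if arr.ndim < 2 or arr.shape[1] < 1:
        raise ValueError("need at least one repetition")
    return arr.mean(axis=1)


def normalize_channels(
    train: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Z-score every channel using training-split statistics only.

    Returns ([train_normalized, *others_normalized], mean, std).  The
    training columns come out with mean 0 and (population) std 1; other
    splits are transformed with the training statistics, never their
    own.  A zero-variance training channel is an explicit error naming
    the channel, since its z-score is undefined.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance training channel(s) {dead.tolist()}: cannot z-score"
        )
    normalized = [(train - mean) / std]
    for other in others:
        other = np.asarray(other, dtype=float)
        if other.shape[1] != train.shape[1]:
            raise ValueError("channel count mismatch between splits")
        normalized.append((other - mean) / std)
    return normalized, mean, std


def sliding_windows(
    trial_ms: int, window_ms: int, stride_ms: int
) -> list[tuple[int, int]]:
    """Sliding half-open windows covering the trial.

    Starts at 0 and advances by ``stride_ms`` while the window fits:
    floor((trial - window)/stride) + 1 windows in total.  The standard
    time-resolved setting (300 ms trial, 100 ms window, 25 ms stride)
    yields nine windows.
    """
    if stride_ms < 1:
        raise ValueError("stride must be >= 1 ms")
    if window_ms < 1 or window_ms > trial_ms:
        raise ValueError("window must be positive and fit inside the trial")
    return [
        (start, start + window_ms)
        for start in range(0, trial_ms - window_ms + 1, stride_ms)
    ]
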