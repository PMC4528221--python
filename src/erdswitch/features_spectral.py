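"""Welch band-power features, ERD/ERS time-frequency maps, EMG summaries.

The classifier's features are Welch power spectral densities over
8-24 Hz at 4 Hz resolution (Hann-tapered 250 ms windows, 50% overlap),
computed separately for the movement window (0-3 s after cue onset, the
ERD range) and the post-movement window (3.5-6 s, the ERS/beta-rebound
range).  For the nine-channel motor set this yields the
9 channels x 5 frequencies x 2 windows = 90 features per trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_epochs import EpochSet
from .session_model import Condition
from .synthetic_data import RawRecording

__all__ = [
    "FeatureMatrix",
    "TFMap",
    "welch_psd",
    "extract_features",
    "tf_map",
    "emg_power_summary",
]

ERD_WINDOW = (0.0, 3.0)
ERS_WINDOW = (3.5, 6.0)
BAND = (8.0, 24.0)
RESOLUTION_HZ = 4.0
WIN_S = 0.25


@dataclass
class FeatureMatrix:
    """Trials x features band-power matrix with per-column metadata.

    ``meta`` is a DataFrame with columns ``channel``, ``frequency_hz`` and
    ``window`` ("ERD" or "ERS"), one row per feature column, ordered
    (channel, frequency, window) with window varying fastest.
    """

    values: np.ndarray
    meta: pd.DataFrame
    labels: list[Condition]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be trials x features")
        if len(self.meta) != self.values.shape[1]:
            raise ValueError("meta rows must equal feature count")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def label_names(self) -> np.ndarray:
        return np.array([c.name for c in self.labels])

    def column_names(self) -> list[str]:
        return [
            f"{r.channel}_{r.frequency_hz:g}Hz_{r.window}"
            for r in self.meta.itertuples()
        ]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "condition", self.label_names)
        df.to_csv(path, sep="\t", index=False)

    def meta_matches(self, other: "FeatureMatrix") -> bool:
        return self.meta.reset_index(drop=True).equals(
            other.meta.reset_index(drop=True)
        )


@dataclass
class TFMap:
    """Relative-baseline time-frequency map: channels x frequencies x time.

    Power averaged over trials, divided per channel-frequency cell by its
    mean over the baseline window, so 1 is average power, values below 1
    mark ERD and values above 1 mark ERS.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    baseline_window: tuple[float, float]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            values=self.values,
            freqs=self.freqs,
            times=self.times,
            channel_labels=np.array(self.channel_labels),
            baseline_window=np.array(self.baseline_window),
        )


def _welch_segmenting(fs: float, win_s: float, overlap: float) -> tuple[int, int]:
    """(nperseg, noverlap) with the step rounded down, so a 3 s segment at
    250 ms windows / 50% overlap yields (3000-250)/125 + 1 = 23 averages."""
    nperseg = int(round(win_s * fs))
    noverlap = math.ceil(nperseg * overlap)
    return nperseg, noverlap


def welch_psd(
    segment: np.ndarray,
    fs: float,
    win_s: float = WIN_S,
    overlap: float = 0.5,
    band: tuple[float, float] = BAND,
    res: float = RESOLUTION_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of ``segment`` (..., samples), band bins only.

    Returns ``(freqs, power)`` where ``freqs`` are the retained bins --
    multiples of ``res`` inside ``band``, endpoints inclusive (8, 12, 16,
    20, 24 Hz for the defaults).  The window length must give exactly the
    requested resolution (win_s = 1/res).

    Raises
    ------
    ValueError
        If the segment is shorter than one window.
    """
    segment = np.asarray(segment)
    nperseg, noverlap = _welch_segmenting(fs, win_s, overlap)
    if segment.shape[-1] < nperseg:
        raise ValueError(
            f"segment of {segment.shape[-1]} samples is shorter than one "
            f"{nperseg}-sample Welch window"
        )
    if not math.isclose(fs / nperseg, res, rel_tol=1e-6):
        raise ValueError(
            f"window of {nperseg} samples at {fs} Hz gives {fs / nperseg:g} Hz "
            f"resolution, not the requested {res:g} Hz"
        )
    freqs, power = sps.welch(
        segment,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    keep = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    return freqs[keep], power[..., keep]


def extract_features(
    epochs: EpochSet,
    channels: "list[str] | tuple[str, ...] | None" = None,
    erd_window: tuple[float, float] = ERD_WINDOW,
    ers_window: tuple[float, float] = ERS_WINDOW,
    log_power: bool = True,
) -> FeatureMatrix:
    """Band-power features for the ERD and ERS windows of every trial.

    Columns are ordered deterministically by (channel, frequency, window),
    window varying fastest.  ``log_power`` applies a log10 transform,
    which conditions the classifier better than raw power.
    """
    if channels is None:
        channels = list(epochs.channel_labels)
    sub = epochs.select_channels(list(channels))
    fs = sub.sample_rate_hz

    def window_power(window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
        lo = int(round((window[0] - sub.times[0]) * fs))
        hi = int(round((window[1] - sub.times[0]) * fs))
        if lo < 0 or hi > sub.data.shape[-1]:
            raise ValueError(f"epochs do not span the {window} s feature window")
        return welch_psd(sub.data[:, :, lo:hi], fs)

    freqs, erd = window_power(erd_window)
    _, ers = window_power(ers_window)
    # (trials, channels, freqs, windows) -> flatten with window fastest
    stacked = np.stack([erd, ers], axis=-1)
    values = stacked.reshape(sub.n_trials, -1)
    if log_power:
        values = np.log10(np.maximum(values, 1e-300))

    meta = pd.DataFrame(
        [
            {"channel": ch, "frequency_hz": f, "window": w}
            for ch in channels
            for f in freqs
            for w in ("ERD", "ERS")
        ]
    )
    return FeatureMatrix(
        values=values, meta=meta, labels=list(sub.labels), log_transformed=log_power
    )


def tf_map(
    epochs: EpochSet,
    condition: Condition | str,
    fmin: float = 2.0,
    fmax: float = 40.0,
    win_s: float = WIN_S,
) -> TFMap:
    """Trial-averaged sliding-window power, relative to the epoch-long baseline.

    Uses the same Hann windowing and hop as the Welch features.  The
    baseline is the mean over the full epoch extent per channel-frequency
    cell, so each cell's time-mean is exactly 1.
    """
    name = condition.name if isinstance(condition, Condition) else condition
    mask = epochs.label_names == name
    if not mask.any():
        raise ValueError(f"no trials with condition {name!r}")
    data = epochs.data[mask]
    fs = epochs.sample_rate_hz
    nperseg, noverlap = _welch_segmenting(fs, win_s, 0.5)
    freqs, times, spec = sps.spectrogram(
        data,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
        axis=-1,
    )
    keep = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    mean_power = spec[:, :, keep].mean(axis=0)  # channels x freqs x time
    baseline = mean_power.mean(axis=-1, keepdims=True)
    values = mean_power / baseline
    return TFMap(
        values=values,
        freqs=freqs[keep],
        times=times + epochs.times[0],
        channel_labels=epochs.channel_labels,
        baseline_window=(float(epochs.times[0]), float(epochs.times[-1])),
    )


def emg_power_summary(
    raw: RawRecording,
    events,
    conditions: "list[str] | None" = None,
    reference_condition: str = "actual",
    window: tuple[float, float] = (0.1, 3.5),
    stat: str = "power",
) -> pd.Series:
    """Per-condition EMG activity as a percentage of the reference condition.

    Processing chain: bipolar difference of the two EMG channels ->
    zero-phase 4th-order Butterworth high-pass at 10 Hz -> magnitude of
    the analytic (Hilbert) signal -> per-trial mean over ``window``
    seconds from cue onset -> per-condition mean -> percent of the
    reference condition.  With ``stat="power"`` (default) the per-trial
    statistic is the squared mean envelope; ``stat="magnitude"`` uses the
    mean envelope itself.
    """
    if stat not in ("power", "magnitude"):
        raise ValueError("stat must be 'power' or 'magnitude'")
    emg = raw.pick("EMG")
    if emg.shape[0] != 2:
        raise ValueError(f"expected exactly 2 EMG channels, found {emg.shape[0]}")
    fs = raw.sample_rate_hz
    bipolar = emg[0] - emg[1]
    sos = sps.butter(4, 10.0, btype="highpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, bipolar)
    envelope = np.abs(sps.hilbert(filtered))

    event_list = events.events if hasattr(events, "events") else list(events)
    per_trial: dict[str, list[float]] = {}
    for e in event_list:
        lo = int(round((e.onset_s + window[0]) * fs))
        hi = int(round((e.onset_s + window[1]) * fs))
        if lo < 0 or hi > envelope.size:
            raise ValueError(f"EMG window of trial at {e.onset_s:.3f} s out of range")
        m = float(envelope[lo:hi].mean())
        per_trial.setdefault(e.condition.name, []).append(
            m**2 if stat == "power" else m
        )

    if conditions is None:
        conditions = list(per_trial)
    if reference_condition not in per_trial:
        raise ValueError(
            f"reference condition {reference_condition!r} has no trials; "
            "cannot compute percentages"
        )
    ref = float(np.mean(per_trial[reference_condition]))
    out = {}
    for name in conditions:
        if name not in per_trial:
            raise ValueError(f"condition {name!r} has no trials")
        out[name] = 100.0 * float(np.mean(per_trial[name])) / ref
    return pd.Series(out, name=f"emg_{stat}_percent")
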