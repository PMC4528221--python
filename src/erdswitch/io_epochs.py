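"""BrainVision-dialect I/O and condition-labeled epoch extraction.

Supports exactly one encoding of the three-file BrainVision format --
text header (.vhdr), little-endian IEEE float32 multiplexed binary (.eeg)
and text marker file (.vmrk) -- written and read bit-exactly.  Any other
encoding is rejected loudly rather than guessed.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .session_model import Condition, SessionPlan, TrialEvent
from .synthetic_data import RawRecording

__all__ = [
    "EpochSet",
    "write_brainvision",
    "read_brainvision",
    "extract_epochs",
]


class BrainVisionFormatError(ValueError):
    """Inconsistent or corrupt BrainVision triplet."""


class UnsupportedDialectError(ValueError):
    """Valid BrainVision file in an encoding this reader does not support."""


@dataclass
class EpochSet:
    """Cut trials: ``data`` is trials x channels x samples (uV).

    ``times`` holds seconds relative to cue onset, covering the half-open
    window [tmin, tmax); ``labels`` carries one :class:`Condition` per
    trial.
    """

    data: np.ndarray
    times: np.ndarray
    labels: list[Condition]
    sample_rate_hz: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels must match channel axis")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("times must match sample axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def label_names(self) -> np.ndarray:
        return np.array([c.name for c in self.labels])

    def select_conditions(self, *names: str) -> "EpochSet":
        mask = np.isin(self.label_names, names)
        if not mask.any():
            raise ValueError(f"no trials with condition(s) {names}")
        return replace(
            self,
            data=self.data[mask],
            labels=[c for c, m in zip(self.labels, mask) if m],
        )

    def select_channels(self, labels: "list[str] | tuple[str, ...]") -> "EpochSet":
        idx = []
        for l in labels:
            if l not in self.channel_labels:
                raise ValueError(f"unknown channel {l!r}")
            idx.append(self.channel_labels.index(l))
        return replace(self, data=self.data[:, idx], channel_labels=tuple(labels))

    def save(self, path: str | Path) -> None:
        """Cache to a portable .npz container (shape + label metadata)."""
        np.savez(
            path,
            data=self.data,
            times=self.times,
            names=self.label_names,
            phase=np.array([c.phase for c in self.labels]),
            sample_rate_hz=self.sample_rate_hz,
            channel_labels=np.array(self.channel_labels),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as z:
            labels = [
                Condition(str(n), int(p)) for n, p in zip(z["names"], z["phase"])
            ]
            return cls(
                data=z["data"],
                times=z["times"],
                labels=labels,
                sample_rate_hz=float(z["sample_rate_hz"]),
                channel_labels=tuple(str(l) for l in z["channel_labels"]),
            )


# --------------------------------------------------------------------------
# BrainVision triplet
# --------------------------------------------------------------------------

_HEADER_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by erdswitch

[Common Infos]
Codepage=UTF-8
DataFile={base}.eeg
MarkerFile={base}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us:g}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_MARKER_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={base}.eeg

[Marker Infos]
{marker_lines}
"""


def write_brainvision(
    rec: RawRecording, events: SessionPlan | None, basepath: str | Path
) -> tuple[Path, Path, Path]:
    """Write ``<basepath>.vhdr``, ``.eeg`` and ``.vmrk``.

    Data is stored as little-endian float32, multiplexed (channel index
    varies fastest).  Each trial event becomes a Stimulus marker whose
    description is the condition name; marker positions are 1-based sample
    indices, per the format's convention.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    channel_lines = "\n".join(
        f"Ch{i + 1}={label},,1,µV" for i, label in enumerate(rec.channel_labels)
    )
    header = _HEADER_TEMPLATE.format(
        base=base.name,
        n_channels=len(rec.channel_labels),
        sampling_interval_us=1e6 / rec.sample_rate_hz,
        channel_lines=channel_lines,
    )
    base.with_suffix(".vhdr").write_text(header, encoding="utf-8")

    rec.data.T.astype("<f4").tofile(base.with_suffix(".eeg"))

    markers = ["Mk1=New Segment,,1,1,0,20000101000000000000"]
    fs = rec.sample_rate_hz
    for k, e in enumerate(events.events if events is not None else []):
        pos = int(round(e.onset_s * fs)) + 1
        size = int(round(e.duration_s * fs))
        markers.append(f"Mk{k + 2}=Stimulus,{e.condition.name},{pos},{size},0")
    vmrk = _MARKER_TEMPLATE.format(base=base.name, marker_lines="\n".join(markers))
    base.with_suffix(".vmrk").write_text(vmrk, encoding="utf-8")
    return base.with_suffix(".vhdr"), base.with_suffix(".eeg"), base.with_suffix(".vmrk")


def _read_ini(path: Path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser(strict=False)
    text = path.read_text(encoding="utf-8")
    # drop the signature line, which is not INI syntax
    body = "\n".join(
        line for line in text.splitlines() if not line.startswith("Brain Vision")
    )
    parser.read_string(body)
    return parser


def _infer_phase(names: set[str]) -> int:
    if "attempted" in names:
        return 2
    return 1


def read_brainvision(basepath: str | Path) -> tuple[RawRecording, SessionPlan]:
    """Inverse of :func:`write_brainvision` for the supported dialect.

    Raises
    ------
    UnsupportedDialectError
        For any DataFormat/Orientation/BinaryFormat other than binary
        multiplexed IEEE float32.
    BrainVisionFormatError
        If the binary size is inconsistent with the channel count.
    """
    base = Path(basepath)
    hdr_path = base.with_suffix(".vhdr")
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    hdr = _read_ini(hdr_path)
    common = hdr["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise UnsupportedDialectError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise UnsupportedDialectError("only MULTIPLEXED orientation is supported")
    binfmt = hdr["Binary Infos"].get("BinaryFormat", "")
    if binfmt.upper() != "IEEE_FLOAT_32":
        raise UnsupportedDialectError(f"unsupported BinaryFormat {binfmt!r}")
    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    labels = []
    kinds = []
    for i in range(n_channels):
        entry = hdr["Channel Infos"][f"Ch{i + 1}"]
        label = entry.split(",")[0]
        labels.append(label)
        kinds.append("EMG" if label.upper().startswith("EMG") else "EEG")

    raw_bytes = base.with_suffix(".eeg").read_bytes()
    if len(raw_bytes) % (4 * n_channels) != 0:
        raise BrainVisionFormatError(
            f"binary size {len(raw_bytes)} bytes is not a whole number of "
            f"float32 frames for {n_channels} channels"
        )
    flat = np.frombuffer(raw_bytes, dtype="<f4")
    data = flat.reshape(-1, n_channels).T.astype(np.float64)

    events: list[TrialEvent] = []
    vmrk = _read_ini(base.with_suffix(".vmrk"))
    raw_markers = []
    for key, value in vmrk["Marker Infos"].items():
        parts = value.split(",")
        if parts[0] != "Stimulus":
            continue
        desc, pos, size = parts[1], int(parts[2]), int(parts[3])
        raw_markers.append((pos, desc, size))
    raw_markers.sort()
    phase = _infer_phase({desc for _, desc, _ in raw_markers})

    seq = -1
    prev_end = -np.inf
    prev_name = None
    for pos, desc, size in raw_markers:
        onset = (pos - 1) / fs
        # sequence boundaries: condition change or a gap longer than the
        # in-sequence cue+silence period
        if desc != prev_name or onset - prev_end > 4.5:
            seq += 1
        events.append(
            TrialEvent(
                onset_s=onset,
                duration_s=size / fs,
                condition=Condition(desc, phase),
                sequence_index=seq,
                block_index=0,
            )
        )
        prev_end = onset + size / fs
        prev_name = desc

    rec = RawRecording(
        data=data,
        sample_rate_hz=fs,
        channel_labels=tuple(labels),
        channel_kinds=tuple(kinds),
    )
    plan = SessionPlan(
        phase=phase,
        events=events,
        sample_rate_hz=fs,
        channel_labels=tuple(labels),
    )
    return rec, plan


# --------------------------------------------------------------------------
# epoching
# --------------------------------------------------------------------------


def extract_epochs(
    rec: RawRecording,
    events: SessionPlan | list[TrialEvent],
    tmin: float = -1.0,
    tmax: float = 6.0,
) -> EpochSet:
    """Cut per-trial windows [onset+tmin, onset+tmax), EEG channels only.

    The default window spans 1 s of pre-cue baseline through the end of
    the post-movement rebound at 6 s; with 7 s between cue onsets,
    consecutive windows never overlap.
    """
    if tmax <= tmin:
        raise ValueError("tmax must exceed tmin")
    event_list = events.events if isinstance(events, SessionPlan) else list(events)
    fs = rec.sample_rate_hz
    n_win = int(round((tmax - tmin) * fs))
    eeg_idx = [i for i, k in enumerate(rec.channel_kinds) if k == "EEG"]
    eeg_labels = tuple(rec.channel_labels[i] for i in eeg_idx)

    trials = np.empty((len(event_list), len(eeg_idx), n_win))
    labels: list[Condition] = []
    for t, e in enumerate(event_list):
        start = int(round((e.onset_s + tmin) * fs))
        stop = start + n_win
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"epoch window of trial {t} (onset {e.onset_s:.3f} s) lies "
                f"outside the recording [0, {rec.duration_s:.3f}) s"
            )
        trials[t] = rec.data[eeg_idx, start:stop]
        labels.append(e.condition)

    times = tmin + np.arange(n_win) / fs
    return EpochSet(
        data=trials,
        times=times,
        labels=labels,
        sample_rate_hz=fs,
        channel_labels=eeg_labels,
    )
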