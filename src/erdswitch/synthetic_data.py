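"""Synthetic cued-movement EEG/EMG sessions.

No data were published with the study this package models, so every
downstream stage is exercised on simulated recordings that carry the
signal structure the analysis assumes:

* a 1/f-shaped Gaussian EEG background on every scalp channel;
* narrowband mu (~10 Hz) and beta (~20 Hz) rhythm sources projected with a
  smooth left-lateralized topography peaking at C3 (right-hand task,
  contralateral cortex) and weakly mirrored at C4;
* event-related desynchronization: during each cue the rhythm amplitude at
  the focal channels is scaled by (1 - erd_depth) for 0-3 s, and by
  (1 + ers_gain) for 3.5-6 s after onset (the post-movement beta rebound),
  with raised-cosine ramps to avoid spectral splatter;
* a 2-channel EMG pair whose first electrode carries band-limited
  (>20 Hz) activity bursts during cues, scaled per condition so mean
  squared-envelope power is ``emg_percent`` % of the actual-movement level.

Everything is reproducible bit-for-bit from the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

from .session_model import (
    DEFAULT_EEG_CHANNELS,
    DEFAULT_EMG_CHANNELS,
    SessionPlan,
)
from .spatial_filter import standard_montage

__all__ = [
    "ConditionProfile",
    "SyntheticConfig",
    "RawRecording",
    "default_condition_profiles",
    "generate_recording",
]


@dataclass(frozen=True)
class ConditionProfile:
    """Effect sizes of one condition.

    erd_depth : fraction in [0, 1]
        Relative reduction of mu/beta rhythm amplitude during the cue.
    ers_gain : fraction >= 0
        Relative amplitude increase during the post-movement rebound
        window (3.5-6 s after cue onset).
    emg_percent : percent
        Squared-envelope EMG power of this condition as a percentage of
        the actual-movement condition.
    """

    erd_depth: float
    ers_gain: float
    emg_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.ers_gain < 0:
            raise ValueError("ers_gain must be >= 0")
        if self.emg_percent < 0:
            raise ValueError("emg_percent must be >= 0")


def default_condition_profiles() -> dict[str, ConditionProfile]:
    """Default effect sizes per condition name.

    EMG percentages follow the magnitudes reported for the original
    volunteers (actual movement 100%, everything else around or below 1%
    of it).  ERD is strong and equal for actual, isometric and attempted
    movement; imagined movement gets a markedly weaker ERD, matching the
    observation that its classification accuracies ran lower.  The
    no-movement baseline has no rhythm modulation at all.
    """
    strong = dict(erd_depth=0.5, ers_gain=0.3)
    return {
        "actual": ConditionProfile(emg_percent=100.0, **strong),
        "isometric": ConditionProfile(emg_percent=1.0, **strong),
        "imagined": ConditionProfile(erd_depth=0.25, ers_gain=0.15, emg_percent=0.5),
        "attempted": ConditionProfile(emg_percent=1.0, **strong),
        "none": ConditionProfile(erd_depth=0.0, ers_gain=0.0, emg_percent=0.5),
    }


def null_condition_profiles(emg_percent: float = 0.5) -> dict[str, ConditionProfile]:
    """Profiles with zero rhythm modulation everywhere: labels carry no
    information about the EEG (chance-level dataset)."""
    flat = {
        name: ConditionProfile(erd_depth=0.0, ers_gain=0.0, emg_percent=emg_percent)
        for name in ("actual", "isometric", "imagined", "attempted", "none")
    }
    flat["actual"] = ConditionProfile(0.0, 0.0, 100.0)
    return flat


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic acquisition.

    ``noise_scale`` is the RMS (uV) of the 1/f background per channel;
    ``rhythm_amp`` the RMS (uV) of each rhythm source at the focal channel,
    so rhythm SNR at C3 is ``rhythm_amp / noise_scale``.
    """

    profiles: dict[str, ConditionProfile] = field(default_factory=default_condition_profiles)
    sample_rate_hz: float = 2500.0
    noise_scale: float = 10.0
    rhythm_amp: float = 10.0
    focal_channel: str = "C3"
    mirror_channel: str = "C4"
    mirror_gain: float = 0.25
    topography_width_rad: float = 0.5
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    rhythm_bandwidth_hz: float = 4.0
    ramp_s: float = 0.2
    emg_amp: float = 50.0
    emg_floor: float = 0.005  # RMS of EMG noise floor, fraction of emg_amp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 2 * self.beta_hz:
            raise ValueError("sample_rate_hz must exceed twice the beta frequency")
        for name in ("noise_scale", "rhythm_amp", "emg_amp", "mirror_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "profiles" in d:
            d["profiles"] = {
                name: p if isinstance(p, ConditionProfile) else ConditionProfile(**p)
                for name, p in d["profiles"].items()
            }
        return cls(**d)


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts.

    ``data`` is channels x samples; ``channel_kinds`` marks each channel
    as "EEG" or "EMG".
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: tuple[str, ...]
    channel_kinds: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.channel_kinds) != self.data.shape[0]:
            raise ValueError("channel_kinds length must match data rows")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def pick(self, kind: str) -> np.ndarray:
        idx = [i for i, k in enumerate(self.channel_kinds) if k == kind]
        return self.data[idx]


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                      corner_hz: float = 1.0) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f power spectrum above ``corner_hz``."""
    n_ch, n = shape
    # pad to an FFT-friendly length, then truncate
    nfast = spfft.next_fast_len(n, real=True)
    white = rng.standard_normal((n_ch, nfast), dtype=np.float32)
    freqs = np.fft.rfftfreq(nfast, 1.0 / fs)
    gain = (1.0 / np.sqrt(np.maximum(freqs, corner_hz))).astype(np.float32)
    spec = spfft.rfft(white, axis=-1, overwrite_x=True)
    spec *= gain
    shaped = spfft.irfft(spec, n=nfast, axis=-1, overwrite_x=True)[:, :n]
    shaped /= shaped.std(axis=-1, keepdims=True)
    return np.ascontiguousarray(shaped)


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    f_lo: float, f_hi: float, edge_hz: float = 0.5) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [f_lo, f_hi] with smooth
    raised-cosine spectral edges."""
    nfast = spfft.next_fast_len(n, real=True)
    white = rng.standard_normal(nfast, dtype=np.float32)
    freqs = np.fft.rfftfreq(nfast, 1.0 / fs)
    mask = np.zeros_like(freqs, dtype=np.float32)
    core = (freqs >= f_lo) & (freqs <= f_hi)
    mask[core] = 1.0
    for f_edge, rising in ((f_lo, True), (f_hi, False)):
        if edge_hz <= 0:
            continue
        if rising:
            sel = (freqs >= f_edge - edge_hz) & (freqs < f_edge)
            x = (freqs[sel] - (f_edge - edge_hz)) / edge_hz
        else:
            sel = (freqs > f_edge) & (freqs <= f_edge + edge_hz)
            x = 1.0 - (freqs[sel] - f_edge) / edge_hz
        mask[sel] = 0.5 - 0.5 * np.cos(np.pi * x)
    out = spfft.irfft(spfft.rfft(white) * mask, n=nfast)[:n]
    std = out.std()
    return out / std if std > 0 else out


def _highpass_noise(rng: np.random.Generator, n: int, fs: float, f_lo: float) -> np.ndarray:
    return _bandpass_noise(rng, n, fs, f_lo, fs / 2.0, edge_hz=2.0)


def _add_smooth_window(out: np.ndarray, fs: float, t_on: float, t_off: float,
                       ramp_s: float, gain: float) -> None:
    """Add ``gain`` times a 0->1->0 window over [t_on, t_off] (raised-cosine
    ramps of ``ramp_s``) into ``out`` in place, touching only the local span."""
    n = out.size
    lo = max(int(np.floor((t_on - ramp_s) * fs)), 0)
    hi = min(int(np.ceil((t_off + ramp_s) * fs)) + 1, n)
    if lo >= hi:
        return
    t = np.arange(lo, hi) / fs
    w = np.zeros(hi - lo)
    w[(t >= t_on) & (t < t_off)] = 1.0
    if ramp_s > 0:
        rise = (t >= t_on - ramp_s) & (t < t_on)
        w[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - (t_on - ramp_s)) / ramp_s)
        fall = (t >= t_off) & (t < t_off + ramp_s)
        w[fall] = 0.5 + 0.5 * np.cos(np.pi * (t[fall] - t_off) / ramp_s)
    out[lo:hi] += gain * w


def _topography(labels: tuple[str, ...], config: SyntheticConfig) -> np.ndarray:
    """Spatial gain of the rhythm source across EEG channels: Gaussian in
    geodesic distance around the focal channel, weakly mirrored."""
    montage = standard_montage(labels)
    pos = montage.positions
    gains = np.zeros(len(labels))
    for center, amp in (
        (config.focal_channel, 1.0),
        (config.mirror_channel, config.mirror_gain),
    ):
        c = montage.position(center)
        ang = np.arccos(np.clip(pos @ c, -1.0, 1.0))
        gains += amp * np.exp(-((ang / config.topography_width_rad) ** 2))
    return gains


# --------------------------------------------------------------------------
# main generator
# --------------------------------------------------------------------------


def generate_recording(
    plan: SessionPlan,
    config: SyntheticConfig | None = None,
    duration_s: float | None = None,
) -> RawRecording:
    """Simulate the continuous EEG+EMG recording of one session plan.

    Parameters
    ----------
    plan : SessionPlan
        Timed, labeled trial events.  Conditions missing from
        ``config.profiles`` raise a ``KeyError``.
    config : SyntheticConfig
        Signal parameters; ``config.seed`` makes the output bit-identical
        across calls.
    duration_s : float, optional
        Total recording length; defaults to the plan's span plus its tail.
        Must contain every cue's 6-second analysis window.
    """
    config = config or SyntheticConfig()
    fs = config.sample_rate_hz
    needed = max((e.onset_s + 6.0 for e in plan.events), default=0.0) + 1.0
    if duration_s is None:
        duration_s = max(plan.duration_s, needed)
    if duration_s < needed:
        raise ValueError(
            f"plan extends beyond requested duration: need >= {needed:.1f} s, "
            f"got {duration_s:.1f} s"
        )
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(config.seed)

    eeg_labels = tuple(l for l in plan.channel_labels if l not in DEFAULT_EMG_CHANNELS)
    if not eeg_labels:
        eeg_labels = DEFAULT_EEG_CHANNELS
    n_eeg = len(eeg_labels)

    for e in plan.events:
        if e.condition.name not in config.profiles:
            raise KeyError(f"no ConditionProfile for condition {e.condition.name!r}")

    # rhythm amplitude envelope shared by mu and beta sources
    envelope = np.ones(n)
    for e in plan.events:
        prof = config.profiles[e.condition.name]
        if prof.erd_depth != 0.0:
            _add_smooth_window(
                envelope, fs, e.onset_s, e.onset_s + e.duration_s,
                config.ramp_s, -prof.erd_depth,
            )
        if prof.ers_gain != 0.0:
            _add_smooth_window(
                envelope, fs, e.onset_s + 3.5, e.onset_s + 6.0,
                config.ramp_s, prof.ers_gain,
            )

    half_bw = config.rhythm_bandwidth_hz / 2.0
    mu = _bandpass_noise(rng, n, fs, config.mu_hz - half_bw, config.mu_hz + half_bw)
    beta = _bandpass_noise(rng, n, fs, config.beta_hz - half_bw, config.beta_hz + half_bw)
    source = config.rhythm_amp * envelope * (mu + beta)

    eeg = config.noise_scale * _one_over_f_noise(rng, (n_eeg, n), fs)
    eeg += np.outer(_topography(eeg_labels, config), source)

    # EMG pair: electrode 1 carries the bursts, electrode 2 only floor noise,
    # so the bipolar difference recovers the bursts.
    burst_env = np.zeros(n)
    for e in plan.events:
        prof = config.profiles[e.condition.name]
        amp = float(np.sqrt(prof.emg_percent / 100.0))
        if amp > 0:
            _add_smooth_window(
                burst_env, fs, e.onset_s, e.onset_s + e.duration_s, config.ramp_s, amp
            )
    emg_band_hi = min(500.0, fs / 2.0)
    burst = config.emg_amp * burst_env * _bandpass_noise(rng, n, fs, 20.0, emg_band_hi)
    floor_rms = config.emg_floor * config.emg_amp
    emg = np.vstack(
        [
            burst + floor_rms * _highpass_noise(rng, n, fs, 10.0),
            floor_rms * _highpass_noise(rng, n, fs, 10.0),
        ]
    )

    data = np.vstack([eeg, emg])
    labels = eeg_labels + DEFAULT_EMG_CHANNELS
    kinds = ("EEG",) * n_eeg + ("EMG",) * 2
    return RawRecording(
        data=data,
        sample_rate_hz=fs,
        channel_labels=labels,
        channel_kinds=kinds,
    )
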