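"""Executable model of the cued-movement experimental design.

The study this package models presented blocks of auditory-cued movement
trials: each sequence holds nine 3-second cues separated by 4-second
silences.  Phase 1 (before neuromuscular block) used four conditions --
actual, isometric and imagined movement plus a no-movement baseline -- with
81 trials per condition spread over three blocks.  Phase 2 (during the
block of the forearm) used attempted movement vs. no movement, 54 trials
each in a single block.  A :class:`SessionPlan` captures that design as a
timed, labeled event list that the synthetic generator and the epoching
code both consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "TrialEvent",
    "SessionPlan",
    "build_sequence",
    "build_session_plan",
    "PHASE_CONDITIONS",
    "MOVEMENT_CONDITIONS",
    "DEFAULT_EEG_CHANNELS",
    "DEFAULT_EMG_CHANNELS",
    "MOTOR_CHANNELS",
    "CHANNEL_SETS",
]

#: Conditions valid in each experimental phase.
PHASE_CONDITIONS: dict[int, tuple[str, ...]] = {
    1: ("actual", "isometric", "imagined", "none"),
    2: ("attempted", "none"),
}

#: The task (non-baseline) conditions per phase.
MOVEMENT_CONDITIONS: dict[int, tuple[str, ...]] = {
    1: ("actual", "isometric", "imagined"),
    2: ("attempted",),
}

#: 30-channel scalp montage of the default cap (a 32-channel 10/20 cap with
#: the two mastoid-adjacent electrodes reassigned to EMG recording).
DEFAULT_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

DEFAULT_EMG_CHANNELS: tuple[str, ...] = ("EMG1", "EMG2")

#: Reduced motor-cortex channel set used for the clinically practical setup.
MOTOR_CHANNELS: tuple[str, ...] = ("C3", "C4", "Cz", "F3", "F4", "P3", "P4", "T7", "T8")

CHANNEL_SETS: dict[str, tuple[str, ...]] = {
    "all30": DEFAULT_EEG_CHANNELS,
    "motor9": MOTOR_CHANNELS,
}

#: Design constants: cue length, inter-trial silence, trials per sequence.
CUE_S = 3.0
GAP_S = 4.0
TRIALS_PER_SEQUENCE = 9


@dataclass(frozen=True)
class Condition:
    """A task condition bound to its experimental phase."""

    name: str
    phase: int

    def __post_init__(self) -> None:
        if self.phase not in PHASE_CONDITIONS:
            raise ValueError(f"unknown phase {self.phase!r}; expected 1 or 2")
        if self.name not in PHASE_CONDITIONS[self.phase]:
            raise ValueError(
                f"condition {self.name!r} is not valid for phase {self.phase}; "
                f"expected one of {PHASE_CONDITIONS[self.phase]}"
            )

    @property
    def is_movement(self) -> bool:
        return self.name != "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class TrialEvent:
    """One cued trial: onset/duration in seconds from recording start."""

    onset_s: float
    duration_s: float
    condition: Condition
    sequence_index: int = 0
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sequence_index < 0 or self.block_index < 0:
            raise ValueError("sequence_index and block_index must be nonnegative")


@dataclass
class SessionPlan:
    """Ordered trial events of one recording session.

    Attributes
    ----------
    phase : int
        Experimental phase (1 or 2).
    events : list of TrialEvent
        Ordered by onset; onsets strictly increase and cue windows never
        overlap (each sequence spaces trials cue + gap = 7 s apart).
    sample_rate_hz : float
        Nominal acquisition rate the plan is intended for.
    channel_labels : tuple of str
        EEG + EMG labels of the intended cap layout.
    seed : int
        Seed that produced the sequence order.
    """

    phase: int
    events: list[TrialEvent]
    sample_rate_hz: float = 2500.0
    channel_labels: tuple[str, ...] = DEFAULT_EEG_CHANNELS + DEFAULT_EMG_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for a, b in zip(self.events, self.events[1:]):
            if a.onset_s + a.duration_s > b.onset_s:
                raise ValueError("cue intervals overlap")

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def conditions(self) -> tuple[str, ...]:
        return PHASE_CONDITIONS[self.phase]

    @property
    def duration_s(self) -> float:
        """Time needed to contain the last cue plus a post-cue analysis tail."""
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset_s + last.duration_s + GAP_S

    def trial_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.conditions}
        for e in self.events:
            counts[e.condition.name] += 1
        return counts

    def select(self, *names: str) -> "SessionPlan":
        """Sub-plan containing only the named conditions (order preserved)."""
        for n in names:
            if n not in self.conditions:
                raise ValueError(f"condition {n!r} not in phase-{self.phase} plan")
        kept = [e for e in self.events if e.condition.name in names]
        return replace(self, events=kept)

    # -- tab-separated event file -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "duration_s": [e.duration_s for e in self.events],
                "condition": [e.condition.name for e in self.events],
                "sequence": [e.sequence_index for e in self.events],
                "block": [e.block_index for e in self.events],
                "phase": self.phase,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_rate_hz: float = 2500.0,
        seed: int = 0,
    ) -> "SessionPlan":
        df = pd.read_csv(path, sep="\t")
        phases = df["phase"].unique()
        if len(phases) != 1:
            raise ValueError("event file mixes phases")
        phase = int(phases[0])
        events = [
            TrialEvent(
                onset_s=float(r.onset_s),
                duration_s=float(r.duration_s),
                condition=Condition(str(r.condition), phase),
                sequence_index=int(r.sequence),
                block_index=int(r.block),
            )
            for r in df.itertuples()
        ]
        return cls(phase=phase, events=events, sample_rate_hz=sample_rate_hz, seed=seed)


def build_sequence(
    condition: Condition,
    n_trials: int = TRIALS_PER_SEQUENCE,
    cue_s: float = CUE_S,
    gap_s: float = GAP_S,
    t0: float = 0.0,
    sequence_index: int = 0,
    block_index: int = 0,
) -> list[TrialEvent]:
    """Events of one cued sequence: ``n_trials`` cues of one condition.

    Trial ``k`` starts at ``t0 + k * (cue_s + gap_s)``.  With the default
    timing (3 s cue, 4 s silence) a nine-trial sequence spans onsets
    0, 7, ..., 56 s.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if cue_s <= 0 or gap_s <= 0:
        raise ValueError("cue_s and gap_s must be positive")
    period = cue_s + gap_s
    return [
        TrialEvent(
            onset_s=t0 + k * period,
            duration_s=cue_s,
            condition=condition,
            sequence_index=sequence_index,
            block_index=block_index,
        )
        for k in range(n_trials)
    ]


def build_session_plan(
    phase: int,
    seed: int,
    cue_s: float = CUE_S,
    gap_s: float = GAP_S,
    inter_sequence_gap_s: float = 10.0,
    lead_in_s: float = 10.0,
    sample_rate_hz: float = 2500.0,
) -> SessionPlan:
    """Full-session plan for one phase of the design.

    Phase 1: three blocks, each holding three nine-trial sequences of every
    one of the four conditions (3 blocks x 3 x 9 = 81 trials/condition).
    Phase 2: a single block of six sequences per condition (54 trials each).
    Sequence presentation order is shuffled within each block with a seeded
    generator; the rest between sequences (a self-paced button press in the
    original protocol) is modeled as a fixed gap.
    """
    if phase not in PHASE_CONDITIONS:
        raise ValueError(f"unknown phase {phase!r}; expected 1 or 2")
    if inter_sequence_gap_s < 0 or lead_in_s < 0:
        raise ValueError("gaps must be nonnegative")

    n_blocks = 3 if phase == 1 else 1
    seqs_per_cond_per_block = 3 if phase == 1 else 6
    rng = np.random.default_rng(seed)

    events: list[TrialEvent] = []
    t = lead_in_s
    seq_counter = 0
    seq_span = TRIALS_PER_SEQUENCE * (cue_s + gap_s)
    for block in range(n_blocks):
        block_conditions = [
            Condition(name, phase)
            for name in PHASE_CONDITIONS[phase]
            for _ in range(seqs_per_cond_per_block)
        ]
        order = rng.permutation(len(block_conditions))
        for idx in order:
            events.extend(
                build_sequence(
                    block_conditions[idx],
                    n_trials=TRIALS_PER_SEQUENCE,
                    cue_s=cue_s,
                    gap_s=gap_s,
                    t0=t,
                    sequence_index=seq_counter,
                    block_index=block,
                )
            )
            t += seq_span + inter_sequence_gap_s
            seq_counter += 1
    return SessionPlan(
        phase=phase, events=events, sample_rate_hz=sample_rate_hz, seed=seed
    )
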