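"""End-to-end orchestration: simulate -> preprocess -> features -> classify.

`run_within_condition` reproduces the shape of the study's main analysis
(ten-fold cross-validated accuracy of every movement condition against
its phase's no-movement baseline, per synthetic subject and channel set,
with binomial and group CIs); `run_transfer` reproduces the clinically
motivated variant where the classifier is trained on a phase-1 movement
condition and tested on attempted movement; `run_detector` turns the
transfer classifier into a sequential brain switch.

Every report embeds the configuration hash, seeds and package version, so
reruns of the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brain_switch import evaluate_brain_switch
from .classifier import crossval_accuracy, transfer_accuracy
from .features_spectral import FeatureMatrix, extract_features
from .io_epochs import EpochSet, extract_epochs, write_brainvision
from .session_model import (
    CHANNEL_SETS,
    MOVEMENT_CONDITIONS,
    SessionPlan,
    build_session_plan,
)
from .spatial_filter import SplineParams, linear_detrend, spherical_spline_laplacian
from .stats_eval import binomial_ci, group_mean_ci
from .synthetic_data import (
    ConditionProfile,
    RawRecording,
    SyntheticConfig,
    default_condition_profiles,
    generate_recording,
)

__all__ = [
    "PipelineConfig",
    "simulate_subject",
    "preprocess",
    "run_within_condition",
    "run_transfer",
    "run_detector",
    "write_report",
]


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; all seeds derive from ``seed``."""

    n_subjects: int = 4
    seed: int = 0
    sample_rate_hz: float = 2500.0
    channel_sets: tuple[str, ...] = ("all30", "motor9")
    profiles: dict[str, ConditionProfile] = field(default_factory=default_condition_profiles)
    spline: SplineParams = field(default_factory=SplineParams)
    noise_scale: float = 10.0
    rhythm_amp: float = 10.0
    k_folds: int = 10
    selection: str = "nested"
    log_power: bool = True
    conditions: tuple[str, ...] | None = None  # movement conditions to analyze
    detector_window_trials: int = 8
    detector_target_fa: float = 0.0

    def __post_init__(self) -> None:
        for cs in self.channel_sets:
            if cs not in CHANNEL_SETS:
                raise ValueError(
                    f"channel_sets entry {cs!r} must be one of {sorted(CHANNEL_SETS)}"
                )
        if self.selection not in ("nested", "flat"):
            raise ValueError("selection must be 'nested' or 'flat'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    # -- serialization & provenance ----------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_sets"] = list(self.channel_sets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "profiles" in d:
            d["profiles"] = {
                k: v if isinstance(v, ConditionProfile) else ConditionProfile(**v)
                for k, v in d["profiles"].items()
            }
        if "spline" in d and not isinstance(d["spline"], SplineParams):
            d["spline"] = SplineParams(**d["spline"])
        if "channel_sets" in d:
            d["channel_sets"] = tuple(d["channel_sets"])
        if d.get("conditions") is not None:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def subject_seed(self, subject: int, phase: int) -> int:
        ss = np.random.SeedSequence([self.seed, subject, phase])
        return int(ss.generate_state(1)[0] % (2**31))


def simulate_subject(
    config: PipelineConfig, subject: int, phase: int
) -> tuple[RawRecording, SessionPlan]:
    """Synthetic recording + plan of one subject-phase, seeded from config."""
    seed = config.subject_seed(subject, phase)
    plan = build_session_plan(phase, seed=seed, sample_rate_hz=config.sample_rate_hz)
    syn = SyntheticConfig(
        profiles=config.profiles,
        sample_rate_hz=config.sample_rate_hz,
        noise_scale=config.noise_scale,
        rhythm_amp=config.rhythm_amp,
        seed=seed,
    )
    return generate_recording(plan, syn), plan


def preprocess(
    rec: RawRecording,
    plan: SessionPlan,
    spline: SplineParams | None = None,
) -> EpochSet:
    """Epoch [-1, 6) s, linear detrend, spherical-spline surface Laplacian.

    The Laplacian always runs on the full scalp montage; channel subsets
    are applied afterwards at the feature stage, so the reduced set still
    benefits from the full-cap spatial filter.
    """
    epochs = extract_epochs(rec, plan, tmin=-1.0, tmax=6.0)
    epochs = linear_detrend(epochs)
    return spherical_spline_laplacian(epochs, params=spline or SplineParams())


def _features(config: PipelineConfig, epochs: EpochSet, channel_set: str) -> FeatureMatrix:
    return extract_features(
        epochs, channels=CHANNEL_SETS[channel_set], log_power=config.log_power
    )


def _metadata(config: PipelineConfig, mode: str) -> dict:
    return {
        "mode": mode,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _append_mean_row(rows: list[dict], group_cols: dict) -> dict:
    accs = [r["accuracy"] for r in rows]
    ci = group_mean_ci(accs)
    return {
        **group_cols,
        "subject": "mean",
        "accuracy": ci.mean,
        "ci_lower": ci.lower,
        "ci_upper": ci.upper,
        "ci_method": "t",
        "n_trials": int(np.sum([r["n_trials"] for r in rows])),
    }


def run_within_condition(config: PipelineConfig) -> dict:
    """Cross-validated accuracy of each movement condition vs. baseline.

    Returns ``{"metadata": ..., "table": DataFrame}`` with one row per
    (channel set, condition, subject) plus a group mean row per pairing.
    """
    wanted = {
        phase: [
            c
            for c in MOVEMENT_CONDITIONS[phase]
            if config.conditions is None or c in config.conditions
        ]
        for phase in (1, 2)
    }
    phases = [p for p in (1, 2) if wanted[p]]
    per_subject: dict[int, dict[int, EpochSet]] = {}
    for s in range(config.n_subjects):
        per_subject[s] = {}
        for phase in phases:
            rec, plan = simulate_subject(config, s, phase)
            per_subject[s][phase] = preprocess(rec, plan, config.spline)

    rows: list[dict] = []
    for channel_set in config.channel_sets:
        for phase in phases:
            for condition in wanted[phase]:
                cond_rows = []
                for s in range(config.n_subjects):
                    epochs = per_subject[s][phase].select_conditions(condition, "none")
                    feats = _features(config, epochs, channel_set)
                    cv = crossval_accuracy(
                        feats,
                        k=config.k_folds,
                        seed=config.subject_seed(s, phase),
                        selection=config.selection,
                    )
                    correct = int(round(cv.overall_accuracy * cv.n_trials))
                    ci = binomial_ci(correct, cv.n_trials)
                    cond_rows.append(
                        {
                            "channel_set": channel_set,
                            "condition": condition,
                            "subject": str(s + 1),
                            "accuracy": 100.0 * cv.overall_accuracy,
                            "ci_lower": ci.lower,
                            "ci_upper": ci.upper,
                            "ci_method": ci.method,
                            "n_trials": cv.n_trials,
                        }
                    )
                rows.extend(cond_rows)
                if len(cond_rows) >= 2:
                    rows.append(
                        _append_mean_row(
                            cond_rows,
                            {"channel_set": channel_set, "condition": condition},
                        )
                    )
    return {"metadata": _metadata(config, "within"), "table": pd.DataFrame(rows)}


def run_transfer(config: PipelineConfig) -> dict:
    """Train on each phase-1 movement condition, test on attempted movement."""
    rows: list[dict] = []
    feats: dict[tuple[int, int, str], EpochSet] = {}
    for s in range(config.n_subjects):
        for phase in (1, 2):
            rec, plan = simulate_subject(config, s, phase)
            feats[(s, phase, "epochs")] = preprocess(rec, plan, config.spline)

    train_conditions = [
        c
        for c in MOVEMENT_CONDITIONS[1]
        if config.conditions is None or c in config.conditions
    ]
    for channel_set in config.channel_sets:
        for train_condition in train_conditions:
            cond_rows = []
            for s in range(config.n_subjects):
                train_epochs = feats[(s, 1, "epochs")].select_conditions(
                    train_condition, "none"
                )
                test_epochs = feats[(s, 2, "epochs")].select_conditions(
                    "attempted", "none"
                )
                ftr = _features(config, train_epochs, channel_set)
                fte = _features(config, test_epochs, channel_set)
                acc = transfer_accuracy(
                    ftr, test_features=fte, seed=config.subject_seed(s, 1)
                )
                n_test = fte.n_trials
                ci = binomial_ci(int(round(acc * n_test)), n_test)
                cond_rows.append(
                    {
                        "channel_set": channel_set,
                        "training_condition": train_condition,
                        "subject": str(s + 1),
                        "accuracy": 100.0 * acc,
                        "ci_lower": ci.lower,
                        "ci_upper": ci.upper,
                        "ci_method": ci.method,
                        "n_trials": n_test,
                    }
                )
            rows.extend(cond_rows)
            if len(cond_rows) >= 2:
                rows.append(
                    _append_mean_row(
                        cond_rows,
                        {
                            "channel_set": channel_set,
                            "training_condition": train_condition,
                        },
                    )
                )
    return {"metadata": _metadata(config, "transfer"), "table": pd.DataFrame(rows)}


def run_detector(config: PipelineConfig, channel_set: str = "motor9") -> dict:
    """Actual-movement-trained brain switch evaluated on phase-2 data.

    Per subject: fit the transfer classifier (actual vs. none, phase 1),
    score every phase-2 trial, combine consecutive attempted-trial scores
    into windows, calibrate the alarm threshold on held-out no-movement
    windows at the configured false-alarm target, and report the achieved
    rates.
    """
    rows = []
    for s in range(config.n_subjects):
        rec1, plan1 = simulate_subject(config, s, 1)
        rec2, plan2 = simulate_subject(config, s, 2)
        ep1 = preprocess(rec1, plan1, config.spline).select_conditions("actual", "none")
        ep2 = preprocess(rec2, plan2, config.spline)
        ftr = _features(config, ep1, channel_set)
        fte = _features(config, ep2, channel_set)
        _, model = transfer_accuracy(
            ftr,
            test_features=fte.values,
            test_labels=fte.label_names,
            seed=config.subject_seed(s, 1),
            return_model=True,
        )
        scores = model.decision_values(fte.values)
        names = fte.label_names
        report = evaluate_brain_switch(
            scores[names == "attempted"],
            scores[names == "none"],
            window_trials=config.detector_window_trials,
            target_fa=config.detector_target_fa,
        )
        rows.append({"subject": str(s + 1), "channel_set": channel_set, **report.to_dict()})
    df = pd.DataFrame(rows)
    mean_row = {
        "subject": "mean",
        "channel_set": channel_set,
        "false_alarm_rate": df["false_alarm_rate"].mean(),
        "true_positive_rate": df["true_positive_rate"].mean(),
        "threshold": np.nan,
        "window_trials": config.detector_window_trials,
        "combine": "mean",
    }
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    return {"metadata": _metadata(config, "detector"), "table": df}


def write_report(result: dict, outdir: str | Path, name: str) -> tuple[Path, Path]:
    """Emit ``<name>.json`` (metadata + records) and ``<name>.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table: pd.DataFrame = result["table"]
    json_path = outdir / f"{name}.json"
    tsv_path = outdir / f"{name}.tsv"
    doc = {"metadata": result["metadata"], "rows": table.to_dict(orient="records")}
    json_path.write_text(json.dumps(doc, indent=1, default=float))
    table.to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def simulate_to_files(config: PipelineConfig, outdir: str | Path) -> list[Path]:
    """Write BrainVision triplets + event TSVs for every subject and phase."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for s in range(config.n_subjects):
        for phase in (1, 2):
            rec, plan = simulate_subject(config, s, phase)
            base = outdir / f"subject{s + 1:02d}_phase{phase}"
            write_brainvision(rec, plan, base)
            plan.to_tsv(base.with_suffix(".events.tsv"))
            written.append(base)
    return written
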