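"""Synthetic electrodermal datasets with known evoked sympathetic arousal.

The generator follows the same peripheral forward model the estimators
invert: per trial, a sudomotor burst of known (truncated-normal,
non-negative) amplitude is placed at a fixed latency after the stimulus
onset, the burst train plus Poisson-distributed spontaneous bursts is
convolved with the canonical response kernel, a tonic level with a
Gaussian random-walk drift is added, the sum is scaled by a log-normal
per-subject gain, and Gaussian observation noise is superimposed.
Event-related designs mirror picture-viewing experiments: 1 s stimuli,
inter-stimulus intervals drawn from {7.65, 9, 10.35} s, 100 Hz
acquisition, and optionally "no picture" dummy events at
Normal(4.5, 0.75²) s after each stimulus.

Because true per-trial amplitudes are recorded, every dataset carries
its own ground truth, which the validity statistics treat as the known
categorical difference between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import truncnorm

from .io import EventTable, ScrRecording, write_events, write_recording
from .kernel import (
    CANONICAL_LATENCY,
    DEFAULT_DURATION,
    DEFAULT_TAU1,
    DEFAULT_TAU2,
    ResponseKernel,
    make_kernel,
)

__all__ = [
    "SimConfig",
    "SubjectData",
    "ExperimentData",
    "simulate_subject",
    "add_dummy_events",
    "simulate_experiment",
    "preset",
]

DUMMY_LABEL = "no picture"


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated experiment.

    ``conditions`` is a list of (label, mean burst amplitude μS, SD μS)
    tuples; amplitudes are drawn truncated-normal at zero, since true
    arousal is non-negative.  Noise magnitudes are not published for the
    emulated recordings; the defaults are invented values chosen so that
    every estimator produces non-degenerate output on desk-scale data.
    """

    n_subjects: int = 10
    conditions: tuple = (("neutral", 0.3, 0.1), ("aversive", 0.6, 0.1))
    trials_per_condition: int = 16
    isi_choices_s: tuple = (7.65, 9.0, 10.35)
    burst_latency_s: float = CANONICAL_LATENCY
    latency_jitter_sd_s: float = 0.0
    spontaneous_rate_hz: float = 0.05
    spontaneous_amp_mean_uS: float = 0.1
    tonic_baseline_uS: float = 2.0
    tonic_drift_sd: float = 0.02
    noise_sd_uS: float = 0.02
    subject_gain_sd: float = 0.4
    fs_acquire: float = 100.0
    tail_s: float = 20.0
    insert_dummies: bool = False
    dummy_event_mean_s: float = 4.5
    dummy_event_sd_s: float = 0.75
    tau1_s: float = DEFAULT_TAU1
    tau2_s: float = DEFAULT_TAU2
    kernel_duration_s: float = DEFAULT_DURATION
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one subject and one trial")
        for label, mean, sd in self.conditions:
            if not label:
                raise ValueError("condition labels must be nonempty")
            if mean < 0 or sd < 0:
                raise ValueError(f"condition {label!r}: amplitudes must be >= 0")
        for name in (
            "latency_jitter_sd_s", "spontaneous_rate_hz", "tonic_drift_sd",
            "noise_sd_uS", "subject_gain_sd", "dummy_event_sd_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.isi_choices_s) <= 0:
            raise ValueError("ISI choices must be positive")

    def kernel(self, fs: float | None = None) -> ResponseKernel:
        return make_kernel(
            fs or self.fs_acquire, self.kernel_duration_s, self.tau1_s, self.tau2_s
        )


@dataclass
class SubjectData:
    recording: ScrRecording
    events: EventTable
    truth: pd.DataFrame  # per-trial: subject_id, condition, trial, amplitude


@dataclass
class ExperimentData:
    config: SimConfig
    subjects: list

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([s.truth for s in self.subjects], ignore_index=True)

    def condition_truth(self) -> pd.DataFrame:
        """True per-subject, per-condition mean burst amplitude."""
        return (
            self.truth.groupby(["subject_id", "condition"], as_index=False)["amplitude"]
            .mean()
        )


def _truncated_normal(mean, sd, size, rng):
    if sd == 0:
        return float(mean) if size is None else np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_subject(
    config: SimConfig, subject_index: int, rng: np.random.Generator
) -> SubjectData:
    """One subject's recording at the acquisition rate plus its events."""
    fs = config.fs_acquire
    labels = [lab for lab, _, _ in config.conditions for _ in range(config.trials_per_condition)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    isis = rng.choice(config.isi_choices_s, size=len(labels))
    onsets = np.cumsum(isis)
    duration = onsets[-1] + config.tail_s
    n = int(round(duration * fs))
    kernel = config.kernel(fs)

    params = {lab: (mean, sd) for lab, mean, sd in config.conditions}
    amps = np.array(
        [_truncated_normal(*params[lab], size=None, rng=rng) for lab in labels]
    )
    jitter = (
        rng.normal(0.0, config.latency_jitter_sd_s, size=len(labels))
        if config.latency_jitter_sd_s > 0
        else np.zeros(len(labels))
    )
    burst_times = onsets + config.burst_latency_s + jitter

    impulses = np.zeros(n)
    for t, a in zip(burst_times, amps):
        i = int(round(t * fs))
        if 0 <= i < n:
            impulses[i] += a
    n_spont = rng.poisson(config.spontaneous_rate_hz * duration)
    if n_spont:
        sp_t = rng.uniform(0.0, duration, size=n_spont)
        sp_a = rng.exponential(config.spontaneous_amp_mean_uS, size=n_spont)
        for t, a in zip(sp_t, sp_a):
            i = int(round(t * fs))
            if i < n:
                impulses[i] += a
    phasic = fftconvolve(impulses, kernel.values)[:n]

    drift = (
        np.cumsum(rng.normal(0.0, config.tonic_drift_sd / np.sqrt(fs), size=n))
        if config.tonic_drift_sd > 0
        else np.zeros(n)
    )
    tonic = config.tonic_baseline_uS + drift
    sigma = config.subject_gain_sd
    gain = float(np.exp(rng.normal(-sigma**2 / 2, sigma))) if sigma > 0 else 1.0
    noise = (
        rng.normal(0.0, config.noise_sd_uS, size=n)
        if config.noise_sd_uS > 0
        else np.zeros(n)
    )
    values = gain * (phasic + tonic) + noise

    subject_id = f"sub{subject_index:03d}"
    events = EventTable(onsets, np.array(labels, dtype=object))
    if config.insert_dummies:
        events = add_dummy_events(
            events, rng, config.dummy_event_mean_s, config.dummy_event_sd_s
        )
    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "condition": labels,
            "trial": np.arange(len(labels)),
            "amplitude": amps,
            "gain": gain,
        }
    )
    recording = ScrRecording(subject_id=subject_id, fs=fs, values=values)
    return SubjectData(recording=recording, events=events, truth=truth)


def add_dummy_events(
    events: EventTable,
    rng: np.random.Generator,
    mean_s: float = 4.5,
    sd_s: float = 0.75,
) -> EventTable:
    """Insert one "no picture" dummy event between each pair of real events.

    The dummy onset is drawn Normal(mean_s, sd_s²) seconds after the
    previous real onset, then clipped to fall strictly between the two
    real onsets.
    """
    if len(events) < 2:
        return events
    eps = 1e-3
    onsets = list(events.onsets)
    labels = list(events.conditions)
    new_onsets, new_labels = [], []
    for i, (o, lab) in enumerate(zip(onsets, labels)):
        new_onsets.append(o)
        new_labels.append(lab)
        if i + 1 < len(onsets):
            d = o + rng.normal(mean_s, sd_s)
            d = float(np.clip(d, o + eps, onsets[i + 1] - eps))
            new_onsets.append(d)
            new_labels.append(DUMMY_LABEL)
    return EventTable(np.array(new_onsets), np.array(new_labels, dtype=object))


def simulate_experiment(config: SimConfig, out_dir=None) -> ExperimentData:
    """Simulate all subjects; optionally write the dataset to `out_dir`.

    The directory layout is ``<subject>_scr.csv`` + ``<subject>_events.csv``
    per subject plus ``ground_truth.csv`` with true per-condition mean
    amplitudes.
    """
    rng = np.random.default_rng(config.seed)
    subjects = [
        simulate_subject(config, i, rng) for i in range(config.n_subjects)
    ]
    exp = ExperimentData(config=config, subjects=subjects)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            write_recording(s.recording, out / f"{s.recording.subject_id}_scr.csv")
            write_events(s.events, out / f"{s.recording.subject_id}_events.csv")
        exp.condition_truth().to_csv(out / "ground_truth.csv", index=False)
    return exp


#: Design presets emulating the four picture-viewing experiments at their
#: published trial counts and subject numbers, plus a desk-scale preset.
_PRESETS = {
    "exp1": dict(
        n_subjects=60,
        conditions=(("neutral", 0.3, 0.1), ("aversive", 0.6, 0.1)),
        trials_per_condition=45,
    ),
    "exp2": dict(
        n_subjects=38,
        conditions=(
            ("neutral", 0.3, 0.1),
            ("aversive", 0.6, 0.1),
            ("positive", 0.5, 0.1),
        ),
        trials_per_condition=16,
    ),
    "exp4": dict(
        n_subjects=61,
        conditions=(("neutral", 0.5, 0.1),),
        trials_per_condition=45,
        insert_dummies=True,
    ),
    "ci": dict(
        n_subjects=10,
        conditions=(("neutral", 0.3, 0.1), ("aversive", 0.6, 0.1)),
        trials_per_condition=16,
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A named design preset, with any SimConfig field overridable."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)
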