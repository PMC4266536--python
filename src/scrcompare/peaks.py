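"""Conventional trough-to-peak scoring of skin conductance responses.

The operational index used by most of the experimental literature: find
the response onset as the first local minimum in a 1–3 s post-stimulus
window that is followed by a rise, take the signal maximum in a 0.5–5 s
window after that onset, and score the trial as peak minus onset value
(zero if no qualifying onset or a non-positive excursion).  Averaging
across all trials including zero responses gives SCR *magnitude*.

Unlike the convolution GLM, these scores live on the raw conductance
scale: they are invariant to additive baseline shifts but scale with any
multiplicative gain, so between-subject gain differences propagate into
the condition contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import EventTable, ScrRecording
from .preprocessing import DEFAULT_TARGET_FS, preprocess, zscore

__all__ = ["peak_score_trial", "peak_trial_table", "peak_pipeline"]

DEFAULT_RESPONSE_WINDOW = (1.0, 3.0)
DEFAULT_PEAK_WINDOW = (0.5, 5.0)


def peak_score_trial(
    signal: np.ndarray,
    onset: float,
    fs: float,
    response_window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    trial_index: int = 0,
) -> float | None:
    """Trough-to-peak magnitude (μS) for one trial; None if window exceeds data.

    The SCR onset is the first sample i in [onset + 1, onset + 3] s with
    s[i] ≤ s[i−1], s[i] ≤ s[i+1] and s[i+1] > s[i]; the peak is the
    signal maximum in [t_i + 0.5, t_i + 5] s.
    """
    signal = np.asarray(signal, dtype=float)
    i0 = int(round((onset + response_window[0]) * fs))
    i1 = int(round((onset + response_window[1]) * fs))
    if i0 < 1 or i1 + 1 >= len(signal):
        warnings.warn(
            f"trial {trial_index}: response window outside recording; dropped",
            stacklevel=2,
        )
        return None
    scr_onset = None
    for i in range(i0, i1 + 1):
        if signal[i] <= signal[i - 1] and signal[i + 1] > signal[i]:
            scr_onset = i
            break
    if scr_onset is None:
        return 0.0
    j0 = scr_onset + int(round(peak_window[0] * fs))
    j1 = scr_onset + int(round(peak_window[1] * fs))
    if j1 >= len(signal):
        warnings.warn(
            f"trial {trial_index}: peak window outside recording; dropped",
            stacklevel=2,
        )
        return None
    magnitude = signal[j0 : j1 + 1].max() - signal[scr_onset]
    return float(max(magnitude, 0.0))


def peak_trial_table(
    recording: ScrRecording,
    events: EventTable,
    response_window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    variant: str = "raw",
    target_fs: float = DEFAULT_TARGET_FS,
    assume_preprocessed: bool = False,
) -> pd.DataFrame:
    """Per-trial trough-to-peak magnitudes in estimate-table layout."""
    if assume_preprocessed or recording.fs == target_fs:
        values, fs = recording.values.astype(float), recording.fs
    else:
        values, fs = preprocess(recording.values, recording.fs, target_fs=target_fs), target_fs
    if variant == "z_data":
        values = zscore(values)
    rows = []
    for i, (onset, cond) in enumerate(zip(events.onsets, events.conditions)):
        mag = peak_score_trial(
            values, onset, fs,
            response_window=response_window, peak_window=peak_window,
            trial_index=i,
        )
        if mag is None:
            continue
        rows.append((recording.subject_id, str(cond), i, "PEAK", mag))
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "trial", "method", "value"]
    )


def peak_pipeline(recording, events, variant: str = "raw", **kwargs) -> pd.DataFrame:
    """Per-condition SCR magnitude: mean of trial scores including zeros."""
    from .decomposition import aggregate

    table = peak_trial_table(recording, events, variant=variant, **kwargs)
    return aggregate(table, variant=variant, conditions=events.condition_labels)
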