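"""Convolution GLM estimation of evoked sympathetic arousal.

Each event type is modelled as a Dirac impulse at its onsets, convolved
with the canonical response function and with its first derivative, to
form two regressors per condition.  Data and design matrix are filtered
with the same unidirectional first-order Butterworth high-pass (0.05 Hz
by default), the filtered data are z-transformed per participant, and
the model is fit by ordinary least squares.  The per-condition response
is reconstructed from the two fitted coefficients and the signed
amplitude of its largest-magnitude peak is the arousal estimate — it
can be negative, since it is a true non-negative arousal plus symmetric
estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable, ScrRecording
from .kernel import CANONICAL_LATENCY, ResponseKernel, make_kernel
from .preprocessing import (
    DEFAULT_HIGHPASS_HZ,
    DEFAULT_TARGET_FS,
    butter1_filter,
    preprocess,
    zscore,
)

__all__ = [
    "DesignMatrix",
    "build_design",
    "cofilter",
    "fit_glm",
    "reconstruct_amplitude",
    "glm_pipeline",
]


@dataclass
class DesignMatrix:
    """Convolution design: one (canonical, derivative) column pair per condition.

    ``labels[j] = (condition, basis)`` with basis in {"canonical",
    "derivative"}; ``X`` has shape (n_samples, 2 × n_conditions).
    """

    X: np.ndarray = field(repr=False)
    labels: list
    fs: float

    @property
    def conditions(self) -> list:
        seen: dict = {}
        for cond, _ in self.labels:
            seen.setdefault(cond, None)
        return list(seen)

    def column(self, condition: str, basis: str) -> np.ndarray:
        j = self.labels.index((condition, basis))
        return self.X[:, j]


def _impulse_column(onset_idx: np.ndarray, kernel_values: np.ndarray, n: int) -> np.ndarray:
    """Superpose kernel copies at onset samples, truncated at n."""
    col = np.zeros(n)
    m = len(kernel_values)
    for i in onset_idx:
        stop = min(n, i + m)
        if stop > i:
            col[i:stop] += kernel_values[: stop - i]
    return col


def build_design(
    events: EventTable, n: int, fs: float, kernel: ResponseKernel
) -> DesignMatrix:
    """Build the convolution design matrix for all conditions in `events`.

    Onset sample index is round(onset · fs).  Convolution is truncated at
    n samples; events whose response outlasts the recording keep their
    truncated columns.
    """
    if len(events) == 0:
        raise ValueError("cannot build a design matrix without events")
    if kernel.fs != fs:
        raise ValueError(f"kernel sampled at {kernel.fs} Hz but design needs {fs} Hz")
    onset_idx = np.round(events.onsets * fs).astype(int)
    if np.any(onset_idx >= n):
        raise ValueError("event onset beyond the end of the recording")
    cols, labels = [], []
    for cond in events.condition_labels:
        idx = onset_idx[[str(c) == cond for c in events.conditions]]
        cols.append(_impulse_column(idx, kernel.values, n))
        labels.append((cond, "canonical"))
        cols.append(_impulse_column(idx, kernel.dvalues, n))
        labels.append((cond, "derivative"))
    return DesignMatrix(X=np.column_stack(cols), labels=labels, fs=fs)


def cofilter(
    data: np.ndarray,
    design: DesignMatrix,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
):
    """Apply one identical causal high-pass to the data and every design column."""
    fdata = butter1_filter(data, design.fs, highpass_hz, "highpass")
    fX = np.column_stack(
        [
            butter1_filter(design.X[:, j], design.fs, highpass_hz, "highpass")
            for j in range(design.X.shape[1])
        ]
    )
    return fdata, DesignMatrix(X=fX, labels=list(design.labels), fs=design.fs)


def fit_glm(y: np.ndarray, X) -> np.ndarray:
    """Ordinary least squares, refusing rank-deficient designs.

    Returns the coefficient vector beta = argmin ||y - X beta||²; the
    residuals are orthogonal to the design columns.
    """
    A = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    return beta


def reconstruct_amplitude(
    beta_canonical: float, beta_derivative: float, kernel: ResponseKernel
) -> float:
    """Signed amplitude of the reconstructed per-condition response.

    r(t) = β₁·k(t) + β₂·k′(t) on the kernel grid; returns r at the time
    of largest |r| (earliest sample on ties).
    """
    r = beta_canonical * kernel.values + beta_derivative * kernel.dvalues
    return float(r[np.argmax(np.abs(r))])


def glm_pipeline(
    recording: ScrRecording,
    events: EventTable,
    kernel: ResponseKernel | None = None,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    target_fs: float = DEFAULT_TARGET_FS,
    assume_preprocessed: bool = False,
) -> pd.DataFrame:
    """Full GLM path: design → co-filter → z-score → OLS → amplitudes.

    Returns one row per condition in estimate-table layout.  Unless
    ``assume_preprocessed``, the recording is first low-pass filtered and
    decimated to ``target_fs``.
    """
    if assume_preprocessed or recording.fs == target_fs:
        values, fs = recording.values, recording.fs
    else:
        values, fs = preprocess(recording.values, recording.fs, target_fs=target_fs), target_fs
    if kernel is None:
        # the canonical kernel of the GLM carries the constant
        # stimulus-to-burst latency in its shape
        kernel = make_kernel(fs, latency_shift=CANONICAL_LATENCY)
    design = build_design(events, len(values), fs, kernel)
    fdata, fdesign = cofilter(values, design, highpass_hz)
    y = zscore(fdata)
    beta = fit_glm(y, fdesign)
    rows = []
    for cond in design.conditions:
        b1 = beta[fdesign.labels.index((cond, "canonical"))]
        b2 = beta[fdesign.labels.index((cond, "derivative"))]
        rows.append(
            {
                "subject_id": recording.subject_id,
                "condition": cond,
                "trial": pd.NA,
                "method": "GLM",
                "value": reconstruct_amplitude(b1, b2, kernel),
            }
        )
    return pd.DataFrame(rows)
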