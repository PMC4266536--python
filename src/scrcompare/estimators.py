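"""Scikit-learn-style estimator classes over the analysis pipelines.

Each estimator consumes a dataset — an :class:`~scrcompare.simulate.ExperimentData`,
a list of :class:`~scrcompare.simulate.SubjectData`, or a list of
``(ScrRecording, EventTable)`` pairs — and after ``fit`` exposes

* ``estimates_``: per-subject × per-condition SA estimates (estimate-table
  layout: subject_id, condition, trial, method, value), and
* ``trial_values_``: per-trial estimates, where the method defines them
  (all methods except the convolution GLM, whose single-trial amplitudes
  are out of scope).

``transform`` returns ``estimates_`` so the estimators compose with
sklearn pipelines and model selection; ``get_params``/``set_params``
come from :class:`sklearn.base.BaseEstimator`.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .decomposition import (
    DEFAULT_DRIVER_THRESHOLD,
    DEFAULT_RIDGE_LAMBDA,
    DEFAULT_WINDOW,
    aggregate,
    cda_trial_table,
    dda_trial_table,
)
from .glm import glm_pipeline
from .kernel import (
    CANONICAL_LATENCY,
    DEFAULT_DURATION,
    DEFAULT_TAU1,
    DEFAULT_TAU2,
    make_kernel,
)
from .peaks import DEFAULT_PEAK_WINDOW, DEFAULT_RESPONSE_WINDOW, peak_trial_table
from .preprocessing import DEFAULT_HIGHPASS_HZ, DEFAULT_TARGET_FS
from .validity import _as_pairs

__all__ = [
    "GlmArousalEstimator",
    "CdaArousalEstimator",
    "DdaArousalEstimator",
    "PeakArousalEstimator",
    "make_estimator",
]


class _DatasetEstimator(BaseEstimator):
    """Shared fit/transform plumbing for dataset-level SA estimators."""

    def fit(self, X, y=None):
        pairs = _as_pairs(X)
        est, trials = self._estimate(pairs)
        self.estimates_ = est
        self.trial_values_ = trials
        self.n_subjects_ = len(pairs)
        return self

    def transform(self, X=None):
        if not hasattr(self, "estimates_"):
            raise RuntimeError("estimator is not fitted")
        return self.estimates_

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform()


class GlmArousalEstimator(_DatasetEstimator):
    """Convolution-GLM arousal amplitudes (z-scored, co-filtered OLS)."""

    method = "GLM"

    def __init__(
        self,
        tau1: float = DEFAULT_TAU1,
        tau2: float = DEFAULT_TAU2,
        kernel_duration: float = DEFAULT_DURATION,
        latency_shift: float = CANONICAL_LATENCY,
        highpass_hz: float = DEFAULT_HIGHPASS_HZ,
        target_fs: float = DEFAULT_TARGET_FS,
    ):
        self.tau1 = tau1
        self.tau2 = tau2
        self.kernel_duration = kernel_duration
        self.latency_shift = latency_shift
        self.highpass_hz = highpass_hz
        self.target_fs = target_fs

    def _estimate(self, pairs):
        kernel = make_kernel(
            self.target_fs, self.kernel_duration, self.tau1, self.tau2,
            latency_shift=self.latency_shift,
        )
        est = pd.concat(
            [
                glm_pipeline(
                    rec, events, kernel=kernel,
                    highpass_hz=self.highpass_hz, target_fs=self.target_fs,
                )
                for rec, events in pairs
            ],
            ignore_index=True,
        )
        return est, None


class _DecompositionEstimator(_DatasetEstimator):
    def __init__(
        self,
        index: str = "amp_sum",
        variant: str = "raw",
        window: tuple = DEFAULT_WINDOW,
        threshold: float = DEFAULT_DRIVER_THRESHOLD,
        ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
        tau1: float = DEFAULT_TAU1,
        tau2: float = DEFAULT_TAU2,
        kernel_duration: float = DEFAULT_DURATION,
        target_fs: float = DEFAULT_TARGET_FS,
    ):
        self.index = index
        self.variant = variant
        self.window = window
        self.threshold = threshold
        self.ridge_lambda = ridge_lambda
        self.tau1 = tau1
        self.tau2 = tau2
        self.kernel_duration = kernel_duration
        self.target_fs = target_fs

    _indices: dict = {}
    _trial_table = staticmethod(cda_trial_table)

    def _estimate(self, pairs):
        if self.index not in self._indices:
            raise ValueError(
                f"index must be one of {sorted(self._indices)}, got {self.index!r}"
            )
        method = self._indices[self.index]
        kernel = make_kernel(self.target_fs, self.kernel_duration, self.tau1, self.tau2)
        trial = pd.concat(
            [
                type(self)._trial_table(
                    rec, events, kernel=kernel, variant=self.variant,
                    window=self.window, threshold=self.threshold,
                    ridge_lambda=self.ridge_lambda, target_fs=self.target_fs,
                )
                for rec, events in pairs
            ],
            ignore_index=True,
        )
        trial = trial[trial["method"] == method].reset_index(drop=True)
        est = aggregate(trial, variant=self.variant)
        return est, trial


class CdaArousalEstimator(_DecompositionEstimator):
    """Continuous-decomposition indices: AmpSum (CDA 1) or mean driver (CDA 2)."""

    _indices = {"amp_sum": "CDA1", "mean_driver": "CDA2"}
    _trial_table = staticmethod(cda_trial_table)


class DdaArousalEstimator(_DecompositionEstimator):
    """Nonnegative-decomposition indices: AmpSum (DDA 1) or AreaSum (DDA 2)."""

    _indices = {"amp_sum": "DDA1", "area_sum": "DDA2"}
    _trial_table = staticmethod(dda_trial_table)


class PeakArousalEstimator(_DatasetEstimator):
    """Trough-to-peak SCR magnitude (mean over trials including zeros)."""

    method = "PEAK"

    def __init__(
        self,
        response_window: tuple = DEFAULT_RESPONSE_WINDOW,
        peak_window: tuple = DEFAULT_PEAK_WINDOW,
        variant: str = "raw",
        target_fs: float = DEFAULT_TARGET_FS,
    ):
        self.response_window = response_window
        self.peak_window = peak_window
        self.variant = variant
        self.target_fs = target_fs

    def _estimate(self, pairs):
        trial = pd.concat(
            [
                peak_trial_table(
                    rec, events,
                    response_window=self.response_window,
                    peak_window=self.peak_window,
                    variant=self.variant, target_fs=self.target_fs,
                )
                for rec, events in pairs
            ],
            ignore_index=True,
        )
        est = aggregate(trial, variant=self.variant)
        return est, trial


def make_estimator(name: str, variant: str = "raw", **kwargs):
    """Factory for the six method variants: glm, cda1, cda2, dda1, dda2, peak."""
    name = name.lower()
    if name == "glm":
        return GlmArousalEstimator(**kwargs)
    if name == "cda1":
        return CdaArousalEstimator(index="amp_sum", variant=variant, **kwargs)
    if name == "cda2":
        return CdaArousalEstimator(index="mean_driver", variant=variant, **kwargs)
    if name == "dda1":
        return DdaArousalEstimator(index="amp_sum", variant=variant, **kwargs)
    if name == "dda2":
        return DdaArousalEstimator(index="area_sum", variant=variant, **kwargs)
    if name == "peak":
        return PeakArousalEstimator(variant=variant, **kwargs)
    raise ValueError(f"unknown method {name!r}")
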