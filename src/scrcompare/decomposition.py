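"""Driver-deconvolution estimation of evoked sympathetic arousal.

Two decomposition families are implemented, both inverting the
peripheral model SCR = SN ⊗ SCRF:

* Continuous decomposition (CDA): deterministic, ridge-regularised
  deconvolution of the conductance signal to a sudomotor-driver time
  series.  The driver is unconstrained and may contain negative values.
  Tonic activity is separated by excising above-threshold driver peaks,
  bridging them by linear interpolation, re-convolving the remaining
  tonic driver with the kernel, and deconvolving the residual to a
  phasic driver.
* Discrete decomposition (DDA): nonnegative least squares on the
  tonic-removed signal, yielding a driver constrained to be ≥ 0 plus a
  remainder series.

Trials are scored on the driver with the conventional window/threshold
rules: sum of above-threshold peak amplitudes ("AmpSum", CDA 1 / DDA 1),
sum of above-threshold peak areas ("AreaSum", DDA 2), and the
unthresholded window mean of the phasic driver ("SCR", CDA 2).

The convolution operator is the square lower-triangular Toeplitz matrix
of the sampled kernel, augmented with one "pre-history" column: the
response of a constant unit driver occupying one kernel length before
the first data sample.  The kernel is causal with k(0)=0, so without
that column no driver could reproduce the baseline conductance at the
very start of a recording (every on-grid response begins one sample
after its impulse).  The fitted pre-history level is carried on the
driver series and treated as tonic; all peak detection and scoring
operate on the on-grid driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import toeplitz
from scipy.optimize import nnls
from scipy.signal import find_peaks
from scipy.sparse.linalg import splu

from .io import EventTable, ScrRecording
from .kernel import ResponseKernel, make_kernel
from .preprocessing import DEFAULT_TARGET_FS, preprocess, zscore

__all__ = [
    "DriverSeries",
    "TrialScore",
    "Deconvolver",
    "deconvolve",
    "tonic_phasic_split",
    "reconstruct",
    "dda_decompose",
    "score_trial",
    "score_trials",
    "aggregate",
    "decomposition_trial_tables",
    "cda_trial_table",
    "dda_trial_table",
    "cda_pipeline",
    "dda_pipeline",
]

#: Ridge weight relative to the mean squared column norm of the
#: convolution operator.
DEFAULT_RIDGE_LAMBDA = 1e-4
#: Driver-scale threshold (μS-equivalent) for phasic peak detection and
#: response scoring.
DEFAULT_DRIVER_THRESHOLD = 0.01
#: Post-onset response window for trial scoring, seconds.
DEFAULT_WINDOW = (1.0, 4.0)


@dataclass
class DriverSeries:
    """Estimated sudomotor driver with its tonic/phasic decomposition.

    ``values`` is aligned with the data grid; ``pre_level`` is the
    fitted level of the constant pre-recording driver (needed for exact
    re-convolution of baselines, and always attributed to the tonic
    component).  ``phasic`` and ``tonic_data`` are populated by
    :func:`tonic_phasic_split`.
    """

    fs: float
    values: np.ndarray = field(repr=False)
    pre_level: float = 0.0
    phasic: np.ndarray | None = field(repr=False, default=None)
    phasic_pre_level: float = 0.0
    tonic_data: np.ndarray | None = field(repr=False, default=None)


@dataclass
class TrialScore:
    """Window/threshold scores of the driver for one trial."""

    trial_index: int
    amp_sum: float
    area_sum: float
    mean_driver: float
    above_threshold: bool


class Deconvolver:
    """Ridge-regularised inverse of the kernel-convolution operator.

    The operator is ``A = [c | K]`` where K is the n × n lower-triangular
    Toeplitz matrix of the kernel and c is the response of a constant
    unit driver occupying ``npre`` samples (one kernel length by
    default) before the recording, so baselines are representable from
    the first sample.  K is banded (bandwidth = kernel length), so the
    normal equations KᵀK + λI are solved by sparse LU, with the single
    dense pre-history column handled by block elimination; the
    factorisation is cached, making repeated deconvolutions of
    same-length series (as in the tonic/phasic iteration) cheap.  lam
    defaults to ``ridge_lambda`` times the mean squared column norm of
    A.
    """

    def __init__(
        self,
        kernel: ResponseKernel,
        n: int,
        lam: float | None = None,
        ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
        npre: int | None = None,
    ):
        k = kernel.values
        m = len(k)
        if npre is None:
            npre = m - 1
        self.kernel = kernel
        self.n = n
        self.npre = npre
        nd = min(m, n)
        self.K = sp.diags(
            [np.full(n - d, k[d]) for d in range(nd)],
            offsets=[-d for d in range(nd)],
            format="csc",
        )
        # c[i] = sum of k over lags i+1 .. i+npre: steady pre-history response
        cs = np.concatenate([[0.0], np.cumsum(k)])
        idx = np.arange(n)
        self.c = cs[np.minimum(idx + 1 + npre, m)] - cs[np.minimum(idx + 1, m)]
        if lam is None:
            # trace(AᵀA)/(n+1): mean squared column norm of [c | K]
            colsq = float(np.sum(k[:nd] ** 2 * (n - np.arange(nd))))
            lam = ridge_lambda * (float(self.c @ self.c) + colsq) / (n + 1)
        self.lam = float(lam)
        B = (self.K.T @ self.K).tocsc() + self.lam * sp.identity(n, format="csc")
        self._lu = splu(B)
        u = self.K.T @ self.c
        w = self._lu.solve(u)
        self._u = u
        self._w = w
        self._schur = float(self.c @ self.c) + self.lam - float(u @ w)

    def solve(self, data: np.ndarray) -> DriverSeries:
        """Driver minimising ||A·driver − data||² + λ||driver||²."""
        data = np.asarray(data, dtype=float)
        if data.shape != (self.n,):
            raise ValueError(f"expected {self.n} samples, got {data.shape}")
        r1 = self.K.T @ data
        t1 = self._lu.solve(r1)
        pre = (float(self.c @ data) - float(self._u @ t1)) / self._schur
        values = t1 - pre * self._w
        return DriverSeries(fs=self.kernel.fs, values=values, pre_level=float(pre))

    def reconvolve(self, driver: np.ndarray, pre_level: float = 0.0) -> np.ndarray:
        """Map an on-grid driver (plus pre-history level) to the data grid."""
        out = self.K @ np.asarray(driver, dtype=float)
        if pre_level:
            out = out + pre_level * self.c
        return out


def deconvolve(
    data,
    kernel: ResponseKernel,
    lam: float | None = None,
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
) -> DriverSeries:
    """Deterministic (CDA-style) deconvolution of `data` to a driver."""
    data = np.asarray(data, dtype=float)
    return Deconvolver(kernel, len(data), lam=lam, ridge_lambda=ridge_lambda).solve(data)


def _flanking_minima(x: np.ndarray, peak: int) -> tuple[int, int]:
    """Indices of the nearest local minima (or edges) flanking `peak`."""
    left = peak
    while left > 0 and x[left - 1] <= x[left]:
        left -= 1
    right = peak
    while right < len(x) - 1 and x[right + 1] <= x[right]:
        right += 1
    return left, right


def _excise_peaks(full_driver: np.ndarray, threshold: float) -> np.ndarray:
    """Remove above-threshold peaks, bridging the gaps by interpolation."""
    peaks, _ = find_peaks(full_driver, height=threshold)
    if peaks.size == 0:
        return full_driver.copy()
    keep = np.ones(len(full_driver), dtype=bool)
    for p in peaks:
        left, right = _flanking_minima(full_driver, p)
        keep[left + 1 : right] = False
    idx = np.arange(len(full_driver))
    tonic = full_driver.copy()
    tonic[~keep] = np.interp(idx[~keep], idx[keep], full_driver[keep])
    return tonic


def tonic_phasic_split(
    driver: DriverSeries,
    kernel: ResponseKernel,
    data,
    threshold: float = DEFAULT_DRIVER_THRESHOLD,
    n_iter: int = 1,
    dec: Deconvolver | None = None,
) -> DriverSeries:
    """Separate the driver into tonic conductance and a phasic driver.

    Above-threshold driver peaks are excised (bridged by linear
    interpolation between their flanking minima); the remaining tonic
    driver is re-convolved with the kernel to a tonic conductance trace,
    and the phasic driver is obtained by deconvolving data − tonic.
    `n_iter` refinement passes (default 1) repeat the peak detection on
    the updated tonic + phasic decomposition.
    """
    data = np.asarray(data, dtype=float)
    if dec is None:
        dec = Deconvolver(kernel, len(data))
    tonic_driver = _excise_peaks(driver.values, threshold)
    tonic_pre = driver.pre_level
    tonic_data = dec.reconvolve(tonic_driver, tonic_pre)
    ph = dec.solve(data - tonic_data)
    for _ in range(n_iter):
        tonic_driver = _excise_peaks(tonic_driver + ph.values, threshold)
        tonic_pre = tonic_pre + ph.pre_level
        tonic_data = dec.reconvolve(tonic_driver, tonic_pre)
        ph = dec.solve(data - tonic_data)
    return DriverSeries(
        fs=driver.fs,
        values=driver.values,
        pre_level=driver.pre_level,
        phasic=ph.values,
        phasic_pre_level=ph.pre_level,
        tonic_data=tonic_data,
    )


def reconstruct(split: DriverSeries, kernel: ResponseKernel) -> np.ndarray:
    """tonic_data + kernel ⊗ phasic driver, on the data grid."""
    if split.phasic is None or split.tonic_data is None:
        raise ValueError("DriverSeries has no tonic/phasic decomposition")
    dec = Deconvolver(kernel, len(split.tonic_data))
    return split.tonic_data + dec.reconvolve(split.phasic, split.phasic_pre_level)


def dda_decompose(data, kernel: ResponseKernel, maxiter: int | None = None):
    """Nonnegative decomposition of tonic-removed data.

    Returns ``(driver, remainder)`` with driver = argmin ||K·driver −
    data||² s.t. driver ≥ 0 on the sample grid, and remainder = data −
    K·driver.  The remainder absorbs whatever a nonnegative driver
    cannot explain (negative-going artefacts in particular).
    """
    data = np.asarray(data, dtype=float)
    n = len(data)
    k = kernel.values
    col = np.zeros(n)
    col[: min(n, len(k))] = k[:n]
    K = toeplitz(col, np.zeros(n))
    driver, _ = nnls(K, data, maxiter=maxiter)
    remainder = data - K @ driver
    return driver, remainder


def score_trial(
    driver: np.ndarray,
    onset: float,
    fs: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    threshold: float = DEFAULT_DRIVER_THRESHOLD,
    trial_index: int = 0,
    taken: set | None = None,
) -> TrialScore | None:
    """Window/threshold scores for one trial on a driver time series.

    Peaks whose maximum falls within [onset + window[0], onset +
    window[1]] seconds are detected; ``amp_sum`` sums the amplitudes of
    those at or above `threshold`, ``area_sum`` sums the positive-part
    time-integral of each above-threshold peak's lobe (between its
    flanking local minima, clipped to the window), and ``mean_driver``
    is the unthresholded window mean.  `taken` tracks peak indices
    already assigned to an earlier trial so overlapping windows never
    double-count a peak.  Returns None (with a warning) when the window
    exceeds the recording.
    """
    driver = np.asarray(driver, dtype=float)
    i0 = int(round((onset + window[0]) * fs))
    i1 = int(round((onset + window[1]) * fs))
    if i0 < 0 or i1 >= len(driver):
        warnings.warn(
            f"trial {trial_index}: response window outside recording; dropped",
            stacklevel=2,
        )
        return None
    peaks, _ = find_peaks(driver)
    peaks = peaks[(peaks >= i0) & (peaks <= i1)]
    if taken is not None:
        peaks = np.array([p for p in peaks if p not in taken], dtype=int)
        taken.update(int(p) for p in peaks)
    amp_sum = 0.0
    area_sum = 0.0
    for p in peaks:
        if driver[p] >= threshold:
            amp_sum += driver[p]
            left, right = _flanking_minima(driver, p)
            left, right = max(left, i0), min(right, i1)
            area_sum += np.clip(driver[left : right + 1], 0.0, None).sum() / fs
    return TrialScore(
        trial_index=trial_index,
        amp_sum=float(amp_sum),
        area_sum=float(area_sum),
        mean_driver=float(driver[i0 : i1 + 1].mean()),
        above_threshold=amp_sum > 0,
    )


def score_trials(
    driver: np.ndarray,
    events: EventTable,
    fs: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    threshold: float = DEFAULT_DRIVER_THRESHOLD,
) -> list[TrialScore | None]:
    """Score every trial in onset order; earlier trials claim shared peaks."""
    taken: set = set()
    return [
        score_trial(
            driver, onset, fs, window=window, threshold=threshold,
            trial_index=i, taken=taken,
        )
        for i, onset in enumerate(events.onsets)
    ]


def aggregate(
    trial_values: pd.DataFrame,
    variant: str = "raw",
    conditions: list | None = None,
) -> pd.DataFrame:
    """Average per-trial SA values within conditions, including zeros.

    variant "raw" (and "z_data", whose z-transform happens upstream on
    the signal): plain condition means.  variant "z_results": each
    subject's trial values are z-scored across all that subject's trials
    (sample SD) before averaging within conditions.
    """
    if variant not in ("raw", "z_data", "z_results"):
        raise ValueError(f"unknown aggregation variant {variant!r}")
    df = trial_values.copy()
    if variant == "z_results":
        def _z(g):
            g = g.copy()
            g["value"] = zscore(g["value"].to_numpy())
            return g
        df = (
            df.groupby("subject_id", group_keys=False)[df.columns]
            .apply(_z)
            .reset_index(drop=True)
        )
    out = (
        df.groupby(["subject_id", "condition", "method"], as_index=False)["value"]
        .mean()
    )
    out["trial"] = pd.NA
    out = out[["subject_id", "condition", "trial", "method", "value"]]
    if conditions is not None:
        missing = set(conditions) - set(out["condition"])
        if missing:
            warnings.warn(f"conditions with zero trials: {sorted(missing)}")
            extra = [
                {
                    "subject_id": s,
                    "condition": c,
                    "trial": pd.NA,
                    "method": m,
                    "value": np.nan,
                }
                for c in sorted(missing)
                for s in out["subject_id"].unique()
                for m in out["method"].unique()
            ]
            out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out


def _prepare(recording, variant, target_fs, assume_preprocessed):
    if assume_preprocessed or recording.fs == target_fs:
        values, fs = recording.values.astype(float), recording.fs
    else:
        values, fs = preprocess(recording.values, recording.fs, target_fs=target_fs), target_fs
    if variant == "z_data":
        values = zscore(values)
    return values, fs


def decomposition_trial_tables(
    recording: ScrRecording,
    events: EventTable,
    families=("cda", "dda"),
    kernel: ResponseKernel | None = None,
    variant: str = "raw",
    window: tuple[float, float] = DEFAULT_WINDOW,
    threshold: float = DEFAULT_DRIVER_THRESHOLD,
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    target_fs: float = DEFAULT_TARGET_FS,
    assume_preprocessed: bool = False,
) -> dict:
    """Per-trial CDA and/or DDA scores, sharing one deconvolution.

    Both families need the same ridge deconvolution and tonic/phasic
    split; computing them together roughly halves the cost of a full
    method comparison.  Returns ``{"cda": DataFrame, "dda": DataFrame}``
    restricted to the requested families (CDA1 = AmpSum, CDA2 = mean
    phasic driver; DDA1 = AmpSum, DDA2 = AreaSum of the nonnegative
    driver fitted to the tonic-removed signal).
    """
    values, fs = _prepare(recording, variant, target_fs, assume_preprocessed)
    if kernel is None:
        kernel = make_kernel(fs)
    dec = Deconvolver(kernel, len(values), ridge_lambda=ridge_lambda)
    split = tonic_phasic_split(
        dec.solve(values), kernel, values, threshold=threshold, dec=dec
    )
    cols = ["subject_id", "condition", "trial", "method", "value"]
    out = {}
    if "cda" in families:
        scores = score_trials(
            split.phasic, events, fs, window=window, threshold=threshold
        )
        rows = []
        for cond, sc in zip(events.conditions, scores):
            if sc is None:
                continue
            rows.append(
                (recording.subject_id, str(cond), sc.trial_index, "CDA1", sc.amp_sum)
            )
            rows.append(
                (recording.subject_id, str(cond), sc.trial_index, "CDA2", sc.mean_driver)
            )
        out["cda"] = pd.DataFrame(rows, columns=cols)
    if "dda" in families:
        driver, _ = dda_decompose(values - split.tonic_data, kernel)
        scores = score_trials(driver, events, fs, window=window, threshold=threshold)
        rows = []
        for cond, sc in zip(events.conditions, scores):
            if sc is None:
                continue
            rows.append(
                (recording.subject_id, str(cond), sc.trial_index, "DDA1", sc.amp_sum)
            )
            rows.append(
                (recording.subject_id, str(cond), sc.trial_index, "DDA2", sc.area_sum)
            )
        out["dda"] = pd.DataFrame(rows, columns=cols)
    return out


def cda_trial_table(recording, events, **kwargs) -> pd.DataFrame:
    """Per-trial CDA scores (CDA1 = AmpSum, CDA2 = mean phasic driver)."""
    return decomposition_trial_tables(recording, events, families=("cda",), **kwargs)["cda"]


def dda_trial_table(recording, events, **kwargs) -> pd.DataFrame:
    """Per-trial DDA scores (DDA1 = AmpSum, DDA2 = AreaSum)."""
    return decomposition_trial_tables(recording, events, families=("dda",), **kwargs)["dda"]


def cda_pipeline(recording, events, variant: str = "raw", **kwargs) -> pd.DataFrame:
    """Per-condition CDA estimates (mean across trials including zeros)."""
    table = cda_trial_table(recording, events, variant=variant, **kwargs)
    return aggregate(table, variant=variant, conditions=events.condition_labels)


def dda_pipeline(recording, events, variant: str = "raw", **kwargs) -> pd.DataFrame:
    """Per-condition DDA estimates (mean across trials including zeros)."""
    table = dda_trial_table(recording, events, variant=variant, **kwargs)
    return aggregate(table, variant=variant, conditions=events.condition_labels)
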