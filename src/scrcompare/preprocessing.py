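"""Signal conditioning for skin conductance recordings.

Raw recordings are conditioned with a unidirectional (single forward
pass, causal) first-order Butterworth low-pass at 5 Hz and decimated to
10 Hz.  The convolution-GLM path additionally high-pass filters data and
design at 0.05 Hz and z-transforms the data per participant.  Two
z-transform orderings exist in practice and both are exposed: the GLM
standard applies it after high-pass filtering; the "z-transformed data"
variant of the decomposition methods applies it to the raw signal before
any analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["butter1_filter", "downsample", "zscore", "preprocess"]

DEFAULT_LOWPASS_HZ = 5.0
DEFAULT_HIGHPASS_HZ = 0.05
DEFAULT_TARGET_FS = 10.0


def butter1_filter(values, fs: float, cutoff: float, mode: str = "lowpass"):
    """Single forward pass of a first-order Butterworth filter.

    The filter state is initialised to the steady state for the first
    sample, suppressing the start-up transient a causal filter would
    otherwise impose on a signal with a nonzero baseline.

    Parameters
    ----------
    values : array-like
        Input samples.
    fs : float
        Sampling rate, Hz.
    cutoff : float
        Cut-off frequency, Hz; must satisfy 0 < cutoff < fs/2.
    mode : {"lowpass", "highpass"}
    """
    if mode not in ("lowpass", "highpass"):
        raise ValueError(f"mode must be 'lowpass' or 'highpass', got {mode!r}")
    if not (0 < cutoff < fs / 2):
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}"
        )
    values = np.asarray(values, dtype=float)
    b, a = sps.butter(1, cutoff, btype=mode, fs=fs)
    zi = sps.lfilter_zi(b, a) * values[0]
    out, _ = sps.lfilter(b, a, values, zi=zi)
    return out


def downsample(values, fs: float, target_fs: float):
    """Keep every (fs/target_fs)-th sample, starting at index 0.

    Plain decimation; callers are expected to have applied the
    anti-aliasing low-pass first.  fs/target_fs must be a positive
    integer.
    """
    ratio = fs / target_fs
    if ratio < 1 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs/target_fs must be a positive integer, got {fs}/{target_fs} = {ratio}"
        )
    step = int(round(ratio))
    return np.asarray(values, dtype=float)[::step]


def zscore(values):
    """Standardise to mean 0 and unit sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("z-scoring is undefined for a constant input")
    return (values - values.mean()) / sd


def preprocess(
    values,
    fs: float,
    lowpass_hz: float = DEFAULT_LOWPASS_HZ,
    target_fs: float = DEFAULT_TARGET_FS,
):
    """Standard conditioning: 5 Hz causal low-pass, then decimate to 10 Hz.

    Returns the conditioned samples; the new rate is ``target_fs``.
    """
    out = butter1_filter(values, fs, lowpass_hz, "lowpass")
    if fs != target_fs:
        out = downsample(out, fs, target_fs)
    return out
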