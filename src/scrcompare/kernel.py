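"""Canonical skin conductance response function (SCRF).

The peripheral forward model treats observed skin conductance as the
convolution of a sudomotor-nerve driver with a stereotyped impulse
response, SCR = SN ⊗ SCRF.  The kernel used here is the two-exponential
Bateman function

    b(t) = exp(-t / tau1) - exp(-t / tau2),   tau1 > tau2 > 0,

peak-normalised so that a unit driver impulse produces a response whose
maximum is 1 μS.  tau1 controls the slow recovery of the response, tau2
the fast rise.  Both are configuration, not fitted quantities: generation
and estimation in this package always share one configured kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "bateman",
    "bateman_peak_time",
    "make_kernel",
    "ResponseKernel",
    "CANONICAL_LATENCY",
]

#: Default slow (recovery) time constant, seconds.
DEFAULT_TAU1 = 10.0
#: Default fast (rise) time constant, seconds.
DEFAULT_TAU2 = 1.0
#: Default sampled kernel duration, seconds. Long enough that the tail of
#: the default kernel (with or without the canonical latency) has decayed
#: below 1% of the peak.
DEFAULT_DURATION = 55.0
#: Canonical response latency, seconds: the fixed delay between stimulus
#: onset and the sudomotor burst.  The simulator places true bursts at
#: this latency and the convolution GLM bakes the same delay into its
#: canonical kernel; the deconvolution methods instead absorb latency in
#: their 1-4 s post-onset scoring window.  Chosen so the evoked driver
#: peak and the trough of the conductance response fall inside the
#: conventional scoring windows.
CANONICAL_LATENCY = 1.3


def _check_taus(tau1: float, tau2: float) -> None:
    if not (tau1 > tau2 > 0):
        raise ValueError(
            f"Bateman kernel requires tau1 > tau2 > 0, got tau1={tau1}, tau2={tau2}"
        )


def bateman(t, tau1: float = DEFAULT_TAU1, tau2: float = DEFAULT_TAU2):
    """Un-normalised Bateman function exp(-t/tau1) - exp(-t/tau2).

    Zero for t < 0 (causal response).
    """
    _check_taus(tau1, tau2)
    t = np.asarray(t, dtype=float)
    out = np.exp(-t / tau1) - np.exp(-t / tau2)
    return np.where(t < 0, 0.0, out)


def bateman_peak_time(tau1: float = DEFAULT_TAU1, tau2: float = DEFAULT_TAU2) -> float:
    """Time of the Bateman maximum, ln(tau1/tau2) / (1/tau2 - 1/tau1)."""
    _check_taus(tau1, tau2)
    return float(np.log(tau1 / tau2) / (1.0 / tau2 - 1.0 / tau1))


@dataclass(frozen=True)
class ResponseKernel:
    """A sampled canonical SCRF and its analytic first derivative.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    duration : float
        Support of the sampled kernel in seconds.
    values : ndarray
        Peak-normalised kernel samples; ``values[0] == 0`` and
        ``values.max() == 1``.
    dvalues : ndarray
        Analytic first time-derivative of the normalised kernel, sampled
        on the same grid.
    params : dict
        ``{"tau1": s, "tau2": s, "latency_shift": s}``.
    """

    fs: float
    duration: float
    values: np.ndarray = field(repr=False)
    dvalues: np.ndarray = field(repr=False)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.values)) / self.fs


def make_kernel(
    fs: float,
    duration: float = DEFAULT_DURATION,
    tau1: float = DEFAULT_TAU1,
    tau2: float = DEFAULT_TAU2,
    latency_shift: float = 0.0,
    tail_tol: float = 0.01,
) -> ResponseKernel:
    """Sample the peak-normalised Bateman kernel and its derivative at fs.

    Parameters
    ----------
    fs : float
        Sampling rate, Hz.
    duration : float
        Kernel support in seconds.  Must be long enough that the kernel
        tail at `duration` is below ``tail_tol`` of the peak; truncating a
        live tail would bias deconvolution.
    tau1, tau2 : float
        Bateman time constants, seconds (tau1 > tau2 > 0).
    latency_shift : float
        Delay (s, >= 0) prepended to the response: the kernel is zero
        until `latency_shift` and follows the Bateman shape thereafter.
        Used by the convolution GLM to model the constant
        stimulus-to-burst latency.

    Raises
    ------
    ValueError
        If the tail criterion is violated or the time constants are
        invalid.
    """
    _check_taus(tau1, tau2)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if latency_shift < 0:
        raise ValueError(f"latency_shift must be >= 0, got {latency_shift}")
    t = np.arange(0.0, duration, 1.0 / fs)
    ts = t - latency_shift
    raw = bateman(ts, tau1, tau2)
    # normalise by the analytic maximum so the sampled kernel is
    # independent of fs (the grid may miss the exact peak time)
    peak = float(bateman(bateman_peak_time(tau1, tau2), tau1, tau2))
    tail = bateman(duration - latency_shift, tau1, tau2) / peak
    if tail >= tail_tol:
        raise ValueError(
            f"kernel tail at {duration} s is {tail:.3%} of peak "
            f"(>= {tail_tol:.0%}); increase duration"
        )
    values = raw / peak
    # analytic derivative of the normalised form (zero before the latency)
    dvalues = np.where(
        ts < 0,
        0.0,
        (-np.exp(-np.maximum(ts, 0) / tau1) / tau1
         + np.exp(-np.maximum(ts, 0) / tau2) / tau2) / peak,
    )
    return ResponseKernel(
        fs=float(fs),
        duration=float(duration),
        values=values,
        dvalues=dvalues,
        params={
            "tau1": float(tau1),
            "tau2": float(tau2),
            "latency_shift": float(latency_shift),
        },
    )
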