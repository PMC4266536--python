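"""Driver deconvolution, tonic/phasic split, NNLS decomposition, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import toeplitz

from scrcompare.decomposition import (
    Deconvolver,
    aggregate,
    dda_decompose,
    deconvolve,
    reconstruct,
    score_trial,
    score_trials,
    tonic_phasic_split,
)
from scrcompare.io import EventTable


def _smooth_bursts(n, events, sd_samples=4):
    """Driver with Gaussian-spread bursts (~0.4 s wide at 10 Hz)."""
    x = np.arange(-4 * sd_samples, 4 * sd_samples + 1)
    g = np.exp(-0.5 * (x / sd_samples) ** 2)
    g /= g.sum()
    driver = np.zeros(n)
    for t, a in events:
        driver[t - 4 * sd_samples : t + 4 * sd_samples + 1] += a * g
    return driver


class TestDeconvolve:
    def test_sparse_round_trip(self, kernel10):
        """Noiseless kernel convolution of a sparse driver inverts exactly."""
        n = 300
        truth = np.zeros(n)
        truth[[30, 100, 180]] = [0.5, 1.0, 0.3]
        dec = Deconvolver(kernel10, n, lam=1e-10)
        data = dec.reconvolve(truth)
        got = dec.solve(data)
        assert np.abs(got.values - truth).max() < 1e-4
        assert abs(got.pre_level) < 1e-6

    def test_kernel_recovers_unit_impulse(self, kernel10):
        ds = deconvolve(kernel10.values.copy(), kernel10, lam=1e-10)
        assert ds.values[0] == pytest.approx(1.0, abs=1e-4)
        assert np.abs(ds.values[1:]).max() < 1e-4

    def test_zero_data_zero_driver(self, kernel10):
        ds = deconvolve(np.zeros(200), kernel10)
        assert np.abs(ds.values).max() == 0.0
        assert ds.pre_level == 0.0

    def test_smooth_round_trip_within_one_percent(self, kernel10, rng):
        """At the default ridge, smooth inputs reconvolve to < 1% L2 error."""
        n = 2000
        smooth = 2 + np.convolve(
            rng.normal(0, 0.05, n), np.hanning(101) / 50, mode="same"
        )
        dec = Deconvolver(kernel10, n)
        ds = dec.solve(smooth)
        rel = np.linalg.norm(
            dec.reconvolve(ds.values, ds.pre_level) - smooth
        ) / np.linalg.norm(smooth)
        assert rel < 0.01


class TestTonicPhasicSplit:
    def test_flat_data_has_no_phasic(self, kernel10):
        n = 2000
        data = np.full(n, 2.0)
        dec = Deconvolver(kernel10, n)
        split = tonic_phasic_split(dec.solve(data), kernel10, data, dec=dec)
        assert np.abs(split.phasic).max() < 0.01
        assert np.abs(split.tonic_data - 2.0).max() < 0.05

    def test_baseline_plus_burst_recovers_tonic(self, kernel10):
        """Tonic trace stays at the baseline level despite a large burst."""
        n = 3000
        b = 2.0
        dec = Deconvolver(kernel10, n)
        driver = _smooth_bursts(n, [(1500, 0.8)])
        data = b + dec.reconvolve(driver)
        split = tonic_phasic_split(dec.solve(data), kernel10, data, dec=dec)
        assert np.abs(split.tonic_data - b).mean() < 0.05 * b
        # the phasic driver concentrates at the burst
        assert split.phasic[1450:1550].max() > 10 * np.abs(split.phasic[:1400]).max()

    def test_decomposition_conservation(self, kernel10):
        """tonic_data + kernel ⊗ phasic reconstructs the input."""
        n = 3000
        dec = Deconvolver(kernel10, n)
        driver = _smooth_bursts(
            n, [(300, 0.5), (800, 0.8), (1500, 0.4), (2200, 0.6)]
        )
        data = 2.0 + dec.reconvolve(driver)
        split = tonic_phasic_split(dec.solve(data), kernel10, data, dec=dec)
        err = np.abs(reconstruct(split, kernel10) - data).max()
        assert err < 1e-3 * data.max()


class TestDdaDecompose:
    def test_nonnegative_oracle_round_trip(self, kernel10):
        """NNLS on data from a nonnegative sparse driver leaves no remainder."""
        n = 200
        truth = np.zeros(n)
        truth[[20, 90, 150]] = [0.3, 0.7, 0.2]
        col = np.zeros(n)
        col[: min(n, len(kernel10))] = kernel10.values[:n]
        data = toeplitz(col, np.zeros(n)) @ truth
        driver, remainder = dda_decompose(data, kernel10)
        assert np.abs(remainder).max() < 1e-6
        np.testing.assert_allclose(driver[[20, 90, 150]], [0.3, 0.7, 0.2], atol=1e-6)

    def test_driver_always_nonnegative(self, kernel10, rng):
        data = rng.normal(0, 0.1, 300)
        driver, _ = dda_decompose(data, kernel10)
        assert driver.min() >= 0

    def test_negative_artefact_forces_zero_driver(self, kernel10):
        data = -kernel10.values[:300].copy()
        driver, remainder = dda_decompose(data, kernel10)
        assert np.abs(driver).max() == 0.0
        np.testing.assert_allclose(remainder, data)

    def test_remainder_never_worse_than_zero_driver(self, kernel10, rng):
        data = rng.normal(0, 0.2, 250) + 0.3
        driver, remainder = dda_decompose(data, kernel10)
        assert np.linalg.norm(remainder) <= np.linalg.norm(data) + 1e-12


class TestScoreTrial:
    fs = 10.0

    def _driver_with_peaks(self, peaks, n=200):
        driver = np.zeros(n)
        for i, a in peaks:
            driver[i - 2 : i + 3] += a * np.array([0.2, 0.7, 1.0, 0.7, 0.2])
        return driver

    def test_below_threshold_peak_scores_zero(self):
        driver = self._driver_with_peaks([(30, 0.005)])
        sc = score_trial(driver, onset=1.0, fs=self.fs)
        assert sc.amp_sum == 0.0
        assert not sc.above_threshold

    def test_two_peaks_sum(self):
        driver = self._driver_with_peaks([(25, 0.02), (35, 0.03)])
        sc = score_trial(driver, onset=1.0, fs=self.fs)
        assert sc.amp_sum == pytest.approx(0.05, abs=1e-9)

    def test_constant_driver_mean_only(self):
        driver = np.full(200, 0.7)
        sc = score_trial(driver, onset=1.0, fs=self.fs)
        assert sc.mean_driver == pytest.approx(0.7)
        assert sc.amp_sum == 0.0

    @pytest.mark.parametrize("thr", [0.0, 0.01, 0.025, 0.05])
    def test_amp_sum_nonincreasing_in_threshold(self, thr):
        driver = self._driver_with_peaks([(25, 0.02), (35, 0.03), (40, 0.004)])
        lo = score_trial(driver, onset=1.0, fs=self.fs, threshold=thr).amp_sum
        hi = score_trial(driver, onset=1.0, fs=self.fs, threshold=thr + 0.01).amp_sum
        assert hi <= lo

    def test_window_beyond_recording_drops_trial(self):
        driver = np.zeros(30)
        with pytest.warns(UserWarning):
            assert score_trial(driver, onset=2.0, fs=self.fs) is None

    def test_shared_peak_assigned_to_earlier_trial(self):
        driver = self._driver_with_peaks([(33, 0.05)], n=200)
        events = EventTable(
            np.array([0.0, 0.5]), np.array(["a", "a"], dtype=object)
        )
        scores = score_trials(driver, events, self.fs)
        # peak at 3.3 s lies in both windows [1,4] and [1.5,4.5]
        assert scores[0].amp_sum == pytest.approx(0.05)
        assert scores[1].amp_sum == 0.0


class TestAggregate:
    def _table(self, values, conditions, subject="s1", method="CDA1"):
        return pd.DataFrame(
            {
                "subject_id": subject,
                "condition": conditions,
                "trial": np.arange(len(values)),
                "method": method,
                "value": values,
            }
        )

    def test_mean_includes_zero_responses(self):
        out = aggregate(self._table([0.0, 0.2], ["a", "a"]))
        assert out["value"].iloc[0] == pytest.approx(0.1)

    def test_z_results_hand_example(self):
        # trials [1,2,3] over conditions A,A,B: z with sample SD gives
        # [-1,0,1], so A averages to -0.5 and B to +1
        out = aggregate(self._table([1.0, 2.0, 3.0], ["A", "A", "B"]), "z_results")
        by_cond = out.set_index("condition")["value"]
        assert by_cond["A"] == pytest.approx(-0.5)
        assert by_cond["B"] == pytest.approx(1.0)

    def test_z_results_degenerate_on_constant_trials(self):
        with pytest.raises(ValueError):
            aggregate(self._table([0.5, 0.5, 0.5], ["A", "A", "A"]), "z_results")

    def test_missing_condition_flagged(self):
        with pytest.warns(UserWarning):
            out = aggregate(self._table([0.1], ["a"]), conditions=["a", "b"])
        missing = out[out["condition"] == "b"]
        assert len(missing) == 1 and np.isnan(missing["value"].iloc[0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self._table([0.1], ["a"]), variant="bogus")
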