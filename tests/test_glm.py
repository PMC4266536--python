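"""Convolution GLM: design construction, co-filtering, OLS, amplitudes."""

import numpy as np
import pytest

from scrcompare.glm import (
    build_design,
    cofilter,
    fit_glm,
    glm_pipeline,
    reconstruct_amplitude,
)
from scrcompare.io import EventTable, ScrRecording
from scrcompare.kernel import make_kernel
from scrcompare.simulate import SimConfig, simulate_subject


def _events(onsets, conds):
    return EventTable(np.asarray(onsets, float), np.asarray(conds, dtype=object))


class TestBuildDesign:
    def test_single_event_at_zero_is_kernel(self, kernel10):
        ev = _events([0.0], ["a"])
        d = build_design(ev, 700, 10.0, kernel10)
        col = d.column("a", "canonical")
        np.testing.assert_allclose(col[: len(kernel10)], kernel10.values)
        np.testing.assert_allclose(col[len(kernel10) :], 0.0)

    def test_superposition_of_two_events(self, kernel10):
        ev = _events([0.0, 3.0], ["a", "a"])
        d = build_design(ev, 800, 10.0, kernel10)
        single0 = build_design(_events([0.0], ["a"]), 800, 10.0, kernel10)
        single3 = build_design(_events([3.0], ["a"]), 800, 10.0, kernel10)
        np.testing.assert_allclose(
            d.column("a", "canonical"),
            single0.column("a", "canonical") + single3.column("a", "canonical"),
        )

    def test_onset_index_arithmetic(self, kernel10):
        ev = _events([5.0], ["a"])
        d = build_design(ev, 600, 10.0, kernel10)
        col = d.column("a", "canonical")
        np.testing.assert_allclose(col[:50], 0.0)
        assert col[50] == kernel10.values[0]
        assert col[51] == kernel10.values[1]

    def test_column_count_and_labels(self, kernel10, two_condition_events):
        d = build_design(two_condition_events, 600, 10.0, kernel10)
        assert d.X.shape == (600, 4)
        assert d.conditions == ["neutral", "aversive"]


class TestCofilter:
    def test_same_operator_on_data_and_columns(self, kernel10, two_condition_events):
        d = build_design(two_condition_events, 600, 10.0, kernel10)
        data = d.column("neutral", "canonical").copy()
        fdata, fd = cofilter(data, d)
        np.testing.assert_allclose(fdata, fd.column("neutral", "canonical"))

    def test_constant_data_blocked(self, kernel10, two_condition_events):
        d = build_design(two_condition_events, 600, 10.0, kernel10)
        fdata, _ = cofilter(np.full(600, 4.2), d)
        assert np.abs(fdata).max() < 1e-9


class TestFitGlm:
    def test_exact_representation(self, kernel10, two_condition_events):
        d = build_design(two_condition_events, 600, 10.0, kernel10)
        y = 2.0 * d.X[:, 0]
        beta = fit_glm(y, d)
        np.testing.assert_allclose(beta, [2, 0, 0, 0], atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        # orthogonal two-column design: beta_j = <x_j, y>/<x_j, x_j>
        X = np.array(
            [[1.0, 1.0], [1.0, -1.0], [1.0, 1.0], [1.0, -1.0], [2.0, 0.0]]
        )
        X[:, 1] -= X[:, 0] * (X[:, 0] @ X[:, 1]) / (X[:, 0] @ X[:, 0])
        y = np.array([0.3, -1.2, 2.5, 0.7, 1.1])
        beta = fit_glm(y, X)
        expected = [X[:, j] @ y / (X[:, j] @ X[:, j]) for j in range(2)]
        np.testing.assert_allclose(beta, expected, atol=1e-12)

    def test_orthogonal_data_gives_zero(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        y = np.array([0.0, 0.0, 5.0])
        np.testing.assert_allclose(fit_glm(y, X), 0.0, atol=1e-12)

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm(np.arange(5.0), X)


class TestReconstructAmplitude:
    def test_canonical_only(self, kernel10):
        assert reconstruct_amplitude(1.0, 0.0, kernel10) == pytest.approx(1.0, abs=1e-3)
        assert reconstruct_amplitude(-1.0, 0.0, kernel10) == pytest.approx(-1.0, abs=1e-3)

    def test_matches_dense_grid_oracle(self):
        # brute-force maximisation of |r| on a 1000 Hz grid
        k_coarse = make_kernel(10.0)
        k_fine = make_kernel(1000.0)
        b1, b2 = 0.5, 0.2
        r_fine = b1 * k_fine.values + b2 * k_fine.dvalues
        oracle = r_fine[np.argmax(np.abs(r_fine))]
        got = reconstruct_amplitude(b1, b2, k_coarse)
        assert got == pytest.approx(oracle, abs=2e-3)


@pytest.fixture(scope="module")
def noiseless_exp():
    cfg = SimConfig(
        n_subjects=1,
        conditions=(("neutral", 0.3, 0.0), ("aversive", 0.6, 0.0)),
        trials_per_condition=8,
        latency_jitter_sd_s=0.0,
        spontaneous_rate_hz=0.0,
        tonic_drift_sd=0.0,
        noise_sd_uS=0.0,
        subject_gain_sd=0.0,
        seed=11,
    )
    rng = np.random.default_rng(cfg.seed)
    return cfg, simulate_subject(cfg, 0, rng)


class TestGlmPipeline:
    def test_noiseless_condition_ratio(self, noiseless_exp):
        """Amplitudes (a, 2a) give an estimated ratio of 2: z-scoring
        rescales both conditions equally."""
        _, sub = noiseless_exp
        est = glm_pipeline(sub.recording, sub.events)
        by_cond = est.set_index("condition")["value"]
        assert by_cond["aversive"] / by_cond["neutral"] == pytest.approx(2.0, rel=0.05)

    def test_zero_amplitude_condition(self):
        cfg = SimConfig(
            n_subjects=1,
            conditions=(("null", 0.0, 0.0), ("active", 0.5, 0.0)),
            trials_per_condition=8,
            spontaneous_rate_hz=0.0,
            tonic_drift_sd=0.0,
            noise_sd_uS=0.0,
            subject_gain_sd=0.0,
            seed=3,
        )
        sub = simulate_subject(cfg, 0, np.random.default_rng(3))
        est = glm_pipeline(sub.recording, sub.events).set_index("condition")["value"]
        assert abs(est["null"]) < 0.05 * abs(est["active"])

    def test_gain_invariance(self, noiseless_exp):
        """Multiplying the recording by any c > 0 leaves estimates unchanged."""
        _, sub = noiseless_exp
        est1 = glm_pipeline(sub.recording, sub.events)
        scaled = ScrRecording(
            sub.recording.subject_id, sub.recording.fs, 10.0 * sub.recording.values
        )
        est2 = glm_pipeline(scaled, sub.events)
        np.testing.assert_allclose(
            est1["value"].to_numpy(), est2["value"].to_numpy(), atol=1e-6
        )

    def test_monotone_in_effect_size(self):
        """Mean estimated condition difference is nondecreasing in the
        true amplitude difference (noise held fixed)."""
        diffs = []
        for mu_diff in (0.0, 0.2, 0.5, 1.0):
            vals = []
            for rep in range(6):
                cfg = SimConfig(
                    n_subjects=1,
                    conditions=(("a", 0.3, 0.05), ("b", 0.3 + mu_diff, 0.05)),
                    trials_per_condition=10,
                    seed=100 + rep,
                )
                sub = simulate_subject(cfg, 0, np.random.default_rng(cfg.seed))
                est = glm_pipeline(sub.recording, sub.events).set_index("condition")[
                    "value"
                ]
                vals.append(est["b"] - est["a"])
            diffs.append(np.mean(vals))
        assert all(np.diff(diffs) > -0.05)
        assert diffs[-1] > diffs[0]
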