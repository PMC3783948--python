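"""Summary statistics of the experiment drivers, on synthetic ensembles."""

import numpy as np
import pytest
from scipy.stats import binom

import ringmem as rm
from ringmem.decoding import TrialResult
from ringmem.experiments import (ConditionSpec, DISTRACTOR_DISTANCES,
                                 displacement_matrix, performance_summary,
                                 tuning_curves, wilson_interval)


def _trial(outcome, theta_R=0.0, theta_D=None, rates=None, idx=0):
    return TrialResult(trial_index=idx, theta_S=0.0, theta_D=theta_D,
                       theta_R=theta_R, modulus_C=0.9, precue_modulus=0.0,
                       outcome=outcome, delay_rates=rates)


class TestPerformanceSummary:
    def test_all_correct(self):
        s = performance_summary([_trial("correct")] * 5)
        assert (s["correct"], s["decaying"], s["emergent"]) == (1.0, 0.0, 0.0)

    def test_counting(self):
        trials = [_trial("correct"), _trial("correct"),
                  _trial("decaying_bump_error"), _trial("emergent_bump_error")]
        s = performance_summary(trials)
        assert s["correct"] == 0.5
        assert s["decaying"] == 0.25
        assert s["emergent"] == 0.25

    def test_fractions_partition(self):
        rng = np.random.default_rng(0)
        outs = rng.choice(["correct", "decaying_bump_error",
                           "emergent_bump_error"], 37)
        s = performance_summary([_trial(o) for o in outs])
        assert s["correct"] + s["decaying"] + s["emergent"] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            performance_summary([])


class TestWilsonInterval:
    @pytest.mark.parametrize("k", [0, 3, 7, 10])
    def test_coverage_against_exact_enumeration(self, k):
        """Wilson CI at n=10 vs brute-force binomial coverage.

        For every true p on a fine grid, exact enumeration of the binomial
        distribution gives the coverage of the Wilson intervals; the average
        coverage must be near nominal (the Wilson interval's defining
        property), and each interval must contain its point estimate.
        """
        n = 10
        lo, hi = wilson_interval(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0
        # exact coverage: p in [lo_k, hi_k] over all k weighted by Binom(n,p)
        ps = np.linspace(0.01, 0.99, 99)
        bounds = np.array([wilson_interval(j, n) for j in range(n + 1)])
        coverage = []
        for p in ps:
            weights = binom.pmf(np.arange(n + 1), n, p)
            inside = (bounds[:, 0] <= p) & (p <= bounds[:, 1])
            coverage.append(weights[inside].sum())
        assert np.mean(coverage) > 0.93  # near-nominal on average


class TestConditionSpec:
    def test_single_axis_enforced(self):
        with pytest.raises(ValueError):
            ConditionSpec(mult_5ht=1.2, mult_1A=0.8)

    def test_serotonin_scales_compose(self):
        c = ConditionSpec(mult_5ht=0.8)
        s = c.serotonin()
        assert s.concentration_scale_1A == pytest.approx(0.8)
        assert s.concentration_scale_2A == pytest.approx(0.8)
        c2 = ConditionSpec(mult_2A=1.2)
        assert c2.serotonin().concentration_scale_1A == 1.0
        assert c2.serotonin().concentration_scale_2A == pytest.approx(1.2)

    def test_distance_grid(self):
        assert DISTRACTOR_DISTANCES[0] == 0.0
        assert DISTRACTOR_DISTANCES[-1] == pytest.approx(180.0)
        assert np.allclose(np.diff(DISTRACTOR_DISTANCES), 11.25)
        assert len(DISTRACTOR_DISTANCES) == 17


class TestDisplacementMatrix:
    def test_columns_sum_to_one_and_bins_place_reports(self):
        rng = np.random.default_rng(2)
        distances = np.array([45.0, 90.0])
        trials = []
        for d in distances:
            for i in range(20):
                # half stay at the cue, half land on the distractor
                theta_R = 0.0 if i % 2 else d
                trials.append(_trial("correct", theta_R=theta_R, theta_D=d,
                                     idx=i))
        mat = displacement_matrix(trials, distances)
        assert np.allclose(mat.fraction.sum(axis=0), 1.0)
        zero_bin = np.argmin(np.abs(mat.bin_centers - 11.25 / 2))
        assert mat.fraction[zero_bin].min() >= 0.5 - 1e-9
        d45_bin = np.argmin(np.abs(mat.bin_centers - (45.0 + 11.25 / 2)))
        assert mat.fraction[d45_bin, 0] == pytest.approx(0.5)


class TestTuningCurves:
    def _gaussian_trials(self, n_neurons=64, n_trials=20, width=25.0,
                         jitter=0.0, seed=0, align_to_report=False):
        rng = np.random.default_rng(seed)
        angles = rm.preferred_angles(n_neurons)
        trials = []
        for i in range(n_trials):
            center = rng.uniform(-10, 10) if jitter else 0.0
            d = ((angles - center + 180) % 360) - 180
            rates = 2.0 + 30.0 * np.exp(-d**2 / (2 * width**2))
            trials.append(_trial("correct", theta_R=center, rates=rates, idx=i))
        return trials, angles

    def test_fit_recovers_shape(self):
        trials, angles = self._gaussian_trials()
        tc = tuning_curves(trials, angles, alignment="cue")
        assert tc.baseline == pytest.approx(2.0, abs=1.5)
        assert tc.amplitude == pytest.approx(30.0, rel=0.3)
        assert 10 < tc.width < 50

    def test_perfect_trials_cue_equals_report(self):
        trials, angles = self._gaussian_trials()
        cue = tuning_curves(trials, angles, "cue")
        rep = tuning_curves(trials, angles, "report")
        assert np.allclose(cue.curve, rep.curve)
        assert cue.sharpness == pytest.approx(rep.sharpness)

    def test_report_alignment_sharper_when_bump_wanders(self):
        """Bumps centered on the (per-trial) report: report tuning wins."""
        rng = np.random.default_rng(4)
        angles = rm.preferred_angles(64)
        trials = []
        for i in range(40):
            center = rng.uniform(-180, 180)  # bump far from the cue
            d = ((angles - center + 180) % 360) - 180
            rates = 2.0 + 30.0 * np.exp(-d**2 / (2 * 25.0**2))
            trials.append(_trial("emergent_bump_error", theta_R=center,
                                 rates=rates, idx=i))
        cue = tuning_curves(trials, angles, "cue", trial_filter="errors_only")
        rep = tuning_curves(trials, angles, "report", trial_filter="errors_only")
        assert rep.sharpness > 3 * max(cue.sharpness, 1e-9)

    def test_filter_and_minimum_trials(self):
        trials, angles = self._gaussian_trials(n_trials=3)
        with pytest.raises(ValueError):
            tuning_curves(trials, angles, "cue", trial_filter="errors_only")
        with pytest.raises(ValueError):
            tuning_curves(trials[:1], angles, "cue")

    def test_bins_tile_circle(self):
        trials, angles = self._gaussian_trials()
        tc = tuning_curves(trials, angles, "cue")
        assert len(tc.bin_centers) == 8
        assert tc.width > 0
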