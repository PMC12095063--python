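"""Psychometric curve fits, landmark interpolation, and quality screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from confleak import psychometric
from confleak.psychometric import (
    FitDataError,
    fit_confidence,
    fit_decision,
    fit_reproduction,
    landmark_effect,
)
from confleak.simulate import ObserverParams, simulate_trials
from conftest import scaled_design


def _decision_frame(lengths, p_long, n_per_length, seed=0):
    """Bernoulli decision trials from an explicit psychometric function."""
    rng = np.random.default_rng(seed)
    rows = []
    for length, p in zip(lengths, p_long):
        responses = rng.random(n_per_length) < p
        for r in responses:
            rows.append((length, "long" if r else "short"))
    frame = pd.DataFrame(rows, columns=["target_length", "response"])
    frame["task"] = "decision"
    frame["confidence"] = "low"
    frame["reproduced_length"] = np.nan
    return frame


def _confidence_frame(lengths, p_high, n_per_length=1000):
    """Decision trials whose per-length 'high' proportions are exact."""
    rows = []
    for length, p in zip(lengths, p_high):
        n_high = round(p * n_per_length)
        rows += [(length, "high")] * n_high + [(length, "low")] * (n_per_length - n_high)
    frame = pd.DataFrame(rows, columns=["target_length", "confidence"])
    frame["task"] = "decision"
    frame["response"] = "long"
    frame["reproduced_length"] = np.nan
    return frame


def _reproduction_frame(lengths, reproduced):
    frame = pd.DataFrame({"target_length": lengths, "reproduced_length": reproduced})
    frame["task"] = "reproduction"
    frame["response"] = ""
    frame["confidence"] = ""
    return frame


class TestDecisionFit:
    def test_recovers_generative_probit_pse(self):
        lengths = np.arange(370, 431, 10)
        p_long = stats.norm.cdf((lengths - 400) / 15)
        trials = _decision_frame(lengths, p_long, 3000, seed=4)
        fit = fit_decision(trials)
        assert fit.quality_pass
        assert fit.landmark == pytest.approx(400, abs=1)

    def test_balanced_responses_fail_quality(self):
        lengths = np.arange(370, 431, 10)
        trials = _decision_frame(lengths, np.full(7, 0.5), 200, seed=1)
        fit = fit_decision(trials)
        assert not fit.quality_pass

    def test_all_identical_responses_fail_without_exception(self):
        lengths = np.arange(370, 431, 10)
        trials = _decision_frame(lengths, np.ones(7), 50, seed=2)
        fit = fit_decision(trials)
        assert not fit.quality_pass and np.isnan(fit.landmark)

    def test_complete_separation_fails_without_exception(self):
        lengths = np.arange(370, 431, 10)
        trials = _decision_frame(lengths, (lengths > 400).astype(float), 50, seed=3)
        fit = fit_decision(trials)
        assert not fit.quality_pass

    def test_pse_invariant_to_response_coding(self):
        lengths = np.arange(370, 431, 10)
        p_long = stats.norm.cdf((lengths - 395) / 12)
        trials = _decision_frame(lengths, p_long, 500, seed=9)
        swapped = trials.copy()
        swapped["response"] = swapped["response"].map({"long": "short", "short": "long"})
        pse = fit_decision(trials).landmark
        pse_swapped = fit_decision(swapped).landmark
        assert pse == pytest.approx(pse_swapped, abs=1e-6)

    def test_too_few_lengths_rejected(self):
        trials = _decision_frame([400], [0.5], 50)
        with pytest.raises(FitDataError):
            fit_decision(trials)


class TestConfidenceFit:
    def test_exact_quadratic_vertex(self):
        lengths = np.arange(380, 421, 10)
        p_high = 0.001 * (lengths - 400.0) ** 2 + 0.2
        fit = fit_confidence(_confidence_frame(lengths, p_high))
        assert fit.quality_pass
        assert fit.landmark == pytest.approx(400, abs=1e-6)

    def test_inverted_u_fails_quality(self):
        lengths = np.arange(380, 421, 10)
        p_high = 0.8 - 0.001 * (lengths - 400.0) ** 2
        fit = fit_confidence(_confidence_frame(lengths, p_high))
        assert not fit.quality_pass

    def test_too_few_lengths_rejected(self):
        with pytest.raises(FitDataError):
            fit_confidence(_confidence_frame([390, 410], [0.5, 0.5]))

    def test_vertex_matches_numeric_minimization(self):
        lengths = np.arange(370, 431, 10)
        p_high = 0.0008 * (lengths - 404.0) ** 2 + 0.3
        fit = fit_confidence(_confidence_frame(lengths, p_high))
        c0, c1, c2 = fit.coefficients
        numeric = optimize.minimize_scalar(
            lambda x: c0 + c1 * x + c2 * x**2, bounds=(300, 500), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert fit.landmark == pytest.approx(numeric, abs=1e-6)


class TestReproductionFit:
    @pytest.mark.parametrize(
        "intercept,slope,expected",
        [(40.0, 0.9, 400.0), (0.0, 1.0, 400.0), (20.0, 1.0, 380.0)],
    )
    def test_exact_line_match_point(self, intercept, slope, expected):
        lengths = np.repeat(np.arange(370, 431, 10), 3).astype(float)
        fit = fit_reproduction(_reproduction_frame(lengths, intercept + slope * lengths))
        assert fit.landmark == pytest.approx(expected, abs=1e-9)

    def test_match_point_matches_root_finding(self):
        lengths = np.repeat(np.arange(370, 431, 10), 5).astype(float)
        rng = np.random.default_rng(8)
        fit = fit_reproduction(
            _reproduction_frame(lengths, 30 + 0.95 * lengths + rng.normal(0, 5, lengths.size))
        )
        a, b = fit.coefficients
        root = optimize.brentq(lambda x: a + b * x - 400.0, 200, 600, xtol=1e-12)
        assert fit.landmark == pytest.approx(root, abs=1e-6)

    def test_zero_length_variance_rejected(self):
        with pytest.raises(FitDataError):
            fit_reproduction(_reproduction_frame([400.0] * 10, np.full(10, 400.0)))


class TestLandmarkEffect:
    def _fit_at(self, pse):
        lengths = np.arange(370, 431, 10)
        p_long = stats.norm.cdf((lengths - pse) / 12)
        return fit_decision(_decision_frame(lengths, p_long, 2000, seed=int(pse)))

    def test_identical_fits_zero_effect(self):
        fit = self._fit_at(400)
        assert landmark_effect(fit, fit) == 0.0

    def test_sign_convention_toward_bias_is_positive(self):
        fit_long = self._fit_at(395)   # biased-to-long: PSE at shorter lengths
        fit_short = self._fit_at(405)
        assert landmark_effect(fit_long, fit_short) == pytest.approx(10, abs=1.5)

    def test_kind_mismatch_rejected(self):
        lengths = np.arange(380, 421, 10)
        conf = fit_confidence(
            _confidence_frame(lengths, 0.001 * (lengths - 400.0) ** 2 + 0.2)
        )
        with pytest.raises(ValueError):
            landmark_effect(self._fit_at(400), conf)

    def test_failed_quality_rejected(self):
        good = self._fit_at(400)
        lengths = np.arange(370, 431, 10)
        bad = fit_decision(_decision_frame(lengths, np.full(7, 0.5), 100, seed=0))
        with pytest.raises(ValueError):
            landmark_effect(good, bad)


class TestCohortRecovery:
    def test_generative_landmarks_recovered_cross_module(self, criterion_observer_trials):
        """Criterion-shift observer: PSE at R + c_dec, vertex near R + c_conf,
        match point at the reference."""
        trials = criterion_observer_trials
        assert fit_decision(trials).landmark == pytest.approx(410, abs=1)
        assert fit_confidence(trials).landmark == pytest.approx(405, abs=1.5)
        assert fit_reproduction(trials).landmark == pytest.approx(400, abs=1)

    def test_fit_table_shape_and_flags(self):
        params = ObserverParams(perceptual_shift=8.0, seed=21)
        design = scaled_design(
            "muller_lyer", "long", n_decision_per_length=60, n_reproduction_per_length=30
        )
        trials = simulate_trials(params, design, subject_id="s1")
        table = psychometric.fit_table(trials)
        assert set(table["task"]) == {"decision", "confidence", "reproduction"}
        assert {"landmark", "p_value", "quality_pass"} <= set(table.columns)
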