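"""Design arithmetic, schedule conservation, and observer generative checks."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confleak import psychometric
from confleak.simulate import (
    BIAS_DIRECTIONS,
    BIAS_SOURCES,
    REFERENCE_LENGTH,
    TARGET_LENGTHS,
    DesignError,
    ObserverParams,
    build_design,
    build_schedule,
    read_trials,
    simulate_trials,
    write_trials,
)
from conftest import scaled_design


class TestDesign:
    @pytest.mark.parametrize("direction", BIAS_DIRECTIONS)
    @pytest.mark.parametrize("source", BIAS_SOURCES)
    def test_design_totals(self, source, direction):
        design = build_design(source, direction)
        assert design.target_lengths == TARGET_LENGTHS
        assert design.reference_length == REFERENCE_LENGTH
        if source == "base_rate":
            assert design.n_decision == 390
            assert design.n_reproduction == 195
        else:
            assert design.n_decision == 280
            assert design.n_reproduction == 140
            assert design.n_total == 420
            assert all(v == 40 for v in design.decision_counts.values())
            assert all(v == 20 for v in design.reproduction_counts.values())

    def test_base_rate_prevalent_counts_far_to_near(self):
        long_design = build_design("base_rate", "long")
        assert [long_design.decision_counts[k] for k in (430, 420, 410)] == [120, 90, 60]
        assert all(long_design.decision_counts[k] == 30 for k in (370, 380, 390, 400))
        short_design = build_design("base_rate", "short")
        assert [short_design.decision_counts[k] for k in (370, 380, 390)] == [120, 90, 60]
        # reproduction counts are exactly half of decision counts
        for design in (long_design, short_design):
            for k in TARGET_LENGTHS:
                assert design.reproduction_counts[k] * 2 == design.decision_counts[k]

    @pytest.mark.parametrize(
        "direction,pen_long,pen_short", [("short", 5, 1), ("long", 1, 5)]
    )
    def test_payoff_penalties(self, direction, pen_long, pen_short):
        design = build_design("payoff", direction)
        assert design.penalty_incorrect_long == pen_long
        assert design.penalty_incorrect_short == pen_short

    def test_flat_penalty_elsewhere(self):
        for source in ("muller_lyer", "base_rate"):
            design = build_design(source, "long")
            assert (design.penalty_incorrect_long, design.penalty_incorrect_short) == (1, 1)

    def test_unknown_enum_rejected(self):
        with pytest.raises(DesignError):
            build_design("anchoring", "long")
        with pytest.raises(DesignError):
            build_design("payoff", "upwards")


class TestSchedule:
    @given(
        source=st.sampled_from(BIAS_SOURCES),
        direction=st.sampled_from(BIAS_DIRECTIONS),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_schedule_conserves_design_counts(self, source, direction, seed):
        design = build_design(source, direction)
        schedule = build_schedule(design, seed)
        expected = Counter()
        for length, count in design.decision_counts.items():
            expected[(length, "decision")] = count
        for length, count in design.reproduction_counts.items():
            expected[(length, "reproduction")] = count
        assert Counter(schedule) == expected

    def test_schedule_lengths(self):
        assert len(build_schedule(build_design("muller_lyer", "long"), 0)) == 420
        assert len(build_schedule(build_design("base_rate", "long"), 0)) == 585

    def test_schedule_seed_determinism(self):
        design = build_design("payoff", "short")
        assert build_schedule(design, 99) == build_schedule(design, 99)
        assert build_schedule(design, 99) != build_schedule(design, 100)


class TestObserver:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(sensory_sd=0.0)
        with pytest.raises(ValueError):
            ObserverParams(reproduction_slope=-1.0)
        with pytest.raises(ValueError):
            ObserverParams(reproduction_sd=-0.1)

    def test_trial_record_invariants(self):
        params = ObserverParams(seed=3)
        design = build_design("base_rate", "short")
        trials = simulate_trials(params, design)
        dec = trials[trials["task"] == "decision"]
        rep = trials[trials["task"] == "reproduction"]
        assert set(dec["response"]) <= {"short", "long"}
        assert set(dec["confidence"]) <= {"low", "high"}
        assert dec["reproduced_length"].isna().all()
        assert (rep["response"] == "").all()
        assert rep["reproduced_length"].notna().all()
        # correctness undefined exactly at the reference length
        at_ref = dec[dec["target_length"] == REFERENCE_LENGTH]
        off_ref = dec[dec["target_length"] != REFERENCE_LENGTH]
        assert at_ref["correct"].isna().all()
        assert off_ref["correct"].notna().all()

    def test_seed_determinism(self):
        params = ObserverParams(perceptual_shift=5.0, seed=77)
        design = build_design("muller_lyer", "long")
        a = simulate_trials(params, design)
        b = simulate_trials(params, design)
        assert a.equals(b)

    def test_reference_target_is_coin_flip_without_bias(self):
        # p = 0, c_dec = 0: the percept is symmetric about the criterion
        params = ObserverParams(seed=5)
        design = scaled_design("muller_lyer", "long", n_decision_per_length=4000)
        trials = simulate_trials(params, design)
        at_ref = trials[trials["target_length"] == REFERENCE_LENGTH]
        p_long = (at_ref["response"] == "long").mean()
        assert abs(p_long - 0.5) < 3 * 0.5 / np.sqrt(len(at_ref))

    def test_perceptual_vs_criterion_dissociation(self):
        """A perceptual shift moves the reproduction match point; an equal
        criterion shift leaves it at the reference."""
        design = scaled_design(
            "muller_lyer", "long", n_decision_per_length=2000, n_reproduction_per_length=2000
        )
        perceptual = simulate_trials(ObserverParams(perceptual_shift=15.0, seed=1), design)
        criterion = simulate_trials(
            ObserverParams(decision_criterion_shift=15.0, seed=2), design
        )
        pse_p = psychometric.fit_decision(perceptual).landmark
        pse_c = psychometric.fit_decision(criterion).landmark
        match_p = psychometric.fit_reproduction(perceptual).landmark
        match_c = psychometric.fit_reproduction(criterion).landmark
        assert pse_p == pytest.approx(385, abs=2)
        assert pse_c == pytest.approx(415, abs=2)
        assert match_p == pytest.approx(385, abs=2)
        assert match_c == pytest.approx(400, abs=2)

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(sensory_sd=0.0)


class TestTrialIO:
    def test_round_trip(self, tmp_path):
        params = ObserverParams(seed=11)
        trials = simulate_trials(params, build_design("payoff", "long"))
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        loaded = read_trials(path)
        assert len(loaded) == len(trials)
        assert (loaded["response"] == trials["response"]).all()
        assert loaded["correct"].equals(trials["correct"])

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,task\nx,decision\n")
        with pytest.raises(DesignError, match="bias_source"):
            read_trials(path)
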