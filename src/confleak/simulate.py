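"""Trial schedules and a generative signal-detection observer.

The experimental design is a line-length discrimination/reproduction study:
on each trial a horizontal target line (370–430 px in steps of 10) is compared
against an implicit 400-px reference.  Three between-subject bias sources
(Müller–Lyer arrowheads, base-rate manipulation, asymmetric payoff) are each
run in two within-subject bias directions ('long' and 'short').

The observer implemented here is the minimal generative model that can
dissociate a *perceptual* shift from a *decisional* one:

* percept        x  = L + p + ε,              ε  ~ N(0, σ²)
* decision       'long'  iff  x ≥ R + c_dec
* confidence     'high'  iff  |x − (R + c_conf)| ≥ max(τ + η, 0),  η ~ N(0, σ_m²)
* reproduction   y  = α + β·(L + p) + ε_r,    ε_r ~ N(0, σ_r²)

with reference R = 400.  A perceptual shift p moves every landmark (decision
PSE, confidence vertex, reproduction match point) by −p; a criterion shift
c_dec moves only the PSE; a confidence-center shift c_conf moves only the
confidence vertex.  Closed forms:

    PSE    = R + c_dec  − p
    vertex = R + c_conf − p
    match  = (R − α)/β  − p

Metacognitive noise σ_m > 0 degrades the confidence–accuracy coupling and
yields M-ratio < 1; σ_m → 0 recovers the metacognitively ideal observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TARGET_LENGTHS",
    "REFERENCE_LENGTH",
    "BIAS_SOURCES",
    "BIAS_DIRECTIONS",
    "TRIAL_COLUMNS",
    "ConditionDesign",
    "ObserverParams",
    "CohortSpec",
    "build_design",
    "build_schedule",
    "simulate_trials",
    "simulate_cohort",
    "write_trials",
    "read_trials",
]

TARGET_LENGTHS: tuple[int, ...] = (370, 380, 390, 400, 410, 420, 430)
REFERENCE_LENGTH: int = 400
BIAS_SOURCES: tuple[str, ...] = ("muller_lyer", "base_rate", "payoff")
BIAS_DIRECTIONS: tuple[str, ...] = ("long", "short")

#: column order of the on-disk trial table (CSV, header row, empty = missing)
TRIAL_COLUMNS = [
    "subject_id",
    "bias_source",
    "bias_direction",
    "task",
    "target_length",
    "response",
    "confidence",
    "reproduced_length",
]


class DesignError(ValueError):
    """Unknown bias source/direction or invalid design input."""


def _check_choice(value: str, choices: Sequence[str], what: str) -> str:
    if value not in choices:
        raise DesignError(f"unknown {what} {value!r}; expected one of {choices}")
    return value


@dataclass(frozen=True)
class ConditionDesign:
    """Trial counts and payoff structure for one bias source × direction."""

    bias_source: str
    bias_direction: str
    target_lengths: tuple[int, ...] = TARGET_LENGTHS
    reference_length: int = REFERENCE_LENGTH
    decision_counts: dict[int, int] = field(default_factory=dict)
    reproduction_counts: dict[int, int] = field(default_factory=dict)
    penalty_incorrect_long: int = 1
    penalty_incorrect_short: int = 1

    @property
    def n_decision(self) -> int:
        return sum(self.decision_counts.values())

    @property
    def n_reproduction(self) -> int:
        return sum(self.reproduction_counts.values())

    @property
    def n_total(self) -> int:
        return self.n_decision + self.n_reproduction


def build_design(bias_source: str, bias_direction: str) -> ConditionDesign:
    """Build the per-direction trial-count design for one bias source.

    Müller–Lyer and payoff present each of the 7 target lengths 40 times in
    the decision/confidence task and 20 times in the reproduction task
    (280 + 140 = 420 trials per direction).  Base rate presents the prevalent
    category 120/90/60 times going from the farthest to the closest length to
    the reference, 30 times for each non-prevalent target and the reference
    length itself (390 decision trials), with reproduction counts exactly half
    (195).  Payoff penalties are 5 points for incorrectly choosing the
    non-biased direction's complement — e.g. under bias-to-short an incorrect
    'long' costs 5 and an incorrect 'short' 1 — and flat (1, 1) otherwise.
    """
    _check_choice(bias_source, BIAS_SOURCES, "bias source")
    _check_choice(bias_direction, BIAS_DIRECTIONS, "bias direction")

    if bias_source == "base_rate":
        if bias_direction == "long":
            prevalent = [430, 420, 410]  # farthest -> closest to reference
        else:
            prevalent = [370, 380, 390]
        dec = {length: 30 for length in TARGET_LENGTHS}
        for length, count in zip(prevalent, (120, 90, 60)):
            dec[length] = count
        rep = {length: count // 2 for length, count in dec.items()}
    else:
        dec = {length: 40 for length in TARGET_LENGTHS}
        rep = {length: 20 for length in TARGET_LENGTHS}

    if bias_source == "payoff":
        if bias_direction == "short":
            pen_long, pen_short = 5, 1
        else:
            pen_long, pen_short = 1, 5
    else:
        pen_long = pen_short = 1

    return ConditionDesign(
        bias_source=bias_source,
        bias_direction=bias_direction,
        decision_counts=dec,
        reproduction_counts=rep,
        penalty_incorrect_long=pen_long,
        penalty_incorrect_short=pen_short,
    )


def build_schedule(design: ConditionDesign, seed: int) -> list[tuple[int, str]]:
    """Expand a design into a seed-reproducible randomized trial order.

    Returns a list of ``(target_length, task)`` pairs whose multiset equals
    the design counts exactly.  Counterbalanced mini-block structure is not
    reproduced; only the marginal counts matter for the analyses.
    """
    entries: list[tuple[int, str]] = []
    for length, count in design.decision_counts.items():
        entries.extend([(length, "decision")] * count)
    for length, count in design.reproduction_counts.items():
        entries.extend([(length, "reproduction")] * count)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the generative SDT observer (all lengths in pixels).

    ``perceptual_shift`` moves the percept itself (Müller–Lyer-like);
    ``decision_criterion_shift`` and ``confidence_center_shift`` move the
    decision criterion and the center of the confidence window without
    touching the percept (base-rate/payoff-like).  A partial "leak" of a
    decisional bias into confidence is modeled by setting
    ``|confidence_center_shift| <= |decision_criterion_shift|``.
    """

    perceptual_shift: float = 0.0
    decision_criterion_shift: float = 0.0
    confidence_center_shift: float = 0.0
    sensory_sd: float = 15.0
    confidence_halfwidth: float = 25.0
    metacognitive_noise_sd: float = 5.0
    reproduction_intercept: float = 0.0
    reproduction_slope: float = 1.0
    reproduction_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sensory_sd > 0:
            raise ValueError("sensory_sd must be > 0 (degenerate observer)")
        if not self.reproduction_slope > 0:
            raise ValueError("reproduction_slope must be > 0")
        for name in ("confidence_halfwidth", "metacognitive_noise_sd", "reproduction_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # closed-form landmark predictions — the test oracle for the simulator
    def predicted_pse(self, reference: float = REFERENCE_LENGTH) -> float:
        return reference + self.decision_criterion_shift - self.perceptual_shift

    def predicted_confidence_vertex(self, reference: float = REFERENCE_LENGTH) -> float:
        return reference + self.confidence_center_shift - self.perceptual_shift

    def predicted_reproduction_match(self, reference: float = REFERENCE_LENGTH) -> float:
        return (
            (reference - self.reproduction_intercept) / self.reproduction_slope
            - self.perceptual_shift
        )


def simulate_trials(
    params: ObserverParams,
    design: ConditionDesign,
    schedule: Iterable[tuple[int, str]] | None = None,
    subject_id: str = "s000",
) -> pd.DataFrame:
    """Generate one trial table (one row per trial) for a single observer.

    ``correct`` is defined by comparing the response to the sign of
    ``target_length − reference`` and is missing at the reference length,
    which belongs to neither stimulus class.
    """
    if schedule is None:
        schedule = build_schedule(design, params.seed)
    schedule = list(schedule)
    lengths = np.array([length for length, _ in schedule], dtype=float)
    tasks = np.array([task for _, task in schedule])
    rng = np.random.default_rng(params.seed)
    ref = float(design.reference_length)

    n = len(schedule)
    response = np.full(n, "", dtype=object)
    confidence = np.full(n, "", dtype=object)
    reproduced = np.full(n, np.nan)

    dec = tasks == "decision"
    x = lengths[dec] + params.perceptual_shift + rng.normal(0.0, params.sensory_sd, dec.sum())
    is_long = x >= ref + params.decision_criterion_shift
    response[dec] = np.where(is_long, "long", "short")
    thresh = params.confidence_halfwidth + rng.normal(
        0.0, params.metacognitive_noise_sd, dec.sum()
    )
    thresh = np.maximum(thresh, 0.0)
    confidence[dec] = np.where(
        np.abs(x - (ref + params.confidence_center_shift)) >= thresh, "high", "low"
    )

    rep = ~dec
    reproduced[rep] = (
        params.reproduction_intercept
        + params.reproduction_slope * (lengths[rep] + params.perceptual_shift)
        + rng.normal(0.0, params.reproduction_sd, rep.sum())
    )

    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "bias_source": design.bias_source,
            "bias_direction": design.bias_direction,
            "task": tasks,
            "target_length": lengths.astype(int),
            "response": response,
            "confidence": confidence,
            "reproduced_length": reproduced,
        }
    )
    frame["correct"] = _derive_correct(frame, ref)
    return frame


def _derive_correct(frame: pd.DataFrame, reference: float) -> pd.Series:
    correct = pd.Series(np.nan, index=frame.index, dtype=object)
    dec = frame["task"] == "decision"
    offref = dec & (frame["target_length"] != reference)
    truth = np.where(frame.loc[offref, "target_length"] > reference, "long", "short")
    correct[offref] = frame.loc[offref, "response"].to_numpy() == truth
    return correct


@dataclass(frozen=True)
class CohortSpec:
    """Group-level description of a simulated cohort for one bias source.

    The bias magnitude applied to each subject is drawn from
    N(``shift_magnitude``, ``between_subject_sd``²); its sign follows the
    bias direction ('long' shifts behavior toward reporting long).  For a
    perceptual source the magnitude feeds ``perceptual_shift``; otherwise it
    feeds ``decision_criterion_shift`` with a partial leak
    ``confidence_leak`` into ``confidence_center_shift``.
    """

    bias_source: str = "muller_lyer"
    n_subjects: int = 35
    shift_magnitude: float = 10.0
    between_subject_sd: float = 6.0
    confidence_leak: float = 0.5
    observer: ObserverParams = field(default_factory=ObserverParams)

    def __post_init__(self) -> None:
        _check_choice(self.bias_source, BIAS_SOURCES, "bias source")


def simulate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate a full between-subject group: every subject runs both bias
    directions with a subject-specific bias magnitude shared across
    directions (magnitudes are mirrored, matching the symmetric
    manipulations)."""
    rng = np.random.default_rng(seed)
    frames = []
    magnitudes = rng.normal(spec.shift_magnitude, spec.between_subject_sd, spec.n_subjects)
    for i, magnitude in enumerate(magnitudes):
        subject = f"{spec.bias_source}_{i:03d}"
        for direction in BIAS_DIRECTIONS:
            sign = 1.0 if direction == "long" else -1.0
            if spec.bias_source == "muller_lyer":
                shifts = dict(
                    perceptual_shift=sign * magnitude,
                    decision_criterion_shift=0.0,
                    confidence_center_shift=0.0,
                )
            else:
                # bias toward 'long' means a *lower* criterion
                shifts = dict(
                    perceptual_shift=0.0,
                    decision_criterion_shift=-sign * magnitude,
                    confidence_center_shift=-sign * magnitude * spec.confidence_leak,
                )
            params = replace(
                spec.observer, seed=int(rng.integers(0, 2**31 - 1)), **shifts
            )
            design = build_design(spec.bias_source, direction)
            frames.append(simulate_trials(params, design, subject_id=subject))
    return pd.concat(frames, ignore_index=True)


def write_trials(frame: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated text; missing fields empty."""
    out = frame.reindex(columns=TRIAL_COLUMNS).copy()
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`, re-deriving
    ``correct``.  Raises ``DesignError`` listing any missing columns."""
    frame = pd.read_csv(
        path, dtype={"response": "string", "confidence": "string", "subject_id": "string"}
    )
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise DesignError(f"trial table is missing columns: {missing}")
    frame["response"] = frame["response"].fillna("").astype(object)
    frame["confidence"] = frame["confidence"].fillna("").astype(object)
    frame["correct"] = _derive_correct(frame, REFERENCE_LENGTH)
    return frame
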