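import numpy as np
import pandas as pd
import pytest

from confleak.simulate import (
    ConditionDesign,
    ObserverParams,
    build_design,
    simulate_trials,
)
from dataclasses import replace


@pytest.fixture(scope="session")
def criterion_observer_trials() -> pd.DataFrame:
    """Large-n trials from a criterion-shift observer (c_dec=10, c_conf=5)."""
    params = ObserverParams(
        decision_criterion_shift=10.0, confidence_center_shift=5.0, seed=123
    )
    design = scaled_design("muller_lyer", "long", n_decision_per_length=3000,
                           n_reproduction_per_length=1500)
    return simulate_trials(params, design)


def scaled_design(
    source: str,
    direction: str,
    n_decision_per_length: int,
    n_reproduction_per_length: int = 0,
) -> ConditionDesign:
    """A design with the standard length menu but custom per-length counts
    (for large-n convergence checks)."""
    base = build_design(source, direction)
    return replace(
        base,
        decision_counts={k: n_decision_per_length for k in base.decision_counts},
        reproduction_counts=(
            {k: n_reproduction_per_length for k in base.reproduction_counts}
            if n_reproduction_per_length
            else {}
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def trials_from_counts(n_hit, n_signal, n_fa, n_noise) -> pd.DataFrame:
    """Build a minimal decision trial table realizing the given hit/FA counts
    (signal = 410 px, noise = 390 px)."""
    rows = []
    for _ in range(n_hit):
        rows.append((410, "long"))
    for _ in range(n_signal - n_hit):
        rows.append((410, "short"))
    for _ in range(n_fa):
        rows.append((390, "long"))
    for _ in range(n_noise - n_fa):
        rows.append((390, "short"))
    frame = pd.DataFrame(rows, columns=["target_length", "response"])
    frame["task"] = "decision"
    frame["subject_id"] = "s"
    frame["confidence"] = "low"
    frame["reproduced_length"] = np.nan
    return frame
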