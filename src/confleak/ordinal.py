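"""Encompassing-prior ordinal/equality-constrained Bayes-factor lattices.

Each between-subject group contributes per-subject effect scores (bias-to-
short minus bias-to-long landmark differences, or decision-minus-confidence
effect differences).  Under the encompassing-prior approach the Bayes factor
of an order-constrained model against the unconstrained model is the ratio
of posterior to prior mass satisfying the constraint; for the symmetric
Cauchy prior on the standardized effect the prior mass of a one-sided
constraint is exactly ½, so

    BF(ordinal vs unconstrained) = 2 · P(δ > 0 | data)
    BF(ordinal vs null)          = BF(ordinal vs unconstrained) · BF₁₀

with BF₁₀ the two-sided JZS Bayes factor.  Because the groups are
independent samples, a lattice model's BF over the all-null baseline is the
product over groups of its per-group factors (1 for groups constrained to
null).  Equality constraints are the group-level null.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import DEFAULT_PRIOR_SCALE, delta_posterior_grid, jzs_bf10_twosided, _t_stat

__all__ = [
    "ConstraintModel",
    "ModelComparisonResult",
    "GroupEffectBF",
    "enumerate_models",
    "group_effect_bf",
    "lattice_bf",
    "task_difference_models",
]

POSITIVE, NULL = "positive_effect", "null_effect"
CONF_GT_DEC, DEC_GT_CONF, EQUAL = "conf_gt_dec", "dec_gt_conf", "equal"


@dataclass(frozen=True)
class ConstraintModel:
    """A labeled assignment of one constraint per group."""

    label: str
    constraints: dict[str, str]

    def __hash__(self) -> int:  # dict field: hash on the canonical items
        return hash((self.label, tuple(sorted(self.constraints.items()))))


@dataclass
class ModelComparisonResult:
    bf_over_null: dict[str, float]
    winning_label: str
    bf_best_over_second: float
    models: list[ConstraintModel]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "model": m.label,
                "constraints": "|".join(f"{g}:{c}" for g, c in m.constraints.items()),
                "bf_over_null": self.bf_over_null[m.label],
                "log10_bf": np.log10(self.bf_over_null[m.label]),
            }
            for m in self.models
        ]
        return pd.DataFrame(rows).sort_values("bf_over_null", ascending=False, ignore_index=True)

    def summary(self) -> str:
        tab = self.table()
        lines = ["Ordinal model comparison (BF over the all-null baseline)"]
        lines += [
            f"  {r.model:>6}  BF = {r.bf_over_null:10.4g}  ({r.constraints})"
            for r in tab.itertuples()
        ]
        lines.append(
            f"  winner: {self.winning_label} "
            f"(BF best/second = {self.bf_best_over_second:.4g})"
        )
        return "\n".join(lines)


def _letter_labels(count: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    labels = letters + [a + b for a in letters for b in letters]
    return labels[:count]


def enumerate_models(groups: list[str]) -> list[ConstraintModel]:
    """Full 2^k lattice of positive-vs-null constraint models.

    Models are ordered by descending number of active effects (lexicographic
    by group order within a level); the all-effects model is labeled 'A' and
    the all-null model 'null'.
    """
    if not 1 <= len(groups) <= 5:
        raise ValueError("supported for 1-5 groups")
    subsets = sorted(
        itertools.product([POSITIVE, NULL], repeat=len(groups)),
        key=lambda pattern: (
            sum(c == NULL for c in pattern),
            tuple(c == NULL for c in pattern),
        ),
    )
    labels = _letter_labels(len(subsets) - 1) + ["null"]
    return [
        ConstraintModel(label, dict(zip(groups, pattern)))
        for label, pattern in zip(labels, subsets)
    ]


@dataclass(frozen=True)
class GroupEffectBF:
    bf_positive_vs_null: float
    posterior_positive_mass: float
    prior_positive_mass: float
    bf10_unconstrained: float


def group_effect_bf(effects, r: float = DEFAULT_PRIOR_SCALE) -> GroupEffectBF:
    """Encompassing-prior BF for 'this group has a positive effect' vs null."""
    t, n, _ = _t_stat(np.asarray(effects, dtype=float))
    bf10 = jzs_bf10_twosided(t, n, r)
    grid, dens = delta_posterior_grid(t, n, r)
    pos_mass = float(np.trapezoid(dens[grid >= 0], grid[grid >= 0]))
    return GroupEffectBF(
        bf_positive_vs_null=2.0 * pos_mass * bf10,
        posterior_positive_mass=pos_mass,
        prior_positive_mass=0.5,
        bf10_unconstrained=bf10,
    )


def lattice_bf(
    effects_by_group: dict[str, np.ndarray],
    models: list[ConstraintModel] | None = None,
    r: float = DEFAULT_PRIOR_SCALE,
) -> ModelComparisonResult:
    """Score every lattice model against the all-null baseline.

    Group independence makes each model's BF the product of per-group
    factors: the encompassing-prior positive-effect BF where the model says
    the group has an effect, and 1 where it says null.
    """
    groups = list(effects_by_group)
    if models is None:
        models = enumerate_models(groups)
    per_group = {g: group_effect_bf(effects_by_group[g], r=r) for g in groups}
    bfs: dict[str, float] = {}
    for model in models:
        missing = [g for g in groups if g not in model.constraints]
        unknown = [g for g in model.constraints if g not in per_group]
        if missing or unknown:
            raise ValueError(
                f"model {model.label}: constraint/effect group mismatch "
                f"(missing {missing}, unknown {unknown})"
            )
        bf = 1.0
        for g, constraint in model.constraints.items():
            if constraint == POSITIVE:
                bf *= per_group[g].bf_positive_vs_null
            elif constraint != NULL:
                raise ValueError(f"unknown constraint {constraint!r}")
        bfs[model.label] = bf
    return _rank(bfs, models)


def _rank(bfs: dict[str, float], models: list[ConstraintModel]) -> ModelComparisonResult:
    ranked = sorted(bfs.items(), key=lambda kv: kv[1], reverse=True)
    best, second = ranked[0], ranked[1] if len(ranked) > 1 else (None, np.nan)
    return ModelComparisonResult(
        bf_over_null=bfs,
        winning_label=best[0],
        bf_best_over_second=best[1] / second[1] if len(ranked) > 1 else np.inf,
        models=models,
    )


def task_difference_models(
    decision_effects: dict[str, np.ndarray],
    confidence_effects: dict[str, np.ndarray],
    r: float = DEFAULT_PRIOR_SCALE,
) -> ModelComparisonResult:
    """Compare all sign-pattern models of the decision-vs-confidence gap.

    Per subject Δ = decision effect − confidence effect; per group the
    constraint 'dec_gt_conf' means Δ > 0, 'conf_gt_dec' means Δ < 0 and
    'equal' is the null Δ ≡ 0.  All 3^k patterns are scored by the product
    rule; models are labeled by their explicit pattern.
    """
    groups = list(decision_effects)
    if set(groups) != set(confidence_effects):
        raise ValueError("decision and confidence effects must cover the same groups")
    stats_by_group = {}
    for g in groups:
        dec = np.asarray(decision_effects[g], dtype=float)
        conf = np.asarray(confidence_effects[g], dtype=float)
        if dec.shape != conf.shape:
            raise ValueError(f"unpaired effects for group {g!r}")
        delta = dec - conf
        t, n, _ = _t_stat(delta)
        bf10 = jzs_bf10_twosided(t, n, r)
        grid, dens = delta_posterior_grid(t, n, r)
        pos = float(np.trapezoid(dens[grid >= 0], grid[grid >= 0]))
        stats_by_group[g] = {
            DEC_GT_CONF: 2.0 * pos * bf10,
            CONF_GT_DEC: 2.0 * (1.0 - pos) * bf10,
            EQUAL: 1.0,
        }
    models = []
    bfs = {}
    for pattern in itertools.product([DEC_GT_CONF, CONF_GT_DEC, EQUAL], repeat=len(groups)):
        label = "|".join(
            f"{g}:{ {DEC_GT_CONF: 'dec>conf', CONF_GT_DEC: 'conf>dec', EQUAL: 'equal'}[c] }"
            for g, c in zip(groups, pattern)
        )
        models.append(ConstraintModel(label, dict(zip(groups, pattern))))
        bf = 1.0
        for g, constraint in zip(groups, pattern):
            bf *= stats_by_group[g][constraint]
        bfs[label] = bf
    return _rank(bfs, models)
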