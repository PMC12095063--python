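"""End-to-end orchestration: simulate/ingest → screen → fit → test → compare.

`run_full` reproduces the study's analysis chain on a trial table (simulated
by default): participant screening, per-subject psychometric landmarks,
one-sided JZS t-tests of the bias effect per bias source and task, the
ordinal model lattice per task, the decision-vs-confidence sign-pattern
comparison, and the metacognitive-efficiency stage (per-subject meta-d′,
group posterior, Savage–Dickey condition comparison).  All randomness flows
from the config seed, so a re-run under the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, metad, ordinal, psychometric, sdt
from .simulate import BIAS_SOURCES, CohortSpec, read_trials, simulate_cohort

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "default_cohort",
    "landmark_effects",
    "run_full",
    "sequential_stopping_sim",
]

log = logging.getLogger("confleak")

TASKS = ("decision", "confidence", "reproduction")


@dataclass
class AnalysisConfig:
    """Configuration for a full pipeline run."""

    input_path: str | None = None  # None -> simulate the default cohort
    prior_scale: float = bayes.DEFAULT_PRIOR_SCALE
    alpha: float = 0.05
    seed: int = 0
    n_subjects: int = 35
    output_dir: str | None = None
    hdi: bool = False
    mratio_scale: str = "log"
    run_metacognition: bool = True
    mcmc_iterations: int = 20000

    def __post_init__(self) -> None:
        if not self.prior_scale > 0:
            raise ValueError("prior_scale must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    """All pipeline output tables, keyed the way the study reports them."""

    measures: pd.DataFrame
    exclusions: pd.DataFrame
    fits: pd.DataFrame
    effects: pd.DataFrame
    bf_tests: pd.DataFrame
    lattice: dict[str, ordinal.ModelComparisonResult]
    task_difference: ordinal.ModelComparisonResult
    mratio: pd.DataFrame | None = None
    mratio_bf: pd.DataFrame | None = None

    def winners(self) -> dict[str, str]:
        return {task: res.winning_label for task, res in self.lattice.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measures.to_csv(outdir / "subject_measures.csv", index=False)
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        self.fits.to_csv(outdir / "psychometric_fits.csv", index=False)
        self.effects.to_csv(outdir / "landmark_effects.csv", index=False)
        self.bf_tests.to_csv(outdir / "bf_tests.csv", index=False)
        for task, res in self.lattice.items():
            res.table().to_csv(outdir / f"lattice_{task}.csv", index=False)
        self.task_difference.table().to_csv(outdir / "task_difference_models.csv", index=False)
        if self.mratio is not None:
            self.mratio.to_csv(outdir / "mratio.csv", index=False)
        if self.mratio_bf is not None:
            self.mratio_bf.to_csv(outdir / "mratio_bf.csv", index=False)


def default_cohort(seed: int, n_subjects: int = 35) -> pd.DataFrame:
    """The default synthetic cohort: a perceptual-shift Müller–Lyer group and
    criterion-shift base-rate/payoff groups with a 0.5 confidence leak."""
    frames = []
    for i, source in enumerate(BIAS_SOURCES):
        spec = CohortSpec(bias_source=source, n_subjects=n_subjects)
        frames.append(simulate_cohort(spec, seed=(seed * 7919 + i) % 2**31))
    return pd.concat(frames, ignore_index=True)


def landmark_effects(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-subject signed landmark effects (short-minus-long) per task.

    Subjects lacking a quality-passing fit in either direction for a task
    are dropped from that task's effect column.
    """
    fits = psychometric.fit_table(trials, alpha=alpha)
    rows = []
    for (subject, source), chunk in fits.groupby(["subject_id", "bias_source"]):
        for task in TASKS:
            pair = chunk[chunk["task"] == task]
            by_dir = {r.bias_direction: r for r in pair.itertuples()}
            if set(by_dir) != {"long", "short"}:
                continue
            if not (by_dir["long"].quality_pass and by_dir["short"].quality_pass):
                continue
            rows.append(
                {
                    "subject_id": subject,
                    "bias_source": source,
                    "task": task,
                    "effect_px": by_dir["short"].landmark - by_dir["long"].landmark,
                }
            )
    return pd.DataFrame(rows)


def _effects_by_group(effects: pd.DataFrame, task: str) -> dict[str, np.ndarray]:
    sub = effects[effects["task"] == task]
    groups = {
        source: chunk["effect_px"].to_numpy()
        for source, chunk in sub.groupby("bias_source")
    }
    # canonical study order (muller_lyer, base_rate, payoff), extras last
    ordered = [s for s in BIAS_SOURCES if s in groups]
    ordered += [s for s in groups if s not in BIAS_SOURCES]
    return {s: groups[s] for s in ordered}


def _paired_effects(
    effects: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Decision and confidence effects restricted to subjects with both."""
    wide = effects.pivot_table(
        index=["bias_source", "subject_id"], columns="task", values="effect_px"
    ).dropna(subset=["decision", "confidence"])
    dec, conf = {}, {}
    present = set(wide.index.get_level_values("bias_source"))
    order = [s for s in BIAS_SOURCES if s in present]
    order += sorted(present - set(BIAS_SOURCES))
    for source in order:
        chunk = wide.xs(source, level="bias_source")
        dec[source] = chunk["decision"].to_numpy()
        conf[source] = chunk["confidence"].to_numpy()
    return dec, conf


def run_full(config: AnalysisConfig) -> ReportBundle:
    """Run the complete analysis chain and return all report tables."""
    if config.input_path is not None:
        trials = read_trials(config.input_path)
        if trials.empty:
            raise ValueError("input trial table is empty")
    else:
        trials = default_cohort(config.seed, config.n_subjects)
    log.info("loaded %d trials from %d subjects", len(trials), trials["subject_id"].nunique())

    measures = sdt.subject_measures(trials)
    kept, exclusions = sdt.screen_participants(measures)
    log.info("screening kept %d/%d subjects", len(kept), len(measures))
    trials = trials[trials["subject_id"].isin(kept)]

    fits = psychometric.fit_table(trials, alpha=config.alpha)
    effects = landmark_effects(trials, alpha=config.alpha)

    bf_rows = []
    for (source, task), chunk in effects.groupby(["bias_source", "task"]):
        res = bayes.jzs_bf_paired(
            chunk["effect_px"].to_numpy(),
            r=config.prior_scale,
            sided="one_positive",
            seed=config.seed,
            hdi=config.hdi,
        )
        bf_rows.append(
            {
                "bias_source": source,
                "task": task,
                "n": res.n,
                "bf10": res.bf10,
                "cohens_d": res.cohens_d,
                "cri_low": res.cri_low,
                "cri_high": res.cri_high,
            }
        )
    bf_tests = pd.DataFrame(bf_rows)

    lattice = {
        task: ordinal.lattice_bf(_effects_by_group(effects, task), r=config.prior_scale)
        for task in TASKS
    }
    task_diff = ordinal.task_difference_models(
        *_paired_effects(effects), r=config.prior_scale
    )

    mratio_table = mratio_bf_table = None
    if config.run_metacognition:
        mratio_table, mratio_bf_table = _metacognition_stage(trials, config)

    bundle = ReportBundle(
        measures=measures,
        exclusions=exclusions,
        fits=fits,
        effects=effects,
        bf_tests=bf_tests,
        lattice=lattice,
        task_difference=task_diff,
        mratio=mratio_table,
        mratio_bf=mratio_bf_table,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def _metacognition_stage(
    trials: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    posteriors: dict[tuple[str, str], metad.GroupMRatioPosterior] = {}
    for (source, direction), chunk in trials.groupby(["bias_source", "bias_direction"]):
        results = []
        for subject, sub in chunk.groupby("subject_id"):
            try:
                res = metad.fit_meta_d(metad.tabulate_type2(sub))
            except metad.MetaDataError:
                continue
            results.append(res)
            rows.append(
                {
                    "bias_source": source,
                    "bias_direction": direction,
                    "subject_id": subject,
                    "d_prime": res.d_prime,
                    "meta_d": res.meta_d,
                    "m_ratio": res.m_ratio,
                    "log_m_ratio": res.log_m_ratio,
                }
            )
        posteriors[(source, direction)] = metad.group_mratio_posterior(
            results, seed=config.seed, n_iter=config.mcmc_iterations
        )
    bf_rows = []
    for source in sorted({s for s, _ in posteriors}):
        sd_res = metad.mratio_difference_bf(
            posteriors[(source, "long")],
            posteriors[(source, "short")],
            prior_scale=config.prior_scale,
            scale=config.mratio_scale,
            seed=config.seed,
        )
        post_long = posteriors[(source, "long")]
        post_short = posteriors[(source, "short")]
        bf_rows.append(
            {
                "bias_source": source,
                "bf10": sd_res.bf10,
                "mean_mratio_long": float(post_long.mean_mratio_draws.mean()),
                "mean_mratio_short": float(post_short.mean_mratio_draws.mean()),
                "rhat_long": post_long.rhat,
                "rhat_short": post_short.rhat,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(bf_rows)


def sequential_stopping_sim(
    effect_d: float,
    start_n: int = 30,
    step: int = 5,
    lower: float = 0.3,
    upper: float = 3.0,
    max_n: int = 100,
    replicates: int = 200,
    seed: int = 0,
    r: float = bayes.DEFAULT_PRIOR_SCALE,
) -> pd.DataFrame:
    """Simulate the optional-stopping recruitment rule.

    Per replicate, subjects' paired difference scores are drawn from
    N(``effect_d``, 1); after the first ``start_n`` subjects (and every
    ``step`` further subjects) a one-sided JZS Bayes factor is computed and
    collection stops at BF₁₀ > ``upper`` (decision 'effect') or BF₁₀ <
    ``lower`` (decision 'null'); otherwise recruitment continues to
    ``max_n``, recorded as 'inconclusive'.
    """
    if not 0 <= lower < 1 < upper:
        raise ValueError("thresholds must satisfy 0 <= lower < 1 < upper")
    if max_n <= 0:
        raise ValueError("max_n must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(replicates):
        data = rng.normal(effect_d, 1.0, max_n)
        n = start_n
        decision = "inconclusive"
        bf = np.nan
        while n <= max_n:
            t = data[:n].mean() / (data[:n].std(ddof=1) / np.sqrt(n))
            bf2 = bayes.jzs_bf10_twosided(float(t), n, r)
            grid, dens = bayes.delta_posterior_grid(float(t), n, r)
            pos = float(np.trapezoid(dens[grid >= 0], grid[grid >= 0]))
            bf = bf2 * 2.0 * pos
            if bf > upper:
                decision = "effect"
                break
            if bf < lower:
                decision = "null"
                break
            n += step
        records.append(
            {"replicate": rep, "final_n": min(n, max_n), "decision": decision, "bf10": bf}
        )
    return pd.DataFrame(records)
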