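"""Meta-d′ and M-ratio: metacognitive efficiency for binary confidence.

Meta-d′ is the type-1 sensitivity a metacognitively ideal observer would
need to produce the observed confidence–accuracy coupling.  The fit follows
the standard maximum-likelihood recipe: hold the type-1 response pattern
fixed through the *relative* criterion c′ = c/d′, place the meta-level
stimulus distributions at ±meta-d′/2, and maximize the type-2 likelihood of
the confidence counts over meta-d′ and one type-2 criterion per response
side (constrained to the correct sides of the type-1 criterion).  M-ratio =
meta-d′/d′ equals 1 for an ideal observer and falls below 1 as
metacognitive noise grows.

The group stage is a deliberately simple Bayesian model — a Normal
likelihood on per-subject log M-ratio with vague priors, sampled by
random-walk Metropolis (4 chains × 20,000 iterations, thinning 2,
convergence requires split-R̂ < 1.02 on the group mean) — in place of a
full hierarchical type-2 SDT model.  Condition comparisons feed posterior
draws of the standardized group difference to the Savage–Dickey ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bayes import DEFAULT_PRIOR_SCALE, SavageDickeyResult, savage_dickey
from .simulate import REFERENCE_LENGTH

__all__ = [
    "Type2Counts",
    "MetaDResult",
    "MetaDModel",
    "GroupMRatioPosterior",
    "tabulate_type2",
    "fit_meta_d",
    "group_mratio_posterior",
    "mratio_difference_bf",
]

_STIM = {"short": 0, "long": 1}
_RESP = {"short": 0, "long": 1}
_CONF = {"low": 0, "high": 1}


class MetaDataError(ValueError):
    """Trial set or count table cannot support a meta-d' fit."""


@dataclass(frozen=True)
class Type2Counts:
    """Confidence counts indexed [stimulus, response, confidence] with
    levels (short, long) × (short, long) × (low, high)."""

    counts: np.ndarray  # shape (2, 2, 2)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2, 2) or np.any(arr < 0):
            raise MetaDataError("counts must be a non-negative 2x2x2 array")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


def tabulate_type2(trials: pd.DataFrame, reference: float = REFERENCE_LENGTH) -> Type2Counts:
    """Tally the 2×2×2 stimulus × response × confidence table.

    Reference-length targets belong to neither stimulus class and are
    dropped, as are non-decision trials.
    """
    dec = trials[
        (trials["task"] == "decision")
        & (trials["target_length"] != reference)
        & (trials["confidence"].isin(["low", "high"]))
    ]
    if dec.empty:
        raise MetaDataError("no decision trials with confidence")
    counts = np.zeros((2, 2, 2), dtype=int)
    stim = (dec["target_length"] > reference).astype(int).to_numpy()
    resp = (dec["response"] == "long").astype(int).to_numpy()
    conf = (dec["confidence"] == "high").astype(int).to_numpy()
    np.add.at(counts, (stim, resp, conf), 1)
    return Type2Counts(counts)


@dataclass
class MetaDResult:
    d_prime: float
    type1_criterion: float
    meta_d: float
    m_ratio: float
    log_m_ratio: float
    type2_criteria: tuple[float, float]  # (short-response side, long-response side)
    fit_log_likelihood: float
    converged: bool = True

    def summary(self) -> str:
        return "\n".join(
            [
                "Meta-d' fit",
                f"  d'            {self.d_prime:.3f}",
                f"  criterion     {self.type1_criterion:.3f}",
                f"  meta-d'       {self.meta_d:.3f}",
                f"  M-ratio       {self.m_ratio:.3f}",
                f"  log M-ratio   {self.log_m_ratio:.3f}",
                f"  type-2 c      ({self.type2_criteria[0]:.3f}, {self.type2_criteria[1]:.3f})",
                f"  logL          {self.fit_log_likelihood:.4f}",
                f"  converged     {self.converged}",
            ]
        )


def _type1_from_counts(counts: np.ndarray) -> tuple[float, float]:
    """Conventional d' and criterion *location* (respond 'long' iff x >= c1,
    stimulus means at ±d'/2) from the collapsed type-1 table."""
    n_long_stim = counts[1].sum()
    n_short_stim = counts[0].sum()
    hr = counts[1, 1].sum() / n_long_stim
    far = counts[0, 1].sum() / n_short_stim
    z_hr, z_far = stats.norm.ppf(hr), stats.norm.ppf(far)
    d = z_hr - z_far
    c1 = -0.5 * (z_hr + z_far)
    return float(d), float(c1)


def type2_negloglik(
    params: np.ndarray, counts: np.ndarray, c_rel: float
) -> float:
    """Negative type-2 log-likelihood of confidence counts.

    ``params`` = (meta_d, offset_short, offset_long) with non-negative
    offsets placing the type-2 criteria at c1_meta ∓ offset.
    """
    meta_d, off_s, off_l = params
    c1 = c_rel * meta_d
    c2s, c2l = c1 - off_s, c1 + off_l
    nll = 0.0
    for s, mu in ((0, -meta_d / 2.0), (1, meta_d / 2.0)):
        p_short = stats.norm.cdf(c1 - mu)
        p_long = 1.0 - p_short
        # 'short' response side: high confidence iff x <= c2s
        p_high_short = stats.norm.cdf(c2s - mu)
        # 'long' response side: high confidence iff x >= c2l
        p_high_long = 1.0 - stats.norm.cdf(c2l - mu)
        probs = {
            (0, 1): p_high_short / p_short if p_short > 0 else 0.0,
            (1, 1): p_high_long / p_long if p_long > 0 else 0.0,
        }
        for resp in (0, 1):
            p_high = min(max(probs[(resp, 1)], 1e-12), 1 - 1e-12)
            nll -= counts[s, resp, 1] * np.log(p_high)
            nll -= counts[s, resp, 0] * np.log(1.0 - p_high)
    return float(nll)


class MetaDModel:
    """Maximum-likelihood meta-d' model for one 2×2×2 count table."""

    def __init__(self, counts: Type2Counts, edge_correction: bool = True):
        arr = np.asarray(counts.counts, dtype=float)
        if edge_correction and np.any(arr == 0):
            arr = arr + 0.5  # pad every cell when any is empty
        if arr[0].sum() == 0 or arr[1].sum() == 0:
            raise MetaDataError("both stimulus classes must be represented")
        if arr[:, 0].sum() == 0 or arr[:, 1].sum() == 0:
            raise MetaDataError("both responses must be represented")
        self.counts = arr

    def fit(self) -> MetaDResult:
        d_prime, c1 = _type1_from_counts(self.counts)
        c_rel = c1 / d_prime if d_prime != 0 else 0.0
        best = None
        for start in ([d_prime, 0.5, 0.5], [max(d_prime, 0.5), 1.0, 1.0], [0.5, 0.2, 0.2]):
            res = optimize.minimize(
                type2_negloglik,
                x0=np.asarray(start, dtype=float),
                args=(self.counts, c_rel),
                method="L-BFGS-B",
                bounds=[(-5.0, 10.0), (0.0, 10.0), (0.0, 10.0)],
            )
            if best is None or res.fun < best.fun:
                best = res
        meta_d, off_s, off_l = best.x
        c1_meta = c_rel * meta_d
        m_ratio = meta_d / d_prime if d_prime != 0 else np.nan
        return MetaDResult(
            d_prime=d_prime,
            type1_criterion=c1,
            meta_d=float(meta_d),
            m_ratio=float(m_ratio),
            log_m_ratio=float(np.log(m_ratio)) if m_ratio > 0 else np.nan,
            type2_criteria=(float(c1_meta - off_s), float(c1_meta + off_l)),
            fit_log_likelihood=float(-best.fun),
            converged=bool(best.success),
        )


def fit_meta_d(counts: Type2Counts, edge_correction: bool = True) -> MetaDResult:
    return MetaDModel(counts, edge_correction=edge_correction).fit()


@dataclass
class GroupMRatioPosterior:
    """Posterior draws for the group mean of log M-ratio."""

    mu_draws: np.ndarray = field(repr=False)
    sigma_draws: np.ndarray = field(repr=False)
    rhat: float = np.nan
    converged: bool = False
    n_subjects: int = 0
    n_excluded: int = 0
    subject_log_mratios: np.ndarray = field(default=None, repr=False)

    @property
    def mean_mratio_draws(self) -> np.ndarray:
        """Draws of the group mean M-ratio (exponentiated location)."""
        return np.exp(self.mu_draws)

    def summary(self) -> str:
        return "\n".join(
            [
                "Group M-ratio posterior (Normal model on log M-ratio)",
                f"  subjects (used/excluded)  {self.n_subjects}/{self.n_excluded}",
                f"  mean log M-ratio          {self.mu_draws.mean():.4f}",
                f"  mean M-ratio              {self.mean_mratio_draws.mean():.4f}",
                f"  split-Rhat (mu)           {self.rhat:.4f}  converged={self.converged}",
            ]
        )


def _split_rhat(chains: np.ndarray) -> float:
    """Potential-scale-reduction statistic on split chains (m × n array)."""
    half = chains.shape[1] // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def group_mratio_posterior(
    results: list[MetaDResult] | np.ndarray,
    seed: int = 0,
    n_iter: int = 20000,
    n_chains: int = 4,
    thin: int = 2,
    rhat_threshold: float = 1.02,
) -> GroupMRatioPosterior:
    """Posterior of the group mean log M-ratio by random-walk Metropolis.

    ``results`` may be per-subject :class:`MetaDResult` objects or raw log
    M-ratio values.  Subjects with undefined log M-ratio (M-ratio <= 0) are
    excluded.  Priors: mu ~ N(0, 5²), sigma ~ half-Normal(5).  The first
    half of each chain is discarded as warm-up before thinning.
    """
    if len(results) and isinstance(results[0], MetaDResult):
        values = np.array([r.log_m_ratio for r in results], dtype=float)
    else:
        values = np.asarray(results, dtype=float)
    mask = np.isfinite(values)
    n_excluded = int((~mask).sum())
    y = values[mask]
    if len(y) < 5:
        raise MetaDataError("need >= 5 subjects with defined log M-ratio")

    n, y_sum, y_sq = len(y), y.sum(), (y**2).sum()

    def logpost(mu: np.ndarray, log_sigma: np.ndarray) -> np.ndarray:
        sigma = np.exp(log_sigma)
        ss = y_sq - 2 * mu * y_sum + n * mu**2
        loglik = -n * log_sigma - ss / (2 * sigma**2)
        logprior = -(mu**2) / (2 * 5.0**2) - (sigma**2) / (2 * 5.0**2) + log_sigma
        return loglik + logprior

    rng = np.random.default_rng(seed)
    mu = rng.normal(y.mean(), 0.1, n_chains)
    log_sigma = np.log(np.full(n_chains, max(y.std(ddof=1), 0.05)))
    log_sigma += rng.normal(0.0, 0.1, n_chains)
    lp = logpost(mu, log_sigma)
    step_mu = 2.0 * y.std(ddof=1) / np.sqrt(n) if y.std(ddof=1) > 0 else 0.05
    step_ls = 0.3
    keep_mu = np.empty((n_chains, n_iter // 2 // thin))
    keep_ls = np.empty_like(keep_mu)
    k = 0
    for i in range(n_iter):
        prop_mu = mu + rng.normal(0.0, step_mu, n_chains)
        prop_ls = log_sigma + rng.normal(0.0, step_ls, n_chains)
        prop_lp = logpost(prop_mu, prop_ls)
        accept = np.log(rng.random(n_chains)) < prop_lp - lp
        mu = np.where(accept, prop_mu, mu)
        log_sigma = np.where(accept, prop_ls, log_sigma)
        lp = np.where(accept, prop_lp, lp)
        if i >= n_iter // 2 and (i - n_iter // 2) % thin == 0 and k < keep_mu.shape[1]:
            keep_mu[:, k] = mu
            keep_ls[:, k] = log_sigma
            k += 1
    keep_mu, keep_ls = keep_mu[:, :k], keep_ls[:, :k]
    rhat = _split_rhat(keep_mu)
    return GroupMRatioPosterior(
        mu_draws=keep_mu.reshape(-1),
        sigma_draws=np.exp(keep_ls.reshape(-1)),
        rhat=rhat,
        converged=bool(rhat < rhat_threshold),
        n_subjects=n,
        n_excluded=n_excluded,
        subject_log_mratios=y,
    )


def mratio_difference_bf(
    posterior_long: GroupMRatioPosterior,
    posterior_short: GroupMRatioPosterior,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    scale: str = "log",
    seed: int = 0,
) -> SavageDickeyResult:
    """Savage–Dickey BF for the bias-to-long vs bias-to-short M-ratio gap.

    Posterior draws of the standardized difference (Cohen's d: difference of
    group means over the pooled subject-level SD) are formed by pairing
    resampled draws from the two condition posteriors; the density of that
    effect-size posterior at zero is compared with a Cauchy prior.
    ``scale='raw'`` works on M-ratio instead of log M-ratio.
    """
    rng = np.random.default_rng(seed)
    n = min(len(posterior_long.mu_draws), len(posterior_short.mu_draws))
    idx_l = rng.integers(0, len(posterior_long.mu_draws), n)
    idx_s = rng.integers(0, len(posterior_short.mu_draws), n)
    if scale == "log":
        draws_l = posterior_long.mu_draws[idx_l]
        draws_s = posterior_short.mu_draws[idx_s]
        subj = np.concatenate(
            [posterior_long.subject_log_mratios, posterior_short.subject_log_mratios]
        )
    elif scale == "raw":
        draws_l = posterior_long.mean_mratio_draws[idx_l]
        draws_s = posterior_short.mean_mratio_draws[idx_s]
        subj = np.exp(
            np.concatenate(
                [posterior_long.subject_log_mratios, posterior_short.subject_log_mratios]
            )
        )
    else:
        raise ValueError(f"unknown scale {scale!r}")
    pooled_sd = subj.std(ddof=1)
    if pooled_sd == 0:
        raise MetaDataError("pooled subject-level SD is zero")
    effect_draws = (draws_l - draws_s) / pooled_sd
    return savage_dickey(effect_draws, prior_scale=prior_scale, theta_label="m_ratio_difference")
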