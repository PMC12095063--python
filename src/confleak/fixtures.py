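"""Deterministic test fixtures and independent numerical oracles.

The oracles deliberately avoid the main code paths they validate:

* :func:`inverse_normal_oracle` — Acklam's rational approximation of the
  standard normal quantile function (no scipy);
* :func:`jzs_quadrature_oracle` — the JZS Bayes factor through the g-prior
  (inverse-gamma mixture) representation rather than the Cauchy-on-δ
  marginal used by :mod:`confleak.bayes`;
* :func:`metad_grid_oracle` — an exhaustive grid search over meta-d′ and
  the two type-2 criteria (the likelihood separates by response side, so
  each criterion is optimized on its own vectorized 1-D grid).

:func:`make_fixture` returns small reproducible inputs together with an
expectation map; derived expectations are recomputed by the bundled oracle
at call time, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import integrate

from .simulate import ObserverParams

__all__ = [
    "inverse_normal_oracle",
    "normal_cdf_oracle",
    "jzs_quadrature_oracle",
    "metad_grid_oracle",
    "make_fixture",
    "CANONICAL_OBSERVERS",
]

# Müller–Lyer-like: pure perceptual shift.  Base-rate/payoff-like: pure
# criterion shift with a partial confidence leak.  The metacognition pair
# differs only in meta-level noise.
CANONICAL_OBSERVERS: dict[str, ObserverParams] = {
    "muller_lyer_like": ObserverParams(perceptual_shift=10.0),
    "base_rate_like": ObserverParams(
        decision_criterion_shift=10.0, confidence_center_shift=5.0
    ),
    "payoff_like": ObserverParams(
        decision_criterion_shift=10.0, confidence_center_shift=5.0
    ),
    "ideal_metacognition": ObserverParams(metacognitive_noise_sd=0.0),
    "noisy_metacognition": ObserverParams(metacognitive_noise_sd=8.0),
}


# --- inverse-normal oracle (Acklam 2003 rational approximation) -------------

_A = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
      1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
_B = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
      6.680131188771972e+01, -1.328068155288572e+01)
_C = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
      -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
_D = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
      3.754408661907416e+00)


def inverse_normal_oracle(p: float) -> float:
    """Standard normal quantile via Acklam's rational approximation, refined
    by one Halley step (relative error well below 1e-9)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    p_low, p_high = 0.02425, 1 - 0.02425
    if p < p_low:
        q = math.sqrt(-2 * math.log(p))
        x = (((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / \
            ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1)
    elif p <= p_high:
        q = p - 0.5
        s = q * q
        x = (((((_A[0] * s + _A[1]) * s + _A[2]) * s + _A[3]) * s + _A[4]) * s + _A[5]) * q / \
            (((((_B[0] * s + _B[1]) * s + _B[2]) * s + _B[3]) * s + _B[4]) * s + 1)
    else:
        q = math.sqrt(-2 * math.log(1 - p))
        x = -(((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / \
            ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1)
    # one Halley refinement step
    e = 0.5 * math.erfc(-x / math.sqrt(2)) - p
    u = e * math.sqrt(2 * math.pi) * math.exp(x * x / 2)
    return x - u / (1 + x * u / 2)


def normal_cdf_oracle(x: np.ndarray) -> np.ndarray:
    """Standard normal CDF through the error function (used by the grid
    oracle so it shares nothing with scipy.stats.norm)."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (1.0 + np.vectorize(math.erf)(x / math.sqrt(2.0)))


# --- JZS quadrature oracle (g-prior representation) --------------------------

def jzs_quadrature_oracle(t: float, n: int, r: float = 0.707) -> float:
    """Two-sided JZS BF₁₀ via the inverse-gamma mixture over g.

    BF₁₀ = ∫₀^∞ (1+ng)^{-1/2} (1 + t²/((1+ng)ν))^{-(ν+1)/2} π(g) dg
           / (1 + t²/ν)^{-(ν+1)/2},
    with π(g) = InvGamma(1/2, r²/2): a mathematically equivalent but
    computationally distinct route to the Cauchy-on-δ marginal.
    """
    nu = n - 1

    def integrand(g: float) -> float:
        shrink = 1.0 + n * g
        like = shrink ** -0.5 * (1.0 + t * t / (shrink * nu)) ** (-(nu + 1) / 2.0)
        prior = (
            (r * r / 2.0) ** 0.5 / math.gamma(0.5) * g ** -1.5 * math.exp(-r * r / (2.0 * g))
        )
        return like * prior

    numerator, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-13, epsrel=1e-11, limit=400
    )
    denominator = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return float(numerator / denominator)


# --- meta-d' grid oracle ------------------------------------------------------

def metad_grid_oracle(
    counts: np.ndarray,
    meta_d_range: tuple[float, float] = (-5.0, 6.0),
    offset_max: float = 5.0,
    step: float = 0.01,
    refine: bool = True,
) -> tuple[float, float]:
    """Exhaustive grid search for the meta-d′ fit.

    Returns ``(best_log_likelihood, best_meta_d)`` maximizing the type-2
    likelihood over a ``step``-resolution grid of meta-d′ and both type-2
    criterion offsets.  The likelihood factorizes over response sides, so
    for each candidate meta-d′ the two offsets are optimized independently
    on vectorized 1-D grids.  With ``refine=True`` a second pass re-grids a
    ±``step`` neighborhood of the coarse optimum at step/20 resolution, so
    the comparison against an optimizer reflects fit quality rather than
    grid granularity.
    """
    ll, md = _metad_grid_pass(counts, meta_d_range, offset_max, step)
    if refine:
        fine = step / 20.0
        ll2, md2 = _metad_grid_pass(
            counts, (md - step, md + step), offset_max, fine
        )
        if ll2 > ll:
            ll, md = ll2, md2
    return ll, md


def _metad_grid_pass(
    counts: np.ndarray,
    meta_d_range: tuple[float, float],
    offset_max: float,
    step: float,
) -> tuple[float, float]:
    counts = np.asarray(counts, dtype=float)
    hr = counts[1, 1].sum() / counts[1].sum()
    far = counts[0, 1].sum() / counts[0].sum()
    z_hr, z_far = inverse_normal_oracle(hr), inverse_normal_oracle(far)
    d_prime = z_hr - z_far
    c_rel = (-0.5 * (z_hr + z_far)) / d_prime

    meta_grid = np.arange(meta_d_range[0], meta_d_range[1] + step / 2, step)
    offsets = np.arange(0.0, offset_max + step / 2, step)
    eps = 1e-12

    c1 = c_rel * meta_grid  # (M,)
    # response-side log-likelihood as a function of (meta_d, offset)
    mus = np.stack([-meta_grid / 2.0, meta_grid / 2.0])  # (2, M)
    p_short = normal_cdf_oracle(c1[None, :] - mus)  # (2, M)
    p_long = 1.0 - p_short
    ll_total = np.zeros_like(meta_grid)
    for side in ("short", "long"):
        ll_side = np.full((len(meta_grid), len(offsets)), 0.0)
        for s in (0, 1):
            if side == "short":
                c2 = c1[:, None] - offsets[None, :]  # (M, K)
                p_joint = normal_cdf_oracle(c2 - mus[s][:, None])
                p_resp = p_short[s][:, None]
                n_high, n_low = counts[s, 0, 1], counts[s, 0, 0]
            else:
                c2 = c1[:, None] + offsets[None, :]
                p_joint = 1.0 - normal_cdf_oracle(c2 - mus[s][:, None])
                p_resp = p_long[s][:, None]
                n_high, n_low = counts[s, 1, 1], counts[s, 1, 0]
            p_high = np.clip(p_joint / np.clip(p_resp, eps, None), eps, 1 - eps)
            ll_side += n_high * np.log(p_high) + n_low * np.log(1.0 - p_high)
        ll_total += ll_side.max(axis=1)
    idx = int(np.argmax(ll_total))
    best_ll, best_md = float(ll_total[idx]), float(meta_grid[idx])
    return best_ll, best_md


# --- named fixtures -----------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    name: str
    data: Any
    expected: dict[str, Any]


def _micro_trials() -> pd.DataFrame:
    """16 hand-written decision trials (hand-tallied in the expected map)."""
    rows = []
    spec = [
        # (target, response, confidence, repeats)
        (430, "long", "high", 3),
        (430, "short", "low", 1),
        (370, "short", "high", 3),
        (370, "long", "low", 1),
        (410, "long", "low", 2),
        (390, "short", "low", 2),
        (400, "long", "low", 2),
        (400, "short", "high", 2),
    ]
    for target, resp, conf, k in spec:
        for _ in range(k):
            rows.append(
                {
                    "subject_id": "micro",
                    "bias_source": "muller_lyer",
                    "bias_direction": "long",
                    "task": "decision",
                    "target_length": target,
                    "response": resp,
                    "confidence": conf,
                    "reproduced_length": np.nan,
                }
            )
    return pd.DataFrame(rows)


def make_fixture(name: str) -> Fixture:
    """Return a named fixture: reproducible input data plus expectations.

    Expected values tagged ``derived`` are recomputed by the bundled oracle
    on request; counts are exact; the rest are closed forms.
    """
    if name == "design_counts":
        return Fixture(
            name,
            data=None,
            expected={
                "ml_total_per_direction": 420,
                "ml_total_both_directions": 840,
                "ml_decision_per_direction": 280,
                "ml_reproduction_per_direction": 140,
                "br_decision_per_direction": 390,
                "br_reproduction_per_direction": 195,
                "br_prevalent_counts_far_to_near": (120, 90, 60),
            },
        )
    if name == "sdt_symmetric":
        # HR = 1 - FAR: unbiased observer, criterion exactly 0
        return Fixture(
            name,
            data={"n_hits": 45, "n_signal": 50, "n_fas": 5, "n_noise": 50},
            expected={"criterion_c": 0.0},
        )
    if name == "micro_trials":
        return Fixture(
            name,
            data=_micro_trials(),
            expected={
                # hand tally after dropping the 4 reference-length trials
                "type2_total": 12,
                "cell_long_long_high": 3,
                "cell_short_short_high": 3,
                "cell_long_resp_long_low": 2,
                "n_reference_dropped": 4,
            },
        )
    if name == "metad_ideal":
        params = CANONICAL_OBSERVERS["ideal_metacognition"]
        return Fixture(
            name,
            data=params,
            expected={"m_ratio": 1.0, "tolerance": 0.05},
        )
    raise KeyError(f"unknown fixture {name!r}")
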