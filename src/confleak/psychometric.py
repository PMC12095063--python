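"""Per-subject psychometric curves and their interpolated landmarks.

Three curves are fitted per subject × bias source × bias direction:

* decision task — cumulative Gaussian (probit) of P('long') on target
  length; landmark = point of subjective equality (PSE), the length at
  which either response is equally likely;
* confidence task — quadratic of the proportion of 'high' responses on
  target length; landmark = the vertex, i.e. the point of maximal
  uncertainty (lowest confidence);
* reproduction task — straight line of reproduced length on target
  length; landmark = the target length whose predicted reproduction
  equals the 400-px reference.

A fit fails the quality screen when its governing coefficient (probit
slope, quadratic curvature, linear slope) is not significantly different
from zero at two-sided p < .05 or has the wrong sign; such subjects are
excluded from group analyses, mirroring standard practice for
uninterpretable psychometric functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import REFERENCE_LENGTH

__all__ = [
    "PsychometricFit",
    "DecisionCurve",
    "ConfidenceCurve",
    "ReproductionCurve",
    "FitDataError",
    "fit_decision",
    "fit_confidence",
    "fit_reproduction",
    "landmark_effect",
    "fit_table",
]

#: landmarks outside this range extrapolate beyond the stimulus menu and are flagged
PLAUSIBLE_RANGE = (340.0, 460.0)


class FitDataError(ValueError):
    """Input trials cannot support the requested curve fit."""


@dataclass
class PsychometricFit:
    """Results of one psychometric curve fit.

    ``coefficients`` are ordered (location, slope) for the probit,
    (intercept, linear, quadratic) for the confidence curve and
    (intercept, slope) for the reproduction line.  ``landmark`` is NaN when
    the curve is degenerate (e.g. complete separation).
    """

    curve_kind: str
    coefficients: np.ndarray
    landmark: float
    slope_or_shape_p_value: float
    quality_pass: bool
    extrapolated: bool = False
    nobs: int = 0

    def summary(self) -> str:
        lines = [
            f"Psychometric fit: {self.curve_kind}",
            f"  n obs            {self.nobs}",
            f"  coefficients     {np.array2string(np.asarray(self.coefficients), precision=4)}",
            f"  landmark (px)    {self.landmark:.2f}",
            f"  shape p-value    {self.slope_or_shape_p_value:.4g}",
            f"  quality pass     {self.quality_pass}",
        ]
        if self.extrapolated:
            lines.append("  NOTE: landmark extrapolates beyond the stimulus range")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot of the fitted curve over the stimulus range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(360, 440, 200)
        if self.curve_kind == "decision_probit":
            loc, slope = self.coefficients
            ax.plot(grid, stats.norm.cdf(loc + slope * grid))
            ax.set_ylabel("P('long')")
        elif self.curve_kind == "confidence_quadratic":
            c0, c1, c2 = self.coefficients
            ax.plot(grid, c0 + c1 * grid + c2 * grid**2)
            ax.set_ylabel("P('high')")
        else:
            a, b = self.coefficients
            ax.plot(grid, a + b * grid)
            ax.set_ylabel("reproduced length (px)")
        if np.isfinite(self.landmark):
            ax.axvline(self.landmark, ls="--", color="gray")
        ax.set_xlabel("target length (px)")
        return ax


def _decision_table(trials: pd.DataFrame) -> pd.DataFrame:
    dec = trials[trials["task"] == "decision"]
    if dec.empty:
        raise FitDataError("no decision trials")
    grouped = dec.groupby("target_length")["response"].agg(
        n_long=lambda r: int((r == "long").sum()), n=len
    )
    return grouped.reset_index()


class DecisionCurve:
    """Probit model of P('long') on target length for one subject × condition.

    The fit maximizes the trial-level Bernoulli likelihood (equivalently the
    grouped binomial likelihood) via a probit GLM.  The PSE is obtained
    analytically as −location/slope; by symmetry it is also the 50% point
    for 'short' responses.
    """

    curve_kind = "decision_probit"

    def __init__(self, trials: pd.DataFrame):
        self.table = _decision_table(trials)
        if len(self.table) < 2:
            raise FitDataError("need >= 2 distinct target lengths")

    def fit(self, alpha: float = 0.05) -> PsychometricFit:
        tab = self.table
        nobs = int(tab["n"].sum())
        n_long = int(tab["n_long"].sum())
        if n_long == 0 or n_long == nobs:
            # all-identical responses: flat curve, undefined PSE
            return PsychometricFit(
                self.curve_kind, np.array([np.nan, np.nan]), np.nan, 1.0, False, nobs=nobs
            )
        endog = np.column_stack([tab["n_long"], tab["n"] - tab["n_long"]])
        exog = sm.add_constant(tab["target_length"].to_numpy(dtype=float))
        try:
            res = sm.GLM(
                endog, exog, family=sm.families.Binomial(sm.families.links.Probit())
            ).fit()
            coef = np.asarray(res.params)
            bse = np.asarray(res.bse)
        except Exception:  # separation / non-convergence
            coef = np.array([np.nan, np.nan])
            bse = np.array([np.nan, np.nan])
        separated = not (np.all(np.isfinite(coef)) and np.all(np.isfinite(bse))) or (
            abs(coef[1]) > 5.0  # px^-1: implausibly steep, separation in disguise
        )
        if separated or coef[1] == 0:
            return PsychometricFit(self.curve_kind, coef, np.nan, 1.0, False, nobs=nobs)
        pvalue = 2 * stats.norm.sf(abs(coef[1] / bse[1]))
        landmark = -coef[0] / coef[1]
        quality = bool(coef[1] > 0 and pvalue < alpha)
        return PsychometricFit(
            self.curve_kind,
            coef,
            float(landmark),
            float(pvalue),
            quality,
            extrapolated=not (PLAUSIBLE_RANGE[0] <= landmark <= PLAUSIBLE_RANGE[1]),
            nobs=nobs,
        )


class ConfidenceCurve:
    """Quadratic model of the per-length proportion of 'high' confidence.

    Ordinary least squares on (1, x, x²) of the per-target-length proportion
    of 'high' responses; the landmark is the vertex −b/(2a), requiring
    upward curvature (a > 0) for a well-formed uncertainty minimum.
    """

    curve_kind = "confidence_quadratic"

    def __init__(self, trials: pd.DataFrame):
        dec = trials[(trials["task"] == "decision") & (trials["confidence"] != "")]
        if dec.empty:
            raise FitDataError("no confidence trials")
        prop = dec.groupby("target_length")["confidence"].agg(
            p_high=lambda c: float((c == "high").mean())
        )
        if len(prop) < 3:
            raise FitDataError("need >= 3 distinct target lengths for a quadratic")
        self.x = prop.index.to_numpy(dtype=float)
        self.y = prop["p_high"].to_numpy()
        self.nobs = len(dec)

    def fit(self, alpha: float = 0.05) -> PsychometricFit:
        exog = np.column_stack([np.ones_like(self.x), self.x, self.x**2])
        res = sm.OLS(self.y, exog).fit()
        coef = np.asarray(res.params)
        a = coef[2]
        pvalue = float(res.pvalues[2]) if np.isfinite(res.pvalues[2]) else 1.0
        landmark = -coef[1] / (2 * a) if a != 0 else np.nan
        quality = bool(a > 0 and pvalue < alpha)
        return PsychometricFit(
            self.curve_kind,
            coef,
            float(landmark),
            pvalue,
            quality,
            extrapolated=not (
                np.isfinite(landmark) and PLAUSIBLE_RANGE[0] <= landmark <= PLAUSIBLE_RANGE[1]
            ),
            nobs=self.nobs,
        )


class ReproductionCurve:
    """Straight-line model of reproduced length on target length.

    The landmark is the target length whose predicted reproduction equals
    the reference: (R − intercept)/slope.
    """

    curve_kind = "reproduction_linear"

    def __init__(self, trials: pd.DataFrame, reference: float = REFERENCE_LENGTH):
        rep = trials[trials["task"] == "reproduction"].dropna(subset=["reproduced_length"])
        if rep.empty:
            raise FitDataError("no reproduction trials")
        self.x = rep["target_length"].to_numpy(dtype=float)
        self.y = rep["reproduced_length"].to_numpy(dtype=float)
        if np.unique(self.x).size < 2:
            raise FitDataError("zero variance in target lengths")
        self.reference = float(reference)

    def fit(self, alpha: float = 0.05) -> PsychometricFit:
        exog = sm.add_constant(self.x)
        res = sm.OLS(self.y, exog).fit()
        intercept, slope = np.asarray(res.params)
        pvalue = float(res.pvalues[1]) if np.isfinite(res.pvalues[1]) else 1.0
        landmark = (self.reference - intercept) / slope if slope != 0 else np.nan
        quality = bool(slope > 0 and pvalue < alpha)
        return PsychometricFit(
            self.curve_kind,
            np.array([intercept, slope]),
            float(landmark),
            pvalue,
            quality,
            extrapolated=not (
                np.isfinite(landmark) and PLAUSIBLE_RANGE[0] <= landmark <= PLAUSIBLE_RANGE[1]
            ),
            nobs=len(self.x),
        )


def fit_decision(trials: pd.DataFrame, alpha: float = 0.05) -> PsychometricFit:
    return DecisionCurve(trials).fit(alpha=alpha)


def fit_confidence(trials: pd.DataFrame, alpha: float = 0.05) -> PsychometricFit:
    return ConfidenceCurve(trials).fit(alpha=alpha)


def fit_reproduction(trials: pd.DataFrame, alpha: float = 0.05) -> PsychometricFit:
    return ReproductionCurve(trials).fit(alpha=alpha)


def landmark_effect(fit_long: PsychometricFit, fit_short: PsychometricFit) -> float:
    """Signed bias effect in pixels for one subject.

    Defined as ``landmark(bias-to-short) − landmark(bias-to-long)`` for every
    curve kind, so a positive value always means behavior shifted toward the
    biased direction (a bias toward reporting/seeing 'long' drags the
    landmark to shorter target lengths, and vice versa).
    """
    if fit_long.curve_kind != fit_short.curve_kind:
        raise ValueError(
            f"curve kind mismatch: {fit_long.curve_kind} vs {fit_short.curve_kind}"
        )
    if not (fit_long.quality_pass and fit_short.quality_pass):
        raise ValueError("both fits must pass the quality screen")
    return float(fit_short.landmark - fit_long.landmark)


_FITTERS = {
    "decision": fit_decision,
    "confidence": fit_confidence,
    "reproduction": fit_reproduction,
}


def fit_table(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit all three curves for every subject × bias source × direction.

    Returns a long table with one row per subject × condition × curve,
    carrying coefficients, landmark, the governing p-value and the quality
    flag.  Subjects whose data cannot support a given fit get a
    quality_pass = False row with NaN landmark.
    """
    rows = []
    keys = ["subject_id", "bias_source", "bias_direction"]
    for (subject, source, direction), chunk in trials.groupby(keys, sort=True):
        for task, fitter in _FITTERS.items():
            try:
                fit = fitter(chunk, alpha=alpha)
            except FitDataError:
                kind = {
                    "decision": "decision_probit",
                    "confidence": "confidence_quadratic",
                    "reproduction": "reproduction_linear",
                }[task]
                fit = PsychometricFit(kind, np.array([]), np.nan, 1.0, False)
            rows.append(
                {
                    "subject_id": subject,
                    "bias_source": source,
                    "bias_direction": direction,
                    "task": task,
                    "curve_kind": fit.curve_kind,
                    "coefficients": ";".join(f"{c:.6g}" for c in np.atleast_1d(fit.coefficients)),
                    "landmark": fit.landmark,
                    "p_value": fit.slope_or_shape_p_value,
                    "quality_pass": fit.quality_pass,
                    "extrapolated": fit.extrapolated,
                }
            )
    return pd.DataFrame(rows)
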