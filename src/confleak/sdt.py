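"""Signal-detection sensitivity, criterion, and participant screening.

Correct 'long' responses are hits and correct 'short' responses are correct
rejections, so HR = P('long' | target longer than reference) and
FAR = P('long' | target shorter).  Sensitivity and criterion are

    d' = Z(HR) − Z(FAR)
    c  = ½ · (Z(HR) + Z(FAR))

with Z the inverse of the standard normal CDF.  Reference-length trials
belong to neither stimulus class and are excluded.  Rates of exactly 0 or 1
are edge-corrected to 1/(2N) and 1 − 1/(2N) before the Z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import REFERENCE_LENGTH

__all__ = ["SDTMeasures", "SDTError", "sdt_measures", "subject_measures", "screen_participants"]


class SDTError(ValueError):
    """Trial set cannot support an SDT computation."""


@dataclass(frozen=True)
class SDTMeasures:
    n_signal: int
    n_noise: int
    HR: float
    FAR: float
    d_prime: float
    criterion_c: float


def _edge_correct(k: int, n: int) -> float:
    rate = k / n
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def sdt_measures(trials: pd.DataFrame, reference: float = REFERENCE_LENGTH) -> SDTMeasures:
    """Compute edge-corrected HR/FAR, d' and c from decision trials."""
    dec = trials[(trials["task"] == "decision") & (trials["target_length"] != reference)]
    signal = dec[dec["target_length"] > reference]
    noise = dec[dec["target_length"] < reference]
    if signal.empty or noise.empty:
        raise SDTError("need at least one long-target and one short-target decision trial")
    hr = _edge_correct(int((signal["response"] == "long").sum()), len(signal))
    far = _edge_correct(int((noise["response"] == "long").sum()), len(noise))
    z_hr, z_far = stats.norm.ppf(hr), stats.norm.ppf(far)
    return SDTMeasures(
        n_signal=len(signal),
        n_noise=len(noise),
        HR=hr,
        FAR=far,
        d_prime=float(z_hr - z_far),
        criterion_c=float(0.5 * (z_hr + z_far)),
    )


def subject_measures(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject SDT measures and mean absolute reproduction error,
    pooled across bias directions (the screening statistics)."""
    rows = []
    for subject, chunk in trials.groupby("subject_id", sort=True):
        m = sdt_measures(chunk)
        rep = chunk[chunk["task"] == "reproduction"].dropna(subset=["reproduced_length"])
        err = float(
            np.mean(np.abs(rep["reproduced_length"] - rep["target_length"]))
        ) if len(rep) else np.nan
        rows.append(
            {
                "subject_id": subject,
                "bias_source": chunk["bias_source"].iloc[0],
                "d_prime": m.d_prime,
                "criterion_c": m.criterion_c,
                "HR": m.HR,
                "FAR": m.FAR,
                "mean_abs_repro_error": err,
            }
        )
    return pd.DataFrame(rows)


def screen_participants(
    measures: pd.DataFrame, n_sd: float = 4.0
) -> tuple[list[str], pd.DataFrame]:
    """Apply the participant screens to a per-subject measure table.

    A subject is excluded when criterion, d' or mean absolute reproduction
    error falls outside ``n_sd`` standard deviations of the grand sample
    mean (pooled across bias-source groups), or when d' < 0.  Degenerate
    zero-SD samples exclude nobody on that statistic.  Returns the kept
    subject ids and an exclusion table with machine-readable reasons.
    """
    if len(measures) < 2:
        raise SDTError("need >= 2 subjects to screen")
    reasons: dict[str, list[str]] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for sid in measures.loc[mask, "subject_id"]:
            reasons.setdefault(sid, []).append(reason)

    flag(measures["d_prime"] < 0, "negative_dprime")
    for col, reason in [
        ("criterion_c", "criterion_outlier"),
        ("d_prime", "dprime_outlier"),
        ("mean_abs_repro_error", "reproduction_error_outlier"),
    ]:
        values = measures[col].astype(float)
        mean, sd = values.mean(), values.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        flag((values - mean).abs() > n_sd * sd, reason)

    excluded = pd.DataFrame(
        [{"subject_id": sid, "reasons": ";".join(r)} for sid, r in sorted(reasons.items())]
    )
    kept = [s for s in measures["subject_id"] if s not in reasons]
    return kept, excluded
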