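"""Certainty-equivalent estimation from choice ratios.

For each gamble, the fraction of safe choices as a function of the safe
magnitude m is fit with a two-parameter logistic psychometric curve

    P(safe | m) = 1 / (1 + exp(-(m - x0) / sigma)),

by Bernoulli maximum likelihood on the trial counts (so levels with more
repeats weigh more).  The inflection x0 is the gamble's certainty equivalent
(CE); sigma is the curve's temperature.  CE > EV marks risk seeking for that
gamble, CE < EV risk aversion, CE = EV (within tolerance) risk neutrality.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special

from .types import Choice, Condition, Gamble, TrialRecord

__all__ = [
    "EligibilityError",
    "PsychometricFit",
    "CEEstimate",
    "choice_ratios",
    "choice_counts",
    "fit_psychometric",
    "estimate_ce",
    "estimate_all_ces",
]

#: CEs within this distance of the EV (ml) count as risk neutral —
#: below the resolution at which reward volumes are delivered.
ATTITUDE_TOL = 1e-3

#: Eligibility filter: at least this many distinct safe levels, each repeated
#: at least this many times, are required before a CE is estimated.
MIN_LEVELS = 3
MIN_REPEATS = 4


class EligibilityError(ValueError):
    """The choice data do not satisfy the CE-eligibility filter."""


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted logistic choice-ratio curve: inflection x0 (= CE) and sigma."""

    x0: float
    sigma: float
    n_levels: int
    converged: bool
    extrapolated: bool  # x0 outside the tested level range

    def predict(self, m) -> np.ndarray:
        return special.expit((np.asarray(m, dtype=float) - self.x0) / self.sigma)


@dataclass(frozen=True)
class CEEstimate:
    gamble: Gamble
    ce: float
    ev: float
    sigma: float
    condition: Optional[Condition]
    session_id: str
    attitude: str  # "seeking" | "averse" | "neutral"
    converged: bool


def _classify(ce: float, ev: float, tol: float = ATTITUDE_TOL) -> str:
    if ce > ev + tol:
        return "seeking"
    if ce < ev - tol:
        return "averse"
    return "neutral"


def choice_counts(
    records: Iterable[TrialRecord], gamble: Gamble
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(levels, n_safe, n_valid) per safe magnitude for the given gamble.

    Error trials are excluded from the denominator; levels with zero valid
    trials are omitted.
    """
    counts: Dict[float, List[int]] = {}
    for r in records:
        if r.gamble != gamble or not r.valid:
            continue
        m = r.safe.magnitude
        c = counts.setdefault(m, [0, 0])
        c[0] += r.chosen is Choice.SAFE
        c[1] += 1
    levels = np.array(sorted(counts))
    n_safe = np.array([counts[m][0] for m in levels], dtype=float)
    n_valid = np.array([counts[m][1] for m in levels], dtype=float)
    return levels, n_safe, n_valid


def choice_ratios(
    records: Iterable[TrialRecord], gamble: Gamble
) -> Dict[float, float]:
    """Fraction of safe choices per safe magnitude (valid trials only)."""
    levels, n_safe, n_valid = choice_counts(records, gamble)
    return {float(m): float(s / n) for m, s, n in zip(levels, n_safe, n_valid)}


def _logistic_mle(
    levels: np.ndarray, n_yes: np.ndarray, n_total: np.ndarray
) -> Tuple[float, float, bool]:
    """MLE of an increasing logistic on count data; returns (x0, sigma, ok)."""
    ratios = n_yes / n_total
    # linear-interpolation initial guess for the 0.5 crossing
    if ratios[0] >= 0.5:
        x0_init = levels[0]
    elif ratios[-1] <= 0.5:
        x0_init = levels[-1]
    else:
        x0_init = float(np.interp(0.5, ratios, levels))
    span = max(levels[-1] - levels[0], 1e-3)
    clip = 1e-10

    def nll(theta: np.ndarray) -> float:
        x0, log_sigma = theta
        p = special.expit((levels - x0) / math.exp(log_sigma))
        p = np.clip(p, clip, 1.0 - clip)
        return float(-(n_yes * np.log(p) + (n_total - n_yes) * np.log(1 - p)).sum())

    best = None
    for sigma0 in (span / 10, span / 3):
        res = optimize.minimize(
            nll, np.array([x0_init, math.log(sigma0)]), method="Nelder-Mead",
            options={"fatol": 1e-10, "xatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(math.exp(best.x[1])), bool(best.success)


def fit_psychometric(
    ratios: Mapping[float, float], counts: Mapping[float, int]
) -> PsychometricFit:
    """Fit the logistic psychometric curve to per-level safe-choice ratios.

    `ratios` maps safe magnitude -> fraction of safe choices, `counts` maps
    safe magnitude -> number of valid trials at that level.  Raises
    EligibilityError unless at least MIN_LEVELS levels have MIN_REPEATS
    repeats each.  All-0 or all-1 ratios are non-identifiable: the fit is
    flagged not-converged with x0 pushed one level step outside the range.
    """
    levels = np.array(sorted(ratios))
    if levels.size == 0:
        raise EligibilityError("no safe levels with valid trials")
    n_total = np.array([counts[m] for m in levels], dtype=float)
    n_yes = np.round(np.array([ratios[m] for m in levels]) * n_total)
    eligible = int((n_total >= MIN_REPEATS).sum())
    if levels.size < MIN_LEVELS or eligible < MIN_LEVELS:
        raise EligibilityError(
            f"CE eligibility requires >= {MIN_LEVELS} safe levels with >= "
            f"{MIN_REPEATS} repeats each; got {eligible} of {levels.size} levels"
        )
    step = float(np.min(np.diff(levels))) if levels.size > 1 else 0.05
    if np.all(n_yes == 0) or np.all(n_yes == n_total):
        # the curve never crosses 0.5 inside the tested range
        always_safe = bool(np.all(n_yes == n_total))
        x0 = float(levels[0] - step) if always_safe else float(levels[-1] + step)
        return PsychometricFit(x0=x0, sigma=step, n_levels=int(levels.size),
                               converged=False, extrapolated=True)
    x0, sigma, ok = _logistic_mle(levels, n_yes, n_total)
    extrapolated = not (levels[0] <= x0 <= levels[-1])
    if extrapolated:
        warnings.warn(
            f"fitted inflection {x0:.3f} ml lies outside the tested safe range",
            RuntimeWarning,
        )
    return PsychometricFit(x0=x0, sigma=sigma, n_levels=int(levels.size),
                           converged=ok, extrapolated=extrapolated)


def estimate_ce(
    records: Sequence[TrialRecord],
    gamble: Gamble,
    session_id: str = "",
    condition: Optional[Condition] = None,
) -> CEEstimate:
    """Estimate one gamble's certainty equivalent from choice records."""
    levels, n_safe, n_valid = choice_counts(records, gamble)
    ratios = {float(m): float(s / n) for m, s, n in zip(levels, n_safe, n_valid)}
    counts = {float(m): int(n) for m, n in zip(levels, n_valid)}
    fit = fit_psychometric(ratios, counts)
    ev = gamble.ev
    return CEEstimate(
        gamble=gamble, ce=fit.x0, ev=ev, sigma=fit.sigma,
        condition=condition, session_id=session_id,
        attitude=_classify(fit.x0, ev), converged=fit.converged,
    )


def estimate_all_ces(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per (session, gamble) CE table across all gambles present.

    Gambles failing the eligibility filter are skipped with a warning.
    Columns follow the CE-table schema: session_id, condition, gamble_p,
    ce_ml, ev_ml, sigma, attitude, converged.
    """
    groups: Dict[Tuple[str, Gamble], List[TrialRecord]] = {}
    conditions: Dict[Tuple[str, Gamble], Condition] = {}
    for r in records:
        key = (r.session_id, r.gamble)
        groups.setdefault(key, []).append(r)
        conditions[key] = r.condition
    rows = []
    for (sid, gamble), recs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].win_probability)
    ):
        try:
            est = estimate_ce(recs, gamble, session_id=sid,
                              condition=conditions[(sid, gamble)])
        except EligibilityError as exc:
            warnings.warn(f"session {sid}, gamble ev {gamble.ev:.3f}: {exc}",
                          RuntimeWarning)
            continue
        rows.append({
            "session_id": sid,
            "condition": est.condition.value if est.condition else "",
            "gamble_p": gamble.win_probability if not gamble.is_safe else 1.0,
            "ce_ml": est.ce, "ev_ml": est.ev, "sigma": est.sigma,
            "attitude": est.attitude, "converged": est.converged,
        })
    return pd.DataFrame(rows)
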