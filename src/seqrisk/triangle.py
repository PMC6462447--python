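"""Marschak-Machina triangle geometry.

The triangle is the 2-simplex of lotteries over three fixed magnitudes
m1 < m2 < m3 (defaults 0, 0.25, 0.5 ml): the x axis carries p1 (probability
of the worst outcome), the y axis p3 (best outcome), and p2 = 1 - p1 - p3.
Indifference lines connect a fixed gamble on one axis to the hypotenuse point
of equal subjective value; their slopes diagnose probability distortion:
linear weighting gives parallel 45-degree-like lines, inverse-S weighting
lines that fan out (slopes increase toward the top-left corner), S-shaped
weighting lines that fan in — regardless of utility curvature.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from . import cpt, psychometrics
from .types import M_MAX, Condition, CPTParams, Gamble

__all__ = [
    "TriangleSpec",
    "TrianglePoint",
    "IndifferenceLine",
    "FanningResult",
    "DEFAULT_X_LEVELS",
    "DEFAULT_Y_LEVELS",
    "DEFAULT_PROBE_P3",
    "gamble_from_point",
    "theoretical_indifference_point",
    "elicit_indifference_point",
    "simulate_triangle_choices",
    "build_indifference_lines",
    "elicit_indifference_lines",
    "fanning_regression",
    "shift_correlation",
]

#: Fixed gambles used for the eight indifference lines, indexed 1..8 running
#: from the lower-right corner (largest p1 on the x axis) to the top-left
#: (largest p3 on the y axis).
DEFAULT_X_LEVELS: Tuple[float, ...] = (0.8, 0.6, 0.4, 0.2)
DEFAULT_Y_LEVELS: Tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

#: Hypotenuse probe grid used when eliciting indifference points from choices.
DEFAULT_PROBE_P3: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class TriangleSpec:
    """Three fixed magnitudes (ml) spanning the triangle."""

    m1: float = 0.0
    m2: float = 0.25
    m3: float = M_MAX

    def __post_init__(self) -> None:
        if not self.m1 < self.m2 < self.m3:
            raise ValueError("magnitudes must satisfy m1 < m2 < m3")


@dataclass(frozen=True)
class TrianglePoint:
    """A lottery as a point (p1, p3); p2 = 1 - p1 - p3 is implicit."""

    p1: float
    p3: float

    def __post_init__(self) -> None:
        if self.p1 < -1e-12 or self.p3 < -1e-12 or self.p1 + self.p3 > 1 + 1e-9:
            raise ValueError("need p1, p3 >= 0 and p1 + p3 <= 1")

    @property
    def p2(self) -> float:
        return 1.0 - self.p1 - self.p3

    @property
    def on_x_axis(self) -> bool:
        return abs(self.p3) <= 1e-9

    @property
    def on_y_axis(self) -> bool:
        return abs(self.p1) <= 1e-9


@dataclass(frozen=True)
class IndifferenceLine:
    """Segment from a fixed axis gamble to its hypotenuse indifference point."""

    index: int  # 1..8, lower-right to top-left
    fixed_point: TrianglePoint
    hyp_point: TrianglePoint
    slope_angle: float  # degrees vs the horizontal axis
    source: str  # "model" | "data"

    def __post_init__(self) -> None:
        if not (self.fixed_point.on_x_axis or self.fixed_point.on_y_axis):
            raise ValueError("fixed point must lie on one of the axes")
        if abs(self.hyp_point.p1 + self.hyp_point.p3 - 1.0) > 1e-9:
            raise ValueError("hypotenuse point must satisfy p1 + p3 = 1")


def gamble_from_point(point: TrianglePoint, spec: TriangleSpec = TriangleSpec()) -> Gamble:
    """The lottery over (m1, m2, m3) that the triangle point represents."""
    outcomes = []
    for m, p in ((spec.m1, point.p1), (spec.m2, point.p2), (spec.m3, point.p3)):
        if p > 1e-12:
            outcomes.append((m, p))
    return Gamble(tuple(outcomes))


def _hyp_point(p3: float) -> TrianglePoint:
    return TrianglePoint(p1=1.0 - p3, p3=p3)


def theoretical_indifference_point(
    fixed: TrianglePoint,
    params: CPTParams,
    spec: TriangleSpec = TriangleSpec(),
) -> float:
    """Hypotenuse probability p3* of equal subjective value to the fixed gamble.

    Solves u(m3) * w(p3) = V(fixed) in closed form using the Prelec-1 inverse
    w^{-1}(q) = exp(-(-ln q)^(1/alpha)).  Rejects fixed gambles whose value
    reaches u(m3) (no interior solution).
    """
    if params.family != "prelec1":
        raise ValueError("closed-form inversion requires the prelec1 family")
    if not (fixed.on_x_axis or fixed.on_y_axis):
        raise ValueError("fixed gamble must lie on a triangle axis")
    v_fixed = cpt.subjective_value(gamble_from_point(fixed, spec), params)
    u_m3 = cpt.utility(spec.m3, params.rho)
    q = v_fixed / u_m3
    if q >= 1.0:
        raise ValueError("fixed gamble at least as valuable as the best outcome; "
                         "no interior indifference point")
    if q <= 0.0:
        return 0.0
    return float(cpt.prelec1_inverse(q, params.alpha))


def simulate_triangle_choices(
    fixed: TrianglePoint,
    params: CPTParams,
    spec: TriangleSpec = TriangleSpec(),
    probe_p3: Sequence[float] = DEFAULT_PROBE_P3,
    reps: int = 20,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulated counts of hypotenuse-gamble choices against the fixed gamble.

    Returns (levels, n_chose_hyp, n_total): per probe p3, the number of times
    a softmax agent with `params` chose the hypotenuse gamble B over A.
    """
    rng = np.random.default_rng(seed)
    v_a = cpt.subjective_value(gamble_from_point(fixed, spec), params)
    levels = np.asarray(probe_p3, dtype=float)
    v_b = np.array([
        cpt.subjective_value(gamble_from_point(_hyp_point(p3), spec), params)
        for p3 in levels
    ])
    p_b = cpt.choice_prob(v_b, v_a, params.lam)
    n_b = rng.binomial(reps, p_b).astype(float)
    return levels, n_b, np.full(levels.shape, float(reps))


def elicit_indifference_point(
    levels: Sequence[float],
    n_chose_hyp: Sequence[float],
    n_total: Sequence[float],
) -> float:
    """Psychometric indifference point on the hypotenuse.

    Fits a logistic to P(choose hypotenuse gamble) versus p3 and returns the
    inflection — the p3 with choice ratio 0.5.  Requires >= 3 probe levels;
    all-0/all-1 data are non-identifiable and rejected.
    """
    levels = np.asarray(levels, dtype=float)
    n_b = np.asarray(n_chose_hyp, dtype=float)
    n_tot = np.asarray(n_total, dtype=float)
    if levels.size < 3:
        raise ValueError("need at least three hypotenuse probe levels")
    if np.all(n_b == 0) or np.all(n_b == n_tot):
        raise ValueError("indifference point not identifiable: one-sided choices")
    x0, _, _ = psychometrics._logistic_mle(levels, n_b, n_tot)
    return float(x0)


def _line(index: int, fixed: TrianglePoint, p3_star: float, source: str) -> IndifferenceLine:
    hyp = _hyp_point(p3_star)
    angle = math.degrees(math.atan2(hyp.p3 - fixed.p3, hyp.p1 - fixed.p1))
    return IndifferenceLine(index=index, fixed_point=fixed, hyp_point=hyp,
                            slope_angle=angle, source=source)


def _fixed_grid(
    x_levels: Sequence[float], y_levels: Sequence[float]
) -> List[TrianglePoint]:
    pts = [TrianglePoint(p1=p1, p3=0.0) for p1 in x_levels]
    pts += [TrianglePoint(p1=0.0, p3=p3) for p3 in y_levels]
    return pts


def build_indifference_lines(
    params: CPTParams,
    spec: TriangleSpec = TriangleSpec(),
    x_levels: Sequence[float] = DEFAULT_X_LEVELS,
    y_levels: Sequence[float] = DEFAULT_Y_LEVELS,
) -> List[IndifferenceLine]:
    """Theoretical indifference lines for the eight standard fixed gambles.

    Lines are indexed 1..8 from the lower-right corner (x axis, largest p1)
    to the top-left (y axis, largest p3).  A fixed gamble with no interior
    solution is skipped with a warning.
    """
    lines: List[IndifferenceLine] = []
    for idx, fixed in enumerate(_fixed_grid(x_levels, y_levels), start=1):
        try:
            p3_star = theoretical_indifference_point(fixed, params, spec)
        except ValueError as exc:
            warnings.warn(f"line {idx}: {exc}", RuntimeWarning)
            continue
        lines.append(_line(idx, fixed, p3_star, "model"))
    return lines


def elicit_indifference_lines(
    params: CPTParams,
    spec: TriangleSpec = TriangleSpec(),
    x_levels: Sequence[float] = DEFAULT_X_LEVELS,
    y_levels: Sequence[float] = DEFAULT_Y_LEVELS,
    probe_p3: Sequence[float] = DEFAULT_PROBE_P3,
    reps: int = 20,
    seed: int = 0,
) -> List[IndifferenceLine]:
    """Closed-loop elicitation: simulate choices from `params`, then fit.

    The data-route counterpart of build_indifference_lines; converges to the
    theoretical lines as `reps` grows.
    """
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(x_levels) + len(y_levels))
    lines: List[IndifferenceLine] = []
    for idx, fixed in enumerate(_fixed_grid(x_levels, y_levels), start=1):
        child = int(streams[idx - 1].generate_state(1)[0] % (2**31))
        levels, n_b, n_tot = simulate_triangle_choices(
            fixed, params, spec, probe_p3=probe_p3, reps=reps, seed=child)
        try:
            p3_star = elicit_indifference_point(levels, n_b, n_tot)
        except ValueError as exc:
            warnings.warn(f"line {idx}: {exc}", RuntimeWarning)
            continue
        # a fitted inflection just outside the probe range is clipped back
        # onto the hypotenuse
        lines.append(_line(idx, fixed, min(max(p3_star, 0.0), 1.0), "data"))
    return lines


@dataclass(frozen=True)
class FanningResult:
    """OLS of indifference-line angle on line index."""

    coefficient: float  # degrees per index step
    intercept: float
    r_squared: float
    p_value: float
    classification: str  # "fanning-out" | "fanning-in" | "parallel"


def fanning_regression(lines: Sequence[IndifferenceLine]) -> FanningResult:
    """Regress slope angles on line index; the sign classifies the fanning.

    Positive coefficient: angles increase toward the top-left corner
    (fanning-out, inverse-S weighting); negative: fanning-in (S-shaped
    weighting); near-zero: parallel lines (linear weighting).
    """
    if len(lines) < 3:
        raise ValueError("need at least three indifference lines")
    idx = np.array([l.index for l in lines], dtype=float)
    ang = np.array([l.slope_angle for l in lines], dtype=float)
    res = stats.linregress(idx, ang)
    coef = float(res.slope)
    if abs(coef) < 1e-6:
        label = "parallel"
    else:
        label = "fanning-out" if coef > 0 else "fanning-in"
    return FanningResult(
        coefficient=coef, intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
        classification=label,
    )


def shift_correlation(
    model_lines: Dict[Condition, Sequence[IndifferenceLine]],
    data_lines: Dict[Condition, Sequence[IndifferenceLine]],
) -> Tuple[float, float, int]:
    """Pearson correlation of modeled vs measured indifference-point shifts.

    Per line index, the shift is the change in hypotenuse p3 between the
    REPEATED and MIXED conditions; the correlation is computed over indices
    present in all four line sets (pairwise-complete, with a warning when
    lines are missing).  Returns (r, p_value, n_pairs).
    """
    def p3_by_index(lines: Sequence[IndifferenceLine]) -> Dict[int, float]:
        return {l.index: l.hyp_point.p3 for l in lines}

    maps = {
        ("model", cond): p3_by_index(model_lines[cond]) for cond in model_lines
    }
    maps.update({
        ("data", cond): p3_by_index(data_lines[cond]) for cond in data_lines
    })
    for src in ("model", "data"):
        for cond in (Condition.MIXED, Condition.REPEATED):
            if (src, cond) not in maps:
                raise ValueError(f"missing {src} lines for condition {cond.value}")
    common = set.intersection(*(set(m) for m in maps.values()))
    expected = max(len(m) for m in maps.values())
    if len(common) < expected:
        warnings.warn(
            f"only {len(common)} complete line pairs; correlating those",
            RuntimeWarning,
        )
    if len(common) < 3:
        raise ValueError("need at least three complete line pairs")
    idx = sorted(common)
    model_shift = [maps[("model", Condition.REPEATED)][i]
                   - maps[("model", Condition.MIXED)][i] for i in idx]
    data_shift = [maps[("data", Condition.REPEATED)][i]
                  - maps[("data", Condition.MIXED)][i] for i in idx]
    r, p = stats.pearsonr(model_shift, data_shift)
    return float(r), float(p), len(idx)
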