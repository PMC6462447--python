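"""Prospect-theory discrete-choice modelling.

Choices between a two-outcome gamble and a safe reward are modelled as a
softmax over subjective values

    P(gamble) = 1 / (1 + exp(-lam * (V_G - V_S)))

with rank-dependent values V = u(m_high) * w(p_high) + u(m_low) * (1 - w(p_high)),
power utility u(m) = (m / m_max)^rho anchored at u(m_max) = 1, and one of four
probability-weighting families w(p):

    prelec1   w(p) = exp(-(-ln p)^alpha)
    prelec2   w(p) = exp(-beta * (-ln p)^alpha)
    tversky   w(p) = p^eps / (p^eps + (1-p)^eps)^(1/eps)
    gonzalez  w(p) = delta * p^gamma / (delta * p^gamma + (1-p)^gamma)

Parameters are estimated by maximum likelihood (Nelder-Mead on log-scale
parameters, best of several seeded restarts) and compared by BIC.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .types import M_MAX, Choice, CPTParams, Gamble, TrialRecord

__all__ = [
    "utility",
    "weight_prob",
    "subjective_value",
    "choice_prob",
    "neg_log_likelihood",
    "fit_mle",
    "compare_models",
    "predicted_ce",
    "parameter_recovery",
    "fit_attention_model",
    "ModelFit",
    "N_FREE_PARAMS",
]

#: Free-parameter count per weighting family (softmax + utility + shape(s)).
N_FREE_PARAMS = {"prelec1": 3, "tversky": 3, "prelec2": 4, "gonzalez": 4}

_CLIP = 1e-12  # choice probabilities are kept inside (CLIP, 1 - CLIP)
_N_SHAPE = {"prelec1": 1, "tversky": 1, "prelec2": 2, "gonzalez": 2}


# ---------------------------------------------------------------------------
# value primitives
# ---------------------------------------------------------------------------

def utility(m, rho: float):
    """Power utility u(m) = (m / m_max)^rho, in [0, 1] for m in [0, m_max] ml."""
    m = np.asarray(m, dtype=float)
    if np.any((m < -1e-12) | (m > M_MAX + 1e-12)):
        raise ValueError(f"magnitude outside [0, {M_MAX}] ml")
    if rho <= 0:
        raise ValueError("rho must be > 0")
    out = np.power(np.clip(m, 0.0, M_MAX) / M_MAX, rho)
    return float(out) if out.ndim == 0 else out


def _weight(family: str, p, shape: Sequence[float]):
    p = np.asarray(p, dtype=float)
    if np.any((p < -1e-12) | (p > 1 + 1e-12)):
        raise ValueError("probability outside [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    interior = (p > 0.0) & (p < 1.0)
    w = np.where(p <= 0.0, 0.0, 1.0)  # endpoints fixed by continuity
    pi = np.where(interior, p, 0.5)  # placeholder avoids log(0) warnings
    # extreme shape parameters explored by the optimizer can overflow to
    # inf/0 inside exp/power; the limits are the correct weights, so the
    # warnings are suppressed rather than the values clipped
    with np.errstate(over="ignore", under="ignore"):
        if family == "prelec1":
            (alpha,) = shape
            wi = np.exp(-np.power(-np.log(pi), alpha))
        elif family == "prelec2":
            alpha, beta = shape
            wi = np.exp(-beta * np.power(-np.log(pi), alpha))
        elif family == "tversky":
            (eps,) = shape
            num = np.power(pi, eps)
            wi = num / np.power(num + np.power(1.0 - pi, eps), 1.0 / eps)
        elif family == "gonzalez":
            gamma, delta = shape
            num = delta * np.power(pi, gamma)
            wi = num / (num + np.power(1.0 - pi, gamma))
        else:  # pragma: no cover - guarded by CPTParams validation
            raise ValueError(f"unknown weighting family {family!r}")
    out = np.where(interior, wi, w)
    return float(out) if out.ndim == 0 else out


def weight_prob(p, params: CPTParams):
    """Subjective decision weight w(p) for the family declared in `params`."""
    return _weight(params.family, p, params.shape_values)


def prelec1_inverse(w, alpha: float):
    """Inverse of the one-parameter Prelec function on (0, 1)."""
    w = np.asarray(w, dtype=float)
    if np.any((w <= 0.0) | (w >= 1.0)):
        raise ValueError("inverse defined on the open interval (0, 1)")
    out = np.exp(-np.power(-np.log(w), 1.0 / alpha))
    return float(out) if out.ndim == 0 else out


def subjective_value(option: Gamble, params: CPTParams) -> float:
    """Rank-dependent subjective value of a <=2-outcome lottery, in utils.

    V = u(m_high) * w(p_high) + u(m_low) * (1 - w(p_high)); reduces to u(m) for
    safe rewards and to u(m) * w(p) for gambles whose low outcome is 0 ml.
    """
    sup = option.support()
    if len(sup) > 2:
        raise ValueError("rank-dependent value only defined for <= 2 outcomes")
    if len(sup) == 1:
        return float(utility(sup[0][0], params.rho))
    (m_lo, _), (m_hi, p_hi) = sup
    w_hi = weight_prob(p_hi, params)
    return float(
        utility(m_hi, params.rho) * w_hi + utility(m_lo, params.rho) * (1.0 - w_hi)
    )


def choice_prob(v_gamble, v_safe, lam: float, k: Optional[float] = None):
    """Softmax probability of choosing the gamble.

    With ``k=None`` the standard rule sigmoid(lam * (v_g - v_s)) is used; a
    numeric k applies attention weights: sigmoid(lam * ((1-k) v_g - k v_s)),
    where k > 0.5 shifts weight toward the safe option (k = 0.5 recovers the
    standard rule up to a rescaling of lam).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    v_gamble = np.asarray(v_gamble, dtype=float)
    v_safe = np.asarray(v_safe, dtype=float)
    if k is None:
        z = lam * (v_gamble - v_safe)
    else:
        if not 0.0 < k < 1.0:
            raise ValueError("k must lie in (0, 1)")
        z = lam * ((1.0 - k) * v_gamble - k * v_safe)
    out = special.expit(z)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# likelihood on trial records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _CellData:
    """Trials aggregated into unique (gamble, safe) cells with choice counts."""

    m_lo: np.ndarray
    m_hi: np.ndarray
    p_hi: np.ndarray
    safe_m: np.ndarray
    n_gamble: np.ndarray
    n_safe: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.n_gamble.sum() + self.n_safe.sum())


def _aggregate(records: Iterable[TrialRecord]) -> _CellData:
    cells: Dict[Tuple[float, float, float, float], List[int]] = {}
    for r in records:
        if not r.valid:
            continue
        m_lo, _, m_hi, p_hi = r.gamble.low_high()
        key = (m_lo, m_hi, p_hi, r.safe.magnitude)
        counts = cells.setdefault(key, [0, 0])
        counts[0 if r.chose_gamble else 1] += 1
    if not cells:
        raise ValueError("no valid choice trials")
    keys = np.array(sorted(cells), dtype=float)
    counts = np.array([cells[tuple(k)] for k in keys], dtype=float)
    return _CellData(
        m_lo=keys[:, 0], m_hi=keys[:, 1], p_hi=keys[:, 2], safe_m=keys[:, 3],
        n_gamble=counts[:, 0], n_safe=counts[:, 1],
    )


def _cell_nll(cells: _CellData, params: CPTParams) -> float:
    u_hi = utility(cells.m_hi, params.rho)
    u_lo = utility(cells.m_lo, params.rho)
    w = weight_prob(cells.p_hi, params)
    v_g = u_hi * w + u_lo * (1.0 - w)
    v_s = utility(cells.safe_m, params.rho)
    pg = np.clip(choice_prob(v_g, v_s, params.lam, params.k), _CLIP, 1.0 - _CLIP)
    return float(-(cells.n_gamble * np.log(pg) + cells.n_safe * np.log(1.0 - pg)).sum())


def neg_log_likelihood(records: Sequence[TrialRecord], params: CPTParams) -> float:
    """Negative log-likelihood (nats) of the observed choices under `params`.

    -sum_i [y_i ln P_G(i) + y'_i ln P_S(i)] over valid trials, with choice
    probabilities clipped away from {0, 1} by 1e-12.
    """
    return _cell_nll(_aggregate(records), params)


# ---------------------------------------------------------------------------
# maximum-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    """Result of one MLE run: parameters, -LL, BIC and convergence flag."""

    params: CPTParams
    neg_ll: float
    n_trials: int
    n_free_params: int
    converged: bool

    @property
    def bic(self) -> float:
        return self.n_free_params * math.log(self.n_trials) + 2.0 * self.neg_ll


def _pack(params: CPTParams) -> np.ndarray:
    theta = [math.log(max(params.lam, 1e-8)), math.log(params.rho)]
    theta += [math.log(v) for v in params.shape_values]
    if params.k is not None:
        theta.append(special.logit(params.k))
    return np.array(theta)


def _unpack(theta: np.ndarray, family: str, attention: bool) -> CPTParams:
    n_shape = _N_SHAPE[family]
    lam = math.exp(theta[0])
    rho = math.exp(theta[1])
    shape = [math.exp(t) for t in theta[2:2 + n_shape]]
    kwargs: Dict[str, float] = {}
    if family == "prelec1":
        kwargs["alpha"] = shape[0]
    elif family == "tversky":
        kwargs["epsilon"] = shape[0]
    elif family == "prelec2":
        kwargs["alpha"], kwargs["beta"] = shape
    else:
        kwargs["gamma"], kwargs["delta"] = shape
    k = float(special.expit(theta[2 + n_shape])) if attention else None
    return CPTParams(family=family, lam=lam, rho=rho, k=k, **kwargs)


_INIT = {"lam": 5.0, "rho": 1.0, "shape": 1.0, "k": 0.5}


def _fit_cells(
    cells: _CellData,
    family: str,
    n_restarts: int,
    seed: int,
    attention: bool,
) -> ModelFit:
    n_shape = _N_SHAPE[family]
    base = [math.log(_INIT["lam"]), math.log(_INIT["rho"])]
    base += [math.log(_INIT["shape"])] * n_shape
    if attention:
        base.append(0.0)  # logit(0.5)
    base = np.array(base)

    def objective(theta: np.ndarray) -> float:
        # clamp the log-scale parameters so simplex excursions cannot
        # underflow exp() to an exactly-zero parameter; e^+-30 never binds
        # at any realistic optimum
        theta = np.clip(theta, -30.0, 30.0)
        try:
            return _cell_nll(cells, _unpack(theta, family, attention))
        except (OverflowError, FloatingPointError):  # pragma: no cover
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    any_success = False
    for r in range(max(1, n_restarts)):
        x0 = base if r == 0 else base + rng.normal(0.0, 0.7, size=base.size)
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 4000, "maxfev": 4000},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        warnings.warn(
            "Nelder-Mead did not converge on any restart; reporting best point found",
            RuntimeWarning,
        )
    params = _unpack(np.clip(best.x, -30.0, 30.0), family, attention)
    return ModelFit(
        params=params,
        neg_ll=float(best.fun),
        n_trials=cells.n_trials,
        n_free_params=N_FREE_PARAMS[family] + (1 if attention else 0),
        converged=any_success,
    )


def fit_mle(
    records: Sequence[TrialRecord],
    family: str = "prelec1",
    n_restarts: int = 10,
    seed: int = 0,
    attention: bool = False,
) -> ModelFit:
    """Best-of-restarts Nelder-Mead maximum-likelihood fit of the choice model.

    Positive parameters are optimized on the log scale (the attention weight k,
    when requested, on the logit scale); restarts jitter the starting point
    around (lam=5, rho=1, shape=1, k=0.5).
    """
    if family not in N_FREE_PARAMS:
        raise ValueError(f"unknown weighting family {family!r}")
    return _fit_cells(_aggregate(records), family, n_restarts, seed, attention)


def compare_models(
    records: Sequence[TrialRecord],
    families: Sequence[str] = ("prelec1", "tversky", "prelec2", "gonzalez"),
    n_restarts: int = 10,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, ModelFit]]:
    """Fit each weighting family and rank them by BIC (lowest first).

    A family whose fit raises is reported with NaNs without aborting the rest.
    """
    if len(families) < 1:
        raise ValueError("need at least one family")
    fits: Dict[str, ModelFit] = {}
    rows = []
    for fam in families:
        try:
            fit = fit_mle(records, family=fam, n_restarts=n_restarts, seed=seed)
        except Exception as exc:  # propagate per-family failure as a row
            warnings.warn(f"fit for family {fam!r} failed: {exc}", RuntimeWarning)
            rows.append({"family": fam, "neg_ll": np.nan, "bic": np.nan,
                         "n_free_params": N_FREE_PARAMS[fam], "converged": False})
            continue
        fits[fam] = fit
        rows.append({
            "family": fam, "neg_ll": fit.neg_ll, "bic": fit.bic,
            "n_free_params": fit.n_free_params, "converged": fit.converged,
        })
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    table["best"] = False
    if table["bic"].notna().any():
        table.loc[table["bic"].idxmin(), "best"] = True
    return table, fits


def predicted_ce(params: CPTParams, p: float) -> float:
    """Model-predicted certainty equivalent of the (M_MAX @ p, else 0) gamble.

    Closed form CE = u^{-1}(w(p) * u(m_max)) = m_max * w(p)^(1/rho).
    """
    w = weight_prob(p, params)
    return float(M_MAX * np.power(w, 1.0 / params.rho))


# ---------------------------------------------------------------------------
# Monte-Carlo parameter recovery
# ---------------------------------------------------------------------------

def _design_cells(
    gambles: Sequence[Gamble], safe_levels: Sequence[float], reps_per_pair: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    m_lo, m_hi, p_hi, safe_m = [], [], [], []
    for g in gambles:
        lo, _, hi, ph = g.low_high()
        for s in safe_levels:
            m_lo.append(lo)
            m_hi.append(hi)
            p_hi.append(ph)
            safe_m.append(s)
    return (np.array(m_lo), np.array(m_hi), np.array(p_hi), np.array(safe_m),
            reps_per_pair)


def _simulate_cells(
    design: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int],
    params: CPTParams,
    rng: np.random.Generator,
) -> _CellData:
    """Draw per-cell gamble-choice counts ~ Binomial(reps, P_G).

    Exactly equivalent to trial-by-trial simulation for a history-free agent.
    """
    m_lo, m_hi, p_hi, safe_m, reps = design
    w = weight_prob(p_hi, params)
    v_g = utility(m_hi, params.rho) * w + utility(m_lo, params.rho) * (1.0 - w)
    v_s = utility(safe_m, params.rho)
    pg = choice_prob(v_g, v_s, params.lam, params.k)
    n_g = rng.binomial(reps, pg).astype(float)
    return _CellData(m_lo=m_lo, m_hi=m_hi, p_hi=p_hi, safe_m=safe_m,
                     n_gamble=n_g, n_safe=reps - n_g)


def parameter_recovery(
    true_params_grid: Sequence[CPTParams],
    gambles: Optional[Sequence[Gamble]] = None,
    safe_levels: Optional[Sequence[float]] = None,
    reps_per_pair: int = 6,
    n_mc: int = 200,
    seed: int = 0,
    n_restarts: int = 3,
) -> pd.DataFrame:
    """Simulate-and-refit validation of the MLE procedure.

    For each parameter set in the grid, `n_mc` datasets are simulated on the
    gamble x safe x repetition design and refit; per free parameter the table
    reports the mean and median estimate, bias, and the percentile 95% CI.
    The default design is the standard one: 9 gambles (p = 0.1..0.9 of the
    0.5 ml payoff), 11 safe magnitudes (0..0.5 ml), 6 repetitions per pair.
    """
    from . import synthetic  # local import to avoid a cycle

    if gambles is None:
        gambles = synthetic.default_gambles()
    if safe_levels is None:
        safe_levels = synthetic.default_safe_levels()
    design = _design_cells(gambles, safe_levels, reps_per_pair)
    n_trials = len(design[0]) * reps_per_pair

    rows = []
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(true_params_grid))
    for cell_idx, true in enumerate(true_params_grid):
        free = [n for n in true.free_names if n != "k"]
        estimates = {name: np.empty(n_mc) for name in free}
        rep_streams = cell_seeds[cell_idx].spawn(n_mc)
        for i in range(n_mc):
            rng = np.random.default_rng(rep_streams[i])
            cells = _simulate_cells(design, true, rng)
            fit = _fit_cells(
                cells, true.family, n_restarts,
                seed=int(rep_streams[i].generate_state(1)[0] % (2**31)),
                attention=true.k is not None,
            )
            for name in free:
                estimates[name][i] = getattr(fit.params, name)
        for name in free:
            est = estimates[name]
            truth = getattr(true, name)
            lo, hi = np.percentile(est, [2.5, 97.5])
            rows.append({
                "cell": cell_idx, "param": name, "true": truth,
                "mean": est.mean(), "median": float(np.median(est)),
                "bias": est.mean() - truth,
                "median_bias": float(np.median(est)) - truth,
                "ci_lo": lo, "ci_hi": hi,
                "in_ci": bool(lo <= truth <= hi),
                "n_mc": n_mc, "n_trials": n_trials,
            })
    return pd.DataFrame(rows)


def fit_attention_model(
    records: Sequence[TrialRecord],
    family: str = "prelec1",
    n_restarts: int = 10,
    seed: int = 0,
) -> Tuple[pd.DataFrame, "stats._result_classes.TtestResult"]:
    """Per-session MLE with an attention weight k, and a test of k against 0.5.

    Returns a per-session table and a one-sample t-test of the session k values
    against the equal-attention null k = 0.5.  With a single session the test
    statistic is NaN and a notice is issued.
    """
    sessions: Dict[str, List[TrialRecord]] = {}
    for r in records:
        sessions.setdefault(r.session_id, []).append(r)
    rows = []
    for sid in sorted(sessions):
        fit = fit_mle(sessions[sid], family=family, n_restarts=n_restarts,
                      seed=seed, attention=True)
        rows.append({
            "session_id": sid, "k": fit.params.k, "lam": fit.params.lam,
            "rho": fit.params.rho, "neg_ll": fit.neg_ll, "bic": fit.bic,
            "converged": fit.converged,
        })
    table = pd.DataFrame(rows)
    if len(table) < 2:
        warnings.warn("a single session: k returned, test against 0.5 skipped",
                      RuntimeWarning)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            test = stats.ttest_1samp(table["k"].to_numpy(), 0.5)
    else:
        test = stats.ttest_1samp(table["k"].to_numpy(), 0.5)
    return table, test
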