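"""Trial-history analyses: lagged-EV regressions, win-stay/lose-shift,
outcome-conditional prospect-theory fits, and the value-updating agent.

The value-updating (reinforcement-learning) model evaluates choices with the
usual softmax but codes values linearly in ml: the safe value is its
magnitude, and the gamble value starts from its objective EV and is shifted
by +eta after a previous-trial gamble win, -eta after a loss, and not at all
when the safe option was chosen.  A single (lambda, eta) pair, interacting
with the trial sequence, is enough to displace certainty equivalents in
opposite directions in MIXED versus REPEATED sequences.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from . import cpt, psychometrics, synthetic
from .types import Choice, Condition, CPTParams, Gamble, RLParams, TrialRecord

__all__ = [
    "RegressionSpec",
    "BASIC_REGRESSION",
    "PAST_EV_REGRESSION",
    "WSLS_REGRESSION",
    "records_frame",
    "standardized_logistic_regression",
    "wsls_model_comparison",
    "conditional_cpt_fit",
    "rl_gamble_value",
    "fit_rl_model",
    "simulate_rl_ces",
]

_LAG_NAMES = tuple(f"EV_gamble_lag_{n}" for n in range(1, 9))
_KNOWN_REGRESSORS = ("EV_gamble", "EV_safe", "Position_LR", "Risk",
                     "Outcome_past") + _LAG_NAMES


@dataclass(frozen=True)
class RegressionSpec:
    """Which regressors enter the per-session logistic choice regression.

    Risk is p*(1-p) of the current gamble; EV_gamble_lag_n is the *offered*
    gamble EV n trials back (lags count trials, including error trials);
    Outcome_past (0/1) is defined only when the previous trial's gamble was
    chosen.  `trial_filter` restricts the fitted trials.
    """

    regressors: Tuple[str, ...]
    trial_filter: str = "all_valid"  # or "prev_gamble_chosen"

    def __post_init__(self) -> None:
        for name in self.regressors:
            if name not in _KNOWN_REGRESSORS:
                raise ValueError(f"unknown regressor {name!r}")
        if self.trial_filter not in ("all_valid", "prev_gamble_chosen"):
            raise ValueError(f"unknown trial filter {self.trial_filter!r}")
        if "Outcome_past" in self.regressors and self.trial_filter != "prev_gamble_chosen":
            raise ValueError("Outcome_past requires trial_filter='prev_gamble_chosen'")

    @property
    def min_history(self) -> int:
        lags = [int(name.rsplit("_", 1)[1]) for name in self.regressors
                if name.startswith("EV_gamble_lag_")]
        return max(lags, default=0)


BASIC_REGRESSION = RegressionSpec(("EV_gamble", "EV_safe", "Position_LR", "Risk"))
PAST_EV_REGRESSION = RegressionSpec(("EV_gamble", "EV_safe") + _LAG_NAMES)
WSLS_REGRESSION = RegressionSpec(
    ("EV_gamble", "EV_safe", "Position_LR", "Outcome_past"),
    trial_filter="prev_gamble_chosen",
)


def records_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame with regressors and history columns."""
    rows = []
    for r in records:
        p = r.gamble.win_probability if not r.gamble.is_safe else 1.0
        rows.append({
            "session_id": r.session_id,
            "trial_index": r.trial_index,
            "condition": r.condition.value,
            "gamble_p": p,
            "EV_gamble": r.gamble.ev,
            "EV_safe": r.safe.magnitude,
            "Risk": p * (1.0 - p),
            "Position_LR": 1.0 if r.gamble_side.value == "right" else 0.0,
            "valid": r.valid,
            "y": 1.0 if r.chose_gamble else 0.0,
            "outcome_ml": r.outcome_ml,
            "chose_gamble": r.chose_gamble,
        })
    df = pd.DataFrame(rows).sort_values(["session_id", "trial_index"])
    grp = df.groupby("session_id", sort=False)
    for n in range(1, 9):
        df[f"EV_gamble_lag_{n}"] = grp["EV_gamble"].shift(n)
    prev_chose = grp["chose_gamble"].shift(1)
    prev_outcome = grp["outcome_ml"].shift(1)
    df["prev_gamble_chosen"] = prev_chose.eq(True)
    df["Outcome_past"] = np.where(
        df["prev_gamble_chosen"] & (prev_outcome > 0), 1.0,
        np.where(df["prev_gamble_chosen"], 0.0, np.nan),
    )
    # previous-outcome sign for the value-updating model
    df["z_prev"] = np.where(
        df["prev_gamble_chosen"], np.where(prev_outcome > 0, 1.0, -1.0), 0.0
    )
    return df.reset_index(drop=True)


def _apply_filter(df: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    out = df[df["valid"]]
    if spec.trial_filter == "prev_gamble_chosen":
        out = out[out["prev_gamble_chosen"]]
    if spec.min_history > 0:
        lag_cols = [f"EV_gamble_lag_{n}" for n in range(1, spec.min_history + 1)]
        out = out.dropna(subset=lag_cols)
    return out


def standardized_logistic_regression(
    records: Sequence[TrialRecord],
    spec: RegressionSpec = BASIC_REGRESSION,
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-session logistic regression of gamble choice, standardized betas.

    Each session is fit separately by ML; coefficients are standardized by
    SD(x) / SD(y) with the sample SD of the binary choice variable as SD(y).
    Sessions with separation or a singular design are flagged and excluded.
    Returns (per-session betas, across-session summary with one-sample
    t-tests, number of excluded sessions).
    """
    df = _apply_filter(records_frame(records), spec)
    session_rows = []
    n_excluded = 0
    for sid, sub in df.groupby("session_id", sort=True):
        X = sub[list(spec.regressors)].to_numpy()
        y = sub["y"].to_numpy()
        sd_y = y.std(ddof=1)
        sd_x = X.std(axis=0, ddof=1)
        if len(sub) <= len(spec.regressors) + 1 or sd_y == 0 or np.any(sd_x == 0):
            n_excluded += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)) or not res.mle_retvals.get(
                    "converged", True):
                raise ValueError("did not converge")
        except Exception:
            n_excluded += 1
            continue
        beta = res.params[1:]  # drop intercept
        row = {"session_id": sid, "n_trials": len(sub)}
        for name, b, sx in zip(spec.regressors, beta, sd_x):
            row[name] = b * sx / sd_y
        session_rows.append(row)
    per_session = pd.DataFrame(session_rows)
    summary_rows = []
    for name in spec.regressors:
        vals = per_session[name].to_numpy() if len(per_session) else np.array([])
        if vals.size >= 2:
            t = stats.ttest_1samp(vals, 0.0)
            tstat, pval = float(t.statistic), float(t.pvalue)
        else:
            tstat = pval = math.nan
        summary_rows.append({
            "regressor": name,
            "mean": vals.mean() if vals.size else math.nan,
            "sem": vals.std(ddof=1) / math.sqrt(vals.size) if vals.size > 1 else math.nan,
            "t": tstat, "p": pval, "n_sessions": vals.size,
        })
    return per_session, pd.DataFrame(summary_rows), n_excluded


def _logit_bic(y: np.ndarray, X: np.ndarray) -> float:
    res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
    k = X.shape[1] + 1
    return float(k * math.log(len(y)) - 2.0 * res.llf)


def wsls_model_comparison(
    records: Sequence[TrialRecord],
    min_trials_per_pair: int = 4,
) -> Tuple[pd.DataFrame, Optional[stats._result_classes.TtestResult]]:
    """Per-session BIC of the win-stay/lose-shift regression vs the basic one.

    Both models are fit only on trials whose previous trial's gamble was
    chosen.  Sessions whose full design offers fewer than `min_trials_per_pair`
    repeats of any gamble-safe pair are excluded (under-sampled sessions).
    Returns the per-session BIC table and a paired t-test (None with < 2
    sessions).
    """
    df = records_frame(records)
    eligible = []
    for sid, sub in df.groupby("session_id", sort=True):
        pair_counts = sub.groupby(["gamble_p", "EV_safe"]).size()
        if pair_counts.min() >= min_trials_per_pair:
            eligible.append(sid)
    if not eligible:
        raise ValueError("no sessions satisfy the per-pair repetition filter")
    sel = df[df["session_id"].isin(eligible) & df["valid"]
             & df["prev_gamble_chosen"]]
    rows = []
    for sid, sub in sel.groupby("session_id", sort=True):
        y = sub["y"].to_numpy()
        if y.std() == 0 or len(sub) < 10:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bic_basic = _logit_bic(
                    y, sub[["EV_gamble", "EV_safe", "Position_LR", "Risk"]].to_numpy())
                bic_wsls = _logit_bic(
                    y, sub[["EV_gamble", "EV_safe", "Position_LR",
                            "Outcome_past"]].to_numpy())
        except Exception:
            continue
        rows.append({"session_id": sid, "n_trials": len(sub),
                     "bic_basic": bic_basic, "bic_wsls": bic_wsls,
                     "delta_bic": bic_wsls - bic_basic})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        test = stats.ttest_rel(table["bic_wsls"], table["bic_basic"])
    else:
        test = None
    return table, test


def _split_by_previous_outcome(
    records: Sequence[TrialRecord],
) -> Tuple[List[TrialRecord], List[TrialRecord]]:
    by_session: Dict[str, List[TrialRecord]] = {}
    for r in records:
        by_session.setdefault(r.session_id, []).append(r)
    wins: List[TrialRecord] = []
    losses: List[TrialRecord] = []
    for sid, recs in by_session.items():
        recs = sorted(recs, key=lambda r: r.trial_index)
        for prev, cur in zip(recs, recs[1:]):
            if not cur.valid or not prev.chose_gamble:
                continue
            (wins if prev.outcome_ml > 0 else losses).append(cur)
    return wins, losses


def conditional_cpt_fit(
    records: Sequence[TrialRecord],
    condition: Optional[Condition] = None,
    family: str = "prelec1",
    n_boot: int = 100,
    min_trials: int = 100,
    seed: int = 0,
    n_restarts: int = 5,
) -> Dict[str, dict]:
    """Prospect-theory fits conditioned on the previous gamble's outcome.

    Trials following a chosen-and-won gamble and trials following a
    chosen-and-lost gamble are pooled across sessions (optionally within one
    condition) and fit separately; bootstrap percentile CIs are attached.
    A split with fewer than `min_trials` trials is flagged.
    """
    if condition is not None:
        records = [r for r in records if r.condition is condition]
    wins, losses = _split_by_previous_outcome(records)
    rng = np.random.default_rng(seed)
    out: Dict[str, dict] = {}
    for label, recs in (("win", wins), ("loss", losses)):
        entry: Dict[str, object] = {"n_trials": len(recs)}
        if len(recs) < max(min_trials, 10):
            warnings.warn(
                f"previous-{label} split has only {len(recs)} trials; flagged",
                RuntimeWarning,
            )
            entry["flagged"] = True
            out[label] = entry
            continue
        fit = cpt.fit_mle(recs, family=family, n_restarts=n_restarts, seed=seed)
        entry.update({"fit": fit, "flagged": not fit.converged})
        boots = {"rho": [], "alpha": []}
        for b in range(n_boot):
            idx = rng.integers(0, len(recs), size=len(recs))
            sample = [recs[i] for i in idx]
            bfit = cpt.fit_mle(sample, family=family, n_restarts=2,
                               seed=seed + b + 1)
            boots["rho"].append(bfit.params.rho)
            if family == "prelec1":
                boots["alpha"].append(bfit.params.alpha)
        if n_boot > 0:
            entry["rho_ci"] = tuple(np.percentile(boots["rho"], [2.5, 97.5]))
            if boots["alpha"]:
                entry["alpha_ci"] = tuple(np.percentile(boots["alpha"], [2.5, 97.5]))
        out[label] = entry
    return out


def rl_gamble_value(
    ev: float,
    prev_outcome: str,
    eta: float,
) -> float:
    """Gamble value (ml) under the one-trial update rule.

    `prev_outcome` is one of "win", "loss", "safe_chosen", "none": EV + eta
    after a win, EV - eta after a loss, the bare EV otherwise.
    """
    if prev_outcome == "win":
        return ev + eta
    if prev_outcome == "loss":
        return ev - eta
    if prev_outcome in ("safe_chosen", "none"):
        return ev
    raise ValueError(f"unknown previous outcome {prev_outcome!r}")


@dataclass(frozen=True)
class RLFit:
    params: RLParams
    neg_ll: float
    n_trials: int
    converged: bool
    flagged: bool  # lambda collapsed: eta unidentifiable


def _fit_rl_session(
    ev: np.ndarray, safe_m: np.ndarray, z: np.ndarray, y: np.ndarray,
    seed: int, n_restarts: int = 3,
) -> RLFit:
    def nll(theta: np.ndarray) -> float:
        lam = math.exp(theta[0])
        eta = theta[1]
        p = special.expit(lam * (ev + eta * z - safe_m))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())

    rng = np.random.default_rng(seed)
    best = None
    ok = False
    for r in range(n_restarts):
        x0 = np.array([math.log(20.0), 0.0])
        if r > 0:
            x0 += rng.normal(0.0, [0.7, 0.01])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"fatol": 1e-8, "xatol": 1e-8,
                                         "maxiter": 2000})
        ok = ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    lam = math.exp(best.x[0])
    # a collapsed softmax (|lam * dV| << 1 everywhere) leaves eta without
    # leverage on the likelihood; typical fitted lambdas are ~20 /ml
    flagged = lam < 0.5
    if flagged:
        warnings.warn("softmax lambda collapsed toward 0; eta unidentifiable",
                      RuntimeWarning)
    return RLFit(params=RLParams(lam=lam, eta=float(best.x[1])),
                 neg_ll=float(best.fun), n_trials=int(y.size),
                 converged=ok, flagged=flagged)


def fit_rl_model(
    records: Sequence[TrialRecord],
    seed: int = 0,
) -> Tuple[pd.DataFrame, Optional[stats._result_classes.TtestResult]]:
    """Per-session MLE of the value-updating model (lambda, eta).

    The previous-outcome indicator is computed from the data, so the
    likelihood is an ordinary logistic in (lambda, eta).  Returns the
    per-session table and a one-sample t-test of eta against 0 (None with
    < 2 usable sessions).
    """
    df = records_frame(records)
    rows = []
    root = np.random.SeedSequence(seed)
    sids = sorted(df["session_id"].unique())
    streams = root.spawn(len(sids))
    for sid, stream in zip(sids, streams):
        sub = df[(df["session_id"] == sid) & df["valid"]]
        if len(sub) < 20 or sub["y"].std() == 0:
            continue
        fit = _fit_rl_session(
            sub["EV_gamble"].to_numpy(), sub["EV_safe"].to_numpy(),
            sub["z_prev"].to_numpy(), sub["y"].to_numpy(),
            seed=int(stream.generate_state(1)[0] % (2**31)),
        )
        rows.append({"session_id": sid, "lam": fit.params.lam,
                     "eta": fit.params.eta, "neg_ll": fit.neg_ll,
                     "n_trials": fit.n_trials, "converged": fit.converged,
                     "flagged": fit.flagged})
    table = pd.DataFrame(rows)
    usable = table[~table["flagged"]] if len(table) else table
    test = (stats.ttest_1samp(usable["eta"].to_numpy(), 0.0)
            if len(usable) >= 2 else None)
    return table, test


def simulate_rl_ces(
    params: RLParams,
    n_sessions: int = 50,
    seed: int = 0,
    reps_per_pair: int = 6,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Certainty-equivalent curves of the value-updating agent per condition.

    Simulates `n_sessions` MIXED and REPEATED sessions with linear utility
    and linear probability coding, estimates each gamble's CE psychometrically
    per session, and aggregates mean +/- SEM per (condition, gamble p).
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for cond in (Condition.MIXED, Condition.REPEATED):
        streams = root.spawn(n_sessions)
        for s, stream in enumerate(streams):
            kids = stream.generate_state(2) % (2**31)
            plan = synthetic.default_plan(cond, reps_per_pair=reps_per_pair,
                                          seed=int(kids[0]))
            sid = f"{cond.value.lower()}-{s:03d}"
            recs = synthetic.simulate_session(plan, params, seed=int(kids[1]),
                                              session_id=sid,
                                              cumulative=cumulative)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ces = psychometrics.estimate_all_ces(recs)
            for _, row in ces.iterrows():
                rows.append({"condition": cond.value, "session": sid,
                             "gamble_p": row["gamble_p"], "ce_ml": row["ce_ml"],
                             "ev_ml": row["ev_ml"]})
    per_session = pd.DataFrame(rows)
    agg = (per_session.groupby(["condition", "gamble_p"])
           .agg(ce_mean=("ce_ml", "mean"),
                ce_sem=("ce_ml", lambda v: v.std(ddof=1) / math.sqrt(len(v))),
                ev_ml=("ev_ml", "first"),
                n_sessions=("ce_ml", "size"))
           .reset_index())
    return agg
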