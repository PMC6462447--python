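"""Synthetic trial sequences and simulated choosers.

Emulates the study design: gambles paying 0.5 ml with probability
p = 0.1..0.9, safe magnitudes 0-0.5 ml in 0.05 ml steps, each gamble-safe
pair repeated several times per session, presented either pseudorandomly
interleaved (MIXED) or one gamble per contiguous block (REPEATED).  Choices
can be simulated from softmax prospect-theory agents or from the one-trial
value-updating agent, so every downstream analysis is testable without any
recorded data.
"""
from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import cpt
from .types import (
    M_MAX,
    Choice,
    Condition,
    CPTParams,
    Gamble,
    RLParams,
    SequencePlan,
    Side,
    TrialRecord,
)

__all__ = [
    "default_gambles",
    "default_safe_levels",
    "default_design",
    "default_plan",
    "build_sequence",
    "simulate_choices",
    "simulate_session",
    "consecutive_ev_variability",
]

PairList = List[Tuple[Gamble, Gamble, Side]]


def default_gambles() -> Tuple[Gamble, ...]:
    """The nine standard gambles: 0.5 ml with p = 0.1, 0.2, ..., 0.9.

    The certain p = 1.0 'gamble' is deliberately excluded: certainty
    equivalents are only elicited for genuinely risky options.
    """
    return tuple(Gamble.from_probability(round(p / 10, 1)) for p in range(1, 10))


def default_safe_levels() -> Tuple[float, ...]:
    """Eleven safe magnitudes, 0.00-0.50 ml in 0.05 ml steps."""
    return tuple(round(0.05 * i, 2) for i in range(11))


def default_design() -> Tuple[Tuple[Gamble, ...], Tuple[float, ...]]:
    """(gambles, safe levels) of the standard elicitation design."""
    return default_gambles(), default_safe_levels()


def default_plan(
    condition: Union[Condition, str],
    reps_per_pair: int = 6,
    seed: int = 0,
) -> SequencePlan:
    gambles, safes = default_design()
    return SequencePlan(
        condition=Condition(condition),
        gambles=gambles,
        safe_levels=safes,
        reps_per_pair=reps_per_pair,
        seed=seed,
    )


def build_sequence(plan: SequencePlan) -> PairList:
    """Ordered (gamble, safe, gamble_side) triples for one session.

    MIXED: every gamble x safe pair, repeated reps_per_pair times, shuffled
    uniformly.  REPEATED: one contiguous block per gamble (block order is a
    seeded shuffle), safes shuffled within the block.  Sides are balanced so
    each pair appears equally often with the gamble on the left and right,
    which requires an even repetition count.
    """
    if plan.reps_per_pair % 2 != 0:
        raise ValueError(
            "reps_per_pair must be even so each gamble-safe pair can appear "
            "equally often on the left and right"
        )
    half = plan.reps_per_pair // 2
    rng = np.random.default_rng(plan.seed)
    safes = [Gamble.safe(m) for m in plan.safe_levels]

    def pair_entries(g: Gamble) -> PairList:
        out: PairList = []
        for s in safes:
            out.extend([(g, s, Side.LEFT)] * half)
            out.extend([(g, s, Side.RIGHT)] * half)
        return out

    if plan.condition is Condition.MIXED:
        seq: PairList = []
        for g in plan.gambles:
            seq.extend(pair_entries(g))
        order = rng.permutation(len(seq))
        return [seq[i] for i in order]

    # REPEATED: seeded shuffle of block order, then shuffle within block
    block_order = rng.permutation(len(plan.gambles))
    seq = []
    for bi in block_order:
        block = pair_entries(plan.gambles[bi])
        order = rng.permutation(len(block))
        seq.extend(block[i] for i in order)
    return seq


def _draw_outcome(option: Gamble, rng: np.random.Generator) -> float:
    u = rng.random()
    acc = 0.0
    for m, p in option.outcomes:
        acc += p
        if u < acc:
            return m
    return option.outcomes[-1][0]


def simulate_choices(
    sequence: PairList,
    params: Union[CPTParams, RLParams],
    seed: int = 0,
    session_id: str = "sim-000",
    condition: Union[Condition, str] = Condition.MIXED,
    error_rate: float = 0.0,
    cumulative: bool = False,
) -> List[TrialRecord]:
    """Simulate one session of choices from a parameterized agent.

    CPTParams agents value options by rank-dependent prospect theory; RLParams
    agents use linear coding (values in ml) with the gamble value updated by
    the previous trial's outcome: EV + eta after a win, EV - eta after a loss,
    EV when the safe option was chosen (or at the session start).  With
    ``cumulative=True`` the updates accumulate over the session instead of
    resetting to EV each trial (an alternative reading of the update rule).
    Realized outcomes are drawn from the chosen option's lottery, so the
    records support trial-history analyses.  ``error_rate`` optionally inserts
    no-choice error trials to exercise downstream filters.
    """
    condition = Condition(condition)
    rng = np.random.default_rng(seed)
    records: List[TrialRecord] = []
    rl_offset = 0.0  # running value offset of the RL agent
    prev_z = 0  # +1 prev gamble win, -1 prev gamble loss, 0 otherwise
    for i, (gamble, safe, side) in enumerate(sequence, start=1):
        if error_rate > 0.0 and rng.random() < error_rate:
            records.append(TrialRecord(
                session_id=session_id, trial_index=i, condition=condition,
                gamble=gamble, safe=safe, gamble_side=side, chosen=Choice.NONE,
            ))
            # an aborted trial delivers no outcome: no value update
            prev_z = 0
            continue
        if isinstance(params, CPTParams):
            v_g = cpt.subjective_value(gamble, params)
            v_s = cpt.subjective_value(safe, params)
            pg = cpt.choice_prob(v_g, v_s, params.lam, params.k)
        else:
            if cumulative:
                rl_offset += params.eta * prev_z
                v_g = gamble.ev + rl_offset
            else:
                v_g = gamble.ev + params.eta * prev_z
            v_s = safe.magnitude
            pg = cpt.choice_prob(v_g, v_s, params.lam)
        chose_gamble = rng.random() < pg
        chosen = Choice.GAMBLE if chose_gamble else Choice.SAFE
        outcome = _draw_outcome(gamble if chose_gamble else safe, rng)
        records.append(TrialRecord(
            session_id=session_id, trial_index=i, condition=condition,
            gamble=gamble, safe=safe, gamble_side=side, chosen=chosen,
            outcome_ml=outcome,
        ))
        if chose_gamble and not gamble.is_safe:
            m_hi = gamble.low_high()[2]
            prev_z = 1 if outcome >= m_hi - 1e-12 else -1
        else:
            prev_z = 0
    return records


def simulate_session(
    plan: SequencePlan,
    params: Union[CPTParams, RLParams],
    seed: int = 0,
    session_id: str = "sim-000",
    error_rate: float = 0.0,
    cumulative: bool = False,
) -> List[TrialRecord]:
    """Build the plan's sequence and simulate choices on it."""
    return simulate_choices(
        build_sequence(plan), params, seed=seed, session_id=session_id,
        condition=plan.condition, error_rate=error_rate, cumulative=cumulative,
    )


def consecutive_ev_variability(
    records: Sequence[TrialRecord],
) -> Tuple[float, float, int]:
    """Mean +/- SEM of |EV_gamble(t) - EV_gamble(t-1)| within sessions.

    The offered gamble's EV is used on every trial (error trials still carry
    an offer).  REPEATED sequences give 0 within blocks, MIXED sequences a
    positive value, which is the signature difference between the designs.
    Returns (mean, sem, n_pairs).
    """
    by_session: dict[str, List[TrialRecord]] = {}
    for r in records:
        by_session.setdefault(r.session_id, []).append(r)
    diffs: List[float] = []
    for sid, recs in by_session.items():
        recs = sorted(recs, key=lambda r: r.trial_index)
        evs = [r.gamble.ev for r in recs]
        diffs.extend(abs(b - a) for a, b in zip(evs, evs[1:]))
    if not diffs:
        raise ValueError("need at least two trials in one session")
    arr = np.asarray(diffs)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return float(arr.mean()), sem, arr.size
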