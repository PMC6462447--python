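"""Core domain containers for binary gamble/safe choice tasks.

The experimental currency is juice volume in millilitres.  All rewards live in
[0, M_MAX] ml; gambles are discrete lotteries over such magnitudes, and a safe
reward is simply a degenerate gamble (one outcome with probability 1).
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

#: Largest deliverable reward (ml); utilities are anchored so u(M_MAX) = 1.
M_MAX = 0.5

_PROB_TOL = 1e-9


class Condition(str, enum.Enum):
    """Trial-sequence structure used during certainty-equivalent elicitation."""

    MIXED = "MIXED"
    REPEATED = "REPEATED"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Choice(str, enum.Enum):
    GAMBLE = "gamble"
    SAFE = "safe"
    NONE = "none"  # error trial: no choice was made


@dataclass(frozen=True)
class Gamble:
    """A discrete reward lottery: tuple of (magnitude_ml, probability) pairs.

    Probabilities must sum to 1; magnitudes lie in [0, M_MAX].  A safe reward
    is a Gamble with a single outcome of probability 1.
    """

    outcomes: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("gamble needs at least one outcome")
        total = 0.0
        for m, p in self.outcomes:
            if not (0.0 - _PROB_TOL <= p <= 1.0 + _PROB_TOL):
                raise ValueError(f"outcome probability {p} outside [0, 1]")
            if not (0.0 <= m <= M_MAX + _PROB_TOL):
                raise ValueError(f"magnitude {m} ml outside [0, {M_MAX}] ml")
            total += p
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"outcome probabilities sum to {total}, not 1")

    # -- constructors -----------------------------------------------------
    @staticmethod
    def from_probability(p: float, m: float = M_MAX) -> "Gamble":
        """The task's standard gamble: `m` ml with probability p, else 0 ml."""
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        if p >= 1.0:
            return Gamble(((m, 1.0),))
        if p <= 0.0:
            return Gamble(((0.0, 1.0),))
        return Gamble(((m, p), (0.0, 1.0 - p)))

    @staticmethod
    def safe(m: float) -> "Gamble":
        return Gamble(((m, 1.0),))

    # -- queries ----------------------------------------------------------
    @property
    def ev(self) -> float:
        """Expected value in ml."""
        return sum(m * p for m, p in self.outcomes)

    def support(self) -> Tuple[Tuple[float, float], ...]:
        """Distinct magnitudes with nonzero probability, sorted ascending."""
        merged: dict[float, float] = {}
        for m, p in self.outcomes:
            if p > _PROB_TOL:
                merged[m] = merged.get(m, 0.0) + p
        return tuple(sorted(merged.items()))

    @property
    def is_safe(self) -> bool:
        return len(self.support()) == 1

    @property
    def magnitude(self) -> float:
        """Magnitude of a safe reward; errors on genuine lotteries."""
        sup = self.support()
        if len(sup) != 1:
            raise ValueError("magnitude is only defined for safe rewards")
        return sup[0][0]

    def low_high(self) -> Tuple[float, float, float, float]:
        """(m_low, p_low, m_high, p_high) for a <=2-outcome lottery."""
        sup = self.support()
        if len(sup) == 1:
            ((m, p),) = sup
            return m, 0.0, m, p
        if len(sup) == 2:
            (m_lo, p_lo), (m_hi, p_hi) = sup
            return m_lo, p_lo, m_hi, p_hi
        raise ValueError("more than two distinct outcomes")

    @property
    def win_probability(self) -> float:
        """Probability of the highest outcome (the 'win' for history analyses)."""
        sup = self.support()
        return sup[-1][1]


@dataclass(frozen=True, eq=False)
class TrialRecord:
    """One binary-choice trial between a gamble and a safe reward."""

    session_id: str
    trial_index: int
    condition: Condition
    gamble: Gamble
    safe: Gamble
    gamble_side: Side
    chosen: Choice
    outcome_ml: float = math.nan
    rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if not self.safe.is_safe:
            raise ValueError("safe option must be a degenerate gamble")
        if self.chosen is Choice.NONE:
            if not math.isnan(self.outcome_ml):
                raise ValueError("error trials carry no outcome")
        else:
            opt = self.gamble if self.chosen is Choice.GAMBLE else self.safe
            mags = {m for m, _ in opt.outcomes}
            if not any(abs(self.outcome_ml - m) <= 1e-9 for m in mags):
                raise ValueError(
                    f"outcome {self.outcome_ml} ml is not an outcome of the chosen option"
                )

    def __eq__(self, other: object) -> bool:
        # field-wise equality with NaN-tolerant outcome comparison, so a
        # written-and-reread error trial compares equal to the original
        if not isinstance(other, TrialRecord):
            return NotImplemented
        same_outcome = (
            self.outcome_ml == other.outcome_ml
            or (math.isnan(self.outcome_ml) and math.isnan(other.outcome_ml))
        )
        return same_outcome and all(
            getattr(self, f) == getattr(other, f)
            for f in ("session_id", "trial_index", "condition", "gamble",
                      "safe", "gamble_side", "chosen", "rt_ms")
        )

    @property
    def valid(self) -> bool:
        return self.chosen is not Choice.NONE

    @property
    def chose_gamble(self) -> bool:
        return self.chosen is Choice.GAMBLE


@dataclass(frozen=True)
class SequencePlan:
    """Blueprint for one session's trial sequence."""

    condition: Condition
    gambles: Tuple[Gamble, ...]
    safe_levels: Tuple[float, ...]
    reps_per_pair: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_pair < 4:
            raise ValueError(
                "reps_per_pair must be >= 4 so the certainty-equivalent "
                "eligibility filter can be satisfied downstream"
            )
        if not self.gambles or not self.safe_levels:
            raise ValueError("plan needs at least one gamble and one safe level")

    @property
    def n_trials(self) -> int:
        return len(self.gambles) * len(self.safe_levels) * self.reps_per_pair


_FAMILY_SHAPE_PARAMS = {
    "prelec1": ("alpha",),
    "prelec2": ("alpha", "beta"),
    "tversky": ("epsilon",),
    "gonzalez": ("gamma", "delta"),
}


@dataclass(frozen=True)
class CPTParams:
    """Parameters of the softmax + power-utility + probability-weighting model.

    `family` selects the weighting function; exactly the parameters of the
    declared family may be set.  `k` is the optional attention weight applied
    to the safe option's value (k = 0.5 means equal weighting).
    """

    family: str
    lam: float
    rho: float
    alpha: Optional[float] = None
    beta: Optional[float] = None
    epsilon: Optional[float] = None
    gamma: Optional[float] = None
    delta: Optional[float] = None
    k: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_SHAPE_PARAMS:
            raise ValueError(f"unknown weighting family {self.family!r}")
        if self.lam < 0:
            raise ValueError("softmax lambda must be >= 0")
        if self.rho <= 0:
            raise ValueError("utility exponent rho must be > 0")
        needed = _FAMILY_SHAPE_PARAMS[self.family]
        for name in ("alpha", "beta", "epsilon", "gamma", "delta"):
            value = getattr(self, name)
            if name in needed:
                if value is None:
                    raise ValueError(f"family {self.family!r} requires {name}")
                if value <= 0:
                    raise ValueError(f"{name} must be > 0")
            elif value is not None:
                raise ValueError(f"family {self.family!r} does not take {name}")
        if self.k is not None and not 0.0 < self.k < 1.0:
            raise ValueError("attention weight k must lie in (0, 1)")

    @property
    def shape_names(self) -> Tuple[str, ...]:
        return _FAMILY_SHAPE_PARAMS[self.family]

    @property
    def shape_values(self) -> Tuple[float, ...]:
        return tuple(getattr(self, name) for name in self.shape_names)

    @property
    def free_names(self) -> Tuple[str, ...]:
        names: Tuple[str, ...] = ("lam", "rho") + self.shape_names
        if self.k is not None:
            names += ("k",)
        return names

    @property
    def n_free(self) -> int:
        return len(self.free_names)


@dataclass(frozen=True)
class RLParams:
    """Value-updating agent: softmax temperature (per ml) and update step eta (ml).

    eta's sign is unconstrained; positive eta adds value after a gamble win and
    removes it after a loss.
    """

    lam: float
    eta: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("softmax lambda must be >= 0")
        if not math.isfinite(self.eta):
            raise ValueError("eta must be finite")
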