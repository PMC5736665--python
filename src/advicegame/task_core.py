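"""Domain types and deterministic mechanics of the two-adviser urn game.

A client searches for a coin hidden in a black or white urn and follows one
of two advisers.  Both advisers see probabilistic evidence — a grid of 100
black/white squares whose colour ratio equals the probability that the coin
is in the black urn — and declare advice on a 10-level signed confidence
scale running from "definitely black" (5B) to "definitely white" (5W).

This module holds the pure, deterministic primitives: the confidence scale,
the evidence grid, the prognostic-value mappings used by the client, the
advice-deviance measure (how far expressed confidence departs from the
confidence the evidence warrants), and the evidence-degradation rule used to
selectively weaken one adviser's information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Urn = Literal["black", "white"]

#: Squares per evidence grid.
GRID_SIZE = 100

#: Contrast reduction (in squares) applied on degraded trials.
DEFAULT_REDUCTION = 20


@dataclass(frozen=True)
class Advice:
    """A signed confidence report: urn plus confidence level 1-5.

    The signed coding is negative for black and positive for white, so the
    ten admissible values are {-5..-1} ∪ {1..5}; zero is not a valid report.
    """

    urn: Urn
    level: int

    def __post_init__(self) -> None:
        if self.urn not in ("black", "white"):
            raise ValueError(f"invalid urn {self.urn!r}")
        if not 1 <= int(self.level) <= 5:
            raise ValueError(f"confidence level must be in 1..5, got {self.level}")

    @property
    def signed(self) -> int:
        """Signed confidence: -level if black, +level if white."""
        return -self.level if self.urn == "black" else self.level

    @classmethod
    def from_signed(cls, signed: int) -> "Advice":
        signed = int(signed)
        if signed == 0 or abs(signed) > 5:
            raise ValueError(f"signed advice must be in ±1..±5, got {signed}")
        return cls(urn="black" if signed < 0 else "white", level=abs(signed))


@dataclass(frozen=True)
class EvidenceGrid:
    """A grid of black and white squares; the black fraction is the
    probability that the coin is in the black urn."""

    n_black: int
    n_white: int

    def __post_init__(self) -> None:
        if self.n_black < 0 or self.n_white < 0:
            raise ValueError("square counts must be non-negative")
        if self.n_black + self.n_white != GRID_SIZE:
            raise ValueError(
                f"grid must contain {GRID_SIZE} squares, got "
                f"{self.n_black}+{self.n_white}"
            )

    @property
    def p_black(self) -> float:
        return self.n_black / (self.n_black + self.n_white)

    @classmethod
    def from_p_black(cls, p_black: float) -> "EvidenceGrid":
        n_black = round(p_black * GRID_SIZE)
        return cls(n_black=n_black, n_white=GRID_SIZE - n_black)


@dataclass(frozen=True)
class Outcome:
    """Revealed coin location plus both advisers' accuracies (+1/-1)."""

    coin_urn: Urn
    accuracy_P: int
    accuracy_R: int

    def __post_init__(self) -> None:
        if self.accuracy_P not in (1, -1) or self.accuracy_R not in (1, -1):
            raise ValueError("accuracies must be +1 or -1")


@dataclass(frozen=True)
class TrialRecord:
    """Full event log of one trial, in stage order: the client's appraisal
    (selection), the evidence each adviser saw (possibly degraded), both
    advice reports, and the resolved outcome."""

    t: int
    selection: Literal["participant", "rival"]
    grid_P: EvidenceGrid
    grid_R: EvidenceGrid
    advice_P: Advice
    advice_R: Advice
    outcome: Outcome
    degraded: Literal["none", "participant", "rival"] = "none"

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("trial index is 1-based")
        if self.selection not in ("participant", "rival"):
            raise ValueError(f"invalid selection {self.selection!r}")
        if self.degraded not in ("none", "participant", "rival"):
            raise ValueError(f"invalid degraded flag {self.degraded!r}")
        for adv, acc in ((self.advice_P, self.outcome.accuracy_P),
                         (self.advice_R, self.outcome.accuracy_R)):
            expect = 1 if adv.urn == self.outcome.coin_urn else -1
            if acc != expect:
                raise ValueError(
                    f"trial {self.t}: accuracy {acc} inconsistent with advice "
                    f"urn {adv.urn} and coin in {self.outcome.coin_urn}"
                )


def prognostic_value(advice: Advice, accuracy: int) -> int:
    """Confidence level multiplied by accuracy (+1 correct, -1 wrong).

    Measures how usefully an advice predicted the outcome: a confident and
    correct advice earns +5, a confident and wrong one -5.
    """
    if accuracy not in (1, -1):
        raise ValueError("accuracy must be +1 or -1")
    return advice.level * accuracy


def client_pa(advice: Advice) -> int:
    """The client's prognostic-value-of-advice (PA) code on a 1-10 scale.

    Black advice (signed -5..-1) maps to 1..5 via ``signed + 6``; white
    advice (signed 1..5) maps to 6..10 via ``signed + 5``.  The map is a
    strictly increasing bijection from the ten signed levels onto 1..10.
    """
    s = advice.signed
    return s + 6 if s < 0 else s + 5


def expected_confidence(p_black: float) -> tuple[str, float]:
    """Zero-deviance policy: the (direction, confidence) the evidence warrants.

    Confidence is anchored linearly between the two calibration points of a
    perfectly evidence-committed adviser: chance evidence (p = 0.5) warrants
    the lowest confidence level 1, certain evidence (p = 0 or 1) warrants the
    top level 5.  Hence ``c* = 1 + 8 (p_maj - 0.5)`` with p_maj the majority
    colour's probability.  At exactly p = 0.5 the direction is ``"tie"``.
    """
    if not 0.0 <= p_black <= 1.0:
        raise ValueError(f"p_black must be in [0, 1], got {p_black}")
    p_maj = max(p_black, 1.0 - p_black)
    c_star = 1.0 + 8.0 * (p_maj - 0.5)
    if p_black > 0.5:
        direction = "black"
    elif p_black < 0.5:
        direction = "white"
    else:
        direction = "tie"
    return direction, c_star


def advice_deviance(advice: Advice, p_black: float) -> float:
    """Signed departure of expressed confidence from warranted confidence.

    The advice is projected onto the evidence-favoured direction (+level if
    it backs the majority urn, -level otherwise) and the warranted confidence
    c* is subtracted; positive values mean overconfidence.  At chance
    evidence (p = 0.5) neither urn is favoured, so only the expressed
    magnitude can deviate: the deviance is ``level - 1``.
    """
    direction, c_star = expected_confidence(p_black)
    if direction == "tie":
        return float(advice.level - 1)
    projection = advice.level if advice.urn == direction else -advice.level
    return projection - c_star


def degrade_evidence(grid: EvidenceGrid, reduction: int = DEFAULT_REDUCTION) -> EvidenceGrid:
    """Reduce the grid's contrast by moving ``reduction`` squares from the
    majority to the minority colour; a 50/50 grid is returned unchanged.

    This makes the square ratio a poor predictor of the coin location for
    whichever adviser receives the degraded grid.
    """
    if reduction < 0:
        raise ValueError("reduction must be non-negative")
    if grid.n_black == grid.n_white:
        return grid
    if grid.n_black > grid.n_white:
        new_black = grid.n_black - reduction
    else:
        new_black = grid.n_black + reduction
    new_white = GRID_SIZE - new_black
    if new_black < 0 or new_white < 0:
        raise ValueError(
            f"reduction {reduction} drives a square count below zero for "
            f"grid {grid.n_black}/{grid.n_white}"
        )
    return EvidenceGrid(n_black=new_black, n_white=new_white)


def resolve_outcome(
    advice_P: Advice,
    advice_R: Advice,
    selection: str,
    coin_urn: Urn,
) -> tuple[Outcome, Urn]:
    """Resolve a trial: the urn advised by the selected adviser is opened and
    both accuracies are scored against the true coin location.

    Returns the outcome and the opened urn.
    """
    if selection not in ("participant", "rival"):
        raise ValueError(f"invalid selection {selection!r}")
    opened = advice_P.urn if selection == "participant" else advice_R.urn
    outcome = Outcome(
        coin_urn=coin_urn,
        accuracy_P=1 if advice_P.urn == coin_urn else -1,
        accuracy_R=1 if advice_R.urn == coin_urn else -1,
    )
    return outcome, opened
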