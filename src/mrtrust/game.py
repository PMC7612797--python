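"""Rules of the 10-round investor-trustee game (MRT).

Each round the investor receives an endowment of 20 coins and transfers some
of it; the transfer is tripled and the trustee chooses how much of the tripled
amount to return.  Play is analysed on a coarse action grid: investments are
binned to the five nominal amounts {0, 5, 10, 15, 20} and returns to the five
fractions {0, 1/6, 1/3, 1/2, 2/3} of the tripled investment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ENDOWMENT = 20
N_ROUNDS = 10

#: Nominal investment bins (coins).
INVESTOR_BINS = (0, 5, 10, 15, 20)
#: Inclusive raw-coin ranges mapped onto each bin.
INVESTOR_BIN_RANGES = ((0, 2), (3, 7), (8, 12), (13, 17), (18, 20))
#: Return fractions of the tripled investment.
RETURN_FRACTIONS = (0.0, 1 / 6, 1 / 3, 1 / 2, 2 / 3)

N_ACTIONS = len(INVESTOR_BINS)


class InvalidTrajectoryError(ValueError):
    """A recorded action violates the rules of the game."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def return_amounts(a_i: int) -> tuple[int, ...]:
    """Coin amounts implied by each return fraction for investment bin ``a_i``.

    All five entries are 0 when ``a_i`` is 0 (the trustee has nothing to act
    on); otherwise the five amounts are distinct on the nominal bins.
    """
    tripled = 3 * a_i
    return tuple(_round_half_up(f * tripled) for f in RETURN_FRACTIONS)


def legal_returns(a_i: int) -> tuple[int, ...]:
    """The distinct legal (binned) return amounts for investment bin ``a_i``."""
    return tuple(sorted(set(return_amounts(a_i))))


def discretize_investment(raw: int) -> int:
    """Map a raw investment (whole coins, 0..20) to its nominal bin."""
    if not float(raw).is_integer():
        raise InvalidTrajectoryError(f"investment must be a whole number of coins, got {raw!r}")
    raw = int(raw)
    if not 0 <= raw <= ENDOWMENT:
        raise InvalidTrajectoryError(f"investment {raw} outside the endowment [0, {ENDOWMENT}]")
    for nominal, (lo, hi) in zip(INVESTOR_BINS, INVESTOR_BIN_RANGES):
        if lo <= raw <= hi:
            return nominal
    raise AssertionError("bin ranges partition [0, 20]")  # pragma: no cover


def discretize_return(raw_return: int, a_i: int) -> int:
    """Map a raw trustee return to the nearest fraction-grid amount.

    ``a_i`` is the (already binned) investment.  Ties round toward the lower
    fraction; returns above 2/3 of the tripled investment clamp to the 2/3 bin.
    """
    if a_i not in INVESTOR_BINS:
        raise InvalidTrajectoryError(f"{a_i} is not a nominal investment bin")
    if raw_return < 0 or raw_return > 3 * a_i:
        raise InvalidTrajectoryError(
            f"return {raw_return} outside [0, {3 * a_i}] for investment {a_i}"
        )
    if a_i == 0:
        return 0
    amounts = return_amounts(a_i)
    best = amounts[0]
    best_dist = abs(raw_return - best)
    for amt in amounts[1:]:
        d = abs(raw_return - amt)
        if d < best_dist:  # strict: ties stay with the lower fraction
            best, best_dist = amt, d
    return best


def return_fraction_index(a_i: int, a_t: int) -> int:
    """Index on the fraction grid of a binned return ``a_t`` (lowest on ties)."""
    amounts = return_amounts(a_i)
    for idx, amt in enumerate(amounts):
        if amt == a_t:
            return idx
    raise InvalidTrajectoryError(f"return {a_t} is not on the grid for investment {a_i}")


def round_outcomes(a_i: int, a_t: int) -> tuple[int, int]:
    """Monetary round outcomes (investor, trustee) for a legal action pair."""
    if a_i not in INVESTOR_BINS:
        raise InvalidTrajectoryError(f"{a_i} is not a nominal investment bin")
    if a_t not in return_amounts(a_i):
        raise InvalidTrajectoryError(f"return {a_t} illegal for investment {a_i}")
    chi_i = ENDOWMENT - a_i + a_t
    chi_t = 3 * a_i - a_t
    return chi_i, chi_t


@dataclass(frozen=True)
class RoundRecord:
    """One completed exchange: binned investment and binned return."""

    round_index: int
    a_i: int
    a_t: int

    def __post_init__(self) -> None:
        if not 1 <= self.round_index <= N_ROUNDS:
            raise InvalidTrajectoryError(f"round index {self.round_index} outside 1..{N_ROUNDS}")
        round_outcomes(self.a_i, self.a_t)  # validates the pair


@dataclass
class History:
    """Ordered record of completed rounds, indices contiguous from 1."""

    rounds: list[RoundRecord] = field(default_factory=list)

    def append(self, a_i: int, a_t: int) -> None:
        self.rounds.append(RoundRecord(len(self.rounds) + 1, a_i, a_t))

    def __len__(self) -> int:
        return len(self.rounds)

    def __iter__(self):
        return iter(self.rounds)

    def validate(self) -> None:
        for pos, rec in enumerate(self.rounds, start=1):
            if rec.round_index != pos:
                raise InvalidTrajectoryError(
                    f"round indices not contiguous: expected {pos}, got {rec.round_index}"
                )

    def total_investment(self) -> int:
        return sum(r.a_i for r in self.rounds)

    def total_earnings(self) -> int:
        return sum(round_outcomes(r.a_i, r.a_t)[0] for r in self.rounds)
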