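"""Subjective utilities: Fehr-Schmidt advantageous-inequality aversion (guilt)
plus multiplicative risk aversion on the investor's kept endowment.

The investor values the coins she keeps with weight ``omega`` (risk aversion:
omega > 1 favours the certain kept amount over the uncertain repayment) and
pays a guilt penalty ``alpha`` per coin by which her subjective outcome exceeds
the trustee's.  The trustee has no kept-endowment term — all his money flows
through the exchange — so his utility carries guilt only.
"""

from __future__ import annotations

from .game import ENDOWMENT, INVESTOR_BINS, return_amounts

#: Inequality-aversion (guilt) grid.
ALPHA_GRID = (0.0, 0.4, 1.0)
#: Risk-aversion grid (investor only; the trustee plays with omega = 1).
OMEGA_GRID = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8)


class InvalidParamsError(ValueError):
    """A preference parameter is off its grid."""


def _check_grid(value: float, grid: tuple[float, ...], name: str) -> None:
    if not any(abs(value - g) < 1e-12 for g in grid):
        raise InvalidParamsError(f"{name}={value} not on grid {grid}")


def investor_utility(a_i: int, a_t: int, alpha: float, omega: float) -> float:
    """Subjective investor utility of a round (coins-equivalent).

    ``u = chi_true - alpha * max(chi_true - chi_T, 0)`` with
    ``chi_true = omega * (20 - a_i) + a_t`` and ``chi_T = 3 a_i - a_t``.
    The guilt comparison deliberately uses the omega-weighted outcome.
    """
    _check_grid(alpha, ALPHA_GRID, "alpha")
    _check_grid(omega, OMEGA_GRID, "omega")
    return _investor_utility_raw(a_i, a_t, alpha, omega)


def _investor_utility_raw(a_i: int, a_t: int, alpha: float, omega: float) -> float:
    chi_true = omega * (ENDOWMENT - a_i) + a_t
    chi_t = 3 * a_i - a_t
    return chi_true - alpha * max(chi_true - chi_t, 0.0)


def trustee_utility(a_i: int, a_t: int, alpha_t: float) -> float:
    """Subjective trustee utility: ``chi_T - alpha_T * max(chi_T - chi_I, 0)``."""
    _check_grid(alpha_t, ALPHA_GRID, "alpha_T")
    return _trustee_utility_raw(a_i, a_t, alpha_t)


def _trustee_utility_raw(a_i: int, a_t: int, alpha_t: float) -> float:
    chi_i = ENDOWMENT - a_i + a_t
    chi_t = 3 * a_i - a_t
    return chi_t - alpha_t * max(chi_t - chi_i, 0.0)


def best_immediate_return(a_i: int, alpha_t: float) -> int:
    """Utility-maximising legal return for a myopic trustee (lowest on ties)."""
    amounts = return_amounts(a_i)
    best, best_u = amounts[0], trustee_utility(a_i, amounts[0], alpha_t)
    for amt in amounts[1:]:
        u = trustee_utility(a_i, amt, alpha_t)
        if u > best_u + 1e-12:
            best, best_u = amt, u
    return best


__all__ = [
    "ALPHA_GRID",
    "OMEGA_GRID",
    "InvalidParamsError",
    "investor_utility",
    "trustee_utility",
    "best_immediate_return",
    "INVESTOR_BINS",
]
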