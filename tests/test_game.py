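import pytest
from hypothesis import given, settings, strategies as st

from mrtrust.game import (
    History,
    INVESTOR_BINS,
    InvalidTrajectoryError,
    discretize_investment,
    discretize_return,
    legal_returns,
    return_amounts,
    round_outcomes,
)


@pytest.mark.parametrize(
    "raw,expected",
    [(0, 0), (2, 0), (3, 5), (7, 5), (8, 10), (12, 10), (13, 15), (17, 15), (18, 20), (20, 20)],
)
def test_investment_binning(raw, expected):
    assert discretize_investment(raw) == expected


@pytest.mark.parametrize("bad", [-1, 21, 3.5])
def test_investment_binning_rejects_illegal(bad):
    with pytest.raises(InvalidTrajectoryError):
        discretize_investment(bad)


def test_investment_binning_idempotent_on_nominal_bins():
    for b in INVESTOR_BINS:
        assert discretize_investment(b) == b


@pytest.mark.parametrize(
    "raw,a_i,expected",
    [
        (10, 10, 10),  # exactly 1/3 of 30
        (25, 10, 20),  # above 2/3 clamps to the 2/3 bin
        (0, 0, 0),  # only legal action after a zero investment
        (4, 10, 5),  # nearest grid point
        (2, 10, 0),  # 2.5 would tie; 2 rounds down
    ],
)
def test_return_binning(raw, a_i, expected):
    assert discretize_return(raw, a_i) == expected


def test_return_binning_tie_goes_to_lower_fraction():
    # a_i=10: grid amounts 0,5,10,15,20; raw 7.5 is not integral, but raw
    # ties occur e.g. for a_i=15 (amounts 0,8,15,23,30): raw 4 -> 0 vs 8
    assert discretize_return(4, 15) == 0


@pytest.mark.parametrize("raw,a_i", [(31, 10), (-1, 10), (5, 0)])
def test_return_binning_rejects_illegal(raw, a_i):
    with pytest.raises(InvalidTrajectoryError):
        discretize_return(raw, a_i)


def test_legal_return_set_sizes():
    for a in INVESTOR_BINS:
        expected = 1 if a == 0 else 5
        assert len(legal_returns(a)) == expected


@pytest.mark.parametrize(
    "a_i,a_t,expected", [(10, 15, (25, 15)), (0, 0, (20, 0)), (20, 0, (0, 60))]
)
def test_round_outcomes(a_i, a_t, expected):
    assert round_outcomes(a_i, a_t) == expected


@given(
    a_idx=st.integers(0, 4),
    f_idx=st.integers(0, 4),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_money_conservation(a_idx, f_idx):
    """chi_I + chi_T = 20 + 2 a_I for every legal pair."""
    a_i = INVESTOR_BINS[a_idx]
    a_t = return_amounts(a_i)[f_idx]
    chi_i, chi_t = round_outcomes(a_i, a_t)
    assert chi_i + chi_t == 20 + 2 * a_i
    assert chi_i >= 0 and chi_t >= 0


def test_history_tracks_totals_and_validates():
    h = History()
    h.append(10, 15)
    h.append(0, 0)
    h.validate()
    assert h.total_investment() == 10
    assert h.total_earnings() == 25 + 20
    with pytest.raises(InvalidTrajectoryError):
        History([*h.rounds][::-1]).validate()
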