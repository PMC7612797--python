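"""Independent brute-force reference implementations used as test oracles.

Plain recursive enumeration with Python lists and dicts — no caching, no
vectorisation, no shortcut for state-free sub-models: every nested belief
state is advanced literally as defined.  Kept deliberately separate from the
engine so the two can only agree by computing the same quantities.
"""

from __future__ import annotations

import math

from mrtrust.game import INVESTOR_BINS, return_amounts
from mrtrust.preferences import ALPHA_GRID

ZETAS = (0.0, 0.25, 0.5, 0.75, 1.0)
EPS = 1e-9


def u_inv(a_i, a_t, alpha, omega):
    chi_true = omega * (20 - a_i) + a_t
    chi_t = 3 * a_i - a_t
    return chi_true - alpha * max(chi_true - chi_t, 0.0)


def u_tr(a_i, a_t, alpha_t):
    chi_i = 20 - a_i + a_t
    chi_t = 3 * a_i - a_t
    return chi_t - alpha_t * max(chi_t - chi_i, 0.0)


def softmax(xs):
    m = max(xs)
    zs = [math.exp(x - m) for x in xs]
    s = sum(zs)
    return [z / s for z in zs]


def params_dict(alpha, omega, k, planning, zeta, q, beta, role):
    return dict(alpha=alpha, omega=omega, k=k, planning=planning,
                zeta=zeta, q=q, beta=beta, role=role)


def partner_of(p, alpha, zeta):
    return params_dict(alpha, p["omega"], p["k"] - 1, p["planning"], zeta,
                       p["q"], p["beta"], "trustee" if p["role"] == "investor" else "investor")


def copy_state(st):
    if st is None:
        return None
    return dict(pa=list(st["pa"]), pz=list(st["pz"]), wp=list(st["wp"]),
                w=st["w"], partner=copy_state(st["partner"]))


def event(observed, expectation, w):
    if observed < expectation - EPS:
        return "escalate"
    return "deescalate" if w > 0 else "none"


def bump(w, zeta, ev):
    if ev == "escalate":
        return min(1.0, w + zeta)
    if ev == "deescalate":
        return max(0.0, w - zeta)
    return w


def irr_investor_policy(p):
    return softmax([p["beta"] * p["omega"] * (20 - a) for a in INVESTOR_BINS])


def irr_trustee_policy(p, a_idx):
    a = INVESTOR_BINS[a_idx]
    return softmax([p["beta"] * u_tr(a, amt, 0.0) for amt in return_amounts(a)])


def investor_policy(p, st, r, w):
    irr = irr_investor_policy(p)
    if p["k"] < 0:
        return irr
    q = investor_q(p, st, min(p["planning"], r), r)
    normal = softmax([p["beta"] * x for x in q])
    return [(1 - w) * n + w * i for n, i in zip(normal, irr)]


def investor_q(p, st, h, r):
    h = min(h, r)
    out = []
    for a_idx, a in enumerate(INVESTOR_BINS):
        pr = predictive_return(p, st, a_idx, r)
        amts = return_amounts(a)
        qa = sum(pr[f] * u_inv(a, amts[f], p["alpha"], p["omega"]) for f in range(5))
        if h > 1 and r > 1:
            for f in range(5):
                if pr[f] <= 1e-14:
                    continue
                nxt = advance_investor(p, st, a_idx, f, r)
                qa += pr[f] * investor_value(p, nxt, h - 1, r - 1)
        out.append(qa)
    return out


def investor_value(p, st, h, r):
    q = investor_q(p, st, h, r)
    normal = softmax([p["beta"] * x for x in q])
    irr = irr_investor_policy(p)
    w = st["w"]
    pol = [(1 - w) * n + w * i for n, i in zip(normal, irr)]
    return sum(pi * qi for pi, qi in zip(pol, q))


def predictive_return(p, st, a_idx, r):
    acc = [0.0] * 5
    for i, alpha_t in enumerate(ALPHA_GRID):
        for j, zeta_t in enumerate(ZETAS):
            pw = st["pa"][i] * st["pz"][j]
            if pw == 0.0:
                continue
            pol = trustee_policy(partner_of(p, alpha_t, zeta_t), st["partner"],
                                 a_idx, r, st["wp"][j])
            for f in range(5):
                acc[f] += pw * pol[f]
    s = sum(acc)
    return [x / s for x in acc]


def trustee_policy(p, st, a_idx, r, w):
    a = INVESTOR_BINS[a_idx]
    irr = irr_trustee_policy(p, a_idx)
    if p["k"] < 0:
        normal = softmax([p["beta"] * u_tr(a, amt, p["alpha"]) for amt in return_amounts(a)])
    else:
        q = trustee_q(p, st, a_idx, min(p["planning"], r), r, w)
        normal = softmax([p["beta"] * x for x in q])
    return [(1 - w) * n + w * i for n, i in zip(normal, irr)]


def trustee_q(p, st, a_idx, h, r, w):
    h = min(h, r)
    a = INVESTOR_BINS[a_idx]
    amts = return_amounts(a)
    q = [u_tr(a, amt, p["alpha"]) for amt in amts]
    if h > 1 and r > 1:
        exp_inv = expected_investment(p, st, r)
        ev = event(a, exp_inv, w)
        w2 = bump(w, p["zeta"], ev)
        for f in range(5):
            nxt = advance_trustee(p, st, a_idx, f, r, own=False)
            pv = predictive_invest(p, nxt, r - 1)
            v = 0.0
            for a2 in range(5):
                if pv[a2] <= 1e-14:
                    continue
                v += pv[a2] * trustee_value_given(p, nxt, a2, h - 1, r - 1, w2)
            q[f] += v
    return q


def trustee_value_given(p, st, a_idx, h, r, w):
    q = trustee_q(p, st, a_idx, h, r, w)
    normal = softmax([p["beta"] * x for x in q])
    irr = irr_trustee_policy(p, a_idx)
    pol = [(1 - w) * n + w * i for n, i in zip(normal, irr)]
    return sum(pi * qi for pi, qi in zip(pol, q))


def expected_investment(p, st, r):
    if p["k"] - 1 < 0:
        pv = irr_investor_policy(p)
    else:
        pv = predictive_invest(p, st, r)
    return sum(pv[a] * INVESTOR_BINS[a] for a in range(5))


def predictive_invest(p, st, r):
    if p["k"] - 1 < 0:
        return irr_investor_policy(p)
    acc = [0.0] * 5
    for i, alpha_i in enumerate(ALPHA_GRID):
        for j, zeta_i in enumerate(ZETAS):
            pw = st["pa"][i] * st["pz"][j]
            if pw == 0.0:
                continue
            pol = investor_policy(partner_of_inv(p, alpha_i, zeta_i), st["partner"],
                                  r, st["wp"][j])
            for a in range(5):
                acc[a] += pw * pol[a]
    s = sum(acc)
    return [x / s for x in acc]


def partner_of_inv(p, alpha, zeta):
    return params_dict(alpha, p["omega"], p["k"] - 1, p["planning"], zeta,
                       p["q"], p["beta"], "investor")


def advance_investor(p, st, a_idx, f_idx, r, own=True):
    a = INVESTOR_BINS[a_idx]
    amts = return_amounts(a)
    amt = amts[f_idx]
    new = copy_state(st)
    if a not in (0, 5):
        like = [[0.0] * 5 for _ in range(3)]
        for i, alpha_t in enumerate(ALPHA_GRID):
            for j, zeta_t in enumerate(ZETAS):
                pol = trustee_policy(partner_of(p, alpha_t, zeta_t), st["partner"],
                                     a_idx, r, st["wp"][j])
                like[i][j] = sum(pol[f] for f in range(5) if amts[f] == amt)
        joint = [[st["pa"][i] * st["pz"][j] * like[i][j] for j in range(5)] for i in range(3)]
        total = sum(map(sum, joint))
        if total > 1e-300:
            new["pa"] = [sum(joint[i]) / total for i in range(3)]
            new["pz"] = [sum(joint[i][j] for i in range(3)) / total for j in range(5)]
    exp_inv = trustee_model_expected_investment(p, st, r)
    new["wp"] = [
        bump(st["wp"][j], ZETAS[j], event(a, exp_inv, st["wp"][j])) for j in range(5)
    ]
    if own:
        pr = predictive_return(p, st, a_idx, r)
        exp_ret = sum(pr[f] * amts[f] for f in range(5))
        new["w"] = bump(st["w"], p["zeta"], event(amt, exp_ret, st["w"]))
    if st["partner"] is not None:
        new["partner"] = advance_trustee(partner_of(p, 0.0, 0.0), st["partner"],
                                         a_idx, f_idx, r, own=False)
    return new


def trustee_model_expected_investment(p, st, r):
    if p["k"] - 1 < 0:
        return sum(INVESTOR_BINS) / len(INVESTOR_BINS)
    return expected_investment(partner_of(p, 0.0, 0.0), st["partner"], r)


def advance_trustee(p, st, a_idx, f_idx, r, own=True):
    a = INVESTOR_BINS[a_idx]
    amts = return_amounts(a)
    new = copy_state(st)
    like = [[0.0] * 5 for _ in range(3)]
    for i, alpha_i in enumerate(ALPHA_GRID):
        for j, zeta_i in enumerate(ZETAS):
            pol = investor_policy(partner_of_inv(p, alpha_i, zeta_i), st["partner"],
                                  r, st["wp"][j])
            like[i][j] = pol[a_idx]
    joint = [[st["pa"][i] * st["pz"][j] * like[i][j] for j in range(5)] for i in range(3)]
    total = sum(map(sum, joint))
    if total > 1e-300:
        new["pa"] = [sum(joint[i]) / total for i in range(3)]
        new["pz"] = [sum(joint[i][j] for i in range(3)) / total for j in range(5)]
    if p["k"] - 1 < 0:
        exp_ret = sum(amts) / len(amts)
    else:
        pr = predictive_return(partner_of_inv(p, 0.0, 0.0), st["partner"], a_idx, r)
        exp_ret = sum(pr[f] * amts[f] for f in range(5))
    amt = amts[f_idx]
    new["wp"] = [
        bump(st["wp"][j], ZETAS[j], event(amt, exp_ret, st["wp"][j])) for j in range(5)
    ]
    if own:
        exp_inv = expected_investment(p, st, r)
        new["w"] = bump(st["w"], p["zeta"], event(a, exp_inv, st["w"]))
    if st["partner"] is not None:
        new["partner"] = advance_investor(partner_of_inv(p, 0.0, 0.0), st["partner"],
                                          a_idx, f_idx, r, own=False)
    return new


# ---------------------------------------------------------------------------
# small statistical oracles


def kendall_tau_b_bruteforce(x, y):
    """Tau-b by O(n^2) pair counting with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else float("nan")
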