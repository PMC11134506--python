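"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the closed-form code paths they check:
binding time courses are integrated with scipy's adaptive LSODA solver
on the raw mass-action ODEs, and competitive equilibria are solved by
bracketed root finding on the monotone free-protein mass balance.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from bindkin import RateConstants


@pytest.fixture
def default_rates() -> RateConstants:
    """kon 1e5 M^-1 s^-1, koff 0.01 s^-1 -> Kd 100 nM."""
    return RateConstants(kon=1e5, koff=0.01)


def ode_binding(p_total, l_total, kon_nm, koff, pl0, t_eval):
    """Integrate d[PL]/dt = kon(P-x)(L-x) - koff x at high accuracy."""

    def rhs(_t, y):
        x = y[0]
        return [kon_nm * (p_total - x) * (l_total - x) - koff * x]

    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        [pl0],
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
    )
    assert sol.success
    return sol.y[0]


def ode_competition(state0, ligand_rates, inhibitor_rates, t_eval):
    """Integrate the full five-species competitive mass-action system.

    ``state0`` = (p, l, i, pl, pi) at t = 0; returns an array of shape
    (5, len(t_eval)).
    """
    kon_l, koff_l = ligand_rates.kon_nm, ligand_rates.koff
    kon_i, koff_i = inhibitor_rates.kon_nm, inhibitor_rates.koff

    def rhs(_t, y):
        p, l, i, pl, pi = y
        v_l = kon_l * p * l - koff_l * pl
        v_i = kon_i * p * i - koff_i * pi
        return [-v_l - v_i, -v_l, -v_i, v_l, v_i]

    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        list(state0),
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
    )
    assert sol.success
    return sol.y


def brute_force_competition_equilibrium(p_total, l_total, i_total, kd, ki):
    """Competitive equilibrium via bracketed root finding on mass balance.

    The free protein p satisfies the strictly increasing balance
    ``p (1 + L_t/(kd+p) + I_t/(ki+p)) - P_t = 0`` on [0, P_t]; solved by
    brentq, then propagated to the other species.  Independent of the
    trigonometric cubic closed form.
    """

    def balance(p):
        return p + l_total * p / (kd + p) + i_total * p / (ki + p) - p_total

    if p_total == 0:
        p = 0.0
    else:
        p = brentq(balance, 0.0, p_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    pl = l_total * p / (kd + p)
    pi = i_total * p / (ki + p)
    return {"p": p, "l": l_total - pl, "i": i_total - pi, "pl": pl, "pi": pi}
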