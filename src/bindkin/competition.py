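"""Competitive binding: exact equilibria and kinetics.

One protein ``P`` with a single site binds a ligand ``L`` (constant
``Kd = koff_L/kon_L``) and a competitive inhibitor ``I``
(``Ki = koff_I/kon_I``) with no cooperativity:

.. math::

    P + L \\leftrightharpoons PL, \\qquad P + I \\leftrightharpoons PI.

Three routes to the behaviour of this system are provided.

**Equilibrium (exact).**  Mass balance reduces the equilibrium to a
cubic in the free protein ``p``:

.. math::

    p^3 + a p^2 + b p + c = 0

with ``a = Kd + Ki + L_t + I_t - P_t``,
``b = Ki (L_t - P_t) + Kd (I_t - P_t) + Kd Ki`` and
``c = -Kd Ki P_t``.  For positive totals the cubic has a unique root in
``[0, P_t]``, obtained here in trigonometric closed form with no
restriction on the relative concentrations.

**Association kinetics (analytical, pseudo-first order).**  When both
ligand and inhibitor stay far from depletion (<10% bound) and no
complex exists at time zero, the labeled-complex time course is the
classical double exponential in the fast/slow rates ``K_F``/``K_S``
(see :func:`motulsky_mahan_pl`).

**Kinetics without concentration restrictions (numerical).**  A
forward-Euler scheme on the full mass-action system, split into two
phases whose step sizes derive from the 99%-equilibrium times of the
two binary subreactions, handles association and dissociation (with
dilution at mixing) at any degree of depletion.  The simulated final
state is checked against the exact cubic equilibrium; a deviation above
0.1% flags the run as unconverged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._checks import require_nonnegative, require_positive
from .kinetics import (
    KineticSystem,
    RateConstants,
    pl_eq_second_order,
    time_to_fraction,
)

__all__ = [
    "CompetitionSystem",
    "CompetitionEquilibrium",
    "CompetitionTimeCourse",
    "wang_equilibrium",
    "motulsky_mahan_pl",
    "dilution_state",
    "simulate_competition",
]

DEFAULT_STEPS = {"association": 200_000, "dissociation": 400_000}


@dataclass(frozen=True)
class CompetitionSystem:
    """Protein, ligand and inhibitor with their rate constants.

    For association, ``p0``/``l0``/``i0`` are working concentrations
    after mixing and both complexes start at zero.  For dissociation,
    they are the *pre-mix* concentrations: protein and ligand are
    equilibrated first, then mixed with the inhibitor solution at volume
    ratio ``volume_ratio : 1`` (protein+ligand : inhibitor).
    """

    p0: float
    l0: float
    i0: float
    ligand_rates: RateConstants
    inhibitor_rates: RateConstants
    volume_ratio: float = 1.0

    def __post_init__(self) -> None:
        require_nonnegative("p0", self.p0)
        require_nonnegative("l0", self.l0)
        require_nonnegative("i0", self.i0)
        if self.volume_ratio < 1.0:
            raise ValueError("volume_ratio must be >= 1")

    @property
    def kd(self) -> float:
        return self.ligand_rates.kd

    @property
    def ki(self) -> float:
        return self.inhibitor_rates.kd


@dataclass(frozen=True)
class CompetitionEquilibrium:
    """Equilibrium concentrations (nM) of all five species."""

    p: float
    l: float
    i: float
    pl: float
    pi: float

    @property
    def p_total(self) -> float:
        return self.p + self.pl + self.pi

    @property
    def l_total(self) -> float:
        return self.l + self.pl

    @property
    def i_total(self) -> float:
        return self.i + self.pi


@dataclass(frozen=True)
class CompetitionTimeCourse:
    """Decimated trajectory of the two-phase numerical simulation."""

    t: np.ndarray
    p: np.ndarray
    l: np.ndarray
    i: np.ndarray
    pl: np.ndarray
    pi: np.ndarray
    phase_boundary: float
    converged: bool
    equilibrium: CompetitionEquilibrium  # exact (cubic) reference
    final: CompetitionEquilibrium  # simulated end state

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "p_nM": self.p,
                "l_nM": self.l,
                "i_nM": self.i,
                "pl_nM": self.pl,
                "pi_nM": self.pi,
            }
        )


def wang_equilibrium(p_total, l_total, i_total, kd, ki):
    """Exact competitive-binding equilibrium from total concentrations.

    Solves the mass-balance cubic for the free protein in trigonometric
    closed form and propagates to all five species.  Accepts scalars or
    broadcastable arrays; returns a :class:`CompetitionEquilibrium` of
    scalars or of arrays accordingly.  Valid for any non-negative totals
    and positive ``kd``, ``ki``.
    """
    p_total = np.asarray(p_total, dtype=float)
    l_total = np.asarray(l_total, dtype=float)
    i_total = np.asarray(i_total, dtype=float)
    if np.any(p_total < 0) or np.any(l_total < 0) or np.any(i_total < 0):
        raise ValueError("total concentrations must be >= 0")
    require_positive("kd", float(np.min(kd)) if np.ndim(kd) else kd)
    require_positive("ki", float(np.min(ki)) if np.ndim(ki) else ki)
    kd = np.asarray(kd, dtype=float)
    ki = np.asarray(ki, dtype=float)

    a = kd + ki + l_total + i_total - p_total
    b = ki * (l_total - p_total) + kd * (i_total - p_total) + kd * ki
    c = -kd * ki * p_total

    # Trigonometric solution of p^3 + a p^2 + b p + c = 0; for these
    # coefficients the discriminant admits three real roots of which
    # -a/3 + (2/3) sqrt(a^2-3b) cos(theta/3) is the physical one.
    q = a * a - 3.0 * b
    q = np.maximum(q, 0.0)
    sqrt_q = np.sqrt(q)
    num = -2.0 * a**3 + 9.0 * a * b - 27.0 * c
    denom = 2.0 * np.maximum(sqrt_q, 1e-300) ** 3
    theta = np.arccos(np.clip(num / denom, -1.0, 1.0))
    p = -a / 3.0 + (2.0 / 3.0) * sqrt_q * np.cos(theta / 3.0)
    p = np.clip(p, 0.0, p_total)

    # The trigonometric root cancels catastrophically when the free
    # protein is orders of magnitude below the dominant coefficients
    # (tiny protein against tight, concentrated competitors).  Polish it
    # on the equivalent -- and well-conditioned -- monotone mass-balance
    # form p*(1 + L/(kd+p) + I/(ki+p)) = P_total with a few Newton steps.
    for _ in range(4):
        g = p + l_total * p / (kd + p) + i_total * p / (ki + p) - p_total
        dg = 1.0 + l_total * kd / (kd + p) ** 2 + i_total * ki / (ki + p) ** 2
        p = np.clip(p - g / dg, 0.0, p_total)

    pl = l_total * p / (kd + p)
    pi = i_total * p / (ki + p)
    out = CompetitionEquilibrium(
        p=p, l=l_total - pl, i=i_total - pi, pl=pl, pi=pi
    )
    if p.ndim == 0:
        out = CompetitionEquilibrium(
            p=float(p), l=float(out.l), i=float(out.i),
            pl=float(pl), pi=float(pi),
        )
    return out


def motulsky_mahan_pl(
    t,
    p0: float,
    l0: float,
    i0: float,
    ligand_rates: RateConstants,
    inhibitor_rates: RateConstants,
):
    """Labeled complex [PL](t) by the pseudo-first-order competition model.

    Closed-form double exponential valid when both complexes start at
    zero and only a small fraction (<10%) of ligand and inhibitor ever
    binds, so free ligand and inhibitor hold at ``l0`` and ``i0``:

    ``KA = kon_L l0 + koff_L``, ``KB = kon_I i0 + koff_I``,
    ``S = sqrt((KA-KB)^2 + 4 kon_L kon_I l0 i0)``,
    ``K_F, K_S = (KA + KB +/- S)/2`` and

    .. math::

        [PL](t) = \\frac{k_{on,L} l_0 p_0}{K_F - K_S}\\Bigl[
            \\frac{k_{off,I}(K_F-K_S)}{K_F K_S}
            + \\frac{k_{off,I}-K_F}{K_F} e^{-K_F t}
            - \\frac{k_{off,I}-K_S}{K_S} e^{-K_S t}\\Bigr].

    With ``i0 = 0`` this collapses to the single-exponential
    pseudo-first-order association curve.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    require_nonnegative("i0", i0)
    kon_l, koff_l = ligand_rates.kon_nm, ligand_rates.koff
    kon_i, koff_i = inhibitor_rates.kon_nm, inhibitor_rates.koff
    ka = kon_l * l0 + koff_l
    kb = kon_i * i0 + koff_i
    s = np.sqrt((ka - kb) ** 2 + 4.0 * kon_l * kon_i * l0 * i0)
    kf = 0.5 * (ka + kb + s)
    ks = 0.5 * (ka + kb - s)
    pref = kon_l * l0 * p0 / (kf - ks)
    out = pref * (
        koff_i * (kf - ks) / (kf * ks)
        + (koff_i - kf) / kf * np.exp(-kf * t_arr)
        - (koff_i - ks) / ks * np.exp(-ks * t_arr)
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DilutionState:
    """Instantaneous concentrations at the moment of mixing (nM)."""

    p: float
    l: float
    pl: float
    i: float
    pi: float = 0.0


def dilution_state(p_eq: float, l_eq: float, pl_eq: float, i0: float, r: float) -> DilutionState:
    """Mix equilibrated protein+ligand with inhibitor at volume ratio r:1.

    Every pre-mix species is scaled by ``r/(r+1)`` and the inhibitor
    stock by ``1/(r+1)``; no protein-inhibitor complex exists yet and
    timing begins at the moment of mixing.
    """
    if r < 1.0:
        raise ValueError("volume ratio must be >= 1")
    f = r / (r + 1.0)
    return DilutionState(p=p_eq * f, l=l_eq * f, pl=pl_eq * f, i=i0 / (r + 1.0))


class SimulationInstabilityError(RuntimeError):
    """A species went negative during explicit stepping; increase steps."""


def _initial_state(system: CompetitionSystem, mode: str) -> tuple[DilutionState, float]:
    """Starting concentrations and the ligand-side 99% time for the mode."""
    if mode == "association":
        state = DilutionState(p=system.p0, l=system.l0, pl=0.0, i=system.i0)
        t99_l = time_to_fraction(
            KineticSystem(p0=system.p0, l0=system.l0, rates=system.ligand_rates), 0.99
        )
        return state, t99_l
    if mode == "dissociation":
        pl_eq = pl_eq_second_order(system.p0, system.l0, system.kd)
        state = dilution_state(
            p_eq=system.p0 - pl_eq,
            l_eq=system.l0 - pl_eq,
            pl_eq=pl_eq,
            i0=system.i0,
            r=system.volume_ratio,
        )
        # decay of the diluted complex toward its own two-species equilibrium
        sub = KineticSystem(
            p0=state.p, l0=state.l, rates=system.ligand_rates, pl_init=state.pl
        )
        x1, _ = sub.roots()
        if state.pl > x1:
            t99_l = time_to_fraction(sub, 0.99, "dissociation")
        else:  # dilution can leave the pair effectively at (or below) equilibrium
            t99_l = time_to_fraction(sub, 0.99, "association") if state.pl < x1 else (
                np.log(100.0) / system.ligand_rates.koff
            )
        return state, t99_l
    raise ValueError(f"unknown mode {mode!r}")


def simulate_competition(
    system: CompetitionSystem,
    mode: Literal["association", "dissociation"] = "association",
    steps_per_phase: int | None = None,
    max_output_rows: int = 2000,
) -> CompetitionTimeCourse:
    """Two-phase forward-Euler simulation of competitive binding.

    Within each step the on and off subprocesses of the two reactions
    are evaluated from the current concentrations and all five species
    are updated simultaneously.  Phase 1 runs to the smaller of the two
    binary 99%-equilibrium times; phase 2 continues to 10x the larger,
    each phase divided into ``steps_per_phase`` equal steps (defaults:
    200,000 for association, 400,000 for dissociation).  The final state
    is compared with the exact cubic equilibrium; ``converged`` is False
    if the simulated [PL] misses it by more than 0.1%.
    """
    if steps_per_phase is None:
        steps_per_phase = DEFAULT_STEPS[mode]
    if steps_per_phase < 1000:
        raise ValueError("steps_per_phase must be >= 1000")

    state, t99_l = _initial_state(system, mode)
    kon_l, koff_l = system.ligand_rates.kon_nm, system.ligand_rates.koff
    kon_i, koff_i = system.inhibitor_rates.kon_nm, system.inhibitor_rates.koff

    # 99% time of the protein+inhibitor binary association
    p_for_i = state.p + state.pl if mode == "association" else state.p
    if system.i0 > 0 and state.i > 0:
        t99_i = time_to_fraction(
            KineticSystem(p0=p_for_i, l0=state.i, rates=system.inhibitor_rates), 0.99
        )
    else:
        t99_i = t99_l

    phase1 = min(t99_l, t99_i)
    t_end = 10.0 * max(t99_l, t99_i)

    p_tot = state.p + state.pl + state.pi
    l_tot = state.l + state.pl
    i_tot = state.i + state.pi
    exact = wang_equilibrium(p_tot, l_tot, i_tot, system.kd, system.ki)

    p, l, i, pl, pi = state.p, state.l, state.i, state.pl, state.pi
    total_steps = 2 * steps_per_phase
    stride = max(1, total_steps // max_output_rows)
    ts, ps, ls, is_, pls, pis = ([] for _ in range(6))

    def record(t_now):
        ts.append(t_now)
        ps.append(p)
        ls.append(l)
        is_.append(i)
        pls.append(pl)
        pis.append(pi)

    t_now = 0.0
    record(t_now)
    step_index = 0
    for dur in (phase1, t_end - phase1):
        dt = dur / steps_per_phase
        for _ in range(steps_per_phase):
            on_l = kon_l * p * l * dt
            off_l = koff_l * pl * dt
            on_i = kon_i * p * i * dt
            off_i = koff_i * pi * dt
            pl += on_l - off_l
            pi += on_i - off_i
            p += off_l + off_i - on_l - on_i
            l += off_l - on_l
            i += off_i - on_i
            t_now += dt
            step_index += 1
            if min(p, l, i, pl, pi) < -1e-12:
                raise SimulationInstabilityError(
                    f"negative concentration at t={t_now:g}s; "
                    "increase steps_per_phase"
                )
            if step_index % stride == 0:
                record(t_now)
    if step_index % stride != 0:
        record(t_now)

    final = CompetitionEquilibrium(p=p, l=l, i=i, pl=pl, pi=pi)
    if exact.pl > 0:
        converged = abs(pl - exact.pl) <= 1e-3 * exact.pl
    else:
        converged = abs(pl) <= 1e-12
    return CompetitionTimeCourse(
        t=np.array(ts),
        p=np.array(ps),
        l=np.array(ls),
        i=np.array(is_),
        pl=np.array(pls),
        pi=np.array(pis),
        phase_boundary=phase1,
        converged=bool(converged),
        equilibrium=exact,
        final=final,
    )
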