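"""Closed-form kinetics of a single 1:1 protein-ligand pair.

The mass-action rate law for ``P + L <-> PL`` with complex concentration
``x`` and totals ``P_tot``, ``L_tot`` is

.. math::

    \\frac{dx}{dt} = k_{on}(P_{tot}-x)(L_{tot}-x) - k_{off}\\,x
                  = k_{on}(x - x_1)(x - x_2),

a Riccati equation whose right-hand side factors through the roots
``x_1 < x_2`` of ``x^2 - (P_tot + L_tot + K_d)x + P_tot L_tot = 0``.
The physical equilibrium is the smaller root ``x_1``; the solution from
any admissible initial complex ``x_0`` is

.. math::

    x(t) = \\frac{x_1 - x_2 Q_0 e^{-\\gamma t}}{1 - Q_0 e^{-\\gamma t}},
    \\qquad Q_0 = \\frac{x_1 - x_0}{x_2 - x_0},\\qquad
    \\gamma = k_{on}(x_2 - x_1),

which covers both association (``x_0 < x_1``) and dissociation toward a
new equilibrium after dilution (``x_0 > x_1``).  Under excess ligand the
process reduces to pseudo-first order with observed rate
``kobs = kon*[L]_0 + koff``, and ideal dissociation without rebinding is
a single exponential ``x(t) = x_0 e^{-koff t}``.

Concentrations are nM; times are seconds; ``kon`` is accepted in
M^-1 s^-1 and converted internally to nM^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._checks import require_nonnegative, require_positive

__all__ = [
    "KON_M_TO_NM",
    "RateConstants",
    "KineticSystem",
    "TimeCourse",
    "quadratic_roots",
    "pl_eq_second_order",
    "pl_eq_pseudo",
    "association_pl",
    "association_time",
    "pseudo_association_pl",
    "dissociation_pl",
    "time_to_fraction",
    "association_timecourse",
    "dissociation_timecourse",
    "iso_affinity_table",
]

#: multiply a kon in M^-1 s^-1 by this to obtain nM^-1 s^-1
KON_M_TO_NM = 1e-9

# Closed form loses precision when the quadratic roots nearly coalesce;
# below this separation (nM) the ODE is integrated numerically instead.
_ROOT_DEGENERACY_NM = 1e-9


@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rate constants of one binding pair.

    kon is in M^-1 s^-1, koff in s^-1.  ``kd`` (nM) and ``kobs`` derive
    from them.
    """

    kon: float
    koff: float

    def __post_init__(self) -> None:
        require_positive("kon", self.kon)
        require_positive("koff", self.koff)

    @property
    def kon_nm(self) -> float:
        """kon in nM^-1 s^-1."""
        return self.kon * KON_M_TO_NM

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant koff/kon, in nM."""
        return self.koff / self.kon_nm

    def kobs(self, l0: float) -> float:
        """Pseudo-first-order observed rate constant kon*[L]0 + koff (s^-1)."""
        return self.kon_nm * l0 + self.koff


@dataclass(frozen=True)
class KineticSystem:
    """Initial state of one binding reaction.

    ``p0`` and ``l0`` are the initial *free* protein and ligand (nM);
    ``pl_init`` is the initial complex (nM, default 0).  Totals are
    ``p0 + pl_init`` and ``l0 + pl_init``; both must be positive.
    """

    p0: float
    l0: float
    rates: RateConstants
    pl_init: float = 0.0

    def __post_init__(self) -> None:
        require_nonnegative("p0", self.p0)
        require_nonnegative("l0", self.l0)
        require_nonnegative("pl_init", self.pl_init)
        if self.p_total <= 0 or self.l_total <= 0:
            raise ValueError("total protein and ligand must both be positive")

    @property
    def p_total(self) -> float:
        return self.p0 + self.pl_init

    @property
    def l_total(self) -> float:
        return self.l0 + self.pl_init

    def roots(self) -> tuple[float, float]:
        return quadratic_roots(self.p_total, self.l_total, self.rates.kd)


@dataclass(frozen=True)
class TimeCourse:
    """Sampled concentration trajectory of one binding reaction."""

    t: np.ndarray
    pl: np.ndarray
    p: np.ndarray
    l: np.ndarray
    label: Literal["second_order", "pseudo_first_order", "dissociation"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "pl_nM": self.pl, "p_nM": self.p, "l_nM": self.l}
        )


def quadratic_roots(p0: float, l0: float, kd: float) -> tuple[float, float]:
    """Roots ``x1 < x2`` of ``x^2 - (p0+l0+kd) x + p0*l0 = 0`` (nM).

    ``x1`` is the equilibrium complex concentration, confined to
    ``(0, min(p0, l0))``; ``x2 > max(p0, l0)`` is unphysical but enters
    the closed-form time course.  Inputs are the *total* protein, total
    ligand and Kd, all positive.
    """
    require_positive("p0", p0)
    require_positive("l0", l0)
    require_positive("kd", kd)
    s = p0 + l0 + kd
    disc = s * s - 4.0 * p0 * l0
    # disc = (p0-l0)^2 + kd^2 + 2 kd (p0+l0) > 0 always
    assert disc > 0.0, "discriminant must be positive for positive inputs"
    sq = np.sqrt(disc)
    x2 = 0.5 * (s + sq)
    x1 = p0 * l0 / x2  # product of roots; avoids cancellation in s - sq
    return x1, x2


def pl_eq_second_order(p0: float, l0: float, kd: float) -> float:
    """Equilibrium complex (nM) with full depletion accounting (smaller root)."""
    return quadratic_roots(p0, l0, kd)[0]


def pl_eq_pseudo(p0: float, l0: float, kd: float) -> float:
    """Equilibrium complex (nM) under the constant-free-ligand approximation."""
    require_positive("p0", p0)
    require_positive("l0", l0)
    require_positive("kd", kd)
    return p0 * l0 / (l0 + kd)


def _riccati_params(system: KineticSystem) -> tuple[float, float, float, float]:
    x1, x2 = system.roots()
    gamma = system.rates.kon_nm * (x2 - x1)
    q0 = (x1 - system.pl_init) / (x2 - system.pl_init)
    return x1, x2, gamma, q0


def association_pl(t, system: KineticSystem):
    """Exact second-order complex concentration at time(s) ``t`` (s).

    Uses the closed-form Riccati solution with initial complex
    ``system.pl_init``; falls back to numerical integration if the two
    quadratic roots nearly coalesce.  Scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    x1, x2, gamma, q0 = _riccati_params(system)
    if x2 - x1 < _ROOT_DEGENERACY_NM:
        out = _association_pl_numeric(t_arr, system)
    else:
        e = q0 * np.exp(-gamma * t_arr)
        out = (x1 - x2 * e) / (1.0 - e)
    return out if out.ndim else float(out)


def _association_pl_numeric(t_arr: np.ndarray, system: KineticSystem) -> np.ndarray:
    from scipy.integrate import solve_ivp

    kon, koff = system.rates.kon_nm, system.rates.koff
    pt, lt = system.p_total, system.l_total

    def rhs(_t, y):
        x = y[0]
        return [kon * (pt - x) * (lt - x) - koff * x]

    flat = np.atleast_1d(t_arr).ravel()
    order = np.argsort(flat)
    t_end = float(flat[order[-1]]) if flat.size else 0.0
    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-30)),
        [system.pl_init],
        t_eval=flat[order],
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    out = np.empty_like(flat)
    out[order] = sol.y[0]
    return out.reshape(t_arr.shape)


def association_time(pl, system: KineticSystem):
    """Exact inverse of :func:`association_pl`: time (s) to reach ``pl`` (nM).

    Requires ``pl_init <= pl < x1`` (the equilibrium); for a dissociating
    system (``pl_init > x1``) requires ``x1 < pl <= pl_init``.
    """
    pl_arr = np.asarray(pl, dtype=float)
    x1, x2, gamma, q0 = _riccati_params(system)
    ascending = system.pl_init < x1
    if ascending:
        bad = (pl_arr < system.pl_init) | (pl_arr >= x1)
    else:
        bad = (pl_arr > system.pl_init) | (pl_arr <= x1)
    if np.any(bad):
        raise ValueError(
            f"pl must lie between pl_init={system.pl_init:g} and the "
            f"equilibrium {x1:g} nM (equilibrium excluded: reached only as t -> inf)"
        )
    out = np.log(q0 * (x2 - pl_arr) / (x1 - pl_arr)) / gamma
    return out if out.ndim else float(out)


def pseudo_association_pl(t, system: KineticSystem):
    """Pseudo-first-order complex concentration at time(s) ``t`` (s).

    ``pl(t) = pl_eq_pseudo * (1 - exp(-kobs t))`` with
    ``kobs = kon*l0 + koff``; valid for ligand in large excess and zero
    initial complex.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    plateau = pl_eq_pseudo(system.p_total, system.l0, system.rates.kd)
    out = plateau * (1.0 - np.exp(-system.rates.kobs(system.l0) * t_arr))
    return out if out.ndim else float(out)


def dissociation_pl(t, pl0: float, koff: float):
    """Ideal dissociation without rebinding: ``pl0 * exp(-koff t)`` (nM)."""
    require_positive("koff", koff)
    require_nonnegative("pl0", pl0)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = pl0 * np.exp(-koff * t_arr)
    return out if out.ndim else float(out)


def time_to_fraction(
    system: KineticSystem,
    f: float = 0.99,
    direction: Literal["association", "dissociation"] = "association",
) -> float:
    """Time (s) to cover fraction ``f`` of the gap to equilibrium.

    Association: time until ``pl = pl_init + f*(x1 - pl_init)``.
    Dissociation: time until ``pl`` has covered ``f`` of the drop from
    ``pl_init`` to the rebinding equilibrium ``x1`` implied by the free
    species present; when both free species are zero this reduces to the
    pure exponential ``ln(1/(1-f))/koff``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must be in (0, 1)")
    if direction == "association":
        x1, _ = system.roots()
        target = system.pl_init + f * (x1 - system.pl_init)
        return float(association_time(target, system))
    if direction == "dissociation":
        if system.p0 == 0.0 and system.l0 == 0.0:
            return float(np.log(1.0 / (1.0 - f)) / system.rates.koff)
        x1, _ = system.roots()
        if system.pl_init <= x1:
            raise ValueError(
                "dissociation requires pl_init above the equilibrium complex"
            )
        target = system.pl_init - f * (system.pl_init - x1)
        return float(association_time(target, system))
    raise ValueError(f"unknown direction {direction!r}")


def _timecourse_from_pl(system: KineticSystem, pl: np.ndarray, t: np.ndarray, label) -> TimeCourse:
    return TimeCourse(
        t=t,
        pl=pl,
        p=system.p_total - pl,
        l=system.l_total - pl,
        label=label,
    )


def association_timecourse(
    system: KineticSystem,
    n_points: int = 1000,
    shown_points: int | None = 990,
    endpoint_fraction: float = 0.99,
) -> TimeCourse:
    """Association curve generated by stepping [PL] and inverting for time.

    [PL] is stepped uniformly from ``pl_init`` toward the equilibrium; the
    final emitted point sits at ``endpoint_fraction`` of the gap (the full
    approach takes infinite time).  Stepping the concentration rather than
    time yields a grid that is dense exactly where the curve bends.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if shown_points is None:
        shown_points = n_points
    x1, _ = system.roots()
    pl_grid = np.linspace(system.pl_init, x1, n_points, endpoint=False)[:shown_points]
    t = np.empty_like(pl_grid)
    t[0] = 0.0
    if len(pl_grid) > 1:
        t[1:] = association_time(pl_grid[1:], system)
    # re-impose the stated endpoint fraction on the last emitted point
    target = system.pl_init + endpoint_fraction * (x1 - system.pl_init)
    if pl_grid[-1] < target:
        pl_grid = np.append(pl_grid, target)
        t = np.append(t, association_time(target, system))
    return _timecourse_from_pl(system, pl_grid, t, "second_order")


def dissociation_timecourse(
    pl0: float,
    koff: float,
    n_points: int = 1000,
    shown_points: int | None = 990,
) -> TimeCourse:
    """No-rebinding dissociation curve on a uniform descending [PL] grid."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if shown_points is None:
        shown_points = n_points
    pl = np.linspace(pl0, 0.0, n_points, endpoint=False)[:shown_points]
    t = np.empty_like(pl)
    t[0] = 0.0
    t[1:] = np.log(pl0 / pl[1:]) / koff
    return TimeCourse(
        t=t, pl=pl, p=pl0 - pl, l=pl0 - pl, label="dissociation"
    )


def iso_affinity_table(
    kon_set=(1e3, 1e4, 1e5, 1e6, 1e7, 1e8),
    koff_set=(1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6),
    p0: float = 100.0,
    l0: float = 150.0,
) -> pd.DataFrame:
    """Equilibrium and timing summary over a kon x koff grid.

    One row per (kon, koff) pair at fixed initial concentrations: Kd,
    equilibrium complex, and the times to 50% and 99% of equilibrium.
    Pairs on an iso-affinity diagonal (equal Kd) share pl_eq but differ
    in their time scales.
    """
    rows = []
    for kon in kon_set:
        for koff in koff_set:
            rates = RateConstants(kon=kon, koff=koff)
            system = KineticSystem(p0=p0, l0=l0, rates=rates)
            x1, _ = system.roots()
            rows.append(
                {
                    "kon_per_M_s": kon,
                    "koff_per_s": koff,
                    "kd_nM": rates.kd,
                    "pl_eq_nM": x1,
                    "t50_s": time_to_fraction(system, 0.50),
                    "t99_s": time_to_fraction(system, 0.99),
                }
            )
    return pd.DataFrame(rows)
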