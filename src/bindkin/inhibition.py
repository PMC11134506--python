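"""Theoretical inhibition curves, IC50 estimation and Ki back-calculation.

A dose-response competition experiment titrates the inhibitor and reads
out the surviving protein-ligand complex.  Two half-inhibition points
are distinguished: the **apparent IC50** is the *total* inhibitor
concentration at 50% inhibition of the blank control, while the **IC50**
proper is the *free* inhibitor concentration at that point -- they
differ whenever the protein sequesters a non-negligible share of the
inhibitor.

Three routes lead from an apparent IC50 back to the inhibitor constant
``Ki``:

Cheng-Prusoff
    ``Ki = IC50 / (1 + [L]_0/K_d)``; requires ligand and inhibitor in
    large excess over protein (so the apparent IC50 approximates IC50
    and ligand depletion is negligible).

Lin-Riggs
    accommodates ligand depletion (``[L]_0`` comparable to ``[P]_0``)
    but still approximates the free inhibitor at half-inhibition by the
    total, requiring ``[I]_0 >> [P]_0``.

Exact mass balance
    with ``pl50 = pl_control/2`` the free ligand, free protein and
    protein-inhibitor complex at half-inhibition follow exactly from
    the known ``[P]_0``, ``[L]_0`` and ``Kd``; subtracting ``[PI]``
    from the apparent IC50 gives the free inhibitor and hence
    ``Ki = p50 * i50 / pi50`` with no approximation.

The theoretical inhibition curve itself is generated by solving the
exact competitive equilibrium (cubic) on a dense grid of total
inhibitor; the grid range is seeded by the Cheng-Prusoff IC50 estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._checks import require_positive
from .competition import wang_equilibrium
from .kinetics import pl_eq_second_order

__all__ = [
    "IC50RangeError",
    "InhibitionCurve",
    "inhibition_curve",
    "cheng_prusoff_ki",
    "wang_group_ki",
    "lin_riggs_ki",
    "apparent_ic50_scan",
]


class IC50RangeError(ValueError):
    """50% inhibition is not bracketed by the inhibitor grid."""


@dataclass(frozen=True)
class InhibitionCurve:
    """Gridded theoretical inhibition curve (all concentrations nM)."""

    i0_grid: np.ndarray
    pl_eq: np.ndarray
    i_eq: np.ndarray
    pl_control: float
    apparent_ic50: float
    ic50: float
    mode: str

    @property
    def inhibition_fraction(self) -> np.ndarray:
        return 1.0 - self.pl_eq / self.pl_control

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i0_nM": self.i0_grid,
                "pl_eq_nM": self.pl_eq,
                "i_eq_nM": self.i_eq,
                "inhibition_fraction": self.inhibition_fraction,
            }
        )


def inhibition_curve(
    p0: float,
    l0: float,
    kd: float,
    ki: float,
    mode: Literal["association", "dissociation"] = "association",
    r: float = 2.0,
    n_grid: int = 20_001,
    max_factor: float = 100.0,
) -> InhibitionCurve:
    """Theoretical inhibition curve with apparent-IC50 and IC50 estimates.

    The total-inhibitor grid spans ``[0, max_factor * A]`` uniformly,
    where ``A = ki*(1 + l0/kd)`` is the Cheng-Prusoff pre-estimate of
    the IC50.  Each grid point is solved exactly via the competitive
    cubic on post-mixing totals.  In association mode ``p0``/``l0`` are
    working concentrations and the blank control is the inhibitor-free
    equilibrium; in dissociation mode ``p0``/``l0`` are pre-mix
    concentrations of the equilibrated pair, diluted by ``r/(r+1)`` at
    mixing (the grid then holds post-mixing inhibitor totals), and the
    blank control is the same dilution mixed with inhibitor-free
    solution.  The apparent IC50 is the grid ``[I]_0`` whose ``[PL]``
    lies closest to half the control (smallest index on ties); the IC50
    is the free inhibitor at that grid point.
    """
    require_positive("p0", p0)
    require_positive("l0", l0)
    require_positive("kd", kd)
    require_positive("ki", ki)
    if n_grid < 1000:
        raise ValueError("n_grid must be >= 1000 for a meaningful IC50 estimate")

    if mode == "association":
        p_tot, l_tot = p0, l0
    elif mode == "dissociation":
        f = r / (r + 1.0)
        p_tot, l_tot = p0 * f, l0 * f
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pl_control = pl_eq_second_order(p_tot, l_tot, kd)
    a_est = ki * (1.0 + l0 / kd)
    i0 = np.linspace(0.0, max_factor * a_est, n_grid)
    eq = wang_equilibrium(p_tot, l_tot, i0, kd, ki)

    target = 0.5 * pl_control
    if eq.pl[-1] > target:
        raise IC50RangeError(
            f"[PL] only falls to {eq.pl[-1]:.4g} nM at the top of the grid "
            f"(target {target:.4g} nM); increase max_factor"
        )
    idx = int(np.argmin(np.abs(eq.pl - target)))
    return InhibitionCurve(
        i0_grid=i0,
        pl_eq=eq.pl,
        i_eq=eq.i,
        pl_control=pl_control,
        apparent_ic50=float(i0[idx]),
        ic50=float(eq.i[idx]),
        mode=mode,
    )


def cheng_prusoff_ki(apparent_ic50: float, l0: float, kd: float) -> float:
    """Ki by Cheng-Prusoff: ``IC50 / (1 + l0/kd)`` (nM).

    Assumes the apparent IC50 approximates the true (free-inhibitor)
    IC50 and that ligand depletion is negligible ([L]0 >> [P]0,
    [I]0 >> [P]0).
    """
    require_positive("apparent_ic50", apparent_ic50)
    require_positive("l0", l0)
    require_positive("kd", kd)
    return apparent_ic50 / (1.0 + l0 / kd)


def _half_inhibition_state(p0: float, l0: float, kd: float) -> tuple[float, float, float]:
    """(pl50, p50, pi50-free part) of the mass balance at 50% inhibition."""
    pl_control = pl_eq_second_order(p0, l0, kd)
    pl50 = 0.5 * pl_control
    l50 = l0 - pl50
    p50 = kd * pl50 / l50
    pi50 = p0 - p50 - pl50
    return pl50, p50, pi50


def wang_group_ki(apparent_ic50: float, p0: float, l0: float, kd: float) -> float:
    """Ki from the apparent IC50 by exact mass balance (nM).

    At half-inhibition the complex is half the inhibitor-free control;
    free ligand, free protein and the protein-inhibitor complex follow
    exactly, the free inhibitor is the apparent IC50 minus the bound
    share, and ``Ki = p50 * i50 / pi50``.  No approximation is made, so
    this inverts the theoretical inhibition curve up to the resolution
    of the apparent-IC50 estimate itself.
    """
    require_positive("apparent_ic50", apparent_ic50)
    _, p50, pi50 = _half_inhibition_state(p0, l0, kd)
    if pi50 <= 0:
        raise ValueError(
            "no inhibitor is bound at half-inhibition; inputs are inconsistent"
        )
    i50 = apparent_ic50 - pi50
    if i50 <= 0:
        raise ValueError(
            f"apparent_ic50={apparent_ic50:g} nM is below the bound inhibitor "
            f"{pi50:g} nM at 50% inhibition; inputs are inconsistent"
        )
    return p50 * i50 / pi50


def lin_riggs_ki(apparent_ic50: float, p0: float, l0: float, kd: float) -> float:
    """Ki accommodating ligand depletion, with free inhibitor ~ total (nM).

    Identical mass-balance chain to :func:`wang_group_ki` except the
    free inhibitor at half-inhibition is approximated by the apparent
    IC50 itself (valid for [I]0 >> [P]0).
    """
    require_positive("apparent_ic50", apparent_ic50)
    _, p50, pi50 = _half_inhibition_state(p0, l0, kd)
    if pi50 <= 0:
        raise ValueError(
            "no inhibitor is bound at half-inhibition; inputs are inconsistent"
        )
    return p50 * apparent_ic50 / pi50


def apparent_ic50_scan(
    ki: float,
    kd_set,
    p0_set,
    l0_grid,
    n_grid: int = 20_001,
    max_factor: float = 100.0,
) -> pd.DataFrame:
    """Apparent IC50 / IC50 across experimental conditions.

    One row per (p0, kd, l0) combination at fixed inhibitor ``ki``;
    conditions whose 50% point escapes the grid are reported with NaN.
    """
    rows = []
    for p0 in p0_set:
        for kd in kd_set:
            for l0 in l0_grid:
                try:
                    curve = inhibition_curve(
                        p0, l0, kd, ki, n_grid=n_grid, max_factor=max_factor
                    )
                    app, ic = curve.apparent_ic50, curve.ic50
                    ratio = app / ic if ic > 0 else np.nan
                except IC50RangeError:
                    app = ic = ratio = np.nan
                rows.append(
                    {
                        "p0_nM": p0,
                        "kd_nM": kd,
                        "l0_nM": l0,
                        "apparent_ic50_nM": app,
                        "ic50_nM": ic,
                        "ratio": ratio,
                    }
                )
    return pd.DataFrame(rows)
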