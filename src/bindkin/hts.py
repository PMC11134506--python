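"""Sensitivity of a competition-based primary screen.

In a high-throughput primary screen each compound is tested once at a
single concentration ``[I]_0`` against a protein / labeled-probe pair.
The observable is the fraction of the blank-control complex that
survives, ``[PL]_eq/[PL]_0``.  This module maps that ratio over the
affinities a screen should detect: given the probe ``Kd``, the labeled
ligand total, the inhibitor dose, and a target baseline occupancy
``[PL]_0`` (set by choosing the protein total), the surviving fraction
is computed from the exact competitive equilibrium for every candidate
``Ki`` -- and, for probe selection, over a ``Kd x Ki`` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._checks import require_positive
from .competition import wang_equilibrium

__all__ = ["ScreenDesign", "required_ptotal", "screen_matrix", "kd_ki_matrix"]


def _default_ki_grid() -> np.ndarray:
    # 1 nM .. 100 uM, log-spaced
    return np.logspace(0.0, 5.0, 61)


def _default_pl0_fractions() -> np.ndarray:
    return np.round(np.arange(0.1, 0.95, 0.1), 10)


@dataclass(frozen=True)
class ScreenDesign:
    """Primary-screen conditions (concentrations nM).

    Defaults follow the canonical setup: probe Kd 100 nM, 10 nM total
    labeled ligand, 10 uM inhibitor dose, baseline occupancies spanning
    10-90% of the ligand.
    """

    kd: float = 100.0
    l_total: float = 10.0
    i0: float = 10_000.0
    pl0_fractions: np.ndarray = field(default_factory=_default_pl0_fractions)
    ki_grid: np.ndarray = field(default_factory=_default_ki_grid)

    def __post_init__(self) -> None:
        require_positive("kd", self.kd)
        require_positive("l_total", self.l_total)
        require_positive("i0", self.i0)
        fr = np.asarray(self.pl0_fractions, dtype=float)
        if np.any((fr <= 0) | (fr >= 1)):
            raise ValueError("pl0_fractions must lie in (0, 1)")


def required_ptotal(kd: float, l_total: float, pl0: float) -> float:
    """Total protein (nM) that puts the blank-control complex at ``pl0``.

    Inverts the binary mass balance:
    ``p_total = pl0 + kd*pl0/(l_total - pl0)``.
    """
    require_positive("kd", kd)
    require_positive("l_total", l_total)
    if not 0.0 < pl0 < l_total:
        raise ValueError("pl0 must lie in (0, l_total)")
    return pl0 + kd * pl0 / (l_total - pl0)


def screen_matrix(design: ScreenDesign) -> pd.DataFrame:
    """Surviving complex fraction over (Ki, baseline occupancy).

    Long-format table with columns ``ki_nM``, ``pl0_fraction``,
    ``pl_ratio`` where ``pl_ratio = [PL]_eq/[PL]_0`` in (0, 1].
    """
    rows = []
    for frac in np.asarray(design.pl0_fractions, dtype=float):
        pl0 = frac * design.l_total
        p_total = required_ptotal(design.kd, design.l_total, pl0)
        eq = wang_equilibrium(
            p_total, design.l_total, np.asarray(design.ki_grid) * 0 + design.i0,
            design.kd, np.asarray(design.ki_grid, dtype=float),
        )
        for ki, pl_eq in zip(np.asarray(design.ki_grid, dtype=float), eq.pl):
            rows.append(
                {"ki_nM": ki, "pl0_fraction": frac, "pl_ratio": pl_eq / pl0}
            )
    return pd.DataFrame(rows)


def kd_ki_matrix(
    l_total: float,
    i0: float,
    pl0_fraction: float,
    kd_grid,
    ki_grid,
) -> pd.DataFrame:
    """Surviving complex fraction over a Kd x Ki grid at fixed occupancy.

    For each probe ``Kd`` the protein total is re-derived to hold the
    baseline occupancy constant, so the matrix isolates the affinity
    trade-off: columns ``kd_nM``, ``ki_nM``, ``pl_ratio``.
    """
    if not 0.0 < pl0_fraction < 1.0:
        raise ValueError("pl0_fraction must lie in (0, 1)")
    rows = []
    pl0 = pl0_fraction * l_total
    for kd in np.asarray(kd_grid, dtype=float):
        p_total = required_ptotal(kd, l_total, pl0)
        eq = wang_equilibrium(
            p_total, l_total, np.full(len(np.atleast_1d(ki_grid)), i0),
            kd, np.asarray(ki_grid, dtype=float),
        )
        for ki, pl_eq in zip(np.asarray(ki_grid, dtype=float), np.atleast_1d(eq.pl)):
            rows.append({"kd_nM": kd, "ki_nM": ki, "pl_ratio": pl_eq / pl0})
    return pd.DataFrame(rows)
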