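"""Theoretical saturation curves and the apparent Kd.

In a saturation (titration) experiment one component -- here the protein,
at total concentration ``[P]_total`` -- is held fixed while the ligand is
titrated until the protein is nearly fully bound.  At equilibrium

.. math::

    K_d = \\frac{[P]_{eq}\\,[L]_{eq}}{[PL]_{eq}}

so for a chosen bound concentration ``[PL]`` the free and total ligand
follow from mass balance alone:

.. math::

    [L]_{eq} = \\frac{K_d\\,[PL]}{[P]_{total} - [PL]},\\qquad
    [L]_{total} = [L]_{eq} + [PL].

When half the protein is bound, ``[L]_eq = Kd`` and the *total* ligand at
that point is the **apparent Kd**, ``Kd + [P]_total/2``.  The apparent Kd
exceeds Kd whenever the fixed component depletes the ligand appreciably
(the "titration regime"); the ratio ``1 + [P]_total/(2 Kd)`` quantifies
the distortion and should stay below about 1.05 if the apparent Kd is to
stand in for Kd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._checks import require_positive, warn_concentration

__all__ = [
    "BindingSystem",
    "SaturationCurve",
    "TitrationVerdict",
    "saturation_curve",
    "apparent_kd",
    "titration_check",
]


@dataclass(frozen=True)
class BindingSystem:
    """A 1:1 protein-ligand pair at equilibrium.

    Parameters
    ----------
    p_total : float
        Total protein concentration in nM (> 0).
    kd : float
        Equilibrium dissociation constant in nM (> 0).
    """

    p_total: float
    kd: float

    def __post_init__(self) -> None:
        require_positive("p_total", self.p_total)
        require_positive("kd", self.kd)
        warn_concentration("p_total", self.p_total)
        warn_concentration("kd", self.kd)


@dataclass(frozen=True)
class SaturationCurve:
    """A gridded saturation curve; all concentrations in nM."""

    pl: np.ndarray
    l_free: np.ndarray
    l_total: np.ndarray
    fraction_bound: np.ndarray
    system: BindingSystem

    def __len__(self) -> int:
        return len(self.pl)


@dataclass(frozen=True)
class TitrationVerdict:
    """Outcome of the titration-regime diagnostic."""

    ratio: float
    max_ratio: float

    @property
    def ok(self) -> bool:
        return self.ratio < self.max_ratio

    @property
    def verdict(self) -> str:
        return "ok" if self.ok else "titration_regime"


def saturation_curve(
    system: BindingSystem,
    n_points: int = 1000,
    shown_points: int | None = 970,
) -> SaturationCurve:
    """Forward-compute the saturation curve on a uniform [PL] grid.

    The grid spans ``[0, p_total)`` -- protein unbound to near-fully
    bound.  The required free ligand diverges as ``[PL] -> p_total``, so
    by default only the first ``shown_points`` of ``n_points`` grid
    points are emitted, trimming the long tail; pass ``shown_points=None``
    for the full grid.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if shown_points is None:
        shown_points = n_points
    if shown_points > n_points:
        raise ValueError("shown_points must be <= n_points")

    pl = np.linspace(0.0, system.p_total, n_points, endpoint=False)
    pl = pl[:shown_points]
    l_free = system.kd * pl / (system.p_total - pl)
    l_total = l_free + pl
    return SaturationCurve(
        pl=pl,
        l_free=l_free,
        l_total=l_total,
        fraction_bound=pl / system.p_total,
        system=system,
    )


def apparent_kd(system: BindingSystem) -> float:
    """Total ligand concentration (nM) at half-maximal protein occupancy.

    Equals ``kd + p_total / 2``: free ligand must sit at Kd while half
    the protein sequesters ``p_total/2`` of the ligand.
    """
    return system.kd + system.p_total / 2.0


def titration_check(system: BindingSystem, max_ratio: float = 1.05) -> TitrationVerdict:
    """Diagnose whether the apparent Kd can stand in for Kd.

    The ratio ``apparent Kd / Kd = 1 + p_total/(2 kd)`` is compared with
    ``max_ratio`` (strictly below passes).
    """
    if not max_ratio > 1:
        raise ValueError("max_ratio must exceed 1")
    ratio = 1.0 + system.p_total / (2.0 * system.kd)
    return TitrationVerdict(ratio=ratio, max_ratio=max_ratio)
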