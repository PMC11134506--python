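"""Shared parameter validation helpers.

Concentrations are nanomolar throughout the library; rate constants are
accepted in the customary units (kon in M^-1 s^-1, koff in s^-1).  The
library itself only rejects physically meaningless input (non-positive
where positivity is required).  The looser "webpage" ranges that a bench
scientist would consider sane are surfaced as warnings here and enforced
as hard limits only by the command-line interface.
"""

from __future__ import annotations

import warnings

# Practical input ranges mirrored from the interactive front end.
CONC_RANGE_NM = (0.001, 50_000.0)
KOFF_RANGE = (1e-6, 1.0)
KON_RANGE = (1e3, 1e8)
VOLUME_RATIO_RANGE = (1.0, 1000.0)


class RangeWarning(UserWarning):
    """A parameter is outside the range the tool was designed around."""


def require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def require_nonnegative(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


def warn_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        warnings.warn(
            f"{name}={value:g} is outside the recommended range "
            f"[{lo:g}, {hi:g}]; results are still computed exactly",
            RangeWarning,
            stacklevel=3,
        )


def warn_concentration(name: str, value: float) -> None:
    warn_range(name, value, *CONC_RANGE_NM)
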