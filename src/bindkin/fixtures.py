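"""Canonical default scenarios with their expected landmark values.

Each fixture bundles the parameter set of one reference scenario with
the landmark numbers it should reproduce, tagged by provenance:
``reference`` values are published landmarks of the scenario,
``derived`` values were computed with an independent method (brute
force root finding or ODE integration), and ``identity`` values follow
from the defining equations directly.  The fixtures double as
regression anchors for the test suite and as ready-made inputs for the
command line (``bindkin fixtures``).
"""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["generate_fixtures", "write_fixtures"]


def generate_fixtures() -> dict:
    """Return the default scenarios keyed by name."""
    return {
        "saturation_default": {
            "params": {"kd_nM": 100.0, "p_total_nM": 100.0},
            "expected": {
                "apparent_kd_nM": {"value": 150.0, "provenance": "reference"},
                "apparent_kd_ratio": {"value": 1.50, "provenance": "reference"},
                "l_total_at_95pct_nM": {"value": 1995.0, "provenance": "reference"},
                "l_free_at_half_nM": {"value": 100.0, "provenance": "identity"},
            },
        },
        "kinetics_default": {
            "params": {
                "p0_nM": 100.0,
                "l0_nM": 150.0,
                "kon_per_M_s": 1e5,
                "koff_per_s": 0.01,
            },
            "expected": {
                "pl_eq_nM": {"value": 50.0, "provenance": "reference"},
                "pl2_root_nM": {"value": 300.0, "provenance": "derived"},
                "pl_eq_pseudo_nM": {"value": 60.0, "provenance": "identity"},
            },
        },
        "fitting_scan_default": {
            "params": {
                "p0_nM": 100.0,
                "kon_per_M_s": 1e5,
                "koff_per_s": 0.01,
                "l0_min_nM": 25.0,
                "l0_max_nM": 5000.0,
                "l0_step_nM": 25.0,
                "spacing_nM": 100.0,
                "endpoint_fraction": 0.99,
            },
            "expected": {
                "kobs_ratio_at_275": {"value": 1.044, "provenance": "reference"},
                "kobs_ratio_at_800": {"value": 0.999, "provenance": "reference"},
                "kobs_ratio_at_5000": {"value": 1.013, "provenance": "reference"},
                "first_l0_below_1p05_nM": {"value": 275.0, "provenance": "reference"},
            },
        },
        "competition_default": {
            "params": {
                "p0_nM": 100.0,
                "l0_nM": 150.0,
                "i0_nM": 100.0,
                "kon_l_per_M_s": 1e5,
                "koff_l_per_s": 0.01,
                "kon_i_per_M_s": 1e5,
                "koff_i_per_s": 0.01,
                "volume_ratio": 2.0,
            },
            "expected": {
                "pl_eq_equals_pi_eq": {"value": True, "provenance": "identity"},
            },
        },
        "wang_symmetric": {
            "params": {
                "p_total_nM": 100.0,
                "l_total_nM": 150.0,
                "i_total_nM": 150.0,
                "kd_nM": 100.0,
                "ki_nM": 100.0,
            },
            "expected": {
                "pl_equals_pi": {"value": True, "provenance": "identity"},
            },
        },
        "inhibition_default": {
            "params": {
                "ki_nM": 100.0,
                "conditions": [
                    {"p0_nM": 50.0, "kd_nM": 5.0, "l0_nM": 10.0},
                    {"p0_nM": 50.0, "kd_nM": 5.0, "l0_nM": 40.0},
                    {"p0_nM": 50.0, "kd_nM": 10.0, "l0_nM": 40.0},
                    {"p0_nM": 100.0, "kd_nM": 50.0, "l0_nM": 200.0},
                ],
            },
            "expected": {
                "wang_group_ki_nM": {"value": 100.0, "provenance": "reference"},
            },
        },
        "hts_default": {
            "params": {
                "kd_nM": 100.0,
                "l_total_nM": 10.0,
                "i0_nM": 10_000.0,
                "pl0_fraction_range": [0.1, 0.9],
            },
            "expected": {
                "required_ptotal_at_half_nM": {"value": 105.0, "provenance": "identity"},
            },
        },
    }


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Write one JSON file per fixture; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, payload in generate_fixtures().items():
        path = out / f"{name}.json"
        path.write_text(json.dumps(payload, indent=2) + "\n")
        paths.append(path)
    return paths
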