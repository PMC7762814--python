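"""Library of optimized 5-minute protocol timings.

These are the published optimized timings for each protocol family (CRLB
cost, uniform 0.5-2 s ATT prior, 300 s budget, 638 ms overhead, max LD
1.8 s): the set compared head-to-head in the Monte Carlo evaluation.  The
``expected`` table records each protocol's number of effective timepoints,
averages, acquired volumes and min:sec duration for cross-checking the
scan-time accounting.
"""

from __future__ import annotations

from typing import Dict

from .protocols import ProtocolSpec

__all__ = ["reference_protocols", "reference_expected", "COMPARISON_SET"]

#: protocols included in the simulation/in-vivo style comparison
COMPARISON_SET = (
    "single_pld",
    "seq_single_ld",
    "had_fixed",
    "had_t1adj",
    "had_freelunch",
    "hybrid_fixed",
    "hybrid_t1adj",
)

#: literature designs (everything except the novel hybrids)
LITERATURE_SET = (
    "single_pld",
    "seq_single_ld",
    "had_fixed",
    "had_t1adj",
    "had_freelunch",
)


def reference_protocols() -> Dict[str, ProtocolSpec]:
    """The optimized protocol set, timings in seconds (ms-exact)."""
    return {
        "single_pld": ProtocolSpec(
            "single_pld", lds=[1.8], plds=[2.0], n_ave=34
        ),
        "seq_single_ld": ProtocolSpec(
            "seq_single_ld",
            lds=[1.8],
            plds=[0.175, 1.050, 1.425, 1.725, 2.075, 2.200, 2.300, 2.300, 2.300],
            n_ave=4,
        ),
        "had_fixed": ProtocolSpec(
            "had_fixed", lds=[0.550] * 7, plds=[0.100], encoding_rows=8, n_ave=8
        ),
        "had_t1adj": ProtocolSpec(
            "had_t1adj",
            lds=[1.150, 0.675, 0.475, 0.375, 0.300, 0.250, 0.225],
            plds=[0.075],
            encoding_rows=8,
            n_ave=9,
        ),
        "had_freelunch": ProtocolSpec(
            "had_freelunch",
            lds=[1.800, 0.625, 0.450, 0.350, 0.300, 0.250, 0.225],
            plds=[0.125],
            encoding_rows=8,
            n_ave=8,
        ),
        "hybrid_fixed": ProtocolSpec(
            "hybrid_fixed",
            lds=[1.275] * 3,
            plds=[0.075, 0.150, 0.600, 0.850, 1.000],
            encoding_rows=4,
            n_ave=3,
        ),
        "hybrid_t1adj": ProtocolSpec(
            "hybrid_t1adj",
            lds=[1.800, 0.850, 0.550],
            plds=[0.200, 0.650, 0.900, 0.900],
            encoding_rows=4,
            n_ave=4,
        ),
        "had_variable": ProtocolSpec(
            "had_variable",
            lds=[1.725, 0.750, 0.650, 0.375, 0.150, 0.150, 0.125],
            plds=[0.100],
            encoding_rows=8,
            n_ave=8,
        ),
        "hybrid_variable": ProtocolSpec(
            "hybrid_variable",
            lds=[
                [1.800, 1.050, 0.775],
                [1.800, 1.225, 0.550],
                [1.800, 0.850, 0.750],
                [1.800, 0.800, 0.800],
            ],
            plds=[0.100, 0.525, 0.575, 0.700],
            encoding_rows=4,
            n_ave=4,
        ),
    }


def reference_expected() -> Dict[str, dict]:
    """Published N_T / N_Ave / N_Acq / duration for each reference protocol."""
    return {
        "single_pld": dict(n_t=1, n_ave=34, n_acq=68, duration="5:02"),
        "seq_single_ld": dict(n_t=7, n_ave=4, n_acq=72, duration="5:00"),
        "had_fixed": dict(n_t=7, n_ave=8, n_acq=64, duration="4:54"),
        "had_t1adj": dict(n_t=7, n_ave=9, n_acq=72, duration="5:00"),
        "had_freelunch": dict(n_t=7, n_ave=8, n_acq=64, duration="5:05"),
        "hybrid_fixed": dict(n_t=15, n_ave=3, n_acq=60, duration="5:00"),
        "hybrid_t1adj": dict(n_t=12, n_ave=4, n_acq=64, duration="4:48"),
        "had_variable": dict(n_t=7, n_ave=8, n_acq=64, duration="4:58"),
        "hybrid_variable": dict(n_t=12, n_ave=4, n_acq=64, duration="4:55"),
    }
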