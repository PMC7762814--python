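"""PCASL protocol families: timing schedules, Hadamard time-encoding and
scan-time accounting.

A protocol is a timing schedule (label durations, final post-labeling
delays), an optional Hadamard encoding and a number of averages.  The module
expands any protocol into its *effective timepoints* — the (LD, PLD) pairs of
the subtracted or decoded perfusion-weighted images, each with the noise
scale of the corresponding difference image — and computes the variable
minimum TR and total scan duration.

Families
--------
``single_pld``       one LD/PLD pair, label/control pairs.
``seq_single_ld``    one LD, N sequential PLDs.
``seq_multi_ld``     N LD/PLD pairs varied together.
``had_*``            Hadamard time-encoded: ``fixed`` (equal sub-boluses),
                     ``t1adj`` (equal decoded signal per sub-bolus),
                     ``freelunch`` (first sub-bolus mimics single-PLD),
                     ``variable`` (free sub-bolus durations).
``hybrid_*``         a time-encoded block repeated at N sequential final
                     PLDs (``fixed``/``t1adj``/``variable``); the variable
                     hybrid carries a separate LD block per PLD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence, Union

import numpy as np

__all__ = [
    "ProtocolSpec",
    "EffectiveTimepoint",
    "EncodingScheme",
    "ScanAccounting",
    "FAMILIES",
    "hadamard_scheme",
    "encode",
    "decode",
    "effective_timepoints",
    "timepoint_arrays",
    "t1_adjusted_lds",
    "free_lunch_lds",
    "scan_accounting",
    "duration_str",
]

SEQUENTIAL_FAMILIES = ("single_pld", "seq_single_ld", "seq_multi_ld")
ENCODED_FAMILIES = ("had_fixed", "had_t1adj", "had_freelunch", "had_variable")
HYBRID_FAMILIES = ("hybrid_fixed", "hybrid_t1adj", "hybrid_variable")
FAMILIES = SEQUENTIAL_FAMILIES + ENCODED_FAMILIES + HYBRID_FAMILIES

#: non-ASL time per TR (presaturation + readout), seconds
DEFAULT_OVERHEAD = 0.638


@dataclass(frozen=True)
class EffectiveTimepoint:
    """One decoded/subtracted difference image.

    ``noise_scale`` is the SD of the difference image in units of the
    per-volume noise SD: sqrt(2) for a label/control subtraction,
    2/sqrt(M+1) after decoding an (M+1) x M Hadamard encoding.
    """

    eff_ld: float
    eff_pld: float
    noise_scale: float


@dataclass(frozen=True)
class EncodingScheme:
    """A Hadamard label/control table and its linear decode weights.

    ``table`` is (M+1, M) with entries -1 (label) / +1 (control); its columns
    are mutually orthogonal and orthogonal to the all-ones vector.
    ``decode_weights`` is (M, M+1); applying it to the acquired volumes
    recovers each sub-bolus difference signal exactly in the noise-free case.
    """

    table: np.ndarray
    decode_weights: np.ndarray

    @property
    def m_sub(self) -> int:
        return self.table.shape[1]


def hadamard_scheme(m_sub: int) -> EncodingScheme:
    """Sylvester-construction Hadamard encoding with ``m_sub`` sub-boluses.

    Requires ``m_sub + 1`` to be a power of two (4x3 and 8x7 are the sizes
    used in practice).  -1 encodes label, +1 control; decode weights are
    ``(2/(M+1)) * column`` so decoded noise is 2*sigma/sqrt(M+1), uncorrelated
    across sub-boluses.
    """
    order = m_sub + 1
    if order < 4 or (order & (order - 1)) != 0:
        raise ValueError(
            f"no Sylvester Hadamard encoding with {m_sub} sub-boluses; "
            "supported sizes have m_sub + 1 a power of two >= 4 "
            "(e.g. 4x3, 8x7, 16x15)"
        )
    h = np.array([[1.0]])
    while h.shape[0] < order:
        h = np.block([[h, h], [h, -h]])
    signed = h[:, 1:]  # drop the all-ones column
    weights = (2.0 / order) * signed.T
    return EncodingScheme(table=signed.astype(int), decode_weights=weights)


def encode(differences, scheme: EncodingScheme, baseline: float = 0.0) -> np.ndarray:
    """Noise-free encoded volumes from per-sub-bolus difference signals.

    Each acquired volume is ``baseline`` minus the sum of the difference
    contributions of the sub-boluses labeled in that row (label/control
    additivity of sub-bolus contributions).
    """
    d = np.asarray(differences, dtype=float)
    if d.shape[-1] != scheme.m_sub:
        raise ValueError(
            f"expected {scheme.m_sub} sub-bolus differences, got {d.shape[-1]}"
        )
    labeled = (scheme.table == -1).astype(float)  # (M+1, M)
    return baseline - d @ labeled.T


def decode(volumes, scheme: EncodingScheme) -> np.ndarray:
    """Decode (M+1) acquired volumes into M sub-bolus difference signals."""
    v = np.asarray(volumes, dtype=float)
    if v.shape[-1] != scheme.m_sub + 1:
        raise ValueError(
            f"expected {scheme.m_sub + 1} volumes, got {v.shape[-1]}"
        )
    return v @ scheme.decode_weights.T


@dataclass(frozen=True)
class ProtocolSpec:
    """A protocol family plus its timing schedule.

    ``lds`` holds the label durations in chronological order: one per
    LD/PLD pair for sequential families, the M sub-bolus durations for
    encoded/hybrid families, or one list of M durations per final PLD for
    ``hybrid_variable``.  ``plds`` are the final post-labeling delays.
    ``encoding_rows`` is M+1 for encoded families and 1 otherwise.
    """

    family: str
    lds: Union[Sequence[float], Sequence[Sequence[float]]]
    plds: Sequence[float]
    encoding_rows: int = 1
    n_ave: int = 1
    overhead: float = DEFAULT_OVERHEAD

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown protocol family {self.family!r}")
        if len(self.plds) == 0:
            raise ValueError("plds must be non-empty")
        if len(self.lds) == 0:
            raise ValueError("lds must be non-empty")
        if self.n_ave < 1 or int(self.n_ave) != self.n_ave:
            raise ValueError("n_ave must be a positive integer")
        if self.family == "hybrid_variable":
            blocks = self.ld_blocks()
            if len(blocks) != len(self.plds):
                raise ValueError("hybrid_variable needs one LD block per PLD")
            m = {len(b) for b in blocks}
            if len(m) != 1:
                raise ValueError("all LD blocks must have the same size")
            m = m.pop()
        elif self.family in ENCODED_FAMILIES + HYBRID_FAMILIES[:2]:
            m = len(self.lds)
        else:
            m = None
        if m is not None:
            if self.encoding_rows != m + 1:
                raise ValueError(
                    f"encoded family needs encoding_rows == m_sub + 1 "
                    f"({m + 1}), got {self.encoding_rows}"
                )
            hadamard_scheme(m)  # validates the order
        elif self.encoding_rows != 1:
            raise ValueError("sequential families must have encoding_rows == 1")
        if self.family in ENCODED_FAMILIES and len(self.plds) != 1:
            raise ValueError("time-encoded families have a single final PLD")
        if self.family == "seq_multi_ld" and len(self.lds) != len(self.plds):
            raise ValueError("seq_multi_ld needs one LD per PLD")
        for x in np.ravel(np.asarray(self.plds, dtype=float)):
            if not np.isfinite(x) or x < 0:
                raise ValueError("plds must be finite and >= 0")
        flat = np.concatenate([np.atleast_1d(np.asarray(b, float)) for b in self.lds]) \
            if self.family == "hybrid_variable" else np.asarray(self.lds, float)
        for x in flat:
            if not np.isfinite(x) or x <= 0:
                raise ValueError("lds must be finite and > 0")

    # -- helpers ---------------------------------------------------------

    def ld_blocks(self) -> List[List[float]]:
        """LD blocks, one per TR type (hybrid_variable: one per PLD)."""
        if self.family == "hybrid_variable":
            return [list(map(float, b)) for b in self.lds]
        return [list(map(float, self.lds))]

    @property
    def encoded(self) -> bool:
        return self.encoding_rows > 1

    @property
    def scheme(self) -> EncodingScheme:
        if not self.encoded:
            raise ValueError("sequential protocols have no encoding scheme")
        return hadamard_scheme(self.encoding_rows - 1)

    def pairs(self) -> List[tuple]:
        """Sequential families: the (LD, PLD) acquisition pairs in order."""
        if self.encoded:
            raise ValueError("pairs() applies to sequential families")
        lds = list(map(float, self.lds))
        plds = list(map(float, self.plds))
        if len(lds) == 1:
            lds = lds * len(plds)
        if len(lds) != len(plds):
            raise ValueError("lds and plds lengths incompatible")
        return list(zip(lds, plds))

    def volumes_per_average(self) -> int:
        if self.encoded:
            if self.family in HYBRID_FAMILIES:
                return self.encoding_rows * len(self.plds)
            return self.encoding_rows
        return 2 * len(self.pairs())

    def n_timepoints(self) -> int:
        """Number of effective PLDs, N_T.

        Sequential families count unique (LD, PLD) pairs (repeated pairs are
        extra averages); encoded and hybrid families count M and N*M decoded
        timepoints respectively, even if a final PLD repeats.
        """
        if self.encoded:
            m = self.encoding_rows - 1
            if self.family in HYBRID_FAMILIES:
                return m * len(self.plds)
            return m
        return len(set(self.pairs()))


def effective_timepoints(p: ProtocolSpec) -> List[EffectiveTimepoint]:
    """Expand a protocol into its decoded/subtracted timepoints.

    Ordering: by final-PLD block in the listed order, then sub-bolus in
    chronological order.  For encoded families, sub-bolus i has
    ``eff_ld = tau_i`` and ``eff_pld = final PLD + sum of later taus``.
    """
    if not p.encoded:
        return [
            EffectiveTimepoint(ld, pld, math.sqrt(2.0)) for ld, pld in p.pairs()
        ]
    m = p.encoding_rows - 1
    scale = 2.0 / math.sqrt(p.encoding_rows)
    blocks = p.ld_blocks()
    if len(blocks) == 1:
        blocks = blocks * len(p.plds)
    out: List[EffectiveTimepoint] = []
    for taus, pld in zip(blocks, map(float, p.plds)):
        tail = np.concatenate([np.cumsum(taus[::-1])[::-1][1:], [0.0]])
        for tau, later in zip(taus, tail):
            out.append(EffectiveTimepoint(float(tau), pld + float(later), scale))
    return out


def timepoint_arrays(p: ProtocolSpec):
    """(eff_ld, eff_pld, noise_scale) arrays for one average of ``p``."""
    tps = effective_timepoints(p)
    return (
        np.array([t.eff_ld for t in tps]),
        np.array([t.eff_pld for t in tps]),
        np.array([t.noise_scale for t in tps]),
    )


def _snap_down(x: float, grid: float) -> float:
    return math.floor(x / grid + 1e-9) * grid


def t1_adjusted_lds(
    ld_last: float,
    final_pld: float,
    m_sub: int,
    t1_blood: float = 1.65,
    grid: float | None = None,
    max_ld: float = 1.8,
) -> List[float]:
    """Sub-bolus durations giving equal decoded signal after complete arrival.

    Solves, from the last sub-bolus backwards,
    ``(1 - exp(-tau_i/T1b)) * exp(-PLD_i/T1b) = const`` with
    ``PLD_i = final_pld + sum of later taus``, compensating the extra blood-T1
    decay of earlier sub-boluses.  If ``grid`` is given each tau is snapped
    *down* to the grid before the next is computed (so the printed timing
    tables are matched to within one grid step).  Returns the durations in
    chronological order (descending).
    """
    if m_sub < 1:
        raise ValueError("m_sub must be >= 1")
    if ld_last < 0.1:
        raise ValueError("last sub-bolus duration must be >= 0.1 s")
    const = (1.0 - math.exp(-ld_last / t1_blood)) * math.exp(-final_pld / t1_blood)
    taus = [float(ld_last)]
    pld_i = final_pld + ld_last
    for i in range(m_sub - 1):
        x = const * math.exp(pld_i / t1_blood)
        sub = m_sub - 2 - i  # chronological index of the sub-bolus being solved
        if x >= 1.0:
            raise ValueError(
                f"equal-signal condition unsatisfiable for sub-bolus {sub}: "
                "required duration is infinite"
            )
        tau = -t1_blood * math.log(1.0 - x)
        if grid is not None:
            tau = _snap_down(tau, grid)
        if tau > max_ld + 1e-9:
            raise ValueError(
                f"sub-bolus {sub} requires duration {tau:.3f} s > max {max_ld} s"
            )
        taus.append(tau)
        pld_i += tau
    return taus[::-1]


def free_lunch_lds(
    first_ld: float,
    ld_last: float,
    final_pld: float,
    m_sub: int,
    t1_blood: float = 1.65,
    grid: float | None = None,
    max_ld: float = 1.8,
) -> List[float]:
    """Free-lunch schedule: a long first sub-bolus (the single-PLD experiment)
    whose long PLD is filled by ``m_sub - 1`` T1-adjusted sub-boluses.

    The first decoded timepoint then reproduces single-PLD data with
    ``eff_pld = final_pld + sum of the later durations``, while the remaining
    sub-boluses add early-timepoint information at no scan-time cost.
    """
    if m_sub < 1:
        raise ValueError("m_sub must be >= 1")
    if m_sub == 1:
        return [float(first_ld)]
    tail = t1_adjusted_lds(ld_last, final_pld, m_sub - 1, t1_blood, grid, max_ld)
    return [float(first_ld)] + tail


@dataclass(frozen=True)
class ScanAccounting:
    """Per-volume TRs, acquired volume count and total scan duration (s)."""

    tr_list: np.ndarray
    n_acq: int
    total_duration: float


def scan_accounting(p: ProtocolSpec) -> ScanAccounting:
    """Variable-minimum-TR accounting.

    The TR of an acquisition is the sum of all label durations played in that
    TR plus its final PLD plus the fixed non-ASL overhead.  Sequential
    families acquire a label and a control volume per LD/PLD pair; encoded
    families acquire ``encoding_rows`` volumes per block (per final PLD for
    hybrids).
    """
    trs: List[float] = []
    if p.encoded:
        blocks = p.ld_blocks()
        if len(blocks) == 1:
            blocks = blocks * len(p.plds)
        for taus, pld in zip(blocks, map(float, p.plds)):
            tr = sum(taus) + pld + p.overhead
            trs.extend([tr] * p.encoding_rows)
    else:
        for ld, pld in p.pairs():
            tr = ld + pld + p.overhead
            trs.extend([tr, tr])  # label + control
    trs = np.array(trs * p.n_ave)
    return ScanAccounting(trs, len(trs), float(trs.sum()))


def duration_str(seconds: float) -> str:
    """Round to the nearest second and format as min:sec."""
    s = int(round(seconds))
    return f"{s // 60}:{s % 60:02d}"


def nearest_budget_averages(p: ProtocolSpec, scan_time: float = 300.0) -> int:
    """Integer average count whose total duration is nearest the budget."""
    one = scan_accounting(replace(p, n_ave=1)).total_duration
    return max(1, round(scan_time / one))
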