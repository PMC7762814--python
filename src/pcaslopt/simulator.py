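"""Monte Carlo generation of noisy label/control or time-encoded ASL data.

Noise-free volumes are assembled from the kinetic model (sub-bolus
contributions add linearly), white Gaussian noise is added per acquired
volume, and the data can be subtracted or decoded back into difference
signals aligned with the protocol's effective timepoints.  Averages are kept
as distinct volumes — data are never pre-averaged — so the fitting stage can
estimate the noise level itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .kinetics import KineticParams, casl_signal
from .protocols import ProtocolSpec, timepoint_arrays

__all__ = ["NoiseModel", "SimulatedDataset", "simulate", "split_halves"]


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise, fixed or linearly ATT-dependent.

    ``fixed``: SD ``sigma0`` per acquired volume (fraction of M0).
    ``linear_att``: SD proportional to ``a*att + b``, rescaled so that
    sigma(ref_att) equals ``sigma0`` — the empirical model in which voxels
    with shorter transit times (nearer large arteries and the head centre)
    are noisier.
    """

    kind: str = "fixed"
    sigma0: float = 1.3e-3
    a: float = -4.28e-4
    b: float = 20.29e-4
    ref_att: float = 1.25

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "linear_att"):
            raise ValueError("kind must be 'fixed' or 'linear_att'")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.kind == "linear_att" and self.a * self.ref_att + self.b <= 0:
            raise ValueError("linear model must be positive at ref_att")

    def sigma(self, att) -> np.ndarray:
        att = np.asarray(att, dtype=float)
        if self.kind == "fixed":
            out = np.full(att.shape, self.sigma0)
        else:
            out = self.sigma0 * (self.a * att + self.b) / (
                self.a * self.ref_att + self.b
            )
        if np.any(out <= 0):
            raise ValueError("noise SD must be positive over the ATT support")
        return out


def _noise_free_average(p: ProtocolSpec, cbf: float, att: np.ndarray,
                        params: KineticParams) -> np.ndarray:
    """Noise-free volumes of one average, shape (n_att, vols_per_average).

    Control volumes sit at a zero baseline (only differences matter after
    calibration); labeled sub-boluses subtract their kinetic-model difference
    signal from it.
    """
    lds, plds, _ = timepoint_arrays(p)
    dm = casl_signal(cbf, att[:, None], lds[None, :], plds[None, :], params)
    if not p.encoded:
        vols = np.zeros((att.size, 2 * dm.shape[1]))
        vols[:, 1::2] = -dm  # [control, label] per pair
        return vols
    labeled = (p.scheme.table == -1).astype(float)  # (M+1, M)
    m = p.encoding_rows - 1
    n_blocks = dm.shape[1] // m
    blocks = dm.reshape(att.size, n_blocks, m)
    vols = -np.einsum("abm,rm->abr", blocks, labeled)  # (n_att, blocks, M+1)
    return vols.reshape(att.size, n_blocks * p.encoding_rows)


@dataclass
class SimulatedDataset:
    """Raw noisy volumes for every (ATT sample, replica), with provenance."""

    protocol: ProtocolSpec
    att: np.ndarray
    cbf_true: float
    volumes: np.ndarray  # (n_att, replicas, n_acq)
    noise: NoiseModel
    seed: Optional[int]

    @property
    def replicas(self) -> int:
        return self.volumes.shape[1]

    def differences(self) -> np.ndarray:
        """Subtract/decode into difference signals, (n_att, reps, n_ave*n_tp)."""
        p = self.protocol
        v = self.volumes
        if not p.encoded:
            return v[..., 0::2] - v[..., 1::2]
        rows = p.encoding_rows
        m = rows - 1
        lead = v.shape[:-1]
        blocks = v.reshape(*lead, v.shape[-1] // rows, rows)
        dec = blocks @ p.scheme.decode_weights.T
        return dec.reshape(*lead, dec.shape[-2] * m)

    def timepoints(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eff_ld, eff_pld, noise_scale) aligned with :meth:`differences`."""
        lds, plds, scales = timepoint_arrays(self.protocol)
        n = self.protocol.n_ave
        return np.tile(lds, n), np.tile(plds, n), np.tile(scales, n)


def simulate(
    p: ProtocolSpec,
    cbf: float,
    att_grid,
    noise: NoiseModel = NoiseModel(),
    replicas: int = 2000,
    seed: Optional[int] = None,
    params: KineticParams = KineticParams(),
) -> SimulatedDataset:
    """Simulate noisy raw data for a protocol at known ground truth.

    For every ATT sample, ``replicas`` independent copies of all ``n_ave``
    averages' volumes are generated with i.i.d. Gaussian noise of SD
    ``noise.sigma(att)`` per volume.  Reproducible given ``seed``.
    """
    att = np.atleast_1d(np.asarray(att_grid, dtype=float))
    if cbf < 0 or np.any(att < 0):
        raise ValueError("cbf and att must be >= 0")
    clean = _noise_free_average(p, cbf, att, params)
    clean = np.tile(clean, (1, p.n_ave))  # (n_att, n_acq)
    sigma = noise.sigma(att)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((att.size, replicas, clean.shape[1]))
    volumes = clean[:, None, :] + sigma[:, None, None] * eps
    return SimulatedDataset(p, att, float(cbf), volumes, noise, seed)


def split_halves(ds: SimulatedDataset) -> Tuple[SimulatedDataset, SimulatedDataset]:
    """Split a dataset into its first and last halves at the average level.

    Odd average counts split k vs k+1 (e.g. 9 -> 4 and 5).  A protocol needs
    at least two averages, and the halves must stay comparable in duration:
    a 1-vs-2 split (3 averages) does not yield two half-duration datasets
    and is rejected.
    """
    n_ave = ds.protocol.n_ave
    n1 = n_ave // 2
    if n_ave < 2 or (n_ave - n1) / n1 > 1.5:
        raise ValueError(
            f"cannot split a dataset with {n_ave} average(s) into comparable "
            "half-duration datasets"
        )
    vpa = ds.protocol.volumes_per_average()
    cut = n1 * vpa
    first = SimulatedDataset(
        replace(ds.protocol, n_ave=n1), ds.att, ds.cbf_true,
        ds.volumes[..., :cut], ds.noise, ds.seed,
    )
    second = SimulatedDataset(
        replace(ds.protocol, n_ave=n_ave - n1), ds.att, ds.cbf_true,
        ds.volumes[..., cut:], ds.noise, ds.seed,
    )
    return first, second
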