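"""Single-compartment CASL kinetic model and its parameter sensitivities.

This module is the single source of truth for ASL difference-signal values:
the protocol optimizer, the Monte Carlo simulator and the Bayesian fitter all
evaluate the same closed-form model defined here.

The model is the standard continuous-labeling solution of the one-compartment
tracer equation: a plug-flow bolus of duration ``ld`` arrives at the voxel
after the arterial transit time ``att``, having decayed with the blood T1
during transit, and subsequently decays with the apparent tissue relaxation
time T1' (which folds in clearance by flow).  The acquired timepoint is
``t = ld + pld``, with the post-labeling delay measured from the end of the
labeling block to excitation.

Units: CBF in mL/100 g/min everywhere at the interface; the conversion to
s^-1 (division by 6000, with the partition coefficient in mL/g) happens in
this module only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KineticParams",
    "PerfusionState",
    "apparent_t1",
    "casl_signal",
    "casl_sensitivities",
]

#: mL/100 g/min -> s^-1 (with lambda in mL/g); applied exactly once, here.
CBF_UNIT_SCALE = 6000.0


@dataclass(frozen=True)
class KineticParams:
    """Physiological and sequence constants of the kinetic model.

    Defaults are the values used throughout the optimizations and
    simulations: blood T1 1.65 s, tissue T1 1.445 s, labeling efficiency
    0.85, brain/blood partition coefficient 0.9 mL/g, and an additive
    per-volume noise SD of 1.3e-3 relative to the equilibrium magnetization.
    """

    t1_blood: float = 1.65
    t1_tissue: float = 1.445
    alpha: float = 0.85
    lam: float = 0.9
    m0: float = 1.0
    noise_sd: float = 1.3e-3

    def __post_init__(self) -> None:
        for name in ("t1_blood", "t1_tissue", "alpha", "lam", "noise_sd", "m0"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and strictly positive")
        if self.alpha > 1:
            raise ValueError("labeling efficiency alpha must be <= 1")

    def with_noise(self, noise_sd: float) -> "KineticParams":
        return replace(self, noise_sd=noise_sd)


@dataclass(frozen=True)
class PerfusionState:
    """A (CBF, ATT) point: perfusion in mL/100 g/min, transit time in s."""

    cbf: float
    att: float

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError("cbf must be >= 0")
        if self.att < 0:
            raise ValueError("att must be >= 0")


def apparent_t1(cbf, params: KineticParams = KineticParams()):
    """Apparent tissue relaxation time T1' (s): 1/T1' = 1/T1t + f/lambda.

    ``cbf`` is in mL/100 g/min and may be an array.  T1' <= T1t, with
    equality at zero flow.
    """
    cbf = np.asarray(cbf, dtype=float)
    if np.any(cbf < 0):
        raise ValueError("cbf must be >= 0")
    f = cbf / CBF_UNIT_SCALE
    out = 1.0 / (1.0 / params.t1_tissue + f / params.lam)
    return out if out.ndim else float(out)


def _validate_timing(ld, pld):
    ld = np.asarray(ld, dtype=float)
    pld = np.asarray(pld, dtype=float)
    if not (np.all(np.isfinite(ld)) and np.all(np.isfinite(pld))):
        raise ValueError("ld and pld must be finite")
    if np.any(ld <= 0):
        raise ValueError("ld must be > 0")
    if np.any(pld < 0):
        raise ValueError("pld must be >= 0")
    return ld, pld


def casl_signal(cbf, att, ld, pld, params: KineticParams = KineticParams()):
    """Difference (control - label) signal as a fraction of M0.

    Three regimes at readout time t = ld + pld:

    * ``t <= att``          : bolus not yet arrived, signal 0;
    * ``att <= t < att+ld`` : inflow,
      ``2*alpha*f*T1'*exp(-att/T1b)*(1 - exp(-(t-att)/T1'))``;
    * ``t >= att+ld``       : complete arrival,
      ``2*alpha*f*T1'*exp(-att/T1b)*(1 - exp(-ld/T1'))*exp(-(t-att-ld)/T1')``,

    with f = cbf/6000 (s^-1).  Continuous in ``att`` across both breakpoints.
    All arguments broadcast.
    """
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    if not (np.all(np.isfinite(cbf)) and np.all(np.isfinite(att))):
        raise ValueError("cbf and att must be finite")
    if np.any(cbf < 0) or np.any(att < 0):
        raise ValueError("cbf and att must be >= 0")
    ld, pld = _validate_timing(ld, pld)

    f = cbf / CBF_UNIT_SCALE
    t1p = 1.0 / (1.0 / params.t1_tissue + f / params.lam)
    dt = ld + pld - att  # time since bolus arrival
    amp = 2.0 * params.alpha * params.m0 * f * t1p * np.exp(-att / params.t1_blood)

    dt_in = np.clip(dt, 0.0, ld)  # guarded exponent for the unused branch
    s_inflow = amp * (1.0 - np.exp(-dt_in / t1p))
    s_post = amp * (1.0 - np.exp(-ld / t1p)) * np.exp(-np.maximum(dt - ld, 0.0) / t1p)
    signal = np.where(dt >= ld, s_post, np.where(dt > 0, s_inflow, 0.0))
    return signal if signal.ndim else float(signal)


def casl_sensitivities(cbf, att, ld, pld, params: KineticParams = KineticParams()):
    """Analytic partial derivatives (dS/dCBF, dS/dATT) of :func:`casl_signal`.

    dS/dCBF is per mL/100 g/min (including the weak nonlinearity through
    T1'), dS/dATT per second.  Both are zero for ``ld + pld <= att``; at the
    regime breakpoints the piecewise-interior (right-hand in readout time)
    derivative is returned.
    """
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    if not (np.all(np.isfinite(cbf)) and np.all(np.isfinite(att))):
        raise ValueError("cbf and att must be finite")
    if np.any(cbf < 0) or np.any(att < 0):
        raise ValueError("cbf and att must be >= 0")
    ld, pld = _validate_timing(ld, pld)

    f = cbf / CBF_UNIT_SCALE
    t1p = 1.0 / (1.0 / params.t1_tissue + f / params.lam)
    dt1p_dcbf = -(t1p ** 2) / params.lam / CBF_UNIT_SCALE
    df_dcbf = 1.0 / CBF_UNIT_SCALE
    c = 2.0 * params.alpha * params.m0 * np.exp(-att / params.t1_blood)
    dt = ld + pld - att

    # inflow regime: S = c*f*T1p*(1 - E), E = exp(-dt/T1p)
    dt_in = np.clip(dt, 0.0, ld)
    e_in = np.exp(-dt_in / t1p)
    s_in = c * f * t1p * (1.0 - e_in)
    de_dcbf = e_in * dt_in / t1p ** 2 * dt1p_dcbf
    dcbf_in = c * ((df_dcbf * t1p + f * dt1p_dcbf) * (1.0 - e_in) - f * t1p * de_dcbf)
    datt_in = -s_in / params.t1_blood - c * f * e_in

    # post-arrival regime: S = c*f*T1p*(1 - EL)*D
    el = np.exp(-ld / t1p)
    d_post = np.exp(-np.maximum(dt - ld, 0.0) / t1p)
    s_post = c * f * t1p * (1.0 - el) * d_post
    del_dcbf = el * ld / t1p ** 2 * dt1p_dcbf
    dd_dcbf = d_post * np.maximum(dt - ld, 0.0) / t1p ** 2 * dt1p_dcbf
    dcbf_post = c * (
        (df_dcbf * t1p + f * dt1p_dcbf) * (1.0 - el) * d_post
        - f * t1p * del_dcbf * d_post
        + f * t1p * (1.0 - el) * dd_dcbf
    )
    datt_post = s_post * (1.0 / t1p - 1.0 / params.t1_blood)

    post = dt >= ld
    inflow = dt > 0
    d_cbf = np.where(post, dcbf_post, np.where(inflow, dcbf_in, 0.0))
    d_att = np.where(post, datt_post, np.where(inflow, datt_in, 0.0))
    if d_cbf.ndim == 0:
        return float(d_cbf), float(d_att)
    return d_cbf, d_att
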