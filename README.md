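# pcaslopt

Design and Monte Carlo evaluation of pseudo-continuous arterial spin
labeling (PCASL) perfusion protocols.

PCASL measures cerebral blood flow (CBF) by magnetically inverting arterial
blood and imaging it after a post-labeling delay (PLD), but the technique is
SNR-limited and the arterial transit time (ATT) confounds the measurement:
a single-delay protocol must guess the ATT, while multi-timepoint protocols
(sequential multi-PLD, Hadamard time-encoded, and hybrids of the two) trade
per-timepoint averaging for sampling of the tracer kinetics.  This package
is for MR physicists and perfusion researchers who want to (a) design the
timings of such protocols optimally and (b) quantify, under controlled
conditions, how confidently, accurately and repeatably each design estimates
CBF.

## What it computes

**Kinetic model.** The single-compartment continuous-labeling solution for
the difference signal at readout time *t* = LD + PLD:

```
ΔM(t) = 0,                                                          t ≤ ATT
ΔM(t) = 2α M0 f T1' e^(−ATT/T1b) (1 − e^(−(t−ATT)/T1')),            ATT ≤ t < ATT+LD
ΔM(t) = 2α M0 f T1' e^(−ATT/T1b) (1 − e^(−LD/T1')) e^(−(t−ATT−LD)/T1'),  t ≥ ATT+LD
```

with `f = CBF/6000` (s⁻¹) and `1/T1' = 1/T1t + f/λ`.

**Design cost.** For a protocol with effective timepoints `(LDᵢ, PLDᵢ)` and
decoded noise SDs `σᵢ`, the Fisher information `F = Σᵢ gᵢgᵢᵀ/σᵢ²`
(`gᵢ = ∂ΔMᵢ/∂(CBF, ATT)`) gives the Cramér–Rao lower bound
`var(CBF) ≥ [F⁻¹]₁₁`.  The optimizer minimizes this bound, averaged over a
tapered uniform ATT prior (0.5–2.0 s) and scaled by the averages realizable
in a fixed scan time, by coordinate-descent grid search over the PLDs, label
durations and Hadamard encoding size.

**Time encoding.** An (M+1)×M Hadamard scheme splits the label train into M
sub-boluses toggled label/control per TR; linear decoding yields M effective
timepoints with noise SD `2σ/√(M+1)` each — the averaging advantage that the
hybrid designs combine with sequentially varied final PLDs.

**Evaluation.** A Monte Carlo simulator generates noisy encoded or
label/control volumes at known (CBF, ATT); a variational-Bayes fitter
returns posterior means and SDs for CBF, ATT and the noise level; protocols
are compared by mean posterior CBF SD (uncertainty), RMSE against truth
(accuracy) and split-half test-retest RMSE (repeatability), with outlier
exclusion, ATT-distribution weighting, bootstrap standard errors and paired
signed-rank tests.

## Worked example

```python
import numpy as np
from pcaslopt import casl_signal, expected_cbf_sd, reference_protocols
from pcaslopt.io import protocol_summary

specs = reference_protocols()   # the optimized 5-minute protocol library
print(protocol_summary({k: specs[k] for k in
                        ("single_pld", "had_freelunch", "hybrid_t1adj")}).to_string())

s = casl_signal(50.0, 1.3, 1.8, 2.0)
print(f"dM(CBF=50, ATT=1.3 | LD=1.8, PLD=2.0) = {s:.3e} * M0")
att = np.array([0.7, 1.3, 1.9])
for name in ("single_pld", "had_freelunch", "hybrid_t1adj"):
    sd = expected_cbf_sd(specs[name], att)
    print(f"{name:14s} predicted CBF SD at ATT 0.7/1.3/1.9 s: "
          + " / ".join(f"{x:.2f}" for x in sd) + "  mL/100g/min")
```

prints

```
                               label_durations_ms             plds_ms  n_t  n_ave  n_acq duration
protocol
single_pld                                   1800                2000    1     34     68     5:02
had_freelunch  1800, 625, 450, 350, 300, 250, 225                 125    7      8     64     5:05
hybrid_t1adj                       1800, 850, 550  200, 650, 900, 900   12      4     64     4:48

dM(CBF=50, ATT=1.3 | LD=1.8, PLD=2.0) = 4.032e-03 * M0
single_pld     predicted CBF SD at ATT 0.7/1.3/1.9 s: 3.97 / 3.97 / 3.97  mL/100g/min
had_freelunch  predicted CBF SD at ATT 0.7/1.3/1.9 s: 3.15 / 3.97 / 4.71  mL/100g/min
hybrid_t1adj   predicted CBF SD at ATT 0.7/1.3/1.9 s: 2.45 / 3.17 / 4.46  mL/100g/min
```

Reading this: in a matched 5-minute scan, the single-PLD protocol's CBF
uncertainty is flat at ~4.0 mL/100 g/min because it assumes a fixed ATT of
1.3 s (it is also *biased* wherever the true ATT differs).  The free-lunch
time-encoded protocol and especially the hybrid design with T1-adjusted
sub-boluses beat it at short-to-mid ATTs while also estimating ATT itself.
The same curves can be confirmed empirically via `simulate` + `fit_dataset`,
whose median posterior SDs track these predictions closely.

The full chain is also available from the shell:

```sh
pcaslopt optimize --family hybrid_t1adj --seed 0 --out protocol.json
pcaslopt simulate --protocol protocol.json --replicas 200 --seed 1 --out ds.npz
pcaslopt fit --data ds.npz --out fits.csv
pcaslopt evaluate --fits fits.csv --out report.csv
pcaslopt run --outdir results --replicas 200 --seed 1   # everything at once
```

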