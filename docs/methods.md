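# Methods

This note records the models, conventions and numerical choices behind
`pcaslopt`, and what the synthetic evaluation does and does not demonstrate.

## Kinetic model

The difference (control − label) signal follows the single-compartment
solution for continuous labeling: a plug-flow bolus of duration LD arrives
after the transit time ATT, decayed by `exp(−ATT/T1b)` during transit, and
subsequently relaxes with the apparent tissue time `1/T1' = 1/T1t + f/λ`
(clearance by flow folded into relaxation).  The acquired timepoint is
`t = LD + PLD`, with the PLD measured from the end of the last labeling
block to excitation.  Conventions:

* CBF is in mL/100 g/min at every interface; the single conversion to s⁻¹
  (division by 6000, λ in mL/g) lives inside `kinetics` to prevent
  double-scaling.
* The model is continuous in ATT but its ATT-derivative is one-sided at the
  two regime breakpoints (`ATT = PLD` and `ATT = LD + PLD`); the
  right-hand (interior) derivative is returned.  Note that after complete
  arrival the signal *increases* with ATT (the tracer spends more of its
  life at the slower blood T1, since T1b > T1'), while during inflow it
  decreases.
* Default constants: T1b 1.65 s, T1t 1.445 s, α 0.85, λ 0.9 mL/g, per-volume
  noise SD 1.3×10⁻³ of M0.  A closed-form/ODE cross-check holds to <0.1%.

## Protocols and time encoding

A protocol is a timing schedule plus an optional Sylvester-Hadamard
encoding.  Decoding an (M+1)×M encoding with weights `(2/(M+1))·(±1 column)`
recovers each sub-bolus difference exactly and yields i.i.d. decoded noise
of SD `2σ/√(M+1)` — equivalently a `√((M+1)/2)` SD advantage over a
label/control pair.  Polarity: −1 ↦ label, decoded difference is
control-minus-label so perfusion signal is positive.

T1-adjusted sub-boluses solve `(1−e^(−τᵢ/T1b))·e^(−PLDᵢ/T1b) = const` from
the last sub-bolus backwards, equalizing per-sub-bolus signal in the
blood-decay regime; with a 25 ms grid each τ is snapped *down* before the
next is computed, which reproduces published schedules to within one grid
step (exact equality then holds only in the blood-decay limit, so tests
verify the recursion with tissue T1 matched to blood T1).  The free-lunch
schedule fixes the first sub-bolus at 1.8 s and fills its long delay with a
T1-adjusted tail; the tail's terminal duration is an explicit parameter
(searched by the optimizer).  For the hybrid T1-adjusted family the
equal-signal condition is referenced to the earliest final PLD.

Scan-time accounting uses the variable minimum TR: each acquisition's TR is
the sum of the label durations played in that TR plus its final PLD plus a
fixed 0.638 s overhead.  Display durations round to the nearest second; the
emitted average count is the integer whose total duration is nearest the
300 s budget (overruns allowed).  N_T bookkeeping is per family: unique
(LD, PLD) pairs for sequential protocols, M for time-encoded, N·M for
hybrids (a repeated final PLD counts as distinct decoded timepoints).

## Design cost and optimizer

The cost is the CBF entry of the inverse Fisher information (2×2 over
CBF and ATT; 1×1 at the fixed assumed ATT of 1.3 s for single-PLD), divided
by the *continuous* number of averages realizable in the scan time, and
averaged over a tapered uniform ATT prior (0.5–2.0 s core, 1 ms sampling,
0.3 s linear taper, weights normalized).  Where the information is singular
(ATT beyond every timepoint, or all informative points in the decay regime)
the variance is capped at that of a pure-noise guess uniform on
[0, 200] mL/100 g/min (200²/12); genuinely singular protocols cost +∞ with
a warning.  The capped spikes at exact breakpoint ATTs are real model
structure — at those points CBF and ATT are momentarily collinear.

Search: cyclic coordinate descent over each timing variable's 25 ms grid
(LD ∈ [0.1, 1.8] s, PLD ∈ [0.075, 2.3] s), ties broken toward the smaller
value, iterated to a full no-change cycle (cap 25 cycles; non-convergence
returns the best iterate with a warning).  Encoding size is enumerated over
{4×3, 8×7} and the timepoint count swept to ≤15.  Deterministic families
start from evenly spaced PLDs and mid-grid LDs (short last sub-boluses for
the equal-signal families, whose long terminal durations are usually
infeasible); the high-dimensional families (seq_multi_ld, had_variable,
hybrid_variable) use seeded uniform-random restarts (default 5) because
their cost landscapes have local minima.  Average counts stay continuous
inside the cost and are integerized only at emission.

## Simulator

Noise-free volumes are assembled by additivity of sub-bolus contributions
(control baseline 0 — after calibration only differences matter), tiled over
all averages, with i.i.d. Gaussian noise per acquired volume.  Averages are
kept as distinct volumes so the fitter estimates the noise itself.  The
ATT-dependent variant scales the SD by the linear model `a·ATT + b`
(a = −4.28×10⁻⁴ s⁻¹, b = 20.29×10⁻⁴), rescaled so σ(1.25 s) equals the
fixed-noise value; it emulates the empirically higher noise at short
transit times and qualitatively flattens the uncertainty-vs-ATT curves at
short ATT.  Split-half datasets partition averages first/second half (k vs
k+1 when odd); a 1-vs-2 split is rejected as incomparable.

## Inference

The posterior over (CBF, ATT, noise precision) is approximated by
variational Bayes with local linearisation: a Gaussian factor on the kinetic
parameters updated by iteratively re-linearised least squares, and a Gamma
factor per noise class (shape 10⁻⁶, scale 10⁶ prior) whose rate includes the
linearised model-uncertainty correction `tr(JΣJᵀ)`.  Priors on CBF and ATT
are effectively flat (0 ± 10⁶ and 1.3 ± 10⁶).  Single-PLD data are fit for
CBF only with ATT fixed at 1.3 s.  Reported negative means are clamped to
zero after inference; posterior SDs are untouched.

Numerical choices, found to matter:

* Initialisation: per-voxel fits use the exact coarse grid search
  (CBF 0–200 by 1, ATT 0–2.5 by 0.01); the batched Monte Carlo path uses an
  equivalent separable initialiser (closed-form least-squares CBF at each
  ATT grid point using the curve shape at a 50 mL/100 g/min reference,
  then the best ATT), refined by the VB iterations.
* Updates are plain linearised-VB steps — no line search — which matches the
  behaviour of established variational perfusion fitters and the published
  comparison statistics.  A divergence guard halves (and ultimately rejects)
  only steps that inflate the weighted misfit by more than 100×: such steps
  occur only at near-zero noise, where the one-sided derivative at a regime
  breakpoint lets a raw Gauss-Newton step jump out of an essentially exact
  fit.  Ordinary noisy updates never approach that ratio.
* After half the iteration budget (60 total), steps are geometrically damped
  so units flip-flopping across a breakpoint settle; iterate clips
  (CBF ∈ [−500, 2000], ATT ∈ [−1, 6]) are numerical only.
* Pooled "ground-truth" fits concatenate several protocols' timepoints and
  estimate one noise magnitude per decoded-noise class (non-encoded, 8-row,
  4-row encoded), the multi-magnitude analogue of weighted least squares;
  this keeps the pooled estimate free of protocol-dependent bias.

## Evaluation

Three metrics on a common included set: weighted mean posterior CBF SD,
weighted RMSE against the reference CBF, and split-half test-retest RMSE.
Units are excluded when any protocol's posterior SD exceeds 500 mL/100 g/min
or 50 s (extremely poor fits), and — when pooled ground-truth fits are used
as reference — when the ground-truth SDs exceed the upper fence Q3 + 3·IQR
(linear-interpolation quantiles).  In simulation the reference is the known
true CBF, so the IQR rule is idle.  Sliding-window median curves use a
0.1 s window stepped by 0.01 s.  ATT-distribution weighting is either
uniform or a synthetic log-normal stand-in for a measured gray-matter
distribution (median 0.97 s, σ_log = 0.336 fitted to the 0.5/1.51 s
5th/95th percentiles).  Group bootstrap SEs resample groups with replacement
(1000 samples, seeded); paired protocol comparisons use the two-sided
Wilcoxon signed-rank test with Bonferroni multiplication, all-tied pairs
flagged and reported non-significant.

## Study conditions and problem sizes

The Monte Carlo comparison simulates the published optimized 5-minute
timings at true CBF 50 mL/100 g/min over a uniform ATT grid.  The package
defaults are 2000 replicas at 0.01 s ATT steps; the shipped test suite and
the acceptance script run the same study at 0.02 s steps with 250 replicas
per ATT sample, a size at which the comparison statistics are stable to a
fraction of a percentage point while a full run completes in minutes.  At
these conditions the median posterior SDs track the CRLB predictions within
a few percent across ATT, and the relative-performance figures (free-lunch
and hybrid designs versus single-PLD) reproduce the published simulation
values to within a few percentage points.

## What the synthetic study does not show

The simulator emulates thermal noise only: no physiological drift, motion,
background-suppression losses, bolus dispersion, or macrovascular signal,
and a single true CBF.  Passing tests therefore validate the estimation
machinery and the *relative* design comparison under the stated model, not
absolute in vivo performance; in vivo, shorter measured ATT distributions
are known to shift the ranking further in favour of T1-adjusted designs.
Known limitations: one-compartment model only (no macrovascular
compartment, no dispersion kernels, no partial-volume or spatial
regularization); Hadamard sizes limited to the Sylvester construction;
test-retest for designs with very few averages is heavy-tail dominated, so
its ranking between closely matched protocols is less stable than the
uncertainty and accuracy metrics.
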