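# Methods

## Model and closed-form forward operator

The irreversible two-tissue compartment model couples the arterial plasma
input C_P to a free and an irreversibly bound tissue compartment per
region (rates K1, k2, k3 > 0, all 1/min; k4 = 0). With C_P polyexponential,
C_P(t) = Σ_j λ_j e^{μ_j t}, the tissue response has the exact form

    C_T(t) = (K1 k2/k) Σ_j λ_j e^{−kt} G(k+μ_j, t)
           + (K1 k3/k) Σ_j λ_j G(μ_j, t),        k = k2 + k3,

with G(d, t) = (e^{dt} − 1)/d. `petkin` evaluates G through
t·expm1(dt)/(dt), which is uniformly accurate in d and reproduces the
degenerate limits exactly: μ_j = 0 yields the linear-in-t trapping term
and k2+k3+μ_j = 0 the resonant t·e^{−kt} term, with no branch switching or
cancellation anywhere. The same φ-type helpers supply the closed-form
derivative ∂G/∂d (series branch below |dt| = 1e−3, accurate to ~1e−13
relative) used by the analytic Jacobian. Correctness is established
against an adaptive-quadrature oracle of the integral representation
(1e−8 relative over randomized configurations including the degenerate
branches) and against central finite differences for the Jacobian (1e−5
with a denominator floored at 1e−6 of the largest entry, below which
central differences are dominated by roundoff).

The joint forward operator stacks, region-major, the tissue curves at the
T frame times (block F¹) and the plasma-consistency residuals
C_WB(s_l)·f_m(s_l) − C_P(s_l) at the q blood-sample times (block F²,
target value 0). C_WB enters F² as measured data and is never recomputed
from the parameters. Measurement times are the frame midpoints of the
acquisition schedule; frame-averaged evaluation would be the natural
alternative for very long frames but changes the synthetic data and the
fit targets consistently, so midpoint evaluation is used throughout.

## Identifiability diagnostics

Unique recovery from noiseless data needs T ≥ 2(p+3) tissue samples and,
per input exponent μ_{j0}, three witness regions with pairwise-distinct k3
and k2+k3 for which the e^{−kt} coefficient of the tissue curve does not
vanish (either because μ_{j0}+k = 0, or because Σ λ_j/(k+μ_j) ≠ 0).
`check_assumption_A` verifies this by direct enumeration over region
triples; `check_region_distinctness` checks the simpler sufficient condition of p+3
regions with pairwise-distinct k3 and k2+k3 by subset search (region
counts in practice are single-digit, so enumeration is exact and cheap).
Floating-point "distinct"/"nonzero" judgements use a relative tolerance of
1e−9 (relative to the magnitudes involved, and to the sum of term
magnitudes for the coefficient sum); margins below 1e−4 are additionally
flagged in the report notes as practically non-identifiable, since a
condition that holds by a hair does not help a noisy fit.

Without blood data the tissue block is invariant under
(λ, K1) → (ζλ, K1/ζ); `align_scale` estimates ζ as the median of the
per-region K1 ratios (robust to a single outlier region), returns the
gauge-aligned copy, and reports the relative spread of the ratios as a
consistency score. The full ratio vector is returned for diagnostics.

## Inversion

The IRGNM step solves (JᵀJ + diag(W_k)) Δ = Jᵀ r + W_k (x_0 − x_k) by
dense Cholesky on the (at most 23×23) normal matrix, falling back to a
symmetric solve if factorization fails, followed by Euclidean projection
onto the domain: kinetic rates clipped to [ε, ∞) with ε = 1e−3, fraction
amplitude to [0, ∞), fraction exponents to (−∞, 0]; λ, μ are
unconstrained by default. Optional model variations (off by default)
constrain μ_j ≤ −ε̃ and pin C_P(0) = 0 via λ_p = −Σ_{j<p} λ_j.

W_k carries three geometric schedules a·2^{−i/c} — one per parameter
block (kinetic rates, input curve, parent fraction) — because the blocks
live on scales spanning three orders of magnitude; with equal blocks the
step reduces exactly to the classical uniformly regularized iteration,
which the test suite verifies against an augmented least-squares oracle.
There is no line search or damping: divergence is a recognized outcome
handled at the experiment level, and iterates that overflow (exponents
driven positive) abort the run and count as divergent. Stopping follows
the Morozov discrepancy principle ‖F(x_N) − y‖ ≤ τ·δ_y, checked from the
initial iterate onward; for noiseless data the threshold is replaced by a
1e−10 residual floor and the iteration cap (300 noiseless, 200 noisy)
terminates the run.

Two solver modes: `full` optimizes all 2p+3+3n parameters; `reduced`
freezes the fraction block m at its initial values — the setting where f
is known and the blood data are noiseless, i.e. C_P is effectively
measured. Error norms and improvement metrics in reduced mode run over
the free parameters only. `include_f2=False` drops the blood block
entirely, exposing the tissue-only problem whose K1 scale is undetermined
(used by the scale-ambiguity demonstration).

## Synthetic data generator

The generator emulates a dynamic FDG-like brain study at the
time-activity-curve level. Defaults are the study conditions themselves:

* input curve λ = (−10.9136, 9.545, 0.7331, 0.6355),
  μ = (−13.4522, −3.2672, −0.1532, −0.0106)/min (coefficients sum to
  zero, so C_P(0) = 0);
* parent fraction f(t) = 0.2 e^{−0.2t} + 0.8 e^{−0.005t} (f(0) = 1);
* four regions (frontal, temporal, occipital cortex, white matter) with
  control-group kinetic rates, e.g. frontal (0.1570, 0.1740, 0.1180)/min;
* 25 frames (4×5 s, 4×10 s, 4×30 s, 2×60 s, 3×150 s, 6×300 s, 2×600 s,
  62.5 min total), blood samples on the same grid; V_B = 0.05.

Noise is signal-proportional zero-mean Gaussian on the tissue entries
(and on the whole-blood samples in the noisy-blood setup), with the whole
perturbation vector rescaled so the realized data-space discrepancy at
the ground truth equals the prescribed δ_y exactly (0.003 / 0.011 / 0.07
for the high / normal / low count levels). This deliberately does not
reproduce the heteroscedasticity a real scanner's reconstruction chain
(Poisson counts, OSEM) would induce across frames — only the discrepancy
level, which is the single noise quantity the stopping rule and the
theory consume. Consequently, replicate means are compared to published
reconstruction statistics at a 3-standard-deviation tolerance rather than
exactly, and passing tests certify the estimator under this calibrated
noise model, not under scanner physics. A pass-through hook for the
mean-of-realizations bias correction exists but is off by default, since
the substitute noise is zero-mean by construction.

Initializations follow x_0 = x†(1 + σγ) elementwise with random signs σ
and γ ~ N(δ_x, δ_x/4), giving E‖x_0−x†‖²/‖x†‖² = δ_x/4 + δ_x² (verified
by Monte Carlo), then projection onto the domain. Each experiment cell
runs 20 replicates from one master seed (independent spawned streams per
replicate for noise and initialization; fully reproducible). A replicate
is divergent when no improvement over the initialization is achieved: for
noisy data this means the discrepancy stop never fired or the stopped
iterate is no closer than x_0 (the reported reconstruction is the stopped
iterate, which otherwise would not exist); for noiseless data, when no
iterate improves. Summaries (mean/std per kinetic parameter) cover
non-divergent replicates only, and the median-representative replicate is
the one whose ρ_d (ρ_opt if no stop) is closest to the median.

Tuned hyperparameters per setup (discrepancy factor τ and schedule
constants for the kinetic/input/fraction blocks): reduced — α_i = 10·2^{−i/5},
β_i = 600·2^{−i/7}, τ = 9.2; full with noiseless blood — 4000/100/200·2^{−i/7},
τ = 6.8; full with noisy blood — 3000/100/400·2^{−i/8}, τ = 17.6.

## Problem sizes

The acceptance script and test suite run the protocol at its native size:
23 unknowns, 125 measurements, 20 replicates × ≤200 iterations per
experiment cell — a few seconds per cell. Monte-Carlo checks of the
initialization statistic use 1e5 draws (tests at 2e4).

## Limitations

Reversible (k4 > 0) models, voxelwise parametric imaging and image
reconstruction are out of scope. The identifiability checks are numeric,
tolerance-based certificates, not symbolic proofs. The generator's noise
model matches real acquisitions only in discrepancy level (see above),
and hyperparameters are the fixed tuned constants — no tuning harness is
included. The unknown-V_B generalization is not implemented; V_B is a
known constant of the simulation.
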