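# petkin

Kinetic parameter identification for dynamic PET using the irreversible
two-tissue compartment model — forward modeling, identifiability
diagnostics, and a regularized Gauss–Newton fitting pipeline that jointly
recovers tissue, input-curve and parent-fraction parameters from noisy
time-activity curves without metabolite analysis.

## The problem

Quantitative dynamic PET estimates, per tissue region *i*, the rate
constants of the irreversible two-tissue compartment model

```
dC_F/dt = K1·C_P − (k2 + k3)·C_F        C_F(0) = 0
dC_B/dt = k3·C_F                        C_B(0) = 0
C_T = C_F + C_B
```

where `C_P` is the metabolite-corrected arterial plasma input, `K1` the
plasma→tissue transport rate, `k2` the efflux rate, and `k3` the
irreversible trapping rate (all 1/min). The standard workflow measures
`C_P` by arterial blood sampling plus metabolite analysis — expensive and
clinically impractical. Image-based surrogates only give the whole-blood
concentration `C_WB = C_P / f(t)`, with `f` the unknown parent plasma
fraction.

`petkin` implements the alternative: parametrize `C_P` as a
polyexponential `Σ λ_j e^{μ_j t}` of degree `p` and `f` as a biexponential
`A e^{ξ1 t} + (1−A) e^{ξ2 t}`, and fit all unknowns

```
x = (λ, μ, m, K¹, …, Kⁿ) ∈ R^{2p+3+3n}      m = (A, ξ1, ξ2)
```

simultaneously to the tissue curves of *n* regions plus (optionally noisy)
whole-blood samples. The theory behind this says: with `T ≥ 2(p+3)` tissue
time points and regions whose `k3` and `k2+k3` are sufficiently distinct,
all `k2`, `k3` are uniquely determined and the `K1` profile up to one
global scale ζ; `q ≥ 4` whole-blood samples pin ζ = 1 and recover `f` —
no metabolite analysis needed. The package ships checkable versions of
these conditions (`check_assumption_A`, `min_timepoints`,
`min_blood_samples`, `align_scale`).

Fitting uses the iteratively regularized Gauss–Newton method (IRGNM):

```
x_{k+1} = P_D ( x_k + (JᵀJ + diag(W_k))⁻¹ (Jᵀ(y − F(x_k)) + W_k (x_0 − x_k)) )
```

with analytic Jacobian `J`, per-block geometric regularization schedules
`W_k` (kinetic / input / fraction), projection `P_D` onto the parameter
domain, and Morozov discrepancy stopping `‖F(x_N) − y‖ ≤ τ·δ_y`.

## Worked example

```python
from petkin import (COUNT_SETTINGS, default_ground_truth, frame_schedule,
                    generate_noisy_data, perturb_initialization, run_irgnm,
                    simulate_ground_truth)
from petkin.experiments import setup_config

gt = default_ground_truth()              # 4 brain regions, degree-4 input
schedule = frame_schedule()              # 25 frames over 62.5 min
clean, aux = simulate_ground_truth(gt, schedule)
setting = COUNT_SETTINGS["normal"]       # delta_y = 0.011
noisy = generate_noisy_data(clean, setting, noisy_cwb=False, seed=4)
x0 = perturb_initialization(gt.parameter_vector(), 0.3, seed=4,
                            frozen_fraction=True)
fit = run_irgnm(x0, noisy.stacked(), setting.delta_y,
                setup_config("reduced", setting), schedule,
                noisy.CWB_samples)
print(fit.stopped_by, fit.stop_iteration)
print(fit.x.regions[0])   # frontal cortex
```

prints

```
discrepancy 140
KineticParams(K1=0.1563..., k2=0.1715..., k3=0.1170...)
```

i.e. starting from a 30%-level random perturbation, the discrepancy
principle stops after 140 iterations with the frontal-cortex rates
recovered to about 1% of the ground truth (0.1570, 0.1740, 0.1180). The
scripts in `examples/` walk through each capability — forward simulation,
identifiability checking, single fits, the 20-replicate protocol, and the
K1-scale-ambiguity demonstration — and print the numbers they compute.

A thin CLI wraps the same functionality:
`petkin simulate|fit|check|experiment --help`.

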