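"""Demonstrate the K1-scale ambiguity of tissue-only fitting.

Without any blood information, the tissue curves determine k2 and k3
exactly but the K1 values and the input amplitude only up to one global
factor zeta: (lambda, K1) and (zeta*lambda, K1/zeta) produce identical
tissue curves.  Fitting only the tissue block from different random starts
therefore converges to different zetas (but always a consistent K1
profile); adding the whole-blood consistency block pins zeta = 1.
"""

import numpy as np

from petkin import (
    COUNT_SETTINGS,
    align_scale,
    default_ground_truth,
    frame_schedule,
    perturb_initialization,
    run_irgnm,
    simulate_ground_truth,
)
from petkin.experiments import setup_config

gt = default_ground_truth()
schedule = frame_schedule()
clean, _ = simulate_ground_truth(gt, schedule)
x_true = gt.parameter_vector()

print("tissue-only fits (no blood data), noiseless, 4 random starts:")
for seed in range(4):
    x0 = perturb_initialization(x_true, 0.1, seed, frozen_fraction=True)
    cfg = setup_config("reduced", COUNT_SETTINGS["noiseless"])
    cfg.include_f2 = False
    fit = run_irgnm(x0, clean.stacked(), 0.0, cfg, schedule,
                    clean.CWB_samples)
    zeta, _, spread, _ = align_scale(x_true, fit.x)
    k2_err = max(abs(K.k2 - Kt.k2) / Kt.k2
                 for K, Kt in zip(fit.x.regions, x_true.regions))
    print(f"  seed {seed}: zeta = {zeta:.4f}  K1-profile spread = "
          f"{spread:.1e}  max k2 rel err = {k2_err:.1e}")

x0 = perturb_initialization(x_true, 0.1, 0, frozen_fraction=True)
cfg = setup_config("reduced", COUNT_SETTINGS["noiseless"])
fit = run_irgnm(x0, clean.stacked(), 0.0, cfg, schedule, clean.CWB_samples)
zeta, _, spread, _ = align_scale(x_true, fit.x)
print(f"\nwith the blood-consistency block: zeta = {zeta:.6f} "
      f"(pinned to 1), spread = {spread:.1e}")
print("\nzeta varies across the tissue-only runs while k2/k3 and the "
      "relative K1\nprofile are recovered exactly — the blood samples only "
      "fix the overall scale.")
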