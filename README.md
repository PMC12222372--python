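# hepaflow

Hepatic blood flow (HBF) quantification from dynamic ¹⁵O-water PET.

The liver is fed by two vessels — the hepatic artery and the portal vein
(PV) — so the standard one-tissue compartment model (1TCM) with a single
arterial input cannot describe its kinetics: the portal input arrives
delayed and dispersed and carries most of the flow. `hepaflow` implements a
dual-input compartment model whose portal input is an image-derived TAC
from the hepatic PV itself,

    dC_T/dt = f_A·C_A(t−Δt₁) + f_P·C_PV(t−Δt₂) − k·C_T(t),
    C_PET   = (1−V_B)·C_T + V_B·(f_A·C_A + f_P·C_PV)/(f_A + f_P),

alongside three comparators: the plain 1TCM and two dual-input variants
whose portal input is a notional dispersed compartment (one fixing the
arterial delay from a spleen pre-fit, one fitting its delay directly).
Arterial HBF is `f_A`, portal HBF `f_P`, total HBF `f = f_A + f_P`
(mL/min/mL), and the water partition coefficient is `V_T = f/k`.

The package is aimed at PET kinetic-modelling researchers: it provides the
forward models (explicit 1-s recursion), least-squares fitting with an
exhaustive integer delay-grid search, VOI TAC extraction from 4-D images
(largest connected component, per-frame 90th-percentile portal TAC),
frame-level error metrics (MRE, MSE in kBq/mL, AIC) with non-parametric
cohort statistics, and a synthetic-data generator so the entire pipeline is
testable without patient data. See `docs/methods.md` for the full model and
numerical details.

## Worked example

Generate one synthetic subject at the default ground truth (arterial flow
0.299, portal flow 0.930 mL/min/mL, washout 1.603 /min, blood volume
fraction 0.095, delays 18 s and 23 s), add 5% frame noise, and fit the
measured-PV model:

```python
import numpy as np
from hepaflow import (FitConfig, SubjectSpec, fit_with_delay_grid,
                      generate_subject, interpolate_to_seconds)

subject = generate_subject(SubjectSpec(noise_fraction=0.05, seed=3))
config = FitConfig(delay_stride=5, refine=True)  # coarse search + refinement
curves = {
    name: interpolate_to_seconds(tac, method=config.interp)
    for name, tac in subject.noisy_tacs.items()
}
result = fit_with_delay_grid(
    "new_dual_input", curves["liver"], curves["aorta"],
    pv=curves["portal_vein"], config=config,
    measured_frames=subject.noisy_tacs["liver"],
)
p, d = result.params, result.derived
print(f"f_A = {p.f_A:.3f}, f_P = {p.f_P:.3f} mL/min/mL, k = {p.k:.3f} /min")
print(f"V_B = {p.V_B:.3f}, delays = ({p.dt1}, {p.dt2}) s")
print(f"total HBF = {d.f_total:.3f} mL/min/mL, V_T = {d.V_T:.3f}, "
      f"portal fraction = {d.portal_fraction:.2f}")
print(f"MRE = {result.metrics.mre:.3f}, MSE = {result.metrics.mse:.4f} (kBq/mL)^2")
```

Output:

```
f_A = 0.341, f_P = 0.927 mL/min/mL, k = 1.662 /min
V_B = 0.091, delays = (19, 26) s
total HBF = 1.268 mL/min/mL, V_T = 0.763, portal fraction = 0.73
MRE = 0.043, MSE = 0.0591 (kBq/mL)^2
```

The fitted total HBF (1.268) recovers the generating 1.229 mL/min/mL to
within about 3% despite the frame noise; the delays land within a few
seconds of the truth, and the portal fraction (~0.73) reflects that the
portal vein carries about three quarters of the liver's blood supply.

A command-line interface covers the same pipeline:

```sh
hepaflow simulate --n 5 --seed 1 --noise 0.05 --phantom --out-dir synth/
hepaflow extract  --pet synth/subject_000_pet.nii.gz \
                  --masks synth/subject_000_masks.nii.gz \
                  --labels synth/subject_000_labels.json \
                  --schedule synth/subject_000_schedule.json \
                  --pv-percentile 90 --out tacs.tsv
hepaflow fit --model new_dual_input --tacs tacs.tsv --out result.json
```

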