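# Methods

## The problem

The liver receives blood from two sources: the hepatic artery and the portal
vein (PV), which drains the splanchnic circulation. Quantifying hepatic
blood flow (HBF) from dynamic ¹⁵O-water PET therefore cannot rely on the
standard one-tissue compartment model (1TCM) with a single arterial input —
the portal input is delayed and dispersed relative to the aorta and carries
the majority of the flow, so a single sharp arterial input forces the model
to misplace the liver uptake and underestimate total flow.

`hepaflow` implements four kinetic models of the liver time-activity curve
(TAC):

1. **1TCM** — `dC_T/dt = f·C_A(t−Δt₁) − k·C_T(t)`, with flow `f`
   (mL/min/mL), washout `k` (/min) and an integer arterial transit delay.
2. **Spleen-delay dual-input** — a notional dispersed portal compartment
   `dC_PV/dt = f_p·C_A(t−Δt₁) − f_p·C_PV(t)` feeds
   `dC_T/dt = f_A·C_A(t−Δt₁−Δt₂) + E·f_p·C_PV(t−Δt₂) − k·C_T(t)`, with the
   arterial delay Δt₁ fixed beforehand by fitting the delayed 1TCM to the
   spleen TAC. `E` is a portosystemic shunting fraction; the effective
   portal flow is `E·f_p`.
3. **Fitted-delay dual-input** — the same two compartments, but with
   undelayed liver inputs `f_A·C_A(t) + E·f_p·C_PV(t)` and the single delay
   Δt₁ (on the portal compartment) searched during the fit.
4. **Measured-PV dual-input** — the portal input is an image-derived TAC
   from the hepatic PV itself, so a single equation suffices:
   `dC_T/dt = f_A·C_A(t−Δt₁) + f_P·C_PV(t−Δt₂) − k·C_T(t)`.

In every model the observable liver signal is a blood-volume mixture
`C_PET = (1−V_B)·C_T + V_B·blood`, where `blood` is the arterial curve for
the 1TCM and the flow-weighted mean of the (undelayed) arterial and portal
curves for the dual-input models. Derived quantities: total flow
`f = f_A + f_P` (with `f_P = E·f_p` for the dispersed variants), water
partition coefficient `V_T = f/k`, and the portal fraction `f_P/f`.
Extraction of water is assumed complete on first pass, and the liver is
treated as one homogeneous region.

## Discretization

All curves live on a 1-s grid `t = 1..280` (zero for `t ≤ 0`), matching the
24-frame acquisition (14×5 s, 3×10 s, 3×20 s, 4×30 s). Each model is
integrated by the explicit recursion

    C_T(i) = f_s·u(i−Δt−1) + (1−k_s)·C_T(i−1),

a forward-Euler step with per-second rates `f_s = f/60`, `k_s = k/60`
(parameters are stored in per-minute units; storing per-step gains instead
is available via `raw_rates` for replication studies, but per-minute is the
only reading under which flows near 1.2 are stable). The recursion keeps
the printed one-sample input lag. Against an independent 0.01-s convolution
of the continuous equations, the recursion stays within 2% relative L2 over
the physiological range (`f, k ∈ [0.1, 3]` /min) on gamma-variate inputs —
verified per model in the test suite and recomputed by
`scripts/acceptance.py`. Explicit Euler is adequate because per-second
rates are ≪ 1 in this regime; no implicit scheme is used.

## Frame ↔ grid conversion

Measured data are frame means. `interpolate_to_seconds` reconstructs a 1-s
curve as a piecewise-linear function anchored at frame midpoints, with a
zero anchor at `t = 0` and constant extrapolation past the last midpoint.
Two anchor conventions are provided:

* **midpoint** (operation default): each frame mean is placed at the frame
  midpoint. Unbiased for curves linear within each frame, but it
  systematically flattens sharp peaks — a frame mean underestimates a peak
  value — which propagates into the kinetic fit: in a noise-free
  end-to-end simulation the recovered portal flow was biased by about −3%.
* **conserving** (fit-pipeline default, `FitConfig.interp`): the anchor
  values are solved (one small linear system per TAC) so that the
  reconstructed curve's frame averages reproduce the measured means
  exactly. This removes the peak-flattening bias; the same end-to-end
  simulation recovers every parameter within 0.05%.

`frame_average` is the inverse direction: the mean of the integer-second
samples in `(start, end]`. Note that this sample mean sits half a sample
past the frame midpoint, so midpoint interpolation round-trips a linear
ramp with a bounded slope/2 offset; only constants round-trip exactly.

## Fitting

The sum of squared differences between the measured (reconstructed) liver
curve and `C_PET` over `t = 1..280` is minimized. Continuous parameters are
fitted by an unconstrained Newton-type method from the standard initial
values `f = 1, k = 1, f_A = 0.5, f_p = 0.6, E = 0.9, f_P = 0.5, V_B = 0.1`;
positivity is imposed by an absolute-value transform and `E, V_B ∈ [0, 1]`
by the inverse logit (boundary values clamp to ±36 on the raw scale).
Because the objective is a sum of squares, the inner solver is a
trust-region Gauss-Newton method on the residual vector
(`scipy.optimize.least_squares`, numeric Jacobian, Jacobian column
scaling) rather than a scalar quasi-Newton iteration: near a perfect fit
the SSE valley is extremely flat and ill-conditioned, and finite
differences of the *scalar* objective sink below rounding noise long
before the parameters are pinned down (measured stalls of 20–47% in
noise-free recovery), whereas residual-level Gauss-Newton descends to
machine precision.

The likelihood surfaces are multimodal: the dual-input models have a
single-input local minimum in which the portal branch collapses to zero,
and the shunting fraction `E` can saturate its logit. Each inner fit
therefore runs from the standard initials plus a small deterministic set
of alternative starts (portal-dominant; slow-kinetics for the
dispersed-compartment models) and keeps the best optimum; the winning grid
cell is additionally polished at machine-precision tolerances.

Integer delays are chosen by exhaustive grid search over 0..65 s —
simultaneously (66² inner fits) for the two-delay models — keeping the
lowest SSE; ties break towards the smaller Δt₁, then Δt₂. Non-converged
inner fits keep their achieved SSE in the argmin and are flagged in the
diagnostics.

Two documented accelerations exist: a coarse `delay_stride` with an
optional stride-1 refinement window around the coarse winner (`refine`),
and `warm_start`, which seeds each cell from the previous cell's solution.
Warm starting is **off by default**: although it roughly halves the search
time, a poor basin in an early cell can be handed down the chain — in a
noise-free experiment it made the true delay cell converge to the wrong
optimum and corrupted the grid argmin. Every cell therefore starts from the
standard initials unless explicitly configured otherwise.

The spleen pre-fit for the spleen-delay model fits the delayed 1TCM to the
spleen TAC (spleen activity standing in for the tissue curve) over the full
delay grid; the blood-volume term is included by default and can be
disabled (`spleen_blood_volume`), since the convention is not fixed by the
procedure's description.

## Evaluation metrics

Goodness of fit is judged on the original frames, not the fitting grid:
the fitted curve is frame-averaged back onto the schedule (the measured
value is itself a frame mean; point-sampling at midpoints is available via
`sample_at_midpoint`) and compared by

    MRE = (1/24) Σ |C̃(tᵢ) − C_PET(tᵢ)| / C̃(tᵢ)
    MSE = (1/24) Σ (C̃(tᵢ) − C_PET(tᵢ))²   [kBq/mL]
    AIC = 24·ln(max(MSE, 1e-12)) + 2N

with `N = 4, 7, 6, 6` parameters for the four models. The natural log is
used (the standard AIC convention); the 1e-12 (kBq/mL)² floor keeps a
perfect fit finite. Frames with near-zero measured activity (< 1e-6 Bq/mL)
are dropped from the MRE with the divisor reduced, since the relative error
is undefined there.

Cohort statistics follow the non-parametric route: one-sided Wilcoxon
signed-rank tests on paired error terms (exact null for n ≤ 25 without
ties, normal approximation with continuity correction beyond), Mann-Whitney
U for group contrasts, and Pearson correlation with the t-based test on
n − 2 degrees of freedom. No multiple-testing correction is applied.

## Synthetic data

The generator emulates the study conditions rather than scanner physics:

* **Arterial input**: gamma-variate `A·(t−t₀)^α·e^{−(t−t₀)/β}` with
  defaults `t₀ = 8 s, α = 3, β = 6 s` (peak near 26 s, i.e. within the
  first minute) and amplitude giving a ≈ 49 kBq/mL peak, plus a
  recirculation shoulder (15% of peak, 40-s time constant) so the tail
  stays elevated the way recirculating water keeps arterial activity from
  returning to zero.
* **Portal input**: the unit-gain dispersion compartment at 1.25 /min with
  a 5-s delay — delayed, lower and broader than the aorta, with the
  dispersion rate at the scale the dispersed-compartment models estimate.
* **Liver**: the measured-PV model at the cohort-mean estimates
  `f_A = 0.299, f_P = 0.930 mL/min/mL, k = 1.603 /min, V_B = 0.095,
  Δt₁ = 18 s, Δt₂ = 23 s` (any other model's parameters can be supplied).
* **Spleen**: a 1TCM of the aorta (`f = 1.0, k = 1.1 /min, V_B = 0.2`,
  delay 22 s), giving the spleen pre-fit a well-defined truth.
* **Noise**: multiplicative Gaussian per frame,
  `value·(1 + σ·z/√(duration/5 s))`, a simple stand-in for count
  statistics in which longer frames average more counts. Default σ = 5% at
  5-s frames. All randomness derives from one recorded seed per subject;
  regeneration is bit-identical.

The phantom writes the four VOIs as disjoint boxes into a 40×40×20 grid
(PET-like 1.65×1.65×2.80 mm voxels); the portal-vein box can carry a cold
outer rim (default 70% of voxels at 50% intensity) emulating the
partial-volume-dimmed shell of a thin vessel, which is what motivates the
90th-percentile TAC over the plain mean.

What the generator does **not** model: scatter, randoms, reconstruction
correlations, respiratory motion, intra-organ heterogeneity, or realistic
covariate structure. Passing the recovery tests therefore shows the
estimation machinery is self-consistent under the stated noise model — not
that real-data estimates carry these error bars.

## VOI extraction

Masks are cleaned by keeping the largest 26-connected component (ties go to
the component met first in scan order; 26-connectivity is the permissive
choice appropriate for thin vessels). CT-grid masks are resampled to the
PET grid by nearest-neighbour voxel-centre mapping through the two
affines. TACs are per-frame in-mask means; the portal vein uses the mean of
voxels at or above the per-frame 90th percentile (linear-interpolation
percentile, inclusive threshold, so at least a tenth of the voxels always
contribute; masks under 10 voxels fall back to the per-frame maximum with a
warning). With `q = 0` the percentile TAC reduces exactly to the mean.

## Validation studies and problem sizes

`hepaflow.studies` packages the validation loops used by the test suite and
`scripts/acceptance.py`:

* discretization check: 20 parameter draws per model against the 0.01-s
  convolution reference;
* noise-free self-recovery: 10 draws per model, delays drawn in 0..28 and
  searched exhaustively on a 0..30 grid (the full 0..65² search behaves
  identically and is simply slower);
* stochastic recovery: 20 replicates at the cohort-mean truth with 5%
  frame noise, fitted with stride-5 coarse search plus stride-1 refinement;
* 1TCM bias direction: 20 replicates, full 0..65 delay grid;
* test calibration: 1000 null simulations at n = 57;
* phantom round trip: one noise-free subject through image → extraction →
  fit, plus the rimmed-PV percentile-vs-mean comparison.

### Structural non-identifiability of the spleen-delay model

In the spleen-delay dual-input model both liver input terms are effectively
the arterial curve delayed by Δt₁+Δt₂: the direct term explicitly, and the
portal term because the dispersion compartment is driven by the Δt₁-delayed
aorta and then shifted by Δt₂. The tissue response to that common input is
a two-exponential kernel that is symmetric under swapping `(k, f_p)` with
reweighted `(f_A, E)`, and the blood-volume mixture adds a further soft
direction. Whenever a swapped or reweighted solution respects the bounds,
*several distinct parameter vectors fit the curve exactly* — verified in
the recovery study, where three vectors (one of them the truth) reach
SSE/energy ≈ 1e-30 with different `E`, `f_A`, `V_B` and even different
total flow `f_A + E·f_p`. No optimizer can prefer the truth among exact
ties, so per-parameter recovery for this model fails on such draws; the
corresponding validation check documents this honestly rather than hiding
it. The delays themselves still recover exactly. The measured-PV model
does not share this degeneracy — its two inputs are genuinely different
curves — which is a quantitative argument for preferring it.

### Identifiability under noise

Noise-free self-fits recover every parameter to optimizer precision and
every delay exactly. Under 5% frame noise the error distribution of the
total flow is heavy-tailed: most replicates land within a few percent, but
occasional replicates miss by ±25% because noise genuinely relocates the
SSE global minimum to a different delay pair — at such optima the wrong
delays fit the noisy curve better than the true ones do, which restarting
the optimizer from the truth confirms. The *median* error (the bias) stays
within a few percent; single-subject estimates should be read with this
tail in mind. The delay/blood-volume/flow trade-off is the main coupling:
underestimated delays are compensated by shifted flow splits.

## Known limitations

* Whole-liver, single-region modelling only; no partial-volume correction.
* Input TACs are treated as noise-free regressors during fitting
  (errors-in-variables effects are visible in the stochastic study).
* The conserving reconstruction assumes the underlying curve is reasonably
  piecewise-linear between frame midpoints; gross undersampling of the
  bolus by the frame schedule cannot be undone.
* The delay grid is integer-second by construction.
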