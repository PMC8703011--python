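# Methods

## Scope and model chain

The package implements a single-cell CiPA-style proarrhythmia assessment:
Hill-equation ion-channel block with bootstrap uncertainty, a paced
O'Hara–Rudy (2011, "ORd") endocardial ventricular myocyte under drug block,
nine electrophysiological biomarkers, a 9-5-3 artificial neural network
three-class TdP-risk classifier, and a bootstrap AUC / likelihood-ratio
evaluation. Tissue-level simulation, epicardial/mid-myocardial cell types,
dynamic (state-dependent) hERG drug binding, and cycle-length sweeps are out
of scope.

## Dose–response model and bootstrap

Fractional block of a channel at concentration D (nM) is
`block(D) = 1/(1+(IC50/D)^h)`. Fitting minimizes squared residuals over all
replicate rows, parameterized as (log10 IC50, h) with bounds
log10 IC50 ∈ [−3, 9] and h ∈ [0.2, 10] (the bounds prevent degenerate fits on
flat or single-sided data; the physiological range of h is ~0.5–4). A channel
whose data show no dose-increasing block (max block ≤ 1% or non-increasing
dose-averaged response) carries the no-block sentinel IC50 = +∞, h = 1, which
makes the inhibition factor exactly 1 at any concentration; every drug sample
therefore always covers all six channels.

Uncertainty is quantified by nonparametric case-resampling bootstrap: rows
are resampled with replacement and refit. The first n fits fix a joint
central-95% box (2.5–97.5 percentiles of log10 IC50 and of h); fits outside
the box are discarded and resampling continues until exactly n (default
2,000) fall inside. This reproduces the contract of "2,000 Hill curves
within the 95% confidence interval" with a far simpler procedure than a
posterior sampler; the box is per-marginal, a deliberate simplification. On
noiseless data every resample refits to the same optimum, so all n samples
equal the point fit.

## Myocyte model and integration

The cell is the full ORd 2011 endocardial formulation (41 states) with five
maximal conductances rescaled per Dutta et al.: IKs ×1.870, ICaL ×1.007,
IKr ×1.013, INaL ×2.661, IK1 ×1.698 (Ito unscaled). Drug block multiplies
each of the six measured channels' conductance by the inhibition factor
`1/(1+(D/IC50)^h)`; the factor is 1 with no drug and 0.5 at D = IC50.

Pacing: basic cycle length 2,000 ms, 1,000 stimuli of 0.1 ms. The stimulus
amplitude starts at −80 A/F and is doubled (at most three times) until the
drug-free model produces an action potential; with the 0.1 ms pulse the
model captures at −320 A/F, and that resolved amplitude is used for all drug
runs so the protocol is fixed across conditions.

Integration is adaptive explicit: Hodgkin–Huxley gates (and the relaxation
form of the SR release flux and the ICaL Ca-dependent mode fraction) advance
by Rush–Larsen exponential updates, everything else by forward Euler. The
step targets 0.2 mV of membrane-potential change (dt ∈ [0.002, 0.5] ms), so
the upstroke integrates at 2 µs steps and diastole at 0.5 ms. Halving all
step controls moves the steady-state APD90 by ~0.35%, within the 0.5%
step-doubling contract. The whole pacing loop is numba-compiled
(~6 ms/beat), deterministic, and free of random numbers. Outputs (Vm,
[Ca²⁺]i, six currents) are linearly interpolated onto a 0.1 ms grid.

qNet and the INaL/ICaL AUCs are accumulated trapezoidally *inside* the
solver at step resolution rather than from the decimated output grid: during
the upstroke the currents sweep their full I–V range in well under 0.1 ms,
and a 0.1 ms grid quadrature is ~0.2% off the true integral after the large
inward/outward cancellation. The in-kernel integral agrees with an
independent midpoint-rectangle quadrature of a 0.01 ms recording to ~0.006%.

The drug-free steady state (1,000 pre-paced beats) ships with the package as
JSON keyed by a hash of the model/protocol configuration and is otherwise
cached on first computation (~15 s). Drug runs start from this drug-free
paced steady state; since only the final beats of a long run are analyzed,
the choice of initial state is immaterial at paper scale and is the sensible
anchor for shortened runs.

## Biomarkers

Among the recorded beats, the representative action potential is the one
maximizing dVm/dt during the repolarization window (from just after the AP
peak to the end of the cycle), excluding beats that fail to depolarize
(peak Vm < 0 mV) or to repolarize (Vm never returns below the 90%
repolarization level within the cycle). A beat carrying an early
afterdepolarization has a large positive repolarization-window dVm/dt, so
the rule deliberately selects the most proarrhythmic beat.

Durations anchor at the instant of maximal upstroke slope (the standard
electrophysiological depolarization point) and end at the linear-interpolated
crossing of `peak − x%·(peak − resting)`; calcium-transient durations are
measured identically on [Ca²⁺]i. AP_resting and Ca_resting are the values
immediately before the stimulus. qNet is reported in µC/µF (A/F integrated
over ms, ÷1000); qInward is exactly 1 for a drug-free beat by construction.
Features are averaged over the four concentrations (1, 2, 3, 4 × free Cmax);
if any concentration has no valid beat the (drug, sample) row is flagged
missing, logged, and excluded from training and from bootstrap test
sampling.

## Classifier

Nine features are min–max scaled from the training rows only (a constant
feature maps to 0.5; test values outside the training range are not
clipped). The network is 9-5-3 (ReLU hidden, softmax output), trained by
Adam (lr 0.01, β₁ 0.9, β₂ 0.999, ε 1e-8) on categorical cross-entropy with
batch size 32 for 100 epochs; initialization is Glorot-uniform and both init
and shuffle order derive from one seed, so training is bit-reproducible.
Leave-one-drug-out cross-validation refits the scaler and network per fold
for validation reporting; the final model is trained once on all training
drugs with the same frozen hyperparameters. Labels are one-hot in the fixed
order (high, intermediate, low); classes are unweighted. Weights round-trip
through JSON, with no binary framework dependence. A feature-subset option
supports ablation experiments (e.g. dropping qInward) but defaults to all
nine.

## Evaluation

A test dataset draws one feature row uniformly per test drug; n_datasets
(default 10,000) datasets give distributions of per-class one-vs-rest AUC
(trapezoidal ROC, ties 0.5 — verified exactly equal to the pairwise
Mann–Whitney statistic) and of likelihood ratios computed from argmax
predictions. Both LR formulas use the corrected specificity
s′ = specificity − 10⁻³, so LR+ = sens/(1−s′) ≤ 1000 and LR− = (1−sens)/s′
are always finite; a perfect classifier yields LR+ = 1000 exactly, and every
evaluation report states this cap. Datasets in which a class has no
positives or no negatives yield undefined entries, which are excluded with a
logged count (impossible with a fixed full panel, possible with small
synthetic ones). Summaries are medians with 2.5–97.5 percentile intervals.

## Synthetic data

The generator emulates a class-structured 28-drug panel (12 training /
16 test, four per class in training; 5/6/5 in test). IC50s are drawn as
ratios to the drug's free Cmax (itself log-uniform on 30–3000 nM), with
Hill coefficients uniform on 0.7–2.0:

* high risk: IKr IC50 at 0.3–0.7 × Cmax, inward channels weak (30–300×);
* intermediate: IKr at 1–3 × Cmax, mild ICaL/INaL block (10–30×);
* low risk, alternating subtypes: balanced (ICaL 0.4–1 × Cmax offsetting
  IKr 1.5–4×) and negligible-block (IKr 8–30×).

Dose–response tables use six doses at 0.25–54 × Cmax, three replicates, and
additive Gaussian noise (σ = 0.05) on fractional block, clipped to [0, 1].
This emulates the potency structure and measurement noise of patch-clamp
panels but not their real covariances, pace dependence, or per-lab
variability — so passing tests demonstrate correct mechanics and
signal-recovery capacity, not clinical-grade discrimination on real drugs.
Piecewise-linear "toy beats" (instantaneous rise, linear decay) provide
analytically known biomarker values for oracle tests.

## Scale presets

The paper-scale protocol (2,000 bootstrap samples per drug, 1,000 beats per
run with the last 250 recorded, 10,000 test datasets — i.e. 24,000 training
rows and ~10⁵ thousand-beat simulations) is the default for real use. The
desk preset, used by the test suite and the acceptance script, runs the same
pipeline at 8 samples per drug, 24 beats per drug run (started from the
cached drug-free steady state, last 4 recorded) and 500 test datasets: a
full 28-drug synthetic run takes ~2 minutes on one CPU. Because drug runs
start from the drug-free steady state, two dozen beats express the bulk of
the drug effect on the biomarkers; slow ionic drift over hundreds of beats
is not captured at desk scale, which slightly compresses (but does not
reorder) class differences.

## Known limitations

* Static Hill block only: no state-dependent hERG binding kinetics, so
  trapping/untrapping differences between hERG blockers are invisible.
* Endocardial single cell at one cycle length; no transmural or rate
  dependence.
* The likelihood-ratio scale is capped at 1000 by the specificity
  correction; reported LR+ medians saturate there for a perfect classifier.
* The per-marginal bootstrap trim box ignores the (IC50, h) correlation
  structure.
* The synthetic panel is deliberately well-separated; real CiPA drugs
  overlap far more, and no claim about real-data AUC follows from the
  synthetic results.
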