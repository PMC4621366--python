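# Methods

`doanet` implements a depth-of-anesthesia (DoA) index pipeline for
intraoperative monitoring research: a single-channel 125 Hz EEG is
EMD-filtered and summarized by windowed sample entropy, fused with six
0.2 Hz vital signs, and mapped to a 0–100 consciousness index by a
small log-sigmoid backpropagation network trained against an averaged
clinician score. This note records the models, the defaults and why
they are what they are, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Signal model and pipeline

**Windowing.** All EEG processing is per non-overlapping 5 s window
(625 samples at 125 Hz), so the EEG feature lands on the same 0.2 Hz
grid as the vitals and the clinician score. Windows are decomposed
independently; no cross-window continuity is attempted, since the
downstream feature (one entropy value per window) does not use phase
across windows. A trailing partial window is dropped with a warning.

**EMD.** Each window is decomposed into intrinsic mode functions by
iterative sifting: cubic-spline envelopes through the local maxima and
minima, with the two outermost extrema mirrored past each end of the
window to tame spline end-swing. A sift stops when the Huang
standard-deviation criterion Σ(h_{k−1}−h_k)²/Σh_{k−1}² < 0.2 is met
*and* the candidate satisfies the IMF criterion (extrema and
zero-crossing counts differ by ≤ 1), with a hard cap of 100 passes —
the SD criterion alone occasionally stops one pass short of a valid IMF
on noisy windows. Decomposition stops when the residual is monotone,
has fewer than three extrema, or carries less than 1% of the source RMS
(without the last condition a pure sinusoid sheds a trail of spurious
micro-IMFs). The reconstruction identity Σc_i + r = x holds to
floating point exactly because each sift subtracts in place.

**Band selection.** The 0.8–32 Hz EEG content is taken as IMFs 2–6:
IMF 1 carries the above-band muscle/instrument noise, the trailing
IMFs and residual carry drift. If a window yields fewer than 6 IMFs
the available ones from 2 upward are used and the result is flagged
`truncated`; fewer than 2 IMFs gives the zero signal flagged `empty`.
The pipeline never errors out mid-record on a degenerate window.

**Sample entropy.** SampEn(m, r, N) = −ln(A/B) with m = 2,
r = 0.15 × SD and N = 625. Both match counts average over the same
template range i ∈ [1, N−m] (templates of length m for B, m+1 for A),
Chebyshev distance, self-matches excluded; this makes A ≤ B structural,
hence SampEn ≥ 0, and makes exactly periodic series give exactly 0.
The tolerance uses the *population* SD (ddof = 0) of each window —
per-window rather than per-record, so the statistic is invariant to
slow amplitude drift and to overall scale. A constant window returns 0
by convention; a window with no matches at either length returns a NaN
sentinel and is dropped (and counted in a log record) when the feature
table is assembled, rather than raising.

**Feature table.** One row per window: `sampen` plus the six vitals
(EMG, HR, pulse, SBP, DBP, SQI), inner-joined on the window-end
timestamp, target = arithmetic mean of the rater scores. SQI is an
input feature, not a row filter. Inputs are min–max normalized to
[0, 1] with bounds fitted on training rows only; out-of-range test
values clip (the log-sigmoid saturates there anyway) and a degenerate
constant column maps to 0.5 with a warning. The target is divided by
100 on the way into the network and the output multiplied by 100 on
the way out.

**Network.** 7 → 10 → 1, log-sigmoid throughout, squared-error loss
E = ½(y−t)², stochastic per-sample updates with momentum
Δw = −η ∂E/∂w + α Δw_prev, η = 0.005, α = 0.15, 10,000 epochs, rows
reshuffled every epoch. Weights initialize uniform on [−0.5, 0.5] from
the seed. No early stopping by default (an optional patience flag
exists); full-batch mode is available behind a config flag. These
update-rule constants are the method's stated configuration; the
initialization scale, online update mode and ×100 output scale are this
package's choices where the method description is silent.

**Cross-validation and ensemble.** Folds are assigned at the patient
level (seeded shuffle, round-robin; sizes differ by ≤ 1) because rows
within a patient are strongly autocorrelated and row-level splits would
leak. Each fold's normalization bounds are fitted on its own training
patients. The final predictor averages the 10 fold models' outputs,
with shared bounds fitted on all modeling patients pooled.

**Sensitivity analysis.** With a trained model and a normalized table:
baseline = output at the vector of column means; each input in turn is
swept over 0.0, 0.1, …, 1.0 with the others held at their means, and
scored by the MSE of the 11 outputs against the baseline — the larger
the MSE, the more the model's output depends on that input. "MSE
against the baseline" is the reading under which the mean-input
simulation in step 2 serves as the comparison target. Per-input MSEs
are averaged across folds for the ranking; adjacent ranks are compared
with a paired two-sided Wilcoxon signed-rank test on the fold-wise
values (α = 0.05; the test used for the published p-values is not
stated, so a paired t-test is offered behind a flag). Ties break by
the fixed input order (sampen, emg, hr, pulse, sbp, dbp, sqi). An
input with zero first-layer weights has sweep MSE exactly 0 and ranks
last.

**Evaluation.** MAE ± SD of |pred − ref| (sample SD, n−1 throughout —
this reproduces the printed cross-validation summary 6.61 ± 0.15 from
the ten per-fold values), Pearson r per patient (NaN sentinel for
constant series), and ROC/AUC with *unconscious* (reference ≤
threshold) as the positive class, so a lower predicted index argues for
the positive class; a flag flips the orientation. The curve is a
hand-built threshold sweep with tied scores collapsed, so the trapezoid
area equals the Mann–Whitney concordance count with ties as ½ exactly.
Thresholds either come from the BIS literature (48.8 = mean BIS during
unconsciousness; 70 = lowest conscious value) as configuration
constants, or are derived from training targets as mean + k·SD for
k ∈ {1, 1.5, 2}.

## Synthetic patients

No intraoperative dataset of this kind is public, so the generator
produces patients with the statistical structure the pipeline assumes.
Every stream derives from one per-patient seed expanded into named
`SeedSequence` substreams, so outputs are bit-reproducible and adding a
channel never perturbs another.

**Latent trajectory.** Consciousness on [0, 100] at 0.2 Hz: awake
plateau (85–95), smooth sigmoid induction (midpoint at 10–20% of the
case), maintenance plateau (15–32) with a small smoothed random wander,
sigmoid emergence (80–90%). Minimum duration 50 s (10 windows).

**EEG.** Three components at a fixed broadband reference amplitude
(~30 µV scale): unit-RMS white noise band-passed to 0.8–32 Hz; a
1–3 Hz slow wave with amplitude 3·(1 − state/100), emulating the
large-amplitude delta activity of deep anesthesia (it also dominates
the window SD, hence the SampEn tolerance, which is what drives the
entropy down); and an above-band noise floor (white noise high-passed
at 50 Hz, 0.4 RMS) standing in for the muscle/instrument noise that
occupies IMF 1 in raw intraoperative EEG. The floor matters twice:
it is the reason band selection starts at IMF 2, and it keeps the IMF
index ladder aligned between clean and artifact-contaminated windows —
without it, a burst inserts a new fastest scale and shifts every IMF
index by one, so fixed index selection would silently un-filter
contaminated windows. An earlier cross-fade design (state-weighted mix
of broadband and slow wave) was abandoned for exactly these reasons:
with no above-band floor the index ladder is unstable under artifacts,
and with one, the broadband's fast content migrates in and out of
IMF 1 as the mixing weight changes, breaking monotonicity of the
filtered entropy in the latent state.

**Vitals.** Each channel is baseline + gain·state + Gaussian noise,
clipped to physiological ranges (HR/pulse 30–180, SBP 60–220, DBP
30–130, SQI 0–100, EMG ≥ 0); excursions saturate rather than error.
The default effect profile gives EMG gain 0.8 and every other channel
0.05 (noise SD 2–3), making EMG the designed dominant input — the
known ground truth for the sensitivity-recovery experiment, mirroring
the reported finding that EMG is the most influential input.

**Raters.** Five scores = latent + independent N(0, 5), clipped to
[0, 100]; their mean is the training target. SD 5 makes a single
rater noticeably noisy while the 5-rater average tracks the latent
closely (the point of averaging).

**Artifacts.** Electrosurgical units switch at hundreds of kHz; what
survives a 125 Hz front end appears at the top of the digital band.
Bursts are therefore white noise high-passed at 55 Hz, scaled to 15×
the clean window RMS (≥ 10× enforced), added to selected windows only;
untouched windows stay bit-identical.

**What the generator does not emulate** — and hence what passing tests
do not show about clinical data: no pharmacokinetics or drug-specific
EEG signatures (burst suppression, spindles), no biophysical EEG (no
neural mass model), no non-stationary artifacts other than the bursts,
no rater bias or drift (noise is independent and zero-mean), and
vital-sign dynamics are memoryless functions of the latent state. The
end-to-end experiments demonstrate that the pipeline recovers structure
it was designed to recover, not clinical performance.

## Study conditions and problem sizes

The synthetic-cohort experiment (`pipeline.run_synthetic_study`, also
what `scripts/acceptance.py` runs) uses 10 modeling patients and 5
held-out test patients of 500 s each (100 windows per patient, ~1,000
modeling rows), 10-fold patient-level cross-validation, and a reduced
training schedule of 500 epochs — the full 10,000-epoch schedule is the
clinical configuration; at these cohort sizes the validation MSE curve
is flat long before 500 epochs, and the reduced schedule keeps the
whole experiment to a couple of minutes on one CPU. Oracle suites use
50 series (N ≤ 200) for SampEn, 100 signals for EMD conservation, 20
configurations for the gradient check and 40 instances for AUC.

## Numerical choices and edge cases

- Envelope splines use natural cubic interpolation (`CubicSpline`)
  over extrema extended by mirroring two extrema past each end;
  reflected knots that collide with an endpoint knot are deduplicated.
- Plateaus in extrema detection are handled by forward-filling slope
  signs, so a flat top counts once.
- The gradient check compares analytic backprop with central finite
  differences (ε = 1e−6) at error relative to the gradient's max-norm;
  per-weight relative error is meaningless for near-zero gradients at
  double precision.
- Wilcoxon on identical fold vectors (all differences zero) is defined
  as p = 1 rather than an error.
- `derive_thresholds` rejects constant targets (no spread → no
  threshold family); thresholds clip into (0, 100).
- Seeds: fold configs use `config.seed + fold`; patient seeds are
  `seed·1000 + index`. All user-facing entry points take one seed.

## Known limitations

- Plain EMD is used; mode mixing on real EEG (intermittent transients)
  would call for ensemble EMD, which is out of scope.
- SampEn is O(N²) per window via a full distance matrix — fine at
  N = 625, not intended for long unwindowed records.
- The network is deliberately minimal (no regularization, no adaptive
  optimizers); it is the method under study, not a general-purpose
  learner.
- ROC thresholds referenced to BIS values (48.8, 70) are literature
  constants, not quantities this package can validate.
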