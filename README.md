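# doanet

A depth-of-anesthesia (DoA) index pipeline for physiological-signal
research: from a raw single-channel 125 Hz EEG and 0.2 Hz vital signs
to a 0–100 consciousness index, with cross-validated training against
clinician scores, input-sensitivity ranking and ROC evaluation.

## The problem

During general anesthesia, clinicians need a continuous estimate of how
conscious the patient is. Commercial monitors (e.g. the bispectral
index, BIS) derive such an index from the EEG alone, but the EEG in an
operating room is routinely corrupted by electrosurgical interference,
and other vital signs — facial EMG, heart rate, blood pressure — carry
complementary information. `doanet` implements a multi-signal index:

1. **EMD filtering** — each 5 s EEG window (625 samples) is decomposed
   into intrinsic mode functions, x(t) = Σᵢ cᵢ(t) + rₙ(t), and the
   0.8–32 Hz EEG content is reconstructed as c₂ + … + c₆; IMF 1
   absorbs above-band noise (including electrosurgical bursts), the
   tail absorbs drift.
2. **Sample entropy** — each filtered window is summarized by
   SampEn(m=2, r=0.15·SD, N=625) = −ln(A/B), the negative log
   conditional probability that template matches of length m extend to
   m+1. Deep anesthesia produces large regular slow waves → low
   entropy; the awake cortex is irregular → high entropy.
3. **Feature fusion** — the entropy index joins six 0.2 Hz vitals
   (EMG, HR, pulse, SBP, DBP, SQI), min–max normalized to [0, 1]; the
   target is the average of five clinician consciousness scores.
4. **Network** — a from-scratch 7→10→1 log-sigmoid network trained by
   backpropagation with momentum (η = 0.005, α = 0.15), with
   patient-level 10-fold cross-validation and a fold-averaging
   ensemble.
5. **Analysis** — perturbation sensitivity ranking of the seven inputs
   (sweep each input 0→1 at the others' means, score by MSE against
   the mean-input baseline, Wilcoxon tests across folds) and
   evaluation by MAE ± SD, per-patient Pearson r, and ROC/AUC at
   consciousness thresholds.

Since no clinical recordings of this kind are public, the package
includes a first-class synthetic-patient generator (`doanet.synthdata`)
whose latent consciousness trajectory drives EEG spectral complexity,
correlated vitals, five noisy rater scores and electrosurgical
artifact bursts — giving known ground truth for every stage. See
`docs/methods.md` for the models and their assumptions.

## Worked example

```python
import numpy as np
from doanet import pipeline

study = pipeline.run_synthetic_study(seed=1)

print("EMG ranked most sensitive in",
      sum(int(np.argmax(f) == 1) for f in study.fold_sensitivity_mse), "of 10 folds")
print("ensemble MAE vs latent state:",
      round(float(np.mean(list(study.test_mae.values()))), 2))
print("constant-predictor MAE:",
      round(float(np.mean(list(study.constant_mae.values()))), 2))
print("median per-patient Pearson r:",
      round(float(np.median(list(study.test_r.values()))), 3))
```

prints (a couple of minutes on one CPU):

```
EMG ranked most sensitive in 10 of 10 folds
ensemble MAE vs latent state: 2.67
constant-predictor MAE: 23.16
median per-patient Pearson r: 0.992
```

The cohort is generated with the EMG channel's latent-state gain 16×
every other vital, so the sensitivity analysis should — and does —
recover EMG as the dominant input in every fold; the ensemble's index
tracks the hidden consciousness trajectory of held-out patients (MAE
2.67 against ~23 for predicting the training mean, r ≈ 0.99).

The same stages are available as a CLI for file-based work:

```sh
doanet synth --patients 10 --duration 500 --seed 1 --dominant emg --out data/
doanet decompose --in data/patient000/eeg.csv --out filtered.csv
doanet sampen --in filtered.csv --out entropy.csv
doanet featurize --patient data/patient000 --out features.csv
doanet train --features features.csv --epochs 500 --seed 1 --out model.json
doanet predict --model model.json --features features.csv --out doa.csv
doanet evaluate --pred doa.csv --ref data/patient000/raters.csv --out metrics.json
doanet crossval --patients data/ --k 10 --seed 1 --epochs 500 --out runs/
doanet sensitivity --models runs/ --features data/ --out sensitivity.json
```

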