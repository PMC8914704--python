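# neuroictal

Automated epileptic-seizure detection for multichannel scalp EEG, built
as an anomaly-detection pipeline that runs within the constraints of
neuromorphic prototype-memory hardware (4096 stored examples, 256 bytes
per example, L1 distances computed in parallel).

The intended application is time-critical: detecting seizure onset in
the EEG monitoring suite quickly enough to trigger a perfusion-tracer
injection for ictal SPECT imaging, where every second between electrical
onset and injection degrades localization of the seizure focus.  That
setting has very little per-patient ictal data (minutes of seizure
against hours of background), which favours fast-learning, data-efficient
prototype classifiers over large trained models.

## Who this is for

Researchers and engineers prototyping epoch-level seizure detectors:
the package provides the full chain — synthetic EEG cohorts, wavelet
preprocessing, nonlinear and sub-band feature extraction, feature
selection, hardware-faithful classifiers, and evaluation protocols —
as a tested Python library plus a `neuroictal` command-line tool.
No clinical data ships with it; a synthetic generator reproduces the
feature-level structure of focal seizures so everything is runnable
and testable out of the box.

## The method

1. **Epoching.** Each session (default 21 channels at 500 Hz) is cut
   into fixed-length epochs (default 5 s, no overlap).  An epoch is
   labelled ictal when at least half of it lies inside a seizure
   annotation.
2. **Cleaning.** Per channel, a six-level discrete wavelet decomposition
   (db4) with soft thresholding at the universal threshold
   σ·√(2·ln N) (σ from the MAD of the finest detail band) plus
   approximation-mean removal suppresses broadband artifacts and
   low-frequency drift.
3. **Features** (up to 23 per channel):
   - *SampEn(m, r)* = −ln(A/B), the sample entropy with m = 2 and
     r = 0.2·SD: A and B count template matches of length m+1 and m
     under the Chebyshev metric, self-matches excluded.  Ictal activity
     is more irregular ⇒ higher SampEn.
   - *CD*, the Grassberger–Procaccia correlation dimension: the scaling
     exponent d log C(r)/d log r of the correlation sum over
     delay-embedded points (E = 5, delay at the first autocorrelation
     zero-crossing, Theiler window).  Ictal discharges are driven by
     low-dimensional dynamics ⇒ lower CD.
   - 21 sub-band statistics: RMS, mean-of-absolute (MA) and
     absolute-of-mean (AM) of the seven DWD sub-signals D1..D6, A6
     (dyadic bands; at 500 Hz, D1 = [125, 250] Hz ... A6 = [0, 3.90625] Hz).
4. **Quantization.** Each feature is affinely mapped to one byte
   ([train-min, train-max] → [0, 255]), so 12 features × 21 channels =
   252 bytes fit the 256-byte hardware pattern.
5. **Classification.** A per-patient (individual) RCE network: each
   stored prototype carries an influence-field radius; training shrinks
   opposite-class fields and commits only uncovered vectors, iterated to
   a fixed point.  Queries outside every field are *Unknown* and are
   resolved by a population-trained 1-NN second stage.  k-NN, linear
   SVM and a small MLP are included as baselines.
6. **Evaluation.** Leave-one-session-out per subject (individual mode)
   or leave-one-subject-out (population mode); sensitivity
   TP/(TP+FN), specificity TN/(TN+FP), precision, recall and F1, in
   percent, with cross-subject mean and population variance.

## Worked example

```python
from neuroictal import (make_cohort, extract_cohort_features,
                        run_individual_protocol, ExperimentProtocol,
                        TwoStageConfig)

cohort = make_cohort(n_subjects=5, sessions_per_subject=3, master_seed=12345)
feats = extract_cohort_features(cohort, epoch_duration_s=5.0,
                                feature_set="rce-rfe")
res = run_individual_protocol(feats, ExperimentProtocol(
    classifier=TwoStageConfig(primary_kind="rce",
                              secondary_kind="population_knn")))
print({k: round(v, 2) for k, v in res.mean.items()})
```

prints (default cohort, shipped master seed 12345):

```
{'sensitivity': 92.19, 'specificity': 99.89, 'precision': 99.08,
 'recall': 92.19, 'f1': 95.13}
```

Sensitivity is the percentage of ictal epochs detected, specificity the
percentage of background epochs passed as normal, averaged over the
leave-one-session-out folds of each synthetic subject and then across
subjects.  The same cohort evaluated population-style (one model trained
on the other subjects) collapses to 1.4 % sensitivity, illustrating
why individual-based training matters when seizure morphology varies
strongly between patients.

The same pipeline from the shell:

```bash
neuroictal synth --subjects 2 --sessions 2 --seed 7 --out-dir data/
neuroictal epoch --input data/S01_s1.npz --epoch-s 5 --features full --out feats.h5
neuroictal select --method anova --store feats.h5 --out importance.csv
neuroictal train --model rce --features feats.h5 --out model.npz
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: it generates the default
5-subject × 3-session cohort from the given seed, extracts the
RCE-RFE feature set, verifies the ictal/interictal contrast of the
nonlinear features, and runs both the individual two-stage and the
population evaluation protocols, printing the summary metrics.  The
JSON output is an empty object: the reference performance figures for
this method were measured on a private clinical dataset that cannot be
redistributed, so there are no numeric reproduction targets — the
synthetic cohort validates mechanism, not clinical numbers.

## A note on the sensitivity formula

Some presentations of these metrics misprint the sensitivity
denominator as TP+TN.  This package uses the standard definition,
sensitivity = TP/(TP+FN)·100 — the fraction of seizure examples
detected — which the tests assert explicitly.

## Layout

| module | contents |
| --- | --- |
| `neuroictal.eeg_data` | Recording/Epoch data model, EDF + fixture I/O, HDF5 feature store, epoching, class balancing |
| `neuroictal.synthetic` | per-subject synthetic EEG cohort generator |
| `neuroictal.features` | wavelet cleaning, DWD statistics, SampEn, CD, byte quantization |
| `neuroictal.selection` | MI / chi² / ANOVA-F / RFE rankings, built-in feature sets |
| `neuroictal.classifiers` | capacity-limited k-NN and RCE networks, SVM/MLP baselines, two-stage composition |
| `neuroictal.evaluation` | metrics, LOSO protocols, sweeps, latency report |
| `neuroictal.cli` | `neuroictal` command-line tool |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
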