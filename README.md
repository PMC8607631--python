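# paravox

Sustained-vowel voice analysis for Parkinson's disease (PD) detection.

Hypokinetic dysarthria is an early motor symptom of PD, and a sustained
/a/ phonation recorded on a phone carries measurable traces of it:
cycle-to-cycle instability of the glottal source (jitter, shimmer,
glottal-quotient dispersion), added turbulent noise (lower HNR, CPP and
GNE), a changed spectral envelope (MFCCs) and altered signal complexity
(RPDE, correlation dimension, PPE, Hurst exponent, Lempel–Ziv,
permutation/Shannon entropy, mutual-information and autocorrelation time
scales, multifractal spectrum width). `paravox` is for researchers
building and stress-testing such screening pipelines: it implements the
complete chain from WAV to decision and, critically, ships synthetic
generators with exact ground truth so every stage is verifiable without
access to clinical recordings.

## The pipeline

1. **Trim** each recording to one second of voiced signal (frame-RMS
   criterion relative to the recording's own peak).
2. **Extract 32 features** per recording; add the sex indicator for the
   33-feature vector x. Recordings of a subject are averaged to one vector
   per subject.
3. **Select features**: 100 repeats of stratified 5-fold RFECV with
   one-feature-per-step elimination. Each repeat r yields an optimal
   subset size n_r; the final size is the first quartile Q1({n_r}), and
   the subset is the top of the mean elimination-order ranking.
4. **Tune** hyperparameters by grid search (stratified 5-fold accuracy).
5. **Evaluate**: 1000 stratified 75/25 holdout splits; scaling and
   imputation fitted on each training side; report accuracy, sensitivity,
   specificity and AUC as mean ± sd with a vertically averaged ROC band.
6. **Transfer**: freeze the selected features and hyperparameters from one
   cohort and evaluate on another; compare reports with Student's t-test.

Six classifier families are available: logistic regression, random
forest, perceptron, passive-aggressive, gradient boosting and SVM.

## Worked example

```python
import paravox as pv

# a synthetic 60-subject cohort: 33 features, 5 informative at 1.5 sd
table = pv.synth_cohort(pv.CohortSpec(
    n_per_class=30, n_features=33,
    informative=(0, 5, 10, 20, 30), effect_sizes=(1.5,) * 5, seed=42,
))

model = pv.VoiceDetectionModel(table, family="logistic",
                               selection_iterations=25,
                               eval_iterations=1000)
results = model.fit(seed=0)
print(results.summary())
```

```
Voice condition analysis — repeated stratified holdout
==========================================================
classifier family : logistic
subjects           : 60 (PD=30, healthy=30)
iterations         : 1000 (test fraction 0.25)
selected features  : 5 -> f31, f11, f01, f21, f06
hyperparameters    : {'C': 0.01}
----------------------------------------------------------
metric              mean        sd
accuracy          0.9608    0.0480
sensitivity       0.9245    0.0953
specificity       0.9970    0.0199
auc               0.9983    0.0058
----------------------------------------------------------
selection          10.75 s
grid_search         0.07 s
classification      3.68 s
```

All five truly informative features were recovered. The mean accuracy
(0.961) lands near — here slightly above — the Monte-Carlo Bayes accuracy
of the generative model (0.953): feature selection saw the full cohort
before the holdout repeats, the mild optimism inherent in this protocol.
`results.plot_roc_band()` draws the averaged ROC with its ±1 sd band;
`results.compare(other)` runs the per-metric t-tests.

Audio works the same way end to end:

```python
w, truth = pv.synth_vowel(pv.SynthesisSpec(
    f0_hz=120, duration_s=5.0, jitter_pct=2.0, shimmer_pct=5.0, hnr_db=15))
feats = pv.extract_features(pv.trim_to_voiced_second(w))
print(feats["jitter_pct"])   # ≈ 2.26: the extractor recovers the
                             # generator's own cycle-truth value
```

(The local-jitter formula applied to Gaussian period perturbations of
sd 2% yields ≈ 2·2/√π ≈ 2.26%, and `truth.cycle_periods_s` lets you check
the extractor against the exact synthesized cycles.)

A CLI mirrors the library: `paravox synth-audio`, `synth-cohort`,
`extract`, `select`, `tune`, `evaluate`, `transfer`, `compare`, `report`
(see `paravox --help`).

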