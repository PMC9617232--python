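# Methods

## Problem and model

`pdscreen` targets binary discrimination of Parkinson's disease (PD) from
controls using two passively recorded channels of a reading task: the voice
(prosody and pausing degrade in parkinsonian dysarthria) and the face
(hypomimia reduces spontaneous movement and blinking). The package has three
layers: deterministic feature extractors, a classical wrapper-selection +
classifier-benchmark pipeline, and a synthetic cohort generator that provides
ground truth for every extractor.

## Voice extraction

The waveform is normalised to the 16-bit signed-integer amplitude scale on
reading, whatever the source bit depth. This matters because the pause rule
uses *absolute* thresholds: a frame is a pause when its volume is below 30
(if the recording's mean volume exceeds 100) or below 20 (otherwise).
"Volume" is the mean absolute amplitude of a 25-ms frame (RMS available via
`VoiceConfig.volume_stat`); the statistic and its unit are a convention of
this package — the thresholds are only meaningful on this scale.

Pitch uses zero-crossing counting in 10-ms frames. A crossing is a sign
change between consecutive samples; zero samples adopt the last nonzero sign
so a single touch of zero counts once. Each consecutive-sample pair is
assigned to the frame containing its right-hand sample — with the naive
"pairs strictly inside the frame" convention, a periodic signal whose
crossings phase-lock to the frame grid (e.g. exactly 100 Hz at a 10-ms
frame) loses a fixed subset of crossings and the estimate biases low by up
to 20%. Average pitch is the mean crossing count over voiced frames divided
by 2 × 10 ms (≈ F0 in Hz for a near-periodic signal); pitch variance is the
mean absolute change between consecutive voiced-frame counts on the same Hz
scale, with the number of differences (not the number of frames) as the
denominator so that a constant change of one count per frame maps to 50 Hz.

Two conventions are deliberate design choices where the method description
leaves room:

* Pitch statistics use only voiced (non-pause) frames, because silent frames
  contribute broadband-noise crossings that would dominate the mean. The
  pause mask is resampled from the 25-ms volume grid to the 10-ms pitch grid
  by time overlap (voiced if ≥ half the pitch frame overlaps non-pause
  volume frames). `VoiceConfig.voiced_frames_only=False` restores
  all-frames behaviour.
* Volume variance is reported ×100 (a percentage-like drift number); the raw
  ratio is `volume_variance(..., x100=False)`. With an odd frame count the
  middle frame joins the first half — arbitrary but fixed.

Known limitation: the 10-ms crossing count quantises instantaneous frequency
to 50-Hz steps, so pitch variance has a quantisation floor for any jittered
signal; group *differences* in planted jitter survive, but the absolute
magnitude is estimator-specific and is not comparable across frame sizes.

## Facial extraction

EAR (eye height / eye width from four landmarks per eye, averaged over both
eyes) is smoothed with a trailing 30-frame rolling mean (≈ 1 s at 30 fps;
edge frames use the available shorter window). A frame is "in blink" at
threshold p ∈ {30, 50, 70, 90} % when the smoothed EAR is below p% of the
mean smoothed EAR; the blink feature is the in-blink fraction of frames.
Any below-threshold frame counts — no explicit local-minimum test — because
the smoothing already suppresses single-frame noise and the quantity of
interest is total time spent blinking. The thresholds use the smoothed
series' own mean (not the raw series'), a documented choice.

All distance-change features divide by the face width *of the current frame*
(distance between two configurable face-outline anchors), so slow zoom drift
cancels to first order; a constant global scale or translation cancels
exactly, and the mouth-angle feature is additionally rotation-invariant.
Exact invariance under *time-varying* zoom is not attainable for the
distance features (the finite difference mixes two frames with different
scales); with a ±2% slow zoom the residual is below ~10% of the feature
value, and the EAR/blink features, being within-frame ratios, are exactly
invariant.

The eye-corner-to-mouth-corner distance uses the *outer* eye corner. The
peri-oral feature requires six points per side (mirror-symmetric rings);
schemas are supplied as JSON, so face-mesh index choices live in
configuration rather than code.

## Feature selection and evaluation

The modelling table has 11 facial features, 5 voice features, optionally a
passthrough phonetic score, and optionally age and encoded sex (male = 1).
Labels are PD = 1 / control = 0.

Sequential forward selection is a greedy wrapper: starting from the empty
set (baseline AUROC 0.5), it adds the feature that maximises the mean
out-of-fold AUROC of the base classifier under stratified k-fold CV (k = 10
by default, folds fixed per run), always admits the best single feature, and
stops when no candidate improves the criterion by more than `tol = 1e-4`.
Ties break to the earlier table column. AUROC is the selection criterion
because it is also the headline evaluation metric.

Nine base classifiers are registered; `decision_tree_c45` is approximated by
an entropy-criterion CART tree (no C4.5 rule post-pruning), all others are
scikit-learn/LightGBM defaults with seeds derived from the experiment seed.
kNN, SVM and logistic regression are standardised with train-fold statistics
only; tree ensembles consume raw values. Evaluation pools out-of-fold
predicted probabilities: AUROC (trapezoidal), accuracy/precision/recall/F1
at the 0.5 probability cutoff, and a 95% AUROC CI by stratified bootstrap
(2000 replicates by default; DeLong available). A model fitted on an
all-constant feature yields non-finite probabilities; these are mapped to
0.5 (no ranking information).

`run_experiment` mirrors a train-on-medicated / validate-on-unmedicated
design: selection and CV on the training cohort, refit on the full training
table with the selected features, then scoring of a subject-disjoint
validation cohort (overlap raises a leakage error). Selection coverage ranks
features by the percentage of classifiers that selected them.

In the large benchmark runs (tests and `scripts/acceptance.py`) selection is
capped at 4 features per classifier: the planted signal saturates by then,
and deep greedy paths with 100-tree ensembles add cost without changing the
selected set materially.

## Synthetic cohort generator

Voiced segments are phase-continuous sinusoids with per-10-ms F0 jitter
(sinusoids, not synthesised speech: the features above are insensitive to
phonetic content, and a sinusoid gives analytic ground truth), alternating
with near-silent pauses; segment boundaries are quantised to a 50-ms grid —
the least common multiple of both analysis frames — so no analysis frame
straddles a boundary, and the first/last segments are voiced so the computed
reading time spans the recording. A linear amplitude drift plants the sign
of volume variance. Additive noise is band-limited (~20 ms correlation) and
rides on a small positive DC bias (room tone): idealised zero-mean broadband
noise in silence would chatter around zero and flood the crossing counter —
real recordings do not sit at exactly zero. A random start phase keeps
crossings off the exact frame-boundary grid.

Faces start from a canonical mirror-symmetric neutral layout in image
coordinates. Blinks arrive at a Poisson rate as raised-cosine EAR valleys
with configurable depth (fraction of baseline EAR removed) and duration;
mouth and peri-oral landmarks oscillate sinusoidally with per-subject
amplitudes; optional global zoom/translation drift and landmark jitter mimic
camera and detector noise. Blink ground truth is defined by applying the
same smoothing + threshold rule to the noiseless planted EAR profile: a
short blink's 30-frame rolling mean may legitimately never cross the deeper
thresholds, so "planted blink time" is only well-defined through the same
statistic the extractor computes.

Cohort defaults plant group effects in the directions the clinical
literature reports as discriminative — longer reading time, higher pause
fraction, lower F0 jitter, fewer/shallower blinks in PD, with magnitudes
(e.g. pause fraction 0.134 ± 0.073 control vs 0.21 ± 0.10 PD; reading time
52.3 ± 12.8 s vs 62 ± 20 s) matching published group statistics — while
mouth-motion amplitudes are drawn identically for both groups, giving
feature selection true negatives. `effect_scale` multiplies every
group-mean separation (0 = exchangeable groups). Training PD subjects are
tagged "on"-phase, validation PD subjects "off"-phase; the two cohorts come
from distinct sub-seeds of one root seed, and the streaming path
(`simulate_feature_tables`) extracts features per subject and discards raw
signals so 100-per-group cohorts stay within a few hundred MB.

What passing tests show — and what they do not: recovery and power results
demonstrate that the extractors measure what the generator plants and that
the pipeline detects separations of the published magnitude at n = 100 per
group. They do not validate the features on real speech (formant structure,
tremor, articulation) or real faces (head pose, detector-specific landmark
error), and the absolute values of volume/pitch statistics depend on the
conventions above.

## Numerical choices and problem sizes

* Benchmarks in tests and the acceptance script use 100 subjects per group
  per cohort, ~25–110-s audio at 44.1 kHz, 30-s video at 30 fps; parameter
  recovery uses 50 subjects; selection-reliability checks use 100 replicates
  of a 100-subject, 8-feature planted table.
* All randomness (cohort draws, fold shuffles, classifier seeds, bootstrap)
  derives from one root seed via `numpy.random.SeedSequence`; the full
  simulate → extract → evaluate chain is bit-reproducible.
* Degenerate inputs raise typed errors rather than returning NaN: all-pause
  audio (reading time), silent audio (volume variance), < 2 voiced frames
  (pitch variance), zero eye/face width or zero-length mouth lines
  (geometry), single-class tables, train/validation subject overlap.
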