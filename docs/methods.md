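# Methods

## Problem and pipeline

`hrvaf` studies how few heart-rate-variability (HRV) descriptors are needed
to separate atrial fibrillation (AF) from sinus rhythm (SR) in 60 s
RR-interval segments, and whether that separation survives patient-disjoint
("blindfold") validation.  The pipeline has five stages:

1. **Cohort input** — annotated RR streams, one per patient: interval
   durations plus per-interval beat-type (sinus / supraventricular /
   ventricular / artifact) and rhythm (AF / SR / other) labels.  A seeded
   synthetic generator is the default input; a plain-text annotation
   adapter can ingest exported Holter annotations.
2. **Segmentation** — non-overlapping 60 s windows, anchored at the start
   of the recording; a window survives iff it is rhythm-pure (all AF or all
   SR), intervals outside [240, 3000] ms (removed as presumed artifacts)
   total < 10% (6 s) of the window — removal of at least 6 s discards the
   window, inclusively — and at least 18 intervals remain.
3. **Features** — 13 time-domain descriptors per segment (pRR50, SD1, SD2,
   SD2/SD1, SDRR, RRdif, CV, relRRdif, meanSuccRat, SDSuccRat, meanRR,
   RRrange, relRRrange).
4. **Ranking** — single-feature ROC AUC, and greedy MRMR on the *training
   split only*.
5. **Evaluation** — seven classifier families over the nested 1..6-feature
   MRMR prefixes, tuned by stratified 5-fold cross-validation on the
   training segments, then refit and validated on segments from entirely
   held-out patients.  The whole matrix is repeated with pRR50 excluded
   from the ranking pool, quantifying how much of the diagnostic signal is
   carried by that single counting statistic.

## Feature definitions and numerical choices

Successive-difference statistics (pRR50, SD1, RRdif, relRRdif, meanSuccRat,
SDSuccRat) are computed over *valid pairs* only: pairs of retained
intervals that were adjacent in the original stream.  A pair spanning a
removed interval is not a physiological successive difference and is never
formed.  Other descriptors (meanRR, SDRR, CV, RRrange, relRRrange, SD2) use
all retained intervals or pairs as defined.

* All standard deviations use the sample convention (n − 1); a `ddof=0`
  switch exists for sensitivity checks.
* pRR50 counts |ΔRR| **≥** 50 ms (inclusive).
* SD1/SD2 are computed by rotating the Poincaré cloud (RR_n, RR_{n+1}) by
  45°: SD1 = SD of (RR_{n+1} − RR_n)/√2, SD2 = SD of (RR_{n+1} + RR_n)/√2.
  The rotation identity SD1² + SD2² = Var(RR_n) + Var(RR_{n+1}) then holds
  exactly and is asserted in tests.
* A segment with SD1 = 0 has an undefined SD2/SD1 and is excluded from the
  feature table with a logged count rather than imputed; imputation would
  silently distort the mutual-information ranking, and the case cannot
  occur in non-degenerate 60 s physiological data.

## Ranking

AUC uses the Mann–Whitney rank-sum identity with midranks for ties, AF
positive, orientation-fixed to [0.5, 1] with the flip recorded.

MRMR is greedy: the first pick maximizes relevance MI(f, class); each later
pick maximizes relevance / mean-redundancy over the selected set (MIQ; the
difference form MID is a config option).  MI is the plug-in estimate
(bits) on an equal-frequency discretization of the feature (16 bins by
default, configurable); the class label is categorical and never binned.

Redundancy between features is measured as **normalized** mutual
information, MI/√(H_a·H_b), by default.  Rationale: plug-in MI between two
finely binned continuous features is inflated by the entropy of the
discretization itself, which makes novel-but-noisy features look as
redundant as true duplicates.  Normalizing puts redundancy on a [0, 1]
scale where an exact duplicate of a selected feature scores 1 and an
unrelated feature scores near MI/√(H_a·H_b) ≪ 1, so duplicates are
reliably deferred behind genuinely novel features.  Raw-MI redundancy is
available (`redundancy="mi"`).  The redundancy denominator is floored at
1e-12 bits.  Ties break by pool order.  Absolute MRMR scores depend on the
discretization and are not comparable across estimators; only orderings
are meaningful.

## Evaluation harness

* **Split** — per database tag, round(2/3 · n) patients are drawn (seeded,
  without replacement) into the training set; no patient's segments ever
  appear on both sides.  Any configuration that would fit and evaluate on
  the same patient raises a hard `LeakageError`.
* **Tuning** — stratified 5-fold CV over training segments, grid search per
  (family × feature count × pool); the grid point with the highest mean
  fold accuracy wins, ties to the earlier grid point.  Fold accuracies and
  the pooled out-of-fold confusion of the winner are reported.  Folds are
  segment-level within the training split; the blindfold contrast is the
  leakage-safe comparison, and a patient-grouped CV can be built from the
  same primitives.
* **Families and grids** (the source gives none; these are this package's
  choices): DT depth 2–20; KNN K 1–51 odd; SVM linear C ∈ {0.01…100};
  SVM RBF C × γ on log grids; AdaBoost 25–200 estimators; RF depth 4–16 ×
  {50, 100, 200} trees; MLP with one ReLU hidden layer of {4…64} units.
  KNN/SVM/ANN get z-score standardization fitted on training folds only;
  tree ensembles are unscaled.
* **Metrics** — accuracy, sensitivity, specificity, PPV (all %, AF
  positive) and the diagnostic odds ratio DOR = (TP·TN)/(FP·FN).  With a
  zero cell the Haldane correction (+0.5 to every cell) is applied by
  default; a strict policy reporting NaN is available.  All metric
  identities are re-derivable from the stored confusion counts.

## The synthetic cohort: what it emulates, and what it does not

The generator defines the study conditions for all desk-scale results.
Defaults: 40 patients per class, 5 min per recording (≈5 windows each),
patients alternating between two database tags, 1% per-beat artifact rate,
10% of patients given a single mid-recording AF↔SR transition.

* **SR** — per-patient mean RR lognormal (900 ± 90 ms); AR(1) fast noise
  (coefficient 0.8, innovation SD 15 ms with ×lognormal(σ=0.5) per-patient
  spread); respiratory sinusoid (25 ms at 0.25 Hz); very-low-frequency
  oscillation (60 ms at 0.03 Hz, ×lognormal(σ=0.6) spread); premature
  (ectopic) beats at per-beat rate 0.05 (×lognormal(σ=0.8) spread, capped
  at 0.15) implemented as a 25–45% shortened interval followed by a
  compensatory pause, labelled supraventricular/ventricular.
* **AF** — per-patient mean RR lognormal (750 ± 160 ms); i.i.d. gamma
  durations with coefficient of variation 0.20 (×lognormal(σ=0.6) spread,
  capped at 0.5), optional small lag-1 moving-average blend (0.05).
  Out-of-band draws are rejection-resampled so injected artifacts remain
  the only out-of-range durations.
* Sinusoids are evaluated at nominal beat times k·meanRR, which keeps
  generation vectorized; the implied lag-1 autocorrelation oracle uses the
  same convention.

These choices are made once as a realistic desk-scale emulation and they
are what produces the qualitative structure the analysis assumes: the VLF
term and ectopy give SR sizable-but-slow or rare-but-large variability, so
SDRR/CV/relRRdif overlap the slow ("rate-controlled") tail of AF, while
the *count* of ≥50 ms successive differences — pRR50 — remains the cleanest
single separator; mean RR distributions overlap substantially.  What the
generator does **not** emulate: true autonomic dynamics, circadian
structure, atrial flutter and other non-AF arrhythmias, database-specific
annotation quirks, or the segment counts of real Holter archives.  Passing
desk-scale tests therefore demonstrates the correctness and the qualitative
behaviour of the pipeline, not clinical performance; headline numbers on
real archives require running the adapter on the actual recordings.

At this scale (≈370 segments, ≈27 held-out patients) blindfold confusion
cells differ by one or two errors between neighbouring configurations, so
DOR is compared between pools per feature-count as a median across the
seven families rather than cell-by-cell; cell-level DOR at this n is
dominated by count discreteness.

## Known limitations

* MI bin count (16) is a bias/variance compromise for ~10²–10³ segments;
  very small tables push the estimator toward its positive bias.
* The MLP occasionally stops at its iteration cap on tiny folds; this
  affects tuning only through the accuracy it achieves and is logged as a
  convergence warning.
* The adapter reads plain-text annotation exports, not binary waveform
  archives; QRS detection is out of scope by design (annotations are the
  input contract).
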