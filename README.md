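# vnsreact

EEG-reactivity analysis for predicting individual response to vagal nerve
stimulation (VNS) in drug-resistant epilepsy.

Chronic VNS gives a substantial (≥ 50 %) seizure reduction in roughly half
of implanted patients, but there is no pre-operative way to tell responders
from non-responders. The hypothesis this pipeline operationalizes is that
the two groups differ in how their EEG *reacts* to the standard activation
procedures of a routine pre-surgical recording — eyes opening/closing,
intermittent photic stimulation (PS) and hyperventilation (HV) — most
prominently in the alpha (8–12 Hz) and gamma (31–45 Hz) bands.

## What the pipeline computes

Given annotated 19-channel 10–20 scalp EEG (EDF, nominally 128 Hz) segmented
into the eight protocol intervals (Rest#1, Open/Close#1, Rest#2, PS, HV,
Open/Close#2, Rest#3, Rest#4):

1. **Band power.** Each channel is zero-phase band-pass filtered into
   theta (4–7.5 Hz), alpha (8–12 Hz), beta (14–30 Hz) and gamma (31–45 Hz);
   the squared magnitude of the analytic (Hilbert) signal gives an
   instantaneous power envelope, averaged within each interval.
2. **Relative power (ERD/ERS).** Per electrode, band and condition,

   RPW = 100 · (P_condition − P_Rest#1) / P_Rest#1  [%]

   so negative values are event-related desynchronization and positive
   values synchronization relative to the resting baseline.
3. **Topographic statistics.** Responders vs. non-responders are compared
   cell-wise with two-sided Mann–Whitney tests (within-group reactivity vs.
   baseline with one-sample Wilcoxon signed-rank tests), Benjamini–Hochberg
   FDR-corrected across the 19 electrodes of each band × condition family,
   significant at q ≤ 0.05.
4. **Predictor development.** RPW cells are aggregated into 196
   electrode-group features (7 conditions × 4 bands × 7 anatomical regions;
   a 532-column single-electrode variant exists). Bidirectional stepwise
   logistic regression is repeated over all n leave-one-out (LOO) subsets;
   features are ranked by how many of the n runs retained them, and the
   frequency threshold is swept to pick a working feature set. Logistic
   regression, linear SVM and LDA classifiers are evaluated with LOO
   cross-validation (accuracy / sensitivity / specificity, Responder
   positive) and compared against chance with an exact one-sided binomial
   test.
5. **External validation.** The developed feature set is applied to an
   independent cohort either by a single classifier trained on all n
   development subjects, or by majority voting of the n jackknife
   classifiers (ties resolve conservatively to NonResponder).

Because clinical recordings are not shipped, a first-class synthetic
generator produces labelled cohorts — either RPW tables directly or full
raw-EEG protocol recordings (pink background noise plus band-confined
oscillators realizing planted reactivity targets) — with the
responder/non-responder alpha/gamma structure the method is built to detect.

## Worked example

```bash
python examples/03_develop_predictor.py
```

runs the development stage on the default synthetic cohort (60 subjects,
35 responders / 25 non-responders, seed 1) and prints:

```
most frequently selected features (count / 60 LOO iterations):
  60  HV|alpha|central
  56  Rest3|theta|right_anterotemporal
  53  PS|alpha|right_anterotemporal
  ...
working point: features selected in >= 53 iterations (3 features)
LOO accuracy 100.0%  sensitivity 100.0%  specificity 100.0%  binomial p vs majority rate 9e-15
```

The two dominant features are the planted group differences (alpha
reactivity to hyperventilation and photic stimulation); the threshold sweep
table shows how LOO accuracy varies with the number of retained feature
groups. `examples/01_raw_cohort_to_rpw.py` (signal recovery from raw EEG),
`examples/02_topographic_statistics.py` (FDR-corrected group maps) and
`examples/04_external_validation.py` (single vs. voting validation) cover
the other stages, each printing what the numbers mean.

The same stages are scriptable from a shell:

```bash
vnsreact simulate --seed 1 --out-dir cohort1
vnsreact develop cohort1/rpw.csv cohort1/labels.csv --out-dir model
vnsreact simulate --seed 2 --out-dir cohort2 --n-responders 12 --n-nonresponders 10
vnsreact validate model cohort1/rpw.csv cohort1/labels.csv cohort2/rpw.csv \
    --external-labels cohort2/labels.csv --out-dir validation
```

Every command writes a manifest (config snapshot, input hashes, seed) that
makes the run bit-reproducible.

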