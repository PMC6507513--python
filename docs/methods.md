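# Methods

## Signal model and band power

The pipeline treats a session as a continuous multichannel record with
eight annotated protocol intervals (Rest#1 2 min, Open/Close#1 10 s,
Rest#2 10 s, PS 2.5 min, HV 4 min, Open/Close#2 10 s, Rest#3 10 s,
Rest#4 2 min; 670 s at the canonical 128 Hz). Band power is estimated per
channel by zero-phase band-pass filtering (forward–backward Butterworth,
order 4 per pass; order configurable) followed by the Hilbert transform of
the full-length filtered record. The *power envelope* is the squared
magnitude of the analytic signal; a config switch (`envelope mode
power|amplitude`) exposes the magnitude itself for users who prefer
amplitude ERD/ERS, but power is the default because relative band power is
conventionally a power (squared-amplitude) quantity. Filtering and the
Hilbert transform are applied before segmentation so interval means carry
no per-segment edge transients; the residual cost is a small exchange of
power across interval boundaries over roughly the filter's impulse-response
width (~0.5 s), which matters only for the 10 s intervals and is measured
below.

Relative mean power per electrode × band × condition is

    RPW = 100 · (P_cond − P_Rest1) / P_Rest1  [percent],

undefined when the baseline cell is nonpositive (hard error naming the
cell). RPW is invariant to any per-channel gain, so no unit calibration or
re-referencing is required; recordings are analysed as stored (the
reference montage of the source recordings is unknown, and the statistic
does not depend on it under the per-channel baseline normalization).

Sampling rates down to 91 Hz (Nyquist for the 45 Hz band edge, with the
same headroom 128 Hz provides) are accepted with a warning and no
resampling; the method is rate-agnostic.

## Topographic statistics

Between-group maps use two-sided Mann–Whitney tests per electrode × band ×
condition on RPW; the exact U distribution when the combined sample is
≤ 20 without ties, otherwise the tie-corrected normal approximation with
midranks. Within-group reactivity maps (is a group's RPW shifted from 0?)
use two-sided one-sample Wilcoxon signed-rank tests; the choice of test for
this map is a package decision — it is the one-sample analogue of the
between-group choice and stays rank-based. Multiplicity is controlled with
Benjamini–Hochberg FDR within each band × condition family of 19
electrodes, matching the way per-head dot maps are read (each head
corrected independently); Benjamini–Yekutieli and a pooled-across-bands
family (all electrodes of one interval) are available via config, because
the family definition is genuinely ambiguous in the source protocol.
Significance is q ≤ 0.05. Degenerate cells (a group empty, or all values
identical) report p = 1 with a warning rather than failing a whole map.

## Feature spaces

The grouped space averages RPW over seven anatomical regions — left/right
frontal (Fp1,F3,Fz / Fp2,F4,Fz), left/right anterotemporal (F7,T3 / F8,T4),
central (C3,Cz,C4), left/right posterior quadrant (P3,Pz,T5,O1 /
P4,Pz,T6,O2) — giving 7 conditions × 4 bands × 7 regions = 196 columns.
Midline electrodes deliberately appear in both hemispheric regions, so
left/right features are correlated by construction. The single-electrode
space is the identity mapping, 532 columns. Column order is fixed
(condition-major, then band, then region/electrode in canonical order) so
selection frequencies are comparable across runs and ties break
deterministically toward lower indices. Features are not standardized at
this stage (RPW is already normalized); z-scoring is a classifier-level
option using training-fold statistics only.

## Stepwise selection and the development procedure

No installed library offers p-value-driven bidirectional stepwise GLM
selection, so the scan is implemented directly: batched Newton-IRLS
logistic fits over all candidate one-feature extensions of the current
model, likelihood-ratio entry tests (add the smallest p < `p_enter`,
default 0.05), then backward removal of any retained feature whose
removal-test p exceeds `p_remove` (default 0.10), iterating to a fixpoint
or a model-size cap of ⌈n/10⌉. Entry/removal thresholds follow standard
stepwise-GLM convention; they are defaults, not reconstructions of the
original (unstated) criteria. Predictors are z-scored internally for
conditioning (LR tests are invariant to affine predictor rescaling). When a
step separates perfectly (non-convergence or |β| > 30 on standardized
predictors), the whole scan switches to a ridge-penalized likelihood
(λ = 0.01) so entry p-values remain comparable; the event is logged.

The development procedure runs the stepwise selection n times, leaving one
subject out per run, and counts per-feature retention. Features retained in
at least `min_iterations` runs form the working set; a sweep of this
threshold against LOO accuracy guides the operator's choice, defaulting to
the accuracy-maximizing threshold with the fewest features. Note that this
procedure — frequency ranking on all n runs, then LOO evaluation of the
fixed set — reuses every subject during selection and therefore yields an
optimistic error estimate; it is implemented as the primary mode for
fidelity, and a fully nested mode (selection recomputed inside every
training fold; the held-out subject's label provably cannot influence its
own fold, which the tests assert by label-flipping) is available for honest
error reporting.

Classifiers: logistic regression with weak L2 (C = 10⁴, i.e. effectively
unpenalized, configurable), linear SVM (C = 1), and LDA (pooled covariance,
no shrinkage). LR and SVM standardize with training-fold statistics; LDA
runs on raw features, being scale-equivariant. Performance is reported as
accuracy/sensitivity/specificity with Responder positive, plus an exact
one-sided binomial test of the LOO hit count against chance; chance
defaults to the majority-class proportion (0.5 via config), since always
guessing the majority is the natural no-information baseline of an
unbalanced cohort.

## External validation

Both validation approaches first restrict the external feature matrix to
the development-selected columns (descriptors must match column-for-column).
The single-classifier approach trains once on all n development subjects;
the voting approach trains n jackknife models and takes the majority vote
per external subject. An even split resolves to NonResponder — the
conservative call for a treatment-benefit prediction — and is logged.
Standardization parameters always come from the training cohort.

## Synthetic cohorts

The generator encodes the qualitative group structure the method targets,
as mean RPW shifts with per-subject random effects. Defaults (all
magnitudes are generator defaults chosen to be detectable at the study
sample sizes, not measured values): responders — alpha PS 0 %, alpha HV
+40 %, gamma PS +15 %, gamma HV +20 %; non-responders — alpha PS −25 %,
alpha Rest#4 −15 %, gamma PS −10 %, gamma HV −10 %; both groups — alpha
−50 % during both eye-opening intervals (Berger effect). Between-subject SD
is 25 pp per effect; cell-level measurement noise is 10 pp (RPW-table mode
only); cohort split 35/25. Values truncate at −100 %.

Raw-EEG mode synthesizes each channel as pink (1/f-power) background noise
(2 µV RMS broadband, flat below 0.5 Hz) plus one oscillator per band:
white noise confined to the band in the frequency domain, RMS-normalized
per interval, amplitude-scaled by √(1 + RPW/100) against Rest#1, with
baseline envelope powers θ 20, α 30, β 10, γ 5 µV². Frequency-domain
confinement (rather than IIR-filtered noise) was chosen because filtered
carriers leak across the adjacent beta/gamma edge (30 vs. 31 Hz) and bias
recovered gamma reactivity toward zero by ~20 %; with confined carriers the
only dilution is the background's in-band power (< 10 % in gamma, < 2 % in
alpha). Measured end-to-end, the pipeline recovers planted targets with a
per-cell mean bias ≤ ~2 pp (the largest component being edge smearing of
the 10 s intervals), well inside the ±10 pp recovery tolerance. What raw
mode does *not* emulate: physiological HV slowing, photic driving
harmonics, EMG contamination, artifacts, or any dipole-level biophysics —
so passing recovery tests demonstrates generator/analyzer consistency of
band-power reactivity, not robustness to real-world contamination.

## Reference experiments and problem sizes

`vnsreact.experiments` fixes three standing studies (all seeded, run by the
test suite and `scripts/acceptance.py`):

* **Raw recovery** — 20 seeds × (3+3)-subject raw cohorts (the statistic
  pools 120 subjects); per planted band × condition cell, the mean
  recovered-minus-planted error must stay within ±10 pp (measured max
  ≈ 1.4 pp), and unplanted cells within ±5 pp. Small per-seed cohorts keep
  the study at desk scale; the pooled subject count, not the per-seed n,
  controls the precision of the bias estimate.
* **Development recovery** — 50 seeds at the full study size (n = 60,
  35/25). Per seed, the top-ranked feature by LOO selection frequency must
  lie in a planted differential cell (observed rate 0.94), and median LR
  LOO accuracy on the top-8 nonzero-count features must beat the
  majority-class rate (observed ≈ 97 % vs. 58.3 %, binomial p ≪ 0.001).
  Never-selected columns are excluded from the ranking; beyond the top few
  ranks the ordering is a tie lottery among once-selected columns and is
  not used as an acceptance quantity.
* **Null control** — 200 seeds of zero-effect 35/25 cohorts. The
  FDR-flagged electrode proportion per band × condition family stays below
  α plus two Monte-Carlo standard errors (observed ≤ 0.005 per family).
  LR LOO accuracy on a fixed pre-specified 8-feature set is also recorded:
  it centres near 50 % (observed ≈ 51 %), *below* the 58.3 % majority
  rate — leave-one-out cross-validation of a nearly unpenalized model on
  signal-free features is pessimistically biased, a known finite-sample
  property of CV, while evaluating on features selected by the non-nested
  development procedure is optimistically biased (≈ 78 % measured). The
  meaningful null guarantee this package makes is one-sided: no variant of
  the honest evaluation shows optimism on null data.

## Numerical and degenerate-input conventions

Sample coordinates are 0-based half-open; second-valued annotations convert
by rounding half-up. The fixture EDF writer quantizes to 16 bits against
the physical range exactly as stored in the (6-significant-digit) header,
bounding round-trip error at half a quantization step. Envelope FFTs pad to
fast lengths and truncate back. Stepwise ties (equal p) resolve to the
lower column index; `choose_working_point` ties resolve to fewer features.
All stochastic components draw from `numpy.random.default_rng` seeded
explicitly; fixed data and config give bit-identical selection frequencies,
sweeps and reports.

## Known limitations

Artifact detection, montage re-referencing and resampling are out of scope;
inputs are assumed artifact-free and protocol-complete. The primary
development mode inherits the optimism of non-nested feature selection (use
nested mode for unbiased error). The synthetic generator's effect sizes are
stylized: real alpha/gamma reactivity differences are unlikely to be
global, Gaussian, or as well separated, so simulated accuracies should not
be read as clinical performance estimates.
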