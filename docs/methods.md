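# Methods

## Problem setting

`neuroauth` implements EEG-based biometric *authentication* (verification of
a claimed identity, not identification) for chronic use: a subject enrols by
recording short motor-task sessions on several days, and later presents one
or more task epochs to be accepted or rejected.  The decoder must tolerate
day-to-day nuisance variability — electrode re-placement, impedance changes,
drifting noise levels — which is what distinguishes the chronic setting from
single-session laboratory decoding.

## Pipeline

1. **Preprocessing.**  Continuous 8-channel recordings at 250 Hz are
   band-passed with a fourth-order Butterworth filter (1–30 Hz), decimated to
   100 Hz, and cut into 3-s task epochs of 8 × 300 samples.  Filtering is
   zero-phase (forward–backward `sosfiltfilt`), applied to the whole
   continuous session before epoching; this doubles the effective filter
   order but avoids both group-delay shifts of the task window and per-epoch
   edge transients.  `filter_order` counts the overall band-pass order (an
   order-4 band-pass from an order-2 low/high prototype pair).  The
   250 → 100 Hz change is the rational factor 2/5, realized by polyphase
   resampling with scipy's Kaiser-windowed anti-alias FIR; since the signal
   is already limited to 30 Hz the resampler dialect is inconsequential.
2. **Spectral features.**  Per channel, each 300-sample epoch is zero-padded
   symmetrically to 330 samples and transformed with a 128-point one-sided
   STFT (periodic Hann taper, hop 3 = 125-sample ≈ 97.7 % overlap), giving a
   65 × 68 complex spectrogram with 100/128 = 0.78125 Hz resolution.  A
   nominal 98 % overlap of 128 samples would need the unrealizable
   fractional hop 2.56; hop 3 is the nearest realizable choice and the
   330-sample pad makes the frame count exactly
   floor((330−128)/3)+1 = 68.  Power is 20·log₁₀|X| dB with a 1e−12
   magnitude floor so silent bins stay finite.  Bins are grouped into five
   sub-bands — 7–11 (mu), 11–16, 16–21, 21–25, 25–30 Hz (beta) — by
   averaging dB values over bins whose centre frequency lies in the
   half-open interval [low, high), so shared edges are never double-counted.
   The mean (rather than sum) keeps rows comparable across bands of unequal
   width.  Stacking per-channel 5 × 68 blocks row-wise yields the feature
   matrix: 40 × 68 in `all_channels` mode (the default) or 25 × 68 in
   `paper_literal` mode, which restricts to the five central/midline
   electrodes Fz, C3, Cz, C4, Pz most relevant to motor rhythms.  Both
   modes are provided because a 5-channel 25-row layout and an 8-channel
   montage are both defensible designs; the evaluation results in this
   repository use `all_channels`.
3. **Weak learner.**  A single-layer LSTM consumes the feature matrix as a
   sequence (68 frames of 25 or 40 dimensions), its final hidden state feeds
   a fully connected layer with a two-unit softmax over {No, Yes}, and
   training minimizes cross-entropy with Adam.  The implementation is plain
   NumPy (forward pass plus backpropagation through time, verified against
   central-difference numerical gradients); at these model sizes a NumPy
   loop is fast on one CPU core and every run is bit-reproducible from the
   config seed, which drives weight initialization and batch shuffling.
   Inputs are z-scored per feature dimension with statistics computed on the
   training set only.  Defaults: 64 hidden units, 60 epochs, batch 8,
   learning rate 1e−3, decision threshold 0.5 (accept at the threshold).
4. **Bagging.**  An ensemble of M weak learners (default M = 9) is trained
   on M bootstrap resamples — the same number of points, drawn with
   replacement — and the majority of accept votes decides (accept iff
   yes-votes > M/2; a tie, possible only for even M, rejects: an
   authentication system fails closed).  The bootstrap is stratified per
   class: the balanced training sets here are small (tens of points) and an
   unstratified resample can lose a class entirely, which is untrainable.
   Per-member seeds derive from the ensemble seed by index.
5. **Authentication.**  One ensemble is trained per (subject, task, arm).
   Positives are the subject's training epochs; negatives are an equal
   number of imposter epochs for the same task, sampled uniformly without
   replacement (with replacement plus a logged warning if the pool is too
   small).  Two scenarios: `known_imposters` (all other cohort members
   supply negatives) and `unseen_imposters` (only a training group does;
   held-out subjects attack a system that has never seen them).  A policy
   combines several (task, arm) authenticators by unanimous conjunction:
   accept only if every component accepts.  The combination rule is an AND
   by design — it is the only simple rule whose signature is a falling
   false-acceptance rate and a rising false-rejection rate as tasks are
   added, and that trade-off is the point of multi-task authentication.
   The rule is an enum so that OR/threshold variants can be added.

## Evaluation

Leave-one-day-out cross-validation: fold *d* trains on all days except *d*
and tests on day *d*, with left- and right-arm trials kept separate.
Genuine attempts are the subject's held-out epochs; imposter attempts are
every other subject's held-out epochs.  Metrics use the standard biometric
definitions FAR = FP/(FP+TN), FRR = FN/(FN+TP), accuracy =
(TP+TN)/(TP+TN+FP+FN) on the full, unbalanced attempt set; all four counts
are exported so any other weighting can be recomputed.  For multi-task
policies the components are scored on the same paired attempts as the
conjunction, which makes FAR(combined) ≤ min FAR(component) and
FRR(combined) ≥ max FRR(component) exact identities rather than statistical
tendencies.  Two sweeps mirror the study design questions: training-set
fraction (10–90 %, single LSTM vs. bagged ensemble on identical subsets and
identical test sets, several seeded runs averaged; default 5 runs) and
bagging size M ∈ {1, 3, 5, 7, 9}.  Scheme comparisons use the two-sided
Wilcoxon signed-rank test at α = 0.05 on per-subject means, dropping zero
differences, with the exact null distribution for up to 12 remaining pairs
and the normal approximation above (exact enumeration is cheap below that
switch point); fewer than 5 nonzero differences is an error rather than a
p-value.

## Synthetic cohort generator

No public recordings exist for this protocol, so the package ships a seeded
generator that emulates the study design: 15 subjects × 5 daily sessions,
each with 10 performed-movement and 10 imagined-movement trials (5 left /
5 right arm, shuffled within blocks), 3-s task epochs separated by 4-s
rests, 8 channels (Fz, C3, Cz, C4, Pz, PO7, Oz, PO8) at 250 Hz.

What it emulates, and how:

- **Subject identity** is a persistent *spectral fingerprint*: per-channel,
  per-sub-band power multipliers drawn log-normally
  (`band_gain_dispersion`, default log-std 0.6 — a deliberately
  well-separated, "strong fingerprint" regime).  Discriminability is
  monotone in this dispersion, which the test suite checks end to end.
- **Motor tasks** appear as event-related desynchronization (ERD):
  multiplicative band-power suppression on the central channel
  contralateral to the cued arm (C3 for right, C4 for left), confined to
  the 3-s task window with 0.15-s cosine ramps.  The mu band is suppressed
  by the full `erd_depth` (default 0.4); the beta sub-bands above 16 Hz by
  0.6 × depth; the 11–16 Hz transition band not at all.  Imagined-task
  depth is 0.7 × the performed depth — imagery modulates the rhythms more
  weakly, and the factor lets the two tasks be distinguished; its magnitude
  is a generator choice, not an estimate.
- **Background** is 1/f-shaped Gaussian noise (exponent 1.0) synthesized in
  the frequency domain below 45 Hz plus a small white sensor-noise floor,
  so all content sits well under the 50 Hz post-decimation Nyquist and
  decimation is alias-safe, and the expected PSD is analytic for test
  oracles.
- **Day-to-day variability**: per-channel log-normal gain jitter (log-std
  0.08), a row-stochastic channel-mixing matrix with 5 % off-diagonal mass
  (electrode re-placement surrogate), and a log-normal noise-level
  multiplier (log-std 0.10).
- **Seeding**: one cohort seed; per-subject fingerprints, per-day effects,
  and per-session noise draw from keyed `SeedSequence` streams
  (`[seed, kind, subject, day]`), so streams are independent and the whole
  cohort is bit-reproducible.

What it does **not** emulate: ocular/muscular artifacts, line noise,
non-stationary drifts within a session, volume-conduction realism, or any
empirically estimated effect size — the real separability of people's EEG
spectra is unknown here, so passing tests demonstrate that the machinery
recovers planted structure under the stated noise model, not that real
cohorts reach these numbers.

### Measuring ERD on the synthetic data

A Welch-PSD check of the mu-band task/rest power ratio should read the
*interior* of the mu band (7.5–10.5 Hz) at full segment-length resolution:
with Hann tapering at coarser resolution, leakage from the adjacent,
unsuppressed 11–16 Hz band (which can carry several times the mu power for
an unlucky fingerprint) biases the ratio upward.

## Problem sizes and numerical choices

- Cohort-scale evaluations (the acceptance script and the end-to-end tests)
  use a compact learner profile — 16 hidden units, 25 epochs, full-batch
  Adam at learning rate 1e−2 — which separates the synthetic fingerprints
  as well as the default profile at a fraction of the cost; the bagging
  comparison across seeds runs on 6-subject × 3-day cohorts for the same
  reason.  These sizes are package choices for routine runs; all of them
  are plain config parameters.
- dB floor 1e−12; z-score std floor 1e−8; forget-gate bias initialized to 1
  (remember-by-default), other weights Glorot-uniform.
- Decision threshold comparisons use ≥ (accept exactly at threshold);
  majority vote uses strict > M/2 (ties reject).
- Degenerate inputs fail loudly with named fields: odd left/right splits,
  single-class training sets, empty imposter pools, bands with no member
  bins, epochs whose window leaves the recording.

## Known limitations

- The printed accuracy/FAR/FRR triple of the motivating chronic study is
  not internally consistent under any attempt-set weighting we tried, so
  its accuracy denominator cannot be replicated; this package defines
  accuracy over the full attempt set and always exports raw counts.
- The LSTM is intentionally shallow and the optimizer fixed; there is no
  hyperparameter search.
- The conjunction rule is the only combination rule implemented.
- Synthetic results quantify machinery, not human EEG discriminability.
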