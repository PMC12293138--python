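# Methods

## Problem and scope

Two-class motor imagery (right hand vs right foot) is decoded from EEG
after projecting the sensor signals onto the cortex, and decoding accuracy
is compared across nested 19-, 30-, 61- and 118-channel caps. The package
implements the full pipeline plus a synthetic data generator with known
ground truth; it does not attempt to reproduce any particular laboratory's
head model, so absolute accuracies on real recordings are expected to
differ from published tables even when the pipeline is identical in
structure.

## Montage

Electrode positions are idealized 10-05 coordinates projected onto the unit
sphere, shipped as the editable text file `mi_esi/data/montage_118.txt`
(one `name x y z` line per electrode). The four caps are nested:
the 19-channel cap is the standard 10-20 set; the 30- and 61-channel caps
are symmetric 10-10 supersets (`subset_19/30/61.txt`, editable); the
118-channel cap adds 10-05 intermediate positions. Channel-name matching is
case-insensitive and whitespace-trimmed because dataset distributions vary
in label case. When real competition files are read, channel names come
from the file itself.

## Forward model

The synthetic head is a homogeneous unit sphere. The gain of a current
dipole at radius `b < 1` with radial moment `m_r` and tangential moment
`m_t` observed at a surface electrode at angular distance `γ` is the
classical Legendre series

    φ = (1/4πσ) Σ_{n≥1} ((2n+1)/n) b^(n-1) [ n m_r P_n(cos γ) + m_t P_n¹(cos γ) ]

truncated at n = 60 (relative truncation error < 1e-3 at the cortical
radius 0.85; the b → 0 limit is the uniform-field solution, so a central
source is not singular). Sources are radially oriented by default. Columns
are scaled to unit norm: absolute source units are arbitrary and only
amplitude ratios matter downstream. Channel subsets see plain row
selections of the full-montage gain so that data generation and inversion
share one physical model.

## Atlas

24 patches (12 per hemisphere: SAC, S1F, S1H, S2, CMA, M1F, M1H, M1L, SMA,
pSMA, PMd, PMv; ids 1–12 left, 13–24 right, counterparts 12 apart) are
placed at homunculus-consistent unit-sphere coordinates — hand areas
lateral, foot areas medial/superior, CMA deep on the medial wall and
flagged non-surface — in the editable file `mi_esi/data/atlas_24.csv`.
Each patch carries `sources_per_patch` dipoles (default 6) in a
deterministic ring of angular radius 0.1 rad around its center.

## Synthetic generator

Defaults are the study conditions: 280 trials per subject (140 per class),
100 Hz sampling, 3.5 s trials with the cue at t = 0 and the imagery
interval at 0.5–2.5 s, 10 Hz mu oscillation. ERD is modeled as amplitude
attenuation of the mu oscillation in the contralateral primary motor patch
during imagery (hand imagery attenuates M1HL, foot imagery M1FL; the other
patch stays at baseline), with 0.1 s raised-cosine ramps; `erd_attenuation`
defaults to 0.4 (band-power ratio 0.16) and sensor SNR (power ratio) to 5,
values a clean laboratory MI recording can plausibly reach. Mu phase is
randomized per trial and per source. The other 22 patches and 50 free
background sources carry 1/f-power-shaped noise (RMS 0.5 relative to the
unit mu amplitude, spectrum flattened below 1 Hz). Sensor data are
gain × sources scaled to a nominal 10 µV plus white sensor noise with
power = signal power / SNR. All draws flow from one generator seed; subject
seeds are independent substreams of the master seed.

What the generator does *not* emulate: artifacts (EMG/EOG/line noise),
non-stationarity across a session, inter-subject anatomical variability,
volume-conduction errors of a misspecified head model, beta-band activity,
or label noise. Passing tests therefore demonstrate correctness of the
pipeline mathematics and qualitative behavior under ideal ERD physiology,
not expected performance on real recordings.

Train/test splits reproduce the real dataset's per-subject budgets
(aa 168/112, al 224/56, av 84/196, aw 56/224, ay 28/252; 280 each),
class-balanced as far as parity allows; an even split with any train count
is also available.

## Preprocessing

4th-order Butterworth band-pass, 8–13 Hz, applied forward–backward
(zero-phase, effective order 8) so covariance structure is not distorted by
phase. Continuous recordings are filtered before epoching; synthetic trials
are filtered whole, their 0.5 s pre-cue and 1 s post-imagery segments
acting as padding, and then cropped to the half-open 0.5–2.5 s window
(exactly 200 samples at 100 Hz). Epochs whose window exceeds the recording
are dropped with a logged count.

## Inverse solution

Minimum-norm kernel `K = Lᵀ(L Lᵀ + αI)⁻¹` with identity noise covariance
and `α = reg_lambda · trace(L Lᵀ)/n_sensors`; sLORETA standardization
divides source j by `√([K L]ⱼⱼ)`. `reg_lambda` defaults to 1/9 (the
conventional assumed-SNR-3 setting) and is the main free parameter; tests
of the zero-localization property use 1e-6 since they are noiseless.
Source orientations are fixed by the forward model.

## ROI series and combination search

Each region contributes the arithmetic mean of its member sources'
standardized time courses (patch averaging commutes with the linear
inverse, so the experiment applies one 24 × channels matrix per subset).
An optional sign-flip mode aligns each source with the patch's first
principal direction before averaging — useful when orientations within a
patch oppose; with the default radial orientations on small patches it is
off. The search fixes {M1HL, M1FL} and adds all 4-subsets of a 16-region
pool (the 24 regions minus the base, both CMA — interior — and both M1L
plus the right-hemisphere M1H/M1F, which are ipsilateral to the imagined
limbs). 16 choose 4 = 1820 candidate sets, enumerated in lexicographic
region-id order; ties in the search resolve to the lowest enumeration
index.

## CSP and features

Implemented exactly as the normalized-covariance formulation: per-trial
`M = D Dᵀ/trace(D Dᵀ)`, arithmetic class means, whitening
`W = λc^{-1/2} Ecᵀ` of `Mc = M̄₁+M̄₂`, shared eigendecomposition of the
whitened class covariances (eigenvalues sorted descending by the class-1
eigenvalue; the pairing `λ₁+λ₂ = I` is asserted in tests to 1e-8), and
`P = Uᵀ W`. Features are raw sample variances (denominator L−1) of the
first and last `n_pairs` rows of `Z = P D` — no log transform, since the
variance itself is the defined feature; a log option exists but is off.
With 6 ROI signals and 3 pairs all components are used. Row signs are fixed
(largest-magnitude entry positive) purely for determinism. A ridge of
1e-10 × trace is added to `Mc` only if it is numerically rank-deficient,
and logged. Inside the search loop features are computed from per-trial
cross-product matrices and row means (sufficient statistics); a test
asserts bit-level agreement with the explicit project-then-variance path.

## Classification and metrics

SVM with linear and RBF kernels (C = 1, `gamma="scale"`), features
standardized by training-set statistics only. Right hand is the positive
class; Acc, Sen, Spec, Pre, F1 are percentages rounded half-up to two
decimals, and zero-denominator metrics are reported as 0.00 with an
explicit `undefined` flag rather than raising mid-experiment. Trials with
unknown labels are excluded from metric computation but counted.

## Experiment design choices

* Combination selection is scored on the test split by default, matching
  how best-combination results are reported in this literature; this is an
  optimistic, selection-biased estimate. A stratified cross-validation mode
  on the training split (`selection="cv"`) provides honest selection.
* With no ERD contrast the *winner* of a 15-combination search is biased
  above 50% even under the null; the chance-level test therefore checks a
  pre-specified combination against a plain binomial interval and the
  winner against a max-of-15 envelope.
* Results are independent of combination evaluation order (deterministic
  enumeration, argmax with first-index tie-break).
* Problem sizes used in the shipped runs: reduced 6-region pool
  (15 combinations per cell) and 4–6 sources per patch, which keep the full
  five-subject ablation to a couple of minutes while exercising every code
  path; the 1820-combination search is a flag away (`02_run_ablation.py
  --full`) and scales linearly.

## Known limitations

* The spherical forward model and explicit regularization mean published
  table values from BEM-based pipelines are reproduced only in aggregate
  arithmetic and qualitative ordering, not cell by cell.
* The 30/61/118-channel cap label sets are standard 10-10/10-05 defaults,
  not copies of any particular commercial cap; montage files are editable.
* The generator's ERD is purely an amplitude effect at one frequency;
  frequency shifts, post-imagery rebound and bilateral ERD are not modeled.
* One row of the shipped published benchmark table prints an F1
  inconsistent with its own Sen/Pre (74.04 vs the implied 73.04); the
  verification command reports it as a known typo.
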