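# Methods

## The problem

Band-power-based classifiers of cognitive workload trained on one
experimental condition usually collapse when applied to another: the spatial
filters and the linear classifier are calibrated to one condition's signal
composition, and the most discriminative contributions — ocular and muscular
activity — are condition-specific. `beamadapt` implements a pipeline in
which the spatial filters are re-derived after every epoch from an
unsupervised running estimate of the data covariance, so that a classifier
trained in one condition remains usable in another.

## Signal model

EEG is modelled as a linear instantaneous mixture

```
x(t) = A s(t) + η(t),          Σ_x = A Σ_s Aᵀ + Σ_η
```

with `x` the channel signals, `A` the mixing (pattern) matrix, `s` the
source activities and `η` everything unmodelled. All filters are solutions
of a generalized Rayleigh quotient

```
w* = argmax_w  (wᵀ S_num w) / (wᵀ S_den w)
```

solved by generalized eigendecomposition (`scipy.linalg.eigh`), with

* **CSP** — `S_num = Σ_high`, `S_den = Σ_high + Σ_low` (class-conditional
  covariances of band-passed 60-s epochs). Eigenvalues lie in [0, 1]; both
  spectrum ends are informative and 3+3 components are kept by default.
* **Beamformer (BF)** — `S_num = Σ_ROI = L Σ_s Lᵀ`, `S_den = Σ_x`, where `L`
  is the spherical-model leadfield over a whole-brain source grid and
  `Σ_s = I`. Eigenvalue order carries no class meaning, so all components
  are kept and the classifier weights them. The covariance form
  `L Σ_s Lᵀ` is used (channel × channel); a source-space ordering of the
  same product would be dimensionally inconsistent with the channel-major
  mixing convention above.

Eigenvectors are denominator-orthonormal (`Wᵀ S_den W = I`). This
normalisation matters: each component's variance is 1 under the covariance
the filters were derived against, so log-variance features stay on the
training scale after the denominator is adapted to a new condition.

Patterns are recovered from filters by `A = Σ_x W (Wᵀ Σ_x W)⁻¹` — for square
invertible `W` this is `(W⁻¹)ᵀ`. Patterns, not filters, are the
physiologically interpretable quantity, and pattern/filter columns are
sign-fixed so the largest-magnitude pattern entry is positive (eigenvector
sign is arbitrary).

## Adaptation (CSPa / BFa)

The running data covariance follows an exponential update per 60-s epoch,

```
Σ_x(M) = (1 − λ) Σ_x(M−1) + λ Σ_{x_M},      λ = 0.1 by default,
```

initialised from the training condition. The update never reads labels.
After each consumed epoch the bank is re-decomposed with its **frozen**
numerator (`Σ_high` from training for CSPa — adapting it would require
labels; `Σ_ROI` for BFa) over the adapted denominator; components are
re-sorted by eigenvalue and sign-aligned with their predecessors.

Ordering is causal: an epoch is filtered and classified with the current
bank *before* its statistics enter the running covariance, so no epoch
influences its own features.

One scale subtlety: CSP's training denominator is the *sum* `Σ_high + Σ_low`
(about twice the pooled data covariance). The CSPa running matrix therefore
starts at half the training denominator and is doubled at re-decomposition
time, making λ → 0 reproduce the training bank exactly.

λ was chosen as a deliberately slow rate — one-epoch covariances of 64
channels are noisy, and per-epoch full re-estimation is known to be
unstable; 0.1 per 60-s epoch forgets with a ~10-epoch time constant. It is
config-exposed (`RunConfig.lam`).

## Head model

An analytic three-shell concentric-spheres model (brain/skull/scalp radii
0.87/0.92/1.0 of the scalp radius; conductivities 1 : 1/50 : 1). For each
spherical-harmonic order the radial potential in shell *j* is
`A_j rⁿ + B_j r^-(n+1)`; continuity of potential and radial current at the
two interfaces plus zero current through the scalp yields a 5×5 linear
system per order whose solution gives the scalp gain. The series is
truncated at 60 terms; sources are kept within 90 % of the brain radius so
the truncated tail is negligible (the term ratio is ≤ 0.78ⁿ). In the
equal-conductivity limit the implementation agrees with the closed-form
homogeneous-sphere solution to < 1e-6 relative error (tested against an
insulated-sphere monopole formula with a finite-difference dipole limit).

Electrode coordinates come from the standard-1005 template (via `mne`),
re-expressed as unit vectors from a least-squares sphere centre. The
leadfield is computed average-referenced and re-referenced to linked
mastoids (TP9/TP10) to match the recording convention. The source grid is a
regular Cartesian lattice (spacing 0.19 of the scalp radius, ≈ 260 in-brain
locations, three orthogonal dipole orientations each) — coarse, but the
whole-brain ROI covariance only needs the subspace geometry, not source
resolution.

## Features and classifier

Band-pass: causal (forward-only) Butterworth of overall order 4 per band
(θ 4–7 Hz, α 8–13 Hz). Causal filtering is the online-plausible choice;
`zero_phase=True` switches to forward–backward filtering for offline study.
Epochs are non-overlapping 60-s windows restarted at each block onset, so no
epoch straddles a class boundary; trailing partial windows are discarded.

Features are `ln var` of each spatially filtered component per epoch (epoch
mean subtracted; variance normalised by n−1), bands concatenated. Band power
is approximately χ²; the log makes the class distributions near-Gaussian
with similar spread, matching LDA's assumptions. LDA is the closed form
`w = Σ_pooled⁻¹ (μ_high − μ_low)` with the boundary midway between projected
class means; the pooled covariance is shrunk toward a scaled identity with
the analytic Ledoit–Wolf coefficient — necessary where 128 features (64
components × 2 bands) meet ≤ 80 epochs. Ties classify as `low`.

Covariance estimates throughout are epoch-averaged sample covariances with
the same shrinkage scheme (`(1−γ)Σ + γ(trΣ/C)I`, analytic γ by default,
fixed-γ override). Shrinkage is the operational stand-in for the never
explicitly estimated sensor-noise term `Σ_η`. If a Rayleigh denominator is
ill-conditioned (condition number > 1e10), shrinkage is raised in steps of
0.01 until positive definite, with a log message.

## Validation

Within a condition, chronological leave-one-block-out cross-validation: one
fold per 4-min block in the n-back paradigm (10 folds), one fold per
repetition in the maneuver paradigm (2 folds). Random epoch-level splits
would leak across the strong autocorrelation of continuous EEG. Spatial
filters and the classifier are fitted on training folds only. Single-block
folds contain one class, where the class-wise loss is undefined; per-fold
numbers report the mean error over present classes, and the headline CV
number is the class-wise normalized loss over the pooled out-of-fold
predictions.

Between conditions, filters and classifier are trained once on the full
training condition and applied to the other condition's epochs in
chronological order (with per-epoch adaptation for CSPa/BFa). When the
maneuver condition is the test side, its two repetitions are scored
separately and averaged. All scores are the class-wise normalized loss
(mean of per-class error rates; 0.5 is chance), and per-subject mean losses
are tested against chance with a two-sided exact Wilcoxon signed-rank test.

The adaptive variants exist for the cross-condition setting; within a
condition they evaluate through their non-adaptive base method.

## The synthetic benchmark

No public recordings accompany the study design, so the package ships a
generative benchmark that reproduces the *structure* of the phenomenon:

* two **neural sources** mixed through the head model — frontal midline θ
  (power 2:1 with workload) and parieto-occipital α (1:2, i.e. suppressed
  under load) — whose class-power maps are identical in both paradigms;
* two **artifact sources** with steep near-electrode exponential gain
  profiles — an ocular source (1–7 Hz, frontopolar) discriminative (3:1)
  only in the maneuver paradigm, and a temporal-muscle source (8–45 Hz)
  discriminative only in the n-back — with matched average power elsewhere;
* a **1/f background** of 40 pink-noise brain sources whose per-source
  amplitudes are re-drawn (lognormally, σ = 1.0) per condition, producing a
  global covariance shift between paradigms;
* a small per-condition **orientation jitter** (0.5 rad) of the neural
  dipoles: a source's scalp pattern is not perfectly reproducible across
  sessions, and this slight pattern change is what defeats exact filter
  transfer even for the shared neural sources;
* white sensor noise.

Schedules follow the paradigms: ten alternating 4-min blocks (low first)
for the n-back; (5 min low + 10 min high) × 2 repetitions for the maneuver.
Default sampling rate is 200 Hz — the α/θ content needs far less than a
kHz, and this keeps a full benchmark grid tractable on one core (1 kHz is
configurable). All randomness flows from a single subject seed;
per-condition draws are independent child streams.

Effect sizes (neural level 1.1, artifact level 2.25, background 2.25, noise
1.0) are benchmark parameters, not claims about any real data set. They
were calibrated once so that the qualitative outcome of the real-data study
emerges robustly across 20 seeded subjects — within-condition losses well
below chance for every method, non-adaptive transfer inside the chance band
[0.4, 0.6] in both directions, adaptive beamforming below 0.4 in both
directions — and then frozen. What passing this benchmark shows is that the
pipeline's machinery produces the transfer phenomenon for the stated
reasons (condition-specific artifacts, covariance shift, pattern
non-stationarity); it does not show that real EEG of any particular task
would yield the same numbers.

Features of real data the generator does not emulate: biophysically
realistic EOG/EMG spectra and waveforms (artifacts are band-limited noise),
inter-subject anatomical variability, electrode impedance drift, line
noise, and genuinely non-stationary within-condition neural dynamics.

## Numerical choices and degenerate inputs

* Covariances are symmetrised after every arithmetic step; PSD is enforced
  through shrinkage rather than eigenvalue clipping.
* Zero-variance components raise rather than silently producing `-inf`
  features.
* A recording whose blocks are all shorter than the epoch length raises
  "no usable epochs".
* The exact Wilcoxon distribution is used up to n = 25 subjects; all-zero
  differences raise rather than returning p = 1.

## Known limitations

* The whole-brain ROI makes beamformer components unspecific by design;
  narrowed anatomical ROIs are out of scope.
* Classifier (as opposed to filter) adaptation is not implemented.
* The spherical model has no eye/muscle compartments; artifact suppression
  rests solely on the covariance statistics.
* Component correspondence across adaptation steps is by eigenvalue rank
  and sign alignment; under very large covariance shifts, rank crossings
  can permute components faster than the classifier can tolerate.
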