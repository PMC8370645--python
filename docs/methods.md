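# Methods

## Setting and threat model

The package operates on cohorts of per-recording multivariate feature time
series: one real-valued signal per (participant, recording, feature), sampled
at a fixed step (0.5 s or 1 s in the emulated datasets) by sliding-window
feature extraction. The database of the ε-DP definition is the cohort; two
cohorts are neighbors when they differ in one participant's data. The
released object is the full noisy time series per feature, one query per
feature at the configured ε (the cross-feature total under sequential
composition is recorded in release provenance but deliberately not enforced —
features are released and analyzed independently, as is standard for this
data). The adversary of interest performs person re-identification from the
released signals and may exploit temporal correlations; the difference-based
mechanism exists to shrink those correlations so that the effective privacy
level stays close to the nominal ε. Estimating the correlation-aware
effective ε itself is out of scope.

## Sensitivity

For feature f and class label c (document type, sensitivity level, ...), the
order-w sensitivity is the maximum L_w distance between the observation
vectors of any two participants, Δ_w = max_{p≠q} ‖X^(p,f) − X^(q,f)‖_w,
computed per class because mechanisms are applied separately per class.
Shorter vectors are zero-padded to the maximum length; chunked scopes use the
common chunk partition of [0, n_max) and take the max pairwise distance per
chunk; the difference scheme applies within-chunk consecutive differencing
(first element preserved) before measuring distances, matching exactly what
the difference mechanism releases. Recordings are treated per-recording (not
concatenated); pairs are only formed across distinct participants. L1
dominates L2 by norm monotonicity and chunk-level Δ₂ never exceeds
whole-signal Δ₂; both are asserted as invariants.

## Mechanisms and calibration

* **LPA** adds i.i.d. Laplace(Δ₁/ε) noise to every sample.
* **FPA** computes the non-unitary DFT (forward sum, 1/n inverse — the
  normalization under which Parseval reads Σ|F_j|² = n·Σ|x_t|²), keeps
  coefficients 0..k−1 (the k lowest frequencies of the full complex layout),
  adds independent real Laplace(λ) noise to the real and the imaginary part
  of each retained coefficient with λ = √(nk)·Δ₂/ε, zero-pads and inverts,
  taking the real part (noisy spectra lose conjugate symmetry; the real part
  is the natural real-signal estimate and is recorded in provenance so
  alternative conventions remain comparable). The √(nk) scale follows from
  Δ₁(F̂) ≤ √k·Δ₂(F̂) ≤ √(nk)·Δ₂(X) (Cauchy–Schwarz plus Parseval), which the
  suite checks on 1000 random pairs for every valid k.
* **CFPA** applies FPA independently to disjoint chunks (sizes 32/64/128 —
  powers of two for fast transforms; the final partial chunk keeps its own
  length, signals are never padded) with chunk-level sensitivities;
  parallel composition over disjoint data preserves ε.
* **DCFPA** differences inside each chunk (d₁ = x₁, d_t = x_t − x_{t−1}),
  applies FPA to the difference signal with difference-scheme sensitivities,
  and rebuilds by prefix sums. The noisy difference sequence is the released
  quantity; prefix summing is post-processing and consumes no further budget,
  which is the tightest defensible accounting. Chunks again compose in
  parallel.

Degenerate sensitivities (Δ = 0, as happens in identical-participant test
cohorts) produce a zero noise scale with a logged warning rather than an
error; all four mechanisms are then identity maps up to spectral round-off,
which is asserted to 1e-9.

## Choice of k

A small k inflates reconstruction error, a large k inflates perturbation
error through λ ∝ √k. For each (feature, class, chunk) scope the candidate k
minimizing the mean |NMSE| over 100 noisy evaluations (default; configurable)
is selected, candidates defaulting to powers of two up to the scope length.
Ties break toward smaller k, which lowers λ and cost. Repetition substreams
are derived deterministically from a root seed and the scope key, so the
"100 noisy evaluations" are exactly re-runnable. Differentially private
selection of k is not attempted.

## Utility metric

NMSE = (1/n)·Σ(xᵢ − x̃ᵢ)² / (x̄ · x̃̄), which can be negative when the means
have opposite signs; all aggregation uses |NMSE|. A zero denominator is a
hard error, reported with signal context. Utility is 1/|NMSE|. Per-feature
utility is defined as the reciprocal of the per-feature mean |NMSE| (the
per-rep mean of reciprocals is heavy-tailed as |NMSE| → 0 and therefore
unstable); the aggregate is the arithmetic mean over non-excluded features,
computed per class first. A perfect release (|NMSE| = 0, possible only in
degenerate cohorts) yields an infinite-utility sentinel excluded from
aggregates with a logged count.

## Correlation profiles

For a feature and class, the profile at lag Δt is the Pearson coefficient
*across participants* between the sample at a reference time step (default
index 5) and the sample Δt steps later, optionally after differencing.
Participants are i.i.d. replicates of the signal process, so this
cross-participant coefficient estimates the process correlation between the
two time points plus the contribution of time-constant participant
signatures — precisely the structure a correlation-exploiting adversary can
use. Zero-variance lags are flagged as undefined (NaN), never dropped
silently.

## Empirical DP audit

The audit histograms mechanism outputs for two neighboring inputs on shared
bins (10⁶ draws by default) and examines the maximum absolute log count
ratio. Bins with fewer than 20 counts on either side are excluded and
counted. The decision rule flags a violation only when a bin's log-ratio
exceeds ε by more than z binomial standard errors with z Šidák-corrected
over the tested bins at a family-wise level of 10⁻³: a flat 3σ-per-bin rule
false-alarms on a correctly calibrated mechanism in roughly one run in ten
purely through multiplicity, while the corrected rule keeps the false-alarm
rate at 0.1% and still detects a halved noise scale (true loss 2ε) from the
high-count central bins. The audit applies to scalar outputs; auditing a
coordinate of a vector release is valid because post-processing cannot
increase privacy loss, but it is a *necessary* check only — the √(nk)
calibration is conservative, so deliberate miscalibration is audited in the
length-1 regime where the bound is tight.

## Classification protocols

Class prediction uses leave-one-person-out cross-validation; person
identification trains on the first half of every recording and tests on the
second half — an adversary's best case, simulating prior knowledge of each
participant's behavior. Signals are decimated (first sample of each
non-overlapping window; windows 10/20 for class tasks and 5/10 for person
identification at 0.5 s/1 s steps) and each retained time step is one example
with the per-window feature vector as features; no sequence models are used,
which is what makes per-time-step majority voting meaningful. Training data
are standardized to zero mean and unit variance with the parameters reused on
test data; constant columns map to zero. Classifiers: k-NN (k = 11), RBF
SVM (C = 1, kernel scale 1/(n_features·Var), the "scale" convention),
decision tree, and a 10-tree random forest, all seeded from the protocol
seed. Majority voting aggregates per (participant, recording) with seeded
uniform tie-breaking. Binary class tasks are run without voting.

## Synthetic cohort generator

Each signal is baseline (10.0, keeping NMSE denominators away from zero, as
nonnegative eye-movement features are) + a class template (two random
low-frequency sinusoids per (class, feature), amplitude 1.5) + a participant
offset drawn once per (participant, feature) (sd 2.0) + AR(1) noise
(ρ = 0.95, innovation sd 0.5) smoothed by a 10-sample moving average. The
AR + moving-average structure is the minimal process reproducing the strong
sliding-window autocorrelation; the participant offsets are the biometric
signature, sized so that clean-data person identification approaches 1.0 —
the regime reported for real recordings — making privacy effects measurable.
Presets: `mpiidpeye_like` (20 participants × 3 document types = 60
recordings, 52 features with the 4 wordbook counts excluded, 0.5 s step) and
`mpiiprivaceye_like` (17 participants × 3 sessions = 51 recordings, binary
sensitivity labels, 1 s step). Lengths default to a desk-scale n = 512 rather
than recording-scale; repeated-evaluation sweeps in the test suite and the
acceptance script additionally restrict to the first 12 active features.
What the generator does **not** emulate: heterogeneous recording durations,
nonstationary bursts, non-Gaussian marginals, cross-feature dependence, and
scene content. Consequences: sensitivity-versus-length effects of real data
are only partially represented, and conclusions about *which* chunked
variant wins at a given ε do not transfer to real recordings — the passing
tests establish the mechanisms' contracts (calibration, identities,
monotonicity, decorrelation, attack resistance), not dataset-level accuracy
numbers.

## Known limitations

* In the noise-dominated regime (smallest ε) with NMSE-optimal k = 1,
  whole-signal FPA noise is a single shared offset per signal while chunked
  noise is a sum of independent per-chunk offsets with at least the same
  total power (the whole-signal max-pair energy decomposes across chunks),
  so chunking cannot improve mean |NMSE| there on a stationary cohort; its
  advantage appears as soon as reconstruction error matters (ε ≥ 2.4 on the
  default cohort). This is a property of the metric and mechanism family,
  not of the implementation.
* The audit is a necessary empirical check, never a proof; vector releases
  are audited through scalar post-processings.
* ε′ (the effective budget under correlation) is characterized only
  indirectly through correlation profiles and attack accuracies.
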