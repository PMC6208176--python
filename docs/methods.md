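# Methods

This note records the models, conventions and design choices behind
`emofuse`, in the spirit of the methods documentation of mature scientific
packages: enough detail that every number the package produces can be traced
to a stated rule.

## Problem setting

Emotions are modelled on the circumplex: a trial's self-assessed arousal and
valence (1–9 scale) place it in one of four quadrants, Q1 = high
valence/high arousal, Q2 = low/high, Q3 = low/low, Q4 = high/low. The
quadrant cutoff is 5.0 (the midpoint of the scale) with ties assigned to the
low side; the cutoff is a package convention, exposed in the config, since
rating scales have no canonical binarization point. The classifier's job is
to recover the quadrant from the epoch's multichannel EEG.

## Synthetic data generator

Real rated-EEG benchmarks are access-restricted, so `emofuse.simulate`
generates epochs with the structural properties the chain depends on, and it
is first-class, tested code — the study conditions, not a throwaway fixture.

* **Spatial structure.** Each quadrant has an active channel set; by default
  8 channels with a shared core {0, 1, 2}, one quadrant-specific extra
  channel each (3–6), and one background channel (7). Active channels carry
  unit-variance signals; background channels are attenuated to gain 0.2
  (active:inactive amplitude ratio 5, comfortably above the 3× floor the
  selection stage assumes).
* **Dynamics.** Signals mix band-limited oscillations (sums of 2–3 sinusoids
  around a dominant EEG-band frequency with random phases) and a chaotic
  component (a logistic-map orbit at r = 4, polyphase-resampled 4× so it is
  band-limited and its phase-space features are non-degenerate). The shared
  core encodes the class: channel 0's chaos fraction follows arousal
  (0.75 high / 0.25 low), channel 1's dominant rhythm follows arousal
  (beta-range vs theta-range), and channel 2's amplitude (×1.8) and
  regularity follow valence. Quadrant extras carry a quadrant-specific
  rhythm. This makes the quadrants separable *from the channels that survive
  the cross-class intersection*, which is the property the real study
  exploits.
* **Noise and ratings.** Per-channel white Gaussian noise at a configurable
  SNR (default 15 dB — rated-trial benchmarks are distributed artifact-
  cleaned, so a mild noise floor is realistic). Ratings are uniform inside
  the quadrant's box. Everything is a deterministic function of the seed.
* **Default sizes.** 40 trials/class, 4096 samples at 128 Hz (32-second
  windows — the shortest length at which the entropy features are stable;
  epochs below 4000 samples trigger a warning). These scaled sizes are the
  package's standard study conditions; full-scale runs (32 channels,
  7680-sample minutes, 1280 trials) are a config away.

What the generator does **not** emulate: inter-subject variability, video-
stimulus time-locking, peripheral channels, volume-conduction lead fields,
or non-stationarity within an epoch. Passing tests therefore demonstrate
that the chain recovers planted class structure through realistic signal
dynamics — not that it attains any particular accuracy on real recordings.

## SOBI and activity maps

`sobi` removes channel means, whitens via the covariance eigendecomposition
(eigenvalues below 1e-10 of the largest are dropped as rank deficiency, with
a warning), and jointly diagonalizes the symmetrized lagged covariances of
the whitened data by Jacobi rotations (closed-form Cardoso–Souloumiac
angles; tolerance 1e-8 on the rotation sine, at most 200 sweeps; the summed
off-diagonal energy is non-increasing across sweeps and is exposed for
verification). Default lags are {1, …, min(100, T/4)} samples: enough lag
diversity to separate sources by their autocorrelation without reaching into
unreliable long-lag estimates. Sign indeterminacy is fixed by making each
mixing column's largest-magnitude entry positive; components are ordered by
energy.

Channel *activity* is `Σ_k |mixing[c,k]| · std(source_k)` — how strongly any
component expresses on the channel, weighted by component energy. This is a
package convention: scalp-map interpolation is out of scope, and the
energy-weighted mixing magnitude preserves the ranking semantics that
"average activity" needs.

Per-class maps are the mean over the class's epochs, normalized by the
**pooled peak magnitude** across the class-mean maps, so all values lie in
[−1, 1] and the dataset's most active channel sits at ±1. An affine min–max
map onto [−1, 1] was rejected deliberately: with nonnegative activities it
pins the quietest channel at −1 in every class, and the sign-blind
|activity| > threshold rule would then select background channels
everywhere, poisoning the cross-class intersection. Peak normalization
keeps quiet channels near 0 and makes absolute-value thresholding mean what
it is meant to mean.

## Channel selection

A channel is *emotional* for a class when |normalized activity| strictly
exceeds the threshold; only channels emotional in all four classes survive
(`intersect_channels`; an empty intersection raises with advice to lower
the threshold). The threshold has no principled value — `tune_threshold`
scans a candidate grid (default 0.1 … 0.9) against a caller-supplied
downstream scorer and breaks ties toward the smaller threshold (more
channels retained). The cross-validation driver uses a fixed default of
0.4 and walks down the grid only if the intersection comes up empty inside
a fold.

## Nonlinear features

Shared embedding conventions: dimension m = 10, delay τ = first zero
crossing of the autocorrelation (per channel, per epoch), Theiler window
m·τ. Long series are decimated to at most `max_points` = 1000 phase-space
points before the quadratic pair computations (CD, LLE, recurrence); the
broadband statistics (FD, SpEn, DeEn) use the full-rate series. m and τ are
reduced automatically if a short series cannot support ~100 embedded
points. All conventions are written to the feature table's JSON sidecar.

* **CD** — Grassberger–Procaccia: slope of log C(r) vs log r with the
  scaling region spanning the 1st–10th percentile of Theiler-masked pair
  distances (small enough that edge effects are negligible; verified to
  recover dimension 1 on a line and 2 on a square within 0.1/0.15).
* **FD** — Higuchi with k_max = 10.
* **LLE** — Rosenstein: nearest neighbours outside the Theiler window,
  mean log divergence over 15 steps, slope fitted on steps 1–7, scaled to
  1/s by the (decimated) sampling rate. Verified against ln 2 on the r = 4
  logistic map.
* **SpEn** — Richman–Moorman with m = 2, r = 0.2·SD (field convention),
  self-matches excluded, N−m templates for both lengths; pair counting via
  a KD-tree in the Chebyshev metric. No (m+1)-matches returns the maximum
  estimable value −ln(2/((N−m−1)(N−m))); a constant series returns 0.
* **RQA** — the recurrence threshold ε is the distance quantile giving a
  fixed recurrence rate of 0.02 per epoch so DET/L/ENT are comparable
  across epochs; l_min = 2. Diagonal lines are counted on both triangles;
  DET = fraction of off-diagonal recurrent points on lines ≥ l_min, L =
  mean qualifying line length, ENT = Shannon entropy (nats) of the
  qualifying line-length histogram; all three are 0 when no line qualifies.
  The brute-force diagonal-scan oracle in the test suite *defines* this
  convention (e.g. an all-ones 10×10 matrix at l_min = 2 gives RR = 1,
  DET = 88/90, L = 5.5, ENT = ln 8).
* **DeEn** — Gaussian closed form ½ ln(2πeσ²) with the unbiased variance,
  computed broadband on the whole window (no band decomposition).

All features are invariant to additive offsets; CD/FD/LLE/RQA are invariant
to positive rescaling (r and ε are defined relative to the SD), and DeEn
shifts by exactly ln(scale).

## Feature trees and the local subset search

The score of a tree is the mean, over training samples, of the fraction of
the sample's k nearest neighbours *within its own locality* (Euclidean
distance over the locality's feature subset; an empty subset falls back to
all features) that share its label. This equals the normalized double sum
1/(K|S|)·ΣΣ[label match] whenever every locality supplies k neighbours;
smaller localities truncate k per sample (a singleton contributes 0), which
keeps the score in [0, 1] and exact on degenerate partitions. k defaults
to 5.

The search treats tree construction as sequential decision making: states
are root-to-node action sequences; actions are feature nodes (features not
already on the path), splitting nodes (threshold fixed at the node-median —
the midpoint of the two middle sorted values — keeping the action set
finite and splits balanced), and termination. Rollouts are ε-greedy
(ε = 0.2) over per-state Monte-Carlo mean values with optimistic
initialization; 500 rollouts and depth ≤ 4 by default; the best tree
encountered is returned, and in unconstrained mode the single-leaf tree is
seeded as the incumbent so the result can never score below no partitioning
at all. Everything is deterministic given the seed.

The two label axes get two independent searches constrained to exactly two
leaves (one split plus feature nodes — the two-locality structure the
problem calls for). Features are then ranked by *selection frequency
weighted by score gain*: each feature accumulates, over the rollout trees
that used it, the tree's score minus the reference level (the larger of the
single-leaf baseline and the mean rollout score). Referencing the mean —
not the baseline alone — matters: when the all-feature baseline is already
high, no rollout clears it and a baseline-only rule degenerates to zero
weights for every feature. The top 10 features per axis are kept (all of
them, with a warning, if fewer exist).

## Classifier and fusion

Each subset's features are z-scored on the training fold. Class prototypes
are the per-class means in that space; a training sample's memberships are
normalized inverse distances to the prototypes (an exact hit gives
membership 1). The evidential target is the set of classes with membership
≥ 0.4 **unioned with the true class**: relabeling softens crisp labels
into composite hypotheses for ambiguous samples, it never discards the
label. (Taken without the union, targets degenerate to nearest-prototype
pseudo-labels — in the 10-dimensional z-scored space memberships are nearly
uniform and the thresholded set is almost always empty — which measurably
corrupted training on cleanly separable synthetic data.) Composite targets
become uniform distributions over their member classes, so any learner
that regresses a target distribution can serve as a base model.

The base learners are scikit-learn `MLPRegressor`s (one hidden layer of 20
logistic units, 500 epochs, seeded) trained on those target distributions.
At test time each MLP's four outputs pass through a max-shifted softmax to
become a singleton mass function; the (two or more) mass functions are
folded by Dempster's rule, and the decision is the maximum-belief singleton
(for singletons Bel = mass), with ties logged and resolved toward the
lowest class index. Test-time masses are singleton-only; composite
hypotheses live in the combination and decision machinery and in training
targets.

## Evaluation

Confusion counts follow rows = decision, columns = target; the confidence
matrix divides each column by its total (×100); CCR is trace over grand
total. Cross-validation is stratified (seeded shuffling) with k = 10 by
default, shrinking with a warning if a class has fewer samples than folds.
CCR is pooled over folds (counts summed, then trace/total) rather than
averaged, matching the grand-total form of the definition. Per-epoch
computations (SOBI activity vectors, feature values) are computed once —
they depend on a single epoch only, so nothing leaks — while class maps,
threshold intersection, subset search, prototypes, scalers and MLP weights
are refit inside every training fold.

## Problem sizes and runtime

The standard scaled study (tests and `scripts/acceptance.py`) uses 40
epochs/class × 4 classes × 8 channels × 4096 samples, 10-fold CV, and a
search budget of 300 rollouts per axis per fold: roughly two minutes on one
CPU, dominated by feature extraction (~1280 channel-epochs at ~80 ms). The
SOBI recovery study uses 4-channel mixtures of narrowband sources with
well-conditioned mixing (random rotation × gains in [0.7, 1.4]): recovery
correlation is then limited by the 20 dB noise floor rather than by the
conditioning of the unmixing problem.

## Known limitations

* The channel-activity definition is a stated convention; other mappings of
  component topographies to channel scores would reorder borderline
  channels.
* The Monte-Carlo search is a practical bandit scheme, not a regret-optimal
  instantiation; with very small budgets it can return weakly supported
  subsets (the ranking rule then falls back gracefully toward frequency).
* Second-order separation cannot isolate sources whose lagged
  autocovariances match (e.g. two white-ish broadband sources); the
  generator's chaotic component is band-limited partly for this reason.
* Synthetic results demonstrate correctness of the machinery, not expected
  accuracy on real EEG.
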