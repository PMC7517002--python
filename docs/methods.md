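# Methods

## Problem and pipeline

Given multi-channel peripheral physiological recordings labeled with either
a discrete emotion or a (valence, arousal) rating pair, the package
classifies fixed-duration windows into four emotion classes. The pipeline
is: time-based segmentation → per-channel entropy features → early fusion
(concatenation) → train-split z-scoring → classification, with the
classifier being either a single learner or the SVM–DT–ELM team strategy.
Segments are treated as i.i.d. samples inheriting their recording's label;
splitting is segment-level by default, with an optional group-aware split
(`ExperimentConfig.group_by`) that keeps all segments of a recording on one
side of the partition for users worried about within-recording leakage.

## Entropy features

All four features operate on a single channel window of length `N`.

**ApEn.** Templates `X_m(i)` of length `m` are compared with the Chebyshev
distance; `C_i = #{j : d(X_i, X_j) ≤ r}/(N−m+1)` including the self-match,
`Φ_m = mean ln C_i`, and `ApEn = Φ_m − Φ_{m+1}`. Self-inclusion guarantees
`C_i > 0`, so the logarithms are always defined.

**SaEn.** The canonical Richman–Moorman form: over the `N−m` templates at
both dimensions, `B` (dimension `m`) and `A` (dimension `m+1`) are the mean
fractions of matching template pairs excluding self-matches, and
`SaEn = −ln(A/B)`. When no pair matches at either dimension the statistic
is undefined and the function raises rather than inventing a value. (Some
printed formulations place the logarithm inside the template average, which
would make the final ratio ill-formed; the plain-average form is the one
whose ratio reduces to a match-probability quotient, and it is what the
package implements.)

**FuEn.** Identical template construction (no subtraction of the template
mean — the distances compare raw samples), with the hard threshold replaced
by the membership `A_ij = exp(−ln2·(D_ij/r)²)`, which equals 1/2 exactly at
`D = r`. Per-template memberships are averaged excluding the self-pair; the
statistic is `ln Φ_m − ln Φ_{m+1}`.

**WpEn.** The window is decomposed with a wavelet packet transform
(PyWavelets, symmetric padding) to level `depth`; terminal-node energies
`E_j = Σ c²` in natural band order are normalized to `p_j` and the feature
is the Shannon entropy `−Σ p_j ln p_j` (natural log, `0·ln 0 := 0`), which
lies in `[0, ln 2^depth]`.

Matching uses `d ≤ r` (the canonical convention; a strict `<` differs only
on measure-zero ties). The tolerance is `r = r_frac · std(window)` with the
population standard deviation of the individual segment channel, making the
three template entropies invariant under amplitude scaling; WpEn is
scale-invariant because it uses energy ratios only. Zero-variance windows
return 0 for ApEn/SaEn/FuEn (perfect regularity) while WpEn raises on an
all-zero signal (no energy distribution to normalize).

Defaults: `m = 2`, `r_frac = 0.2` (inside the customary 0.1–0.25 band),
`wavelet = "db4"`, `depth = 3`. None of these is forced by the method
itself; all are exposed in `EntropyParams`. Feature order within a channel
block is fixed as (ApEn, SaEn, FuEn, WpEn).

## Fusion and scaling

Fusion is pure concatenation of channel blocks in configured channel order
— no weighting or reduction — so a 4-channel setup yields 16 features and
single-channel tables are exact sub-projections of the fused table. A
z-score scaler is fitted on training rows only (fitting on test rows is a
contract violation) because the RBF-SVM and the ELM are scale-sensitive;
constant columns pass through unchanged, and the scaler can be disabled or
serialized to JSON.

## Classifiers

**SVM.** One-vs-one RBF SVM (libsvm via scikit-learn): k(k−1)/2 binary
models, prediction by vote count. Hyperparameters are chosen by grid search
over `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}` and `γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}` with 5-fold
stratified, unshuffled cross-validation on accuracy; ties go to the
smallest `C`, then the smallest `γ`, so selection is deterministic. The
pairwise decision values follow the verified libsvm convention: columns are
ordered pairs (i, j), i < j in class order, positive favoring class i. The
QP solver is deliberately not reimplemented; the package's obligations are
the OvO bookkeeping, decision-value access, and the grid search.

**Decision tree.** The classical gain-based construction assumes
categorical attributes; entropy features are continuous, so the tree uses
the standard C4.5 adaptation: binary splits at midpoints of consecutive
sorted unique values, scored by gain ratio (information gain divided by
split information, both in bits). Growth stops at pure nodes, unsplittable
nodes, or when the best gain ratio falls below `ε` (default 1e−7, i.e.
effectively "grow until pure"); no pruning.

**ELM.** Single hidden layer with weights and biases drawn i.i.d.
uniform(−1, 1) from an explicit seed, sigmoid activation by default (an RBF
activation variant is available), one-hot targets, and output weights
`β = H⁺Y` via the Moore–Penrose pseudo-inverse — the least-squares solution
of `Hβ = Y`, decoded by argmax. Default hidden size
`M = min(10·d, N_train)`.

## Team-collaboration strategy

The SVM decides alone when it is confident (principle I). A sample is
referred when (a) its top vote count is tied, or (b) the four-inequality
margin predicate in the README holds. The predicate's quantities are the
extreme |decision values| of the pairwise models involving the SVM's top
and second-ranked classes; ranking ties are broken by the summed signed
decision values in each class's favor. The margin sets are taken over the
runner-up's models regardless of its exact vote count, and the predicate is
isolated in `margin_predicate` so alternative readings of its grouping can
be swapped in. For referred samples: if DT or ELM matches the SVM's top
class it stands (principle II, minority obeys majority); else if one of
them matches the second-ranked class, that class wins (principle III); if
neither holds — a case the principles do not cover — the verdict falls back
to the SVM's top class, tagged FALLBACK so it is visible in the logs. When
referral never triggers, team output is identical to SVM output sample for
sample.

## Evaluation protocol

Repeated hold-out: optionally subsample `subsample_n` rows uniformly
without replacement (redrawn fresh each repetition), then split at
`train_fraction` (stratified by class by default; stratification is
disableable and a group-aware variant exists). All arms of an experiment
share each repetition's split, so comparisons are paired. Accuracies are
kept on the percent scale; the summary is the mean and the `N−1`-denominator
standard deviation. Reports are a pure function of (table, config, seed);
per-repetition seeds derive from `SeedSequence([seed, rep_index])`.

## Synthetic data generator

Each channel is `amp · (sin(2πft + φ) + w·z(t) + g·nsr·ε(t))`: a sinusoid
at a channel-specific base frequency, a logistic-map component
`z_{n+1} = a·z_n(1−z_n)` iterated at 32 Hz (first 1000 iterates discarded,
standardized, resampled to the channel rate), and white Gaussian noise.
The class controls `a` (3.58 / 3.70 / 3.90 / 3.99 — chaotic-regime values
chosen away from periodic windows) and the noise-to-signal ratio `nsr`
(0.08 / 0.18 / 0.32 / 0.50), so class identity lives in complexity, which
is exactly what the entropy features measure. Amplitude and phase are
randomized per channel and recording, so trivial amplitude statistics carry
no class information. Channels differ in their sensitivity `(w, g)` to the
chaos and noise effects, which makes each single channel only partially
informative and gives fusion something real to add.

Three layouts are provided: a music-induction shape (4 named emotions × 25
recordings × 120 s; one 256 Hz channel, three at 32 Hz; segments to 1000
samples at 12 s windows), a video-induction shape (40 trials × 63 s at
128 Hz with a 3 s baseline and jittered 1–9 valence/arousal ratings;
segments to 400 samples per subject), and a compact 4-class bench layout
(4 × 15 recordings × 24 s, 32–64 Hz channels, 6 s windows → 240 segments)
sized so that a full multi-arm experiment runs in tens of seconds on one
CPU; the bench layout is the default for end-to-end experiments and the
acceptance run.

What the generator does **not** emulate: physiological morphology (no
PQRST complexes, no SCR events, no respiratory coupling), inter-subject
variability, artifacts, or non-stationarity within a recording. Passing
end-to-end tests therefore demonstrates that the pipeline recovers
complexity-coded class structure, not that it attains any particular
accuracy on real recordings.

## Numerical choices and degenerate inputs

- Pairwise template distances are built incrementally (running max over
  offsets), so memory is one (N−m+1)² matrix, never an (N,N,m) array.
- Decision-value 0 votes for the first class of the pair (measure-zero).
- `segment_recording` counts windows as `floor((duration − baseline)/window)`
  with a 1e−9 epsilon so exact divisions are not lost to float rounding;
  trailing partial windows are dropped; concatenating segments reconstructs
  the parent series bit-exactly.
- Ratings of exactly 5 map to Low in the quadrant scheme.
- SVM grid search with fewer samples per class than folds falls back to the
  grid median rather than failing (small-fixture convenience).

## Known limitations

- Subject-independent (cross-subject) evaluation is out of scope; the
  protocol is subject-dependent hold-out.
- The team strategy is specified for four classes; the vote arithmetic
  generalizes to other k, but principles I–III were not designed beyond 4.
- The gain-ratio tree has no pruning, and the ELM has no regularization;
  both follow the plain formulations deliberately.
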