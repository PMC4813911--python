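# Methods

## Model and procedure

QSA folds a four-channel EEG block into one scalar series per sample.  With
channels (c₁, c₂, c₃, c₄) the stream is quat(t) = (c₁, c₂, c₃, c₄)(t) in
(w, x, y, z) order — the first channel of the block is the scalar
component.  The lagged pure stream r(t) carries the vector part of
quat(t − dt), the rotation q_rot(t) = quat(t) ⊗ r(t) ⊗ quat(t)⁻¹ is applied
samplewise, and q_mod(t) = ‖q_rot(t)‖ is summarised per cue/rest segment by
mean, sample variance, contrast Σq_mod²/N² and homogeneity Σ 1/(1+q_mod²)
(cluster shade Σ(q_mod−μ)³ and prominence Σ(q_mod−μ)⁴ are implemented but
not in the default feature set, which matches the published four-column
matrix).  Segments are maximal runs of constant cue label; coordinates are
0-based half-open everywhere.

Two algebraic facts shape the implementation and are enforced by tests:

* **Norm preservation.**  With the true inverse q̄/‖q‖², conjugation
  preserves the vector norm for *any* nonzero quat(t), so
  q_mod(t) = ‖(c₂, c₃, c₄)(t − dt)‖ exactly.  The default `eq6_inverse`
  mode therefore makes dt a pure relabelling of time, explaining its
  empirically flat effect on accuracy.  The `conjugate` mode
  (q ⊗ r ⊗ q̄) scales the output by ‖q‖² and lets the scalar channel
  influence the modulus; it is exposed for exploring that variant.
* **Degenerate samples.**  A zero-norm quaternion defines no rotation; such
  samples produce zero output and a logged warning rather than NaNs.

### Feature formula reconstruction

The variance and contrast formulas circulate in typographically corrupted
form; neither printed string parses as a well-formed expression.  This
package uses the standard sample variance (ddof = 1) and the natural
Haralick-style contrast Σq_mod²/N².  Any consistent discriminative statistic
serves the pipeline equally; the choice is documented here precisely because
it is a reconstruction, not a transcription.

## Segmentation and boundaries

Segmentation is event-driven (10 s cue → sample_rate × 10 samples), not
hard-coded to per-segment sample counts, so it is well-defined at any rate.
The rotated stream is undefined for t < dt; the default `drop_prefix`
policy drops those ≤ 10 samples (affecting only the first segment) instead
of fabricating data, and `zero_pad` substitutes zeros for users who need
aligned lengths.  A segment emptied by trimming is an error naming the
segment.

## Channel blocks

The ten standard blocks are reproduced verbatim, including the fact that
blocks 5 and 6 are printed identically (F3 F4 FC5 FC6); the duplication is
flagged in the API docs rather than silently repaired, and user-defined
blocks are accepted anywhere a block id is.

## Synthetic sessions

The generator reproduces the cue protocol exactly: 40 left/right cues in
strict alternation starting left, 10 s each, every cue followed by a 5 s
rest — the only reading under which 40 × 15 s equals the stated 10 min —
at 128 Hz over FC5, FC6, P7, P8, T7, T8, F3, F4, i.e. 76,800 samples per
channel.  (The alternative 1200/600-samples-per-segment bookkeeping implies
120 Hz and contradicts the 128 Hz device rate; the simulator follows the
device rate, and the event-driven segmentation handles either.)

Each channel is `gain(t)·A·sin(2πft + φ_c) + ε(t)`:

| parameter        | default | meaning                                         |
|------------------|---------|-------------------------------------------------|
| `osc_freq`       | 10 Hz   | mu-band rhythm frequency                        |
| `osc_amp` (A)    | 1.0     | oscillation amplitude (signal units)            |
| `baseline_sigma` | 0.1     | std of i.i.d. Gaussian noise ε                  |
| `erd_factor`     | 0.8     | fractional cue-time attenuation, gain = 1−erd   |
| `lateral_map`    | contralateral | class 1 attenuates FC6, P8, T8, F4; class 2 attenuates FC5, P7, T7, F3 |

Defaults are the conditions under which the pipeline's signal-recovery
property is asserted: a strong, clean ERD (0.8 attenuation over σ = 0.1
noise).  Phases are drawn per channel per session (seeded) to avoid
degenerate cross-channel phase locking.  The model omits 1/f background,
eye/muscle artifacts, volume conduction and subject variability, so passing
tests demonstrate that the pipeline recovers a lateralised amplitude
signature when one exists — not that it attains any particular accuracy on
real recordings, whose published accuracies (≈ 0.85 for DT at best) sit far
below the ≈ 1.0 this idealised generator yields.

## Classification design

Stratified 30/70 train/validation splits (per-class rounding, at least one
training and one validation segment per class), 20 repeats, seeds derived
from a master seed via `numpy` seed sequences (all child seeds < 2³¹).
Classifier defaults mirror the published environment's stated defaults:
CART with Gini impurity and unlimited depth; KNN with k = 1 and Euclidean
distance; SVM with Gaussian RBF kernel, kernel scale 1 (K = exp(−‖u−v‖²/s²),
i.e. gamma = 1/s²) and C = 1, extended one-vs-rest with three binary
machines fused by argmax of their decision values (exact ties to the lowest
class index, matching the one-hot codeword scheme where exactly one machine
is positive).  Features are fed raw, without scaling, as in the original
design.

## Metrics

All metrics come from the pooled 3×3 confusion matrix (rows = true class,
columns = predicted) in exact rational arithmetic, so RT + ET = 1,
Σ_d (n_d/N)·S_d = RT and FA_d = 1 − Sp_d hold exactly rather than to float
tolerance.  Specificity is implemented as the recognition rate among
samples whose true class is not d (the literal defining ratio); the
false-alarm rate is its complement, the only reading consistent with the
published tables.  PP_d = S_d/(1 − Sp_d) and NP_d = (1 − S_d)/Sp_d are
implemented exactly as defined and flagged `None` (never NaN) where the
denominator vanishes; the `weighted_lr` option multiplies PP (divides NP)
by the class-prevalence odds n_d/(N − n_d) as an exploratory variant, since
the published prevalence-weighting rule for these quotients was never
stated.

## Known limitations and an honest negative result

The homogeneity and contrast features are, by construction, unnormalised in
segment length N (homogeneity grows ∝ N, contrast shrinks ∝ 1/N), and rest
segments are half the length of cue segments.  The rest class is therefore
identifiable from segment duration alone: in a control run with
`erd_factor = 0` (no class signal whatsoever) the decision tree still
scores ≈ 0.72 validation accuracy — 0.5 from perfectly recognising rest by
duration plus chance-level left/right discrimination — rather than falling
to the 0.5 majority-class baseline.  The corresponding negative-control
test asserts the at-chance behaviour and fails, deliberately: it documents
that duration leakage is a property of the method's own feature definitions
(consistent with published results where rest sensitivity is exactly 1 for
every classifier), not an implementation artifact.  Users who need a
duration-blind pipeline should restrict `feature_set` to the
length-invariant statistics (mean, variance) or equalise segment lengths.

## Problem sizes

The test suite runs the full 76,800-sample session only where the protocol
itself is under test; elsewhere it uses shortened protocols (a few cues at
32–64 Hz) that exercise identical code paths.  The acceptance script
simulates one full session and evaluates 3 classifiers × 20 repeats on the
80 × 4 feature matrix, completing in a few seconds on one CPU.
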