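# Methods

`oscnet` characterizes the brain-wide organization of oscillatory activity
in multichannel EEG-like recordings. It treats each recording block ("data
segment") as a point in network space: for every frequency band and
oscillation metric, the segment is summarized by a *network vector* — the
pattern of spectral power across electrodes, or of functional connectivity
across electrode pairs — and all subsequent analyses operate on Pearson
correlations between these vectors ("network similarity"). The package
covers the full chain from signals to statistics: spectral feature
extraction, connectivity estimation, vector assembly and normalization,
representational-similarity aggregation with a resampling statistical
engine, and kNN-based classification of behavioral state and subject
identity.

## Sensor geometry

A montage is an ordered list of named sensors with 3D positions. All
distance computations first center positions on the sensor centroid and
scale them to unit mean radius, so neighbor thresholds are dimensionless
and independent of cap size. Channel pairs are enumerated row-major over
the strict upper triangle — for 60 channels, 1,770 pairs — and this
ordering is inherited by every connectivity vector and mask downstream.

Pairs of *neighboring* electrodes are excluded from connectivity vectors
to limit residual volume-conduction (spurious short-range coupling). The
packaged 60-channel reference cap is a standard extended 10-20 subset
(built at run time from the template positions shipped with mne); its
exclusion threshold is *calibrated* — set midway between the 192nd and
193rd smallest inter-sensor distances (≈ 0.629 at unit mean radius) — so
that exactly 192 pairs (11% of 1,770) are excluded and connectivity
vectors have the canonical length 1,578. A conventional fixed threshold
of 0.55 would excise a different number of pairs on this particular
template; since only the excluded *count* is meaningful for reproducing
vector lengths, calibration is the stable choice. Searchlight
neighborhoods use a wider threshold (default 0.65), giving sets of one
seed electrode plus its neighbors (mean set size ≈ 7.7, range 5-10 on the
reference cap) and all non-excluded pairs among them.

## Spectral features and connectivity

Bands default to theta (3-7 Hz), alpha (8-12 Hz), beta (13-30 Hz) and
gamma (32-60 Hz). Band-pass filtering uses windowed-sinc (Hamming) FIR
filters applied forward-backward (zero phase), with transition width
min(2 Hz, 25% of bandwidth) so adjacent pass-bands overlap minimally;
one filter length at each segment edge is flagged and trimmed before
phase/amplitude analysis.

Per-channel band power is estimated with Welch's method (5-s Hamming
windows, 50% overlap); each PSD bin is transformed to dB as
10·log10(power) and dB values are averaged over bins whose center lies in
the band, edges inclusive. The dB-then-average order is deliberate and
fixed; it differs from averaging raw power first whenever the in-band
spectrum is non-flat. Instantaneous phase and amplitude come from the
Hilbert analytic signal of the band-passed data.

Connectivity is estimated per pair after splitting each segment's
phase/amplitude series into 10 equal fragments (floor division, trailing
remainder dropped), computing the metric within each fragment, and
averaging — which bounds the influence of outliers and accommodates
nonstationary phase relations. Metrics:

- **PLV** (phase locking value): |mean over samples of exp(i(φⱼ − φₖ))|,
  1 for a perfectly consistent phase relation at any lag.
- **AEC** (amplitude envelope correlation): Spearman rank correlation of
  the two Hilbert envelopes (envelopes are generally non-normal, so a
  rank metric is used).
- **wPLI** (weighted phase lag index): |mean Im S| / mean |Im S| with S
  the sample cross-spectrum; insensitive to zero-lag coupling. An
  exactly-real cross-spectrum is reported as 0 (with a tolerance guard
  against float noise).
- **oAEC** (orthogonalized envelope correlation): at each sample the
  component of one analytic signal parallel to the other is removed
  (residual envelope |Im(x_k · conj(x_j))| / |x_j|), the residual
  envelope is Spearman-correlated with the reference envelope, and the
  two directions are averaged. Note that this estimator is *attenuated*
  relative to the latent envelope correlation — the residual carries a
  |sin Δφ| factor — so it is used as a directional volume-conduction
  control, not as an unbiased effect-size estimate. A degenerate residual
  (signals identical up to real scale) is defined as 0.

wPLI and oAEC are flagged as control metrics; PLV and AEC are the primary
measures.

## Network vectors

Power networks V hold one dB value per electrode (length 60); connectivity
networks U hold one value per non-neighboring pair (length 1,578 on the
reference cap). Connectivity values are skewed, so before Pearson-based
similarity each U is (1) shifted by +1 so entries are positive (PLV maps
into [1,2], AEC into [0,2]; an exact 0 from the theoretical AEC = −1 edge
is nudged to 1e−12), (2) Box-Cox power transformed with a per-vector
exponent λ, and (3) z-scored. λ is selected on a grid over [−5, 5] in
steps of 0.01 by minimizing the standard deviation of the geometric-mean-
normalized transform (x^λ − 1)/(λ·GM^(λ−1)); this normalization makes SDs
comparable across λ and is equivalent to maximizing the Box-Cox profile
likelihood, whereas minimizing the raw transformed SD is ill-posed (it
degenerates as λ → −∞). Both modes are exposed; "normalized" is the
default, and the grid choice is cross-checked in the tests against an
independent maximum-likelihood optimizer. The transform is monotone, so
Spearman correlations between vectors are exactly invariant to it; power
vectors are approximately normal after the dB transform and are never
Box-Cox transformed.

To compare power and connectivity networks directly, power vectors can be
*expanded* to pair format: the entry for pair (j,k) is (Vⱼ + Vₖ)/2, with
neighbor pairs dropped. With all pairs retained this expansion provably
leaves Pearson similarity unchanged (each expanded vector is a linear map
of the original, and the centered cross-products are proportional); with
the 192-pair exclusion the agreement is near-exact (mean |Δ| well below
0.01 on simulated populations; worst-case single-pair deviations up to a
few times that at moderate similarity levels). Global power/connectivity
is the plain mean over (untransformed) vector elements.

## Similarity and resampling statistics

Network similarity is the Pearson correlation between two equally-indexed
vectors — invariant to overall scale and offset, hence a pure pattern
measure. All-pairs similarity matrices carry full label metadata, and
aggregation averages similarity over labeled pair categories (e.g. the 21
rest-rest pairs or 14 rest-task pairs within one subject's first
session).

Statistical evaluation resamples the observed quantity: a null
distribution is built by repeatedly drawing as many networks as entered
the observation (the observed networks stay eligible) and averaging the
pairwise similarities of the draw. If the number of distinct combinations
is at most 1,000, all are enumerated exactly once (e.g. C(8,2) = 28);
otherwise 1,000 Monte-Carlo draws are taken. The *baseline* is the null
mean. Observations are z-scored against the null; p-values are one-tailed
upper normal tails (every hypothesis is directional: observed similarity
exceeds baseline; a two-tailed option exists). Raw permutation p-values
use the (b+1)/(m+1) convention and are floored at 1/1001 with 1,000
iterations — the z-based values are preferred because they resolve
effects beyond that floor. Benjamini-Hochberg FDR is applied within
nested families (across subjects within one network type, or across
groups within one analysis), not across every comparison at once. A
one-sample t test of per-subject observed scores against the baseline
provides the group-level summary.

The canonical comparison schemes are: within-subject rest consistency,
within-subject task consistency, rest-task cross-state consistency
(always evaluated against a per-individual null that pairs random rest
networks with the subject's own task networks), and group-level
clustering by frequency band, by oscillation metric (with and without
power), and by behavioral state. The exact shuffling mechanics per scheme
are a design choice of this package: within-state schemes draw from the
pooled same-state networks with a null shared across subjects by default
(`null_scope="per_subject"` redraws the Monte-Carlo sample per subject;
the null construction is identical, and simulation shows the
family-level type-I rate is close to the nominal q either way, ~0.043 at
q = 0.05 under a true null), and clustering schemes draw from the pool
across all levels of the clustered factor while holding the remaining
factors fixed.

On calibration: under a complete null with independent p-values the BH
procedure rejects *at least one* hypothesis with probability exactly q
(Simes' identity), while the expected per-hypothesis rejection fraction
is below q. The package's calibration checks therefore target the
replicate-level any-rejection rate.

MDS embedding (metric SMACOF on 1 − R distances, fixed seed; nonmetric
optional) is provided for visualization only — statistics always operate
on full-dimensional vectors.

## Classification

Classifiers are kNN with k = 5 on correlation distance (1 − Pearson R),
with inverse-distance-weighted voting normalized over the k neighbors; a
zero-distance neighbor (duplicate up to affine scaling) wins outright,
and argmax ties break deterministically toward the first class in sorted
order. One classifier is trained per network type (band × metric).
Behavioral state (rest vs task) is classified leave-one-subject-out;
subject identity is classified across sessions (train on sessions A+B,
test on C; chance = 1/n_training_subjects, 4.8% for 21 identities).

Evidence combination follows three stages: *fusion* averages per-class
posteriors across classifiers ("class weights", which need not sum to 1);
*pooling* averages class weights across a subject's test segments,
separately for rest and task; the *merge* takes the per-class maximum of
the composite rest and task weights and assigns the argmax identity.
Performance is tested with exact binomial tails at the chance rate and
with permutation tests that re-train classifiers on shuffled training
labels ((b+1)/(m+1) convention).

Network-size analyses subsample elements (connections or electrodes) at
random, re-train and re-test at each size, repeat (default 10 times), and
t-test each size's accuracies against chance. The searchlight analysis
trains and tests fused local classifiers on each electrode's neighborhood
(members' power values plus the non-excluded connections among members)
and maps per-electrode identification accuracy. Note the default
protocol's 7:2 rest/task imbalance means raw state-classification
accuracy has a majority-vote baseline near 78%, not 50%; balanced designs
or the resampling tests should be used when a 50% reference is needed.

## Synthetic data

Raw recordings for this kind of study are not generally redistributable,
so the package ships two generators whose outputs have the statistical
structure the analyses assume; all parameters derive deterministically
from an integer seed.

**Signal level.** For each frequency band, latent band-limited sources
(band-passed white noise, unit variance) are projected to the sensors
through a mixing matrix composed of a group template plus
subject-specific, state-specific and session-specific perturbations
(scaled by `subject_effect`, `state_effect`, `session_drift`), on top of
1/f-shaped Gaussian background noise (`noise_level`) — oscillations
riding on arrhythmic background. Latent sources are keyed by (session,
block, band) only, *not* by subject: two subjects differ solely through
their mixing matrices, so zeroing the subject effect (and noise) makes
their recordings literally identical — a degeneracy the tests exploit.
The default protocol replicates a three-session longitudinal design of 20
blocks (session A: 7 rest + 2 task; B: 4 rest; C: 5 rest + 2 task).
Defaults are 200 Hz / 60 s segments for test speed; recording-scale
values (400 Hz, ~290 s) are a configuration change. The generator does
not model volume conduction, biophysical head geometry, or artifacts —
it emulates data *after* spatial filtering and cleaning, which is the
level the analysis pipeline consumes. Passing tests therefore validate
the analysis chain, not any claim about raw-EEG preprocessing.

**Vector level.** Network vectors are drawn directly from an additive
variance-components model: x = G(band,metric) + T(band,metric,state) +
S(subject,band,metric) + e with variances v_group, v_state, v_subject,
v_noise. The expected Pearson similarity of any pair relation is the
shared variance over the total variance — e.g. (v_group + v_subject +
v_state)/total for same-subject-same-state pairs — and
`expected_similarity` returns these closed forms, giving exact oracles
for recovery tests and calibration studies (e.g. v_group = v_subject =
v_noise = 1, v_state = 0 gives 2/3 within subject and 1/3 between).

## Numerical and design choices

- Pair order, λ grid, MC iteration count (1,000), argmax tie-breaks, and
  fragment remainder handling are all fixed and deterministic; every
  pipeline output records the config hash and seed.
- Degenerate inputs: zero-variance envelopes flag NaN (propagated as
  missing matrix entries and rejected at vector assembly); a zero-spread
  null or a constant network vector raises instead of silently producing
  0/0; constant vectors in kNN get maximal correlation distance with a
  warning, and vectors shorter than 2 elements fall back to scaled
  Euclidean distance (relevant only to single-electrode searchlights).
- Problem sizes in tests and the acceptance script (vector lengths
  40-600, 6-12 subjects, 500 calibration replicates) were chosen to keep
  Monte-Carlo error well inside the stated tolerances; the structural
  constants (1,770 / 192 / 1,578 / 28 / 20 / 4.8%) are exact.

## Known limitations

- The reference cap is a standard template, not any specific product
  cap; only the excluded-pair *count* (192), not the identity of the
  excluded pairs, is reproducible across caps.
- oAEC attenuation (above) means its magnitude is not comparable to AEC.
- The EDF path is read-only; segments are written to the package's plain
  text container.
- The pipeline's similarity caching is per-run; recomputation across
  separate processes is not cached.
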