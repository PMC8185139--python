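# Methods

## The model

Each sample is one 4 s EEG segment paired with its subject's eye-tracking
features, represented as an undirected 14-node graph: nodes 1–7 carry the
EEG features (channel-mean amplitude, STFT spectral entropy, mean pairwise
Pearson correlation, approximate/sample/permutation/wavelet entropy), nodes
8–14 the per-test total fixation durations.  A single binary adjacency is
shared by every sample graph: features are z-scored across the *training*
samples, their correlation matrix computed, and an edge placed where
|corr| > τ.  Sample graphs are stacked block-diagonally (no cross-graph
edges) and classified by a two-weight-matrix GCN with the renormalization
trick,

Ã = D̃^{−1/2}(Â + I)D̃^{−1/2},  Z = softmax(Ã·ReLU(Ã X W⁰) W¹),

whose spectral radius is ≤ 1 by construction (asserted numerically in the
tests).  Training minimizes the node-level cross-entropy over labeled
nodes; every node of a training graph inherits the graph's label.  At
inference, a graph is scored by the mean of its 14 node probability rows
(argmax; exact ties resolve to the lower class index).  This node-labeled
training / mean-pool readout pair is one of two defensible readings of a
node-level loss applied to graph classification; the alternative
(mean-pool before the loss) is available via `TrainConfig.pooling`.

The optimized objective is the cross-entropy *per labeled node* (the sum
divided by the number of labeled rows).  This leaves the minimizer
unchanged while making the gradient magnitude — and hence the usable
learning rate — independent of how many graphs are batched; with the raw
sum, full-batch descent at a fixed step diverges once a few thousand
graphs are stacked.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| segment length | 4 s, no overlap | resting-state convention for 256 Hz pediatric EEG; 1024 samples give stable entropy estimates |
| ApEn/SampEn | m = 2, r = 0.2·SD | the standard embedding/tolerance pair; relative r makes both statistics amplitude-invariant |
| SampEn degenerate counts | cap = ln((N−m)(N−m−1)/2) | when no template pairs match, −ln(A/B) is undefined; the cap (the largest finite value attainable with one match) keeps feature vectors finite and is configurable |
| permutation entropy | order 3, delay 1, ties by order of appearance | shortest order with non-trivial pattern set at this window length; normalized by log 3! to [0, 1] |
| wavelet entropy | db4, 5 levels, periodization mode | 5 dyadic bands + approximation span ≈0.5–45 Hz at 256 Hz; periodization keeps the filter bank exactly invertible and oracle-checkable |
| STFT entropy | 1 s Hann window, 0.5 s hop, complete frames only | 1 Hz frequency resolution; no zero-padding so the distribution has no boundary bins |
| channel reduction | mean over 8 channels (median selectable) | a node carries one scalar; averaging is the least-structured reduction |
| fixation validity | 60 ms minimum duration | shorter dwells are treated as unconscious gazing and discarded |
| random forest | 500 trees, impurity importance, keep all 7 | the ranking is reported, but the 14-node graph uses all seven eye features; `rf_keep_k` can filter |
| τ (edge threshold) | 0.3 on \|corr\| | the covariance threshold is the method's main free structural choice; `edge_density_table` prints density vs τ so users can match a target density. Absolute-value thresholding treats positively and negatively covarying features alike as related; `mode="signed"` gives the literal covariance-above-threshold reading |
| GCN | hidden 16, lr 0.01, momentum 0.9, 200 epochs, Glorot-uniform init | small widths suffice for 14 scalar-attribute nodes; full-batch descent keeps training exactly deterministic per seed |
| split | 8:2 stratified, segment unit | subject-level splitting (`split_unit="subject"`) keeps all of a subject's segments on one side and is the safer protocol for new studies (see Limitations) |
| t-test | Welch, two-sided, subject-level means | unequal group variances are the safe default; Student's pooled variant selectable |

## The synthetic cohort

Real recordings of this kind are clinical and not redistributable, so the
generator emulates the *statistical structure* the pipeline assumes, one
knob per feature family.  Per channel,

x_t = offset + A·sin(2π·10·t/f_s) + AR(1; φ) innovations,

where the AR innovations mix a channel-private and a cohort-shared
standard-normal driver at weight c (giving tunable inter-channel
correlation).  φ controls regularity (entropies), A the oscillatory share
(time-frequency entropies), the noise SD broadband complexity, the offset
the mean-value node, and c the synchronization node.  Fixation logs draw a
per-test total duration from Normal(mean, SD), split it into events of at
least 60 ms, and add Poisson-many sub-60 ms events that downstream
thresholding must remove.  Per-subject seeds are hashed from
(master seed, subject index), so extending a cohort never reshuffles
existing subjects.

The default group parameters are deliberately well separated — every
affected feature family differs by more than two pooled subject-level
SDs, with the clinical group less regular, noisier, less synchronized, and
fixating less on face/social stimuli — because the generator's role is a
strong-effect surrogate of a cohort that a multimodal classifier should
separate almost perfectly.  What the generator does **not** emulate:
volume conduction and realistic spectra (1/f background, band structure
beyond one oscillation), artifacts (the pipeline assumes artifact-free
in-band signals; the band-pass utility exists only for real EDF input),
saccade dynamics and AOI geometry, and between-subject parameter
heterogeneity within a group.  Passing tests therefore demonstrate that
the pipeline recovers group structure *of the assumed form* — not
clinical-grade performance on real recordings.

## Numerical and design choices

* **ApEn/SampEn conventions.**  ApEn includes self-matches
  (Φ^m over N−m+1 templates); SampEn excludes them and counts pairs over
  the first N−m templates for both m and m+1.  Both are computed in one
  O(n²) pairwise sweep (numba-jitted, with a pure-numpy fallback) since the
  (m+1)-pair set of the two statistics coincides.
* **Zero-variance inputs.**  Constant series: ApEn = SampEn = 0 (every
  template matches).  A zero-variance channel is an error in the
  correlation feature (named in the message); a zero-energy segment has
  spectral entropy 0 by convention.
* **Covariance is fitted on the training fold only**, as are the feature
  standardization and the random-forest ranking; refitting on all samples
  is available only behind an explicit, warning-emitting
  `allow_leakage=True`.
* **Two-layer wording vs two weight matrices.**  The forward model has two
  propagation steps and two weight matrices (one hidden representation);
  this is implemented as written above rather than as two *hidden* layers,
  which would need a third matrix.
* **Probability floors.**  log-of-zero in the loss is floored at the
  smallest positive double; loss values stay finite and ≥ 0.
* **Determinism.**  One seed governs split, forest, and weight
  initialization; two runs with equal (features, config, seed) produce
  identical metrics, traces and predictions (tested).

## Problem sizes used by the checks

The headline surrogate runs the full study geometry: 21 + 21 subjects,
8 channels × 360 s at 256 Hz → 90 segments/subject → 3 780 sample graphs,
with the mean held-out accuracy taken over ten split/training seeds.
Calibration checks use deliberately small cohorts (2–4 channels, 8–24 s
recordings, 8–10 subjects per group) so that 200 replicate null cohorts
and repeated pipeline runs stay cheap; the quantities they estimate
(type-I error of the per-feature t-tests, chance-level accuracy at zero
effect) do not depend on the study-scale geometry.  Null-accuracy checks
use subject-level splits: with segment-level splits a subject's constant
eye features appear on both sides, and a classifier can fingerprint
subjects instead of groups — a leakage mode users of segment-level
protocols should weigh (the default remains segment-level to mirror the
published protocol's apparent sample accounting).

## Known limitations

* The per-segment "sample" treats a subject's 90 segments as exchangeable;
  segment-level splits therefore share subjects across folds (see above).
* Eye features are constant within a subject, so at segment level the eye
  modality is 42 effective observations replicated 90×.
* The GCN input is one scalar per node; widening node attributes (e.g.,
  per-channel features as multi-dimensional attributes) is out of scope.
* Weighted or learned adjacencies, dropout, and deeper architectures are
  intentionally not provided.
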