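# Methods

This note documents the models and procedures `caldemix` implements, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not establish.

## The factorization model

A movie is a matrix `Y` of `d` pixels by `T` frames, modeled as
`Y = A C + B + E`. Footprints (columns of `A`) and traces (rows of `C`)
are nonnegative; `B` is the background; `E` is noise. For two-photon
data the background is low-rank, `B = b f` with a small rank `n_b`
(default 2). For one-photon microendoscopic data the integration volume
is much larger and a low-rank model underfits; instead each pixel's
background is a nonnegative combination of the component-subtracted
traces of the pixels on an annulus around it, `B = W (Y − A C)`, with the
annulus at twice the neuron radius and at most 32 regressors per pixel
(rows of `W` solved by nonnegative least squares).

Fitting alternates exact blockwise nonnegative coordinate updates
(hierarchical alternating least squares): traces given footprints,
footprints given traces (support-constrained to the current nonzero
support dilated by one pixel, so footprints can grow slowly without
losing locality), and the background factors warm-started from their
current values. Every update is an exact coordinate minimization, so the
Frobenius objective is non-increasing; the refinement loop verifies this
each iteration (tolerance `1e-8` relative plus `1e-8` absolute) and
aborts with diagnostics on violation. Background factors are refined by
warm-started HALS rather than a fresh factorization per iteration: a
re-initialized factorization could raise the objective, and warm-started
coordinate descent reaches the same stationary points monotonically.

## Movie storage

Patches are read from a pixel-major on-disk layout (`.pmap`): a 128-byte
header (magic, dims, dtype code) followed by the raw float32 array of
shape `(d, T)` in C order, so one pixel's full time series is one
contiguous byte range and reading a spatial patch touches only its
pixels' ranges. Pixel index is row-major over the field of view
(`p = row * cols + col`); coordinates are 0-based, ranges half-open.
Writes are chunked (frames spilled to per-chunk temporaries, then
concatenated), and the file bytes are independent of the chunk size.
Single precision is used on disk throughout.

## Batch pipeline

1. **Tiling.** The FOV is tiled with patches (default 48×48, overlap 8);
   stride is `patch − overlap` and the last patch of each axis is
   clamped at the border, so seams are exactly `overlap` pixels wide.
2. **Per-patch factorization.** Greedy initialization (below), then a
   few HALS iterations, then a quality filter using the spatial
   consistency and trace-SNR tests only. The footprint-shape test is
   deferred: a footprint clipped by a patch border is a legitimate half
   of a seam-straddling neuron, not a bad shape.
3. **Combination.** Footprints are embedded at their patch offsets and
   each pixel divided by the number of patches covering it, so signal in
   seam pixels is not counted twice. Groups of components with
   overlapping footprints and temporal correlation at or above the merge
   threshold (default 0.8, connected closure) are replaced by the
   nonnegative rank-1 pair minimizing `‖A_old C_old − a c'‖`, fit by 50
   alternating exact updates initialized from the largest-energy member.
   Patch backgrounds are compressed to rank `g_b` each (default 1,
   pass-through when already at that rank), embedded
   coverage-normalized, and compressed once more to rank `n_b` when the
   collected modes exceed it.
4. **Full-FOV refinement, then quality.** A HALS pass over the whole
   FOV runs *before* quality assessment; it repairs the seam artifacts
   (coverage-halved strips, clipped footprints) that would otherwise
   fail the tests. Footprint hygiene follows: each footprint keeps only
   the connected blob containing its peak — disconnected satellites are
   leftovers of neighboring sources.
5. **Quality filter, duplicates, final refit, deconvolution** (below).

Defaults are sized to desk-scale movies (64×64×1000 frames, ~20
neurons): 12 components per patch, merge threshold 0.8, 5 HALS
iterations per stage.

## Initialization

- **GreedyROI / RollingGreedyROI**: the movie minus its per-pixel 20th
  percentile (a crude background removal that keeps sparse activity
  nonnegative) is spatially smoothed with a Gaussian of half the neuron
  radius; components are seeded at successive maxima of the per-pixel
  variance (or its maximum over rolling windows, default 3 s with
  half-window stride) and fit by rank-1 NMF in a local square of side
  `4·width + 1` (10 alternating updates or relative change < 1e-4),
  their activity subtracted before the next seed. The smoothed residual
  is updated incrementally (smoothing is linear), so each seed costs one
  local factorization, not a re-smoothing pass.
- **GreedyCorr**: seeds at local maxima of the product of the
  correlation image and the peak-to-noise-ratio image exceeding both
  thresholds; no preset component count. The local-maximum neighborhood
  is `(2·width + 1)²`.
- **Seeded**: given masks, the temporal background is factorized from
  mask-free pixels first, then spatial background, traces, and
  mask-constrained footprints, with a short HALS polish.

The correlation image is each pixel's mean Pearson correlation with its
4- or 8-neighbors (border pixels use existing neighbors; zero-variance
pixels contribute 0). The max-correlation image takes the pointwise
maximum of per-batch correlation images (default 33 s batches), which
preserves briefly active neurons that the full-movie image dilutes.

## Quality assessment

Three per-component tests, with one shared baseline definition (running
percentile, block stride equal to the window with linear interpolation,
constant global percentile for traces shorter than the window; the
percentile level defaults to the one whose value matches the mode of a
Gaussian-kernel density estimate of the trace on ≤ 10⁴ subsampled
points, Silverman bandwidth):

- **Noise level** (for the z-score): the standard deviation of
  sub-baseline samples divided by `sqrt(1 − 2/π)` — the scale of the
  half-normal distribution those samples follow when transients are
  positive-only. When called standalone the split point is the running
  median: the half-normal formula assumes the split sits at the noise
  center, and the median estimate is much more stable than the
  density-mode percentile (spread below 1% versus ~4% on pure-noise
  traces).
- **Peak-SNR**: z-score the trace, convert frames to upper-tail
  probabilities `p(t) = Φ(−z(t))`, take the geometric mean over every
  full window of `N_s = ceil(0.4 s × frame rate)` frames, and return
  `−Φ⁻¹` of the smallest window probability. Computed in the log domain
  (`log_ndtr` / `ndtri_exp`), so it is exact where a direct product
  underflows; truncated windows at the trace end are skipped. Constant
  z-scores give SNR equal to that z exactly. Default acceptance
  threshold 2.
- **Spatial consistency**: around the top 5 local peaks of the trace
  (window 50 ms back, 300 ms forward; peaks during which a spatially
  overlapping component has z > 2 are skipped so a neighbor cannot
  vouch for this footprint), the data minus all *other* components and
  the background is averaged over time; the Pearson correlation of that
  average image with the footprint, both restricted to a box of side
  4× the footprint radius around its centroid, must exceed the
  threshold (module default 0.5; the batch pipeline uses 0.75). A trace
  with no local peak scores 0 with reason "no activity".
- **Shape score**: the default scorer is deterministic geometry on the
  footprint crop (thresholded at half max): the geometric mean of
  compactness `4πA/P²` and solidity, weighted by the largest connected
  piece's share, with a decisive soma-size gate — when the crop box is
  fixed at twice the expected neuron radius (the batch pipeline sets
  this from its initialization width), a mask filling more than ~30% of
  the crop is diffuse background and its score is driven to 0. A
  learned classifier (an MLP on downsampled crops, trained on synthetic
  somata versus noise/edge/fragment/streak/oversized-blob negatives,
  fully regenerated from a seed) can be passed instead; it is not the
  default because pixel-space models extrapolate unreliably to
  extracted footprints, whereas the size cue separates the observed
  failure mode — background-tracking components — decisively.
  Acceptance uses a low floor (default 0.1) plus an optional
  high-confidence override of a marginal SNR failure (off by default).

**Duplicates**: overlap `O_ij = |m_i ∩ m_j| / |m_j|` on binarized masks
(threshold 0.2 of each footprint's max); while any entry exceeds the
threshold (default 0.7), the lower-scoring member of the worst pair is
removed (ties keep the lower index). The survivors are pairwise below
threshold by construction.

## Deconvolution

Calcium dynamics are AR(1): `c_t = γ c_{t−1} + s_t` with spikes
`s_t ≥ 0`. The convex program `min ½‖y − c‖² + λ Σ s_t` subject to the
AR constraints is solved exactly by one left-to-right
pool-adjacent-violators sweep: each frame opens a pool and adjacent
pools merge while the inter-pool constraint (plus an optional hard
minimum spike size `s_min`) is violated; the L1 term is absorbed into
the data (`λ` enters as `y − λμ` with `μ_t = 1 − γ`, `μ_T = 1`). Pool
merging is strictly sequential, hence deterministic. Defaults: `λ = 0`
with `s_min` screening. AR(2) dynamics are out of scope.

When `γ` is unknown it is estimated as the lag-2/lag-1 autocovariance
ratio (exact for AR(1) observed in white noise), clipped to [0, 0.998]
and zeroed when the lag-1 autocovariance is within sampling noise of
zero; the noise level comes from the flat upper half of the Welch power
spectral density.

## Streaming pipeline

The state after `t` frames is the current `[A, b]`, the last trace
values, the sufficient statistics `stat_yc = Y[C; f]'/t` and
`stat_cc = [C; f][C; f]'/t`, a rolling buffer of the last `l_b` residual
frames (default `max(100, ceil(3.3 × frame rate))`), a partition of
components into non-overlapping groups (greedy graph coloring), and the
shape-update counters. Per frame:

1. **Traces**: block-coordinate descent over groups (members of a group
   have disjoint footprints, so their joint update is exact), two
   passes, background temporal values included.
2. **Detection**: the positive-part energy image of the buffer is
   high-pass filtered (minus a Gaussian blur at twice the neuron
   radius); up to `N_comp` local maxima at pairwise distance ≥ 2r are
   proposed. Each is screened on the mean residual crop — by Pearson
   correlation against a centered Gaussian soma template (threshold
   0.6) by default, or a supplied classifier — and by the buffer-trace
   peak-SNR (threshold 1.2) of its local rank-1 factorization. The 2r
   separation rule is also enforced against existing component peaks,
   with a cosine-overlap gate (0.3), so residual shells around an
   imperfect fit cannot spawn satellites. Accepted components join with
   zero past history; their buffer activity is subtracted from the
   residual buffer so the same transient is not re-proposed.
3. **Statistics**: rank-1 running-mean updates with the new frame.
4. **Shapes**: counters start logarithmically spaced in (1, 2]
   (`q_i = 2^(i/K)`) and decay by `0.5^(1/T_u)` per frame; components
   whose counter crosses 1 are updated (counter topped up by 1), which
   guarantees every footprint is refreshed at least once per `T_u`
   frames (default 200). On frames with additions no shapes update;
   instead the counters of overlapping neighbors are zeroed, forcing
   their update next frame. The update itself is the dictionary-learning
   step `a_i ← max(a_i + (stat_yc[:,i] − [A,b] stat_cc[:,i]) /
   stat_cc[i,i], 0)` on the dilated support; background spatial modes
   are refreshed by the same rule whenever any component is due.

Initialization is "bare" by default: background factorization plus two
greedy components on the first 200 frames; everything else is found
while streaming. Batch and mask-seeded initializations are available.
Additional epochs replay the movie with detection still enabled and
overwrite the recorded traces, back-filling components detected late.
Deconvolution is applied to the completed traces at the end of the run
rather than interleaved per frame; for a finished trace the two give the
same spike train and the streaming loop stays simple. A final duplicate
sweep (overlap 0.7, SNR as score) removes multiply-detected cells.
Inputs are assumed motion-corrected; no registration is applied per
frame.

## Registration across sessions

Footprints are binarized at 0.2 of their maximum. The distance between
two cells is `1 − J` (Jaccard) when at most the match threshold
(default 0.5), 0 when one mask contains the other (containment wins even
when `1 − J` exceeds the threshold — conservative annotations are
subsets of extracted footprints), and infinite otherwise. The Hungarian
method on this matrix (infinities as a large penalty) maximizes the
number of finite matches and, among those, minimizes the summed
distance; this is verified against exhaustive enumeration on small
instances. Alignment, when requested, is a rigid integer-pixel
translation from the cross-correlation peak of the session templates;
out-of-FOV pixels are dropped. Multi-session registration keeps a
running union: matched union members are replaced by the newer
footprints, unmatched new components appended, and per-session matching
lists map session indices to union indices. The transitivity index is
the fraction of 1→2→3 chains whose composition agrees with the direct
1→3 match; it is undefined (None) when no chains are composable.

## ΔF/F

`f_i = ‖a_i‖²(c_i + r_i)` (the residual trace `r_i = R'a_i/‖a_i‖²` can
be omitted), `f0_i = BASELINE(f_i + B'a_i)`,
`ΔF/F_i = (f_i − BASELINE(f_i)) / f0_i`, with the running-percentile
baseline described above (default window 100 s). The numerator's
baseline uses `f_i` alone while the denominator adds the background
projection, as specified; a non-positive `f0` anywhere raises an error
naming the component. The output is invariant to jointly scaling a
footprint by α and its trace by 1/α.

## Detection metrics

Precision/recall/F1 against reference footprints use registration
matching at Jaccard distance 0.7. SNR-stratified curves take aligned
per-pair SNRs (missing sides carry 0): the plain curves threshold one
side each; the AND variant requires both sides above threshold; the OR
variant counts a pair above threshold when either side is, *among pairs
with the reference (respectively detected) side present* — with that
denominator the chain AND ≤ plain ≤ OR holds provably at every
threshold, with equality at threshold 0, and the implementation asserts
it. (An OR denominator of all detected components, without the
threshold, admits counterexamples: many low-SNR false positives deflate
the OR precision below the plain one.)

## The synthetic generator

`generate_movie` draws from exactly the package's model: isotropic
Gaussian footprints with sigma = radius/2, truncated at 3×radius and
unit-normalized, centers rejection-sampled with minimum separation
2×radius (a capped retry budget fails loudly instead of clumping);
Bernoulli spikes at `spike_rate/frame_rate` per frame driving AR(1)
traces with per-spike jump `transient_amplitude`; background spatial
modes as unit-norm smoothed random surfaces with temporal modes that
drift ±5% around a resting level an order of magnitude above the noise
floor (neuropil dominates raw fluorescence); i.i.d. Gaussian noise.
With unit-norm footprints the per-transient trace-domain peak SNR is
`amplitude/noise_sigma`. Defaults define the study conditions used
throughout: 64×64 pixels, 1000 frames at 30 Hz, 20 neurons of radius 3,
0.5 Hz spiking, γ = 0.95, amplitude 10, background rank 2, noise 1.
An optional linear multiplicative decay flag emulates photobleaching
for detrending tests. `generate_sessions` draws per-session subsets of
a master pool (presence probability = the overlap fraction; 0 partitions
the pool, 1 includes everything), applies rigid integer shifts, and
returns the master-to-session correspondence table.

What the generator does *not* emulate: motion artifacts, overlapping
footprints beyond what the separation override allows, dendrites and
axons, signal-dependent (Poisson) noise, slow focal drift. Passing the
synthetic benchmarks therefore demonstrates correctness of the
algorithms under their own model assumptions, not performance on real
recordings; thresholds that are comfortable here (e.g., the 10-sigma
transient peaks) are optimistic relative to dim real data.

## Problem sizes and reproducibility

The end-to-end checks run on 64×64×1000-frame movies with 20 neurons
(the benchmark), with smaller movies (16×16 to 32×32) for the many
property tests; these sizes keep the whole suite and the acceptance
script in the minutes range on one CPU while leaving every pathway
(patches, seams, merging, detection, registration) exercised. All
randomness flows from explicit seeds: generators, factorization
initializations and the optional classifier training are deterministic
given the seed, and repeated runs produce identical result files.

## Known limitations

- The one-photon ring background solves one nonnegative least-squares
  problem per pixel; it is quadratic-ish in FOV size and intended for
  desk-scale movies.
- Patch processing is sequential (results are independent of order by
  construction); no cluster or GPU execution.
- Merging fits a single rank-1 component per group; a group that
  wrongly chains several distinct cells (very high merge thresholds
  avoid this) would lose them.
- The shape scorer's size gate assumes roughly soma-sized sources; it
  will reject legitimate large or elongated structures (dendrites are
  out of scope).
- AR(1) dynamics only; indicators with pronounced rise times (AR(2))
  are approximated by their decay.
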