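# Methods

This note documents the models and procedures implemented in
`precisionmap`, the parameters that matter, what the synthetic cohort
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Data model

All operations are indexed by *grayordinate* — a cortical surface vertex
(left or right hemisphere) or subcortical voxel — with 0-based indexing
throughout. A `GrayordinateSpace` carries per-grayordinate structure tags,
millimetre coordinates and a symmetric, irreflexive adjacency used by
every contiguity operation. When a space arrives without mesh adjacency
(the plain-text dialect, or CIFTI files without companion surfaces), a
symmetrized 6-nearest-neighbour graph on the coordinates stands in; k = 6
approximates the typical degree of a triangulated surface mesh.

CIFTI-2 matrices do not carry vertex coordinates (those live in separate
surface files), so both dialects write a JSON sidecar with the repetition
time, structure tags and coordinates; the CIFTI reader uses the sidecar
when present and otherwise synthesizes index-based placeholder coordinates.

## Motion handling

Framewise displacement sums absolute frame-to-frame translations plus
rotations converted to arc length on a 50 mm sphere (approximately the
cortex-to-head-centre distance); FD of the first frame is 0 by convention
(no predecessor). Censoring is three staged rules, applied in order:

1. FD > 0.2 mm (default) removes the frame;
2. any surviving run of fewer than 5 contiguous retained frames is
   removed (short segments between motion spikes carry spin-history and
   interpolation artifacts);
3. optionally, frames whose spatial BOLD s.d. deviates from the median by
   more than 3 × 1.4826 × MAD are removed. The median and MAD are taken
   over the frames still retained after stages 1–2; the constants are the
   standard normal-consistent choice. This stage runs last; the ordering
   between the outlier rule and the segment rule is a convention of this
   package.

Exact-duration sampling draws `round(minutes·60/TR)` retained frames
uniformly at random, so every participant's correlation matrix rests on
the same amount of data regardless of how much survived censoring.

Nuisance regression residualizes against intercept + 3 tissue-mean series
(whole brain, ventricles, white matter) + 6 rigid-body parameters + first
differences of those 9 + squares of all 18 — 37 columns; collinear columns
are dropped by a rank-revealing sweep rather than failing. Band-pass
filtering is a first-order Butterworth (9–80 mHz) applied forward and
backward (zero phase, squared magnitude response). Both operate on the
full contiguous series; censoring masks are applied later, when
correlations are formed, because zero-phase filtering needs contiguous
samples.

## Connectivity

Pearson correlations over retained frames only, accumulated in double
precision and stored single precision (a dense double matrix at full
grayordinate resolution is impractical). Block z-scoring standardizes
each structural block — within-left, within-right, inter-hemispheric,
within-subcortex, cortex–subcortex — with its own mean and s.d.,
compensating the lower subcortical SNR. The inter-hemispheric block is
kept separate so that every other block stays pure; a single convention
had to be chosen and this one preserves the within-hemisphere statistics
exactly. Distance exclusion zeroes connections under 30 mm before any
density ranking (short-range correlations are inflated by spatial
smoothing and would otherwise dominate sparse graphs). Density
thresholding keeps the top ⌊d% · n_pairs⌋ signed weights, ties broken by
index order for determinism; negative edges never reach the retained
percentiles at the densities used (0.3–3%, extended by 4–5% for combined
cortex+subcortex runs).

## Template matching

Templates: per-participant network seed maps (network mean series
correlated with every grayordinate), averaged across the template cohort,
z-scored *across grayordinates within each network's map*, support
= {z ≥ 1}. The per-map standardization is what makes the support ~15.9%
of grayordinates for an approximately Gaussian map (1 − Φ(1) = 0.1587).

Matching: each grayordinate's block-z-scored row is binarized at z ≥ 1
and compared with each binary template support by η² over the full
grayordinate vector, zeros included. Binarizing both sides and comparing
full-length makes the statistic support-size aware and deterministic; on
binary vectors η² has the closed form used by the vectorized
implementation (numerator ‖a−b‖²/2), which the test suite verifies
against a scalar brute-force evaluation to 1e-10. Disjoint supports in a
mostly-zero space score ≈ 0.48 by this formula — this is the "low mode"
of the OMNI histograms below, not 0. Ties in winner-take-all go to the
lowest palette index and are counted; empty binarized rows yield
unassigned, also counted.

## OMNI thresholds

Per participant and per network, the η² values across grayordinates are
binned into 10,000 fixed bins on [0, 1] (so bin indices are meaningful η²
values: bins 4,000–7,000 ⇔ η² 0.4–0.7), interpolated with a cubic spline,
and smoothed with a Savitzky–Golay filter (2,000-bin window, cubic
order — the order matches the spline and is a package choice). The
membership threshold is the valley of the bimodal shape: a sign change
(− to +) of the derivative inside the window.

Three numerical choices matter here and were made after observing failure
modes on spiky 10,000-bin histograms:

- the derivative is the Savitzky–Golay *analytic* derivative (`deriv=1`
  of the same local polynomial fit), not central differences of the
  filtered curve — central differences flicker sign at single-bin scale
  and report spurious "valleys" at the window edge;
- a sign change only qualifies as a valley if the smoothed curve carries
  real mass (> 1% of its maximum) on both sides of it, which rejects
  wiggles in the empty stretches of a unimodal histogram;
- among qualifying valleys the *deepest* is taken, not the first — a
  shoulder on the flank of the non-member mode can form a shallow local
  minimum well before the true inter-mode valley, and thresholding there
  admits entire non-member populations.

If no qualifying valley exists (unimodal distribution), the argmin of the
smoothed curve in the window is used and flagged `fallback_used`.

## Community-detection consensus

The map-equation optimizer itself is a backend contract: any callable
from a weighted edge list to a partition. The shipped reference backend —
connected components followed by weighted asynchronous label propagation
with a seeded, fixed node order — is deterministic and recovers planted
partitions (NMI ≥ 0.95 on a two-block benchmark); python-igraph's
`community_infomap` is wrapped as an optional adapter and serves as an
independent cross-check in the tests, never as the tested implementation.

Community naming is Jaccard-based with a priority order (default, visual,
somatomotor, frontoparietal, cingulo-opercular, dorsal attention before
the smaller systems): one pass in which each network is claimed by its
best-matching unassigned community (Jaccard ≥ 0.1), then leftover
communities take their overall best match ≥ 0.1, so several communities
may share a name (a network can split into pieces at sparse densities)
while a head-to-head contest is still resolved in favour of the higher
Jaccard. Communities under 0.1 everywhere stay unassigned. The consensus
keeps, per grayordinate, the label at the sparsest density where it was
nonzero. Cluster cleanup merges labeled contiguous components under 30
grayordinates into the adjacent network with the largest map-wide size,
one component per pass (smallest first); because every merge unions the
component with an adjacent same-label component, the component count
strictly decreases and termination is guaranteed. At group level,
networks of ≤ 400 grayordinates are relabeled unassigned.

## Atlases

Probability maps are assignment frequencies over the cohort; single-
assignment mode guarantees column sums ≤ 1, overlap mode allows up to K.
ROI sets take per-network connected components of {P ≥ 0.8} (0.75 is a
supported preset) of at least 30 grayordinates; components never cross
the cortex/subcortex structure boundary, and parcel ids are assigned
network-major then by descending size so outputs diff cleanly.
Integration zones threshold the cohort-mean overlap count at 2.2 networks
and keep components past the same size filter.

The cluster-size floors are stated for the full ~91k-grayordinate space;
at desk scale they are scaled in proportion (the test suite and
acceptance study use 5 at 1,500 grayordinates — 30 grayordinates there
would correspond to a cortical area ~60× larger than intended).

## Reliability

NMI between two label maps is normalized by the arithmetic mean of the
entropies (scikit-learn's convention) over grayordinates assigned in
*both* maps — unassigned is absence of evidence, not a community. The
split-half design maps each half of each participant's series
(interleaved frames by default), compares intra-participant NMI against
the null of all cross-participant half pairs, and tests the difference
with a one-tailed Welch t-test; Welch–Satterthwaite degrees of freedom
are reported. Brain–behavior vectors are edge-wise Pearson correlations
across participants; subset reliability resamples group 1 without
replacement at each size, correlates each subsample's vector against the
full group-2 reference, and fits y = y₀ + a(1 − e^(−bx)) by nonlinear
least squares (b constrained non-negative; a flat response is flagged
degenerate; the start point is derived from the data range).

## Synthetic cohort generator

The generator is the package's test oracle. It emulates, at desk scale,
the structure of a developmental resting-state cohort:

- **Space.** Cortical grayordinates on two mirrored 70 mm spherical caps,
  subcortical ones in a 25 mm central ball; 6-NN adjacency.
- **Networks.** K seed points spread by farthest-point sampling and
  relaxed by Lloyd iterations in a *mirror-symmetrized spherical
  embedding* (hemispheres folded by x → |x|, subcortex projected radially
  onto the sphere). Networks therefore come out bilateral and cross
  structures, as real large-scale networks do, and their sizes are
  roughly equal — without the relaxation, rim-adjacent seeds produce tiny
  networks whose fixed-fraction z ≥ 1 template supports badly overshoot
  their membership. Per participant, the seeds are jittered by an
  isotropic Gaussian (default σ = 3 mm) before the nearest-seed
  partition: topographic variability with a jitter-stable core.
- **Hubs.** Zones of radius 12 mm at 3-way corners of the partition
  (where three territories meet, mirroring the observation that
  integration zones sit at network intersections); inside a zone the
  member networks share weight 1/3 each. Three member networks is a
  deliberate ceiling: the mixing weight of an equal m-network hub bounds
  its correlation to any member's time series by 1/√m, and at m = 3 that
  bound (0.577) stays above the z ≥ 1 block cutoff of the study regime
  while the union row still yields member η² ≈ 0.64, clearly above the
  detected valleys; at m ≥ 4 both margins collapse into the valley.
- **Signals.** K latent series, white Gaussian draws band-limited to the
  9–80 mHz analysis band and then QR-orthogonalized: at a few hundred
  effective degrees of freedom, raw "independent" draws carry sample
  correlations of ±0.1–0.2 that leak systematic network-to-network
  coupling into every participant; orthogonalization enforces the
  declared independence in-sample (linear combinations stay inside the
  band). Each grayordinate mixes the latents through its membership
  weights scaled to unit norm — so the network-signal s.d. is 1
  everywhere and `snr` means the same signal-to-noise ratio at hubs as at
  one-hot grayordinates — plus white noise of s.d. 1/snr.
- **Motion.** A small Gaussian random walk (baseline step s.d. 0.02 mm
  per frame across the six parameters, keeping FD well under the 0.2 mm
  threshold) plus Bernoulli spikes of 1 mm in a random translation,
  guaranteeing censorable frames.
- **Behavior.** Scores are linear in chosen connectome edges plus
  Gaussian noise.

Default conditions — 20 participants per group, 1,500 grayordinates,
K = 8, SNR 4, σ = 3 mm, TR 0.8 s, 750 frames (10 min), three 3-network
hubs — are the desk-scale analogue of a short-scan developmental cohort
design and are what the acceptance study runs.

What the generator does **not** emulate: hemodynamic response convolution,
physiological noise and scanner drift, spatial autocorrelation of the
noise, graded (non-step) network boundaries, distance-dependent motion
artifacts, multi-site effects, and family structure. Consequently,
passing recovery tests show the *pipeline logic* is correct and
well-conditioned under the stated noise model; they do not certify
performance on real BOLD data, where boundary gradations and structured
noise make every margin thinner. Two places where this idealization is
visible: template-matching recovery at SNR 4 is essentially perfect
(accuracy ≈ 1.0), and split-half intra-participant NMI saturates near 1,
both far above what real cohorts show.

## Known limitations

- The subcortex is a single structure tag; real CIFTI spaces distinguish
  ~19 subcortical structures. Whether block z-scoring should split them
  further is unresolved and unmodelled.
- η² is computed on binarized patterns over the full grayordinate vector;
  computing it on continuous suprathreshold values, or over the support
  union only, are plausible alternative readings of the method and would
  shift the OMNI histogram shapes.
- The reference community backend is a stand-in contract implementation;
  scientific use should prefer the Infomap adapter.
- Probability-map split-half correlations at n = 20 per half sit at the
  ceiling set by binomial sampling noise (~0.94–0.98 depending on the
  draw); they converge toward 1 only with much larger groups.
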