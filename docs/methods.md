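# Methods

This note documents the models, defaults and numerical choices behind
`spikecl`, and what the synthetic-data experiments do and do not show.

## Synthetic spike trains

The generator emulates the standard structure of simulated extracellular
test signals: `K` units with distinct mean waveforms, independent
homogeneous Poisson firing, and additive i.i.d. Gaussian noise.

**Templates** are differences of two shifted Gaussians — a sharp negative
trough followed by a slower positive bump — peak-normalized to 1.  Unit
`u` of `K` gets a trough width interpolated over ~1.1–2.3 samples
(Gaussian sd; trough FWHM roughly 0.1–0.25 ms at the default 24 kHz),
with matching spread in the repolarization width, lag and amplitude, plus
a small seeded jitter.  These shapes guarantee a unique global extremum
(well-defined alignment) and distinct area ratios (PDAC separability);
templates whose zero-lag correlation reaches 0.99 are rejected as
indistinct.  The generator does not model electrode drift, bursting,
waveform variability within a unit, or correlated/colored noise — so
passing tests demonstrate correctness of the algorithms under the stated
noise model, not robustness to every property of in-vivo recordings.

**Events.**  Each unit fires as a Poisson process (default 5 Hz); the
merged per-channel stream is thinned so that consecutive events are at
least the refractory period (default 3 ms = 72 samples) apart.  Because
the refractory exceeds the 64-sample window, within-channel overlaps are
structurally excluded; the generator still counts near-coincident events
and warns if they exceed 1% of the total.

**SNR convention.**  `snr_db = 10 log10(P_spike / sigma^2)` where
`P_spike` is the mean squared template amplitude over the m-sample window
(averaged across units) and `sigma` the noise sd.  A power-ratio
definition was chosen over a peak-amplitude one because it makes the
1–8 dB sweep span the meaningful difficulty range for this detector: at
1 dB the trough is ~4x the noise sd (hard), at 8 dB ~9x (easy).  Under a
peak-amplitude convention (`20 log10(A_peak/sigma)`), 6 dB would mean a
trough only 2x the noise sd, for which the NEO statistic of any
realistically shaped spike (at most ~0.5 A^2 ~ 2 sigma^2) sits far below
the white-noise NEO tail over a multi-second record (~10 sigma^2), and
threshold detection is impossible for any template or scale factor.  The
`realized_snr_db` helper recomputes the achieved ratio from the generated
data for verification.

## Detection

`neo_transform` implements `psi(j) = S(j)^2 - S(j-1)S(j+1)` with the two
undefined boundary samples set to 0 (the operator cannot fire there,
matching a hardware buffer).  Before thresholding, `detect_spikes`
smooths `psi` with a Bartlett window (default 8 samples ~ the trough
width).  Smoothing is standard NEO practice and is essential under white
noise: the raw NEO tail crosses `8 sigma^2` roughly every 200 samples,
which at the default event rates would produce ~10 false alarms per true
spike; averaging ~4 effective samples pulls the noise tail below the
threshold while spike bumps, being several samples wide, survive.

The threshold is `gamma = c * sigma_hat^2` with
`sigma_hat = median(|S|)/0.6745` (MAD estimate, robust to the embedded
spikes) and default `c = 8`; `gamma` lives in squared-amplitude units,
consistent with the NEO output.  On an essentially noiseless record
(median |S| = 0) the estimator falls back to `1e-3 * RMS` so clean test
signals remain detectable; an identically zero signal is an error.

After a trigger, the alignment step searches the next `m` samples for the
maximum-|amplitude| sample (signed maximum optional) and cuts an
m-sample window with the extremum at `peak_position` (default `m/4`),
zero-padding at the recording edges (or raising, if padding is
disabled).  A post-trigger lockout (default `m` samples) yields one
detection per spike.  Multichannel processing applies the identical
per-channel pipeline and merges results in (peak time, channel) order —
a logical model of the round-robin hardware schedule, not a cycle-level
one.  Configs with more channels than `Mmax = floor(rc/rs)` are rejected
up front.

With these defaults the detector reaches (pooled over recordings)
sensitivity ≳ 0.95 at 6 dB and ~1.0 at 8 dB with false-alarm rates of
~0.01–0.04 per true spike; at 1 dB it is deliberately conservative and
misses weak spikes rather than flooding the classifier with noise.

## PDAC features

Indices are 0-based internally (the classical description is 1-based;
the index difference `imin - imax` is origin-invariant).  Arg-extrema
ties break to the first occurrence, like a sequential scan.  The
denominator is the *signed* difference `imin - imax`, following the
formula literally; features are therefore negative for min-before-max
spikes, which is irrelevant to clustering (a global sign flip of the
feature plane).  An `abs_denominator` switch provides the unsigned
variant.  A constant waveform (imin == imax) raises
`DegenerateWaveformError` instead of returning zeros, since silent zeros
would corrupt training.  The implementation is vectorized; its
equivalence to the literal one-sample-at-a-time accumulation is pinned by
an oracle test (the hardware-relevant property is that a single pass
suffices).

PCA (scikit-learn, full SVD) and a hand-written GHA (Sanger's rule,
learning rate `lr/(1+epoch)`, divergence guard at weight norm 10^3) serve
as baseline extractors on mean-centered aligned waveforms.

## Competitive learning

Defaults: `K = 2`, `eta = 2^-5`, single training pass (multi-epoch
optional for small sets), initial centers drawn uniformly without
replacement from the training vectors, ties in the winner competition
broken toward the smaller cluster index, no learning-rate decay, and no
dead-unit re-seeding.  Each winner update satisfies the exact contraction
`||C'-X||^2 = (1-eta)^2 ||C-X||^2`, and repeated presentation of a
constant input converges geometrically,
`C(n) = X - (1-eta)^n (X - C(0))` — both are pinned as tests.  A
distance-evaluation counter verifies the `K x presentations` cost
accounting that makes single-pass CL cheaper than iterative batch
clustering.

`shift_mode` reproduces the hardware datapath: operands are scaled by
`2^15`, rounded to integers, and the `eta` multiply becomes an arithmetic
right shift by 5 (flooring toward -inf, as two's-complement shifters do).
The result equals the float update exactly when the scaled difference is
divisible by `2^5` and is within one LSB (`2^-15`) otherwise.  The 16-bit
scale is a package choice, adequate for unit-normalized amplitudes.

**Adaptive K** starts from 2 random centers and appends the current
vector as a new center whenever its winning squared distance exceeds a
threshold (default heuristic: 9x the median winning distance over the
first 50 vectors, measured against the initial centers), capped at
`k_max = 8`; suppressed creations are logged, not fatal.

**Baselines.**  K-means is a hand-written batch Lloyd loop (it exposes
the per-iteration SSE history used by the monotonicity test, and is
cross-checked against scikit-learn's KMeans in the suite); FCM is the
standard alternating membership/center scheme (fuzzifier 2, crisp
memberships for points numerically on a center); OSORT is the simplified
waveform-domain variant: assign to the nearest running mean, create when
the distance exceeds a threshold, merge means that drift within it.  The
benchmark's OSORT threshold is data-driven —
`max(1.5 * q10, 0.05 * q95)` of subsampled pairwise squared waveform
distances — sitting above the within-unit (noise) spread (~2 m sigma^2)
and below the between-unit separation on both clean and noisy records.

## Evaluation

CSR uses the optimal cluster-to-class assignment
(`scipy.optimize.linear_sum_assignment`, maximize), so it is invariant to
any relabeling of the predicted clusters; a greedy mapping could
understate it.  Detections are matched to ground truth greedily by
increasing time difference, one-to-one, within `m/2` samples by default;
false alarms are reported separately and excluded from CSR (detection and
classification are separate error axes).  The robustness study repeats
CL training `R = 300` times with seeds `base_seed .. base_seed+R-1` on
one fixed feature set and reports the per-run CSR.

## Study conditions and problem sizes

The standard conditions used throughout the tests and the acceptance
script: 2 units, 10–20 s records at 24 kHz, 5 Hz per unit, SNR 1/4/6/8 dB,
`m = 64`.  Feature-space experiments use isotropic Gaussian clusters;
"moderate overlap" means a center separation of 3.5 sd (Bayes-optimal
CSR ~96%, matching the regime where CL's initialization robustness is
interesting).  Parameter-recovery checks use 10 sd separation.  These
sizes keep the full suite under a minute while leaving every measured
rate a few hundred events or more.

## Known limitations

- The absolute CSR values of published hardware evaluations depend on
  external labeled databases and simulators (with unstated SNR
  conventions) and are not reproduced here; only the qualitative
  relations (CL ~ K-means ~ FCM; PCA ≥ PDAC; high initialization
  robustness) are expected to transfer.
- Detection below ~4 dB (power convention) is conservative by design;
  sorting at 1 dB operates on the detected subset only.
- The multichannel path models scheduling logically; it does not emulate
  buffer occupancy, fixed-point word widths (beyond the shift update) or
  timing.
- OSORT here is the simplified core (nearest-mean assign/create/merge),
  not the full published heuristic set.
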