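# Methods

## Coding model

The encoder correlates a single-channel image with the eight 3×3 Kirsch
compass masks. The mask set is generated from the canonical East stencil
`[[-3,-3,5],[-3,0,5],[-3,-3,5]]` by repeated 45° counter-clockwise rotation
of the border ring, so it is closed under 45° rotation, every mask has
three +5 weights, five −3 weights and a zero centre (zero sum), and mask
`i+4` is the 180° rotation of mask `i`. Masks are applied as correlation
stencils (no flip); this choice is observable only through the direction
labels, which are documented so that "0° = East" is meaningful.

The eight responses are split into the two symmetric direction groups
(0°–135° and 180°–315°). Each group's four responses are thresholded
against the group mean with `S(x) = 1 iff x ≥ 0` — ties code as 1 — and
packed with bit `i` ↔ mask index `i` (binary strings are printed
most-significant-bit first). The comparison is evaluated as
`4·M_ji − Σ_i M_ji ≥ 0`, which is algebraically identical to
`M_ji − mean ≥ 0` and exact in float64 for 8-bit imagery (all intermediate
values are integers far below 2⁵³), so tie behaviour is deterministic.

Consequences used throughout the tests: a constant image codes `1111` in
both groups everywhere (all comparisons tie); codes are exactly invariant
under `a·I + b` with `a > 0`; and for any *one-dimensional* texture
(intensity a function of one projected coordinate) the group-2 code is the
bitwise complement of the group-1 code, because the 180°-rotated masks see
the negated gradient.

## Features

Border policy: by default only pixels with full 3×3 support are coded
(`crop`), so a 128×128 image yields 126×126 code maps; replicate padding
(`pad`) is available by configuration. Cropping avoids fabricating edge
responses; since histograms are raw counts, the slightly smaller edge
blocks are acceptable.

The block grid splits each side into `N` runs as evenly as possible, with
the shortfall assigned to the two outermost runs (126 px at `N = 8` gives
runs 15,16,…,16,15), keeping interior blocks at the nominal 16×16. Each
block contributes two histograms over the 14 informative codes (bins
ordered by decimal code value 1…14; codes 0 and 15 are skipped). Stacking
adds the two histograms element-wise (14 dims/block); concatenation lays
them side by side (28 dims/block). Stacking is the default: it halves the
feature length at equal block count and is the configuration under which
the 896-dimensional whole-image feature arises (64 blocks × 14 bins).
Histograms are raw counts; an optional flag L1-normalises the final
vector but defaults off.

## Baselines

LBP, CS-LBP and LDP share the block machinery with a single code map per
image and plain concatenation. The neighbour ring is 8-connected, counter-
clockwise from East, matching the mask direction order; bit `i` has weight
`2^i`. LBP sets a bit when `neighbour ≥ centre` (16384 dims at the default
grid); CS-LBP when a centre-symmetric pair differs by more than a threshold
`T` (strict inequality, default `T = 0`; 1024 dims); LDP sets bits on the
`k = 3` masks with largest absolute response, breaking rank ties toward the
lower mask index (16384 dims, 56 attainable codes of the 256-bin domain).
The CS-LBP threshold used in the comparison literature is not standardised;
0 is the default and configurable.

## Evaluation protocol

Leave-one-sample-out KNN: every sample is classified against all others.
`k` defaults to 1 — the standard choice in this comparison literature,
and free of vote ties; for `k > 1` a vote tie falls back to the nearest
neighbour's label. Distances: Euclidean (default) or χ² with an
ε-guarded denominator (`ε = 1e-10`), the canonical histogram distance.
Neighbour order uses a stable sort, so equal distances resolve by sample
index and the whole evaluation is deterministic.

Class-membership profiles use inverse-square-distance weights against
per-class centres. "Centre" is read as the class-mean feature vector (a
medoid option exists). The weight formula is undefined at distance zero;
in that limit all mass is assigned to the zero-distance class(es), split
equally.

## Noise models

Salt-and-pepper noise is parameterised by corruption density `p` (the
conventional toolkit reading of the sweep's 0–0.2 range, consistent with
density 0 being the identity): each pixel is independently replaced by 0
or 255 with equal probability. AWGN is parameterised by SNR in dB with
noise variance `mean(I²)/10^(SNR/10)` — signal power is the mean square
intensity of the clean image — and the output is clipped to [0, 255].
A 40 dB corruption is still applied (it is *approximately* the identity,
never treated as exactly so). Noise is applied after any resize/crop and
before feature extraction; all noise is seeded and reproducible.

## Synthetic data

The generator produces the texture structure the encoder is designed to
detect, so the pipeline is testable without external image databases:

* **oriented ramps** — a plane ramp rising along one of the 8 compass
  directions; every pixel shares the gradient, so the dominant-response
  mask equals the generated direction (used for mechanism-recovery tests);
* **oriented sawtooth gratings** — period 16 px, rising over 7/8 of each
  period and resetting sharply, so the slow gradient points along the
  generated direction on most pixels; random phase per image;
* **crossed gratings (plaids)** — the mean of two gratings; component
  gradients add vectorially, so the modal dominant direction is the
  bisector of the two orientations;
* **isotropic fields** — Gaussian-smoothed white noise with no dominant
  direction.

The default labeled set has 6 classes × 10 images at 128×128 (the working
resolution of the block configuration): gratings at 0°/45°/90°/135°, a
0°+90° plaid, and an isotropic field, with peak-to-peak contrast 160 and
additive Gaussian jitter σ = 2 before 8-bit quantisation. Within-class
variation comes from grating phase / field realisation and jitter. Every
image's parameters and seed are recorded in a manifest from which the
dataset regenerates bit-identically.

Why not six plain orientations: stacking adds the two group histograms,
and for 1-D textures the group-2 code is the complement of the group-1
code, so a texture and its 180° flip have *identical* stacked histograms —
orientation alone supports at most four stack-separable classes. Grating
frequency is also nearly invisible to the sign-based code (measured
class-mean separation far below within-class spread), so the extra classes
come from genuinely different texture families (plaid, isotropic) instead.

What the generator does not emulate: the spatial heterogeneity, curvature
and subject-identity structure of real face images. Passing tests
demonstrate that the implementation realises the coding model and that the
descriptor discriminates dominant-direction structure; they do not certify
recognition rates on face databases. In particular, the relative ranking
of descriptors under heavy impulse noise observed on faces need not
transfer to stationary gratings: on this synthetic set basic LBP's
16384-dimensional histograms remain at ceiling across the salt-and-pepper
grid, while the AWGN sweep does reproduce the stacked descriptor's
robustness advantage (its group-mean margins are an order of magnitude
wider than LBP's neighbour-centre margins relative to the local gradient,
e.g. LOSO accuracy 0.65 vs 0.37 at 12 dB in a low-contrast regime).

## Numerical and design choices

* Mask weights and direction assignment follow the standard Kirsch
  convention of the directional-pattern literature; the 0° mask has its
  +5 column on the right.
* `S(0) = 1`: ties are 1-bits, per the sign function's `x ≥ 0` branch.
* Integer-exact sign evaluation via `4M − ΣM` (see above).
* Block remainders go to the outermost runs, symmetrically.
* LDP rank ties break toward the lower mask index; KNN distance ties
  break toward the lower sample index (stable sort).
* Degenerate inputs: images smaller than 3×3, empty blocks, single-class
  datasets, `k ≥ n` and zero-power images for AWGN are rejected with
  explicit errors.
* Image size for sweep tests is reduced (64×64, 4 classes × 5 images)
  where only the harness mechanics are under test; the default 6×10 set
  at 128×128 is used where the claim concerns the study conditions.

## Known limitations

* The face-region cropping used in expression studies has no published
  geometry; the loader offers only a generic centre-crop fraction plus
  resize as a stand-in.
* Recognition rates on face databases are out of scope; all accuracy
  statements concern the synthetic generator's study conditions.
* The encoder is defined for single-channel 2-D images only; colour and
  multi-scale (5×5) mask variants are not implemented.
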