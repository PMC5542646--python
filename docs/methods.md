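# Methods

`salret` implements a content-based retrieval pipeline for grayscale
radiograph-like images. An image is represented by a fused descriptor that
combines a whole-image feature vector with a feature vector of its most
visually conspicuous region, and the collection is indexed both for exact
linear search and for sublinear approximate search with binary hash keys.
This note records the model, its assumptions, the tunable parameters and the
deliberate design choices.

## Preprocessing

Feature extraction expects a square input of side `T = 224`. An image of
width `w` and height `h` is rescaled by `S_f = T/h` if `h > w` else `T/w`
(bilinear interpolation), so the longer side lands exactly on `T`, and the
shorter axis is zero-padded symmetrically. Rescaled sizes are rounded
half-away-from-zero; an odd padding remainder goes to the trailing
(bottom/right) side. The square is replicated into three identical planes
and a per-pixel mean image, computed over the *indexed* collection only and
persisted with the index, is subtracted so queries are centered with the
same statistics. Padding pixels are exactly zero before mean subtraction;
after it they carry the negated mean values.

Assumptions: inputs are 8-bit grayscale (color inputs are reduced by
luminance); intensity windowing and histogram equalization are out of scope.

## Saliency

Saliency follows the graph-based (Markov-chain) construction. Five feature
channels are built at a working resolution of `r x r` (default `r = 32`):
the downsampled intensity and four gradient-orientation energies (0, 45,
90 and 135 degrees; squared directional derivatives of the downsampled
image). Each
channel map `M` is clamped to `M >= 1e-6` so log-ratios are defined, and a
fully connected directed graph is formed with edge weight

    w((i,j) -> (p,q)) = |log(M(i,j)/M(p,q))| * exp(-((i-p)^2+(j-q)^2)/(2 sigma^2)),

with `sigma = r/10` by default (configurable up to `r/5`). Row-normalising
the weights gives a Markov chain whose equilibrium distribution is the
activation map: nodes that differ from their spatial neighbourhood
accumulate mass. A second chain with edge weight into `(p,q)` proportional
to `A(p,q) * F(i-p, j-q)` concentrates the mass around strong activations.
Both equilibria are computed by power iteration from a uniform start vector
(L1 tolerance `1e-9`, cap 10,000 iterations; a single-precision warm-start
phase is used on large graphs, with final convergence always judged in
double precision). A constant (degenerate) channel has all-zero weights and
is assigned the uniform distribution: a featureless map has no salient
location.

Channel equilibria are averaged, upsampled bilinearly to image resolution
and affinely rescaled to [0, 1] (a constant map becomes 0.5 everywhere).
The salient region is `S >= tau` with `tau = mean(S)`; the masked image
(original pixels inside the region, zero outside) is cropped to the mask's
bounding box and preprocessed like a whole image before feature extraction.
A mask under 16 pixels falls back to the whole frame. Feeding the
full-frame masked image instead of the bounding-box crop is available
behind `crop_salient_to_bbox=False`; the crop is the default because it
preserves the region's scale for the fixed-size extractor.

Known limitation: the mass-concentration chain is not translation-invariant
near the grid border, so a uniform activation map acquires a mild center
bias (stationary mass is proportional to node degree, which is lower at the
border). This is inherent to the graph construction on a bounded grid and
is visible as a slight central preference on featureless images.

One concentration pass per channel is performed; running more passes
sharpens maps but did not change which location wins on the synthetic
benchmarks, so the minimal choice is kept.

## Feature extraction

Downstream code only requires a deterministic fixed-length vector per
preprocessed image, exposed as a registry of backbones keyed by id. The
built-in backbone partitions the `T x T` plane into `g x g` cells (default
4) and accumulates an `o`-bin (default 8) histogram of unsigned gradient
orientation weighted by gradient magnitude per cell, L2-normalised per cell,
giving `n = g*g*o = 128` dimensions. Gradients are central differences with
one-sided borders. A learned network's activation vector can be registered
under another id without touching the pipeline; the built-in backbone
exists so the whole system is testable without any trained model, and its
cell structure makes locality properties exactly checkable.

## Descriptor fusion and normalisation

The fused descriptor is `alpha * whole + beta * salient` with
`alpha + beta = 1`; defaults `alpha = 0.4`, `beta = 0.6`, exposing the
saliency influence as a user-tunable weight. Before hashing, descriptors
are min-max normalised into [0, 1] using a single global scalar minimum and
maximum fitted over the indexed descriptors (a per-dimension variant sits
behind the `normalization="per_dimension"` flag). Query-time values outside
the fitted range are clamped rather than rejected, since queries are not
part of the fitted set.

## Kernelized locality-sensitive hashing

`rho` anchor descriptors (default 300, clamped to the collection size) are
sampled without replacement; their RBF kernel matrix
`K(x,y) = exp(-gamma ||x-y||^2)` uses the median heuristic
`gamma = 1/median(||x-y||^2)` over anchor pairs unless a bandwidth is given.
`K` is double-centered (row means, column means, grand mean). Each of the
`b = 128` hash functions draws `t = 30` distinct anchor indices forming an
indicator vector `e_s` and uses the weight row `w = K^{-1/2} e_s`; a
descriptor `x` gets bit 1 iff `sum_i w(i) kappa(x, anchor_i) >= 0` (the sign
of zero is taken as 1 for determinism). All draws derive from one explicit
seed, so fit-plus-hash is reproducible from (data, config, seed).

`K^{-1/2}` is computed by symmetric eigendecomposition with eigenvalues at
or below `1e-12` *excluded* (a truncated pseudo-inverse). The centered
kernel always annihilates the all-ones direction, and inverting that null
space would amplify the constant component of `e_s` until every hash
function saturates to a constant bit; truncation keeps the inverse on the
retained eigenspace, where `K^{-1/2} K K^{-1/2}` acts as the identity, and
preserves locality sensitivity on rank-deficient kernels.

## Index and search

The index stores, per image: id, label, normalised descriptor and packed
hash key, together with the mean image, normaliser, hashing model and a
SHA-256 fingerprint of the configuration. Similarity between the
non-negative normalised descriptors is cosine, which lies in [0, 1];
identical descriptors score exactly 1 and a zero vector scores 0. Linear
queries score every record; ties break by ascending id for
reproducibility.

Hashed queries probe hash buckets in increasing Hamming radius from the
query key, stopping once at least `3k` candidates are gathered or the
radius cap (default 16) is passed, then rerank the candidates by cosine. A
cap of `b` or more disables the early stop and exhausts every bucket, which
makes the hashed ranking provably identical to the linear one — the
consistency anchor for the approximate search. The efficiency contract is
count-based (candidates examined versus index size), not wall-clock-based.

## Evaluation

Relevance is category-label equality. Precision is `N_R/(N_R+N_I)` over a
retrieved set, recall is `N_R/T_R` against all relevant records in the
index. Per-query PR curves use standard interpolated precision on the
recall grid {0.1, ..., 1.0} (at level `r`, the maximum precision over all
cutoffs achieving recall >= `r`; unreached levels score 0), macro-averaged
over queries; AUC is the trapezoidal integral over [0, 1] with the first
grid value extended to recall 0. Micro- versus macro-averaging is a
genuinely open choice; macro (per-query averaging) was picked so each query
counts equally regardless of category size.

The fusion-weight sweep recomputes fusion, normalisation and linear
retrieval per `(alpha, 1-alpha)` pair over cached code pairs, reporting
mean interpolated precision at recall 0.1 and mean precision@10. The noise
sweep corrupts queries only (salt-&-pepper flip probability, or zero-mean
Gaussian with a given variance, seeded and clamped to [0, 255]) with an
optional 3x3 median-filter denoising pass, and reports mean precision@10
per level; level 0 reproduces the clean baseline bit-exactly.

## Synthetic data generator

The generator emulates the gross statistics of a small radiograph archive:
eight parametric motif families (skull-like ellipse, ribcage bands, long
bone, hand, spine, knee, foot, shoulder) cycled over categories with
per-image parameter jitter; image sides drawn from [120, 512]; additive
Gaussian noise (sigma 6 intensity units); a random linear illumination
gradient (up to 20% relative slope); 50% horizontal flips. A fraction of
images (default prevalence 0.3) carries a planted anomaly recorded in a
binary mask: a bright calcification-like blob (a saturating plateau profile
with a sharp rim, placed on locally dark tissue) or a dark fracture-like
transverse gap across a rod. Motif amplitude and blob contrast are
calibrated so planted anomalies are conspicuous to the saliency stage and
categories are separable by the built-in descriptor — the generator is a
controlled test fixture, not a radiograph simulator.

Each image derives its RNG stream from `(dataset seed, image index)`, so
datasets are bit-reproducible and stable under any generation order.

What passing tests on this data do *not* show: robustness to anatomical
variability, modality physics (scatter, beam hardening), annotation noise,
or the semantic gap of real archives. The pipeline's behaviour on real
radiographs depends on substituting a descriptor backbone trained for that
domain.

## Numerical choices and degenerate inputs

- Rounding of rescaled sizes: half-away-from-zero (deterministic,
  symmetric).
- Feature-map clamp `1e-6`; cell-normalisation guard `1e-12`.
- Power iteration: uniform start, L1 tolerance `1e-9`, cap 10,000;
  non-convergence raises an error carrying the iteration count.
- Constant feature maps, constant saliency maps, all-zero descriptors and
  near-duplicate anchor sets all have defined, tested behaviour (uniform
  equilibrium, map value 0.5, similarity 0, finite hash weights
  respectively).
- A constant descriptor collection cannot be min-max normalised and is
  rejected.

## Problem sizes used in the validation suite

The test suite exercises the default operating point on a 500-image index
with 50 labeled queries, a 120-image anomaly benchmark with 24 blob-bearing
queries, and 100 planted-blob images for the localization check; the
acceptance script rebuilds a 160-image index with 32 queries. These sizes
give stable statistics for the rank and binomial tests while keeping the
suite quick to run end to end.
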