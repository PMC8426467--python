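# Methods

This note documents the models, conventions and numerical choices behind
`histotile`, in the order a tile flows through the pipeline. It records the
design decisions that were genuinely open, and what the synthetic fixtures
do and do not establish about behaviour on real slides.

## Tiles and dataset layout

The unit of processing is an 8-bit raster tile, grayscale `(H, W)` or RGB
`(H, W, 3)`. Datasets live on disk as `root/<class>/<patient>[/<roi>]/<tile>`;
the class is always the first directory level below the root. Alpha channels
are discarded on read; 16-bit inputs are rejected rather than rescaled,
because silent bit-depth coercion is lossy and ambiguous. PNG is the default
output format everywhere (lossless round-trip is asserted in tests); JPEG
output requires an explicit opt-in.

Every mutating operation writes a `histotile_manifest.json` beside its
output: operation name, parameters, the effective RNG seed, and one
`(source, action, destination)` entry per file touched. Seeds may be given
explicitly; when omitted, a time-derived seed is used and recorded, so any
run can be replayed.

Patient-level splitting assigns `floor(fraction · n_patients)` patients to
test and validation and the remainder to train. Floor-plus-remainder (rather
than rounding each split) guarantees the training set is never starved by
accumulated rounding; for the canonical 70/15/15 split of 20 patients this
gives 14/3/3.

## Patching

Patches are exact crops at top-left offsets `(row·stride_v, col·stride_h)`,
stride defaulting to the patch size (non-overlapping). Partial edge tiles
are dropped by default: classifier inputs must have consistent dimensions,
and padding would fabricate pixels. Overlapping grids are available by
passing a smaller stride. The grid origin is fixed at the image's top-left
pixel — no random offsets — so the patch set is a pure function of (image,
grid). Names carry 0-based grid coordinates (`_r<row>_c<col>`), making the
patch→source mapping injective and reassembly testable.

## Tissue thresholding

H&E background (whitespace) is bright, stained tissue dark, so *tissue is
the below-threshold class* in all three mask methods. This polarity is the
only reading consistent with bright-background staining; it is asserted,
not configurable.

* Fixed: `v < T`, default `T = 220` — typical H&E background sits above
  this; exposed as a flag for exploration.
* Otsu: integer threshold `t` maximising `ω₀ω₁(μ₀−μ₁)²` over all 256 splits
  `{v < t} / {v ≥ t}`, ties broken toward the lowest threshold
  (deterministic). Implemented with cumulative sums; tests compare it
  against a naive exhaustive scan and against scikit-image's partition.
  Constant images raise a degenerate-histogram error rather than returning
  an arbitrary threshold.
* Adaptive: `v < mean(block×block window) − offset`, defaults block 51,
  offset 10, computed with an edge-repeating reflective local mean. The
  defaults are conventional values for ~250 px tiles; the method, not the
  constants, is the contract.

Colour tiles are converted by Rec. 601 luma (0.299 R + 0.587 G + 0.114 B,
rounded half-up) before masking; thresholding operates on intensity, not
colour.

Coverage filtering keeps tiles with `coverage ≥ cutoff`: the survival rule
is inclusive at the boundary, so "cutoff 0.8" keeps a tile at exactly 0.8.
Removed tiles are deleted or relocated with their tree structure preserved,
and the per-tile (path, coverage, action) table is exportable as CSV.

## Class balancing

The 8 axis-aligned symmetries of the square are parameterised as an
optional horizontal mirror applied first, followed by a clockwise rotation
of 0/90/180/270° — any consistent convention generates the same 8-element
group, and the group laws (closure, unique inverses) are verified bit-exactly
in tests. The 7 non-identity elements are the augmentation alphabet; they
are exact pixel permutations, so no interpolation artefacts enter the
dataset. For symmetric inputs some of the 7 outputs coincide ("up to 7
unique images"); the planner does not attempt content deduplication for
such degenerate tiles.

Balancing modes: `to_min` removes surplus tiles down to the smallest class;
`to_max` augments up to the largest; `to_mean` targets the rounded mean,
reducing classes above it and augmenting those below (the symmetric
reading of "balance to the average"). Augmentation modes require the
one-eighth precondition — no class below `max/8`, boundary inclusive — which
bounds every deficit by 7× the class size. The planner then draws sources
in rounds of without-replacement sampling, consuming each source's
transforms from a per-source shuffled order, so a `(source, transform)` pair
can never repeat: the no-duplicate guarantee is structural, not checked
after the fact. Surplus tiles are relocated to a `Removed Images` directory
*beside* the dataset root (structure preserved) so that rescanning the root
never counts relocated tiles as a class; hard deletion is opt-in.

## Stain normalisation

Histogram matching remaps each channel monotonically so its cumulative
distribution matches a single target image's:
`m(v) = min{u : F_target(u) ≥ F_source(v)}` (min-inverse of the target CDF,
ties toward the smallest gray level). Channels are matched independently in
RGB; single-channel images are promoted to RGB by replication first. One
fixed target profile is used for a whole batch.

The sup-distance between a matched image's CDF and the target's is bounded
by the largest single-level probability mass in the source histogram —
matching cannot split the pixels of one input gray level across two output
levels. Self-matching is therefore exact for every occurring value, and
"distribution recovery" claims are only as strong as the histograms are
smooth. Matching corrects colour distributions, not content: when source
and target content differ strongly it can manufacture artefactual
whitespace. The package documents this failure mode and does not attempt to
suppress it.

## Augmentation

Emboss convolves each channel with `K = (1−α)·E + α·M(s)` where `E` is the
identity kernel and `M(s) = [[−1−s,−s,0],[−s,1,s],[0,s,1+s]]`; `s ≥ 0` is
the strength ("intensity") and `α ∈ [0,1]` the blend. `M(s)` sums to 1 for
every `s`, so constant regions — whitespace in particular — keep their mean
level, and constant images are exact fixed points. This kernel family
follows the common image-augmentation convention for emboss; since any
other kernel changes downstream pixel values, the kernel is exposed as
`emboss_kernel` and pinned by a hand-convolution test. All convolutions use
edge-repeating reflective padding, avoiding dark halos at tile borders that
would corrupt whitespace estimates. Outputs are clipped to [0, 255] after
every operator.

Six further operators (Gaussian blur, unsharp-mask sharpen, additive
Gaussian noise, affine contrast, pixel dropout, channel dropout) span the
usual catalogue categories; seeded operators are pure functions of (input,
parameters, seed). Pipelines derive per-step seeds from one master seed via
`SeedSequence` spawning, and directory runs derive per-file seeds, so batch
outputs are byte-reproducible and independent of file enumeration order.

## Evaluation layer

Immature stroma is the positive class throughout. A tile with probability
`p` is classified immature iff `p ≥ cutoff` (default 0.5 — the boundary is
inclusive). Tile labels are majority-voted to ROI level and ROI labels to
patient level; an exact tie at patient level is called mature. The tie
direction at ROI level is not independently specified by the aggregation
rule, so the same conservative direction is applied there by default and
exposed as a parameter. Ground truth above tile level is derived by the
same voting applied to tile truth labels; heterogeneous ROIs are voted, not
rejected, since annotated regions can genuinely contain mixed stroma.

Metrics with empty denominators return `None`, never 0 — a 0 would be a
plausible-looking lie. Confidence intervals are Clopper–Pearson exact
(beta quantiles); the exact method is conservative but well-defined at the
small patient counts this layer serves. ROC AUC is the rank-based
Mann–Whitney statistic with midranks for ties, equal to the pairwise
comparison probability (asserted against an O(n²) oracle). Fleiss' κ uses
the standard `(P̄ − P̄ₑ)/(1 − P̄ₑ)` with `None` when expected agreement is 1.
Reported tables round to 3 decimals; internal computation is full precision.

## Synthetic fixtures

The generators emulate just enough structure to exercise every code path:

* Fibre tiles: a unit-variance mix of oriented sinusoidal banding (three
  wavelengths: 6, 11, 17 px) and band-pass isotropic noise, weighted by a
  `coherence` parameter in [0, 1]; low-coherence tiles additionally get
  pale, oedema-like blobs. Fine Gaussian intensity noise (σ = 6 gray
  levels) and per-channel chroma noise (σ = 3) keep histograms smooth — as
  stained tissue's are — which is what makes histogram-matching recovery to
  sup-distance < 0.02 achievable at all. Textures are mapped into a
  pink/purple H&E-like palette (per-channel gains 0.72–0.82) chosen so a
  moderate stain shift cannot clip. A structure-tensor anisotropy statistic
  `(λ₁−λ₂)/(λ₁+λ₂)` recovers the requested orientation within ±5° at full
  coherence and cleanly separates the two regimes, giving end-to-end tests
  a recoverable class signal.
* Whitespace tiles: bright background (≥ 240) with a dark (≤ 120) blob of
  exactly `round(coverage·size²)` pixels, obtained by thresholding a smooth
  random field at its order statistic — measured coverage is exact up to
  that rounding.
* Stain shift: channel-wise affine `gain·v + bias`, clipped; dataset trees
  give each patient its own shift (gain 1 ± 0.08, bias ± 8), a deliberately
  moderate batch effect.
* Dataset trees: `class/patient/roi` layout, default 250 px tiles, mature
  patients drawn at coherence 0.85–1.0 and immature at 0.05–0.2.

What passing these tests shows: the pipeline's mechanics — masking
arithmetic, naming, voting, distribution matching, reproducibility — are
correct. What they do not show: performance on real H&E appearance. The
fixtures have no nuclei, no stain co-localisation structure, and
unrealistically clean class separation; any claim about classifier accuracy
on real slides is out of scope here.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run on deliberately small
problems — 10×10 to 250×250 px images, trees of tens of tiles, 50–200
randomised property cases — chosen so the full suite completes in seconds
while still covering every branch; all the guarantees checked (bit-exact
crops and permutations, oracle equality for Otsu and AUC, ≤ 1 gray level for
self-matching, < 0.02 CDF sup-distance for stain recovery) are
size-independent. Floating-point comparisons against independent oracles use
1e-12 absolute tolerance; image comparisons are exact unless a rounding step
is inherent, in which case ±1 gray level is allowed.

## Known limitations

* No whole-slide formats (.svs/.ndpi), magnification pyramids, or viewers.
* Histogram matching is per-channel RGB; stain-deconvolution methods
  (Reinhard, Macenko) are intentionally out of scope.
* The balancer equalises on disk before training; sampler- or loss-based
  balancing inside a training loop is not provided.
* `to_mean` reduces above-mean classes; users wanting augmentation-only
  balancing should use `to_max`.
* Partial-tile padding is not offered; edge content beyond the grid is
  simply not used.
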