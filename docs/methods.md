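# Methods

`histograph` turns a collection of histology fields of view into a
navigable similarity graph.  This note records the model, the defaults
and the numerical choices, and what the synthetic test bed does and
does not establish.

## Image representation

**Preprocessing.** Colour images are reduced to luminance with the
ITU-R BT.601 weights (0.299, 0.587, 0.114) and denoised with
Perona–Malik anisotropic diffusion: the explicit 4-neighbour scheme

    I ← I + γ Σ_d g(|∇_d I|) ∇_d I,   g(s) = exp(−(s/κ)²)

with Neumann (zero-flux) boundaries.  The scheme conserves total
intensity exactly, smooths where gradients are small relative to κ and
preserves edges where they are large.  Defaults on [0, 1] intensities:
10 iterations, κ = 0.1, γ = 0.2; γ is restricted to (0, 0.25] — the
stability range of the explicit update.

**Local descriptors.** SIFT-style gradient-orientation descriptors:
over a square support window (default 16 px) divided into an
n × n cell grid (default 4), each cell accumulates a histogram of
gradient orientations (default 8 hard-assigned bins, magnitude-weighted
and weighted by an isotropic Gaussian with σ = half the window).
Concatenation gives d = n²·8 = 128 dimensions at the defaults.
Descriptors are sampled on a dense grid (step 8 px) by default — bag-of-
features codebooks are conventionally trained on dense samples — with a
DoG interest-point mode available behind `sampling="interest_points"`.

*Normalisation.*  Each descriptor is L2-normalised, clipped at 0.2,
renormalised, then clipped once more.  The final clip trades exact unit
norm (vectors end at ‖v‖ ≤ 1, not = 1) for a hard guarantee that no bin
exceeds the clip threshold, which keeps a single dominant orientation
from carrying a whole descriptor even when only a few bins have mass.
Zero-gradient windows yield exact zero vectors and are **kept**: they
quantise deterministically to some word, and dropping them would
silently shift histogram mass between images of different uniformity.

**Codebook and encoding.** Up to 500 descriptors per image (uniform,
seeded, without replacement) train a k-means codebook; Lloyd's
algorithm with k-means++ initialisation, convergence when the largest
centroid shift is < 1e−6 or after 100 iterations.  Empty clusters are
reseeded to the point farthest from its assigned centre.  The
per-iteration inertia history is stored on the `Codebook` and is
guaranteed non-increasing.  Default k = 25 words, a size appropriate to
collections of a few hundred fields; larger, more heterogeneous
collections may warrant more.  Each image becomes the L1-normalised
histogram of nearest-word (Euclidean; ties to the lowest index)
assignments of its descriptors.  Relative frequencies rather than raw
counts make images of different sizes comparable; the raw descriptor
count is kept alongside for auditability.

## Similarity graph

Pairwise Euclidean distances between BoFs histograms are pruned to an
unweighted k-NN graph (default k_nn = 3, distinct from the codebook's
k).  Symmetrisation is by **union**: an edge exists when either
endpoint ranks the other in its top k_nn.  Union keeps sparse graphs
connected more often than mutual-kNN and yields between ⌈n·k_nn/2⌉ and
n·k_nn edges; distance ties are broken by ascending node index so the
graph is reproducible.

**Layout.** Fruchterman–Reingold: repulsion k²/d between all pairs,
attraction d²/k along edges, with spring length k = √(area/n) for unit
area.  Nodes start on a jittered circle (seeded), step sizes are capped
by a temperature cooled geometrically (×0.95) from 0.1 over 300
iterations.  The final configuration is recentred on (0.5, 0.5) and
uniformly rescaled only when it overflows the unit square, so relative
distances — e.g. the two-body equilibrium separation d = k — are
preserved whenever possible.  A single node sits at the centre;
isolated nodes are placed by repulsion alone.  Exported coordinates are
advisory: any downstream viewer may re-run its own layout.

## Feature ranking

For two disjoint groups of images (≥ 2 each), every word is scored by
the classic pooled-variance two-sample Student's t on its frequencies
(df = n_a + n_b − 2, two-sided p); Welch's variant is available behind
`equal_var=False`.  Words are listed by ascending p, ties broken by
descending |t| then ascending index.  Benjamini–Hochberg q-values are
computed and reported alongside but never used for ranking: the
mechanism is interactive exploration, not formal inference, so raw
p-values order the display.  Zero-pooled-variance words have no defined
t; they are flagged `degenerate` and pinned to p = 1 (equal constant
means) or p = 0 with t = ±∞ (unequal), so constant words can neither
dominate nor silently vanish.  Quartiles for the boxplot summaries use
the linear-interpolation (type-7) convention, stated in the ranking
file header.

**Refinement.** `subset_and_rebuild` restricts every histogram to the
selected word coordinates **without renormalising** — renormalisation
would let discarded noise words re-enter through the denominator — and
rebuilds distances and graph in the sub-space.  Restricting to all
words therefore reproduces the full graph exactly.

## Superpixel patches

Heterogeneous slides are decomposed with SLIC (k-means in joint
intensity–position space, grid-initialised), default 50 segments,
compactness 0.5 on [0, 1] intensities.  The achieved count can deviate
from the request by roughly ±25%: SLIC does not return exact counts,
and orphan regions smaller than 5% of the mean segment size are merged
into their largest neighbour.  The compactness default was chosen so
that both blob-like and strongly periodic textures keep near-nominal
segment counts; very low compactness lets intensity dominate and can
collapse periodic textures into a handful of stripes.  Patches are
bounding-box crops with out-of-mask pixels filled by the patch mean —
masking with a constant unrelated to the patch would manufacture strong
artificial edges at superpixel boundaries, which dense gradient
descriptors would then encode.

## Annotations

Per-image records hold an ordinal score (declared range, default 0–3:
none → extreme abnormality), a free-string label (e.g. epithelium /
stroma), a note and a timestamp.  Batch scoring updates only the score
field.  CSV export uses the fixed header `image_id,score,label,note,
timestamp` and round-trips losslessly, including unicode notes;
duplicate ids on import are an error naming the offending id.

## Synthetic test bed

The generator emulates the two canonical tissue-texture families at
desk scale rather than photorealistic H&E: *blobs* (random dark
ellipses, semi-axes ~8 px, ~2.5 motifs per 10⁴ px², on a light
background — epithelium-like nuclear texture) and *fibres* (oriented
quasi-periodic streaks, half-period 6 px, with mild along-fibre
modulation — stroma-like).  Contrast (default 0.8) and additive
Gaussian noise (default sd 0.05) control class separation.  Per-image
seeds are SHA-256 hashes of (master seed, class name, index) folded to
31 bits, so collections regenerate bitwise identically and image seeds
never collide in practice.

The standard study condition is 2 classes × 20 images at 256 × 256 —
small enough that the full pipeline over 20 master seeds completes in a
few minutes on one CPU — with the default pipeline (128-D dense
descriptors, 25 words, k_nn = 3).  Graph separation is quantified by
**neighbour purity**: the mean over (non-isolated) nodes of the
fraction of graph neighbours sharing the node's true class.

What passing shows: the full chain — diffusion, descriptors, codebook,
histograms, graph — preserves and exposes genuine texture differences,
and t-test word selection does not destroy (and typically sharpens)
that structure.  What it does not show: performance on real H&E, where
staining variability, artifacts, magnification differences and far
subtler phenotype gradations dominate; the synthetic classes are
cleanly separated by construction, so near-ceiling purity there is a
correctness check, not a performance claim.

The t-test calibration simulations use 20 images per group and 1000
words: the null setting (both groups from one distribution) checks the
empirical fraction of p < 0.05 against the nominal level, and the
planted setting (one word shifted by 2 pooled sd) checks that the
planted word tops the ranking in nearly all replicates.

## Degenerate inputs and tie-breaks (summary)

- grayscale of a 1-channel image: identity; 2-channel input: error.
- diffusion with n_iter = 0: the input object, unchanged.
- descriptor window with zero gradient: zero vector, kept.
- images smaller than the descriptor window: error (16 px minimum
  record size throughout).
- empty descriptor set: all-zero histogram with n_descriptors = 0.
- k-means ties / empty clusters: lowest-index assignment; farthest-point
  reseeding.
- k-NN distance ties: ascending node index.
- single-node layout: (0.5, 0.5); same seed ⇒ bitwise-identical coords.
- constant word under the t-test: flagged, p pinned as above.

## Known limitations

- Hard orientation binning (no trilinear interpolation) makes
  descriptors slightly less smooth under sub-pixel shifts than
  reference SIFT; the dense-grid setting and cell pooling absorb most
  of the difference.
- Gaussian weighting is applied at pixel resolution within the window
  but descriptors are computed at a single scale; no multi-scale
  pooling.
- SLIC segment counts are approximate by nature; requests below ~10 on
  strongly periodic images may still undershoot.
- The force-directed layout is a local minimiser; different seeds give
  different (equally valid) embeddings.
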