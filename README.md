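# histograph

Bag-of-features similarity graphs for histology image collections.

Annotating and comparing large collections of histology fields of view
slide-by-slide is slow and subjective.  `histograph` gives researchers
and pathologists a quantitative backbone for that work: it encodes each
image by the texture it contains, links similar images into a graph,
and lets the user ask *which* texture elements separate two groups of
images — so mis-annotations, phenotype gradients and tissue subtypes
become visible at the collection level instead of one image at a time.

## What it computes

1. **Representation.** Each image is converted to grayscale, denoised
   with Perona–Malik anisotropic diffusion, and covered with dense
   SIFT-style local descriptors: gradient-orientation histograms (8
   bins) over a 4 × 4 cell grid, i.e. 128 dimensions per descriptor.
   A visual codebook of k = 25 "words" is learned by k-means over
   descriptors sampled across the collection, and each image becomes
   the L1-normalised histogram **h** of nearest-word assignments — its
   bag-of-features (BoFs) vector.
2. **Similarity graph.** Euclidean distances ‖h_i − h_j‖ between BoFs
   vectors are pruned to an unweighted k-nearest-neighbour graph
   (k_nn = 3 by default; an edge exists when either endpoint ranks the
   other in its top k_nn), laid out with a seeded Fruchterman–Reingold
   force simulation and exported as GraphML or node-link JSON.
3. **Feature ranking.** For two user-chosen groups, every word w is
   scored by the pooled two-sample Student's t on its frequencies,

       t_w = (x̄_A − x̄_B) / (s_p · √(1/n_A + 1/n_B)),  df = n_A + n_B − 2,

   listed by ascending p, with per-group boxplot summaries and BH
   q-values for reference.  The graph can be rebuilt on the top-ranked
   words to sharpen group separation.
4. **Patches and annotations.** Heterogeneous slides can be split into
   ~50 SLIC superpixel patches analysed as images in their own right;
   ordinal scores (default 0–3), labels and notes attach to images,
   support batch annotation, and round-trip through CSV.

A seeded synthetic-texture generator (blob-rich "epithelium-like" vs
fibre-rich "stroma-like" classes with controllable contrast and noise)
makes every stage testable end to end without any dataset.

## Worked example

```python
from histograph import (PipelineConfig, GroupAssignment, generate_collection,
                        neighbor_purity, rank_words_ttest, run_pipeline,
                        subset_and_rebuild)

coll = generate_collection(10, master_seed=7, height=128, width=128)
res = run_pipeline(coll.images, PipelineConfig())
print(f"images: {len(coll.images)}  words: {res.codebook.k_words}  "
      f"edges: {res.graph.graph.number_of_edges()}  "
      f"purity: {neighbor_purity(res.graph, coll.truth):.3f}")

classes = sorted(set(coll.truth.values()))
groups = GroupAssignment(
    group_a=frozenset(i for i, c in coll.truth.items() if c == classes[0]),
    group_b=frozenset(i for i, c in coll.truth.items() if c == classes[1]))
ranking = rank_words_ttest(res.histograms, groups)
for e in ranking.entries[:3]:
    print(f"word {e.word_index:2d}  t = {e.t_statistic:+.2f}  p = {e.p_value:.2e}")

g10 = subset_and_rebuild(res.histograms, ranking.top(10), k_nn=3)
print(f"top-10-word purity: {neighbor_purity(g10, coll.truth):.3f}")
```

prints

```
images: 20  words: 25  edges: 43  purity: 1.000
word  6  t = -79.53  p = 2.22e-24
word  3  t = -67.66  p = 4.03e-23
word  0  t = -56.94  p = 8.85e-22
top-10-word purity: 1.000
```

Neighbour purity is the mean fraction of each node's graph neighbours
sharing its true class: 1.000 means every edge of the k-NN graph
connects images of the same texture class, both with all 25 words and
after restricting to the 10 most discriminative ones.  The huge |t|
values say several visual words have essentially disjoint frequency
ranges in the two classes.

The same stages are available as shell subcommands:

```
histograph simulate --classes blobs,fibres --n 20 --size 256 --seed 7 --out imgs/
histograph run      --images imgs/ --knn 3 --out out/
histograph select   --histograms out/histograms.csv --groups groups.csv \
                    --top 10 --out ranking.csv
histograph graph    --histograms out/histograms.csv --words 0,3,6 \
                    --knn 3 --out refined.graphml
```

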