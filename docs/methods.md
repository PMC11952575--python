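# Methods

## Problem setting

Input is (i) a transcript table — one row per detected molecule with gene
identity, (x, y[, z]) position in micrometers, and a phred-like quality
score — and (ii) a set of staining-derived nucleus (or cell) outlines keyed
by cell id. Optionally, a gene × cell-type mean-expression matrix stands in
for a matched scRNA-seq atlas. Output is a per-transcript record: a cell id,
a fragment id, or UNASSIGNED, plus the derived cell × gene count matrix.

Segmentation is treated as supervised link prediction. The supervision is
free: a transcript lying inside a nucleus almost certainly belongs to that
cell, and a transcript inside nucleus A almost certainly does not belong to
neighboring nucleus B. These overlap-derived positive/negative edge labels
train a model that is then asked the harder question — which cell do the
*cytoplasmic* (non-overlapping) transcripts belong to?

## Graph construction

Two node types. Transcript nodes carry a gene embedding; cell nodes carry
six standardized geometric descriptors of their outline (area, perimeter,
circularity 4πA/P², second-moment elongation, convexity A/A_hull, and
log1p of the number of transcripts inside). Edges:

- transcript–transcript: symmetric k-nearest neighbors (k = 5) under
  √(Δx²+Δy²+(z_scale·Δz)²), cut at 5 µm; exact distance ties break toward
  the smaller transcript id, so construction is order-independent.
- transcript–cell candidates: each transcript to its 4 nearest nuclei by
  centroid within 15 µm (its containing nucleus is always included). Each
  candidate edge stores both the centroid distance and the distance to the
  nucleus outline (zero inside). Labels: containing nucleus → positive;
  other nearby nuclei → negative for nucleus-overlapping transcripts;
  transcripts inside no nucleus contribute only unlabeled edges. A point on
  an outline counts as inside; a point inside several overlapping nuclei is
  ambiguous and left unlabeled.

Defaults are sized for Xenium-like densities and all config-exposed
(`graph:` section).

### Tiling

Large extents are split by recursive bisection along the longer axis at the
median transcript coordinate until each core tile holds at most
`tile_target` transcripts (adaptive to density, balanced by construction).
Cores are half-open rectangles that exactly partition the extent; each tile
is padded by a margin and nuclei intersecting the padded rectangle are
duplicated into the tile with features computed from the full polygon and
slide-wide interior counts. The default margin is
`(2+R)·tc_max_dist + (1+R)·tt_max_dist` (R = refinement iterations, below):
the complete scoring receptive field of any core transcript. Because
everything a core transcript's score depends on lives inside its padded
tile, stitching (keeping each transcript's record from its unique core
tile) reproduces the untiled result *exactly*, not approximately — this is
tested as an identity, not a tolerance.

## Gene embeddings

Reference mode: rows of log1p(mean expression across cell types) are
unit-L2-normalized and projected onto the top-d principal directions of the
(uncentered) gene × type matrix; uncentered SVD keeps orthogonal expression
patterns orthogonal in the embedding, and component signs are fixed by
making each direction's largest-magnitude loading positive, so the result
is fully deterministic. d defaults to min(16, number of types). Learned
mode: a trainable gene table initialized i.i.d. N(0, 1/d). Which mode the
published approach uses internally is not something we pin down; both are
first-class here and selectable.

## Network

Input projections map gene embeddings (transcripts) and geometric features
(cells) to a shared d_latent = 64 space. Each of the 2 layers runs two
multi-head (4 heads) attention passes with separate parameters:

1. transcripts ← neighboring transcripts (tt edges);
2. cells ← the transcripts overlapping their boundary.

Pass 2 deliberately uses only overlap edges, not all candidates: a 15 µm
candidate disc covers three to four cells, and aggregating it would make
every cell latent a type mixture (measured during development: it destroys
the expression-mismatch signal). The overlap set is derived from input
geometry, so it is equally available at inference.

Attention logits take the additive form
`leaky_relu(a_q·W_q h_dst + a_k·W_k h_src + w_d·dist)` per head; weights are
softmax-normalized over each destination's incoming edges (they are
nonnegative and sum to one per head — a tested invariant). Updates are
residual, `h ← h + relu(W_o · concat_heads)`, so a node with no incoming
edges of a type keeps its state exactly.

The whole network is plain float64 numpy on a small reverse-mode autodiff
(`linkseg.nn`), which makes training bit-reproducible for a fixed seed on
any platform; no accelerator or deep-learning framework is involved.

## Scoring head: calibrated evidence channels

A candidate edge's logit is the sum of four channels plus a global
intercept, squashed by one sigmoid:

| channel | definition | role |
| --- | --- | --- |
| latent dot | h_t·h_c / √d | learned expression compatibility / mismatch veto |
| margin | (outline dist of c − outline dist of t's nearest other candidate) / r_c | competitive geometry: is this the closest cell, and by how much |
| coherence | cosine(mean embedding of transcripts within 5 µm of t, mean embedding of c's nuclear transcripts) | local expression program vs cell program |
| absolute distance | outline dist / r_c | evidence that t belongs to *no* detected cell |

with r_c = √(area/π) the cell's equivalent radius, and learned nonnegative
scales (softplus) on the geometric channels.

Why this structure instead of a single jointly-trained score: the training
labels are linearly separable by the margin feature alone (nuclear positives
sit deep inside their cell, negatives far outside), so joint optimization
collapses onto margin, leaves the other scales near their initialization,
and the resulting boundary does not transfer to cytoplasmic edges — the
classic shortcut problem under label shift. Instead each channel is
calibrated by its own binary cross-entropy against the overlap labels, and
only the global intercept is trained on the (frozen) summed log-odds —
naive-Bayes-style stacking. The geometric channels are dimensionless (cell
radii), so their class-conditional distributions are nearly identical for
nuclear training edges and cytoplasmic inference edges, and the calibrated
boundary transfers. A mild ridge (`head_l2 = 0.01`) keeps the margin scale
finite on separable data. Division of labor in practice: margin ranks
candidates, the absolute-distance channel withholds transcripts of
undetected (nucleus-free) cells, and the dot/coherence channels veto
expression mismatches.

## Training

- Loss: per-channel BCE + stacked BCE for the intercept, positives weighted
  by `neg_per_pos` to undo the sampling-ratio intercept bias; negatives are
  resampled each epoch at 4 per positive; unlabeled edges never enter any
  loss.
- Optimizer: Adam, lr = 1e-2 (the desk-scale regime sees only ~50–100
  full-graph gradient steps, so the conventional 1e-3 cannot converge;
  scoring-head scalars get a further 10× because Adam's per-step
  displacement is ~lr regardless of gradient magnitude).
- 50 epochs; dropout 0.1 on node states during training only.
- Validation: a held-out 10% of tiles when several tiles exist, otherwise a
  held-out 10% of the single tile's labeled edges; the parameters of the
  best validation-AUROC epoch are returned.
- Every random choice (init, negative sampling, dropout, splits) flows from
  one seeded generator; two runs with the same seed produce bitwise
  identical loss curves and parameters (tested).

## Inference and refinement

Scores are computed for every candidate edge in eval mode. One refinement
iteration (R = 1 by default) then re-estimates each cell's expression
profile from its provisionally assigned transcripts (argmax ≥ 0.5) plus its
nuclear transcripts and rescores the coherence channel — the trained model
refining its own assignments. Assignment: each transcript takes its
highest-scoring candidate if that score ≥ 0.5 (the natural boundary for a
calibrated probability), exact ties breaking toward the smaller cell id.

Unassigned transcripts are grouped into **fragments**: connected components
of the graph joining unassigned transcripts within 5 µm whose model-latent
cosine similarity is ≥ 0.5, keeping components of ≥ 5 members. Fragments
are entities distinct from cells — they never absorb cell-assigned
transcripts and never merge with cells — and get deterministic ids ordered
by smallest member transcript id.

## Synthetic tissue

The simulator provides the ground truth every test is anchored on:

- **Geometry.** n_cells seed points (uniform with ≥ 4 µm separation) on a
  w × h patch; cell territories are Voronoi regions clipped to the extent
  (cells tile space and share boundaries, reproducing the
  adjacent-cell-ambiguity failure mode); nuclei are territories shrunk
  linearly by 0.5 toward their centroid. A floor(fraction × n) random
  subset of cells has no nucleus.
- **Expression.** Types are assigned uniformly; the reference gives each
  type a profile with a uniform positive background and 4 designated
  markers per type, boosted 10× in their own type and *zero* elsewhere.
  Exclusivity by construction is what makes the metric oracles exact:
  under ground-truth assignment PMP is identically 1 and the MECR of
  cross-type marker pairs identically 0, at any sequencing depth.
- **Molecules.** Per cell Poisson(60) transcripts; gene by the type
  profile; position uniform in the nucleus with probability 0.2 (the
  cytoplasm carries ~4× more molecules than the nucleus, as in tissue) and
  uniform in the cytoplasm otherwise; 5% of molecules are then displaced by
  a per-axis N(0, 2 µm) kick. The source cell is recorded before
  displacement.
- Defaults: 200 cells on 200 × 200 µm (≈ 200 µm² per cell, matching
  reported median iST cell areas), 60 genes, 5 types, z = 0.

What it does **not** emulate: irregular (non-convex) cell shapes, nuclear
texture, segmentation errors in the input outlines themselves, dropout,
doublets, panel-specific gene correlations, or 3D stacking (a slab mode
exists but defaults off). Passing tests therefore demonstrate the
machinery is correct and that the method beats a nearest-nucleus expansion
baseline *under these idealized conditions*; they do not certify
performance on any real slide.

## Evaluation

- **PMP** per cell: own-type marker counts over all marker counts
  (marker-only denominator); cells with no marker transcripts are excluded
  and reported.
- **Exclusive pairs**: all gene pairs with codetection rate < 1% in a
  pseudo-scRNA-seq sample drawn from the reference (Poisson counts at depth
  200 per cell, 100 cells per type); **MECR** per pair on segmented counts:
  cells detecting both over cells detecting either, undefined (and excluded
  from summaries) when no cell detects either.
- **Precision/recall/F1** against synthetic truth: predicted cells are
  matched to true cells greedily by largest transcript overlap; a
  transcript is a true positive iff its predicted cell matches its true
  cell. Precision is over model-assigned transcripts, recall over all
  transcripts (fragment members count as unrecovered). Greedy matching
  carries the classical 1/2-approximation guarantee and is exact on the
  diagonally-dominant overlap tables segmentation actually produces; both
  properties are tested against a brute-force matcher.
- **Baseline**: assign every transcript to the nucleus with the nearest
  outline within 15 µm — the nucleus-expansion heuristic. The model must
  beat it on both F1 and mean PMP, which it does by ~0.02–0.03 F1 and
  ~0.05 PMP on the standard conditions (computed, not asserted, by
  `scripts/acceptance.py`).
- Cell and fragment summaries (counts, medians) are computed after
  discarding objects with fewer than 5 transcripts.

## Numerical and degenerate-input choices

- Point-in-polygon uses shapely `covers`, so outline points count as
  inside.
- Zero-area polygons, < 3 distinct vertices, or self-intersections are
  rejected at read time with the offending cell ids.
- Cells with no overlapping transcripts keep a zero expression profile
  (neutral coherence 0) and their residual latent.
- Empty transcript tables, empty tiles, and graphs with no candidate edges
  all produce empty-but-valid outputs rather than errors.
- A transcript with a single candidate uses the candidate search radius as
  its phantom competitor in the margin feature.
- All randomness is `numpy.random.default_rng` from explicit seeds; there
  is no global-state RNG anywhere.

## Known limitations

- Nucleus-overlap labels are trusted as clean; contamination *inside*
  nuclei is not modeled or filtered.
- Transcripts of an undetected cell whose type matches a neighboring cell
  are indistinguishable from that neighbor's cytoplasm by any evidence this
  model sees; they are the dominant residual error class.
- The per-channel calibration assumes the geometric features are
  cell-size-scale-free; tissues with extreme within-slide cell-size
  gradients may violate this.
- Model transfer across gene panels is out of scope (the vocabulary is
  fixed at training time).
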