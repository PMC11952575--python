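# linkseg

Cell segmentation for imaging-based spatial transcriptomics (iST), framed as
**transcript-to-cell link prediction** on a heterogeneous graph.

Platforms such as Xenium, CosMx and MERFISH detect individual transcript
molecules at subcellular resolution, but deciding *which cell each molecule
belongs to* remains the hard step: cells overlap, transcripts diffuse between
cells, membrane staining is usually absent, and some cells lack a detectable
nucleus. Nucleus-only assignment is clean but discards the cytoplasmic
majority of molecules; naive nucleus expansion recovers them at the price of
heavy cross-cell contamination.

`linkseg` is for computational biologists who have a transcript point table
and staining-derived nucleus (or cell) outlines and want per-transcript cell
assignments plus a cell-by-gene count matrix, with the leftover molecules
organized into *fragments* rather than silently dropped.

## Method

Transcripts and cells are two node types of one graph. Transcript–transcript
edges connect spatial k-nearest neighbors; transcript–cell candidate edges
connect each transcript to its nearby nuclei. Edges from a transcript to the
nucleus that contains it are **positive** training labels, edges to other
nearby nuclei **negative**; transcripts inside no nucleus are unlabeled. A
multi-head graph attention network (written in numpy, with its own small
reverse-mode autodiff) embeds both node types; gene identities enter either
through an scRNA-seq-derived embedding (log1p profiles, row-normalized, PCA)
or a jointly learned gene table.

A candidate edge (t, c) is scored as

```
p(t→c) = σ( h_t·h_c/√d  −  s_m·margin(t,c)  +  s_sim·coherence(t,c)  −  s_a·dist(t,c)  +  b )
```

where `margin` is the outline distance of `c` minus the distance of `t`'s
nearest other candidate (in units of the cell's equivalent radius √(A/π)),
`coherence` is the cosine between the transcript's local expression profile
and the cell's nuclear profile, and `dist` is the absolute outline distance
in cell radii. Each channel is calibrated against the nucleus-overlap labels
independently (stacked binary cross-entropy), because the geometric channels
are scale-free and therefore transfer from nuclear training edges to
cytoplasmic edges at inference. Each transcript then takes its best-scoring
candidate if the probability clears 0.5; unassigned transcripts are grouped
into fragments — connected components gated on both spatial proximity and
latent-space similarity. Large slides are processed as rectangular tiles
whose padded margins cover the full scoring receptive field, so tiled and
untiled runs produce identical assignments.

Evaluation follows the field's marker-based statistics: **PMP** (positive
marker purity — of a cell's cell-type-marker molecules, the fraction
belonging to its own annotated type) and **MECR** (mutually exclusive
co-expression rate — for gene pairs essentially never co-expressed in a
matched single-cell reference, the fraction of segmented cells detecting
both among those detecting either). A bundled synthetic-tissue simulator
(Voronoi cell territories, interior nuclei, typed gene programs with
exclusive markers, Gaussian transcript diffusion, nucleus-free cells)
provides exact ground truth for precision/recall.

## Worked example

```python
import linkseg as ls
from linkseg.embeddings import reference_embedding
from linkseg.graph import GraphConfig, build_dataset
from linkseg.model import ModelConfig, train

tissue = ls.simulate(seed=0)            # 200 cells, 11,778 transcripts, 5 cell types
emb = reference_embedding(tissue.reference, d=5)
cfg = GraphConfig()
plan, graphs, stats = build_dataset(tissue.transcripts, tissue.nuclei, emb, cfg)
model = train(graphs, ModelConfig(seed=0), emb, cfg, stats)
result, report = ls.segment_dataset(tissue.transcripts, tissue.nuclei, model)

print(report["n_cell_assigned"], report["n_fragment"], report["n_unassigned"])
print(ls.assignment_prf(result, tissue.truth.true_assignment))
```

On this simulation the run prints

```
10838 758 182
(0.9146521498431445, 0.8416539310579045, 0.8766360099044924)
```

meaning 10,838 of 11,778 molecules were assigned to cells, 758 grouped
into fragments (largely the transcripts of the 10% of cells simulated
without a nucleus), and 182 left unassigned; transcript-level precision is
0.91, recall 0.84, F1 0.88. For comparison, assigning every molecule to the
nearest nucleus within 15 µm reaches F1 ≈ 0.85 with markedly lower marker
purity (mean PMP ≈ 0.89 vs ≈ 0.94 for the model).

The same pipeline is available from the shell:

```bash
linkseg simulate --out tissue/ --seed 0
linkseg train --transcripts tissue/transcripts.csv --boundaries tissue/nuclei.csv \
              --reference tissue/reference --out model.npz
linkseg segment --transcripts tissue/transcripts.csv --boundaries tissue/nuclei.csv \
                --model model.npz --out segmented/
linkseg benchmark --segmentation segmented/segmentation.csv \
                  --transcripts tissue/transcripts.csv \
                  --cell-types tissue/cell_types.csv --reference tissue/reference \
                  --truth tissue/truth.csv --out metrics.json
```

## Layout

- `src/linkseg/io.py` — readers/writers (transcripts, boundaries, reference
  matrices, segmentations, MatrixMarket count matrices)
- `src/linkseg/simulate.py` — ground-truthed synthetic tissue
- `src/linkseg/embeddings.py` — gene feature vectors
- `src/linkseg/graph.py` — heterogeneous graph construction and tiling
- `src/linkseg/nn.py` — minimal numpy autodiff + Adam
- `src/linkseg/model.py` — attention GNN, scoring head, training
- `src/linkseg/segment.py` — assignment, fragments, tile stitching
- `src/linkseg/metrics.py` — PMP, MECR, summaries, precision/recall
- `src/linkseg/cli.py` — `linkseg` command-line interface

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
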