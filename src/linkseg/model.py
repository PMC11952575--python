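"""Heterogeneous graph attention network for transcript-to-cell link scoring.

Two edge types carry messages with separate parameters: transcript nodes
attend over their spatial transcript neighbors, and cell nodes attend over
the transcripts overlapping their boundary (the staining-derived initial
assignment), so cell latents reflect their own expression rather than the
surrounding mixture. A residual update keeps nodes without incoming edges
unchanged.

The link score for a candidate edge is a sigmoid over summed evidence
channels, each calibrated against the nucleus-overlap labels on its own:
the latent dot product (learned expression compatibility), the competitive
distance margin (how much closer this cell's outline is than the nearest
competitor's, in cell radii), the neighborhood-vs-nuclear expression
coherence cosine, and the absolute outline distance in cell radii. The
geometric channels are scale-free, so a decision boundary calibrated on
nuclear training edges transfers to cytoplasmic distances at inference;
joint training of the scales is deliberately avoided because it collapses
onto whichever single feature separates the (nucleus-derived) training
labels and then fails off-distribution.

Training minimizes binary cross-entropy per channel plus a stacked loss
for the global intercept (nucleus-overlap positives vs nearby-nucleus
negatives, negatives subsampled per epoch), selecting the epoch with the
best held-out AUROC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .embeddings import GeneEmbedding
from .graph import FeatureStats, GraphConfig, HeteroGraph, NEGATIVE, POSITIVE
from .nn import Adam, Tensor, bce_with_logits, parameter

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1"


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Sized for CPU desk scale; all config-exposed. ``d_latent`` must be
    divisible by ``n_heads``.
    """

    d_latent: int = 64
    n_layers: int = 2
    n_heads: int = 4
    dropout: float = 0.1
    lr: float = 1e-2
    epochs: int = 50
    batch_tiles: int = 1
    neg_per_pos: int = 4
    val_fraction: float = 0.1
    aux_dot_weight: float = 1.0
    head_l2: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_latent % self.n_heads:
            raise ValueError("d_latent must be divisible by n_heads")
        if self.epochs < 1 or self.neg_per_pos < 1:
            raise ValueError("epochs and neg_per_pos must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def score_link(z_t: np.ndarray, z_c: np.ndarray) -> float:
    """Sigmoid of the dot product of two joint-space latents."""
    z_t = np.asarray(z_t, dtype=float)
    z_c = np.asarray(z_c, dtype=float)
    if z_t.shape != z_c.shape:
        raise ValueError("latent vectors must have equal length")
    return float(1.0 / (1.0 + np.exp(-float(z_t @ z_c))))


def attention_message_pass(
    h_dst: Tensor,
    h_src: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    dist: np.ndarray,
    params: dict[str, Tensor],
    n_heads: int,
    return_attention: bool = False,
):
    """One multi-head attention pass over a single edge type.

    Attention logits take the additive graph-attention form
    ``leaky_relu(a_q.Wq h_dst + a_k.Wk h_src + w_d dist)`` with per-head
    parameters; the destination- and source-side contributions collapse to
    per-node scalars, so per-edge work stays O(E x heads). Weights are
    softmax-normalized over each destination's incoming edges. The
    destination update is residual (``h + relu(W_o . concat_heads)``), so
    nodes without incoming edges of this type keep their state exactly.
    """
    n_dst, d = h_dst.shape
    dh = d // n_heads
    if len(src) == 0:
        out = h_dst + (Tensor(np.zeros((n_dst, d))) @ params["Wo"]).relu()
        return (out, np.empty((0, n_heads))) if return_attention else out
    # per-node attention scalars, one per head
    aq = ((h_dst @ params["Wq"]).reshape(n_dst, n_heads, dh) * params["a_q"]).sum(axis=2)
    ak = ((h_src @ params["Wk"]).reshape(-1, n_heads, dh) * params["a_k"]).sum(axis=2)
    v = (h_src @ params["Wv"]).reshape(-1, n_heads, dh)
    logits = (aq.gather(dst) + ak.gather(src) + Tensor(dist[:, None]) * params["wd"]).leaky_relu()
    alpha = logits.segment_softmax(dst, n_dst)
    msg = v.gather(src) * alpha.reshape(len(src), n_heads, 1)
    agg = msg.segment_sum(dst, n_dst).reshape(n_dst, d)
    out = h_dst + (agg @ params["Wo"]).relu()
    return (out, alpha.data.copy()) if return_attention else out


def _layer_param_names(prefix: str) -> list[str]:
    return [f"{prefix}_{n}" for n in ("Wq", "Wk", "Wv", "a_q", "a_k", "wd", "Wo")]


def init_params(
    cfg: ModelConfig, d_emb: int, n_gene: int, learn_embedding: bool, rng: np.random.Generator
) -> dict[str, Tensor]:
    d, h = cfg.d_latent, cfg.n_heads
    dh = d // h

    def mat(n_in, n_out):
        return parameter(rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)))

    p: dict[str, Tensor] = {
        "t_in_W": mat(d_emb, d),
        "t_in_b": parameter(np.zeros(d)),
        "c_in_W": mat(6, d),
        "c_in_b": parameter(np.zeros(d)),
        "score_m_raw": parameter(np.array(0.0)),
        "score_sim_raw": parameter(np.array(0.0)),
        "score_a_raw": parameter(np.array(0.0)),
        "score_b": parameter(np.array(0.0)),
        "score_b_m": parameter(np.array(0.0)),
        "score_b_sim": parameter(np.array(0.0)),
        "score_b_a": parameter(np.array(0.0)),
        "score_b_dot": parameter(np.array(0.0)),
    }
    for layer in range(cfg.n_layers):
        for et in ("tt", "tc"):
            prefix = f"{et}{layer}"
            p[f"{prefix}_Wq"] = mat(d, d)
            p[f"{prefix}_Wk"] = mat(d, d)
            p[f"{prefix}_Wv"] = mat(d, d)
            p[f"{prefix}_a_q"] = parameter(rng.normal(0.0, 1.0 / np.sqrt(dh), size=(h, dh)))
            p[f"{prefix}_a_k"] = parameter(rng.normal(0.0, 1.0 / np.sqrt(dh), size=(h, dh)))
            p[f"{prefix}_wd"] = parameter(np.zeros(h))
            p[f"{prefix}_Wo"] = mat(d, d)
    if learn_embedding:
        p["gene_emb"] = parameter(rng.normal(0.0, 1.0 / np.sqrt(d_emb), size=(n_gene, d_emb)))
    return p


def _layer_params(p: dict[str, Tensor], prefix: str) -> dict[str, Tensor]:
    return {n.split("_", 1)[1]: p[n] for n in _layer_param_names(prefix)}


def _forward(
    p: dict[str, Tensor],
    cfg: ModelConfig,
    graph: HeteroGraph,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Node latents (transcripts, cells) after all message-passing layers."""
    if "gene_emb" in p:
        if (graph.t_gene_idx < 0).any():
            raise TrainingError("graph contains genes absent from the trainable embedding")
        xt = p["gene_emb"].gather(graph.t_gene_idx)
    else:
        xt = Tensor(graph.t_feat)
    h_t = (xt @ p["t_in_W"] + p["t_in_b"]).relu()
    h_c = (Tensor(graph.c_feat) @ p["c_in_W"] + p["c_in_b"]).relu()

    def dropout(h: Tensor) -> Tensor:
        if not training or cfg.dropout <= 0.0:
            return h
        keep = 1.0 - cfg.dropout
        mask = (rng.random(h.shape) < keep) / keep
        return h * mask

    h_t, h_c = dropout(h_t), dropout(h_c)
    # cells listen to the transcripts that overlap their boundary (the
    # initial staining-derived assignment, known at inference as well), so
    # a cell latent reflects its own expression, not the whole
    # candidate neighborhood's mixture
    ov = np.nonzero(graph.tc_label == POSITIVE)[0]
    ov_t, ov_c, ov_d = graph.tc_t[ov], graph.tc_c[ov], graph.tc_dist[ov]
    for layer in range(cfg.n_layers):
        h_t = attention_message_pass(
            h_t, h_t, graph.tt_src, graph.tt_dst, graph.tt_dist,
            _layer_params(p, f"tt{layer}"), cfg.n_heads,
        )
        h_c = attention_message_pass(
            h_c, h_t, ov_t, ov_c, ov_d,
            _layer_params(p, f"tc{layer}"), cfg.n_heads,
        )
        if layer < cfg.n_layers - 1:
            h_t, h_c = dropout(h_t), dropout(h_c)
    return h_t, h_c


def edge_geometry(graph: HeteroGraph, max_dist: float) -> np.ndarray:
    """Per-candidate-edge scoring covariates.

    Column 0 is the competitive distance margin: the edge distance minus
    the transcript's distance to its nearest OTHER candidate cell, in
    units of the cell's equivalent radius sqrt(area/pi) (``max_dist``
    stands in for the missing competitor when a transcript has a single
    candidate). Being scale-free, its class-conditional distribution is
    the same for nucleus-overlap training edges and cytoplasmic inference
    edges, so a decision boundary calibrated on the former transfers.
    Column 1 is the expression coherence cosine from
    :func:`edge_coherence`. Column 2 is the absolute outline distance in
    cell radii: own-cell cytoplasm stays within roughly one radius of its
    nucleus outline, while the nearest foreign nucleus of a transcript from
    an undetected (nucleus-free) cell is farther — the evidence that lets
    such transcripts be left to fragment grouping.
    """
    e = len(graph.tc_t)
    out = np.zeros((e, 3))
    if e == 0:
        return out
    r = np.where(graph.c_radius > 0, graph.c_radius, 1.0)[graph.tc_c]
    d = graph.tc_pdist  # distance to the nucleus outline, like an expansion rule
    # nearest-other distance per transcript: min over its edges, or the
    # runner-up where this edge itself is the unique minimum
    df = pd.DataFrame({"t": graph.tc_t, "d": d})
    grp = df.groupby("t")["d"]
    min1 = grp.min()
    nsmall = grp.nsmallest(2).reset_index(level=0)
    min2 = nsmall.groupby("t")["d"].max()  # second smallest (== min when single edge)
    cnt = grp.size()
    m1 = min1[graph.tc_t].to_numpy()
    m2 = min2[graph.tc_t].to_numpy()
    single = (cnt[graph.tc_t] == 1).to_numpy()
    is_min = d <= m1
    other = np.where(is_min, m2, m1)
    other = np.where(single, max_dist, other)
    out[:, 0] = (d - other) / r
    out[:, 1] = edge_coherence(graph)
    out[:, 2] = d / r
    return out


def _unit_rows(x: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(x, axis=1)
    return x / np.where(nrm > 0, nrm, 1.0)[:, None]


def transcript_profiles(graph: HeteroGraph, radius: float = 5.0) -> np.ndarray:
    """Local expression profile per transcript: the mean gene embedding of
    the transcript and every transcript within ``radius`` micrometers (a
    full disc, not just the kNN, so the profile averages enough molecules
    to pin down the local expression program without crossing cells)."""
    from scipy.spatial import cKDTree

    n, _ = graph.t_feat.shape
    tree = cKDTree(graph.t_pos)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    tprof = graph.t_feat.copy()
    cnt = np.ones(n)
    if len(pairs):
        np.add.at(tprof, pairs[:, 0], graph.t_feat[pairs[:, 1]])
        np.add.at(tprof, pairs[:, 1], graph.t_feat[pairs[:, 0]])
        np.add.at(cnt, pairs[:, 0], 1.0)
        np.add.at(cnt, pairs[:, 1], 1.0)
    return tprof / cnt[:, None]


def cell_profiles(
    graph: HeteroGraph, extra_t: np.ndarray | None = None, extra_c: np.ndarray | None = None
) -> np.ndarray:
    """Expression profile per cell: mean gene embedding of its overlap
    (nuclear) transcripts, optionally extended with currently assigned
    transcripts during refinement. Cells with no contributing transcript
    keep the zero profile."""
    _, d = graph.t_feat.shape
    ov = graph.tc_label == POSITIVE
    cprof = np.zeros((graph.n_cells, d))
    ccnt = np.zeros(graph.n_cells)
    np.add.at(cprof, graph.tc_c[ov], graph.t_feat[graph.tc_t[ov]])
    np.add.at(ccnt, graph.tc_c[ov], 1.0)
    if extra_t is not None and len(extra_t):
        np.add.at(cprof, extra_c, graph.t_feat[extra_t])
        np.add.at(ccnt, extra_c, 1.0)
    return cprof / np.where(ccnt > 0, ccnt, 1.0)[:, None]


def edge_coherence(graph: HeteroGraph, radius: float = 5.0) -> np.ndarray:
    """Cosine similarity between a transcript's local expression profile and
    the candidate cell's nuclear profile, one value per candidate edge.

    Cells with no overlapping transcript get a zero profile and hence a
    neutral similarity of 0.
    """
    if len(graph.tc_t) == 0:
        return np.empty(0)
    tprof = transcript_profiles(graph, radius)
    cprof = cell_profiles(graph)
    return np.einsum(
        "ij,ij->i", _unit_rows(tprof)[graph.tc_t], _unit_rows(cprof)[graph.tc_c]
    )


def _edge_logits(
    p: dict[str, Tensor], cfg: ModelConfig, h_t: Tensor, h_c: Tensor,
    tc_t: np.ndarray, tc_c: np.ndarray, geom: np.ndarray,
    return_dot: bool = False,
):
    """Edge logit = latent dot product + calibrated edge covariates.

    The dot product carries learned expression compatibility; the
    covariates are the competitive distance margin and the
    neighborhood-vs-nuclear-profile coherence, each with a learned
    nonnegative scale.
    """
    dot = (h_t.gather(tc_t) * h_c.gather(tc_c)).sum(axis=1) * (1.0 / np.sqrt(cfg.d_latent))
    s_m = p["score_m_raw"].softplus()
    s_sim = p["score_sim_raw"].softplus()
    s_a = p["score_a_raw"].softplus()
    logits = (
        dot + p["score_b_dot"]
        + s_m * Tensor(-geom[:, 0]) + p["score_b_m"]
        + s_sim * Tensor(geom[:, 1]) + p["score_b_sim"]
        + s_a * Tensor(-geom[:, 2]) + p["score_b_a"]
        + p["score_b"]
    )
    return (logits, dot) if return_dot else logits


@dataclass
class TrainedModel:
    """Learned parameters plus everything needed to rebuild graphs."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    graph_config: GraphConfig
    feat_stats: FeatureStats
    embedding: GeneEmbedding
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    version: str = MODEL_FORMAT_VERSION

    @property
    def genes(self) -> list[str]:
        return list(self.embedding.genes)

    def _tensors(self) -> dict[str, Tensor]:
        return {k: Tensor(v) for k, v in self.params.items()}

    def latents(self, graph: HeteroGraph) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic (eval-mode) transcript and cell latents."""
        self._check_vocabulary(graph)
        h_t, h_c = _forward(self._tensors(), self.config, graph, training=False)
        out = (h_t.data, h_c.data)
        h_t.release(); h_c.release()
        return out

    def _check_vocabulary(self, graph: HeteroGraph) -> None:
        if (graph.t_gene_idx < 0).any() and "gene_emb" in self.params:
            raise TrainingError("graph was built with genes outside the model vocabulary")

    def predict(self, graph: HeteroGraph, refine_iters: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(tc edge probabilities, transcript latents) in eval mode.

        With ``refine_iters`` > 0 (default: the graph config's value), cell
        expression profiles are re-estimated from provisionally assigned
        transcripts and the coherence channel rescored — the model refining
        its own transcript-to-cell assignments.
        """
        self._check_vocabulary(graph)
        if refine_iters is None:
            refine_iters = self.graph_config.refine_iters
        p = self._tensors()
        h_t, h_c = _forward(p, self.config, graph, training=False)
        if len(graph.tc_t) == 0:
            h_t.release(); h_c.release()
            return np.empty(0), h_t.data
        geom = edge_geometry(graph, self.graph_config.tc_max_dist)
        logits = _edge_logits(p, self.config, h_t, h_c, graph.tc_t, graph.tc_c, geom)
        data = logits.data.copy()
        latents = h_t.data
        logits.release()
        if refine_iters > 0:
            s_sim = _softplus_scalar(float(self.params["score_sim_raw"]))
            dot_part = data - s_sim * geom[:, 1]
            tprof_u = _unit_rows(transcript_profiles(graph))
            for _ in range(refine_iters):
                sel_t, sel_c = _provisional_argmax(graph, data)
                cprof = cell_profiles(graph, extra_t=sel_t, extra_c=sel_c)
                cos = np.einsum(
                    "ij,ij->i", tprof_u[graph.tc_t], _unit_rows(cprof)[graph.tc_c]
                )
                data = dot_part + s_sim * cos
        return 1.0 / (1.0 + np.exp(-data)), latents

    def predict_scores(self, graph: HeteroGraph) -> np.ndarray:
        """Link probability for every tc edge of the graph (labeled or not)."""
        return self.predict(graph)[0]

    def save(self, path: str | Path) -> None:
        """Single-archive serialization (npz with a JSON metadata entry)."""
        from dataclasses import asdict

        meta = {
            "version": self.version,
            "config": asdict(self.config),
            "graph_config": asdict(self.graph_config),
            "feat_mean": self.feat_stats.mean.tolist(),
            "feat_std": self.feat_stats.std.tolist(),
            "genes": self.embedding.genes,
            "embedding_mode": self.embedding.mode,
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays["embedding_vectors"] = self.embedding.vectors
        arrays["history_loss"] = self.history.get("loss", pd.Series(dtype=float)).to_numpy()
        arrays["history_val_auroc"] = self.history.get("val_auroc", pd.Series(dtype=float)).to_numpy()
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            params = {k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")}
            emb_vec = z["embedding_vectors"]
            hist = pd.DataFrame({"loss": z["history_loss"], "val_auroc": z["history_val_auroc"]})
        if meta["version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta['version']}")
        emb = GeneEmbedding(genes=meta["genes"], vectors=emb_vec, mode=meta["embedding_mode"])
        return cls(
            params=params,
            config=ModelConfig(**meta["config"]),
            graph_config=GraphConfig(**meta["graph_config"]),
            feat_stats=FeatureStats(np.asarray(meta["feat_mean"]), np.asarray(meta["feat_std"])),
            embedding=emb,
            history=hist,
        )


def _softplus_scalar(x: float) -> float:
    return float(np.log1p(np.exp(-abs(x))) + max(x, 0.0))


def _provisional_argmax(graph: HeteroGraph, logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge indices of each transcript's best candidate with logit >= 0,
    ties toward the smaller cell id (matches the assignment rule)."""
    df = pd.DataFrame({
        "t": graph.tc_t,
        "cell": graph.cell_ids[graph.tc_c],
        "c": graph.tc_c,
        "s": logits,
    })
    best = df.sort_values(["t", "s", "cell"], ascending=[True, False, True]).drop_duplicates("t")
    best = best[best["s"] >= 0.0]
    return best["t"].to_numpy(), best["c"].to_numpy()


def _labeled_indices(graph: HeteroGraph) -> tuple[np.ndarray, np.ndarray]:
    return np.nonzero(graph.tc_label == POSITIVE)[0], np.nonzero(graph.tc_label == NEGATIVE)[0]


def train(
    graphs: list[HeteroGraph],
    cfg: ModelConfig,
    embedding: GeneEmbedding,
    graph_cfg: GraphConfig | None = None,
    feat_stats: FeatureStats | None = None,
) -> TrainedModel:
    """Fit the link-prediction network on labeled tile graphs.

    Positives are nucleus-overlap edges, negatives edges to other nearby
    nuclei; negatives are subsampled to ``neg_per_pos`` per positive each
    epoch and unlabeled edges never enter the loss. Validation is a
    held-out tile fraction when several tiles exist, otherwise a held-out
    10% of the single tile's labeled edges; the parameters of the best
    validation-AUROC epoch are returned. Fully deterministic under
    ``cfg.seed``.
    """
    graph_cfg = graph_cfg or GraphConfig()
    feat_stats = feat_stats or FeatureStats(np.zeros(6), np.ones(6))
    n_pos_total = sum(int((g.tc_label == POSITIVE).sum()) for g in graphs)
    if n_pos_total == 0:
        raise TrainingError(
            "no positive transcript-cell edges: check that nuclei overlap transcripts "
            "(boundary kind, coordinate units) before training"
        )
    rng = np.random.default_rng(cfg.seed)
    params = init_params(
        cfg, d_emb=embedding.d, n_gene=len(embedding.genes),
        learn_embedding=embedding.mode == "learned", rng=rng,
    )
    if embedding.mode == "learned":
        params["gene_emb"].data[...] = embedding.vectors

    # --- train/validation split -------------------------------------------
    labeled = [_labeled_indices(g) for g in graphs]
    if len(graphs) >= 2:
        n_val = max(1, int(round(cfg.val_fraction * len(graphs))))
        val_tiles = set(rng.choice(len(graphs), size=n_val, replace=False).tolist())
        train_sets = [
            (i, pos, neg) for i, (pos, neg) in enumerate(labeled) if i not in val_tiles
        ]
        val_sets = [(i, np.concatenate(labeled[i])) for i in sorted(val_tiles) if len(labeled[i][0])]
        if not any(len(pos) for _, pos, _ in train_sets):
            raise TrainingError("validation split left no positive edges for training")
    else:
        pos, neg = labeled[0]
        n_vp = max(1, int(round(cfg.val_fraction * len(pos))))
        n_vn = max(1, int(round(cfg.val_fraction * len(neg)))) if len(neg) else 0
        vp = rng.choice(pos, size=n_vp, replace=False)
        vn = rng.choice(neg, size=n_vn, replace=False) if n_vn else np.empty(0, np.int64)
        val_edges = np.concatenate([vp, vn])
        train_sets = [(0, np.setdiff1d(pos, vp), np.setdiff1d(neg, vn))]
        val_sets = [(0, val_edges)]

    geoms = [edge_geometry(g, graph_cfg.tc_max_dist) for g in graphs]
    # the scoring head is three scalars; let them calibrate fast so the
    # network capacity goes to the residual (expression-mismatch) signal
    head_lr = {
        k: 10 * cfg.lr
        for k in ("score_m_raw", "score_sim_raw", "score_a_raw", "score_b",
                  "score_b_m", "score_b_sim", "score_b_a", "score_b_dot")
    }
    opt = Adam(params, lr=cfg.lr, lr_overrides=head_lr)
    best = {"auroc": -np.inf, "params": None}
    history = []
    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for gi, pos, neg in train_sets:
            if len(pos) == 0:
                continue
            g = graphs[gi]
            n_neg = cfg.neg_per_pos * len(pos)
            if len(neg):
                sampled = rng.choice(neg, size=n_neg, replace=len(neg) < n_neg)
                sel = np.concatenate([pos, sampled])
                labels = np.concatenate([np.ones(len(pos)), np.zeros(n_neg)])
            else:
                sel, labels = pos, np.ones(len(pos))
            opt.zero_grad()
            h_t, h_c = _forward(params, cfg, g, training=True, rng=rng)
            geom = geoms[gi][sel]
            dot = (
                h_t.gather(g.tc_t[sel]) * h_c.gather(g.tc_c[sel])
            ).sum(axis=1) * (1.0 / np.sqrt(cfg.d_latent))
            pw = cfg.neg_per_pos
            # each evidence channel is calibrated on its own: jointly
            # trained scales collapse onto whichever single feature
            # separates the (nucleus-derived) training labels, which does
            # not transfer to cytoplasmic edges at inference
            ch_m = params["score_m_raw"].softplus() * Tensor(-geom[:, 0]) + params["score_b_m"]
            ch_sim = params["score_sim_raw"].softplus() * Tensor(geom[:, 1]) + params["score_b_sim"]
            ch_a = params["score_a_raw"].softplus() * Tensor(-geom[:, 2]) + params["score_b_a"]
            ch_dot = dot + params["score_b_dot"]
            loss = (
                bce_with_logits(ch_m, labels, pos_weight=pw)
                + bce_with_logits(ch_sim, labels, pos_weight=pw)
                + bce_with_logits(ch_a, labels, pos_weight=pw)
                + cfg.aux_dot_weight * bce_with_logits(ch_dot, labels, pos_weight=pw)
            )
            # the global intercept sees the combined log-odds with the
            # channels frozen (naive-Bayes style stacking)
            combined = Tensor(ch_m.data + ch_sim.data + ch_a.data + ch_dot.data) + params["score_b"]
            loss = loss + bce_with_logits(combined, labels, pos_weight=pw)
            if cfg.head_l2 > 0:
                # mild ridge: the margin channel alone separates the
                # training labels completely, so its scale would diverge
                s_m = params["score_m_raw"].softplus()
                s_sim = params["score_sim_raw"].softplus()
                s_a = params["score_a_raw"].softplus()
                loss = loss + cfg.head_l2 * (s_m * s_m + s_sim * s_sim + s_a * s_a)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1

        # validation AUROC in eval mode
        y_true, y_score = [], []
        for gi, edges in val_sets:
            g = graphs[gi]
            h_t, h_c = _forward(params, cfg, g, training=False)
            logits = _edge_logits(
                params, cfg, h_t, h_c, g.tc_t[edges], g.tc_c[edges], geoms[gi][edges]
            )
            y_true.append((g.tc_label[edges] == POSITIVE).astype(int))
            y_score.append(logits.data)
            logits.release()
        y_true = np.concatenate(y_true) if y_true else np.empty(0, int)
        y_score = np.concatenate(y_score) if y_score else np.empty(0)
        if len(np.unique(y_true)) == 2:
            auroc = float(roc_auc_score(y_true, y_score))
        else:
            auroc = float("nan")
        mean_loss = epoch_loss / max(n_batches, 1)
        history.append({"epoch": epoch, "loss": mean_loss, "val_auroc": auroc})
        if np.isnan(auroc) or auroc >= best["auroc"]:
            best = {"auroc": auroc, "params": {k: v.data.copy() for k, v in params.items()}}
        logger.debug("epoch %d loss %.4f val AUROC %.4f", epoch, mean_loss, auroc)

    return TrainedModel(
        params=best["params"],
        config=cfg,
        graph_config=graph_cfg,
        feat_stats=feat_stats,
        embedding=embedding,
        history=pd.DataFrame(history),
    )


def predict_scores(model: TrainedModel, graph: HeteroGraph) -> np.ndarray:
    """Module-level convenience wrapper around ``TrainedModel.predict_scores``."""
    return model.predict_scores(graph)
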