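"""Gene feature vectors for transcript nodes.

Genes can be represented either by a fixed embedding computed from an
scRNA-seq-style reference (log1p-transformed, row-normalized cell-type
profiles projected onto their principal directions) or by a randomly
initialized table intended to be trained jointly with the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ReferenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneEmbedding:
    genes: list[str]
    vectors: np.ndarray  # genes x d
    mode: str  # "reference" | "learned"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.genes):
            raise ValueError("vectors must be a (n_genes, d) matrix")
        if len(self.genes) and not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def rows(self, genes: np.ndarray, missing: str = "error") -> np.ndarray:
        """Feature rows for an array of gene names.

        ``missing='error'`` raises on unknown genes; ``missing='zero'``
        substitutes the zero vector.
        """
        idx = self.index()
        out = np.zeros((len(genes), self.d))
        for i, g in enumerate(genes):
            j = idx.get(g)
            if j is None:
                if missing == "zero":
                    continue
                raise KeyError(f"gene {g!r} absent from embedding vocabulary")
            out[i] = self.vectors[j]
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = [f"v{i + 1}" for i in range(self.d)]
        return pd.DataFrame(self.vectors, index=pd.Index(self.genes, name="gene"), columns=cols)


def reference_embedding(ref: ReferenceMatrix, d: int = 16) -> GeneEmbedding:
    """PCA embedding of log-transformed cell-type expression profiles.

    Each gene's profile across cell types is log1p-transformed and unit-L2
    normalized (all-zero genes keep the zero vector, with a warning), then
    projected onto the top-``d`` principal directions of the gene x type
    matrix itself (uncentered, so orthogonal expression patterns stay
    orthogonal in the embedding). Component signs are fixed by making each
    component's largest-magnitude loading positive, so the result is
    deterministic.
    """
    n_types = len(ref.cell_types)
    if d > n_types:
        raise ValueError(f"d={d} exceeds the number of cell types ({n_types})")
    X = np.log1p(np.asarray(ref.mean_expr, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    zero_rows = norms == 0
    if zero_rows.any():
        logger.warning("%d all-zero gene rows get the zero embedding", int(zero_rows.sum()))
    X = np.where(zero_rows[:, None], 0.0, X / np.where(zero_rows, 1.0, norms)[:, None])

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each principal direction positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = (U * S)[:, :d]
    return GeneEmbedding(genes=list(ref.genes), vectors=scores, mode="reference")


def reconstruct_from_embedding(ref: ReferenceMatrix, emb: GeneEmbedding) -> np.ndarray:
    """Reconstruction of the normalized log-profile matrix from a full-rank
    reference embedding; used to verify that projection loses nothing when
    d equals the number of cell types."""
    X = np.log1p(np.asarray(ref.mean_expr, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    X = np.where((norms == 0)[:, None], 0.0, X / np.where(norms == 0, 1.0, norms)[:, None])
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
    return emb.vectors @ Vt[: emb.d]


def learned_embedding_init(genes: list[str], d: int = 16, seed: int = 0) -> GeneEmbedding:
    """Trainable gene table initialized i.i.d. Gaussian(0, 1/d)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    vectors = rng.normal(0.0, 1.0 / np.sqrt(d), size=(len(genes), d))
    return GeneEmbedding(genes=list(genes), vectors=vectors, mode="learned")
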