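"""Compound-pathway association scores from node embeddings.

The score of pathway i for compound j is the weighted sum of cosine
similarities between the pathway's embedding vector and the vectors of the
compound's response-correlated genes (RCGs):

    s_ij = sum_{k in RCG(j)} w_k * cos(V_k, V_{i+n})

with w_k the gene's signed expression-response Pearson correlation.  Scores
rank pathways; they are not significance values, and a negative score means
lack of evidence, not negative association.  Empirical p-values come from a
pooled null of scores of k random gene sets of matched size: the observed
score's add-one fractional rank among the k*m null scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .chemosensitivity import RCGSet
from .embedding import DCAEmbedding, EmbeddingMatrix
from .network import GeneNetwork, PathwayCollection, build_heterogeneous_network

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "PACER",
    "gene_pathway_cosines",
    "pacer_score",
    "empirical_pvalues",
    "rank_pathways",
]


@dataclass
class ScoreTable:
    """Compound x pathway scores with matching empirical p-values."""

    scores: pd.DataFrame
    pvals: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)


def _row_normalize(V: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    out = np.zeros_like(V)
    nz = norms[:, 0] > 0
    out[nz] = V[nz] / norms[nz]
    return out


def gene_pathway_cosines(emb: EmbeddingMatrix) -> np.ndarray:
    """(n_genes x n_pathways) cosine similarities; zero vectors give 0."""
    G = _row_normalize(emb.gene_vectors)
    P = _row_normalize(emb.pathway_vectors)
    return G @ P.T


def _resolve_rcg_indices(
    emb: EmbeddingMatrix, rcg: RCGSet
) -> tuple[np.ndarray, np.ndarray]:
    index = {g: i for i, g in enumerate(emb.node_ids[: emb.n_genes])}
    idx, w = [], []
    missing = 0
    for gene, weight in zip(rcg.genes, rcg.weights):
        if gene in index:
            idx.append(index[gene])
            w.append(weight)
        else:
            missing += 1
    if missing:
        logger.warning(
            "%d RCG gene(s) of %s absent from the embedding; dropped",
            missing,
            rcg.compound_id,
        )
    if not idx:
        raise ValueError(f"no usable RCGs for compound {rcg.compound_id}")
    idx = np.asarray(idx)
    w = np.asarray(w, dtype=float)
    # canonical gene order makes the floating-point sum independent of the
    # caller's RCG ordering (bitwise-reproducible scores)
    order = np.argsort(idx)
    return idx[order], w[order]


def pacer_score(
    emb: EmbeddingMatrix,
    rcg: RCGSet,
    normalize: str = "sum",
    cosines: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Score every pathway against one compound's RCG set.

    ``normalize="sum"`` is the weighted sum above; ``"mean"`` divides by the
    number of usable RCGs (affects cross-compound comparability only, never
    the within-compound ranking).
    """
    if normalize not in ("sum", "mean"):
        raise ValueError("normalize must be 'sum' or 'mean'")
    C = gene_pathway_cosines(emb) if cosines is None else cosines
    idx, w = _resolve_rcg_indices(emb, rcg)
    s = w @ C[idx]
    if normalize == "mean":
        s = s / len(idx)
    return s


def _empirical_p(observed: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    """Add-one upper-tail rank: p = (1 + #{null >= s}) / (1 + #null)."""
    total = null_sorted.size
    n_ge = total - np.searchsorted(null_sorted, observed, side="left")
    return (1.0 + n_ge) / (1.0 + total)


def empirical_pvalues(
    emb: EmbeddingMatrix,
    rcg: RCGSet,
    k: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    normalize: str = "sum",
    null_weights: str = "permute",
    cosines: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical p-value per pathway from random matched-size gene sets.

    Draws ``k`` uniform gene sets (without replacement, from the embedded
    genes) of the same size as the usable RCG set, scores each against all m
    pathways (weights permuted onto the random genes, or all-ones with
    ``null_weights="unit"``), pools the k*m null scores and returns the
    add-one fractional rank of each observed score.

    Returns
    -------
    (scores, pvals) : ndarray of shape (m,), ndarray of shape (m,)
    """
    if k < 100:
        logger.warning("k=%d null sets makes the p-value tail unstable", k)
    if null_weights not in ("permute", "unit"):
        raise ValueError("null_weights must be 'permute' or 'unit'")
    C = gene_pathway_cosines(emb) if cosines is None else cosines
    idx, w = _resolve_rcg_indices(emb, rcg)
    observed = w @ C[idx]
    if normalize == "mean":
        observed = observed / len(idx)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_genes, size = emb.n_genes, len(idx)
    if size > n_genes:
        raise ValueError("RCG set larger than the embedded-gene universe")
    m = C.shape[1]
    # chunked vectorized draws keep peak memory ~O(chunk * size * m)
    chunk = max(1, int(2e7) // max(1, size * m))
    null = np.empty((k, m))
    done = 0
    while done < k:
        b = min(chunk, k - done)
        # uniform sets without replacement: smallest `size` of random keys
        keys = rng.random((b, n_genes))
        sets = np.argpartition(keys, size - 1, axis=1)[:, :size]
        if null_weights == "permute":
            W = np.stack([rng.permutation(w) for _ in range(b)])
        else:
            W = np.ones((b, size))
        null[done : done + b] = np.einsum("ks,ksm->km", W, C[sets])
        done += b
    if normalize == "mean":
        null = null / size
    null_sorted = np.sort(null, axis=None)
    pvals = _empirical_p(observed, null_sorted)
    return observed, pvals


def rank_pathways(
    scores: np.ndarray, pathway_ids: list[str], top_n: Optional[int] = None
) -> list[str]:
    """Pathways by descending score; ties broken by pathway id."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    m = len(pathway_ids)
    if top_n is None:
        top_n = m
    if top_n > m:
        logger.warning("top_n=%d exceeds %d pathways; capped", top_n, m)
        top_n = m
    order = sorted(range(m), key=lambda i: (-scores[i], pathway_ids[i]))
    return [pathway_ids[i] for i in order[:top_n]]


class PACER(BaseEstimator):
    """Network-embedding pathway ranker for gene sets of interest.

    ``fit`` assembles the heterogeneous gene-pathway network and embeds it;
    ``score_pathways`` / ``score_table`` rank pathways for one or many
    weighted gene sets (typically a compound's RCGs).

    Parameters
    ----------
    n_components : int, default 100
        Embedding dimension.
    restart_prob : float, default 0.5
        RWR restart probability.
    null_k : int, default 10000
        Number of random gene sets behind each empirical p-value.
    normalize : {"sum", "mean"}
        Weighted sum per the score definition, or its mean variant.
    null_weights : {"permute", "unit"}
        How weights are assigned to null gene sets.
    random_state : int or None
        Seed for the null draws (the embedding itself is deterministic).

    Attributes
    ----------
    embedding_ : EmbeddingMatrix
    cosines_ : ndarray (n_genes, n_pathways)
    pathway_ids_ : list of str
    """

    def __init__(
        self,
        n_components: int = 100,
        restart_prob: float = 0.5,
        pseudocount: Optional[float] = None,
        rwr_method: str = "auto",
        tol: float = 1e-12,
        max_iter: int = 10_000,
        null_k: int = 10_000,
        normalize: str = "sum",
        null_weights: str = "permute",
        random_state: Optional[int] = None,
    ):
        self.n_components = n_components
        self.restart_prob = restart_prob
        self.pseudocount = pseudocount
        self.rwr_method = rwr_method
        self.tol = tol
        self.max_iter = max_iter
        self.null_k = null_k
        self.normalize = normalize
        self.null_weights = null_weights
        self.random_state = random_state

    def fit(self, network: GeneNetwork, pathways: PathwayCollection):
        """Embed the heterogeneous network built from ``network`` + ``pathways``."""
        het = build_heterogeneous_network(network, pathways)
        dca = DCAEmbedding(
            n_components=self.n_components,
            restart_prob=self.restart_prob,
            tol=self.tol,
            max_iter=self.max_iter,
            pseudocount=self.pseudocount,
            method=self.rwr_method,
        ).fit(het)
        self.embedding_ = dca.embedding_matrix_
        self.cosines_ = gene_pathway_cosines(self.embedding_)
        self.pathway_ids_ = list(pathways.pathway_ids)
        self.gene_ids_ = list(network.gene_ids)
        return self

    def score_pathways(self, rcg: RCGSet) -> np.ndarray:
        """Scores of all fitted pathways for one RCG set."""
        return pacer_score(
            self.embedding_, rcg, normalize=self.normalize, cosines=self.cosines_
        )

    def score_table(
        self, rcg_sets: dict[str, RCGSet], with_pvalues: bool = True
    ) -> ScoreTable:
        """Score every compound against every pathway, optionally with p-values."""
        rng = np.random.default_rng(self.random_state)
        rows_s, rows_p = {}, {}
        for comp, rcg in rcg_sets.items():
            if with_pvalues:
                s, p = empirical_pvalues(
                    self.embedding_,
                    rcg,
                    k=self.null_k,
                    rng=rng,
                    normalize=self.normalize,
                    null_weights=self.null_weights,
                    cosines=self.cosines_,
                )
                rows_p[comp] = p
            else:
                s = self.score_pathways(rcg)
            rows_s[comp] = s
        cols = pd.Index(self.pathway_ids_, name="pathway")
        scores = pd.DataFrame.from_dict(rows_s, orient="index", columns=cols)
        scores.index.name = "compound"
        pvals = None
        if with_pvalues:
            pvals = pd.DataFrame.from_dict(rows_p, orient="index", columns=cols)
            pvals.index.name = "compound"
        return ScoreTable(
            scores=scores,
            pvals=pvals,
            provenance={
                "null_k": self.null_k,
                "null_seed": self.random_state,
                "n_components": self.n_components,
                "restart_prob": self.restart_prob,
                "normalize": self.normalize,
                "null_weights": self.null_weights,
            },
        )
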