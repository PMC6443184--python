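"""Diffusion states and low-dimensional node vectors for the heterogeneous network.

A random walk with restart (RWR) from each source node yields its diffusion
state: the stationary visitation distribution ``s_i`` solving

    s_i = r * e_i + (1 - r) * s_i @ P

with restart probability ``r`` and row-stochastic transition matrix ``P``.
Diffusion component analysis (DCA) then compresses the diffusion-state
matrix ``S`` into d-dimensional node vectors.  We use the closed-form
variant: ``L = log(S + c) - log(c)`` with pseudocount ``c = 1/(n+m)``,
truncated SVD of ``L``, and ``V = U_d @ sqrt(Sigma_d)``.  Nodes that are
close in the network receive similar vectors, so cosine similarity in the
embedded space is a network-proximity score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .network import HeterogeneousNetwork

__all__ = [
    "DiffusionStates",
    "EmbeddingMatrix",
    "DCAEmbedding",
    "rwr_diffusion",
    "embed_dca",
    "cosine",
]


@dataclass
class DiffusionStates:
    """RWR visitation distributions; row i is the diffusion state of node i."""

    S: np.ndarray
    restart_prob: float
    node_ids: Optional[list[str]] = None
    n_genes: Optional[int] = None
    n_pathways: Optional[int] = None


@dataclass
class EmbeddingMatrix:
    """d-dimensional node vectors, genes first then pathways."""

    V: np.ndarray
    node_ids: list[str]
    n_genes: int
    n_pathways: int

    @property
    def d(self) -> int:
        return self.V.shape[1]

    @property
    def gene_vectors(self) -> np.ndarray:
        return self.V[: self.n_genes]

    @property
    def pathway_vectors(self) -> np.ndarray:
        return self.V[self.n_genes :]


def _as_dense_adjacency(H) -> np.ndarray:
    if isinstance(H, HeterogeneousNetwork):
        H = H.H
    if sp.issparse(H):
        H = H.toarray()
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("adjacency must be square")
    return H


def _transition_matrix(H: np.ndarray) -> np.ndarray:
    """Row-normalize; zero-degree rows become restart indicators (walker stays)."""
    deg = H.sum(axis=1)
    P = np.zeros_like(H)
    nz = deg > 0
    P[nz] = H[nz] / deg[nz, None]
    idx = np.flatnonzero(~nz)
    P[idx, idx] = 1.0
    return P


def rwr_diffusion(
    H,
    restart_prob: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    method: str = "auto",
) -> DiffusionStates:
    """Compute all-source RWR diffusion states on a (heterogeneous) network.

    Parameters
    ----------
    H : HeterogeneousNetwork or array-like
        Symmetric non-negative adjacency.
    restart_prob : float in (0, 1]
        Probability of teleporting back to the source at each step.
    method : {"auto", "iterative", "direct"}
        "iterative" repeats ``S <- r*I + (1-r)*S@P`` until the max row-L1
        change is below ``tol``; "direct" solves the linear system
        ``S = r * (I - (1-r)P)^{-1}`` exactly.  "auto" picks direct for
        networks small enough to invert densely.

    Returns
    -------
    DiffusionStates
        Rows are probability vectors (sum to 1).
    """
    if not 0 < restart_prob <= 1:
        raise ValueError("restart_prob must be in (0, 1]")
    node_ids = n = m = None
    if isinstance(H, HeterogeneousNetwork):
        node_ids, n, m = H.node_ids, H.n, H.m
    A = _as_dense_adjacency(H)
    N = A.shape[0]
    P = _transition_matrix(A)
    r = float(restart_prob)
    if method == "auto":
        method = "direct" if N <= 2000 else "iterative"
    if method == "direct":
        M = np.eye(N) - (1.0 - r) * P
        S = r * np.linalg.inv(M)
    elif method == "iterative":
        S = np.eye(N)
        rI = r * np.eye(N)
        for _ in range(max_iter):
            S_next = rI + (1.0 - r) * (S @ P)
            resid = np.abs(S_next - S).sum(axis=1).max()
            S = S_next
            if resid < tol:
                break
        else:
            raise RuntimeError(
                f"RWR did not converge in {max_iter} iterations (residual {resid:.3e})"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return DiffusionStates(
        S=S, restart_prob=r, node_ids=node_ids, n_genes=n, n_pathways=m
    )


def _sign_fix(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.abs(U).argmax(axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def dca_log_transform(S: np.ndarray, pseudocount: Optional[float] = None) -> np.ndarray:
    """L = log(S + c) - log(c) with default pseudocount c = 1/(n+m)."""
    N = S.shape[0]
    c = 1.0 / N if pseudocount is None else float(pseudocount)
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log(S + c) - np.log(c)


def embed_dca(
    S: DiffusionStates, d: int, pseudocount: Optional[float] = None
) -> EmbeddingMatrix:
    """Closed-form DCA: truncated SVD of the log-transformed diffusion states.

    ``V = U_d @ sqrt(Sigma_d)`` with a deterministic sign convention (each
    singular vector's largest-magnitude entry is positive).
    """
    N = S.S.shape[0]
    if d < 1 or d > N:
        raise ValueError(f"d={d} must be in [1, {N}]")
    L = dca_log_transform(S.S, pseudocount)
    U, sigma, _ = np.linalg.svd(L, full_matrices=False)
    U = _sign_fix(U[:, :d])
    V = U * np.sqrt(sigma[:d])
    node_ids = S.node_ids if S.node_ids is not None else [str(i) for i in range(N)]
    n = S.n_genes if S.n_genes is not None else N
    m = S.n_pathways if S.n_pathways is not None else 0
    return EmbeddingMatrix(V=V, node_ids=node_ids, n_genes=n, n_pathways=m)


def cosine(u, v) -> float:
    """Cosine similarity; zero vectors score 0 (no evidence convention)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vector length mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


class DCAEmbedding(BaseEstimator):
    """Diffusion-component-analysis node embedding as a transductive estimator.

    Fits on a (heterogeneous) network adjacency and exposes the node vectors
    via ``embedding_`` / ``fit_transform``; there is no out-of-sample
    ``transform`` because the embedding is defined only for fitted nodes
    (compare ``sklearn.manifold.SpectralEmbedding``).

    Parameters
    ----------
    n_components : int, default 100
        Embedding dimension d.
    restart_prob : float, default 0.5
        RWR restart probability.
    tol, max_iter : iterative RWR stopping rule (ignored for direct solve).
    pseudocount : float or None
        DCA log pseudocount; None means 1/(n+m).
    method : {"auto", "iterative", "direct"}
        RWR solver.
    """

    def __init__(
        self,
        n_components: int = 100,
        restart_prob: float = 0.5,
        tol: float = 1e-12,
        max_iter: int = 10_000,
        pseudocount: Optional[float] = None,
        method: str = "auto",
    ):
        self.n_components = n_components
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.pseudocount = pseudocount
        self.method = method

    def fit(self, X, y=None):
        """Compute diffusion states and node vectors for network ``X``."""
        states = rwr_diffusion(
            X,
            restart_prob=self.restart_prob,
            tol=self.tol,
            max_iter=self.max_iter,
            method=self.method,
        )
        d = min(self.n_components, states.S.shape[0])
        emb = embed_dca(states, d=d, pseudocount=self.pseudocount)
        self.diffusion_states_ = states
        self.embedding_ = emb.V
        self.embedding_matrix_ = emb
        self.n_features_in_ = states.S.shape[0]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_
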