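"""Gene network, pathway collection and heterogeneous network containers and I/O.

The heterogeneous network couples a weighted gene-gene interaction graph
(adjacency ``A``, ``n`` genes) with binary gene-pathway membership
(``B``, ``n x m``) into a single symmetric block matrix

    H = [[A,   B],
         [B.T, 0]]

with no pathway-pathway edges.  Gene identifiers are opaque strings; mapping
between identifier namespaces (e.g. STRING protein ids vs. HGNC symbols) is
the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "PathwayCollection",
    "HeterogeneousNetwork",
    "read_edge_list",
    "write_edge_list",
    "integrate_string_channels",
    "read_gmt",
    "build_heterogeneous_network",
]


@dataclass
class GeneNetwork:
    """Weighted undirected gene-gene graph.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique node identifiers, fixing the row/column order of ``adjacency``.
    adjacency : scipy.sparse matrix or ndarray, shape (n, n)
        Symmetric non-negative edge weights in [0, 1], zero diagonal.
    """

    gene_ids: list[str]
    adjacency: sp.csr_matrix
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        A = self.adjacency
        if not sp.issparse(A):
            A = sp.csr_matrix(np.asarray(A, dtype=float))
        A = A.tocsr().astype(float)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match {n} genes")
        if A.diagonal().any():
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if (A - A.T).count_nonzero() and abs(A - A.T).max() > 1e-9:
            raise ValueError("adjacency must be symmetric")
        if A.nnz and A.data.min() < 0:
            raise ValueError("edge weights must be non-negative")
        self.adjacency = A
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def degrees(self, weighted: bool = True) -> np.ndarray:
        """Per-gene degree: sum of incident edge weights (or edge count)."""
        A = self.adjacency
        if weighted:
            return np.asarray(A.sum(axis=1)).ravel()
        return np.asarray((A != 0).sum(axis=1)).ravel()


@dataclass
class PathwayCollection:
    """Named gene sets as a binary membership matrix over a gene universe."""

    pathway_ids: list[str]
    membership: np.ndarray  # (n, m) binary
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.pathway_ids = list(self.pathway_ids)
        self.gene_ids = list(self.gene_ids)
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("pathway_ids must be unique")
        B = np.asarray(self.membership)
        if B.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("membership shape mismatch")
        if not np.isin(B, (0, 1)).all():
            raise ValueError("membership entries must be binary")
        if len(self.pathway_ids) and (B.sum(axis=0) == 0).any():
            raise ValueError("every pathway must have at least one member gene")
        self.membership = B.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.pathway_ids)

    def genes_in(self, pathway: str) -> set[str]:
        j = self.pathway_ids.index(pathway)
        return {self.gene_ids[i] for i in np.flatnonzero(self.membership[:, j])}


@dataclass
class HeterogeneousNetwork:
    """Block matrix over genes-then-pathways with no pathway-pathway edges."""

    node_ids: list[str]
    H: sp.csr_matrix
    n: int
    m: int

    def __post_init__(self) -> None:
        total = self.n + self.m
        if len(self.node_ids) != total or self.H.shape != (total, total):
            raise ValueError("node/H size mismatch")


def _parse_weight(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"line {lineno}: cannot parse weight {token!r}") from None


def read_edge_list(
    path,
    dialect: str = "string_links",
    min_weight: float = 0.0,
) -> GeneNetwork:
    """Read a 3-column edge list (node1, node2, score) into a :class:`GeneNetwork`.

    ``dialect="string_links"`` expects STRING protein-links scores on the
    0-1000 scale and divides by 1000; ``"plain_tsv"`` takes weights as-is in
    [0, 1].  Duplicate edges collapse to the maximum weight; self-loops are
    dropped with a warning.  A header row is detected by a non-numeric third
    field.  Low-confidence edges are kept by default (``min_weight=0``).
    """
    if dialect not in ("string_links", "plain_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: dict[tuple[str, str], float] = {}
    genes: set[str] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            if lineno == 1:
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header row
            w = _parse_weight(fields[2], lineno)
            if w < 0:
                raise ValueError(f"line {lineno}: negative weight {w}")
            if dialect == "string_links":
                w /= 1000.0
            if w > 1.0 + 1e-9:
                raise ValueError(f"line {lineno}: weight {w} outside [0, 1]")
            if a == b:
                n_self += 1
                continue
            if w < min_weight:
                continue
            key = (a, b) if a < b else (b, a)
            edges[key] = max(edges.get(key, 0.0), w)
            genes.add(a)
            genes.add(b)
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    gene_ids = sorted(genes)
    index = {g: i for i, g in enumerate(gene_ids)}
    rows, cols, vals = [], [], []
    for (a, b), w in edges.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(gene_ids), len(gene_ids)))
    return GeneNetwork(gene_ids=gene_ids, adjacency=A)


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write the upper-triangle edge set as node1 TAB node2 TAB weight (6 dp)."""
    coo = sp.triu(net.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\t{w:.6f}\n")


def integrate_string_channels(
    channel_scores: Iterable[float], prior: float = 0.041
) -> float:
    """Combine per-channel STRING confidence scores under a shared prior.

    Each channel score ``s`` is prior-corrected to ``s' = max(0, (s-p)/(1-p))``,
    evidence is combined as ``c' = 1 - prod(1 - s')``, and the prior is
    re-added: ``c = c' + p*(1 - c')``.
    """
    if not 0 <= prior < 1:
        raise ValueError("prior must be in [0, 1)")
    scores = list(channel_scores)
    for s in scores:
        if not 0 <= s <= 1:
            raise ValueError(f"channel score {s} outside [0, 1]")
    corrected = [max(0.0, (s - prior) / (1.0 - prior)) for s in scores]
    residual = 1.0
    for s in corrected:
        residual *= 1.0 - s
    combined = 1.0 - residual
    return combined + prior * (1.0 - combined)


def read_gmt(path, universe: Sequence[str]) -> PathwayCollection:
    """Read gene sets in GMT format, intersected with a gene universe.

    Genes outside ``universe`` are dropped; pathways emptied by the
    intersection are removed with a logged warning.  The membership matrix
    rows follow the order of ``universe``.
    """
    universe = list(universe)
    uindex = {g: i for i, g in enumerate(universe)}
    names: list[str] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT needs name, description, >=1 gene")
            name = fields[0]
            if name in names:
                raise ValueError(f"duplicate pathway name {name!r} at line {lineno}")
            col = np.zeros(len(universe), dtype=np.int8)
            for g in fields[2:]:
                if g in uindex:
                    col[uindex[g]] = 1
            if col.sum() == 0:
                n_dropped += 1
                logger.warning("pathway %r has no genes in universe; removed", name)
                continue
            names.append(name)
            columns.append(col)
    if not names:
        raise ValueError("no pathways" + (" left after intersection" if n_dropped else " in file"))
    B = np.stack(columns, axis=1)
    return PathwayCollection(pathway_ids=names, membership=B, gene_ids=universe)


def build_heterogeneous_network(
    net: GeneNetwork, paths: PathwayCollection
) -> HeterogeneousNetwork:
    """Assemble H = [[A, B], [B.T, 0]] over genes-then-pathways."""
    if list(net.gene_ids) != list(paths.gene_ids):
        raise ValueError("gene ordering of network and pathway collection differ")
    n, m = net.n, paths.m
    A = net.adjacency
    if m == 0:
        H = A.tocsr()
    else:
        B = sp.csr_matrix(paths.membership.astype(float))
        H = sp.bmat([[A, B], [B.T, None]], format="csr")
    return HeterogeneousNetwork(
        node_ids=list(net.gene_ids) + list(paths.pathway_ids), H=H.tocsr(), n=n, m=m
    )
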