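"""Self-contained synthetic fixtures with planted ground truth.

The generator emulates the statistical structure the embedding method
exploits: a modular gene network (stochastic block model, within-community
edge probability ``p_in`` > cross-community ``p_out``) whose communities
seed the pathways, a basal expression matrix with planted gene-response
correlations, and perturbation z-score profiles with planted DEGs.

Two overlap modes set up the central contrast:

- ``member``: the genes correlated with a compound's response are members of
  the planted pathway, so both overlap tests and network proximity can find
  the association;
- ``adjacent_only``: the correlated genes are community neighbours of the
  planted pathway but never members, so overlap-based enrichment is blind
  (Fisher p = 1 by construction) while network proximity still works.

Planted correlations use a single latent factor per compound: each planted
gene's expression is ``sqrt(rho)*f + sqrt(1-rho)*noise`` and the response is
``sqrt(rho)*f + sqrt(1-rho)*noise``, so every planted gene has marginal
expression-response Pearson correlation exactly ``rho`` (the effect size)
for any number of planted genes, and planted genes are mutually correlated
as co-regulated pathway genes are.

All draws are reproducible from ``(scenario, scenario.seed)``; each
generator consumes an independent seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import GeneNetwork, PathwayCollection

__all__ = [
    "SyntheticScenario",
    "ScenarioData",
    "generate_network",
    "generate_pharmaco",
    "generate_zscores",
    "simulate",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic benchmark.

    Defaults give the desk-scale setting used throughout the test-bench:
    400 genes in 20 communities of 20, one pathway per community, 200 cell
    lines, 10 compounds each planted on a distinct pathway with marginal
    gene-response correlation 0.5.
    """

    n_genes: int = 400
    n_pathways: int = 20
    n_cell_lines: int = 200
    n_compounds: int = 10
    p_in: float = 0.4
    p_out: float = 0.01
    pathway_fraction: float = 0.8  # member mode: fraction of a community in its pathway
    planted_genes_per_compound: int = 8
    effect_size: float = 0.5
    overlap_mode: str = "member"  # or "adjacent_only"
    weight_low: float = 0.5
    weight_high: float = 1.0
    n_conditions: int = 5
    background_z_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_mode not in ("member", "adjacent_only"):
            raise ValueError("overlap_mode must be 'member' or 'adjacent_only'")
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")
        if self.n_genes < 2 * self.n_pathways:
            raise ValueError("need at least 2 genes per community")

    @property
    def community_size(self) -> int:
        return self.n_genes // self.n_pathways

    def communities(self) -> np.ndarray:
        """Community label per gene; leftover genes get -1 (background)."""
        comm = np.full(self.n_genes, -1, dtype=int)
        size = self.community_size
        for c in range(self.n_pathways):
            comm[c * size : (c + 1) * size] = c
        return comm


@dataclass
class ScenarioData:
    """Everything one benchmark run consumes, plus the planted truth."""

    scenario: SyntheticScenario
    network: GeneNetwork
    pathways: PathwayCollection
    expression: pd.DataFrame
    response: pd.DataFrame
    truth: dict  # compound -> {"pathway": id, "genes": [gene ids]}
    targets: dict = field(default_factory=dict)  # compound -> set of target genes
    zscores: dict = field(default_factory=dict)  # compound -> genes x conditions frame


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _pathway_ids(m: int) -> list[str]:
    return [f"PW{c:02d}" for c in range(m)]


def generate_network(
    scenario: SyntheticScenario,
) -> tuple[GeneNetwork, PathwayCollection]:
    """Stochastic-block-model gene graph plus community-derived pathways."""
    sc = scenario
    if sc.p_in <= sc.p_out:
        raise ValueError("p_in must exceed p_out (no recoverable structure)")
    rng = np.random.default_rng([sc.seed, 0])
    n = sc.n_genes
    comm = sc.communities()
    same = (comm[:, None] == comm[None, :]) & (comm[:, None] >= 0)
    prob = np.where(same, sc.p_in, sc.p_out)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    W = np.where(upper, rng.uniform(sc.weight_low, sc.weight_high, (n, n)), 0.0)

    gene_ids = _gene_ids(n)
    size = sc.community_size
    members: list[np.ndarray] = []
    for c in range(sc.n_pathways):
        block = np.arange(c * size, (c + 1) * size)
        if sc.overlap_mode == "member":
            k = max(1, round(sc.pathway_fraction * size))
        else:
            k = max(1, size // 2)
        members.append(np.sort(rng.choice(block, size=k, replace=False)))

    if sc.overlap_mode == "adjacent_only":
        # guarantee every non-member community gene touches its pathway
        for c, mem in enumerate(members):
            block = np.arange(c * size, (c + 1) * size)
            outside = np.setdiff1d(block, mem)
            for g in outside:
                if not (W[g, mem].any() or W[mem, g].any()):
                    tgt = rng.choice(mem)
                    i, j = min(g, tgt), max(g, tgt)
                    W[i, j] = rng.uniform(sc.weight_low, sc.weight_high)

    A = W + W.T
    net = GeneNetwork(gene_ids=gene_ids, adjacency=sp.csr_matrix(A))
    B = np.zeros((n, sc.n_pathways), dtype=np.int8)
    for c, mem in enumerate(members):
        B[mem, c] = 1
    paths = PathwayCollection(
        pathway_ids=_pathway_ids(sc.n_pathways), membership=B, gene_ids=gene_ids
    )
    return net, paths


def _eligible_planted(
    sc: SyntheticScenario, paths: PathwayCollection, pathway_idx: int
) -> np.ndarray:
    """Indices a compound's planted genes may be drawn from."""
    size = sc.community_size
    block = np.arange(pathway_idx * size, (pathway_idx + 1) * size)
    member = np.flatnonzero(paths.membership[:, pathway_idx])
    if sc.overlap_mode == "member":
        return member
    return np.setdiff1d(block, member)


def generate_pharmaco(
    scenario: SyntheticScenario,
    net: GeneNetwork,
    paths: PathwayCollection,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Expression and response matrices with planted correlations.

    Returns ``(expression, response, truth)`` where truth maps each compound
    to its planted pathway and planted genes.  With ``effect_size = 0`` no
    signal is planted (null scenario) and truth gene lists are empty.
    """
    sc = scenario
    rng = np.random.default_rng([sc.seed, 1])
    n, L = sc.n_genes, sc.n_cell_lines
    X = rng.standard_normal((n, L))
    Y = np.empty((sc.n_compounds, L))
    rho = sc.effect_size
    truth: dict = {}
    used: set[int] = set()
    compounds = [f"CPD{j:03d}" for j in range(sc.n_compounds)]
    for j, comp in enumerate(compounds):
        pw_idx = j % sc.n_pathways
        f = rng.standard_normal(L)
        eta = rng.standard_normal(L)
        planted: list[int] = []
        if rho > 0:
            eligible = np.setdiff1d(_eligible_planted(sc, paths, pw_idx), list(used))
            q = sc.planted_genes_per_compound
            if len(eligible) < q:
                raise ValueError(
                    f"not enough eligible genes ({len(eligible)}) to plant {q}"
                )
            planted = sorted(rng.choice(eligible, size=q, replace=False).tolist())
            used.update(planted)
            a = np.sqrt(rho)
            for g in planted:
                X[g] = a * f + np.sqrt(1 - rho) * rng.standard_normal(L)
            Y[j] = a * f + np.sqrt(1 - rho) * eta
        else:
            Y[j] = eta
        truth[comp] = {
            "pathway": paths.pathway_ids[pw_idx],
            "genes": [net.gene_ids[g] for g in planted],
        }
    cells = [f"CL{i:03d}" for i in range(L)]
    expr = pd.DataFrame(X, index=pd.Index(net.gene_ids, name="gene"), columns=cells)
    resp = pd.DataFrame(Y, index=pd.Index(compounds, name="compound"), columns=cells)
    return expr, resp, truth


def generate_zscores(
    scenario: SyntheticScenario,
    planted_degs: Mapping[str, Sequence[str]],
    z_min: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Per-compound z-score profiles (genes x conditions) with planted DEGs.

    Planted genes get |z| above ``z_min`` in one randomly chosen condition;
    background entries are N(0, background_z_sd), so background genes stay
    below the threshold with high probability.
    """
    sc = scenario
    rng = np.random.default_rng([sc.seed, 2])
    genes = _gene_ids(sc.n_genes)
    gindex = {g: i for i, g in enumerate(genes)}
    conditions = [f"cond{t}" for t in range(sc.n_conditions)]
    out: dict[str, pd.DataFrame] = {}
    for comp, degs in planted_degs.items():
        Z = rng.normal(0.0, sc.background_z_sd, (sc.n_genes, sc.n_conditions))
        for g in degs:
            t = rng.integers(sc.n_conditions)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            Z[gindex[g], t] = sign * (z_min + 0.5 + abs(rng.standard_normal()))
        out[comp] = pd.DataFrame(
            Z, index=pd.Index(genes, name="gene"), columns=conditions
        )
    return out


def simulate(
    scenario: Optional[SyntheticScenario] = None, **overrides
) -> ScenarioData:
    """Generate a complete scenario bundle (network, pharmacology, truth,
    target map and z-score profiles) from one seed.

    Targets are two planted genes per compound (members of the planted
    pathway in member mode); planted DEGs are the planted pathway's member
    genes, so the perturbation-derived reference pathway set contains the
    planted pathway.
    """
    sc = scenario if scenario is not None else SyntheticScenario()
    if overrides:
        sc = replace(sc, **overrides)
    net, paths = generate_network(sc)
    expr, resp, truth = generate_pharmaco(sc, net, paths)
    targets = {}
    planted_degs = {}
    for comp, info in truth.items():
        pw_genes = sorted(paths.genes_in(info["pathway"]))
        if sc.overlap_mode == "member" and info["genes"]:
            targets[comp] = set(info["genes"][:2])
        elif pw_genes:
            targets[comp] = set(pw_genes[:2])
        planted_degs[comp] = pw_genes
    zs = generate_zscores(sc, planted_degs)
    return ScenarioData(
        scenario=sc,
        network=net,
        pathways=paths,
        expression=expr,
        response=resp,
        truth=truth,
        targets=targets,
        zscores=zs,
    )
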