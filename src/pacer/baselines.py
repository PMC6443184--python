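"""Statistical baselines: Fisher's-exact overlap enrichment and the
Kruskal-Wallis correlation-profile test.

The Fisher baseline tests, per compound and pathway, whether the overlap
between the compound's RCGs and the pathway's genes is larger than expected
under hypergeometric sampling from the gene universe (one-sided enrichment
tail), with Benjamini-Hochberg FDR across the pathways of each compound.

The Kruskal-Wallis baseline compares, per compound and pathway, the
expression-response correlation values of in-pathway genes against those of
all out-of-pathway genes, ranking pathways by the resulting p-value.  The
full correlation profile is used, not only the RCGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chemosensitivity import CorrelationTable, RCGSet
from .network import PathwayCollection

__all__ = [
    "KWResult",
    "hypergeom_enrichment_p",
    "fisher_enrichment",
    "kruskal_wallis_pathway",
    "kruskal_wallis_all",
    "rank_by_pvalue",
]


@dataclass
class KWResult:
    compound_id: str
    pathway_id: str
    H_statistic: float
    p_value: float


def hypergeom_enrichment_p(overlap, universe, pathway_size, rcg_size):
    """One-sided (upper-tail) hypergeometric p: P(X >= overlap).

    Accepts scalars or broadcastable arrays.
    """
    return stats.hypergeom.sf(np.asarray(overlap) - 1, universe, pathway_size, rcg_size)


def fisher_enrichment(
    rcg: RCGSet, paths: PathwayCollection, universe: Sequence[str]
) -> pd.DataFrame:
    """RCG/pathway overlap enrichment for one compound.

    Returns a frame indexed by pathway with the 2x2 counts
    (overlap, rcg_only, pathway_only, neither), the one-sided p-value and
    the BH q-value across this compound's pathways.
    """
    universe = list(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty gene universe")
    uset = set(universe)
    rcg_genes = {g for g in rcg.genes if g in uset}
    n_rcg = len(rcg_genes)
    rows = []
    for pw in paths.pathway_ids:
        pw_genes = paths.genes_in(pw) & uset
        K = len(pw_genes)
        x = len(pw_genes & rcg_genes)
        p = float(hypergeom_enrichment_p(x, N, K, n_rcg))
        rows.append(
            {
                "pathway": pw,
                "overlap": x,
                "rcg_only": n_rcg - x,
                "pathway_only": K - x,
                "neither": N - K - n_rcg + x,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("pathway")
    out["fdr_q"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def _kw_two_group(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all values tied: no separation by convention
    H, p = stats.kruskal(x, y)
    return float(H), float(p)


def kruskal_wallis_pathway(
    C: CorrelationTable, compound: str, pathway: str, paths: PathwayCollection
) -> KWResult:
    """Tie-corrected two-group Kruskal-Wallis H on in- vs out-of-pathway
    correlation values for one compound."""
    r = C.R.loc[compound]
    pw_genes = paths.genes_in(pathway)
    in_vals = r[[g for g in r.index if g in pw_genes]].dropna().to_numpy()
    out_vals = r[[g for g in r.index if g not in pw_genes]].dropna().to_numpy()
    if in_vals.size + out_vals.size == 0:
        raise ValueError(f"no correlation values for compound {compound}")
    H, p = _kw_two_group(in_vals, out_vals)
    return KWResult(compound_id=compound, pathway_id=pathway, H_statistic=H, p_value=p)


def kruskal_wallis_all(
    C: CorrelationTable, paths: PathwayCollection, compounds: Sequence[str] = None
) -> pd.DataFrame:
    """KW statistic and p for every (compound, pathway); long-format frame."""
    if compounds is None:
        compounds = list(C.R.index)
    gene_cols = np.array(C.R.columns)
    member = {
        pw: np.isin(gene_cols, list(paths.genes_in(pw))) for pw in paths.pathway_ids
    }
    rows = []
    for comp in compounds:
        r = C.R.loc[comp].to_numpy(dtype=float)
        finite = np.isfinite(r)
        for pw in paths.pathway_ids:
            mask = member[pw]
            res = _kw_two_group(r[finite & mask], r[finite & ~mask])
            rows.append(
                {"compound": comp, "pathway": pw, "H": res[0], "p_value": res[1]}
            )
    return pd.DataFrame(rows)


def rank_by_pvalue(results: pd.DataFrame, p_col: str = "p_value") -> list[str]:
    """Pathway ids by ascending p; ties broken lexicographically."""
    if "pathway" in results.columns:
        items = list(zip(results["pathway"], results[p_col]))
    else:
        items = list(zip(results.index, results[p_col]))
    return [pw for pw, _ in sorted(items, key=lambda t: (t[1], t[0]))]
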