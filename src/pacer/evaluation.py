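"""Benchmark protocols: target-based AUROC and perturbation-signature concordance.

Target benchmark: a pathway is a true association for a compound iff it
contains at least one known target gene of the compound; per-compound AUROC
measures how highly the method ranks such pathways.

Perturbation benchmark: a reference pathway set is derived from
post-treatment differential-expression z-scores (top 250 genes by max |z|
across conditions, provided |z| > 2, then Fisher overlap with pathways at
p < 0.05); a compound counts as concordant when its predicted pathway set
overlaps the reference set significantly (one-sided Fisher p < 0.05).  For
a fair comparison all methods predict the same number of pathways as the
Fisher baseline finds significant at the chosen FDR.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .baselines import hypergeom_enrichment_p
from .network import PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "pathway_labels_from_targets",
    "auroc",
    "auroc_per_compound",
    "lincs_degs",
    "concordance_test",
    "matched_size_prediction",
]


def pathway_labels_from_targets(
    targets: Mapping[str, set], paths: PathwayCollection
) -> pd.DataFrame:
    """Binary (compound x pathway) labels: 1 iff the pathway contains a target."""
    rows = {}
    for comp, tset in targets.items():
        if not tset:
            logger.warning("compound %s has no targets; excluded", comp)
            continue
        rows[comp] = [
            1 if (paths.genes_in(pw) & set(tset)) else 0 for pw in paths.pathway_ids
        ]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=pd.Index(paths.pathway_ids, name="pathway")
    )
    out.index.name = "compound"
    return out


def auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann-Whitney formulation, midrank ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def auroc_per_compound(
    score_table: pd.DataFrame, labels: pd.DataFrame
) -> pd.Series:
    """AUROC for each compound present in both frames; single-class compounds
    are excluded with a warning."""
    out = {}
    shared = [c for c in score_table.index if c in labels.index]
    for comp in shared:
        y = labels.loc[comp, score_table.columns].to_numpy()
        if y.min() == y.max():
            logger.warning("compound %s has single-class labels; excluded", comp)
            continue
        out[comp] = auroc(score_table.loc[comp].to_numpy(), y)
    return pd.Series(out, name="auroc")


def lincs_degs(
    zscores: pd.DataFrame, top_k: int = 250, z_min: float = 2.0, mode: str = "abs"
) -> list[str]:
    """Differentially expressed genes from per-condition z-score profiles.

    Each gene is summarized by its maximum differential expression across
    conditions (``mode="abs"``: max of |z|; ``"signed"``: max of signed z,
    thresholded on its absolute value); genes with summary |z| > ``z_min``
    are ranked descending and capped at ``top_k``.
    """
    Z = zscores.to_numpy(dtype=float)
    if mode == "abs":
        stat = np.nanmax(np.abs(Z), axis=1)
        passes = stat > z_min
    elif mode == "signed":
        stat = np.nanmax(Z, axis=1)
        passes = np.abs(stat) > z_min
    else:
        raise ValueError("mode must be 'abs' or 'signed'")
    genes = np.array(zscores.index)
    cand = [(float(stat[i]), genes[i]) for i in np.flatnonzero(passes)]
    cand.sort(key=lambda t: (-abs(t[0]), t[1]))
    if not cand:
        logger.info("no gene passed |z| > %g", z_min)
    return [g for _, g in cand[:top_k]]


def concordance_test(
    predicted: set, reference: set, m: int
) -> float:
    """One-sided Fisher p for the overlap of two pathway sets in a universe of m."""
    if not reference:
        raise ValueError("empty reference pathway set")
    predicted = set(predicted)
    reference = set(reference)
    if len(predicted) > m or len(reference) > m:
        raise ValueError("set larger than the pathway universe")
    x = len(predicted & reference)
    return float(hypergeom_enrichment_p(x, m, len(reference), len(predicted)))


def matched_size_prediction(
    pacer_scores: Optional[pd.Series],
    kw_pvalues: Optional[pd.Series],
    fisher_qvalues: pd.Series,
    fdr: float = 0.05,
) -> dict[str, set]:
    """Same-size predicted pathway sets for one compound.

    The Fisher baseline's significant set at q < ``fdr`` fixes the size n;
    the embedding method contributes its n highest-scoring pathways and the
    Kruskal-Wallis method its n smallest p-values.  n = 0 yields empty sets
    for every method.
    """
    sig = fisher_qvalues[fisher_qvalues < fdr]
    n = len(sig)
    out = {"fisher": set(sig.index)}
    if pacer_scores is not None:
        order = sorted(pacer_scores.index, key=lambda pw: (-pacer_scores[pw], pw))
        out["pacer"] = set(order[:n])
    if kw_pvalues is not None:
        order = sorted(kw_pvalues.index, key=lambda pw: (kw_pvalues[pw], pw))
        out["kw"] = set(order[:n])
    return out
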