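"""Basal-expression vs. compound-response correlation and RCG selection.

Cellular response to a compound is summarized per cell line as the area
under the dose-response curve (AUC).  For each (gene, compound) pair we
compute the Pearson correlation between the gene's basal expression and the
compound's AUC across shared cell lines.  A compound's response-correlated
genes (RCGs) are the genes whose correlation is significant at
p < alpha after Bonferroni correction, capped at the top_k most significant;
the signed correlation coefficient serves as the gene weight downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationTable",
    "RCGSet",
    "correlate",
    "select_rcgs",
    "filter_compounds",
    "degree_association_test",
]


@dataclass
class CorrelationTable:
    """Per-pair Pearson coefficients, two-sided p-values and sample counts.

    All three frames are compounds x genes; entries are NaN where a pair had
    fewer than 3 shared observations or zero variance.
    """

    R: pd.DataFrame
    P: pd.DataFrame
    n_obs: pd.DataFrame


@dataclass
class RCGSet:
    """A compound's response-correlated genes with signed-r weights."""

    compound_id: str
    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes/weights length mismatch")

    def __len__(self) -> int:
        return len(self.genes)


def correlate(X: pd.DataFrame, Y: pd.DataFrame, min_obs: int = 3) -> CorrelationTable:
    """Pearson-correlate every gene's expression with every compound's response.

    Parameters
    ----------
    X : DataFrame, genes x cell lines
        Basal expression; NaN marks missing measurements.
    Y : DataFrame, compounds x cell lines
        AUC response values.

    Notes
    -----
    Missing values are removed pairwise per (gene, compound); pairs with
    fewer than ``min_obs`` shared observations, or with a constant vector,
    get NaN r and p (logged).  Two-sided p-values come from the t transform
    ``t = r * sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom.
    """
    shared = [c for c in X.columns if c in set(Y.columns)]
    if len(shared) < min_obs:
        raise ValueError(f"only {len(shared)} shared cell lines; need >= {min_obs}")
    Xv = X[shared].to_numpy(dtype=float)
    genes = list(X.index)
    compounds = list(Y.index)
    R = np.full((len(compounds), len(genes)), np.nan)
    P = np.full_like(R, np.nan)
    Nobs = np.zeros_like(R, dtype=int)
    Xfinite = np.isfinite(Xv)
    n_degenerate = 0
    for ci, comp in enumerate(compounds):
        y = Y.loc[comp, shared].to_numpy(dtype=float)
        M = Xfinite & np.isfinite(y)[None, :]
        n = M.sum(axis=1)
        Xm = np.where(M, Xv, 0.0)
        ym = np.where(M, y[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = Xm.sum(axis=1)
            sy = ym.sum(axis=1)
            cov = (Xm * ym).sum(axis=1) - sx * sy / n
            varx = (Xm**2).sum(axis=1) - sx**2 / n
            vary = (ym**2).sum(axis=1) - sy**2 / n
            denom = np.sqrt(varx * vary)
            r = np.where((n >= min_obs) & (denom > 0), cov / denom, np.nan)
            r = np.clip(r, -1.0, 1.0)
            df = n - 2
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
            p = np.where(np.isfinite(r), 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
            p = np.where(np.isfinite(r) & (np.abs(r) >= 1.0), 0.0, p)
        n_degenerate += int(((n >= min_obs) & (denom <= 0)).sum())
        R[ci], P[ci], Nobs[ci] = r, p, n
    if n_degenerate:
        logger.warning("%d gene-compound pair(s) had zero variance; recorded as missing", n_degenerate)
    idx = pd.Index(compounds, name="compound")
    cols = pd.Index(genes, name="gene")
    return CorrelationTable(
        R=pd.DataFrame(R, index=idx, columns=cols),
        P=pd.DataFrame(P, index=idx, columns=cols),
        n_obs=pd.DataFrame(Nobs, index=idx, columns=cols),
    )


def _bonferroni_multiplier(
    bonferroni_m: Union[str, float], n_tested_compound: int, n_tested_total: int
) -> float:
    if bonferroni_m == "per_compound":
        return float(n_tested_compound)
    if bonferroni_m == "global":
        return float(n_tested_total)
    return float(bonferroni_m)


def select_rcgs(
    C: CorrelationTable,
    top_k: int = 250,
    alpha: float = 1e-4,
    bonferroni_m: Union[str, float] = "per_compound",
) -> dict[str, RCGSet]:
    """Select each compound's response-correlated genes.

    Genes pass if ``p * m < alpha`` where m is the Bonferroni multiplier
    ("per_compound": genes tested for that compound, "global": all tested
    pairs, or an explicit number).  Survivors are ranked by p ascending
    (ties: larger \\|r\\| first, then gene id) and truncated to ``top_k``.
    Empty sets are allowed.
    """
    n_total = int(np.isfinite(C.P.to_numpy()).sum())
    out: dict[str, RCGSet] = {}
    for comp in C.P.index:
        p = C.P.loc[comp]
        r = C.R.loc[comp]
        tested = p.notna()
        mult = _bonferroni_multiplier(bonferroni_m, int(tested.sum()), n_total)
        passed = tested & (p * mult < alpha)
        sub = pd.DataFrame({"p": p[passed], "r": r[passed]})
        # deterministic ordering: p ascending, then |r| descending, then id
        order = sorted(
            sub.index, key=lambda g: (sub.at[g, "p"], -abs(sub.at[g, "r"]), g)
        )[:top_k]
        out[comp] = RCGSet(
            compound_id=comp,
            genes=list(order),
            weights=np.array([sub.at[g, "r"] for g in order], dtype=float),
        )
    return out


def filter_compounds(
    rcg_sets: dict[str, RCGSet], min_rcgs: int = 5
) -> dict[str, RCGSet]:
    """Keep compounds with strictly more than ``min_rcgs`` RCGs."""
    kept = {c: s for c, s in rcg_sets.items() if len(s) > min_rcgs}
    if not kept:
        logger.warning("no compound passed the >%d RCG filter", min_rcgs)
    return kept


def degree_association_test(
    C: CorrelationTable,
    net: GeneNetwork,
    compound_count_threshold: int = 100,
    alpha: float = 1e-4,
    bonferroni_m: Union[str, float] = "per_compound",
    weighted: bool = True,
) -> tuple[float, float]:
    """Do hub genes correlate with more compounds?

    Genes are split by the number of compounds they are significantly
    correlated with (strictly more than ``compound_count_threshold`` vs. the
    rest, using the same Bonferroni rule as RCG selection); the two groups'
    network degrees are compared with a two-sided Mann-Whitney rank-sum test.

    Returns
    -------
    (statistic, p_value)
    """
    P = C.P
    n_total = int(np.isfinite(P.to_numpy()).sum())
    sig = np.zeros(P.shape, dtype=bool)
    for ci, comp in enumerate(P.index):
        p = P.loc[comp]
        mult = _bonferroni_multiplier(bonferroni_m, int(p.notna().sum()), n_total)
        sig[ci] = (p * mult < alpha).fillna(False).to_numpy()
    counts = pd.Series(sig.sum(axis=0), index=P.columns)
    genes_in_net = [g for g in P.columns if g in net._index]
    if len(genes_in_net) < len(P.columns):
        logger.warning(
            "%d gene(s) absent from the network excluded from the degree test",
            len(P.columns) - len(genes_in_net),
        )
    deg = pd.Series(net.degrees(weighted=weighted), index=net.gene_ids)
    high = [g for g in genes_in_net if counts[g] > compound_count_threshold]
    low = [g for g in genes_in_net if counts[g] <= compound_count_threshold]
    if not high or not low:
        raise ValueError("one of the degree-test groups is empty")
    stat, p = stats.mannwhitneyu(deg[high], deg[low], alternative="two-sided")
    return float(stat), float(p)
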