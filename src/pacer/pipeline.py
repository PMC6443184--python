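"""End-to-end orchestration: chain network building, embedding, RCG
selection, scoring, baselines and evaluation; no computation of its own.

Every artifact is a TSV with a documented header so fixture-scale runs stay
inspectable; each run writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import baselines, evaluation
from .chemosensitivity import RCGSet, correlate, filter_compounds, select_rcgs
from .network import read_edge_list, read_gmt
from .scoring import PACER, rank_pathways

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    edges: str
    gmt: str
    expression: str
    response: str
    out_dir: str
    targets: Optional[str] = None
    zscores: Optional[str] = None
    dialect: str = "plain_tsv"
    min_weight: float = 0.0
    restart_prob: float = 0.5
    n_components: int = 100
    top_k: int = 250
    alpha: float = 1e-4
    bonferroni: str = "per_compound"
    min_rcgs: int = 5
    null_k: int = 10_000
    normalize: str = "sum"
    null_weights: str = "permute"
    seed: int = 17
    fdr: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Header row of column ids, first column row ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_targets_tsv(path) -> dict[str, set]:
    """compound TAB gene, one pair per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["compound", "gene"])
    return {c: set(g["gene"]) for c, g in df.groupby("compound")}


def read_zscores_tsv(path) -> dict[str, pd.DataFrame]:
    """Long format: compound, gene, condition, z."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for comp, sub in df.groupby("compound"):
        out[comp] = sub.pivot_table(index="gene", columns="condition", values="z")
    return out


def write_embedding_tsv(emb, path) -> None:
    d = emb.d
    cols = [f"v{i+1}" for i in range(d)]
    types = ["gene"] * emb.n_genes + ["pathway"] * emb.n_pathways
    df = pd.DataFrame(emb.V, columns=cols)
    df.insert(0, "node_type", types)
    df.insert(0, "node_id", emb.node_ids)
    df.to_csv(path, sep="\t", index=False)


def write_rcg_tsv(rcg_sets: dict[str, RCGSet], C, path) -> None:
    rows = []
    for comp, rcg in rcg_sets.items():
        for rank, (g, w) in enumerate(zip(rcg.genes, rcg.weights), start=1):
            rows.append(
                {
                    "compound": comp,
                    "gene": g,
                    "r": w,
                    "p": C.P.at[comp, g],
                    "rank": rank,
                }
            )
    pd.DataFrame(rows, columns=["compound", "gene", "r", "p", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_rcg_tsv(path) -> dict[str, RCGSet]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for comp, sub in df.groupby("compound"):
        sub = sub.sort_values("rank")
        out[comp] = RCGSet(
            compound_id=comp,
            genes=list(sub["gene"]),
            weights=sub["r"].to_numpy(dtype=float),
        )
    return out


def write_score_tsv(table, path) -> None:
    rows = []
    for comp in table.scores.index:
        s = table.scores.loc[comp]
        ordered = rank_pathways(s.to_numpy(), list(s.index))
        ranks = {pw: i + 1 for i, pw in enumerate(ordered)}
        for pw in s.index:
            row = {"compound": comp, "pathway": pw, "score": s[pw], "rank": ranks[pw]}
            if table.pvals is not None:
                row["empirical_p"] = table.pvals.at[comp, pw]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Stages: build-net -> embed -> rcg -> score -> baselines -> eval.
    Counts after every filter are logged; all artifacts are TSV.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    @_stage("build-net")
    def _build():
        net = read_edge_list(config.edges, dialect=config.dialect, min_weight=config.min_weight)
        paths = read_gmt(config.gmt, universe=net.gene_ids)
        logger.info("network: %d genes, %d pathways", net.n, paths.m)
        return net, paths

    net, paths = _build()

    @_stage("load-pharmaco")
    def _load():
        expr = read_matrix_tsv(config.expression)
        resp = read_matrix_tsv(config.response)
        off_network = [g for g in expr.index if g not in net._index]
        if off_network:
            logger.warning(
                "%d expression gene(s) absent from the network dropped", len(off_network)
            )
        expr = expr.loc[[g for g in expr.index if g in net._index]]
        return expr, resp

    expr, resp = _load()

    @_stage("embed+score")
    def _fit():
        model = PACER(
            n_components=config.n_components,
            restart_prob=config.restart_prob,
            null_k=config.null_k,
            normalize=config.normalize,
            null_weights=config.null_weights,
            random_state=config.seed,
        ).fit(net, paths)
        write_embedding_tsv(model.embedding_, out / "embedding.tsv")
        return model

    model = _fit()

    @_stage("rcg")
    def _rcg():
        C = correlate(expr, resp)
        rcg_sets = select_rcgs(
            C, top_k=config.top_k, alpha=config.alpha, bonferroni_m=config.bonferroni
        )
        kept = filter_compounds(rcg_sets, min_rcgs=config.min_rcgs)
        logger.info(
            "RCG filter: %d of %d compounds retained (> %d RCGs)",
            len(kept),
            len(rcg_sets),
            config.min_rcgs,
        )
        write_rcg_tsv(kept, C, out / "rcg.tsv")
        return C, kept

    C, kept = _rcg()

    @_stage("score")
    def _score():
        table = model.score_table(kept, with_pvalues=True)
        write_score_tsv(table, out / "scores.tsv")
        return table

    table = _score()

    @_stage("baselines")
    def _base():
        universe = list(expr.index)
        fisher_frames = []
        for comp, rcg in kept.items():
            f = baselines.fisher_enrichment(rcg, paths, universe).reset_index()
            f.insert(0, "compound", comp)
            fisher_frames.append(f)
        fisher = (
            pd.concat(fisher_frames, ignore_index=True)
            if fisher_frames
            else pd.DataFrame(columns=["compound", "pathway", "p_value", "fdr_q"])
        )
        fisher.to_csv(out / "fisher.tsv", sep="\t", index=False)
        kw = baselines.kruskal_wallis_all(C, paths, compounds=list(kept))
        kw.to_csv(out / "kw.tsv", sep="\t", index=False)
        return fisher, kw

    fisher, kw = _base()

    if config.targets:

        @_stage("eval-targets")
        def _targets():
            targets = read_targets_tsv(config.targets)
            labels = evaluation.pathway_labels_from_targets(targets, paths)
            aur = evaluation.auroc_per_compound(table.scores, labels)
            aur.rename_axis("compound").reset_index().to_csv(
                out / "auroc.tsv", sep="\t", index=False
            )

        _targets()

    if config.zscores:

        @_stage("eval-lincs")
        def _lincs():
            zs = read_zscores_tsv(config.zscores)
            universe = list(expr.index)
            rows = []
            for comp in table.scores.index:
                if comp not in zs:
                    continue
                degs = set(evaluation.lincs_degs(zs[comp]))
                ref = {
                    pw
                    for pw in paths.pathway_ids
                    if baselines.hypergeom_enrichment_p(
                        len(degs & paths.genes_in(pw)),
                        len(universe),
                        len(paths.genes_in(pw) & set(universe)),
                        len(degs & set(universe)),
                    )
                    < 0.05
                }
                if not ref:
                    continue
                fq = fisher[fisher["compound"] == comp].set_index("pathway")["fdr_q"]
                kwp = kw[kw["compound"] == comp].set_index("pathway")["p_value"]
                preds = evaluation.matched_size_prediction(
                    table.scores.loc[comp], kwp, fq, fdr=config.fdr
                )
                for method, pred in preds.items():
                    concordant = (
                        bool(pred)
                        and evaluation.concordance_test(pred, ref, paths.m) < 0.05
                    )
                    rows.append(
                        {
                            "compound": comp,
                            "method": method,
                            "n_predicted": len(pred),
                            "n_reference": len(ref),
                            "concordant": int(concordant),
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "concordance.tsv", sep="\t", index=False)

        _lincs()

    return out
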