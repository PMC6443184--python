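"""Fisher overlap enrichment (with BH-FDR) and the Kruskal-Wallis baseline."""

import math

import numpy as np
import pandas as pd
import pytest

from pacer.baselines import (
    fisher_enrichment,
    hypergeom_enrichment_p,
    kruskal_wallis_all,
    kruskal_wallis_pathway,
    rank_by_pvalue,
)
from pacer.chemosensitivity import CorrelationTable, RCGSet
from pacer.network import PathwayCollection


def hypergeom_tail_oracle(x, N, K, n):
    """Exhaustive enumeration of the upper tail via exact binomials."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(x, min(K, n) + 1)
    ) / total


def kw_rank_oracle(groups):
    """Independently coded tie-corrected Kruskal-Wallis H with chi2 p."""
    from scipy.stats import chi2

    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # midranks, 1-based
        i = j + 1
    N = len(pooled)
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(sorted_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    if tie == 0:
        return 0.0, 1.0
    H /= tie
    return H, float(chi2.sf(H, len(groups) - 1))


def collection(defs, universe):
    B = np.zeros((len(universe), len(defs)), dtype=np.int8)
    for j, genes in enumerate(defs.values()):
        for g in genes:
            B[universe.index(g), j] = 1
    return PathwayCollection(
        pathway_ids=list(defs), membership=B, gene_ids=list(universe)
    )


class TestFisherEnrichment:
    def test_full_overlap_matches_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        paths = collection({"P": universe[:10]}, universe)
        rcg = RCGSet("d", universe[:10], np.full(10, 0.5))
        res = fisher_enrichment(rcg, paths, universe)
        expected = 1 / math.comb(100, 10)
        assert res.at["P", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert res.at["P", "p_value"] == pytest.approx(
            hypergeom_tail_oracle(10, 100, 10, 10), rel=1e-9
        )

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(30)]
        paths = collection({"P": universe[:5]}, universe)
        rcg = RCGSet("d", universe[10:15], np.full(5, 0.5))
        res = fisher_enrichment(rcg, paths, universe)
        assert res.at["P", "p_value"] == 1.0

    def test_half_universe_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        paths = collection({"P": universe[:5]}, universe)
        rcg = RCGSet("d", universe[:5], np.full(5, 0.5))
        res = fisher_enrichment(rcg, paths, universe)
        assert res.at["P", "p_value"] == pytest.approx(1 / 252, rel=1e-9)

    def test_contingency_counts_sum_to_universe(self):
        universe = [f"g{i}" for i in range(40)]
        paths = collection({"P": universe[:7], "Q": universe[5:20]}, universe)
        rcg = RCGSet("d", universe[3:12], np.full(9, 0.5))
        res = fisher_enrichment(rcg, paths, universe)
        totals = res[["overlap", "rcg_only", "pathway_only", "neither"]].sum(axis=1)
        assert (totals == 40).all()

    def test_empty_universe_errors(self):
        paths = collection({"P": ["g1"]}, ["g1"])
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(RCGSet("d", ["g1"], [0.5]), paths, [])

    def test_bh_q_monotone_and_at_least_p(self, rng):
        universe = [f"g{i}" for i in range(60)]
        defs = {
            f"P{j}": [universe[i] for i in rng.choice(60, 8, replace=False)]
            for j in range(12)
        }
        paths = collection(defs, universe)
        rcg = RCGSet("d", [universe[i] for i in rng.choice(60, 15, replace=False)],
                     np.full(15, 0.5))
        res = fisher_enrichment(rcg, paths, universe)
        assert (res["fdr_q"] >= res["p_value"] - 1e-12).all()
        s = res.sort_values("p_value")
        assert (np.diff(s["fdr_q"].to_numpy()) >= -1e-12).all()


def corr_table(rvals, genes, compound="d"):
    R = pd.DataFrame([rvals], index=[compound], columns=genes)
    return CorrelationTable(R=R, P=R * np.nan, n_obs=R.notna().astype(int))


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        genes = [f"g{i}" for i in range(6)]
        paths = collection({"P": genes[:3]}, genes)
        C = corr_table([0.1, 0.2, 0.3, 0.1, 0.2, 0.3], genes)
        res = kruskal_wallis_pathway(C, "d", "P", paths)
        assert res.H_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_match_rank_oracle(self):
        genes = [f"g{i}" for i in range(6)]
        paths = collection({"P": genes[:3]}, genes)
        C = corr_table([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], genes)
        res = kruskal_wallis_pathway(C, "d", "P", paths)
        H_ref, p_ref = kw_rank_oracle([[1, 2, 3], [4, 5, 6]])
        assert res.H_statistic == pytest.approx(H_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixtures_match_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_in, n_out = rng.integers(3, 10), rng.integers(3, 15)
        # draw from a small discrete set to force ties
        vals = rng.choice([-0.2, -0.1, 0.0, 0.1, 0.3], n_in + n_out)
        genes = [f"g{i}" for i in range(n_in + n_out)]
        paths = collection({"P": genes[:n_in]}, genes)
        C = corr_table(vals, genes)
        res = kruskal_wallis_pathway(C, "d", "P", paths)
        H_ref, p_ref = kw_rank_oracle([vals[:n_in], vals[n_in:]])
        assert res.H_statistic == pytest.approx(H_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_all_values_tied_degenerate_guard(self):
        genes = [f"g{i}" for i in range(5)]
        paths = collection({"P": genes[:2]}, genes)
        C = corr_table([0.5] * 5, genes)
        res = kruskal_wallis_pathway(C, "d", "P", paths)
        assert (res.H_statistic, res.p_value) == (0.0, 1.0)

    def test_agrees_with_normal_approx_ranksum_for_large_groups(self, rng):
        from scipy.stats import mannwhitneyu

        vals = rng.standard_normal(80)
        genes = [f"g{i}" for i in range(80)]
        paths = collection({"P": genes[:30]}, genes)
        C = corr_table(vals, genes)
        res = kruskal_wallis_pathway(C, "d", "P", paths)
        _, p_rs = mannwhitneyu(
            vals[:30], vals[30:], alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        assert res.p_value == pytest.approx(p_rs, rel=0.05)

    def test_null_rejection_rates_calibrated(self):
        # correlations iid across genes: Fisher and KW reject ~ alpha
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(80)]
        paths = collection({"P": genes[:15]}, genes)
        kw_rej = fisher_rej = 0
        reps = 1000
        for _ in range(reps):
            vals = rng.standard_normal(80)
            C = corr_table(vals, genes)
            res = kruskal_wallis_pathway(C, "d", "P", paths)
            kw_rej += res.p_value < 0.05
            # "RCGs" as a uniform random subset: overlap is hypergeometric
            rcg_genes = [genes[i] for i in rng.choice(80, 12, replace=False)]
            f = fisher_enrichment(
                RCGSet("d", rcg_genes, np.full(12, 0.5)), paths, genes
            )
            fisher_rej += f.at["P", "p_value"] < 0.05
        assert 0.03 <= kw_rej / reps <= 0.07
        # discrete hypergeometric p is conservative: at or below alpha
        assert fisher_rej / reps <= 0.07

    def test_all_gene_table_variant_matches_single_calls(self, rng):
        genes = [f"g{i}" for i in range(20)]
        paths = collection({"P": genes[:5], "Q": genes[5:12]}, genes)
        C = corr_table(rng.standard_normal(20), genes)
        table = kruskal_wallis_all(C, paths)
        for _, row in table.iterrows():
            single = kruskal_wallis_pathway(C, row["compound"], row["pathway"], paths)
            assert row["H"] == pytest.approx(single.H_statistic, abs=1e-12)


class TestRankByPvalue:
    def test_ascending_order(self):
        df = pd.DataFrame({"pathway": ["a", "b", "c"], "p_value": [0.01, 0.5, 0.001]})
        assert rank_by_pvalue(df) == ["c", "a", "b"]

    def test_ties_lexicographic(self):
        df = pd.DataFrame({"pathway": ["b", "a"], "p_value": [0.5, 0.5]})
        assert rank_by_pvalue(df) == ["a", "b"]

    def test_singleton(self):
        df = pd.DataFrame({"pathway": ["only"], "p_value": [0.2]})
        assert rank_by_pvalue(df) == ["only"]
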