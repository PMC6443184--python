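"""Expression-response correlation, RCG selection and the degree test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pacer.chemosensitivity import (
    correlate,
    degree_association_test,
    filter_compounds,
    select_rcgs,
)

from conftest import random_network


def pearson_oracle(x, y):
    """Independent covariance-formula implementation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def frame(values, index, columns):
    return pd.DataFrame(values, index=index, columns=columns)


def _corr_single(x, y):
    X = frame([x], ["g"], [f"c{i}" for i in range(len(x))])
    Y = frame([y], ["d"], [f"c{i}" for i in range(len(x))])
    return correlate(X, Y)


class TestCorrelate:
    def test_identical_vectors_give_r_one(self):
        C = _corr_single([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert C.R.iloc[0, 0] == pytest.approx(1.0)

    def test_negated_vector_gives_minus_one(self):
        C = _corr_single([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        assert C.R.iloc[0, 0] == pytest.approx(-1.0)

    def test_matches_hand_coded_covariance_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        C = _corr_single(x, y)
        assert C.R.iloc[0, 0] == pytest.approx(pearson_oracle(x, y), abs=1e-10)
        assert C.R.iloc[0, 0] == pytest.approx(0.8219949365267865, abs=1e-10)

    def test_pvalue_matches_t_transform(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        y = x * 0.5 + rng.standard_normal(30)
        C = _corr_single(x, y)
        from scipy import stats

        r_ref, p_ref = stats.pearsonr(x, y)
        assert C.R.iloc[0, 0] == pytest.approx(r_ref, abs=1e-12)
        assert C.P.iloc[0, 0] == pytest.approx(p_ref, rel=1e-9)

    def test_constant_vector_recorded_missing(self, caplog):
        with caplog.at_level("WARNING"):
            C = _corr_single([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(C.R.iloc[0, 0]) and np.isnan(C.P.iloc[0, 0])
        assert "zero variance" in caplog.text

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0]
        C = _corr_single(x, y)
        expected = pearson_oracle([1, 2, 4, 5], [2, 1, 3, 6])
        assert C.R.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert C.n_obs.iloc[0, 0] == 4

    def test_invariant_under_joint_cell_permutation(self, rng):
        X = frame(rng.standard_normal((4, 10)), list("abcd"), [f"c{i}" for i in range(10)])
        Y = frame(rng.standard_normal((2, 10)), ["d1", "d2"], X.columns)
        perm = rng.permutation(10)
        C1 = correlate(X, Y)
        C2 = correlate(X.iloc[:, perm], Y.iloc[:, perm])
        pd.testing.assert_frame_equal(C1.R, C2.R)

    def test_too_few_shared_cells_errors(self):
        X = frame([[1.0, 2.0]], ["g"], ["c1", "c2"])
        Y = frame([[1.0, 2.0]], ["d"], ["c1", "c2"])
        with pytest.raises(ValueError, match="shared cell lines"):
            correlate(X, Y)


def make_corr_table(pvals, rvals, compounds=None):
    from pacer.chemosensitivity import CorrelationTable

    genes = [f"g{i:03d}" for i in range(len(pvals[0]))]
    compounds = compounds or [f"d{i}" for i in range(len(pvals))]
    P = frame(pvals, compounds, genes)
    R = frame(rvals, compounds, genes)
    return CorrelationTable(R=R, P=P, n_obs=P.notna().astype(int) * 100)


class TestSelectRCGs:
    def test_truncates_to_top_k_smallest_p(self):
        n = 300
        p = [np.linspace(1e-12, 1e-9, n)]
        r = [np.full(n, 0.5)]
        sets = select_rcgs(make_corr_table(p, r), top_k=250, bonferroni_m=1)
        (s,) = sets.values()
        assert len(s) == 250
        assert s.genes == [f"g{i:03d}" for i in range(250)]

    def test_no_significant_genes_gives_empty_set(self):
        sets = select_rcgs(make_corr_table([[0.5, 0.9]], [[0.1, 0.1]]))
        (s,) = sets.values()
        assert len(s) == 0

    def test_all_subthreshold_passers_kept_in_p_order(self):
        p = [[1e-9, 1e-7, 1e-8, 0.9]]
        r = [[0.9, 0.7, 0.8, 0.1]]
        sets = select_rcgs(make_corr_table(p, r), bonferroni_m=1)
        (s,) = sets.values()
        assert s.genes == ["g000", "g002", "g001"]
        np.testing.assert_allclose(s.weights, [0.9, 0.8, 0.7])

    def test_bonferroni_multiplier_per_compound(self):
        # 4 tested genes: p must be < alpha/4
        p = [[2e-5, 3e-5, 0.5, 0.5]]
        r = [[0.5, 0.5, 0.0, 0.0]]
        sets = select_rcgs(make_corr_table(p, r), alpha=1e-4)
        (s,) = sets.values()
        assert s.genes == ["g000"]  # 2e-5*4 < 1e-4 <= 3e-5*4

    def test_tie_break_larger_abs_r_then_gene_id(self):
        p = [[1e-9, 1e-9, 1e-9]]
        r = [[0.5, -0.8, 0.5]]
        sets = select_rcgs(make_corr_table(p, r), bonferroni_m=1)
        (s,) = sets.values()
        assert s.genes == ["g001", "g000", "g002"]

    def test_invariant_to_gene_input_order(self, rng):
        p = rng.uniform(1e-10, 1e-6, 20)
        r = rng.uniform(0.3, 0.9, 20)
        C1 = make_corr_table([p], [r])
        perm = rng.permutation(20)
        C2 = make_corr_table([p[perm]], [r[perm]])
        C2.P.columns = C2.R.columns = [f"g{i:03d}" for i in perm]
        s1 = next(iter(select_rcgs(C1, bonferroni_m=1).values()))
        s2 = next(iter(select_rcgs(C2, bonferroni_m=1).values()))
        assert s1.genes == s2.genes


class TestFilterCompounds:
    @pytest.mark.parametrize("n_rcgs,kept", [(5, False), (6, True)])
    def test_strictly_more_than_threshold(self, n_rcgs, kept):
        from pacer.chemosensitivity import RCGSet

        sets = {
            "d": RCGSet("d", [f"g{i}" for i in range(n_rcgs)], np.ones(n_rcgs) * 0.5)
        }
        assert ("d" in filter_compounds(sets, min_rcgs=5)) is kept

    def test_all_below_threshold_warns(self, caplog):
        from pacer.chemosensitivity import RCGSet

        sets = {"d": RCGSet("d", ["g1"], [0.5])}
        with caplog.at_level("WARNING"):
            out = filter_compounds(sets)
        assert out == {} and "no compound" in caplog.text


def ranksum_enumeration_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # distinct values assumed
    obs = sum(ranks[v] for v in x)
    n = len(x)
    stats = [
        sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n)
    ]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestDegreeAssociationTest:
    def _table_and_net(self, rng, n_genes=60, n_compounds=150):
        net = random_network(rng, n_genes, density=0.4)
        p = rng.uniform(0, 1, (n_compounds, n_genes))
        r = rng.uniform(-1, 1, (n_compounds, n_genes))
        C = make_corr_table(list(p), list(r))
        C.P.columns = C.R.columns = C.n_obs.columns = net.gene_ids
        return C, net

    def test_perfect_separation_tiny_p(self, rng):
        import scipy.sparse as sp

        from pacer.network import GeneNetwork

        C, _ = self._table_and_net(rng, n_genes=120)
        # first 60 genes: dense clique (high degree) and significant for every
        # compound; last 60: a sparse matching (degree 1), never significant
        A = np.zeros((120, 120))
        A[:60, :60] = 1.0
        np.fill_diagonal(A, 0.0)
        for i in range(60, 120, 2):
            A[i, i + 1] = A[i + 1, i] = 1.0
        net = GeneNetwork(gene_ids=C.P.columns.tolist(), adjacency=sp.csr_matrix(A))
        C.P.iloc[:, :60] = 1e-12
        C.P.iloc[:, 60:] = 0.99
        _, p = degree_association_test(C, net, compound_count_threshold=100)
        assert p < 1e-6

    def test_small_groups_match_enumeration_oracle(self):
        from scipy.stats import mannwhitneyu

        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(ranksum_enumeration_p(x, y), abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_type_one_error_calibration(self):
        # both groups from the same degree distribution: rejection ~ alpha
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            deg = rng.gamma(2.0, 2.0, 400)
            labels = rng.random(400) < 0.5
            _, p = mannwhitneyu(deg[labels], deg[~labels], alternative="two-sided")
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_empty_group_errors(self, rng):
        C, net = self._table_and_net(rng)
        C.P.iloc[:, :] = 0.99  # nobody passes: high group empty
        with pytest.raises(ValueError, match="empty"):
            degree_association_test(C, net, compound_count_threshold=100)
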