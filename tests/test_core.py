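import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from srcca.core import (
    combine_lists,
    heatmap_zscore,
    spearman_rho,
    srcca_rank,
    top_n,
)
from srcca.errors import DegenerateInputError, GeneLookupError, UsageError
from srcca.expression_io import ExpressionMatrix


def closed_form_rho(x, y):
    """Tie-free closed form 1 - 6*sum(d^2)/(n(n^2-1))."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    d = rx - ry
    n = len(x)
    return 1.0 - 6.0 * (d @ d) / (n * (n * n - 1.0))


class TestSpearmanRho:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # sum(d^2) = 2 -> 1 - 12/60
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_tied_ranks_use_averages(self):
        # ranks (1.5, 1.5, 3) vs (1, 2, 3): Pearson = sqrt(3)/2
        assert spearman_rho([1, 1, 2], [1, 2, 3]) == pytest.approx(
            np.sqrt(3) / 2, abs=1e-12)

    def test_contract_errors(self):
        with pytest.raises(UsageError):
            spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(UsageError):
            spearman_rho([1, 2], [2, 1])
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3.0 * y + 7.0) == pytest.approx(base, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_closed_form_on_tie_free_input(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(15).astype(float)
        y = rng.normal(size=15)
        assert spearman_rho(x, y) == pytest.approx(closed_form_rho(x, y),
                                                   abs=1e-12)


def brute_force_ranking(m, target):
    """Independent per-gene ranking: scipy.spearmanr, same tie-break rule."""
    tvec = m.gene_row(target)
    rows = []
    for g in m.gene_ids:
        if g == target:
            continue
        vec = m.gene_row(g)
        if np.ptp(vec) == 0:
            continue
        rho = scipy.stats.spearmanr(tvec, vec).statistic
        rows.append((g, rho))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows


class TestSrccaRank:
    def test_duplicate_of_target_ranks_first(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=8)
        values = np.vstack([t, t, rng.normal(size=(3, 8))])
        m = ExpressionMatrix(np.abs(values),
                             ["TARGET", "COPY", "a", "b", "c"],
                             [f"c{i}" for i in range(8)], "log2tpm1")
        ranked = srcca_rank(m, "TARGET")
        assert ranked.genes[0] == "COPY"
        assert ranked.rho[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix(rng.integers(0, 20, size=(5, 6)).astype(float),
                             [f"g{i}" for i in range(5)],
                             [f"c{j}" for j in range(6)], "log2tpm1")
        ranked = srcca_rank(m, "g0")
        oracle = brute_force_ranking(m, "g0")
        assert ranked.genes == [g for g, _ in oracle]
        np.testing.assert_allclose(ranked.rho, [r for _, r in oracle],
                                   atol=1e-12)

    def test_constant_gene_excluded_with_audit(self):
        rng = np.random.default_rng(4)
        values = rng.integers(1, 9, size=(4, 6)).astype(float)
        values[2] = 5.0
        m = ExpressionMatrix(values, ["t", "a", "flat", "b"],
                             [f"c{j}" for j in range(6)], "log2tpm1")
        ranked = srcca_rank(m, "t")
        assert "flat" not in ranked.genes
        assert ranked.excluded == ["flat"]

    def test_invariant_to_cell_permutation(self, random_matrix):
        m = random_matrix(n_genes=10, n_cells=9, seed=6)
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n_cells)
        shuffled = ExpressionMatrix(m.values[:, perm],
                                    list(m.gene_ids),
                                    [m.cell_ids[i] for i in perm], m.unit)
        a = srcca_rank(m, "G0")
        b = srcca_rank(shuffled, "G0")
        assert a.genes == b.genes
        np.testing.assert_allclose(a.rho, b.rho, atol=1e-12)

    def test_missing_target_reports_candidates(self, random_matrix):
        with pytest.raises(GeneLookupError):
            srcca_rank(random_matrix(), "NOPE")

    def test_constant_target_is_degenerate(self):
        m = ExpressionMatrix(np.array([[1.0, 1.0, 1.0], [1, 2, 3]]),
                             ["t", "a"], ["c1", "c2", "c3"], "log2tpm1")
        with pytest.raises(DegenerateInputError):
            srcca_rank(m, "t")


class TestTopN:
    def test_full_length_and_prefix_property(self, random_matrix):
        ranked = srcca_rank(random_matrix(n_genes=12, n_cells=8, seed=9), "G0")
        assert top_n(ranked, len(ranked.genes)) == ranked.genes
        assert set(top_n(ranked, 5)) <= set(top_n(ranked, 10))

    def test_oversized_request_errors(self, random_matrix):
        ranked = srcca_rank(random_matrix(seed=2), "G0")
        with pytest.raises(UsageError, match=str(len(ranked.genes))):
            top_n(ranked, len(ranked.genes) + 1)


class TestHeatmap:
    def test_row_zscore_closed_form(self):
        m = ExpressionMatrix(np.array([[3.0, 2.0, 1.0], [1.0, 2.0, 3.0]]),
                             ["t", "g"], ["c1", "c2", "c3"], "log2tpm1")
        hm = heatmap_zscore(m, "t", ["g"])
        # cells ordered by t descending: c1, c2, c3 -> g = (1, 2, 3)
        np.testing.assert_allclose(hm.values[0],
                                   [-1.224744871, 0.0, 1.224744871])

    def test_constant_row_zeroed_and_flagged(self):
        m = ExpressionMatrix(np.array([[3.0, 2.0, 1.0], [5.0, 5.0, 5.0]]),
                             ["t", "flat"], ["c1", "c2", "c3"], "log2tpm1")
        hm = heatmap_zscore(m, "t", ["flat"])
        assert hm.constant_genes == ["flat"]
        np.testing.assert_array_equal(hm.values[0], 0.0)

    def test_columns_sorted_by_target_descending(self, random_matrix):
        m = random_matrix(n_genes=6, n_cells=10, seed=13)
        hm = heatmap_zscore(m, "G0", ["G1", "G2"])
        key = dict(zip(m.cell_ids, m.gene_row("G0")))
        assert sorted(hm.cells, key=lambda c: (-key[c], c)) == hm.cells
        assert sorted(hm.cells) == sorted(m.cell_ids)

    def test_rows_standardised(self, random_matrix):
        m = random_matrix(n_genes=6, n_cells=10, seed=14)
        hm = heatmap_zscore(m, "G0", ["G1", "G2", "G3"])
        np.testing.assert_allclose(hm.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(hm.values.std(axis=1), 1.0, atol=1e-9)

    def test_empty_gene_set_rejected(self, random_matrix):
        with pytest.raises(UsageError):
            heatmap_zscore(random_matrix(), "G0", [])


class TestCombineLists:
    def test_identical_sets(self):
        res = combine_lists({"A": {"x", "y"}, "B": {"x", "y"}})
        assert res.core == {"x", "y"}
        assert res.region("A") == frozenset()

    def test_three_set_enumeration(self):
        res = combine_lists({"A": {"g1", "g2", "g3"},
                             "B": {"g2", "g3", "g4"},
                             "C": {"g3"}})
        assert res.core == {"g3"}
        assert res.region("A") == {"g1"}
        assert res.region("A", "B") == {"g2"}
        assert sum(len(v) for v in res.regions.values()) == 4

    def test_disjoint_sets(self):
        res = combine_lists({"A": {"a"}, "B": {"b"}})
        assert res.core == frozenset()
        assert res.region("A") == {"a"} and res.region("B") == {"b"}

    def test_duplicate_names_rejected(self):
        with pytest.raises(UsageError):
            combine_lists({1: {"a"}, "1": {"b"}})

    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None)
    def test_region_conservation(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        universe = [f"g{i}" for i in range(30)]
        sets = {f"S{i}": set(rng.choice(universe,
                                        size=int(rng.integers(0, 20)),
                                        replace=False))
                for i in range(k)}
        res = combine_lists(sets)
        union = set().union(*sets.values())
        assert sum(len(v) for v in res.regions.values()) == len(union)
        assert res.union == union
        # regions are pairwise disjoint
        seen = set()
        for members in res.regions.values():
            assert not (seen & members)
            seen |= members
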