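import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microclust import (
    CombinedConfig,
    OTUTable,
    aitchison,
    bray_curtis,
    combined_metric,
    generalized_unifrac,
    generate_tree,
    normalize_by_max,
    parse_newick,
    relative_abundance,
    unweighted_unifrac,
    weighted_unifrac,
)
from microclust.io import FormatError
from conftest import make_random_table

# ---------------------------------------------------------------------------
# naive UniFrac oracle: enumerate every non-root branch, recompute its
# descendant leaf set from scratch, and accumulate the defining sums directly
# ---------------------------------------------------------------------------

def _branches(tree):
    for node in tree.root.traverse():
        if node is tree.root:
            continue
        tips = [t.name for t in node.tips()] or [node.name]
        yield float(node.length or 0.0), set(tips)


def oracle_uu(table, tree, i, j):
    pres = {o: (table.counts[r, i] > 0, table.counts[r, j] > 0)
            for r, o in enumerate(table.otu_ids)}
    num = den = 0.0
    for length, tips in _branches(tree):
        in_i = any(pres[t][0] for t in tips)
        in_j = any(pres[t][1] for t in tips)
        if in_i or in_j:
            den += length
            if in_i != in_j:
                num += length
    return num / den if den else 0.0


def oracle_gu(table, tree, i, j, gamma):
    ab = relative_abundance(table).abundances
    share = {o: (ab[r, i], ab[r, j]) for r, o in enumerate(table.otu_ids)}
    num = den = 0.0
    for length, tips in _branches(tree):
        pa = sum(share[t][0] for t in tips)
        pb = sum(share[t][1] for t in tips)
        s = pa + pb
        if s > 0:
            num += length * s**gamma * abs(pa - pb) / s
            den += length * s**gamma
    return num / den if den else 0.0


def oracle_wu(table, tree, i, j):
    return oracle_gu(table, tree, i, j, gamma=1.0)


def random_tree_and_table(seed, max_leaves=12):
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(3, max_leaves + 1))
    n_samples = int(rng.integers(2, 6))
    tree = generate_tree(n_leaves, seed=seed)
    counts = rng.integers(0, 20, size=(n_leaves, n_samples))
    counts[rng.random(counts.shape) < 0.35] = 0  # sparse, distinct presence patterns
    counts[rng.integers(0, n_leaves), :] += 1  # no empty sample
    table = OTUTable(
        counts, [f"OTU_{i + 1}" for i in range(n_leaves)],
        [f"S{j + 1}" for j in range(n_samples)],
    )
    return table, tree


class TestBrayCurtis:
    def test_identity_and_maximal(self):
        table = OTUTable(np.array([[3, 3, 5], [2, 2, 0]]), ["A", "B"], ["S1", "S2", "S3"])
        d = bray_curtis(table).values
        assert d[0, 1] == pytest.approx(0.0)
        # disjoint supports at different depths -> 1
        t2 = OTUTable(np.array([[7, 0], [0, 3]]), ["A", "B"], ["S1", "S2"])
        assert bray_curtis(t2).values[0, 1] == pytest.approx(1.0)

    def test_hand_worked_value(self):
        # sum|nA-nB| = 4+0+4+0 = 8, sum(nA+nB) = 6+6+4+4 = 20
        table = OTUTable(
            np.array([[5, 1], [3, 3], [0, 4], [2, 2]]), list("WXYZ"), ["A", "B"]
        )
        assert bray_curtis(table).values[0, 1] == pytest.approx(0.4)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 7))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_depth_scaling_invariance(self, seed, factor):
        """Multiplying every column by a common integer leaves BC unchanged."""
        table = make_random_table(np.random.default_rng(seed), p=9, n=5, depth=120)
        scaled = OTUTable(table.counts * factor, table.otu_ids, table.sample_ids)
        assert np.allclose(bray_curtis(table).values, bray_curtis(scaled).values)

    def test_count_sensitivity(self):
        """Unlike UU, BC reacts to count changes that keep the zero pattern."""
        table = OTUTable(np.array([[5, 1], [5, 9]]), ["A", "B"], ["S1", "S2"])
        bumped = OTUTable(np.array([[5, 4], [5, 6]]), ["A", "B"], ["S1", "S2"])
        assert not np.allclose(bray_curtis(table).values, bray_curtis(bumped).values)


class TestUniFracFamily:
    def test_worked_three_leaf_values(self, three_leaf_tree, three_leaf_table):
        uu = unweighted_unifrac(three_leaf_table, three_leaf_tree).values[0, 1]
        wu = weighted_unifrac(three_leaf_table, three_leaf_tree).values[0, 1]
        assert uu == pytest.approx(0.4)  # (1+1)/(1+1+1+2)
        assert wu == pytest.approx(0.25)  # 1.0/4.0

    def test_identical_patterns_zero(self, three_leaf_tree):
        table = OTUTable(np.array([[3, 6], [0, 0], [5, 10]]), ["A", "B", "C"], ["S1", "S2"])
        assert unweighted_unifrac(table, three_leaf_tree).values[0, 1] == 0.0
        t2 = OTUTable(np.array([[3, 6], [1, 2], [5, 10]]), ["A", "B", "C"], ["S1", "S2"])
        assert weighted_unifrac(t2, three_leaf_tree).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_two_leaf(self):
        tree = parse_newick("(A:1,B:1);")
        table = OTUTable(np.array([[4, 0], [0, 9]]), ["A", "B"], ["S1", "S2"])
        assert unweighted_unifrac(table, tree).values[0, 1] == pytest.approx(1.0)

    def test_uu_abundance_invariance(self):
        """UU depends only on the zero pattern."""
        rng = np.random.default_rng(11)
        table, tree = random_tree_and_table(11)
        bumped = table.counts + (table.counts > 0) * rng.integers(
            0, 50, size=table.counts.shape
        )
        t2 = OTUTable(bumped, table.otu_ids, table.sample_ids)
        assert np.allclose(
            unweighted_unifrac(table, tree).values,
            unweighted_unifrac(t2, tree).values,
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_oracle(self, seed):
        table, tree = random_tree_and_table(seed)
        uu = unweighted_unifrac(table, tree).values
        wu = weighted_unifrac(table, tree).values
        gu = generalized_unifrac(table, tree, gamma=0.5).values
        for i in range(table.n_samples):
            for j in range(i + 1, table.n_samples):
                assert uu[i, j] == pytest.approx(oracle_uu(table, tree, i, j), abs=1e-10)
                assert wu[i, j] == pytest.approx(oracle_wu(table, tree, i, j), abs=1e-10)
                assert gu[i, j] == pytest.approx(
                    oracle_gu(table, tree, i, j, 0.5), abs=1e-10
                )

    @pytest.mark.parametrize("seed", range(6))
    def test_gu_gamma_one_equals_weighted(self, seed):
        table, tree = random_tree_and_table(seed)
        assert np.allclose(
            generalized_unifrac(table, tree, gamma=1.0).values,
            weighted_unifrac(table, tree).values,
            atol=1e-12,
        )

    def test_matches_skbio(self):
        """Cross-check against an independent UniFrac implementation."""
        from skbio.diversity import beta_diversity

        table, tree = random_tree_and_table(21)
        for metric, ours in (
            ("unweighted_unifrac", unweighted_unifrac(table, tree).values),
            ("weighted_unifrac", weighted_unifrac(table, tree).values),
        ):
            ref = beta_diversity(
                metric,
                table.counts.T,
                ids=table.sample_ids,
                tree=tree.root,
                taxa=table.otu_ids,
                **({"normalized": True} if metric == "weighted_unifrac" else {}),
            )
            assert np.allclose(ours, ref.data, atol=1e-10)

    def test_gamma_out_of_range(self, three_leaf_tree, three_leaf_table):
        with pytest.raises(ValueError):
            generalized_unifrac(three_leaf_table, three_leaf_tree, gamma=1.5)

    def test_empty_sample_named(self, three_leaf_tree):
        table = OTUTable(np.array([[1, 0], [1, 0], [1, 1]]), ["A", "B", "C"], ["S1", "S2"])
        table.counts[2, 1] = 0
        table.counts[0, 0] = 2  # keep S1 populated
        with pytest.raises(FormatError, match="S2"):
            unweighted_unifrac(
                OTUTable(table.counts, table.otu_ids, table.sample_ids), three_leaf_tree
            )


class TestAitchison:
    def test_identical_columns_zero(self):
        table = OTUTable(np.array([[4, 4], [6, 6]]), ["A", "B"], ["S1", "S2"])
        assert aitchison(table).values[0, 1] == pytest.approx(0.0)

    def test_two_part_hand_value(self):
        # CLR difference for (1,1) vs (1,3) is (ln3/2, -ln3/2): distance ln3/sqrt2
        table = OTUTable(np.array([[1, 1], [1, 3]]), ["A", "B"], ["S1", "S2"])
        d = aitchison(table, pseudocount=0).values[0, 1]
        assert d == pytest.approx(math.log(3) / math.sqrt(2), abs=1e-12)

    def test_scale_invariance_without_pseudocount(self):
        table = OTUTable(np.array([[2, 4], [3, 1], [5, 7]]), ["A", "B", "C"], ["S1", "S2"])
        scaled = OTUTable(
            table.counts * np.array([1, 13]), table.otu_ids, table.sample_ids
        )
        assert np.allclose(
            aitchison(table, 0).values, aitchison(scaled, 0).values, atol=1e-12
        )

    def test_pseudocount_validation(self):
        table = OTUTable(np.array([[1, 0], [1, 3]]), ["A", "B"], ["S1", "S2"])
        with pytest.raises(ValueError):
            aitchison(table, pseudocount=-1)
        with pytest.raises(ValueError):
            aitchison(table, pseudocount=0)  # zeros present


class TestCombined:
    def test_normalize_by_max(self, two_block_dm):
        normed = normalize_by_max(two_block_dm)
        assert normed.values.max() == pytest.approx(1.0)
        assert np.allclose(normed.values, two_block_dm.values / 0.9)
        again = normalize_by_max(normed)
        assert np.allclose(again.values, normed.values)

    def test_order_preserved(self, two_block_dm):
        normed = normalize_by_max(two_block_dm)
        orig = two_block_dm.condensed()
        new = normed.condensed()
        assert np.array_equal(np.argsort(orig), np.argsort(new))

    def test_endpoints(self, three_leaf_tree):
        table = OTUTable(
            np.array([[5, 0, 1], [0, 5, 1], [5, 5, 8]]), ["A", "B", "C"],
            ["S1", "S2", "S3"],
        )
        uu = normalize_by_max(unweighted_unifrac(table, three_leaf_tree))
        bc = normalize_by_max(bray_curtis(table))
        assert np.allclose(
            combined_metric(table, three_leaf_tree, CombinedConfig(1.0)).values, uu.values
        )
        assert np.allclose(
            combined_metric(table, three_leaf_tree, CombinedConfig(0.0)).values, bc.values
        )
        mid = combined_metric(table, three_leaf_tree, CombinedConfig(0.5)).values
        assert np.allclose(mid, 0.5 * uu.values + 0.5 * bc.values)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            CombinedConfig(1.5)


class TestMetricProperties:
    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_diagonal_range_permutation(self, seed):
        table, tree = random_tree_and_table(seed)
        rng = np.random.default_rng(seed + 100)
        perm = rng.permutation(table.n_samples)
        permuted = OTUTable(
            table.counts[:, perm], table.otu_ids,
            [table.sample_ids[p] for p in perm],
        )
        for fn in (
            lambda t: bray_curtis(t),
            lambda t: unweighted_unifrac(t, tree),
            lambda t: weighted_unifrac(t, tree),
            lambda t: combined_metric(t, tree),
        ):
            d = fn(table)
            v = d.values
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 0)
            assert v.min() >= 0 and v.max() <= 1 + 1e-12
            dp = fn(permuted).values
            assert np.allclose(dp, v[np.ix_(perm, perm)], atol=1e-12)
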