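import itertools
import math

import numpy as np
import pandas as pd
import pytest

from radsig import strain_similarity as sim
from radsig.snp_selection import MISSING


def make_pattern(alleles):
    n = len(alleles)
    loci = pd.DataFrame({"chrom": ["1"] * n, "pos": np.arange(1, n + 1) * 10})
    return sim.Pattern(loci, np.asarray(alleles, dtype=object))


class TestSimilarityScore:
    def test_extremes_and_arithmetic(self):
        pat = make_pattern(["G"] * 20)
        assert sim.similarity_score(["G"] * 20, pat) == (100.0, 20)
        assert sim.similarity_score(["A"] * 20, pat) == (0.0, 20)
        score, n = sim.similarity_score(["G"] * 19 + ["A"], pat)
        assert score == pytest.approx(95.0)

    def test_missing_calls_excluded_from_denominator(self):
        pat = make_pattern(["G", "G", "G", "G"])
        score, n = sim.similarity_score(["G", MISSING, "A", MISSING], pat)
        assert (score, n) == (50.0, 2)
        score, n = sim.similarity_score([MISSING] * 4, pat)
        assert math.isnan(score) and n == 0

    def test_locus_order_invariance(self):
        rng = np.random.default_rng(0)
        alleles = rng.choice(["A", "G"], 30)
        pat_alleles = rng.choice(["A", "G"], 30)
        perm = rng.permutation(30)
        s1, _ = sim.similarity_score(alleles, make_pattern(pat_alleles))
        s2, _ = sim.similarity_score(alleles[perm], make_pattern(pat_alleles[perm]))
        assert s1 == s2


def medcouple_bruteforce(values):
    """Independent O(n^2) enumeration of the medcouple kernel."""
    x = np.sort(np.asarray(values, float))
    med = np.median(x)
    left = [v for v in x if v <= med]
    right = [v for v in x if v >= med]
    k = int(np.sum(x == med))
    hs = []
    tie_rank = 0
    for i, xi in enumerate(left):
        for j, xj in enumerate(right):
            if xi == med and xj == med:
                # signed kernel for pairs tied at the median
                # indices: i counts from the smallest tied value upward,
                # j from the median tie going up; standard -1/0/+1 rule
                p = len(left) - 1 - i  # rank of xi among ties, from top
                q = j
                hs.append(float(np.sign(q - p)))
            elif xi == xj:
                hs.append(0.0)
            else:
                hs.append(((xj - med) - (med - xi)) / (xj - xi))
    return float(np.median(hs))


class TestMedcouple:
    def test_symmetric_sample_is_zero(self):
        assert sim.medcouple([1, 2, 3, 4, 5]) == pytest.approx(0.0)

    def test_known_skewed_example(self):
        # brute-force enumeration of {1,2,3,4,10}: kernel median is 0
        assert sim.medcouple([1, 2, 3, 4, 10]) == pytest.approx(
            medcouple_bruteforce([1, 2, 3, 4, 10])
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=11) ** 3  # continuous, no ties
        assert sim.medcouple(x) == pytest.approx(medcouple_bruteforce(x), abs=1e-12)

    def test_right_skew_is_positive(self):
        rng = np.random.default_rng(7)
        assert sim.medcouple(rng.exponential(size=200)) > 0

    def test_bounds_and_location_scale_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(size=50)
        mc = sim.medcouple(x)
        assert -1.0 <= mc <= 1.0
        assert sim.medcouple(3.0 * x + 7.0) == pytest.approx(mc, abs=1e-12)

    def test_constant_sample(self):
        assert sim.medcouple([2.0, 2.0, 2.0]) == 0.0


class TestAdjustedBoxplot:
    def test_symmetric_data_reduces_to_standard_fences(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])  # MC = 0
        out = sim.adjusted_boxplot_outliers(x)
        q1, q3 = np.percentile(x, [25, 75])
        assert out["medcouple"].iloc[0] == pytest.approx(0.0)
        assert out["fence_lower"].iloc[0] == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert out["fence_upper"].iloc[0] == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_planted_high_scores_flagged(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(
            {
                "strain": [f"bg{i}" for i in range(60)] + ["hit95", "hit87"],
                "score": list(np.clip(rng.normal(50, 5, 60), 0, 100)) + [95.0, 87.0],
            }
        )
        out = sim.adjusted_boxplot_outliers(scores)
        high = set(out.loc[out["side"] == "high", "strain"])
        assert high == {"hit95", "hit87"}

    def test_skew_adjustment_flags_fewer_than_plain_rule(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(10.0, size=300)
        out = sim.adjusted_boxplot_outliers(x)
        q1, q3 = np.percentile(x, [25, 75])
        plain_high = int((x > q3 + 1.5 * (q3 - q1)).sum())
        adjusted_high = int((out["side"] == "high").sum())
        assert adjusted_high < plain_high

    def test_needs_five_scores(self):
        with pytest.raises(ValueError):
            sim.adjusted_boxplot_outliers([1.0, 2.0, 3.0])


class TestJukesCantor:
    def test_identical_vectors(self):
        assert sim.jukes_cantor(["A", "G", "A"], ["A", "G", "A"]) == 0.0

    def test_closed_form(self):
        # 3 of 10 mismatches -> p = 0.3
        a = ["A"] * 10
        b = ["G"] * 3 + ["A"] * 7
        assert sim.jukes_cantor(a, b) == pytest.approx(-0.75 * math.log(0.6))

    def test_domain_boundary_is_infinite(self):
        a, b = ["A"] * 4, ["G", "G", "G", "A"]
        with pytest.warns(UserWarning):
            assert math.isinf(sim.jukes_cantor(a, b))

    def test_missing_pairs_excluded(self):
        a = ["A", MISSING, "A", "A"]
        b = ["G", "G", "A", MISSING]
        # compared loci: 1st (mismatch) and 3rd (match) -> p = 0.5
        assert sim.jukes_cantor(a, b) == pytest.approx(-0.75 * math.log(1 - 2 / 3))

    def test_strictly_increasing_in_mismatch_fraction(self):
        ds = [
            sim.jukes_cantor(["A"] * 20, ["G"] * m + ["A"] * (20 - m))
            for m in range(0, 14)
        ]
        assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))


def random_ultrametric(labels, rng):
    """Distance matrix of a random ultrametric tree (random merge heights)."""
    clusters = [[lab] for lab in labels]
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    height = 0.0
    while len(clusters) > 1:
        height += rng.uniform(0.5, 2.0)
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d.loc[a, b] = d.loc[b, a] = 2 * height
        clusters[i] = clusters[i] + clusters.pop(j)
    return d


def tree_leaf_distances(tree):
    """Path distances between all leaf pairs (2 * LCA height)."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return [node.name]
        below = [walk(c) for c in node.children]
        for g1, g2 in itertools.combinations(below, 2):
            for a in g1:
                for b in g2:
                    out[frozenset((a, b))] = 2 * node.height
        return [leaf for grp in below for leaf in grp]

    walk(tree)
    return out


class TestUpgma:
    def test_two_leaves(self):
        d = pd.DataFrame([[0.0, 4.0], [4.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = sim.upgma(d)
        assert tree.height == pytest.approx(2.0)
        assert sorted(tree.leaf_names()) == ["A", "B"]
        assert sim.write_newick(tree) == "(A:2,B:2);"

    def test_three_leaf_hand_computation(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = sim.upgma(d)
        assert sim.write_newick(tree) == "((A:1,B:1):2,C:3);"

    def test_reproduces_ultrametric_input_exactly(self):
        rng = np.random.default_rng(12)
        labels = [f"L{i}" for i in range(8)]
        d = random_ultrametric(labels, rng)
        tree = sim.upgma(d)
        dist = tree_leaf_distances(tree)
        for a in labels:
            for b in labels:
                if a != b:
                    assert dist[frozenset((a, b))] == pytest.approx(
                        d.loc[a, b], rel=1e-9
                    )

    def test_output_always_ultrametric(self):
        rng = np.random.default_rng(13)
        n = 7
        m = rng.uniform(1, 10, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"S{i}" for i in range(n)]
        tree = sim.upgma(pd.DataFrame(m, index=labels, columns=labels))

        def heights(node, acc):
            if node.is_leaf:
                acc.append(node.height)
            for c in node.children:
                assert c.height <= node.height + 1e-12
                heights(c, acc)
            return acc

        assert all(h == 0 for h in heights(tree, []))

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(14)
        n = 9
        m = rng.uniform(1, 10, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"S{i}" for i in range(n)]
        tree = sim.upgma(pd.DataFrame(m, index=labels, columns=labels))
        link = hierarchy.linkage(squareform(m), method="average")

        def merge_heights(node, acc):
            if not node.is_leaf:
                acc.append(node.height)
                for c in node.children:
                    merge_heights(c, acc)
            return acc

        ours = sorted(2 * h for h in merge_heights(tree, []))
        np.testing.assert_allclose(ours, sorted(link[:, 2]), rtol=1e-9)

    def test_invalid_matrix_rejected(self):
        bad = pd.DataFrame([[0.0, -1.0], [-1.0, 0.0]], index=["A", "B"],
                           columns=["A", "B"])
        with pytest.raises(ValueError):
            sim.upgma(bad)


class TestNewick:
    def test_roundtrip_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(15)
        labels = [f"T{i}" for i in range(6)]
        d = random_ultrametric(labels, rng)
        tree = sim.upgma(d)
        text = sim.write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for a in labels:
            for b in labels:
                if a != b:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        d.loc[a, b], rel=1e-9
                    )
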