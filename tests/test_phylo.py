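"""Distances, neighbor joining (vs additive-matrix exactness and an
independent implementation), bootstrap supports and the divergence
regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from skbio import DistanceMatrix

from apemeth import phylo
from apemeth import synthetic_data as sd
from tests.conftest import make_sheet


class TestSequenceDistances:
    def test_identical_sequences_zero(self):
        blocks = [{"A": "ACGT" * 10, "B": "ACGT" * 10}]
        d = phylo.sequence_pairwise_distances(blocks)
        assert d["A", "B"] == 0.0

    def test_one_substitution_per_kb(self):
        s = "A" * 1000
        t = "A" * 999 + "C"
        d = phylo.sequence_pairwise_distances([{"A": s, "B": t}])
        assert d["A", "B"] == pytest.approx(1.0)

    def test_gapped_columns_fully_excluded(self):
        # the gap column differs but must not contribute to either side
        blocks = [{"A": "AAAA", "B": "AA-A"}]
        d = phylo.sequence_pairwise_distances(blocks)
        assert d["A", "B"] == 0.0
        blocks = [{"A": "CAAA", "B": "AA-A"}]
        d = phylo.sequence_pairwise_distances(blocks)
        assert d["A", "B"] == pytest.approx(1 / 3 * 1000)

    def test_missing_taxon_raises(self):
        with pytest.raises(ValueError):
            phylo.sequence_pairwise_distances([{"A": "AC"}, {"A": "AC", "B": "AC"}])

    def test_simulated_truth_identity(self, ape_tree):
        blocks, truth = sd.simulate_alignment_blocks(
            ape_tree, length=4000, rate=5.0, indel_rate=0.02, seed=3, n_blocks=2
        )
        d = phylo.sequence_pairwise_distances(blocks)
        truth = truth.filter(sorted(truth.ids))  # align taxon order
        np.testing.assert_allclose(d.data, truth.data, atol=1e-9)

    def test_zero_rate_zero_distances(self, ape_tree):
        blocks, truth = sd.simulate_alignment_blocks(ape_tree, 500, rate=0.0, seed=4)
        assert truth.data.max() == 0.0
        assert phylo.sequence_pairwise_distances(blocks).data.max() == 0.0


class TestMethylationDistances:
    def test_identical_profiles_zero(self):
        sheet = make_sheet(2, taxa=("Human", "Pan"))
        betas = pd.DataFrame(0.5, index=["p1", "p2"], columns=sheet.index)
        d = phylo.methylation_distances(betas, sheet)
        assert d["Human", "Pan"] == 0.0

    def test_single_probe_full_range(self):
        sheet = make_sheet(2, taxa=("Human", "Pan"))
        betas = pd.DataFrame(
            [[0.0, 0.0, 1.0, 1.0]], index=["p1"], columns=sheet.index
        )
        d = phylo.methylation_distances(betas, sheet)
        assert d["Human", "Pan"] == pytest.approx(1.0)

    def test_euclidean_arithmetic(self):
        sheet = make_sheet(2, taxa=("Human", "Pan"))
        betas = pd.DataFrame(
            {s: [0.0, 0.0] for s in sheet.index[:2]} | {s: [0.3, 0.4] for s in sheet.index[2:]},
            index=["p1", "p2"],
        )
        d = phylo.methylation_distances(betas, sheet)
        assert d["Human", "Pan"] == pytest.approx(0.5)  # sqrt(0.09 + 0.16)

    def test_sample_order_invariant(self, cohort_small):
        betas, sheet, _ = cohort_small
        d1 = phylo.methylation_distances(betas, sheet)
        perm = betas.sample(frac=1, axis=1, random_state=0)
        d2 = phylo.methylation_distances(perm, sheet)
        np.testing.assert_allclose(d1.data, d2.data)

    def test_missing_values_pairwise_rescaled(self):
        sheet = make_sheet(2, taxa=("Human", "Pan"))
        betas = pd.DataFrame(
            {s: [0.0, 0.0] for s in sheet.index[:2]} | {s: [0.4, 0.4] for s in sheet.index[2:]},
            index=["p1", "p2"],
        )
        betas.iloc[1, 0] = np.nan  # drops probe 2 for the Human mean? no: mean of available
        d_full = phylo.methylation_distances(betas, sheet)
        assert d_full["Human", "Pan"] == pytest.approx(np.sqrt(0.16 + 0.16))


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive lengths; returns (skbio tree,
    patristic DistanceMatrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [skbio.TreeNode(name=l, length=float(rng.uniform(0.1, 2.0))) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.uniform(0.1, 2.0)), children=[a, b])
        nodes.append(parent)
    root = skbio.TreeNode(children=nodes)
    dm = root.tip_tip_distances()
    order = np.argsort(list(dm.ids))
    data = dm.data[np.ix_(order, order)]
    return root, DistanceMatrix(data, ids=sorted(dm.ids))


def quartet_split(D, quartet):
    """Four-point-condition oracle: the quartet pairing with the
    smallest pair-sum is the split."""
    a, b, c, d = quartet
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, d])]): D[a, b] + D[c, d],
        frozenset([frozenset([a, c]), frozenset([b, d])]): D[a, c] + D[b, d],
        frozenset([frozenset([a, d]), frozenset([b, c])]): D[a, d] + D[b, c],
    }
    return min(sums, key=sums.get)


def induced_quartet(parts, taxa, quartet):
    """The quartet split induced by a tree's bipartition set."""
    for side in parts:
        inside = [t for t in quartet if t in side]
        outside = [t for t in quartet if t not in side]
        if len(inside) == 2:
            return frozenset([frozenset(inside), frozenset(outside)])
    # star-like: no informative bipartition; treat as unresolved
    return None


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        D = DistanceMatrix(
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
            ids=list("ABCD"),
        )
        tree = phylo.neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == [1.0]
        assert phylo.tree_bipartitions(tree) == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float), ids="ABC")
        tree = phylo.neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_equidistant_matrix_zero_internal(self):
        D = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("ABCD"))
        tree = phylo.neighbor_joining(D)
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == [0.0]

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ids="AB"))

    def test_additive_recovery_random_trees(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            true_tree, D = random_additive_tree(rng, n)
            est = phylo.neighbor_joining(D)
            # patristic distances reproduced exactly
            dm_est = est.tip_tip_distances()
            order = np.argsort(list(dm_est.ids))
            np.testing.assert_allclose(
                dm_est.data[np.ix_(order, order)], D.data, atol=1e-9
            )
            # topology identical to the generating tree
            true_parts = phylo.tree_bipartitions(true_tree)
            assert phylo.tree_bipartitions(est) == true_parts

    def test_agrees_with_skbio_nj(self, rng):
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            n = int(rng.integers(4, 8))
            _, D = random_additive_tree(rng, n)
            ours = phylo.tree_bipartitions(phylo.neighbor_joining(D))
            theirs = phylo.tree_bipartitions(skbio_nj(D))
            assert ours == theirs


class TestBootstrap:
    def test_single_replicate_supports_binary(self, cohort_small):
        betas, sheet, _ = cohort_small
        tree = phylo.bootstrap_supports(betas.iloc[:300], sheet, n_boot=1, seed=0)
        sup = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert set(sup) <= {0, 100}

    def test_seeded_determinism(self, cohort_small):
        betas, sheet, _ = cohort_small
        t1 = phylo.bootstrap_supports(betas.iloc[:300], sheet, n_boot=20, seed=5)
        t2 = phylo.bootstrap_supports(betas.iloc[:300], sheet, n_boot=20, seed=5)
        assert str(t1) == str(t2)

    def test_strong_signal_high_support(self, cohort_small):
        betas, sheet, _ = cohort_small
        tree = phylo.bootstrap_supports(betas, sheet, n_boot=100, seed=2)
        parts = phylo.tree_bipartitions(tree)
        assert frozenset({"Human", "Pan"}) in parts or frozenset({"Gorilla", "Pongo"}) in parts
        sup = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert min(sup) >= 80  # smoke check at n_boot=100; the rigorous
        # support bound runs at full depth in the acceptance suite


class TestRegression:
    def test_perfectly_linear(self):
        ids = list("ABCD")
        X = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
        mdm = DistanceMatrix(2 * X + 0, ids=ids)
        sdm = DistanceMatrix(X, ids=ids)
        slope, intercept, r2, p = phylo.regress_divergences(mdm, sdm)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_methylation_zero_slope(self):
        ids = list("ABCD")
        X = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
        ones = np.ones((4, 4)) - np.eye(4)
        slope, _, _, _ = phylo.regress_divergences(DistanceMatrix(ones, ids=ids),
                                                   DistanceMatrix(X, ids=ids))
        assert slope == pytest.approx(0.0)

    def test_three_point_closed_form(self):
        # OLS on the 3 pairs of a 3-taxon comparison, hand computed
        mdm = DistanceMatrix(np.array([[0, 1.0, 2.0], [1.0, 0, 4.0], [2.0, 4.0, 0]]), ids="ABC")
        sdm = DistanceMatrix(np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]]), ids="ABC")
        slope, intercept, r2, _ = phylo.regress_divergences(mdm, sdm)
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        bx = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert slope == pytest.approx(bx)
        assert intercept == pytest.approx(y.mean() - bx * x.mean())
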