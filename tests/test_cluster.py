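import numpy as np
import pytest

from stimscreen import SignalKey, cut_tree, diana, gower_binary
from stimscreen.cluster import DissimilarityMatrix
from stimscreen.errors import IncomparablePairError, StimscreenError, ValidationError

from _oracles import diana_oracle, divisive_coefficient_oracle, gower_symmetric_oracle
from conftest import make_activation


def random_dissimilarity(rng, n):
    a = rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0)
    return d


class TestGowerBinary:
    def test_symmetric_is_simple_matching(self):
        am = make_activation([[1, 0, 1, 1], [1, 1, 0, 1]])
        dm = gower_binary(am)
        assert dm.d[0, 1] == pytest.approx(0.5)  # 2 mismatches / 4 signals

    def test_identical_profiles_have_zero_distance(self):
        am = make_activation([[1, 0, 1], [1, 0, 1]])
        assert gower_binary(am).d[0, 1] == 0.0

    def test_asymmetric_excludes_joint_absences(self):
        am = make_activation([[1, 0, 0], [0, 0, 1]])
        dm = gower_binary(am, mode="gower_asymmetric")
        # position 2 is a 0/0 match: mismatches {1,3} over comparable {1,3}
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_symmetric_equals_hamming_over_m(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n, m = rng.integers(2, 8), rng.integers(1, 12)
            calls = (rng.random((n, m)) < 0.4).astype(int)
            dm = gower_binary(make_activation(calls))
            for i in range(n):
                for j in range(i + 1, n):
                    assert dm.d[i, j] == gower_symmetric_oracle(
                        calls[i].tolist(), calls[j].tolist())

    def test_masked_cells_excluded_pairwise(self):
        mask = [[False, True, False], [False, False, False]]
        am = make_activation([[1, 0, 0], [1, 0, 1]], mask=mask)
        # only positions 0 and 2 comparable: 1 mismatch / 2
        assert gower_binary(am).d[0, 1] == pytest.approx(0.5)

    def test_incomparable_pair_raises(self):
        am = make_activation([[0, 0], [0, 0]])
        with pytest.raises(IncomparablePairError):
            gower_binary(am, mode="gower_asymmetric")

    def test_all_one_column_contributes_zero_in_symmetric_mode(self):
        am = make_activation([[1, 1], [1, 0]])
        assert gower_binary(am).d[0, 1] == pytest.approx(0.5)


class TestDissimilarityMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DissimilarityMatrix(items=["a", "b"], d=[[0, 2.0], [2.0, 0]],
                                metric="gower_symmetric")
        with pytest.raises(ValidationError):
            DissimilarityMatrix(items=["a", "b"], d=[[0, 0.2], [0.4, 0]],
                                metric="gower_symmetric")


class TestDiana:
    def test_hand_executed_four_item_example(self):
        # two tight pairs far apart: first split separates the pairs at the
        # cross-pair distance, then each pair splits at its own diameter
        d = np.array([
            [0, 1, 10, 10],
            [1, 0, 10, 10],
            [10, 10, 0, 1],
            [10, 10, 1, 0],
        ], dtype=float)
        tree = diana(d)
        first = tree.divisions[0]
        assert first.height == 10
        kids = {frozenset(c.items) for c in first.children}
        assert kids == {frozenset({0, 1}), frozenset({2, 3})}
        assert [n.height for n in tree.divisions] == [10, 1, 1]
        assign = cut_tree(tree, 2)
        assert assign.labels == {"0": 1, "1": 1, "2": 2, "3": 2}

    def test_two_items_single_split(self):
        tree = diana(np.array([[0, 0.4], [0.4, 0]]))
        assert len(tree.divisions) == 1
        assert tree.divisions[0].height == pytest.approx(0.4)

    def test_matches_literal_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            d = random_dissimilarity(rng, n)
            tree = diana(d)
            expected = diana_oracle(d.tolist())
            assert len(tree.divisions) == len(expected)
            for node, (cluster, height, part_a, part_b) in zip(
                    tree.divisions, expected):
                assert sorted(node.items) == cluster
                assert node.height == pytest.approx(height, rel=1e-12)
                kids = {frozenset(c.items) for c in node.children}
                assert kids == {frozenset(part_a), frozenset(part_b)}
            dc = divisive_coefficient_oracle(expected, n)
            assert tree.divisive_coefficient == pytest.approx(dc, rel=1e-12)

    def test_heights_nonincreasing_and_dc_in_unit_interval(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            tree = diana(random_dissimilarity(rng, 9))
            assert 0 <= tree.divisive_coefficient <= 1

            def check(node):
                if node.children is None:
                    return
                for c in node.children:
                    assert c.height <= node.height + 1e-12
                    check(c)

            check(tree.root)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(55)
        d = random_dissimilarity(rng, 7)
        perm = rng.permutation(7)
        d_p = d[np.ix_(perm, perm)]
        for k in (2, 3, 4):
            lab = cut_tree(diana(d), k).labels
            lab_p = cut_tree(diana(d_p), k).labels
            # partition of original items must be identical up to relabeling
            part = {}
            for i in range(7):
                part.setdefault(lab[str(i)], set()).add(i)
            part_p = {}
            for pos in range(7):
                part_p.setdefault(lab_p[str(pos)], set()).add(int(perm[pos]))
            assert set(map(frozenset, part.values())) == set(
                map(frozenset, part_p.values()))

    def test_single_item_rejected(self):
        with pytest.raises(StimscreenError):
            diana(np.zeros((1, 1)))

    def test_nonfinite_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValidationError):
            diana(d)


class TestCutTree:
    @pytest.fixture()
    def tree(self):
        rng = np.random.default_rng(8)
        return diana(random_dissimilarity(rng, 6))

    def test_k1_and_kn_extremes(self, tree):
        assert set(cut_tree(tree, 1).labels.values()) == {1}
        assert sorted(cut_tree(tree, 6).labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_labels_numbered_by_first_occurrence(self, tree):
        labels = cut_tree(tree, 3).labels
        seen = []
        for i in range(6):
            lab = labels[str(i)]
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)

    def test_k_out_of_range(self, tree):
        with pytest.raises(StimscreenError):
            cut_tree(tree, 0)
        with pytest.raises(StimscreenError):
            cut_tree(tree, 7)


class TestGowerIntoDiana:
    def test_signal_keys_flow_through(self):
        signals = [SignalKey(a, "secreted", "24h") for a in "wxyz"]
        am = make_activation(
            [[1, 1, 0, 0], [1, 1, 0, 1], [0, 0, 1, 1], [0, 1, 1, 1]],
            stimuli=["lpa", "tnf", "hgf", "ang1"], signals=signals)
        dm = gower_binary(am)
        tree = diana(dm)
        labels = cut_tree(tree, 2).labels
        assert labels["lpa"] == labels["tnf"]
        assert labels["hgf"] == labels["ang1"]
        assert labels["lpa"] != labels["hgf"]
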