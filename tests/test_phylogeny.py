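import itertools

import numpy as np
import pandas as pd
import pytest

from clonedeconv.event_unification import unify_events
from clonedeconv.phylogeny import (
    PNode,
    Phylogeny,
    _fitch_score,
    _leaf_states,
    compare_topologies,
    detect_contradictions,
    hamming_matrix,
    ml_tree,
    mp_tree,
    optimize_branch_lengths,
    tree_stats,
)
from conftest import make_record

MB = 1_000_000


def nested_matrix():
    """Perfect phylogeny: chain Stem -> A -> B with 3/1/2 private events."""
    data = {
        "Stem": [1, 1, 1, 0, 0, 0],
        "A": [1, 1, 1, 1, 0, 0],
        "B": [1, 1, 1, 1, 1, 1],
    }
    return pd.DataFrame(data, index=[f"s{i}" for i in range(3)] + ["a0", "b0", "b1"])


def sibling_matrix():
    """Stem with 3 events; siblings A (+1) and B (+2)."""
    data = {
        "Stem": [1, 1, 1, 0, 0, 0],
        "A": [1, 1, 1, 1, 0, 0],
        "B": [1, 1, 1, 0, 1, 1],
    }
    return pd.DataFrame(data, index=["s0", "s1", "s2", "a0", "b0", "b1"])


class TestHamming:
    def test_identical_and_counted_differences(self):
        E = pd.DataFrame({"X": [1, 1, 0], "Y": [1, 1, 0], "Z": [1, 0, 1]})
        H = hamming_matrix(E)
        assert H.loc["X", "Y"] == 0
        assert H.loc["Y", "Z"] == 2
        assert (np.diag(H.to_numpy()) == 0).all()

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        E = pd.DataFrame(rng.integers(0, 2, size=(10, 6)),
                         columns=[f"S{i}" for i in range(6)])
        H = hamming_matrix(E).to_numpy()
        n = H.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert H[i, j] <= H[i, k] + H[k, j]


class TestMaximumParsimony:
    def test_perfect_phylogeny_score_equals_event_count(self):
        E = nested_matrix()
        tree = mp_tree(E, seed=0)
        assert tree.score == E.shape[0]  # no homoplasy
        rep = detect_contradictions(tree, E)
        assert len(rep) == 0

    def test_sibling_fixture_fitch_acctran_lengths(self):
        E = sibling_matrix()
        tree = mp_tree(E, seed=0)
        lengths = {n.label: n.length for n in tree.postorder() if n.label}
        assert lengths["A"] == 1 and lengths["B"] == 2
        stats = tree_stats(tree)
        assert stats.stem_length == 3
        assert stats.total_branch_length == 6

    def test_score_beats_random_topologies(self):
        rng = np.random.default_rng(9)
        E = pd.DataFrame(rng.integers(0, 2, size=(12, 6)),
                         columns=[f"S{i}" for i in range(6)])
        tree = mp_tree(E, ratchet_iters=20, seed=1)
        taxa, states = _leaf_states(E, include_root=True)
        weights = np.ones(E.shape[0])

        def random_rooted(labels, rng):
            nodes = [PNode(l) for l in labels]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                parent = PNode()
                parent.add(nodes[i])
                parent.add(nodes[j])
                nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
                nodes.append(parent)
            root = PNode("Root")
            root.add(nodes[0])
            return root

        leaf_labels = list(E.columns)
        for _ in range(100):
            rand = random_rooted(leaf_labels, rng)
            assert tree.score <= _fitch_score(rand, states, weights) + 1e-9

    def test_single_subclone_degenerates_to_stem_line(self):
        E = pd.DataFrame({"Stem": [1, 1, 1]}, index=["s0", "s1", "s2"])
        tree = mp_tree(E)
        stats = tree_stats(tree)
        assert stats.stem_length == 3 and stats.n_branches == 0
        assert tree.leaf_labels() == ["Stem"]


class TestMaximumLikelihood:
    def test_two_leaf_closed_form_distance(self):
        # p differing sites -> ML distance -0.5 * ln(1 - 2p) per site
        n, k = 40, 8
        E = pd.DataFrame({
            "X": [0] * n,
            "Y": [1] * k + [0] * (n - k),
        })
        root = PNode("X")
        root.add(PNode("Y", 1.0))
        tree = Phylogeny(root=root)
        opt = optimize_branch_lengths(tree, E, include_root=False)
        p = k / n
        expected = -0.5 * np.log(1 - 2 * p) * n  # alterations
        total = sum(nd.length for nd in opt.postorder() if nd.parent)
        assert total == pytest.approx(expected, rel=1e-3)

    def test_identical_subclones_get_zero_length_edge(self):
        E = pd.DataFrame({"X": [1, 0, 1], "Y": [1, 0, 1], "Z": [0, 1, 0]})
        tree = ml_tree(E)
        # the X and Y leaves must be (near) zero distance apart
        leaves = {n.label: n for n in tree.leaves()}
        assert leaves["X"].length + leaves["Y"].length < 0.05

    def test_perfect_phylogeny_ml_matches_mp_topology(self):
        for E in (nested_matrix(), sibling_matrix()):
            mp = mp_tree(E, seed=0)
            ml = ml_tree(E)
            assert compare_topologies(mp, ml, collapse_tol=0.2)

    def test_likelihood_score_is_finite_and_negative(self):
        tree = ml_tree(sibling_matrix())
        assert np.isfinite(tree.score) and tree.score < 0


class TestContradictions:
    def test_parallel_gain_detected_once(self):
        # x arises independently in the (A,C) and (B,D) clades
        E = pd.DataFrame({
            "A": [1, 1, 0, 0, 1],
            "C": [1, 1, 0, 0, 0],
            "B": [0, 0, 1, 1, 1],
            "D": [0, 0, 1, 1, 0],
        }, index=["e1a", "e1b", "e2a", "e2b", "x"])
        tree = mp_tree(E, seed=0)
        rep = detect_contradictions(tree, E)
        kinds = {(c.event_id, c.kind) for c in rep.items}
        assert ("x", "PLC") in kinds or ("x", "BMC") in kinds
        assert all(c.event_id == "x" for c in rep.items)

    def test_exemption_follows_event_scope(self):
        records = [
            make_record("whole", chrom="17", start=1, end=83_257_441,
                        mcf={"P1": 50.0}),
            make_record("seg", chrom="17", start=30 * MB, end=40 * MB,
                        mcf={"P1": 50.0}),
        ]
        catalog = unify_events(records)
        from clonedeconv.genome import load_genome
        from clonedeconv.event_unification import annotate_scopes
        annotate_scopes(catalog, load_genome())
        # hand-built tree with ancestral states forcing one PLC per event
        root = PNode("Root")
        mid = root.add(PNode())
        a = mid.add(PNode("A", 1))
        b = mid.add(PNode("B", 1))
        E = pd.DataFrame({"A": [1, 1], "B": [1, 1]}, index=["whole", "seg"])
        root.states = np.array([0, 0])
        mid.states = np.array([0, 0])
        a.states = np.array([1, 1])
        b.states = np.array([1, 1])
        tree = Phylogeny(root=root)
        rep = detect_contradictions(tree, E, catalog)
        by_event = {c.event_id: c for c in rep.items}
        assert by_event["whole"].exempt is True
        assert by_event["seg"].exempt is False

    def test_back_mutation_on_cnni_never_exempt(self):
        records = [make_record("loh", chrom="17", start=1, end=83_257_441,
                               alt_type="cnni", mcf={"P1": 50.0})]
        catalog = unify_events(records)
        from clonedeconv.genome import load_genome
        from clonedeconv.event_unification import annotate_scopes
        annotate_scopes(catalog, load_genome())
        root = PNode("Root")
        a = root.add(PNode("A", 1))
        b = a.add(PNode("B", 1))
        root.states = np.array([1])  # present ancestrally
        a.states = np.array([1])
        b.states = np.array([0])  # lost below
        E = pd.DataFrame({"A": [1], "B": [0]}, index=["loh"])
        rep = detect_contradictions(Phylogeny(root=root), E, catalog)
        assert rep.items[0].kind == "BMC"
        assert rep.items[0].exempt is False

    def test_nested_matrix_clean(self):
        E = nested_matrix()
        rep = detect_contradictions(mp_tree(E, seed=0), E)
        assert len(rep) == 0


class TestTopologyComparison:
    def test_tree_vs_itself(self):
        t = mp_tree(sibling_matrix(), seed=0)
        assert compare_topologies(t, t)

    def test_different_leaf_sets_error(self):
        t1 = mp_tree(sibling_matrix(), seed=0)
        E = nested_matrix().rename(columns={"B": "C"})
        t2 = mp_tree(E, seed=0)
        with pytest.raises(ValueError):
            compare_topologies(t1, t2)

    def test_distinguishes_different_structures(self):
        E1 = sibling_matrix()
        # move B under A: chain instead of siblings
        E2 = nested_matrix()
        E2.columns = ["Stem", "A", "B"]
        t1 = mp_tree(E1, seed=0)
        t2 = mp_tree(E2, seed=0)
        assert not compare_topologies(t1, t2)
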