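import numpy as np
import pytest

from clonedeconv.clustering import ClusterSet, ClusterSizeMatrix
from clonedeconv.deconvolution import (
    ROOT,
    allocate_within_biopsy,
    alternative_solutions,
    brute_force_min_violations,
    build_event_matrix,
    integrate_across_biopsies,
    largest_available_space,
    reconstructed_mcf,
    subclone_fractions,
)
from clonedeconv.segment_io import RulesMatrix


def make_instance(sizes, biopsies=None, stem_row=True):
    """sizes: list of per-biopsy size rows, first row = stem if stem_row."""
    sizes = np.atleast_2d(np.asarray(sizes, dtype=float))
    biopsies = biopsies or [f"P{i+1}" for i in range(sizes.shape[1])]
    ids = (["Stem"] if stem_row else []) + [
        chr(ord("A") + i) for i in range(sizes.shape[0] - int(stem_row))
    ]
    clusters = ClusterSet(
        clusters={cid: [f"{cid.lower()}1"] for cid in ids},
        stem_cluster="Stem" if stem_row else None,
    )
    Z = ClusterSizeMatrix(cluster_ids=ids, biopsies=biopsies, values=sizes)
    return clusters, Z


class TestWithinBiopsy:
    def test_smallest_cluster_has_two_candidate_parents(self):
        clusters, Z = make_instance([[100.0], [60.0], [30.0]])
        cand = allocate_within_biopsy(Z, clusters, "P1")
        # 30 fits inside A (60 available) or beside it under the stem (40 left)
        assert sorted(cand["B"]) == ["A", "Stem"]

    def test_pigeonhole_forces_single_candidate(self):
        clusters, Z = make_instance([[100.0], [70.0], [40.0]])
        cand = allocate_within_biopsy(Z, clusters, "P1", tol_overlap=0.5)
        assert cand["B"] == ["A"]  # the root's remaining 30 cannot hold 40

    def test_full_cluster_only_fits_the_root(self):
        clusters, Z = make_instance([[100.0]])
        cand = allocate_within_biopsy(Z, clusters, "P1")
        assert cand["Stem"] == [ROOT]

    def test_oversized_cluster_flagged_infeasible(self):
        # stem fills 90 of the biopsy; a 95% cluster fits nowhere
        clusters, Z = make_instance([[90.0], [95.0]])
        cand = allocate_within_biopsy(Z, clusters, "P1", tol_overlap=2.0)
        assert cand["A"] == []


class TestLargestAvailableSpace:
    def test_picks_larger_space(self):
        assert largest_available_space(["root", "A"], {"root": 40.0, "A": 60.0}) == "A"

    def test_single_candidate(self):
        assert largest_available_space(["A"], {"root": 90.0, "A": 10.0}) == "A"

    def test_tie_breaks_to_earliest_created(self):
        spaces = {"root": 50.0, "A": 50.0, "B": 50.0}
        for _ in range(5):
            assert largest_available_space(["B", "A"], spaces) == "A"


class TestIntegration:
    def test_second_biopsy_forces_siblings(self, sibling_size_matrix):
        # biopsy 2 has A=0 but B=80: B under A would violate biopsy 2
        clusters, Z = sibling_size_matrix
        tree = integrate_across_biopsies(Z, clusters)
        assert tree.subclones["A"].parent == "Stem"
        assert tree.subclones["B"].parent == "Stem"
        assert tree.n_violations == 0

    def test_single_biopsy_largest_space_nests(self, single_biopsy_matrix):
        clusters, Z = single_biopsy_matrix
        tree = integrate_across_biopsies(Z, clusters)
        assert tree.subclones["B"].parent == "A"  # A has 60 free vs stem's 40

    def test_rule_respected_when_alternative_exists(self, single_biopsy_matrix):
        clusters, Z = single_biopsy_matrix
        rules = RulesMatrix([("a1", "b1")])
        tree = integrate_across_biopsies(Z, clusters, rules=rules)
        assert tree.subclones["B"].parent == "Stem"
        assert tree.n_rule_violations == 0

    def test_impossible_rule_kept_with_advice(self):
        clusters, Z = make_instance([[100.0], [70.0], [40.0]])
        rules = RulesMatrix([("a1", "b1")])  # but B only fits under A
        tree = integrate_across_biopsies(Z, clusters, rules=rules, tol_overlap=0.5)
        assert tree.subclones["B"].parent == "A"
        assert tree.n_rule_violations == 1
        assert any("revise" in w for w in tree.warnings)

    def test_contradictory_sizes_warn(self):
        # A and B cross in size between biopsies: no nesting fits both
        clusters, Z = make_instance(
            [[100.0, 100.0], [90.0, 20.0], [30.0, 90.0]]
        )
        tree = integrate_across_biopsies(Z, clusters, tol_overlap=5.0)
        assert tree.n_violations > 0
        assert any("contradiction" in w for w in tree.warnings)


class TestEventMatrixAndFractions:
    def test_stem_only_tumor_single_all_one_column(self):
        clusters, Z = make_instance([[100.0, 100.0]])
        tree = integrate_across_biopsies(Z, clusters)
        E = build_event_matrix(tree)
        assert E.shape == (1, 1)
        assert (E.to_numpy() == 1).all()

    def test_chain_nesting_superset_columns(self):
        clusters, Z = make_instance([[100.0], [60.0], [30.0]])
        tree = integrate_across_biopsies(Z, clusters)
        E = build_event_matrix(tree)
        cols = {c: set(E.index[E[c] == 1]) for c in E.columns}
        assert cols["Stem"] <= cols["A"] <= cols["B"]
        assert (E.loc["stem1"] == 1).all()  # stem event in every subclone

    def test_siblings_share_exactly_stem_rows(self, sibling_size_matrix):
        clusters, Z = sibling_size_matrix
        tree = integrate_across_biopsies(Z, clusters)
        E = build_event_matrix(tree)
        shared = set(E.index[(E["A"] == 1) & (E["B"] == 1)])
        assert shared == set(E.index[E["Stem"] == 1])

    def test_fraction_subtraction_and_conservation(self):
        clusters, Z = make_instance([[100.0], [60.0]])
        tree = integrate_across_biopsies(Z, clusters)
        frac = tree.fractions
        assert frac.loc["Stem", "P1"] == pytest.approx(40.0)
        assert frac.loc["A", "P1"] == pytest.approx(60.0)
        assert frac["P1"].sum() == pytest.approx(100.0)

    def test_leaf_fraction_is_own_size(self, sibling_size_matrix):
        clusters, Z = sibling_size_matrix
        tree = integrate_across_biopsies(Z, clusters)
        assert tree.fractions.loc["B", "P2"] == pytest.approx(80.0)

    def test_mcf_conservation_on_consistent_data(self, sibling_size_matrix):
        clusters, Z = sibling_size_matrix
        tree = integrate_across_biopsies(Z, clusters)
        recon = reconstructed_mcf(tree)
        for cid, eid in [("Stem", "s1"), ("A", "a1"), ("B", "b1")]:
            assert np.allclose(recon.loc[eid].to_numpy(), Z.row(cid))

    def test_negative_residual_clipped_with_warning(self):
        clusters, Z = make_instance([[100.0], [50.0], [45.0], [40.0]])
        tree = integrate_across_biopsies(Z, clusters, tol_overlap=40.0)
        frac = subclone_fractions(tree, Z, tol_overlap=1.0)
        assert (frac.to_numpy() >= 0).all()


class TestAlternativeSolutions:
    def test_fully_constrained_has_no_alternatives(self):
        clusters, Z = make_instance([[100.0], [70.0], [40.0]])
        tree = integrate_across_biopsies(Z, clusters, tol_overlap=0.5)
        alts, certainty = alternative_solutions(tree, clusters, seed=1,
                                                tol_overlap=0.5)
        assert alts == []
        assert all(v == 1 for v in certainty.values())

    def test_two_feasible_parents_give_two_solutions(self, single_biopsy_matrix):
        clusters, Z = single_biopsy_matrix
        tree = integrate_across_biopsies(Z, clusters)
        alts, certainty = alternative_solutions(tree, clusters, n_alt=5, seed=1)
        assert certainty["B"] == 2
        assert len(alts) == 1  # exactly one alternative beside the primary
        assert alts[0].subclones["B"].parent == "Stem"

    def test_alternatives_pass_feasibility(self, single_biopsy_matrix):
        clusters, Z = single_biopsy_matrix
        tree = integrate_across_biopsies(Z, clusters)
        alts, _ = alternative_solutions(tree, clusters, seed=0)
        for alt in alts:
            assert alt.n_violations == 0 or alt.fractions.min().min() >= 0


def random_consistent_instance(rng, n_clusters, n_biopsies, crossing=False):
    """Generate cluster sizes from a random true nesting (consistent
    unless ``crossing``), so a zero-violation assignment exists."""
    parents = [ROOT]
    for i in range(1, n_clusters):
        parents.append(rng.integers(0, i))
    sizes = np.zeros((n_clusters, n_biopsies))
    for b in range(n_biopsies):
        # distribute space top-down along the random tree
        def fill(node_children, parent_space, node):
            kids = [i for i in range(n_clusters) if parents[i] == node]
            space = parent_space
            for k in kids:
                s = rng.uniform(0, space)
                sizes[k, b] = s
                fill(node_children, s, k)
                space -= s

        roots = [i for i in range(n_clusters) if parents[i] == ROOT]
        space = 100.0
        for r in roots:
            s = rng.uniform(0, space)
            sizes[r, b] = s
            fill(None, s, r)
            space -= s
    if crossing:
        i, j = rng.choice(n_clusters, size=2, replace=False)
        sizes[[i, j]] = sizes[[j, i]]
    ids = [chr(ord("A") + i) for i in range(n_clusters)]
    clusters = ClusterSet(clusters={cid: [f"{cid.lower()}1"] for cid in ids})
    Z = ClusterSizeMatrix(cluster_ids=ids, biopsies=[f"P{b+1}" for b in range(n_biopsies)],
                          values=np.round(sizes, 1))
    return clusters, Z


class TestOracleEquivalence:
    @pytest.mark.parametrize("crossing", [False, True])
    def test_violation_count_matches_brute_force(self, crossing):
        """The branch-and-bound must be contradiction-minimal: its
        violation count equals exhaustive forest enumeration's minimum."""
        rng = np.random.default_rng(11 if crossing else 7)
        for _ in range(12):
            n_clusters = int(rng.integers(2, 6))
            n_biopsies = int(rng.integers(1, 4))
            clusters, Z = random_consistent_instance(
                rng, n_clusters, n_biopsies, crossing=crossing
            )
            tree = integrate_across_biopsies(Z, clusters, tol_overlap=0.5)
            oracle = brute_force_min_violations(Z, clusters, tol_overlap=0.5)
            assert tree.n_violations == oracle

    def test_consistent_instances_are_violation_free(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            clusters, Z = random_consistent_instance(rng, 5, 2)
            tree = integrate_across_biopsies(Z, clusters, tol_overlap=0.5)
            assert tree.n_violations == 0
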