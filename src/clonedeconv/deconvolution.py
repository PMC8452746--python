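"""Subclonal deconvolution by nested space allocation across biopsies.

Each biopsy offers 100% of cellular space (the space matrix constraint:
per biopsy, partition sizes sum to 100).  Clusters of events are
allocated into that space in decreasing size order: placing a cluster
inside a partition spends the parent's space, and the nesting built up
this way *is* the clone tree — a cluster's subclone carries the events
of every cluster on its path to the root.  A placement is feasible in a
biopsy when the parent partition still has at least the cluster's size
(minus a measurement-uncertainty overlap tolerance) available.

Because one tree must agree with every biopsy simultaneously, the
placement of each cluster is chosen globally: a bounded branch-and-
bound over per-cluster parent choices minimizes, lexicographically,
(1) the number of (cluster, biopsy) capacity violations,
(2) the number of user-rule violations (rules are only enforced when
    the data allow an alternative placement),
(3) minus the number of biopsies supporting the placement,
breaking remaining ties by the largest-available-space rule.  Candidate
orderings are greedy-first, so even when the search budget is exhausted
the result is the classical decreasing-size / largest-available-space
allocation.  When no violation-free assignment exists, the best effort
tree is returned and each violation is reported as a warning — such
conflicts surface later as parallel-evolution or back-mutation
contradictions in the phylogeny.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterSet, ClusterSizeMatrix
from .segment_io import RulesMatrix

__all__ = [
    "ROOT",
    "DEFAULT_TOL_OVERLAP",
    "Subclone",
    "CloneTree",
    "AllocationCandidates",
    "allocate_within_biopsy",
    "largest_available_space",
    "integrate_across_biopsies",
    "build_event_matrix",
    "subclone_fractions",
    "reconstructed_mcf",
    "alternative_solutions",
    "brute_force_min_violations",
]

ROOT = "__root__"
DEFAULT_TOL_OVERLAP = 10.0  # percentage points of MCF measurement uncertainty
_SEARCH_BUDGET = 30_000  # placements explored by the branch-and-bound


@dataclass
class Subclone:
    id: str
    parent: str  # parent subclone id, or ROOT
    events: frozenset


@dataclass
class CloneTree:
    """Nested subclone structure with per-biopsy genotype fractions."""

    subclones: dict[str, Subclone]
    order: list[str]  # insertion (allocation) order
    z: ClusterSizeMatrix
    fractions: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    n_violations: int = 0
    n_rule_violations: int = 0

    def children(self, sid: str) -> list[str]:
        return [s.id for s in self.subclones.values() if s.parent == sid]

    def genotype(self, sid: str) -> frozenset:
        """Full genotype: own events plus all ancestral events."""
        events: set = set()
        cur = sid
        while cur != ROOT:
            sc = self.subclones[cur]
            events |= sc.events
            cur = sc.parent
        return frozenset(events)

    def parent_assignment(self) -> dict[str, str]:
        return {sid: sc.parent for sid, sc in self.subclones.items()}


@dataclass
class AllocationCandidates:
    """Feasible parent partitions per (cluster, biopsy), plus support counts."""

    feasible: dict[tuple[str, str], list[str]]  # (cluster, biopsy) -> parents
    infeasible: list[tuple[str, str]]
    support: dict[str, dict[str, int]]  # cluster -> parent -> #biopsies


def _cluster_order(Z: ClusterSizeMatrix, clusters: ClusterSet) -> list[str]:
    """Global allocation order: stem first, then by decreasing total size,
    larger member count first, then lexicographic id."""

    def key(cid: str):
        row = Z.row(cid)
        return (-float(row.sum()), -len(clusters.members(cid)), cid)

    ids = list(Z.cluster_ids)
    stem = clusters.stem_cluster
    sub = sorted((c for c in ids if c != stem), key=key)
    return ([stem] if stem in ids else []) + sub


def largest_available_space(
    feasible_parents: Sequence[str], spaces: dict[str, float]
) -> str:
    """Pick the feasible parent with maximal available space.

    Exact ties go to the earliest-created partition (insertion order of
    ``spaces``), which keeps reruns deterministic.
    """
    if not feasible_parents:
        raise ValueError("no feasible parent")
    creation = {p: i for i, p in enumerate(spaces)}
    return max(feasible_parents, key=lambda p: (spaces[p], -creation.get(p, 0)))


def allocate_within_biopsy(
    Z: ClusterSizeMatrix,
    clusters: ClusterSet,
    biopsy: str,
    tol_overlap: float = DEFAULT_TOL_OVERLAP,
) -> dict[str, list[str]]:
    """All feasible parents per cluster in one biopsy.

    Clusters with size > 0 are processed in decreasing size order; at
    each step every partition whose available space covers the cluster
    (within the overlap tolerance) is recorded as feasible, and the
    cluster is then provisionally placed by the largest-available-space
    rule so later, smaller clusters see realistic remaining space.
    Clusters that fit nowhere get an empty list.
    """
    b = Z.biopsies.index(biopsy)
    present = [c for c in _cluster_order(Z, clusters) if Z.values[Z.cluster_ids.index(c), b] > 0]
    avail: dict[str, float] = {ROOT: 100.0}
    out: dict[str, list[str]] = {}
    for cid in present:
        size = Z.values[Z.cluster_ids.index(cid), b]
        feasible = [p for p in avail if avail[p] >= size - tol_overlap]
        out[cid] = feasible
        if feasible:
            chosen = largest_available_space(feasible, avail)
            avail[chosen] -= size
        avail[cid] = size
    return out


def compute_candidates(
    Z: ClusterSizeMatrix,
    clusters: ClusterSet,
    tol_overlap: float = DEFAULT_TOL_OVERLAP,
) -> AllocationCandidates:
    """Per-biopsy feasibility and cross-sample support for each cluster."""
    feasible: dict[tuple[str, str], list[str]] = {}
    infeasible: list[tuple[str, str]] = []
    support: dict[str, dict[str, int]] = {}
    for biopsy in Z.biopsies:
        per = allocate_within_biopsy(Z, clusters, biopsy, tol_overlap)
        for cid, parents in per.items():
            feasible[(cid, biopsy)] = parents
            if not parents:
                infeasible.append((cid, biopsy))
            counts = support.setdefault(cid, {})
            for p in parents:
                counts[p] = counts.get(p, 0) + 1
    return AllocationCandidates(feasible=feasible, infeasible=infeasible, support=support)


def _rule_violated(
    rules: RulesMatrix | None,
    cluster_events: frozenset,
    parent_genotype: frozenset,
) -> bool:
    if rules is None or not rules.pairs:
        return False
    for mother, daughter in rules.pairs:
        if daughter in cluster_events and mother in parent_genotype:
            return True
    return False


class _Searcher:
    """Branch-and-bound over per-cluster parent choices.

    Clusters are charged against their parent's remaining space in one
    fixed global order (decreasing total size); the parent of a cluster
    may be *any* other cluster — even a smaller one, at the price of
    capacity violations — so the search space coincides with the set of
    all rooted forests.  Candidates are ordered greedily (violation-free
    first, then best supported across biopsies, then largest available
    space), so the first complete solution is the classical allocation
    and remains available if the exploration budget runs out.
    """

    def __init__(
        self,
        Z: ClusterSizeMatrix,
        clusters: ClusterSet,
        rules: RulesMatrix | None,
        tol: float,
        budget: int = _SEARCH_BUDGET,
    ):
        self.Z = Z
        self.clusters = clusters
        self.rules = rules
        self.tol = tol
        self.budget = budget
        self.order = _cluster_order(Z, clusters)
        self.zrow = {c: Z.row(c) for c in Z.cluster_ids}
        self.events = {c: frozenset(clusters.members(c)) for c in Z.cluster_ids}
        self.support = compute_candidates(Z, clusters, tol).support
        self.best_assign: dict[str, str] | None = None
        self.best_score: tuple | None = None
        self.solutions: list[tuple[tuple, dict[str, str]]] | None = None
        self.truncated = False
        # optimistic per-cluster support, for pruning the tie-break search
        max_supp = {c: max(self.support.get(c, {}).values(), default=0)
                    for c in Z.cluster_ids}
        self._rem_supp = [0] * (len(self.order) + 1)
        for i in range(len(self.order) - 1, -1, -1):
            self._rem_supp[i] = self._rem_supp[i + 1] + max_supp[self.order[i]]

    # --- helpers -----------------------------------------------------
    def _creates_cycle(self, cid: str, parent: str, assign: dict[str, str]) -> bool:
        cur = parent
        while cur != ROOT:
            if cur == cid:
                return True
            cur = assign.get(cur, ROOT)
        return False

    def _partial_rule(self, cid: str, parent: str, assign: dict[str, str]) -> int:
        """Rule violations detectable from the currently-known ancestor
        chain (exact accounting happens on complete assignments)."""
        if self.rules is None or not self.rules.pairs:
            return 0
        genotype: set = set()
        cur = parent
        while cur != ROOT:
            genotype |= self.events[cur]
            cur = assign.get(cur, ROOT)
        return int(_rule_violated(self.rules, self.events[cid], frozenset(genotype)))

    def _total_rules(self, assign: dict[str, str]) -> int:
        if self.rules is None or not self.rules.pairs:
            return 0
        total = 0
        for cid in self.order:
            genotype: set = set()
            cur = assign[cid]
            while cur != ROOT:
                genotype |= self.events[cur]
                cur = assign[cur]
            total += int(_rule_violated(self.rules, self.events[cid],
                                        frozenset(genotype)))
        return total

    def _candidates(self, cid, avail, assign):
        """Parents ordered greedily: fewest violations, rule-clean so
        far, best-supported, largest available space, earliest listed."""
        z = self.zrow[cid]
        cands = []
        for idx, parent in enumerate(avail):
            if parent == cid or self._creates_cycle(cid, parent, assign):
                continue
            viol = int(np.sum((z > 0) & (avail[parent] < z - self.tol)))
            rule = self._partial_rule(cid, parent, assign)
            supp = self.support.get(cid, {}).get(parent, 0)
            space = float(np.sum(np.maximum(avail[parent], 0.0)))
            cands.append((viol, rule, -supp, -space, idx, parent))
        cands.sort()
        return cands

    # --- optimization ------------------------------------------------
    def run(self) -> tuple[dict[str, str], tuple, bool]:
        avail = {ROOT: np.full(len(self.Z.biopsies), 100.0)}
        for cid in self.order:
            avail[cid] = self.zrow[cid].astype(float).copy()
        self._explored = 0
        self._dfs(0, avail, {}, 0, 0)
        assert self.best_assign is not None
        return self.best_assign, self.best_score, self.truncated

    def _dfs(self, i, avail, assign, viol, neg_supp):
        if self.best_score is not None:
            if (viol,) > self.best_score[:1]:
                return
            # support can improve by at most the remaining optimistic sum;
            # skipped while enumerating alternatives, which need every
            # violation-optimal assignment
            if (
                self.solutions is None
                and self.rules is None
                and viol == self.best_score[0]
                and neg_supp - self._rem_supp[i] >= self.best_score[2]
            ):
                return
        if i == len(self.order):
            score = (viol, self._total_rules(assign), neg_supp)
            if self.best_score is None or score < self.best_score:
                self.best_score = score
                self.best_assign = dict(assign)
            if self.solutions is not None:
                self.solutions.append((score[:2], dict(assign)))
            return
        cid = self.order[i]
        stem_forced = self.clusters.stem_cluster == cid
        for v, _r, ns, _space, _idx, parent in self._candidates(cid, avail, assign):
            if stem_forced and parent != ROOT:
                continue
            if self._explored >= self.budget and self.best_assign is not None:
                self.truncated = True
            if self.truncated:
                if self.best_assign is not None:
                    return
            self._explored += 1
            z = self.zrow[cid]
            avail[parent] = avail[parent] - z
            assign[cid] = parent
            self._dfs(i + 1, avail, assign, viol + v, neg_supp + ns)
            del assign[cid]
            avail[parent] = avail[parent] + z
            if stem_forced:
                break  # stem always sits directly under the root


def integrate_across_biopsies(
    Z: ClusterSizeMatrix,
    clusters: ClusterSet,
    rules: RulesMatrix | None = None,
    tol_overlap: float = DEFAULT_TOL_OVERLAP,
    search_budget: int = _SEARCH_BUDGET,
) -> CloneTree:
    """Choose one global parent per cluster, concordant with every biopsy.

    Always returns a best-effort tree; capacity or rule conflicts are
    reported in ``tree.warnings`` rather than raised.
    """
    searcher = _Searcher(Z, clusters, rules, tol_overlap, search_budget)
    assign, score, truncated = searcher.run()
    warnings: list[str] = []
    order = searcher.order
    subclones = {
        cid: Subclone(id=cid, parent=assign[cid], events=searcher.events[cid])
        for cid in order
    }
    tree = CloneTree(
        subclones=subclones,
        order=order,
        z=Z,
        warnings=warnings,
        n_violations=score[0],
        n_rule_violations=score[1],
    )
    if score[0] > 0:
        # name the offending (cluster, biopsy) pairs
        avail = {ROOT: np.full(len(Z.biopsies), 100.0)}
        for cid in order:
            avail[cid] = searcher.zrow[cid].astype(float).copy()
        for cid in order:
            parent = assign[cid]
            z = searcher.zrow[cid]
            for bi, biopsy in enumerate(Z.biopsies):
                if z[bi] > 0 and avail[parent][bi] < z[bi] - tol_overlap:
                    warnings.append(
                        f"contradiction: cluster {cid} (size {z[bi]:.1f}) does not fit "
                        f"under {parent} in biopsy {biopsy}; expect parallel-evolution "
                        "or back-mutation signals — consider revising the input data"
                    )
            avail[parent] = avail[parent] - z
    if score[1] > 0:
        warnings.append(
            "user rules could not be satisfied: the data allow no alternative "
            "placement; please revise the original data set"
        )
    if truncated:
        warnings.append("allocation search budget exhausted; result is best-effort")
    tree.fractions = subclone_fractions(tree, Z, tol_overlap)
    return tree


def subclone_fractions(
    tree: CloneTree,
    Z: ClusterSizeMatrix,
    tol_overlap: float = DEFAULT_TOL_OVERLAP,
) -> pd.DataFrame:
    """Fraction of cells whose exact genotype is each subclone.

    Per biopsy, a subclone's fraction is its cluster size minus its
    children's sizes; small negative residuals (within tolerance) are
    clipped to zero, larger ones clipped with a warning.
    """
    data = np.zeros((len(tree.order), len(Z.biopsies)))
    for i, sid in enumerate(tree.order):
        own = Z.row(sid).astype(float).copy()
        for child in tree.children(sid):
            own -= Z.row(child)
        for bi, val in enumerate(own):
            if val < -tol_overlap:
                tree.warnings.append(
                    f"subclone {sid}: children exceed parent size by {-val:.1f} points "
                    f"in biopsy {Z.biopsies[bi]} (clipped to 0)"
                )
        data[i] = np.maximum(own, 0.0)
    return pd.DataFrame(data, index=tree.order, columns=Z.biopsies)


def build_event_matrix(
    tree: CloneTree, event_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Binary events x subclones matrix: 1 iff the event is in the
    subclone's full genotype (own plus ancestral events)."""
    if event_order is None:
        event_order = [e for sid in tree.order for e in sorted(tree.subclones[sid].events)]
    genotypes = {sid: tree.genotype(sid) for sid in tree.order}
    data = [
        [1 if e in genotypes[sid] else 0 for sid in tree.order] for e in event_order
    ]
    return pd.DataFrame(data, index=list(event_order), columns=tree.order, dtype=int)


def reconstructed_mcf(tree: CloneTree) -> pd.DataFrame:
    """Per-event MCF implied by the tree: sum of fractions of subclones
    whose genotype contains the event (used to check MCF conservation)."""
    assert tree.fractions is not None
    events = sorted({e for sid in tree.order for e in tree.subclones[sid].events})
    genotypes = {sid: tree.genotype(sid) for sid in tree.order}
    data = np.zeros((len(events), tree.fractions.shape[1]))
    for i, e in enumerate(events):
        for sid in tree.order:
            if e in genotypes[sid]:
                data[i] += tree.fractions.loc[sid].to_numpy()
    return pd.DataFrame(data, index=events, columns=tree.fractions.columns)


def alternative_solutions(
    tree: CloneTree,
    clusters: ClusterSet,
    rules: RulesMatrix | None = None,
    n_alt: int = 3,
    seed: int = 0,
    tol_overlap: float = DEFAULT_TOL_OVERLAP,
    max_enumerated: int = 500,
) -> tuple[list[CloneTree], dict[str, int]]:
    """Distinct equally-valid trees, plus a per-cluster certainty table.

    All assignments matching the optimal (violation, rule-violation)
    score are enumerated (up to a cap); clusters whose parent varies
    across them are the uncertain ones.  Up to ``n_alt`` alternatives
    distinct from the primary tree are sampled uniformly (seeded).
    """
    searcher = _Searcher(tree.z, clusters, rules, tol_overlap)
    searcher.solutions = []
    _, score, _ = searcher.run()
    primary = tree.parent_assignment()
    seen: set[tuple] = set()
    uniq: list[dict[str, str]] = []
    for sol_score, sol in searcher.solutions:
        if sol_score != score[:2]:
            continue
        key = tuple(sorted(sol.items()))
        if key not in seen:
            seen.add(key)
            uniq.append(sol)
        if len(uniq) >= max_enumerated:
            break
    certainty = {
        cid: len({sol[cid] for sol in uniq}) for cid in tree.order
    }
    others = [s for s in uniq if s != primary]
    rng = np.random.default_rng(seed)
    if len(others) > n_alt:
        idx = rng.choice(len(others), size=n_alt, replace=False)
        others = [others[int(i)] for i in sorted(idx)]
    alt_trees = []
    for sol in others:
        sub = {
            cid: Subclone(id=cid, parent=sol[cid], events=searcher.events[cid])
            for cid in tree.order
        }
        alt = CloneTree(subclones=sub, order=list(tree.order), z=tree.z)
        alt.fractions = subclone_fractions(alt, tree.z, tol_overlap)
        alt_trees.append(alt)
    return alt_trees, certainty


def brute_force_min_violations(
    Z: ClusterSizeMatrix,
    clusters: ClusterSet,
    tol_overlap: float = DEFAULT_TOL_OVERLAP,
) -> int:
    """Exhaustive enumeration of every rooted forest of clusters,
    returning the minimum total number of (cluster, biopsy) capacity
    violations.  Independent oracle for small instances (it shares no
    code path with the branch-and-bound)."""
    ids = list(Z.cluster_ids)
    stem = clusters.stem_cluster
    choose_for = [c for c in ids if c != stem]
    parents_options = []
    for c in choose_for:
        opts = [ROOT] + [p for p in ids if p != c]
        parents_options.append(opts)
    best = None
    for combo in itertools.product(*parents_options):
        assign = dict(zip(choose_for, combo))
        if stem is not None:
            assign[stem] = ROOT
        # reject cycles
        ok = True
        for c in ids:
            seen = {c}
            cur = assign[c]
            while cur != ROOT:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = assign[cur]
            if not ok:
                break
        if not ok:
            continue
        viol = 0
        charge_order = _cluster_order(Z, clusters)
        for bi in range(len(Z.biopsies)):
            load = {ROOT: 100.0}
            for c in ids:
                load[c] = float(Z.values[ids.index(c), bi])
            remaining = dict(load)
            # charge children in the same global order as the searcher
            for c in charge_order:
                z = load[c]
                p = assign[c]
                if z > 0 and remaining[p] < z - tol_overlap:
                    viol += 1
                remaining[p] -= z
        if best is None or viol < best:
            best = viol
            if best == 0:
                break
    return int(best if best is not None else 0)
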