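"""Rooted clone phylogenies from binary event matrices.

Subclones are the taxa; characters are the binary event rows of the
event matrix.  Trees are rooted in a cell carrying no alterations (a
pseudo-taxon with an all-zero genotype, labelled ``Root``), and branch
lengths are expressed in units of genetic alterations.

Maximum parsimony uses Fitch small-parsimony scoring with a ratchet-
style search (seeded random character reweighting around NNI
hill-climbs) started from a neighbor-joining tree on Hamming
distances; ancestral states and integer branch lengths come from a
minimum-change (Sankoff) refinement with accelerated-transformation
tie-breaking, which pushes state changes toward the root.

Maximum likelihood uses a time-reversible symmetric two-state Markov
model (the binary-character analog of equal-rates/equal-frequencies
nucleotide models): P(no flip over length t) = (1 + e^(-2t)) / 2.
Edge lengths of the NJ start tree are optimized numerically; topology
search via NNI is available but off by default.  Reported ML lengths
are rescaled to expected alterations per edge.

Contradiction analysis flags parallel evolution (the same event gained
on two or more branches, PLC) and back mutation (an event present in an
ancestor but absent in a descendant, BMC); events spanning a whole
chromosome or chromosome arm are marked exempt, except that a BMC on a
copy-number-neutral imbalance (an LOH-type event) is never exempt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .event_unification import EventCatalog

__all__ = [
    "Phylogeny",
    "PNode",
    "Contradiction",
    "ContradictionReport",
    "TreeStats",
    "hamming_matrix",
    "mp_tree",
    "ml_tree",
    "detect_contradictions",
    "tree_stats",
    "compare_topologies",
]

ROOT_LABEL = "Root"


class PNode:
    """Tree node; ``label`` is set for taxa (subclone ids) and the root."""

    __slots__ = ("label", "length", "children", "parent", "states")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length  # edge length to parent, in alterations
        self.children: list[PNode] = []
        self.parent: PNode | None = None
        self.states: np.ndarray | None = None  # per-event ancestral states

    def add(self, child: "PNode") -> "PNode":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in units of genetic alterations."""

    root: PNode
    method: str = "mp"  # {"mp", "ml", "manual"}
    score: float | None = None  # parsimony score or log-likelihood

    # -- traversal ----------------------------------------------------
    def postorder(self) -> list[PNode]:
        out: list[PNode] = []

        def walk(n: PNode):
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def preorder(self) -> list[PNode]:
        out: list[PNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def leaves(self) -> list[PNode]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[tuple[PNode, PNode]]:
        return [(n.parent, n) for n in self.postorder() if n.parent is not None]

    # -- Newick -------------------------------------------------------
    def to_newick(self) -> str:
        def min_leaf(n: PNode) -> str:
            if n.is_leaf():
                return n.label or ""
            return min(min_leaf(c) for c in n.children)

        def fmt_len(x: float) -> str:
            return f"{int(round(x))}" if abs(x - round(x)) < 1e-9 else f"{x:.6g}"

        def render(n: PNode) -> str:
            if n.is_leaf():
                return f"{n.label}:{fmt_len(n.length)}"
            inner = ",".join(render(c) for c in sorted(n.children, key=min_leaf))
            name = n.label or ""
            return f"({inner}){name}:{fmt_len(n.length)}"

        r = self.root
        inner = ",".join(render(c) for c in sorted(r.children, key=min_leaf))
        return f"({inner}){r.label or ''};"

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        s = text[:-1]
        pos = 0

        def parse_node() -> PNode:
            nonlocal pos
            node = PNode()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse_node())
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
            # name
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            name = s[start:pos].strip()
            if name:
                node.label = name
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                node.length = float(s[start:pos])
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in Newick: {s[pos:]!r}")
        return cls(root=root, method="manual")

    def copy(self) -> "Phylogeny":
        def dup(n: PNode) -> PNode:
            m = PNode(n.label, n.length)
            m.states = None if n.states is None else n.states.copy()
            for c in n.children:
                m.add(dup(c))
            return m

        return Phylogeny(root=dup(self.root), method=self.method, score=self.score)


# ---------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------

def hamming_matrix(E: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hamming distances between subclone columns (in events)."""
    X = E.to_numpy(dtype=int)
    diff = (X[:, :, None] != X[:, None, :]).sum(axis=0)
    return pd.DataFrame(diff, index=E.columns, columns=E.columns)


def _nj(labels: list[str], D: np.ndarray) -> PNode:
    """Plain neighbor joining; returns an unrooted tree represented as a
    rooted structure whose root is an arbitrary internal node."""
    nodes = [PNode(lab) for lab in labels]
    D = D.astype(float).copy()
    active = list(range(len(labels)))
    while len(active) > 2:
        n = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best, pair = None, None
        for ai in range(n):
            for bi in range(ai + 1, n):
                i, j = active[ai], active[bi]
                q = (n - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, pair = q, (i, j)
        i, j = pair
        vi = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (n - 2))
        vj = D[i][j] - vi
        parent = PNode()
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            D[k][m] = D[m][k] = 0.5 * (D[i][m] + D[j][m] - D[i][j])
        nodes.append(parent)
        active = [m for m in active if m not in (i, j)] + [k]
    i, j = active
    root = PNode()
    nodes[i].length = D[i][j] / 2
    nodes[j].length = D[i][j] / 2
    root.add(nodes[i])
    root.add(nodes[j])
    return root


def _reroot_at_leaf(tree_root: PNode, leaf_label: str) -> PNode:
    """Re-orient an (effectively unrooted) tree so the named leaf becomes
    the root, with a single child carrying that leaf's edge length."""
    # locate the leaf
    target = None
    stack = [tree_root]
    while stack:
        n = stack.pop()
        if n.is_leaf() and n.label == leaf_label:
            target = n
            break
        stack.extend(n.children)
    if target is None:
        raise ValueError(f"leaf {leaf_label!r} not found")

    # flip parent pointers along the path root..target
    path = []
    cur = target
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    new_root = PNode(target.label)
    attach = new_root
    edge_len = target.length
    for prev, node in zip(path, path[1:]):
        node.children = [c for c in node.children if c is not prev]
        node.parent = None
        carried = node.length
        node.length = edge_len
        edge_len = carried
        attach.add(node)
        attach = node
    # collapse degree-1 internal nodes created by removing the old root
    def collapse(n: PNode):
        for c in list(n.children):
            collapse(c)
        if not n.is_leaf() and len(n.children) == 1 and n.parent is not None and n.label is None:
            child = n.children[0]
            child.length += n.length
            n.parent.children[n.parent.children.index(n)] = child
            child.parent = n.parent

    for c in list(new_root.children):
        collapse(c)
    return new_root


# ---------------------------------------------------------------------
# maximum parsimony
# ---------------------------------------------------------------------

def _leaf_states(E: pd.DataFrame, include_root: bool) -> tuple[list[str], dict[str, np.ndarray]]:
    taxa = list(E.columns)
    states = {t: E[t].to_numpy(dtype=int) for t in taxa}
    if include_root:
        if ROOT_LABEL in states:
            raise ValueError(f"{ROOT_LABEL!r} clashes with a subclone id")
        taxa = [ROOT_LABEL] + taxa
        states[ROOT_LABEL] = np.zeros(E.shape[0], dtype=int)
    return taxa, states


def _fitch_score(root: PNode, states: dict[str, np.ndarray], weights: np.ndarray) -> float:
    """Weighted Fitch parsimony score of a rooted tree (root is the
    all-zero taxon with a single child)."""
    score = 0.0

    def sets(n: PNode) -> np.ndarray:
        nonlocal score
        if n.is_leaf():
            return (states[n.label] + 1).astype(np.int8)  # bitmask: 1->{0}, 2->{1}
        acc = None
        for c in n.children:
            cs = sets(c)
            if acc is None:
                acc = cs
            else:
                inter = acc & cs
                union_mask = inter == 0
                score += float(weights[union_mask].sum())
                acc = np.where(union_mask, acc | cs, inter)
        return acc

    child_sets = sets(root.children[0]) if root.children else None
    if child_sets is not None:
        own = (states[root.label] + 1).astype(np.int8)
        mism = (own & child_sets) == 0
        score += float(weights[mism].sum())
    return score


def _assign_states_min_change(tree: Phylogeny, states: dict[str, np.ndarray]) -> None:
    """Minimum-change ancestral states via per-character Sankoff costs,
    breaking ties toward changes near the root (acctran-style), then set
    integer branch lengths from state differences."""
    n_char = len(next(iter(states.values())))
    post = tree.postorder()
    cost: dict[int, np.ndarray] = {}  # id(node) -> (n_char, 2)
    INF = 1e18
    for n in post:
        c = np.zeros((n_char, 2))
        if n.is_leaf():
            sv = states[n.label]
            c[sv == 0, 1] = INF
            c[sv == 1, 0] = INF
        else:
            for ch in n.children:
                cc = cost[id(ch)]
                c[:, 0] += np.minimum(cc[:, 0], cc[:, 1] + 1)
                c[:, 1] += np.minimum(cc[:, 1], cc[:, 0] + 1)
            if n.label is not None:  # labelled internal (the root taxon)
                sv = states[n.label]
                c[sv == 0, 1] += INF
                c[sv == 1, 0] += INF
        cost[id(n)] = c

    root = tree.root
    rc = cost[id(root)]
    root.states = np.argmin(rc, axis=1).astype(np.int8)
    for n in tree.preorder():
        if n is root:
            continue
        ps = n.parent.states
        c = cost[id(n)]
        keep = c[np.arange(n_char), ps]
        flip = c[np.arange(n_char), 1 - ps] + 1
        # tie -> flip (accelerated transformation: change on this edge)
        n.states = np.where(flip <= keep, 1 - ps, ps).astype(np.int8)
        n.length = float(np.sum(n.states != ps))


def mp_tree(
    E: pd.DataFrame,
    ratchet_iters: int = 50,
    reweight_frac: float = 0.25,
    seed: int = 0,
) -> Phylogeny:
    """Maximum-parsimony clone tree rooted in the zero-alteration cell.

    Fitch scoring, NJ start tree, NNI hill-climbing wrapped in a
    seeded ratchet (a fraction of characters is double-weighted, the
    perturbed optimum re-climbed under unit weights); ancestral states
    and integer branch lengths by minimum-change refinement.
    """
    distinct = E.T.drop_duplicates().shape[0]
    taxa, states = _leaf_states(E, include_root=True)
    n_char = E.shape[0]
    weights1 = np.ones(n_char)

    if len(E.columns) == 1 or distinct == 1:
        # degenerate: a single (possibly repeated) genotype under the root
        root = PNode(ROOT_LABEL)
        for t in E.columns:
            root.add(PNode(t))
        tree = Phylogeny(root=root, method="mp")
        _assign_states_min_change(tree, states)
        tree.score = sum(n.length for n in tree.postorder() if n.parent)
        return tree

    H = hamming_matrix(pd.concat(
        [pd.Series(0, index=E.index, name=ROOT_LABEL), E], axis=1
    ))
    unrooted = _nj(list(H.columns), H.to_numpy())
    tree = Phylogeny(root=_reroot_at_leaf(unrooted, ROOT_LABEL), method="mp")

    def climb(t: Phylogeny, w: np.ndarray) -> Phylogeny:
        best = t
        best_score = _fitch_score(best.root, states, w)
        improved = True
        while improved:
            improved = False
            for nb in _rooted_nni(best):
                sc = _fitch_score(nb.root, states, w)
                if sc < best_score - 1e-9:
                    best, best_score = nb, sc
                    improved = True
                    break
        return best

    rng = np.random.default_rng(seed)
    best = climb(tree, weights1)
    best_score = _fitch_score(best.root, states, weights1)
    k = max(1, int(round(reweight_frac * n_char)))
    for _ in range(ratchet_iters):
        w = weights1.copy()
        w[rng.choice(n_char, size=k, replace=False)] += 1.0
        cand = climb(best.copy(), w)
        cand = climb(cand, weights1)
        sc = _fitch_score(cand.root, states, weights1)
        if sc < best_score - 1e-9:
            best, best_score = cand, sc
    _assign_states_min_change(best, states)
    best.score = float(sum(n.length for n in best.postorder() if n.parent is not None))
    return best


def _rooted_nni(tree: Phylogeny) -> list[Phylogeny]:
    """All NNI rearrangements: for each internal node v with parent u,
    exchange one child of v with one sibling of v."""
    out: list[Phylogeny] = []
    nodes = tree.postorder()
    for vi, v in enumerate(nodes):
        if v.is_leaf() or v.parent is None:
            continue
        u = v.parent
        for ci in range(len(v.children)):
            for s in u.children:
                if s is v:
                    continue
                si = u.children.index(s)
                t2 = tree.copy()
                n2 = t2.postorder()
                v2 = n2[vi]
                u2 = v2.parent
                child = v2.children[ci]
                sib = u2.children[si]
                v2.children[ci] = sib
                u2.children[si] = child
                sib.parent = v2
                child.parent = u2
                out.append(t2)
    return out


# ---------------------------------------------------------------------
# maximum likelihood (symmetric two-state model)
# ---------------------------------------------------------------------

def _log_likelihood(root: PNode, states: dict[str, np.ndarray], lengths: np.ndarray,
                    edge_index: dict[int, int]) -> float:
    """Felsenstein pruning under the binary symmetric model with
    equilibrium (1/2, 1/2); lengths are expected flips per character."""
    def partials(n: PNode) -> np.ndarray:
        if n.is_leaf() and n.label in states:
            sv = states[n.label]
            P = np.zeros((len(sv), 2))
            P[np.arange(len(sv)), sv] = 1.0
            return P
        acc = None
        for c in n.children:
            t = lengths[edge_index[id(c)]]
            psame = 0.5 * (1.0 + math.exp(-2.0 * t))
            pdiff = 1.0 - psame
            Pc = partials(c)
            M = Pc @ np.array([[psame, pdiff], [pdiff, psame]])
            acc = M if acc is None else acc * M
        if n.label in states:  # labelled internal node: clamp to its genotype
            sv = states[n.label]
            mask = np.zeros_like(acc)
            mask[np.arange(len(sv)), sv] = 1.0
            acc = acc * mask
        return acc

    top = partials(root)
    site = 0.5 * top.sum(axis=1)
    site = np.maximum(site, 1e-300)
    return float(np.log(site).sum())


def optimize_branch_lengths(
    tree: Phylogeny, E: pd.DataFrame, include_root: bool = True
) -> Phylogeny:
    """Numerically maximize the two-state likelihood over edge lengths.

    Edge lengths on the returned tree are rescaled to expected
    alterations (flips per character x number of characters); the
    log-likelihood is stored in ``tree.score``.
    """
    _, states = _leaf_states(E, include_root=include_root)
    t = tree.copy()
    edges = [n for n in t.postorder() if n.parent is not None]
    edge_index = {id(n): i for i, n in enumerate(edges)}
    n_char = E.shape[0]
    x0 = np.array([max(n.length / max(n_char, 1), 1e-4) for n in edges])

    def neg(x):
        return -_log_likelihood(t.root, states, x, edge_index)

    res = minimize(neg, x0, method="L-BFGS-B", bounds=[(1e-9, 20.0)] * len(x0))
    for n, ti in zip(edges, res.x):
        n.length = float(ti * n_char)
    t.score = float(-res.fun)
    t.method = "ml"
    return t


def ml_tree(
    E: pd.DataFrame,
    nni_moves: bool = False,
    seed: int = 0,
) -> Phylogeny:
    """Maximum-likelihood clone tree under the symmetric two-state model.

    NJ starting topology from Hamming distances; edge lengths optimized
    numerically (the model is time reversible, so root placement does
    not affect the likelihood); the tree is then rooted at the
    zero-alteration cell.  With ``nni_moves=True`` an NNI hill-climb on
    the likelihood wraps the edge optimization.
    """
    distinct = E.T.drop_duplicates().shape[0]
    taxa, states = _leaf_states(E, include_root=True)
    if len(E.columns) == 1 or distinct == 1:
        root = PNode(ROOT_LABEL)
        for t in E.columns:
            root.add(PNode(t))
        tree = Phylogeny(root=root, method="ml")
        _assign_states_min_change(tree, states)
        return optimize_branch_lengths(tree, E)

    n_char = E.shape[0]
    H = hamming_matrix(pd.concat(
        [pd.Series(0, index=E.index, name=ROOT_LABEL), E], axis=1
    ))
    unrooted = _nj(list(H.columns), H.to_numpy())
    tree = Phylogeny(root=_reroot_at_leaf(unrooted, ROOT_LABEL), method="ml")
    best = optimize_branch_lengths(tree, E)
    if nni_moves:
        improved = True
        while improved:
            improved = False
            for nb in _rooted_nni(best):
                cand = optimize_branch_lengths(nb, E)
                if cand.score > best.score + 1e-6:
                    best = cand
                    improved = True
                    break
    _ml_ancestral_states(best, states)
    return best


def _ml_ancestral_states(tree: Phylogeny, states: dict[str, np.ndarray]) -> None:
    """Maximum marginal ancestral states by clamping each node in turn."""
    edges = [n for n in tree.postorder() if n.parent is not None]
    edge_index = {id(n): i for i, n in enumerate(edges)}
    n_char = len(next(iter(states.values())))
    lengths = np.array([max(n.length / max(n_char, 1), 1e-9) for n in edges])

    # leaf/labelled states are known
    for n in tree.postorder():
        if n.label in states:
            n.states = states[n.label].astype(np.int8)
    # marginal argmax per unlabelled node via state clamping
    for n in tree.postorder():
        if n.states is not None:
            continue
        best = np.zeros(n_char, dtype=np.int8)
        ll = {}
        for s in (0, 1):
            clamp = {**states, "__clamp__": np.full(n_char, s, dtype=int)}
            n.label = "__clamp__"
            ll[s] = _sitewise_ll(tree.root, clamp, lengths, edge_index)
            n.label = None
        best[ll[1] > ll[0]] = 1
        n.states = best


def _sitewise_ll(root: PNode, states: dict[str, np.ndarray], lengths: np.ndarray,
                 edge_index: dict[int, int]) -> np.ndarray:
    def partials(n: PNode) -> np.ndarray:
        if n.is_leaf() and n.label in states:
            sv = states[n.label]
            P = np.zeros((len(sv), 2))
            P[np.arange(len(sv)), sv] = 1.0
            return P
        acc = None
        for c in n.children:
            t = lengths[edge_index[id(c)]]
            psame = 0.5 * (1.0 + math.exp(-2.0 * t))
            M = partials(c) @ np.array([[psame, 1 - psame], [1 - psame, psame]])
            acc = M if acc is None else acc * M
        if n.label in states:
            sv = states[n.label]
            mask = np.zeros_like(acc)
            mask[np.arange(len(sv)), sv] = 1.0
            acc = acc * mask
        return acc

    top = partials(root)
    return np.log(np.maximum(0.5 * top.sum(axis=1), 1e-300))


# ---------------------------------------------------------------------
# contradictions and statistics
# ---------------------------------------------------------------------

@dataclass
class Contradiction:
    event_id: str
    kind: str  # "PLC" or "BMC"
    branches: list[str]
    exempt: bool


@dataclass
class ContradictionReport:
    items: list[Contradiction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def non_exempt(self) -> list[Contradiction]:
        return [c for c in self.items if not c.exempt]

    def counts(self) -> dict[str, int]:
        return {
            "PLC": sum(1 for c in self.items if c.kind == "PLC"),
            "BMC": sum(1 for c in self.items if c.kind == "BMC"),
        }


def _branch_name(node: PNode) -> str:
    if node.label:
        return node.label
    labels = sorted(l.label for l in Phylogeny(root=node).leaves() if l.label)
    return "{" + ",".join(labels) + "}"


def detect_contradictions(
    tree: Phylogeny,
    E: pd.DataFrame,
    catalog: EventCatalog | None = None,
) -> ContradictionReport:
    """PLC/BMC scan over the tree's ancestral state reconstruction.

    PLC: an event gained (0 -> 1) on two or more distinct branches.
    BMC: an event lost (1 -> 0) on any branch.  Whole-chromosome and
    chromosome-arm events are flagged exempt (biologically plausible),
    but a BMC on a cnni event is never exempt.
    """
    if any(n.states is None for n in tree.postorder()):
        raise ValueError("tree has no ancestral states; build it with mp_tree/ml_tree")
    events = list(E.index)
    report = ContradictionReport()
    edges = [(p, c) for p, c in tree.edges()]
    for i, ev in enumerate(events):
        gains = [c for p, c in edges if p.states[i] == 0 and c.states[i] == 1]
        losses = [c for p, c in edges if p.states[i] == 1 and c.states[i] == 0]
        scope = catalog.scope.get(ev, "segmental") if catalog else "segmental"
        alt = None
        if catalog is not None:
            for rec in catalog.unique_events:
                if rec.event_id == ev:
                    alt = rec.alt_type
                    break
        scope_exempt = scope in {"whole_chromosome", "chromosome_arm"}
        if len(gains) >= 2:
            report.items.append(Contradiction(
                event_id=ev, kind="PLC",
                branches=[_branch_name(n) for n in gains],
                exempt=scope_exempt,
            ))
        if losses:
            bmc_exempt = scope_exempt and alt != "cnni"
            report.items.append(Contradiction(
                event_id=ev, kind="BMC",
                branches=[_branch_name(n) for n in losses],
                exempt=bmc_exempt,
            ))
    return report


@dataclass
class TreeStats:
    n_branches: int
    total_branch_length: float
    stem_length: float


def tree_stats(tree: Phylogeny) -> TreeStats:
    """Branch count, total length and stem length.

    The stem is the initial non-branching path from the root; branches
    are the remaining edges, not counting zero-length pendant edges
    (subclones identical to an ancestral genotype)."""
    stem_length = 0.0
    node = tree.root
    while len(node.children) == 1:
        node = node.children[0]
        stem_length += node.length
    below = [n for n in Phylogeny(root=node).postorder() if n is not node]
    n_branches = sum(1 for n in below if n.length > 1e-9)
    total = sum(n.length for n in tree.postorder() if n.parent is not None)
    return TreeStats(
        n_branches=n_branches,
        total_branch_length=float(total),
        stem_length=float(stem_length),
    )


def _canonical(node: PNode, collapse_tol: float):
    if node.is_leaf():
        return ("L", node.label)
    parts = []
    for c in node.children:
        sub = _canonical(c, collapse_tol)
        if not c.is_leaf() and c.length <= collapse_tol:
            parts.extend(sub[1])  # collapse short internal edge into parent
        else:
            parts.append(sub)
    return ("N", tuple(sorted(parts, key=repr)))


def compare_topologies(t1: Phylogeny, t2: Phylogeny, collapse_tol: float = 0.01) -> bool:
    """Unordered rooted-tree isomorphism on subclone labels.

    Branch lengths are ignored except that internal edges shorter than
    ``collapse_tol`` (alterations) are collapsed into polytomies first,
    so a fully resolved tree and its polytomous equivalent compare
    equal.  Raises on differing leaf sets.
    """
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return _canonical(t1.root, collapse_tol) == _canonical(t2.root, collapse_tol)
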