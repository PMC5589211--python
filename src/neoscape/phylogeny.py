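"""Tumor sample phylogenetics on binary mutation presence/absence characters.

The sample tree is reconstructed by maximum parsimony on the binary
non-silent mutation matrix: a UPGMA (average-linkage) starting tree on
Hamming distances, Fitch small-parsimony scoring, a parsimony-ratchet
search (alternating nearest-neighbor-interchange hill climbs on randomly
upweighted and original characters), and accelerated-transformation
(ACCTRAN-style) assignment of character changes to branches so that branch
lengths are in mutation units and sum to the parsimony score.

Scoring treats the tree as unrooted (the Fitch count is invariant under
re-rooting); an explicit all-zero outgroup row (e.g. a normal sample) may
be included for rooting and display.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


class PhylogenyError(ValueError):
    pass


@dataclass
class Node:
    """Tree node; ``length`` is the branch above the node (mutation units)."""

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node
    parsimony_score: int | None = None

    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def taxa(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def copy(self) -> "Tree":
        return Tree(root=copy.deepcopy(self.root),
                    parsimony_score=self.parsimony_score)

    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:g}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}):{n.length:g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# Distances and UPGMA starting tree
# ---------------------------------------------------------------------------

def hamming_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Unweighted Hamming distances between taxa (rows) of a binary matrix."""
    values = matrix.to_numpy(dtype=np.int8)
    if not np.isin(values, (0, 1)).all():
        raise PhylogenyError("binary matrix entries must be 0/1")
    diff = (values[:, None, :] != values[None, :, :]).sum(axis=2)
    return pd.DataFrame(diff, index=matrix.index, columns=matrix.index)


def upgma(dist: pd.DataFrame) -> Tree:
    """Average-linkage agglomerative (UPGMA) ultrametric tree.

    Taxa are sorted by id before clustering so equal-distance ties break
    deterministically.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise PhylogenyError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0):
        raise PhylogenyError("distance matrix diagonal must be zero")
    taxa = sorted(str(t) for t in dist.index)
    if len(taxa) < 2:
        raise PhylogenyError("need >= 2 taxa")
    d = dist.loc[taxa, taxa].to_numpy(dtype=float)
    if len(taxa) == 2:
        half = d[0, 1] / 2
        root = Node(children=[Node(taxa[0], half), Node(taxa[1], half)])
        return Tree(root=root)
    z = linkage(squareform(d, checks=False), method="average")
    nodes: dict[int, tuple[Node, float]] = {
        i: (Node(name=t), 0.0) for i, t in enumerate(taxa)
    }
    next_id = len(taxa)
    for a, b, dist_ab, _ in z:
        height = dist_ab / 2.0
        left, hl = nodes.pop(int(a))
        right, hr = nodes.pop(int(b))
        left.length = height - hl
        right.length = height - hr
        nodes[next_id] = (Node(children=[left, right]), height)
        next_id += 1
    (root, _), = nodes.values()
    return Tree(root=root)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _char_arrays(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    values = matrix.to_numpy(dtype=np.int8)
    if not np.isin(values, (0, 1)).all():
        raise PhylogenyError("binary matrix entries must be 0/1")
    return {str(t): values[i] for i, t in enumerate(matrix.index)}


def _fitch_sets(node: Node, chars: dict[str, np.ndarray],
                weights: np.ndarray, total: list[float]) -> np.ndarray:
    """Bottom-up Fitch pass; states as 2-bit masks (1 -> state 0, 2 -> state 1)."""
    if node.is_leaf:
        if node.name not in chars:
            raise PhylogenyError(f"taxon {node.name!r} missing from the matrix")
        return np.where(chars[node.name] == 1, 2, 1).astype(np.int8)
    masks = [_fitch_sets(c, chars, weights, total) for c in node.children]
    acc = masks[0]
    for m in masks[1:]:
        inter = acc & m
        union_needed = inter == 0
        total[0] += float(weights[union_needed].sum())
        acc = np.where(union_needed, acc | m, inter).astype(np.int8)
    return acc


def fitch_score(tree: Tree, matrix: pd.DataFrame,
                weights: np.ndarray | None = None) -> float:
    """Minimum number of (weighted) character changes on the tree.

    The score is invariant under re-rooting, so it is the unrooted
    parsimony score.
    """
    chars = _char_arrays(matrix)
    tree_taxa = set(tree.taxa())
    if tree_taxa != set(chars):
        raise PhylogenyError("tree leaves must equal matrix taxa")
    n_chars = matrix.shape[1]
    if weights is None:
        weights = np.ones(n_chars)
    total = [0.0]
    _fitch_sets(tree.root, chars, np.asarray(weights, dtype=float), total)
    return total[0]


# ---------------------------------------------------------------------------
# Re-rooting (topology-only; lengths reassigned by ACCTRAN afterwards)
# ---------------------------------------------------------------------------

def _adjacency(root: Node) -> dict[int, list[Node]]:
    adj: dict[int, list[Node]] = {}

    def walk(n: Node) -> None:
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append(c)
            adj.setdefault(id(c), []).append(n)
            walk(c)

    walk(root)
    return adj


def reroot_at_leaf(tree: Tree, leaf_name: str) -> Tree:
    """Root the (unrooted) topology on the edge leading to a leaf.

    The new root has the leaf as its first child; degree-2 nodes left over
    from the old rooting are suppressed.  Branch lengths are discarded.
    """
    adj = _adjacency(tree.root)
    by_id = {}

    def index(n: Node) -> None:
        by_id[id(n)] = n
        for c in n.children:
            index(c)

    index(tree.root)
    leaf = next((l for l in tree.leaves() if l.name == leaf_name), None)
    if leaf is None:
        raise PhylogenyError(f"leaf {leaf_name!r} not in tree")
    (anchor,) = adj[id(leaf)]

    def build(n: Node, parent: Node) -> Node:
        kids = [k for k in adj[id(n)] if k is not parent]
        if n.is_leaf and not kids:
            return Node(name=n.name)
        if len(kids) == 1:  # suppress degree-2 node (old root)
            return build(kids[0], n)
        return Node(children=[build(k, n) for k in kids])

    root = Node(children=[Node(name=leaf.name), build(anchor, leaf)])
    return Tree(root=root)


# ---------------------------------------------------------------------------
# NNI local search and the parsimony ratchet
# ---------------------------------------------------------------------------

def _internal_edges(tree: Tree) -> list[tuple[Node, Node]]:
    """(parent, child) pairs with both internal and parent not the root
    (with the root on a leaf edge these are exactly the internal edges of
    the unrooted topology)."""
    edges = []

    def walk(n: Node, is_root: bool) -> None:
        for c in n.children:
            if not is_root and not n.is_leaf and not c.is_leaf:
                edges.append((n, c))
            walk(c, False)

    walk(tree.root, True)
    return edges


def _apply_nni(tree: Tree, edge_index: int, option: int) -> Tree:
    """NNI rearrangement ``option`` (0 or 1) on internal edge ``edge_index``,
    returned as a new tree.  For edge (parent, child) the child's
    ``option``-th subtree is exchanged with the child's sibling; the two
    options are the two NNI neighbors across that edge."""
    out = tree.copy()
    parent, child = _internal_edges(out)[edge_index]
    sib_pos = next(i for i, c in enumerate(parent.children) if c is not child)
    sibling = parent.children[sib_pos]
    parent.children[sib_pos] = child.children[option]
    child.children[option] = sibling
    return out


def _nni_local_search(tree: Tree, matrix: pd.DataFrame,
                      weights: np.ndarray) -> tuple[Tree, float]:
    """First-improvement NNI hill climb to a local optimum."""
    score = fitch_score(tree, matrix, weights)
    improved = True
    while improved:
        improved = False
        n_edges = len(_internal_edges(tree))
        for e in range(n_edges):
            for option in (0, 1):
                candidate = _apply_nni(tree, e, option)
                s = fitch_score(candidate, matrix, weights)
                if s < score:
                    tree, score = candidate, s
                    improved = True
                    break
            if improved:
                break
    return tree, score


def parsimony_ratchet(
    matrix: pd.DataFrame,
    start: Tree | None = None,
    iterations: int = 100,
    reweight_fraction: float = 0.25,
    reweight_multiplier: float = 5.0,
    seed: int | None = None,
) -> Tree:
    """Parsimony-ratchet search for a minimum-length unrooted topology.

    Each iteration upweights a random ``reweight_fraction`` of characters
    by ``reweight_multiplier``, hill-climbs by NNI on the weighted score,
    restores unit weights and climbs again; the walk continues from each
    cycle's endpoint while the best tree seen is retained.  The multiplier
    is larger than the classic weight-doubling because the NNI
    neighborhood is far smaller than the tree-bisection searches the
    ratchet was designed around: a stronger deformation of the score
    landscape is needed to dislodge the walk from strict NNI local optima.
    With <= 3 taxa the topology is unique and the start tree is returned
    unchanged.  Branch lengths of the returned tree are ACCTRAN change
    counts and its ``parsimony_score`` is set.
    """
    if iterations < 1:
        raise PhylogenyError("iterations must be >= 1")
    if start is None:
        start = upgma(hamming_distances(matrix))
    taxa = sorted(start.taxa())
    if len(taxa) <= 3:
        out = start.copy()
        out.parsimony_score = int(fitch_score(out, matrix))
        return acctran_branch_lengths(out, matrix)
    rng = np.random.default_rng(seed)
    n_chars = matrix.shape[1]
    unit = np.ones(n_chars)

    current = reroot_at_leaf(start, taxa[0])
    current, current_score = _nni_local_search(current, matrix, unit)
    best, best_score = current, current_score
    for _ in range(iterations):
        heavy = unit.copy()
        k = max(1, round(reweight_fraction * n_chars))
        heavy[rng.choice(n_chars, size=k, replace=False)] = reweight_multiplier
        current = current.copy()
        current, _ = _nni_local_search(current, matrix, heavy)
        current, current_score = _nni_local_search(current, matrix, unit)
        # the walk continues from the cycle endpoint even when it did not
        # improve on the incumbent — that drift is what escapes local optima
        if current_score < best_score:
            best, best_score = current, current_score
    best.parsimony_score = int(best_score)
    return acctran_branch_lengths(best, matrix)


# ---------------------------------------------------------------------------
# ACCTRAN branch lengths
# ---------------------------------------------------------------------------

def acctran_branch_lengths(tree: Tree, matrix: pd.DataFrame) -> Tree:
    """Assign character changes to branches, preferring early placement.

    After the bottom-up Fitch pass, internal states are resolved top-down:
    the root takes state 0 (character absence — the state of a somatic
    mutation before it arises, and of any outgroup) whenever its state set
    is ambiguous; a child inherits the parent state when compatible and
    otherwise changes on the connecting branch, which places changes as
    close to the root as the ambiguity allows.  Branch lengths are per-edge
    change counts summed over characters; their sum equals the parsimony
    score, which is (re)computed and stored on the tree.
    """
    chars = _char_arrays(matrix)
    if set(tree.taxa()) != set(chars):
        raise PhylogenyError("tree leaves must equal matrix taxa")
    n_chars = matrix.shape[1]
    weights = np.ones(n_chars)
    sets: dict[int, np.ndarray] = {}

    def up(node: Node) -> np.ndarray:
        if node.is_leaf:
            mask = np.where(chars[node.name] == 1, 2, 1).astype(np.int8)
        else:
            masks = [up(c) for c in node.children]
            acc = masks[0]
            for m in masks[1:]:
                inter = acc & m
                acc = np.where(inter == 0, acc | m, inter).astype(np.int8)
            mask = acc
        sets[id(node)] = mask
        return mask

    up(tree.root)

    root_set = sets[id(tree.root)]
    # ambiguous root -> state 0 (absence); else the determined state
    root_state = np.where(root_set == 2, 1, 0).astype(np.int8)

    def down(node: Node, state: np.ndarray) -> float:
        total = 0.0
        for c in node.children:
            cset = sets[id(c)]
            cstate_mask = np.int8(1) << state  # parent state as a mask
            compatible = (cset & cstate_mask) != 0
            child_state = np.where(
                compatible, state, np.where(cset == 2, 1, 0)
            ).astype(np.int8)
            changes = int(np.sum(child_state != state))
            c.length = float(changes)
            total += changes
            total += down(c, child_state)
        return total

    total = down(tree.root, root_state)
    tree.root.length = 0.0
    tree.parsimony_score = int(total)
    return tree


# ---------------------------------------------------------------------------
# Exact small-instance solver (exhaustive enumeration)
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa: list[str]) -> Iterator[Tree]:
    """All distinct unrooted binary topologies, as trees rooted on the
    first taxon's edge.  Feasible for <= ~8 taxa ((2n-5)!! topologies)."""
    taxa = sorted(taxa)
    if len(taxa) < 2:
        raise PhylogenyError("need >= 2 taxa")

    def grow(tree_root: Node, remaining: list[str]) -> Iterator[Node]:
        if not remaining:
            yield copy.deepcopy(tree_root)
            return
        nxt, rest = remaining[0], remaining[1:]

        def edges(n: Node):
            for i, c in enumerate(n.children):
                yield n, i
                yield from edges(c)

        for parent, i in list(edges(tree_root)):
            old = parent.children[i]
            parent.children[i] = Node(children=[old, Node(name=nxt)])
            yield from grow(tree_root, rest)
            parent.children[i] = old

    if len(taxa) == 2:
        yield Tree(root=Node(children=[Node(name=taxa[0]), Node(name=taxa[1])]))
        return
    base = Node(children=[Node(name=taxa[0]),
                          Node(children=[Node(name=taxa[1]), Node(name=taxa[2])])])
    for root in grow(base, taxa[3:]):
        yield Tree(root=root)


def exhaustive_min_score(matrix: pd.DataFrame) -> float:
    """Exact minimum parsimony score by enumerating every unrooted topology."""
    taxa = [str(t) for t in matrix.index]
    return min(
        fitch_score(t, matrix) for t in enumerate_unrooted_topologies(taxa)
    )
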