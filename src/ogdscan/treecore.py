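"""Unrooted bifurcating trees with exact prune/regraft geometry.

This module is the coordinate system for the whole package: branches are
identified by the leaf set ("clade") on their designated side, points on
branches are (branch, offset) pairs, and every distance reported downstream
(placement distances, dating intervals, donor--acceptor distances) is a
path length in substitutions per site measured here.

Conventions
-----------
* Trees are unrooted and fully bifurcating (internal nodes have degree 3).
  An optional *root point* may sit anywhere on one branch; when it is set,
  every branch's clade is its root-distal leaf set, and the branch carrying
  the root point uses the side designated at rooting time.
* Without a root point, branches are oriented away from a fixed traversal
  anchor (the internal node adjacent to the lexicographically smallest
  leaf), which makes enumeration deterministic and reproducible.
* Branch lengths are nonnegative; zero-length branches are legal and
  contribute nothing to path lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy

__all__ = [
    "Tree",
    "BranchRef",
    "TreePoint",
    "PrunedTree",
    "Subtree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "enumerate_branches",
    "root_between",
    "prune_clade",
    "insertion_points",
    "regraft",
    "path_length",
    "clade_total_length",
    "lca",
    "branch_midpoint",
    "trees_equal",
]

LENGTH_TOL = 1e-9


class NewickError(ValueError):
    """Raised for malformed, non-bifurcating or duplicate-label Newick input."""


@dataclass(frozen=True)
class BranchRef:
    """A branch identified by the leaf set on its designated (distal) side."""

    clade: FrozenSet[str]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        names = sorted(self.clade)
        shown = ",".join(names[:4]) + (",..." if len(names) > 4 else "")
        return f"BranchRef({{{shown}}})"


@dataclass(frozen=True)
class TreePoint:
    """A point on a branch, ``offset`` substitutions/site from the proximal end.

    The proximal end of a branch is its anchor-ward (or root-ward) endpoint
    under the tree's orientation convention.
    """

    branch: BranchRef
    offset: float


@dataclass
class Subtree:
    """The component removed by :func:`prune_clade`.

    ``adj``/``labels`` describe the internal structure, ``root`` is the node
    that was attached to the residual tree, and ``stem_length`` is the length
    of the branch that connected it.  A pruned single leaf has an empty
    adjacency and ``root`` equal to the leaf node.
    """

    adj: Dict[int, Dict[int, float]]
    labels: Dict[int, str]
    root: int
    stem_length: float

    @property
    def leaves(self) -> FrozenSet[str]:
        return frozenset(self.labels.values())


class Tree:
    """Unrooted bifurcating phylogeny with branch lengths and optional root point."""

    def __init__(
        self,
        adj: Dict[int, Dict[int, float]],
        labels: Dict[int, str],
    ) -> None:
        self.adj = adj
        self.labels = labels
        self.leaf_of = {name: node for node, name in labels.items()}
        # root point, stored structurally: (node_u, node_v, offset_from_u, side_clade)
        self._root_edge: Optional[Tuple[int, int, float, FrozenSet[str]]] = None
        self._validate()
        self._index()

    # -- validation / indexing -------------------------------------------------

    def _validate(self) -> None:
        if len(self.labels) != len(set(self.labels.values())):
            raise NewickError("duplicate leaf labels")
        for node, nbrs in self.adj.items():
            deg = len(nbrs)
            if node in self.labels:
                if deg != 1:
                    raise NewickError(f"leaf {self.labels[node]!r} has degree {deg}")
            elif deg != 3:
                raise NewickError(
                    f"internal node has degree {deg}; tree must be fully bifurcating"
                )
            for other, length in nbrs.items():
                if length < 0:
                    raise ValueError("negative branch length")
                if not math.isclose(
                    self.adj[other][node], length, rel_tol=0, abs_tol=0
                ):
                    raise ValueError("asymmetric adjacency")
        n = len(self.labels)
        if n < 3:
            raise ValueError("tree must have at least 3 leaves")

    def _index(self) -> None:
        """Orient every edge away from the anchor (or root point) and cache clades."""
        self._anchor_leaf = min(self.leaf_of)
        # parent map: child node -> (parent node, branch length)
        parent: Dict[int, Tuple[int, float]] = {}
        if self._root_edge is None:
            start = next(iter(self.adj[self.leaf_of[self._anchor_leaf]]))
            roots = [start]
        else:
            u, v, _off, _side = self._root_edge
            roots = [u, v]
            # the two halves of the root edge are oriented away from the point
        seen = set(roots)
        order: List[int] = list(roots)
        i = 0
        while i < len(order):
            node = order[i]
            i += 1
            for nbr, length in self.adj[node].items():
                if nbr in seen:
                    continue
                if self._root_edge is not None:
                    u, v, _o, _s = self._root_edge
                    if {node, nbr} == {u, v}:
                        continue  # the root edge is split by the root point
                seen.add(nbr)
                parent[nbr] = (node, length)
                order.append(nbr)
        if len(seen) != len(self.adj):
            raise ValueError("tree is not connected")
        self._parent = parent
        self._preorder = order
        self._orient_roots = roots
        # leaf set below each node (relative to orientation)
        below: Dict[int, FrozenSet[str]] = {}
        for node in reversed(order):
            if node in self.labels:
                below[node] = frozenset([self.labels[node]])
            else:
                kids = [c for c in self.adj[node] if self._parent.get(c, (None,))[0] == node]
                acc: FrozenSet[str] = frozenset()
                for c in kids:
                    acc |= below[c]
                below[node] = acc
        # top-of-tree nodes (roots of orientation) get full leaf sets of their side
        self._below = below
        # build branch table: clade -> (proximal node, distal node, length)
        branches: Dict[FrozenSet[str], Tuple[int, int, float]] = {}
        for child, (par, length) in parent.items():
            branches[below[child]] = (par, child, length)
        if self._root_edge is not None:
            u, v, off, side = self._root_edge
            length = self.adj[u][v]
            # the root branch appears once, with its designated side as clade;
            # proximal endpoint = the endpoint on the non-designated side.
            if below[u] == side:
                branches[side] = (v, u, length)
            elif below[v] == side:
                branches[side] = (u, v, length)
            else:  # side stored explicitly (must equal one component's leaves)
                raise ValueError("root designated side does not match either component")
        else:
            # the anchor leaf's pendant branch: oriented with the anchor distal
            anchor_node = self.leaf_of[self._anchor_leaf]
            par = next(iter(self.adj[anchor_node]))
            branches[frozenset([self._anchor_leaf])] = (
                par,
                anchor_node,
                self.adj[anchor_node][par],
            )
        self._branches = branches

    # -- basic properties ------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_names(self) -> FrozenSet[str]:
        return frozenset(self.labels.values())

    @property
    def root_point(self) -> Optional[TreePoint]:
        if self._root_edge is None:
            return None
        u, v, off, side = self._root_edge
        ref = BranchRef(side)
        prox, dist, length = self._branches[side]
        # stored offset is from u; express it from the proximal endpoint
        offset = off if prox == u else length - off
        return TreePoint(ref, offset)

    @property
    def is_rooted(self) -> bool:
        return self._root_edge is not None

    def branches(self) -> List[BranchRef]:
        """Deterministic branch list (post-order over the oriented tree)."""
        order: List[BranchRef] = []
        seen = set()

        def key(clade: FrozenSet[str]) -> str:
            return min(clade)

        # post-order: children before parents, siblings sorted by smallest leaf
        def visit(node: int) -> None:
            kids = sorted(
                (c for c in self.adj[node] if self._parent.get(c, (None,))[0] == node),
                key=lambda c: min(self._below[c]),
            )
            for c in kids:
                visit(c)
                clade = self._below[c]
                if clade in self._branches and clade not in seen:
                    seen.add(clade)
                    order.append(BranchRef(clade))

        for top in sorted(set(self._orient_roots), key=lambda t: min(self._below[t])):
            visit(top)
        # branches not reachable as child edges (root branch / anchor pendant)
        for clade in self._branches:
            if clade not in seen:
                order.append(BranchRef(clade))
                seen.add(clade)
        return order

    def branch_length(self, branch: BranchRef) -> float:
        return self._resolve(branch)[2]

    def _resolve(self, branch: BranchRef) -> Tuple[int, int, float]:
        """Return (proximal node, distal node, length) for a branch.

        A reference by the complement leaf set resolves to the same physical
        edge with the orientation flipped, so callers may name either side of
        a bipartition; the requested side is always the distal one.
        """
        if branch.clade in self._branches:
            return self._branches[branch.clade]
        comp = self.leaf_names - branch.clade
        if comp in self._branches:
            prox, dist, length = self._branches[comp]
            return dist, prox, length
        raise KeyError(f"branch {branch!r} not in tree")

    def has_branch(self, branch: BranchRef) -> bool:
        return (
            branch.clade in self._branches
            or (self.leaf_names - branch.clade) in self._branches
        )

    def copy(self) -> "Tree":
        t = Tree(
            {n: dict(nb) for n, nb in self.adj.items()},
            dict(self.labels),
        )
        t._root_edge = self._root_edge
        t._index()
        return t

    # -- geometry helpers ------------------------------------------------------

    def node_distances(self, source: int) -> Dict[int, float]:
        dist = {source: 0.0}
        stack = [source]
        while stack:
            node = stack.pop()
            for nbr, length in self.adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    stack.append(nbr)
        return dist


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Strictly bifurcating input is required: any polytomy is rejected because
    the placement algebra (2n-3 branch counts, unique merge on prune) assumes
    bifurcation.  A rooted Newick (two children at the top level) is read as
    an unrooted tree with a root point at the junction of the two top-level
    branches.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from None

    seed = dtree.seed_node
    top_children = seed.child_nodes()
    if len(top_children) not in (2, 3):
        raise NewickError(
            f"top-level node has {len(top_children)} children; expected 2 (rooted) or 3 (unrooted)"
        )

    adj: Dict[int, Dict[int, float]] = {}
    labels: Dict[int, str] = {}
    ids: Dict[object, int] = {}

    def nid(dnode: object) -> int:
        if dnode not in ids:
            ids[dnode] = len(ids)
            adj[ids[dnode]] = {}
        return ids[dnode]

    for dnode in dtree.preorder_node_iter():
        kids = dnode.child_nodes()
        if dnode is not seed and kids and len(kids) != 2:
            raise NewickError(f"polytomy of degree {len(kids) + 1} rejected")
        if not kids:
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickError("leaf without a label")
            labels[nid(dnode)] = dnode.taxon.label
        else:
            nid(dnode)
        for kid in kids:
            length = kid.edge.length
            length = 0.0 if length is None else float(length)
            if length < 0:
                raise NewickError("negative branch length")
            a, b = nid(dnode), nid(kid)
            adj[a][b] = length
            adj[b][a] = length

    root_info: Optional[Tuple[int, int, float, FrozenSet[str]]] = None
    if len(top_children) == 2:
        # merge the two top edges; the root point sits at the junction
        r = ids[seed]
        (c1, c2) = (ids[top_children[0]], ids[top_children[1]])
        l1, l2 = adj[r][c1], adj[r][c2]
        del adj[c1][r], adj[c2][r], adj[r]
        adj[c1][c2] = l1 + l2
        adj[c2][c1] = l1 + l2
        # leaves on c1's side
        side = _component_leaves(adj, labels, c1, c2)
        root_info = (c1, c2, l1, frozenset(side))

    if len(labels) != len(set(labels.values())):
        dupes = sorted(
            {v for v in labels.values() if sum(1 for x in labels.values() if x == v) > 1}
        )
        raise NewickError(f"duplicate leaf labels: {dupes}")

    tree = Tree(adj, labels)
    if root_info is not None:
        tree._root_edge = root_info
        tree._index()
    return tree


def _component_leaves(
    adj: Dict[int, Dict[int, float]],
    labels: Dict[int, str],
    start: int,
    blocked: int,
) -> set:
    seen = {start, blocked}
    stack = [start]
    out = set()
    while stack:
        node = stack.pop()
        if node in labels:
            out.add(labels[node])
        for nbr in adj[node]:
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return out


def _fmt_len(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: Tree) -> str:
    """Serialise a :class:`Tree`; rooted Newick is emitted when a root point is set."""

    def subtree_str(node: int, parent: int) -> str:
        if node in tree.labels:
            return tree.labels[node]
        kids = sorted(
            (nbr for nbr in tree.adj[node] if nbr != parent),
            key=lambda c: min(_component_leaves(tree.adj, tree.labels, c, node)),
        )
        parts = [
            f"{subtree_str(k, node)}:{_fmt_len(tree.adj[node][k])}" for k in kids
        ]
        return "(" + ",".join(parts) + ")"

    if tree._root_edge is not None:
        u, v, off, side = tree._root_edge
        total = tree.adj[u][v]
        su = f"{subtree_str(u, v)}:{_fmt_len(off)}"
        sv = f"{subtree_str(v, u)}:{_fmt_len(total - off)}"
        # designated side written first for reproducibility
        u_side = _component_leaves(tree.adj, tree.labels, u, v)
        first, second = (su, sv) if frozenset(u_side) == side else (sv, su)
        return f"({first},{second});"

    # unrooted: trifurcation at the internal node next to the anchor leaf
    anchor = tree.leaf_of[min(tree.leaf_of)]
    hub = next(iter(tree.adj[anchor]))
    kids = sorted(
        tree.adj[hub],
        key=lambda c: min(_component_leaves(tree.adj, tree.labels, c, hub)),
    )
    parts = [f"{subtree_str(k, hub)}:{_fmt_len(tree.adj[hub][k])}" for k in kids]
    return "(" + ",".join(parts) + ");"


# ---------------------------------------------------------------------------
# Branch enumeration / rooting
# ---------------------------------------------------------------------------


def enumerate_branches(tree: Tree) -> List[BranchRef]:
    """All 2n-3 branches in a deterministic post-order."""
    if tree.n_leaves < 4:
        raise ValueError("branch enumeration requires at least 4 leaves")
    return tree.branches()


def root_between(
    tree: Tree,
    branch: BranchRef,
    fraction: float,
    designated_side: Optional[FrozenSet[str]] = None,
) -> Tree:
    """Place the root point ``fraction`` of the way along ``branch``.

    ``fraction`` is measured from the branch's proximal endpoint under the
    current orientation.  ``designated_side`` names the clade recorded for
    the branch that carries the root point (default: the branch's current
    distal side).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    prox, dist, length = tree._resolve(branch)
    side = frozenset(designated_side) if designated_side is not None else branch.clade
    if side not in (
        frozenset(_component_leaves(tree.adj, tree.labels, prox, dist)),
        frozenset(_component_leaves(tree.adj, tree.labels, dist, prox)),
    ):
        raise ValueError("designated side must be one side of the root branch")
    out = Tree({n: dict(nb) for n, nb in tree.adj.items()}, dict(tree.labels))
    # offset stored from `prox`; Tree stores it from its first node u = prox
    out._root_edge = (prox, dist, fraction * length, side)
    out._index()
    return out


# ---------------------------------------------------------------------------
# Prune / regraft
# ---------------------------------------------------------------------------


@dataclass
class PrunedTree:
    """Residual tree after removing a clade, plus what is needed to restore it."""

    residual: Tree
    attachment_point: TreePoint
    subtree: Subtree
    pruned_branch: BranchRef  # the branch of the original tree that was pruned


def prune_clade(tree: Tree, branch: BranchRef) -> PrunedTree:
    """Detach ``branch``'s clade; the two branches flanking its attachment merge."""
    prox, dist, stem_len = tree._resolve(branch)
    clade = branch.clade
    residual_leaves = tree.leaf_names - clade
    if len(residual_leaves) < 3:
        raise ValueError(
            f"cannot prune clade of {len(clade)} leaves: residual tree must keep >= 3 leaves"
        )
    # collect subtree nodes (dist side)
    sub_nodes = _component_nodes(tree.adj, dist, prox)
    sub_adj = {
        n: {m: l for m, l in tree.adj[n].items() if m in sub_nodes} for n in sub_nodes
    }
    sub_labels = {n: tree.labels[n] for n in sub_nodes if n in tree.labels}
    subtree = Subtree(adj=sub_adj, labels=sub_labels, root=dist, stem_length=stem_len)

    # residual adjacency
    res_adj = {
        n: dict(nb)
        for n, nb in tree.adj.items()
        if n not in sub_nodes
    }
    for n in res_adj:
        for m in list(res_adj[n]):
            if m in sub_nodes:
                del res_adj[n][m]
    # prox now has exactly 2 neighbours a, b: merge
    a, b = sorted(res_adj[prox])
    la, lb = res_adj[prox][a], res_adj[prox][b]
    del res_adj[a][prox], res_adj[b][prox], res_adj[prox]
    res_adj[a][b] = la + lb
    res_adj[b][a] = la + lb
    res_labels = {n: l for n, l in tree.labels.items() if n not in sub_nodes}
    residual = Tree(res_adj, res_labels)

    merged_ref = _branch_of_edge(residual, a, b)
    rprox, rdist, rlen = residual._resolve(merged_ref)
    # attachment offset measured from the merged branch's proximal endpoint
    offset = la if rprox == a else lb
    point = TreePoint(merged_ref, offset)
    return PrunedTree(
        residual=residual, attachment_point=point, subtree=subtree, pruned_branch=branch
    )


def _component_nodes(adj: Dict[int, Dict[int, float]], start: int, blocked: int) -> set:
    seen = {start, blocked}
    stack = [start]
    out = {start}
    while stack:
        node = stack.pop()
        for nbr in adj[node]:
            if nbr not in seen:
                seen.add(nbr)
                out.add(nbr)
                stack.append(nbr)
    return out


def _branch_of_edge(tree: Tree, a: int, b: int) -> BranchRef:
    for clade, (p, d, _l) in tree._branches.items():
        if {p, d} == {a, b}:
            return BranchRef(clade)
    raise KeyError("edge not found")


def insertion_points(
    pruned: PrunedTree, position: str = "midpoint"
) -> List[TreePoint]:
    """One candidate point per residual branch (2m-3 for m residual leaves).

    Candidates sit at each residual branch's midpoint (or proximal endpoint
    when ``position='proximal'``), except that on the branch holding the
    original attachment the exact attachment point is used, so the original
    placement is always a member of the candidate set.
    """
    if position not in ("midpoint", "proximal"):
        raise ValueError("position must be 'midpoint' or 'proximal'")
    res = pruned.residual
    points = []
    for ref in res.branches():
        if ref == pruned.attachment_point.branch:
            points.append(pruned.attachment_point)
        else:
            length = res.branch_length(ref)
            off = length / 2.0 if position == "midpoint" else 0.0
            points.append(TreePoint(ref, off))
    return points


def regraft(pruned: PrunedTree, point: TreePoint) -> Tree:
    """Reattach the pruned subtree at ``point`` on the residual tree."""
    res = pruned.residual
    prox, dist, length = res._resolve(point.branch)
    if not -LENGTH_TOL <= point.offset <= length + LENGTH_TOL:
        raise ValueError("insertion point lies off its branch")
    off = min(max(point.offset, 0.0), length)

    new_id = max(
        max(res.adj), max(pruned.subtree.adj, default=pruned.subtree.root)
    ) + 1
    adj = {n: dict(nb) for n, nb in res.adj.items()}
    labels = dict(res.labels)
    # splice subtree structure in (node ids are disjoint by construction: the
    # subtree kept its original ids, the residual kept its own)
    for n, nb in pruned.subtree.adj.items():
        adj[n] = dict(nb)
    labels.update(pruned.subtree.labels)

    w = new_id
    del adj[prox][dist], adj[dist][prox]
    adj[w] = {}
    adj[prox][w] = off
    adj[w][prox] = off
    adj[dist][w] = length - off
    adj[w][dist] = length - off
    g = pruned.subtree.root
    if g not in adj:
        adj[g] = {}
    adj[w][g] = pruned.subtree.stem_length
    adj[g][w] = pruned.subtree.stem_length
    return Tree(adj, labels)


# ---------------------------------------------------------------------------
# Path-length geometry
# ---------------------------------------------------------------------------


def _point_nodes(tree: Tree, p: TreePoint) -> Tuple[int, float, int, float]:
    prox, dist, length = tree._resolve(p.branch)
    if not -LENGTH_TOL <= p.offset <= length + LENGTH_TOL:
        raise ValueError("point offset outside branch")
    off = min(max(p.offset, 0.0), length)
    return prox, off, dist, length - off


def path_length(tree: Tree, a: TreePoint, b: TreePoint) -> float:
    """Sum of branch-length segments along the unique path between two points."""
    if a.branch == b.branch:
        return abs(a.offset - b.offset)
    pa, offa, da, resta = _point_nodes(tree, a)
    pb, offb, db, restb = _point_nodes(tree, b)
    dist_from_pa = tree.node_distances(pa)
    dist_from_da = tree.node_distances(da)
    # exit point a through either endpoint; tree metric => min is the true path
    best = min(
        offa + dist_from_pa[pb] + offb,
        offa + dist_from_pa[db] + restb,
        resta + dist_from_da[pb] + offb,
        resta + dist_from_da[db] + restb,
    )
    return best


def branch_midpoint(tree: Tree, branch: BranchRef) -> TreePoint:
    return TreePoint(branch, tree.branch_length(branch) / 2.0)


def clade_total_length(tree: Tree, branch: BranchRef) -> float:
    """Total branch length inside the clade a branch defines.

    For an internal branch this sums every branch strictly inside the clade
    (the subtending branch itself is excluded); for a leaf branch it is the
    leaf's own branch length.
    """
    if not tree.is_rooted:
        raise ValueError("clade_total_length requires a rooted tree")
    if not tree.has_branch(branch):
        raise KeyError("branch not in tree")
    clade = branch.clade
    if len(clade) == 1:
        return tree.branch_length(branch)
    total = 0.0
    for other, (_p, _d, length) in tree._branches.items():
        if other != clade and other <= clade:
            total += length
    return total


def lca(tree: Tree, a: BranchRef, b: BranchRef) -> Tuple[Optional[int], bool]:
    """Last common ancestor of two branches' clades on the rooted tree.

    Returns ``(node, nested)``.  ``node`` is a node id, or ``None`` when the
    LCA is the root point itself (the two branches hang off opposite sides of
    the root).  ``nested`` is True when one branch is ancestral to the other,
    in which case ``node`` is the ancestral branch's proximal node.
    Consumers (the ancestral-donor filter, dating) treat nested pairs
    specially.
    """
    if not tree.is_rooted:
        raise ValueError("lca requires a rooted tree")
    if a == b:
        raise ValueError("lca of a branch with itself is undefined")
    ca, cb = a.clade, b.clade
    if ca <= cb or cb <= ca:
        anc = a if cb <= ca else b
        prox, _dist, _l = tree._resolve(anc)
        return prox, True
    # walk root-ward from a's proximal node until the clade covers both
    prox_a, _da, _la = tree._resolve(a)
    node = prox_a
    target = ca | cb
    while True:
        below = tree._below.get(node, frozenset())
        if target <= below:
            return node, False
        up = tree._parent.get(node)
        if up is None:
            # ran past a top node: the LCA is the virtual root point
            return None, False
        node = up[0]


def lca_point(tree: Tree, node: Optional[int]) -> TreePoint:
    """Represent an :func:`lca` result as a :class:`TreePoint` for distances."""
    if node is None:
        rp = tree.root_point
        assert rp is not None
        return rp
    # locate a branch whose proximal or distal endpoint is the node
    for clade, (prox, dist, length) in tree._branches.items():
        if dist == node:
            return TreePoint(BranchRef(clade), length)
        if prox == node:
            return TreePoint(BranchRef(clade), 0.0)
    raise KeyError("node not on any branch")


def root_to_point_distance(tree: Tree, p: TreePoint) -> float:
    """Path length from the root point to ``p``."""
    rp = tree.root_point
    if rp is None:
        raise ValueError("tree has no root point")
    return path_length(tree, rp, p)


def is_ancestral(tree: Tree, candidate_ancestor: BranchRef, branch: BranchRef) -> bool:
    """True if ``candidate_ancestor`` lies on the root-ward path of ``branch``."""
    if not tree.is_rooted:
        raise ValueError("ancestry requires a rooted tree")
    return (
        candidate_ancestor != branch and branch.clade < candidate_ancestor.clade
    )


# ---------------------------------------------------------------------------
# Equality helper (used by round-trip tests and regraft identity checks)
# ---------------------------------------------------------------------------


def trees_equal(t1: Tree, t2: Tree, tol: float = 1e-9) -> bool:
    """Topology + branch-length equality on the unrooted shape."""
    if t1.leaf_names != t2.leaf_names:
        return False
    b1 = _bipartition_lengths(t1)
    b2 = _bipartition_lengths(t2)
    if set(b1) != set(b2):
        return False
    return all(abs(b1[k] - b2[k]) <= tol for k in b1)


def _bipartition_lengths(tree: Tree) -> Dict[FrozenSet[str], float]:
    all_leaves = tree.leaf_names
    out: Dict[FrozenSet[str], float] = {}
    for clade, (_p, _d, length) in tree._branches.items():
        comp = all_leaves - clade
        key = clade if min(clade) == min(min(clade), min(comp)) else comp
        out[key] = out.get(key, 0.0) + length
    # a root point splits one branch into two entries of the same bipartition;
    # the accumulation above re-merges them
    return out
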