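"""Rooted phylogenetic trees: Newick I/O, traversal, and random tree generation.

Trees are lightweight linked node structures.  Node ids are assigned
deterministically: tips get ``0..N-1`` in preorder-encounter order, internal
nodes get ``N..2N-2`` (for a bifurcating tree) in preorder-encounter order,
so the root always has id ``N``.  All traversals are iterative — caterpillar
trees with 10^5 tips must not hit the recursion limit.

Newick parsing is delegated to dendropy (position-aware syntax errors,
child order preserved as written); validation of branch lengths and tip
names, and the byte-exact writer, live here.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "TreeNode",
    "PhyloTree",
    "parse_newick",
    "to_newick",
    "preorder",
    "tree_depth",
    "yule_harding_tree",
    "star_tree",
    "caterpillar_tree",
    "balanced_tree",
]


class TreeError(ValueError):
    """Malformed Newick input or invalid tree structure."""


class TreeNode:
    __slots__ = ("id", "name", "length", "children", "parent")

    def __init__(self, name=None, length=None):
        self.id = None
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover
        kind = "tip" if self.is_tip else "internal"
        return f"<TreeNode {kind} id={self.id} name={self.name!r} length={self.length}>"


class PhyloTree:
    """A rooted tree with named tips and branch lengths on non-root edges."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate_and_index()

    def _validate_and_index(self) -> None:
        order = self.preorder()
        names = set()
        tip_id = 0
        tips = []
        for node in order:
            if node is not self.root:
                if node.length is None:
                    raise TreeError(
                        f"missing branch length on edge above {node.name or 'internal node'}"
                    )
                if node.length < 0:
                    raise TreeError(
                        f"negative branch length {node.length} above {node.name or 'internal node'}"
                    )
            if node.is_tip:
                if not node.name:
                    raise TreeError("unnamed tip")
                if node.name in names:
                    raise TreeError(f"duplicate tip name {node.name!r}")
                names.add(node.name)
                node.id = tip_id
                tip_id += 1
                tips.append(node)
        internal_id = tip_id
        for node in order:
            if not node.is_tip:
                node.id = internal_id
                internal_id += 1
        self.n_tips = tip_id
        self._tips = tips
        if self.n_tips < 1:
            raise TreeError("tree has no tips")
        self.depth = tree_depth(self)

    def preorder(self) -> list[TreeNode]:
        """Nodes in preorder: parent before children, children in stored order."""
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[TreeNode]:
        """Tips in preorder-encounter order (= id order)."""
        return list(self._tips)

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self._tips]

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree n_tips={self.n_tips} depth={self.depth}>"


def preorder(tree: PhyloTree) -> list[TreeNode]:
    return tree.preorder()


def tree_depth(tree: PhyloTree) -> int:
    """Maximum number of edges on a root-to-tip path."""
    best = 0
    stack = [(tree.root, 0)]
    while stack:
        node, d = stack.pop()
        if node.is_tip:
            best = max(best, d)
        else:
            stack.extend((c, d + 1) for c in node.children)
    return best


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick tree.

    A top-level multifurcation (unrooted convention) is accepted and treated
    as rooted at the top-level node.  Every non-root edge must carry a
    non-negative decimal branch length; tip names must be unique.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy errors carry line/column info
        raise TreeError(f"Newick parse error: {exc}") from None

    mapping: dict[int, TreeNode] = {}
    root = None
    for dnode in dtree.preorder_node_iter():
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(name=name, length=dnode.edge.length)
        mapping[id(dnode)] = node
        if dnode.parent_node is None:
            root = node
            node.length = None  # a root edge length carries no information
        else:
            mapping[id(dnode.parent_node)].add_child(node)
    return PhyloTree(root)


def _format_length(x: float) -> str:
    return repr(float(x))  # shortest exact round-trip representation


def to_newick(tree: PhyloTree) -> str:
    """Serialize with exact branch-length round trip; iterative (deep-tree safe)."""
    pieces: dict[int, str] = {}
    stack: list[tuple[TreeNode, bool]] = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.children and not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.children))
            continue
        if node.is_tip:
            s = node.name
        else:
            s = "(" + ",".join(pieces.pop(id(c)) for c in node.children) + ")"
        if node.parent is not None:
            s += ":" + _format_length(node.length)
        pieces[id(node)] = s
    return pieces[id(tree.root)] + ";"


def write_newick(tree: PhyloTree, path) -> None:
    with io.open(path, "w", encoding="ascii") as fh:
        fh.write(to_newick(tree) + "\n")


def read_newick(path) -> PhyloTree:
    with io.open(path, "r", encoding="ascii") as fh:
        return parse_newick(fh.read())


def yule_harding_tree(N: int, mean_branch_length: float, rng) -> PhyloTree:
    """Random rooted bifurcating tree under the Yule–Harding model.

    Grown from a two-tip tree by repeatedly splitting a uniformly chosen
    current tip until ``N`` tips exist.  Labels ``T1..TN`` are assigned to
    tips by a random permutation (labels are exchangeable under the model),
    then every non-root branch draws an i.i.d. Exponential length with the
    given mean.  Fully deterministic for a fixed stream.
    """
    if N < 2:
        raise TreeError(f"Yule–Harding tree needs N >= 2, got {N}")
    if mean_branch_length <= 0:
        raise TreeError(f"mean branch length must be > 0, got {mean_branch_length}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    root = TreeNode()
    tips = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    while len(tips) < N:
        i = int(rng.integers(len(tips)))
        node = tips[i]
        tips[i] = node.add_child(TreeNode())
        tips.append(node.add_child(TreeNode()))
    labels = rng.permutation(N)
    for tip, lab in zip(tips, labels):
        tip.name = f"T{lab + 1}"

    # Branch lengths assigned in preorder for a pinned draw order.
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    lengths = rng.exponential(mean_branch_length, size=len(order) - 1)
    j = 0
    for node in order:
        if node is not root:
            node.length = float(lengths[j])
            j += 1
    return PhyloTree(root)


def star_tree(N: int, branch_length: float = 0.1) -> PhyloTree:
    """N tips hanging directly off the root (depth 1)."""
    root = TreeNode()
    for i in range(N):
        root.add_child(TreeNode(name=f"T{i + 1}", length=branch_length))
    return PhyloTree(root)


def caterpillar_tree(N: int, branch_length: float = 0.1) -> PhyloTree:
    """Fully pectinate (ladder) tree: depth N - 1."""
    if N < 2:
        raise TreeError("caterpillar needs N >= 2")
    root = TreeNode()
    node = root
    for i in range(N - 1):
        node.add_child(TreeNode(name=f"T{i + 1}", length=branch_length))
        if i < N - 2:
            node = node.add_child(TreeNode(length=branch_length))
        else:
            node.add_child(TreeNode(name=f"T{N}", length=branch_length))
    return PhyloTree(root)


def balanced_tree(depth: int, branch_length: float = 0.1) -> PhyloTree:
    """Complete binary tree with 2**depth tips."""
    if depth < 1:
        raise TreeError("balanced tree needs depth >= 1")
    root = TreeNode()
    frontier = [root]
    for _ in range(depth):
        nxt = []
        for node in frontier:
            nxt.append(node.add_child(TreeNode(length=branch_length)))
            nxt.append(node.add_child(TreeNode(length=branch_length)))
        frontier = nxt
    for i, tip in enumerate(frontier):
        tip.name = f"T{i + 1}"
    return PhyloTree(root)
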