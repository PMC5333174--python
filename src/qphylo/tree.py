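"""Rooted trees with node ages and branch mutation annotations.

A single lightweight tree class serves both the simulated truth (a dated
genealogy whose branches carry the mutations dropped on them) and the trees
inferred by the parsimony search (where branches carry the site changes mapped
back onto them).  Newick parsing and serialisation are delegated to dendropy.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "rf_distance"]


class Node:
    """Tree node. ``age`` is in years before present; ``mutations`` is the
    list of site positions whose state change is assigned to the branch above
    this node (empty for the root)."""

    __slots__ = ("label", "children", "parent", "age", "mutations", "platform")

    def __init__(self, label: Optional[str] = None, age: float = 0.0):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.age = age
        self.mutations: list[int] = []
        self.platform: Optional[str] = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_years(self) -> float:
        """Duration of the branch above this node."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, age={self.age}, nmut={len(self.mutations)})"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Node:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labeled {label!r}")

    def tips_below(self, node: Node) -> list[Node]:
        stack, tips = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                tips.append(n)
            stack.extend(n.children)
        return tips

    # ------------------------------------------------------------------ #
    # invariants

    def validate(self) -> None:
        """Check genealogy invariants: ages decrease rootward->tipward,
        tips at age 0, internal nodes with >=2 children."""
        for node in self.postorder():
            if node.is_leaf:
                if abs(node.age) > 1e-9:
                    raise ValueError(f"tip {node.label!r} has nonzero age {node.age}")
            else:
                if len(node.children) < 2:
                    raise ValueError("internal node with a single child")
                for child in node.children:
                    if child.age >= node.age:
                        raise ValueError(
                            f"child age {child.age} not below parent age {node.age}"
                        )

    # ------------------------------------------------------------------ #
    # topology utilities

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            dup = Node(node.label, node.age)
            dup.mutations = list(node.mutations)
            dup.platform = node.platform
            for child in node.children:
                dup.add_child(rec(child))
            return dup

        return Tree(rec(self.root))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits in the unrooted sense.

        Each split is canonicalised as the side that does NOT contain the
        lexicographically smallest leaf label, so rootings of the same
        unrooted topology yield identical sets.
        """
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                side = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = side
                if anchor in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(side)
        return splits

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Restrict to a subset of tips, suppressing unifurcations.

        Mutations on a suppressed chain of branches are concatenated onto the
        surviving branch, so path mutation counts are preserved.
        """
        keep = set(keep)
        missing = keep - set(self.leaf_labels())
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    dup = Node(node.label, node.age)
                    dup.mutations = list(node.mutations)
                    dup.platform = node.platform
                    return dup
                return None
            kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                # suppress this unifurcation: absorb branch mutations
                child = kept[0]
                child.mutations = list(node.mutations) + child.mutations
                return child
            dup = Node(node.label, node.age)
            dup.mutations = list(node.mutations)
            for c in kept:
                dup.add_child(c)
            return dup

        new_root = rec(self.root)
        if new_root is None:
            raise ValueError("pruning removed every tip")
        new_root.mutations = []  # root has no branch above it
        new_root.parent = None
        return Tree(new_root)

    def reroot_on_outgroup(self, outgroup: str) -> "Tree":
        """Return a copy rooted on the branch leading to ``outgroup``.

        The new root is placed on the outgroup's pendant edge; branch
        mutation lists travel with their (re-oriented) branches.
        """
        tree = self.copy()
        og = tree.find(outgroup)
        if og.parent is None:
            raise ValueError("outgroup is already the root")
        if og.parent is tree.root and len(tree.root.children) == 2:
            return tree  # already rooted on that edge
        # collect edges as adjacency, then re-hang from a new root
        path = []
        node = og
        while node is not None:
            path.append(node)
            node = node.parent
        # reverse parent pointers along the path root -> og.parent
        muts_above = {id(n): list(n.mutations) for n in path}
        new_root = Node(None, og.age + 0.0)
        # detach og from its parent
        parent = og.parent
        parent.children.remove(og)
        og.parent = None
        # reverse the chain: parent becomes a child of og-side root
        prev = new_root
        carry = muts_above[id(og)]
        new_root.add_child(og)
        og.mutations = []
        node = parent
        child_carry = carry
        while node is not None:
            nxt = node.parent
            if nxt is not None:
                nxt.children.remove(node)
            node.parent = None
            prev.add_child(node)
            node_muts = muts_above[id(node)]
            node.mutations = child_carry
            child_carry = node_muts
            prev = node
            node = nxt
        # drop degree-2 nodes created by re-hanging (the old root)
        _suppress_unifurcations(new_root)
        return Tree(new_root)

    # ------------------------------------------------------------------ #
    # newick I/O (via dendropy)

    def to_newick(self, *, lengths: str = "years", annotate: bool = False) -> str:
        """Serialise to Newick.

        lengths: "years" (branch durations) or "mutations" (annotation counts).
        annotate: attach mutation position lists as node comments.
        """

        def rec(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    s += node.label
            if annotate and node.mutations:
                s += "[&mut={}]".format("|".join(str(p) for p in node.mutations))
            if node.parent is not None:
                if lengths == "years":
                    s += f":{node.branch_years:g}"
                elif lengths == "mutations":
                    s += f":{len(node.mutations)}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        def rec(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(label)
            for comment in dnode.comments or []:
                if comment.startswith("&mut="):
                    node.mutations = [
                        int(x) for x in comment[len("&mut="):].split("|") if x
                    ]
            for dchild in dnode.child_nodes():
                node.add_child(rec(dchild))
            return node

        tree = cls(rec(dt.seed_node))
        # recover ages from edge lengths when present (tips at 0)
        depths: dict[int, float] = {}

        def depth(dnode, acc):
            depths[id(dnode)] = acc
            for ch in dnode.child_nodes():
                depth(ch, acc + (ch.edge.length or 0.0))

        depth(dt.seed_node, 0.0)
        maxd = max(depths.values()) if depths else 0.0

        def set_ages(node: Node, dnode):
            node.age = maxd - depths[id(dnode)]
            for ch, dch in zip(node.children, dnode.child_nodes()):
                set_ages(ch, dch)

        set_ages(tree.root, dt.seed_node)
        return tree

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            taxon_namespace=taxon_namespace,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_tips={len(self.leaves())})"


def _suppress_unifurcations(root: Node) -> None:
    while len(root.children) == 1 and root.children[0].children:
        only = root.children[0]
        root.label = root.label or only.label
        root.children = only.children
        for c in root.children:
            c.parent = root
    stack = list(root.children)
    while stack:
        node = stack.pop()
        while len(node.children) == 1:
            child = node.children[0]
            child.mutations = node.mutations + child.mutations
            parent = node.parent
            parent.children[parent.children.index(node)] = child
            child.parent = parent
            node = child
        stack.extend(node.children)


def rf_distance(t1: Tree, t2: Tree) -> tuple[int, float]:
    """Robinson-Foulds distance: (raw bipartition symmetric difference,
    value normalised by 2(n-3), the maximum for unrooted binary trees)."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    raw = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3)
    return raw, (raw / denom if denom > 0 else 0.0)
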