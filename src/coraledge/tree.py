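"""Rooted phylogenetic trees: data model, Newick I/O, and structural edits.

The tree model is deliberately small: a :class:`PhyloTree` wraps a root
:class:`Node`, each node carrying a branch length (the edge subtending it;
``None`` means *unknown*, which is distinct from an explicit ``0.0``), an
optional label (mandatory and unique for tips) and an optional support
value. Newick parsing is delegated to :mod:`dendropy`; the structures here
exist so that downstream algorithms (polytomy resolution, fair-proportion
distinctiveness, parsimony scoring) can manipulate trees without fighting a
heavyweight API.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "ResolutionSet",
    "NewickError",
    "read_newick",
    "write_newick",
    "resolve_polytomies",
    "prune_to",
    "assign_missing_terminal_lengths",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class Node:
    __slots__ = ("parent", "children", "length", "label", "support")

    def __init__(self, label=None, length=None, support=None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length: float | None = length
        self.label: str | None = label
        self.support: float | None = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length}>"


class PhyloTree:
    """A rooted tree with branch lengths, tip labels and node supports."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        # iterative two-stack postorder
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    def total_length(self) -> float:
        """Sum of all branch lengths; ``None`` lengths count as 0."""
        return sum(n.length or 0.0 for n in self.preorder())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.internal_nodes())

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"no tip labelled {label!r}")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        if not want:
            raise ValueError("empty label set")
        tips = {n.label: n for n in self.leaves()}
        unknown = want - tips.keys()
        if unknown:
            raise KeyError(f"unknown tip labels: {sorted(unknown)}")
        paths = []
        for lab in want:
            path = []
            node = tips[lab]
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = self.root
        for level in zip(*paths):
            first = level[0]
            if all(n is first for n in level):
                mrca = first
            else:
                break
        return mrca

    def clades(self, include_trivial: bool = False) -> set[frozenset]:
        """Set of clades (frozensets of tip labels) defined by the tree.

        Non-trivial clades only (2 <= size < n tips) unless
        ``include_trivial``.
        """
        n = self.n_leaves
        below: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                cl = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = cl
                if include_trivial or 2 <= len(cl) < n:
                    out.add(cl)
        if include_trivial:
            out.update(below[id(t)] for t in self.leaves())
        return out

    def topology_key(self) -> frozenset:
        """Hashable identifier of the rooted topology (ignores lengths)."""
        return frozenset(self.clades(include_trivial=True))

    # ------------------------------------------------------------------
    # copying / validation
    # ------------------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            dup = Node(node.label, node.length, node.support)
            for c in node.children:
                dup.add_child(_copy(c))
            return dup

        return PhyloTree(_copy(self.root))

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise NewickError(f"duplicate tip labels: {sorted(dups)}")
        if any(lab is None for lab in labels):
            raise NewickError("every tip must be labelled")
        for n in self.preorder():
            if n.length is not None and n.length < 0:
                raise NewickError(
                    f"negative branch length {n.length} at {n.label!r}"
                )

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} tips>"


@dataclass
class ResolutionSet:
    """A base tree plus fully bifurcating random resolutions of it."""

    base: PhyloTree
    replicates: list[PhyloTree]
    seed: int

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.replicates)


# ----------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ----------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, internal_labels: str) -> PhyloTree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = Node(length=dnode.edge.length)
        if dnode.is_leaf():
            node.label = label
        else:
            if label is not None and internal_labels == "support":
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
            else:
                node.label = label
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = root.length if root.length else 0.0
    return PhyloTree(root)


def read_newick(source, internal_labels: str = "support") -> PhyloTree:
    """Parse a Newick string, file path or file object into a PhyloTree.

    Numeric labels on internal nodes are interpreted as support values when
    ``internal_labels == "support"`` (the default); pass ``"label"`` to keep
    them as plain labels.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if not text.lstrip().startswith("(") and "\n" not in text:
            try:
                with open(text) as fh:
                    text = fh.read()
            except OSError:
                pass
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse error: {exc}") from exc
    tree = _from_dendropy(dtree, internal_labels)
    tree.validate()
    return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_newick(tree: PhyloTree, include_supports: bool = True) -> str:
    """Serialize a tree to a Newick string (supports as internal labels)."""

    def render(node: Node) -> str:
        if node.is_leaf:
            s = _quote(node.label or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label is not None:
                s += _quote(node.label)
            elif include_supports and node.support is not None:
                s += _format_number(node.support)
        if node.length is not None and (
            node.parent is not None or node.length != 0
        ):
            s += ":" + _format_number(node.length)
        return s

    return render(tree.root) + ";"


# ----------------------------------------------------------------------
# polytomy resolution
# ----------------------------------------------------------------------

def _resolve_node_sequential(node: Node, rng: np.random.Generator) -> None:
    """Resolve one polytomy by repeated random pairwise joins."""
    while len(node.children) > 2:
        i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
        a, b = node.children[i], node.children[j]
        joint = Node(length=0.0)
        node.children = [c for c in node.children if c is not a and c is not b]
        joint.add_child(a)
        joint.add_child(b)
        node.add_child(joint)


def _resolve_node_uniform(node: Node, rng: np.random.Generator) -> None:
    """Resolve one polytomy uniformly over its (2k-3)!! binary topologies.

    Builds the local binary arrangement by attaching each child subtree to a
    uniformly chosen edge of the partial tree (including the root edge),
    which yields the exact uniform law over rooted binary shapes.
    """
    children = list(node.children)
    k = len(children)
    if k <= 2:
        return
    order = rng.permutation(k)
    local_root = Node(length=0.0)
    local_root.add_child(children[order[0]])
    local_root.add_child(children[order[1]])
    # edges are identified with their child node; the virtual root edge is
    # represented by local_root itself
    edges = [children[order[0]], children[order[1]], local_root]
    for idx in order[2:]:
        leaf = children[idx]
        target = edges[rng.integers(len(edges))]
        new = Node(length=0.0)
        if target is local_root:
            new.add_child(local_root)
            new.add_child(leaf)
            local_root = new
        else:
            parent = target.parent
            parent.remove_child(target)
            new.add_child(target)
            new.add_child(leaf)
            parent.add_child(new)
        edges.extend([leaf, new])
    node.children = []
    for c in local_root.children:
        node.add_child(c)


def resolve_polytomies(
    tree: PhyloTree,
    n_replicates: int,
    seed: int,
    method: str = "sequential",
) -> ResolutionSet:
    """Generate random fully bifurcating resolutions of a tree.

    Every polytomy is replaced by a random binary arrangement of its
    children; new internal edges get branch length 0, so total branch length
    is conserved and every clade of the input survives in every replicate.

    ``method="sequential"`` (default) repeatedly joins two random children —
    simple and fast, exactly uniform over topologies for trichotomies but
    mildly non-uniform for higher-degree polytomies. ``method="uniform"``
    samples exactly uniformly over the (2k-3)!! binary resolutions of each
    polytomy.

    Replicate ``i`` is generated from its own RNG stream derived from
    ``(seed, i)``, so it is identical regardless of ``n_replicates``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if method not in ("sequential", "uniform"):
        raise ValueError(f"unknown resolution method {method!r}")
    resolver = (
        _resolve_node_sequential if method == "sequential" else _resolve_node_uniform
    )
    replicates = []
    for i in range(n_replicates):
        rng = np.random.default_rng([seed, i])
        rep = tree.copy()
        for node in list(rep.preorder()):
            if len(node.children) > 2:
                resolver(node, rng)
        replicates.append(rep)
    return ResolutionSet(base=tree, replicates=replicates, seed=seed)


# ----------------------------------------------------------------------
# pruning and terminal-length edits
# ----------------------------------------------------------------------

def prune_to(
    tree: PhyloTree, keep: Iterable[str], include_root_path: bool = True
) -> PhyloTree:
    """Restrict a tree to a subset of tips.

    Unbranched internal nodes left behind are suppressed, their branch
    lengths summed. With ``include_root_path`` (default) the path from the
    MRCA of the kept tips up to the original root is retained as extra
    subtending length on the returned root, which keeps Faith's PD additive
    over nested subsets; with it off the returned root is the MRCA itself.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("empty keep set")
    tips = set(tree.leaf_labels())
    unknown = keep - tips
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")

    pruned = tree.copy()
    # drop unwanted leaves, then iteratively clean up
    for leaf in list(pruned.leaves()):
        if leaf.label not in keep:
            leaf.parent.remove_child(leaf)
    # remove now-empty internal nodes bottom-up
    changed = True
    while changed:
        changed = False
        for node in list(pruned.postorder()):
            if node.is_leaf and node.label is None and node.parent is not None:
                node.parent.remove_child(node)
                changed = True
    # suppress single-child chains (keeping lengths)
    for node in list(pruned.postorder()):
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            node.remove_child(child)
            parent.children[idx] = child
            child.parent = parent
    # handle the root chain
    root = pruned.root
    accumulated = 0.0
    while len(root.children) == 1:
        accumulated += root.length or 0.0
        root = root.children[0]
        root.parent = None
    if include_root_path:
        root.length = (root.length or 0.0) + accumulated
    else:
        root.length = 0.0
    return PhyloTree(root)


def assign_missing_terminal_lengths(
    tree: PhyloTree, species_without_data: Iterable[str]
) -> PhyloTree:
    """Set the terminal branch length of the listed tips to exactly zero.

    Models species placed in a tree from taxonomy alone: they contribute no
    terminal length but remain represented by their ancestral branches,
    giving a conservative lower bound on their distinctiveness.
    """
    missing = set(species_without_data)
    out = tree.copy()
    tips = {n.label: n for n in out.leaves()}
    unknown = missing - tips.keys()
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    for lab in missing:
        tips[lab].length = 0.0
    return out
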