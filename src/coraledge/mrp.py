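"""Matrix representation with parsimony (MRP) supertree assembly.

Each clade of each source tree is coded as one binary character (members 1,
non-members 0, taxa absent from that source missing), weighted by the
clade's support value — bootstrap percentages for data-derived trees, unit
weights for taxonomy-derived trees. The combined weighted matrix is analysed
under parsimony and the strict consensus of the equally best trees is the
supertree.

Scoring uses Hartigan's generalization of the Fitch pass, so multifurcating
trees are scored exactly. Parsimony length is invariant to root placement,
so searches operate on unrooted topologies internally; to recover *rooted*
clades, add the conventional all-zero hypothetical outgroup
(``add_root_taxon=True`` in :func:`encode_mrp`) and pass its label as
``root_taxon`` to :func:`parsimony_search` — best trees are then rooted on
it and the outgroup dropped.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tree import Node, PhyloTree, read_newick

__all__ = [
    "SourceTree",
    "WeightedCharacterMatrix",
    "ParsimonyResult",
    "ROOT_TAXON",
    "encode_mrp",
    "fitch_score",
    "parsimony_search",
    "strict_consensus",
    "build_supertree",
    "read_source_trees",
    "random_nni",
]

ROOT_TAXON = "__MRP_ROOT__"

MISSING = -1


@dataclass
class SourceTree:
    """A rooted input tree with per-clade support weights."""

    tree: PhyloTree
    provenance: str = "molecular"  # molecular | morphological | taxonomic
    name: str = ""
    default_weight: float = 1.0

    def __post_init__(self):
        if self.provenance not in ("molecular", "morphological", "taxonomic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def node_weight(self, node: Node) -> float:
        if self.provenance == "taxonomic":
            return 1.0
        if node.support is None:
            return self.default_weight
        if node.support <= 0:
            raise ValueError(f"non-positive support {node.support} in {self.name}")
        return float(node.support)


@dataclass
class WeightedCharacterMatrix:
    """Taxa x binary characters with per-character weights.

    ``states`` is an int8 array with entries 0, 1 or -1 (missing).
    """

    taxa: list[str]
    states: np.ndarray
    weights: np.ndarray
    character_provenance: list[str]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def validate(self) -> None:
        if self.states.shape != (self.n_taxa, self.n_characters):
            raise ValueError("states shape mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("character weights must be positive")
        for j in range(self.n_characters):
            col = self.states[:, j]
            if not ((col == 0).any() and (col == 1).any()):
                raise ValueError(f"character {j} is uninformative (constant)")

    def to_nexus(self) -> str:
        """NEXUS export with a WTSET in an ASSUMPTIONS block."""
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_characters};",
            '  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";',
            "  MATRIX",
        ]
        for i, taxon in enumerate(self.taxa):
            row = "".join(
                "?" if s == MISSING else str(int(s)) for s in self.states[i]
            )
            lines.append(f"    {taxon.replace(' ', '_')}  {row}")
        lines += ["  ;", "END;", "BEGIN ASSUMPTIONS;"]
        wt = ", ".join(
            f"{w:g}: {j + 1}" for j, w in enumerate(self.weights)
        )
        lines.append(f"  WTSET * mrp_weights = {wt};")
        lines += ["END;", ""]
        return "\n".join(lines)


@dataclass
class ParsimonyResult:
    trees: list[PhyloTree]
    score: float
    n_rearrangements: int
    search_log: str = ""


# ----------------------------------------------------------------------
# coding
# ----------------------------------------------------------------------

def encode_mrp(
    sources: list[SourceTree],
    all_taxa: set[str] | None = None,
    add_root_taxon: bool = False,
) -> WeightedCharacterMatrix:
    """Baum–Ragan coding of source trees into a weighted binary matrix.

    One character per non-root internal node whose clade has >= 2 members
    and fewer members than that source's tip count. With ``add_root_taxon``
    a hypothetical all-zero outgroup (:data:`ROOT_TAXON`) is appended, which
    lets a parsimony search recover rooted clades.
    """
    if not sources:
        raise ValueError("at least one source tree is required")
    union: set[str] = set()
    for s in sources:
        union |= set(s.tree.leaf_labels())
    if all_taxa is None:
        all_taxa = union
    else:
        extra = union - set(all_taxa)
        if extra:
            raise ValueError(f"source taxa outside the declared universe: {sorted(extra)}")
    taxa = sorted(all_taxa)
    if add_root_taxon:
        taxa = taxa + [ROOT_TAXON]
    index = {t: i for i, t in enumerate(taxa)}

    columns, weights, prov = [], [], []
    for s in sources:
        tips = s.tree.leaf_labels()
        if len(tips) < 3:
            warnings.warn(
                f"source {s.name!r} has fewer than 3 tips; contributes no characters"
            )
            continue
        n_tips = len(tips)
        tip_idx = [index[t] for t in tips]
        below: dict[int, list[int]] = {}
        for node in s.tree.postorder():
            if node.is_leaf:
                below[id(node)] = [index[node.label]]
            else:
                members = list(
                    itertools.chain.from_iterable(below[id(c)] for c in node.children)
                )
                below[id(node)] = members
                if node.parent is None:
                    continue
                if len(members) < 2 or len(members) >= n_tips:
                    continue
                col = np.full(len(taxa), MISSING, dtype=np.int8)
                col[tip_idx] = 0
                col[members] = 1
                if add_root_taxon:
                    col[index[ROOT_TAXON]] = 0
                columns.append(col)
                weights.append(s.node_weight(node))
                prov.append(s.name)
    if not columns:
        raise ValueError("no informative characters in any source tree")
    matrix = WeightedCharacterMatrix(
        taxa=taxa,
        states=np.column_stack(columns).astype(np.int8),
        weights=np.asarray(weights, dtype=float),
        character_provenance=prov,
    )
    matrix.validate()
    return matrix


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def _leaf_state_sets(matrix: WeightedCharacterMatrix) -> np.ndarray:
    """(n_taxa, n_chars, 2) boolean: which states each tip may take."""
    s = matrix.states
    sets = np.empty(s.shape + (2,), dtype=bool)
    sets[..., 0] = (s == 0) | (s == MISSING)
    sets[..., 1] = (s == 1) | (s == MISSING)
    return sets


def fitch_score(tree: PhyloTree, matrix: WeightedCharacterMatrix) -> float:
    """Weighted parsimony length of a tree on an MRP matrix.

    Missing states are treated as "any state", which for binary characters
    equals scoring each character on the subtree induced by its non-missing
    taxa. Polytomies are scored exactly (Hartigan's algorithm). The value is
    invariant to root placement.
    """
    tip_index = {t: i for i, t in enumerate(matrix.taxa)}
    leaf_sets = _leaf_state_sets(matrix)
    present = {n.label for n in tree.leaves()}
    absent = [t for t in matrix.taxa if t not in present]
    if absent:
        raise ValueError(f"matrix taxa absent from tree: {absent}")
    changes = np.zeros(matrix.n_characters, dtype=float)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            idx = tip_index.get(node.label)
            if idx is None:
                # tip with no data in the matrix: uninformative
                sets[id(node)] = np.ones((matrix.n_characters, 2), dtype=bool)
            else:
                sets[id(node)] = leaf_sets[idx]
        else:
            counts = sum(
                sets.pop(id(c)).astype(np.int16) for c in node.children
            )
            k = counts.max(axis=1)
            changes += len(node.children) - k
            sets[id(node)] = counts == k[:, None]
    return float(matrix.weights @ changes)


# ----------------------------------------------------------------------
# topology utilities
# ----------------------------------------------------------------------

def _unrooted_key(tree: PhyloTree) -> frozenset:
    """Canonical identifier of the unrooted topology."""
    all_tips = frozenset(tree.leaf_labels())
    parts = set()
    for clade in tree.clades():
        other = all_tips - clade
        if len(clade) >= 2 and len(other) >= 2:
            parts.add(frozenset((clade, other)))
    return frozenset(parts)


def reroot_at_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Reroot so that ``outgroup`` is one of the two children of the root.

    Topology-only (branch lengths on the reoriented path are not preserved);
    intended for parsimony search trees.
    """
    tree = tree.copy()
    leaf = tree.find_leaf(outgroup)
    if leaf.parent is None:
        raise ValueError("outgroup is the root")
    # walk up from the leaf, reversing parent links
    path = []
    node = leaf
    while node is not None:
        path.append(node)
        node = node.parent
    new_root = Node(length=0.0)
    new_root.add_child(path[0])  # will re-set parent below
    path[0].parent = new_root
    prev = new_root
    for i in range(1, len(path)):
        node = path[i]
        node.children = [c for c in node.children if c is not path[i - 1]]
        node.parent = None
        prev.add_child(node)
        prev = node
    # suppress degree-1 leftovers (the old root)
    out = PhyloTree(new_root)
    for node in list(out.postorder()):
        if not node.is_leaf and len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            parent = node.parent
            idx = parent.children.index(node)
            node.remove_child(child)
            parent.children[idx] = child
            child.parent = parent
    return out


def drop_tip(tree: PhyloTree, label: str) -> PhyloTree:
    keep = [t for t in tree.leaf_labels() if t != label]
    from .tree import prune_to

    return prune_to(tree, keep, include_root_path=False)


def random_nni(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """Apply one random nearest-neighbour interchange (returns a copy)."""
    tree = tree.copy()
    candidates = [
        n
        for n in tree.preorder()
        if not n.is_leaf and n.parent is not None and len(n.children) >= 2
    ]
    if not candidates:
        return tree
    v = candidates[rng.integers(len(candidates))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    s = siblings[rng.integers(len(siblings))]
    c = v.children[rng.integers(len(v.children))]
    u.children[u.children.index(s)] = c
    v.children[v.children.index(c)] = s
    s.parent, c.parent = v, u
    return tree


def _nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All NNI neighbours of a binary tree (as copies)."""
    out = []
    nodes = list(tree.preorder())
    for vi, v in enumerate(nodes):
        if v.is_leaf or v.parent is None:
            continue
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        for s in sibs:
            for c in list(v.children):
                dup = tree.copy()
                dnodes = list(dup.preorder())
                dv = dnodes[vi]
                du = dv.parent
                ds = du.children[u.children.index(s)]
                dc = dv.children[v.children.index(c)]
                du.children[du.children.index(ds)] = dc
                dv.children[dv.children.index(dc)] = ds
                ds.parent, dc.parent = dv, du
                out.append(dup)
    return out


def _tree_from_splits(tips: list[str]) -> PhyloTree:
    root = Node(length=None)
    for t in tips:
        root.add_child(Node(label=t))
    return PhyloTree(root)


def _insert_leaf_above(tree: PhyloTree, target_index: int, label: str) -> PhyloTree:
    """Copy of ``tree`` with a new leaf attached on the edge above the node
    at preorder position ``target_index``."""
    dup = tree.copy()
    nodes = list(dup.preorder())
    target = nodes[target_index]
    parent = target.parent
    new = Node(length=None)
    idx = parent.children.index(target)
    parent.children[idx] = new
    new.parent = parent
    new.add_child(target)
    new.add_child(Node(label=label))
    return dup


# ----------------------------------------------------------------------
# search
# ----------------------------------------------------------------------

def _two_leaf_base(a: str, b: str) -> PhyloTree:
    root = Node(length=None)
    root.add_child(Node(label=a))
    root.add_child(Node(label=b))
    return PhyloTree(root)


def _attachment_points(tree: PhyloTree) -> list[int]:
    """Preorder indices of nodes whose subtending edge can take a new leaf.

    The tree is rooted at an arbitrary base pair; every non-root node's edge
    is a distinct unrooted edge except that the two root children share one,
    so the first root child is skipped.
    """
    nodes = list(tree.preorder())
    points = []
    first_root_child_skipped = False
    for i, n in enumerate(nodes):
        if n.parent is None:
            continue
        if n.parent.parent is None and not first_root_child_skipped:
            first_root_child_skipped = True
            continue
        points.append(i)
    return points


def _branch_and_bound(
    matrix: WeightedCharacterMatrix, upper_bound: float | None
) -> tuple[list[PhyloTree], float]:
    taxa = list(matrix.taxa)
    best_score = np.inf if upper_bound is None else upper_bound
    best: list[PhyloTree] = []
    base = _two_leaf_base(taxa[0], taxa[1])

    def recurse(tree: PhyloTree, next_idx: int):
        nonlocal best_score, best
        score = fitch_score(tree, _submatrix(matrix, taxa[:next_idx]))
        if score > best_score:
            return
        if next_idx == len(taxa):
            if score < best_score:
                best_score, best = score, [tree]
            elif score == best_score:
                best.append(tree)
            return
        for point in _attachment_points(tree):
            recurse(_insert_leaf_above(tree, point, taxa[next_idx]), next_idx + 1)

    recurse(base, 2)
    return best, best_score


def _submatrix(matrix: WeightedCharacterMatrix, taxa: list[str]) -> WeightedCharacterMatrix:
    idx = [matrix.taxa.index(t) for t in taxa]
    return WeightedCharacterMatrix(
        taxa=list(taxa),
        states=matrix.states[idx],
        weights=matrix.weights,
        character_provenance=matrix.character_provenance,
    )


def _random_addition_tree(
    matrix: WeightedCharacterMatrix, rng: np.random.Generator
) -> PhyloTree:
    order = list(rng.permutation(len(matrix.taxa)))
    taxa = [matrix.taxa[i] for i in order]
    tree = _two_leaf_base(taxa[0], taxa[1])
    for k in range(2, len(taxa)):
        label = taxa[k]
        scored = [matrix.taxa[i] for i in sorted(order[: k + 1])]
        sub = _submatrix(matrix, scored)
        best_tree, best_score = None, np.inf
        for point in _attachment_points(tree):
            cand = _insert_leaf_above(tree, point, label)
            sc = fitch_score(cand, sub)
            if sc < best_score:
                best_tree, best_score = cand, sc
        tree = best_tree
    return tree


def parsimony_search(
    matrix: WeightedCharacterMatrix,
    strategy: str = "hill_climb",
    n_starts: int = 10,
    rearrangement_limit: int = 100_000,
    seed: int = 0,
    root_taxon: str | None = None,
) -> ParsimonyResult:
    """Search for minimum-length trees under weighted parsimony.

    ``branch_and_bound`` enumerates exhaustively with pruning (guarded to
    <= 15 taxa) and returns *all* optimal topologies. ``hill_climb`` runs
    ``n_starts`` random-addition starting trees each refined by
    first-improvement NNI until no neighbour improves or the shared
    ``rearrangement_limit`` is exhausted; all distinct topologies attaining
    the best score found are returned.

    Parsimony length is root-invariant, so candidate trees are deduplicated
    by unrooted topology. If ``root_taxon`` is given (conventionally the
    all-zero outgroup added by :func:`encode_mrp`), every best tree is
    rerooted on it and the outgroup removed, yielding rooted supertrees.
    """
    if matrix.n_taxa < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    if rearrangement_limit <= 0:
        raise ValueError("rearrangement_limit must be positive")
    if strategy not in ("branch_and_bound", "hill_climb"):
        raise ValueError(f"unknown strategy {strategy!r}")
    log_lines = []
    n_rearr = 0
    if strategy == "branch_and_bound":
        if matrix.n_taxa > 15:
            raise ValueError("branch_and_bound is limited to 15 taxa")
        rng = np.random.default_rng(seed)
        start = _random_addition_tree(matrix, rng)
        bound = fitch_score(start, matrix)
        trees, score = _branch_and_bound(matrix, upper_bound=bound)
        log_lines.append(
            f"branch-and-bound: initial bound {bound:g}, best {score:g}, "
            f"{len(trees)} optimal tree(s) before deduplication"
        )
    else:
        best_score = np.inf
        found: dict[frozenset, PhyloTree] = {}
        plateau_cap = 500  # per start: topologies explored at the optimum
        for s in range(n_starts):
            rng = np.random.default_rng([seed, s])
            tree = _random_addition_tree(matrix, rng)
            score = fitch_score(tree, matrix)
            # first-improvement NNI descent, then a breadth-first walk over
            # the equal-score plateau to collect all minimum-length
            # topologies reachable by NNI (resuming descent if the plateau
            # has a downhill exit)
            while n_rearr < rearrangement_limit:
                improved = False
                neighbors = _nni_neighbors(tree)
                for j in rng.permutation(len(neighbors)):
                    if n_rearr >= rearrangement_limit:
                        break
                    n_rearr += 1
                    sc = fitch_score(neighbors[j], matrix)
                    if sc < score:
                        tree, score = neighbors[j], sc
                        improved = True
                        break
                if improved:
                    continue
                plateau = {_unrooted_key(tree): tree}
                queue = [tree]
                escaped = False
                while (
                    queue
                    and len(plateau) < plateau_cap
                    and n_rearr < rearrangement_limit
                    and not escaped
                ):
                    cur = queue.pop()
                    for nb in _nni_neighbors(cur):
                        if n_rearr >= rearrangement_limit:
                            break
                        n_rearr += 1
                        sc = fitch_score(nb, matrix)
                        if sc < score:
                            tree, score = nb, sc
                            escaped = True
                            break
                        if sc == score:
                            key = _unrooted_key(nb)
                            if key not in plateau and len(plateau) < plateau_cap:
                                plateau[key] = nb
                                queue.append(nb)
                if escaped:
                    continue
                if score < best_score:
                    best_score = score
                    found = {}
                if score == best_score:
                    found.update(plateau)
                break
            log_lines.append(
                f"start {s}: local optimum {score:g} "
                f"({len(found)} optimum topologies so far)"
            )
        trees = list(found.values())
        score = best_score
    # deduplicate by unrooted topology
    unique: dict[frozenset, PhyloTree] = {}
    for t in trees:
        unique.setdefault(_unrooted_key(t), t)
    trees = list(unique.values())
    if root_taxon is not None:
        rooted = {}
        for t in trees:
            rt = reroot_at_outgroup(t, root_taxon)
            rt = drop_tip(rt, root_taxon)
            rooted.setdefault(rt.topology_key(), rt)
        trees = list(rooted.values())
    for t in trees:
        for n in t.preorder():
            n.length = None
        t.root.length = 0.0
    scores = (
        [fitch_score(t, matrix) for t in trees]
        if root_taxon is None
        else [score] * len(trees)
    )
    if any(abs(s - score) > 1e-9 for s in scores):
        raise AssertionError("inconsistent scores among returned trees")
    return ParsimonyResult(
        trees=trees,
        score=float(score),
        n_rearrangements=n_rearr,
        search_log="\n".join(log_lines),
    )


# ----------------------------------------------------------------------
# consensus
# ----------------------------------------------------------------------

def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the clades shared by every input tree."""
    if not trees:
        raise ValueError("empty tree list")
    tip_sets = [frozenset(t.leaf_labels()) for t in trees]
    if len(set(tip_sets)) != 1:
        raise ValueError("trees have different tip sets")
    tips = tip_sets[0]
    shared = trees[0].clades()
    for t in trees[1:]:
        shared &= t.clades()
    # build: attach every clade under its smallest strict superset
    clades = sorted(shared, key=len, reverse=True)
    root = Node(length=0.0)
    node_of: dict[frozenset, Node] = {tips: root}
    ordered = [tips] + clades
    for clade in clades:
        parent = min(
            (c for c in ordered if len(c) > len(clade) and clade < c),
            key=len,
        )
        node_of[clade] = node_of[parent].add_child(Node())
    for tip in sorted(tips):
        parent = min(
            (c for c in ordered if tip in c and len(c) >= 1 and c != frozenset([tip])),
            key=len,
        )
        node_of[parent].add_child(Node(label=tip))
    return PhyloTree(root)


# ----------------------------------------------------------------------
# convenience pipeline and I/O
# ----------------------------------------------------------------------

def build_supertree(
    sources: list[SourceTree],
    strategy: str = "hill_climb",
    n_starts: int = 10,
    rearrangement_limit: int = 100_000,
    seed: int = 0,
) -> tuple[PhyloTree, ParsimonyResult]:
    """Encode, search (rooted via the all-zero outgroup) and take the strict
    consensus: the standard MRP pipeline in one call."""
    matrix = encode_mrp(sources, add_root_taxon=True)
    result = parsimony_search(
        matrix,
        strategy=strategy,
        n_starts=n_starts,
        rearrangement_limit=rearrangement_limit,
        seed=seed,
        root_taxon=ROOT_TAXON,
    )
    return strict_consensus(result.trees), result


def read_source_trees(manifest_path: str | Path) -> list[SourceTree]:
    """Read source trees listed in a tab-separated manifest.

    Columns: ``file`` (Newick path, relative to the manifest), ``provenance``
    and ``name``.
    """
    manifest_path = Path(manifest_path)
    sources = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for req in ("file", "provenance", "name"):
            if req not in cols:
                raise ValueError(f"manifest missing column {req!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            tree = read_newick(manifest_path.parent / fields[cols["file"]])
            sources.append(
                SourceTree(
                    tree=tree,
                    provenance=fields[cols["provenance"]],
                    name=fields[cols["name"]],
                )
            )
    return sources
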