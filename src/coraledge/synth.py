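"""Synthetic study generator: trees, Red List categories, binary traits and
source-tree collections with controlled phylogenetic structure.

The generator emulates the inputs of a reef-coral conservation study
without any sequence data: a birth-death (default pure-birth) species tree
degraded into a consensus-like supertree (a fraction of internal edges
collapsed into polytomies, a fraction of terminals set to zero length to
mimic species placed from taxonomy alone), a Red List census at fixed
category counts, binary threat traits that are either phylogenetically
clumped (thresholded Brownian liability) or random (tip permutation), and
overlapping source trees extracted from the species tree for supertree
reconstruction.

Counts are exact (hypergeometric-style assignment), not Bernoulli draws:
a configured prevalence of 0.3 over 100 species yields exactly 30 carriers.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .edge import RedListCategory
from .mrp import SourceTree, random_nni
from .signal import TraitVector, _Indexed
from .tree import Node, PhyloTree, prune_to, write_newick

__all__ = [
    "PAPER_CATEGORY_COUNTS",
    "TraitSpec",
    "SyntheticStudyConfig",
    "StudyData",
    "scaled_category_counts",
    "simulate_tree",
    "simulate_categories",
    "simulate_binary_traits",
    "extract_source_trees",
    "simulate_study",
    "write_study",
]

#: Red List census of the 837 reef-building corals: 4 CR, 23 EN, 198 VU,
#: 174 NT, 289 LC and 149 DD.
PAPER_CATEGORY_COUNTS = {
    RedListCategory.CR: 4,
    RedListCategory.EN: 23,
    RedListCategory.VU: 198,
    RedListCategory.NT: 174,
    RedListCategory.LC: 289,
    RedListCategory.DD: 149,
}


@dataclass(frozen=True)
class TraitSpec:
    name: str
    prevalence: float
    structure: str = "clumped_brownian_threshold"  # or random_permutation
    liability_correlation_group: str | None = None

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.structure not in (
            "clumped_brownian_threshold",
            "random_permutation",
        ):
            raise ValueError(f"unknown trait structure {self.structure!r}")


def _default_trait_specs() -> list[TraitSpec]:
    """Eight binary threat/response traits at the study's prevalences.

    Structures follow the study's findings: threat susceptibility,
    resistance, recovery and collection pressure are phylogenetically
    clumped; range restriction is random. Bleaching and disease
    susceptibility share one liability, inducing the observed positive
    association between them.
    """
    c, r = "clumped_brownian_threshold", "random_permutation"
    return [
        TraitSpec("bleaching_susceptible", 0.419, c, "susceptibility"),
        TraitSpec("bleaching_resistant", 0.116, c),
        TraitSpec("disease_susceptible", 0.310, c, "susceptibility"),
        TraitSpec("disease_resistant", 0.058, c),
        TraitSpec("quick_recovery", 0.134, c),
        TraitSpec("cots_predation_susceptible", 0.273, c),
        TraitSpec("restricted_range", 0.124, r),
        TraitSpec("collected_over_1000_per_year", 0.157, c),
    ]


@dataclass
class SyntheticStudyConfig:
    n_species: int = 837
    tree_model: str = "yule"  # yule | birth_death
    birth_rate: float = 1.0
    death_rate: float = 0.0
    category_frequencies: dict | None = None  # defaults to the census, scaled
    trait_specs: list[TraitSpec] = field(default_factory=_default_trait_specs)
    polytomy_fraction: float = 0.3
    # 365 of the 837 reef species had sequence data; the rest enter the tree
    # with zero-length terminals
    missing_data_fraction: float = (837 - 365) / 837
    n_source_trees: int = 15
    source_size_range: tuple = (8, 40)
    include_taxonomy_source: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.tree_model not in ("yule", "birth_death"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.tree_model == "birth_death" and self.death_rate >= self.birth_rate:
            raise ValueError("death_rate must be below birth_rate")
        if not 0.0 <= self.polytomy_fraction < 1.0:
            raise ValueError("polytomy_fraction must be in [0, 1)")
        if not 0.0 <= self.missing_data_fraction < 1.0:
            raise ValueError("missing_data_fraction must be in [0, 1)")
        self.category_counts()  # validate any explicit census up front

    def category_counts(self) -> dict:
        if self.category_frequencies is not None:
            counts = {
                RedListCategory.coerce(k): int(v)
                for k, v in self.category_frequencies.items()
            }
            if sum(counts.values()) != self.n_species:
                raise ValueError("category counts must sum to n_species")
            return counts
        return scaled_category_counts(self.n_species)


@dataclass
class StudyData:
    config: SyntheticStudyConfig
    tree: PhyloTree
    categories: dict
    traits: dict
    sources: list
    abundance: dict
    representation: dict


def scaled_category_counts(n_species: int) -> dict:
    """The Red List census scaled to ``n_species`` by largest remainder."""
    total = sum(PAPER_CATEGORY_COUNTS.values())
    quotas = {
        cat: n_species * c / total for cat, c in PAPER_CATEGORY_COUNTS.items()
    }
    counts = {cat: int(np.floor(q)) for cat, q in quotas.items()}
    short = n_species - sum(counts.values())
    remainders = sorted(
        quotas, key=lambda cat: quotas[cat] - counts[cat], reverse=True
    )
    for cat in remainders[:short]:
        counts[cat] += 1
    return counts


# ----------------------------------------------------------------------
# tree simulation
# ----------------------------------------------------------------------

def _birth_death_tree(config: SyntheticStudyConfig) -> PhyloTree:
    from dendropy.model import birthdeath

    rng = _random.Random(int(config.seed) & 0x7FFFFFFF)
    dtree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate if config.tree_model == "birth_death" else 0.0,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    # the simulation stops at the n-th speciation, leaving two zero-length
    # terminals; evolve the stopped process for one more waiting time so
    # every extant terminal has positive length
    extra = rng.expovariate(config.n_species * config.birth_rate)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra

    counter = [0]
    width = len(str(config.n_species))

    def convert(dnode) -> Node:
        node = Node(length=dnode.edge.length or 0.0)
        if dnode.is_leaf():
            counter[0] += 1
            node.label = f"S{counter[0]:0{width}d}"
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    tree = PhyloTree(root)
    tree.validate()
    return tree


def _collapse_node(node: Node) -> None:
    parent = node.parent
    idx = parent.children.index(node)
    for c in node.children:
        c.length = (c.length or 0.0) + (node.length or 0.0)
        c.parent = parent
    parent.children[idx : idx + 1] = node.children
    node.children = []
    node.parent = None


def simulate_tree(config: SyntheticStudyConfig) -> PhyloTree:
    """Simulate the synthetic supertree.

    A birth-death tree is degraded in two ways that mimic a strict
    consensus supertree: a fraction of internal edges is collapsed into
    polytomies (each collapsed edge's length is pushed onto its children so
    root-to-tip path lengths are conserved), and a fraction of terminals is
    set to zero length, standing in for species with no character data.
    """
    tree = _birth_death_tree(config)
    rng = np.random.default_rng([config.seed, 1])
    internals = [
        n for n in tree.preorder() if not n.is_leaf and n.parent is not None
    ]
    n_collapse = int(round(config.polytomy_fraction * len(internals)))
    if n_collapse:
        chosen = rng.choice(len(internals), size=n_collapse, replace=False)
        # collapse children-first so parent links stay valid
        post = {id(n): i for i, n in enumerate(tree.postorder())}
        for i in sorted(chosen, key=lambda i: post[id(internals[i])]):
            _collapse_node(internals[i])
    leaves = tree.leaves()
    n_missing = int(round(config.missing_data_fraction * len(leaves)))
    if n_missing:
        for i in rng.choice(len(leaves), size=n_missing, replace=False):
            leaves[i].length = 0.0
    return tree


# ----------------------------------------------------------------------
# categories and traits
# ----------------------------------------------------------------------

def _brownian_liability(tree: PhyloTree, rng: np.random.Generator) -> dict:
    from .signal import simulate_brownian_tips

    vals, labels = simulate_brownian_tips(tree, 1, rng)
    return dict(zip(labels, vals[:, 0]))


def simulate_categories(
    tree: PhyloTree,
    config: SyntheticStudyConfig,
    clustering: str = "none",
) -> dict:
    """Assign Red List categories to tips at exact configured counts.

    ``clustering="none"`` permutes species uniformly (no phylogenetic
    signal in threat status, the study's empirical finding);
    ``"brownian"`` ranks species by a Brownian liability and slices the
    ranking into category blocks from most to least threatened (a clumped
    alternative for power analyses).
    """
    counts = config.category_counts()
    labels = tree.leaf_labels()
    if sum(counts.values()) != len(labels):
        raise ValueError("category counts do not match tip count")
    rng = np.random.default_rng([config.seed, 2])
    if clustering == "none":
        order = [labels[i] for i in rng.permutation(len(labels))]
    elif clustering == "brownian":
        liab = _brownian_liability(tree, rng)
        order = sorted(labels, key=lambda s: -liab[s])
    else:
        raise ValueError(f"unknown clustering {clustering!r}")
    out = {}
    pos = 0
    for cat in (
        RedListCategory.CR,
        RedListCategory.EN,
        RedListCategory.VU,
        RedListCategory.NT,
        RedListCategory.LC,
        RedListCategory.DD,
    ):
        for sp in order[pos : pos + counts.get(cat, 0)]:
            out[sp] = cat
        pos += counts.get(cat, 0)
    return out


def simulate_binary_traits(
    tree: PhyloTree, config: SyntheticStudyConfig
) -> dict:
    """Generate the configured binary traits on the tree's tips.

    Clumped traits threshold a unit-rate Brownian liability at the exact
    prevalence count (the top carriers get state 1); random traits permute
    an exact-count 0/1 vector across tips. Traits sharing a
    ``liability_correlation_group`` reuse one liability with their own
    thresholds, which induces a positive association between them.
    """
    labels = tree.leaf_labels()
    n = len(labels)
    rng = np.random.default_rng([config.seed, 3])
    liabilities: dict[str, dict] = {}
    out: dict[str, TraitVector] = {}
    for spec in config.trait_specs:
        m = int(round(spec.prevalence * n))
        m = min(max(m, 1), n - 1)
        if spec.structure == "random_permutation":
            vec = np.zeros(n)
            vec[:m] = 1.0
            vec = vec[rng.permutation(n)]
            values = dict(zip(labels, vec))
        else:
            group = spec.liability_correlation_group or f"__solo__{spec.name}"
            if group not in liabilities:
                liabilities[group] = _brownian_liability(tree, rng)
            liab = liabilities[group]
            ranked = sorted(labels, key=lambda s: -liab[s])
            carriers = set(ranked[:m])
            values = {s: 1.0 if s in carriers else 0.0 for s in labels}
        out[spec.name] = TraitVector(
            values=values, trait_name=spec.name, kind="binary"
        )
    return out


# ----------------------------------------------------------------------
# source trees
# ----------------------------------------------------------------------

def extract_source_trees(
    tree: PhyloTree,
    config: SyntheticStudyConfig,
    conflict_rate: float = 0.0,
    support_range: tuple = (50, 100),
) -> list[SourceTree]:
    """Extract overlapping source trees for supertree reconstruction.

    Each source is the induced subtree on a random taxon subset (sizes
    uniform over ``config.source_size_range``); with probability
    ``conflict_rate`` a source receives one random NNI perturbation,
    emulating conflicting phylogenetic hypotheses. Clade supports are drawn
    uniformly (integers) from ``support_range``; if the configuration asks
    for a taxonomy source, the first source is flagged taxonomic and its
    clades get unit weights regardless of the drawn supports.
    """
    if config.n_source_trees < 1:
        raise ValueError("n_source_trees must be >= 1")
    if not 0.0 <= conflict_rate < 1.0:
        raise ValueError("conflict_rate must be in [0, 1)")
    labels = tree.leaf_labels()
    lo, hi = config.source_size_range
    lo = max(3, lo)
    hi = min(hi, len(labels))
    if lo > hi:
        raise ValueError("source subset size range is empty")
    rng = np.random.default_rng([config.seed, 4])
    sources = []
    for i in range(config.n_source_trees):
        size = int(rng.integers(lo, hi + 1))
        subset = [labels[j] for j in rng.choice(len(labels), size, replace=False)]
        sub = prune_to(tree, subset, include_root_path=False)
        if conflict_rate > 0 and rng.random() < conflict_rate:
            sub = random_nni(sub, rng)
        for node in sub.internal_nodes():
            if node.parent is not None:
                node.support = float(rng.integers(support_range[0], support_range[1] + 1))
        provenance = (
            "taxonomic"
            if (config.include_taxonomy_source and i == 0)
            else "molecular"
        )
        sources.append(
            SourceTree(tree=sub, provenance=provenance, name=f"source_{i:02d}")
        )
    return sources


# ----------------------------------------------------------------------
# whole-study assembly and serialization
# ----------------------------------------------------------------------

_ABUNDANCE_CLASSES = ("common", "uncommon", "rare")


def simulate_study(
    config: SyntheticStudyConfig,
    category_clustering: str = "none",
    conflict_rate: float = 0.0,
) -> StudyData:
    """Generate every input of the study from one configuration and seed."""
    tree = simulate_tree(config)
    categories = simulate_categories(tree, config, clustering=category_clustering)
    traits = simulate_binary_traits(tree, config)
    sources = extract_source_trees(tree, config, conflict_rate=conflict_rate)
    labels = tree.leaf_labels()
    rng = np.random.default_rng([config.seed, 5])
    # neutral default: equal thirds of common / uncommon / rare
    classes = np.array(
        [_ABUNDANCE_CLASSES[i % 3] for i in range(len(labels))], dtype=object
    )
    abundance = dict(zip(labels, classes[rng.permutation(len(labels))]))
    representation = {s: 0 for s in labels}
    for src in sources:
        for t in src.tree.leaf_labels():
            representation[t] += 1
    return StudyData(
        config=config,
        tree=tree,
        categories=categories,
        traits=traits,
        sources=sources,
        abundance=abundance,
        representation=representation,
    )


def write_study(study: StudyData, outdir) -> None:
    """Write the generated study to plain-text files.

    Produces ``supertree.nwk``, ``sources/*.nwk`` with ``manifest.tsv``,
    ``species_table.tsv`` (species, category, abundance, representation),
    ``traits.tsv`` and a ``manifest.yaml`` echoing the configuration and
    seed for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "supertree.nwk").write_text(write_newick(study.tree) + "\n")
    srcdir = outdir / "sources"
    srcdir.mkdir(exist_ok=True)
    rows = ["file\tprovenance\tname"]
    for src in study.sources:
        fname = f"{src.name}.nwk"
        (srcdir / fname).write_text(write_newick(src.tree) + "\n")
        rows.append(f"{fname}\t{src.provenance}\t{src.name}")
    (srcdir / "manifest.tsv").write_text("\n".join(rows) + "\n")
    labels = study.tree.leaf_labels()
    lines = ["species\tcategory\tabundance\tn_source_trees"]
    for s in labels:
        lines.append(
            f"{s}\t{study.categories[s].value}\t{study.abundance[s]}\t"
            f"{study.representation[s]}"
        )
    (outdir / "species_table.tsv").write_text("\n".join(lines) + "\n")
    trait_names = list(study.traits)
    lines = ["species\t" + "\t".join(trait_names)]
    for s in labels:
        vals = "\t".join(
            str(int(study.traits[t].values[s])) for t in trait_names
        )
        lines.append(f"{s}\t{vals}")
    (outdir / "traits.tsv").write_text("\n".join(lines) + "\n")
    cfg = asdict(study.config)
    cfg["trait_specs"] = [asdict(t) for t in study.config.trait_specs]
    cfg["category_frequencies"] = {
        k.value: v for k, v in study.config.category_counts().items()
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump({"synthetic_study": cfg}, sort_keys=False)
    )
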