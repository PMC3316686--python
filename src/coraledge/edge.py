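"""EDGE prioritization: evolutionary distinctiveness x extinction probability.

Evolutionary distinctiveness (ED) follows the fair-proportion rule: every
branch is divided equally among the tips that descend from it, and a
species' ED is the sum of its shares along the path to the root. ED summed
over all species therefore equals the tree's total branch length — a useful
conservation identity that the tests rely on.

ED is multiplied by a probability of extinction (PE) derived from the IUCN
Red List category to give the EDGE score, the expected loss of evolutionary
history attributable to that species over the transformation's horizon
(100 years here). Scores are aggregated over random polytomy resolutions of
the supertree: means and standard deviations per species, then a rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .tree import PhyloTree, ResolutionSet

__all__ = [
    "RedListCategory",
    "PETransform",
    "EdgeScore",
    "evolutionary_distinctiveness",
    "pe_from_category",
    "edge_scores",
    "rank_stability",
]


class RedListCategory(str, Enum):
    CR = "CR"  # Critically Endangered
    EN = "EN"  # Endangered
    VU = "VU"  # Vulnerable
    NT = "NT"  # Near Threatened
    LC = "LC"  # Least Concern
    DD = "DD"  # Data Deficient
    NE = "NE"  # Not Evaluated

    @classmethod
    def coerce(cls, value) -> "RedListCategory":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().upper())


THREATENED = (RedListCategory.CR, RedListCategory.EN, RedListCategory.VU)

#: Probabilities of extinction within 100 years per Red List category for
#: the IUCN100 transformation. LC is anchored at 0.001 (about one of the
#: ~289 LC corals lost in a century) and NT at 0.01; the CR/EN/VU values are
#: the standard IUCN100 table of Mooers et al. (2008). DD defaults to the
#: midpoint of the LC and NT values (see :func:`PETransform.iucn100`).
_IUCN100_BASE = {
    RedListCategory.CR: 0.999,
    RedListCategory.EN: 0.667,
    RedListCategory.VU: 0.1,
    RedListCategory.NT: 0.01,
    RedListCategory.LC: 0.001,
}

# Isaac et al. (2007): PE doubles with each step up in threat.
_ISAAC = {
    RedListCategory.CR: 0.4,
    RedListCategory.EN: 0.2,
    RedListCategory.VU: 0.1,
    RedListCategory.NT: 0.05,
    RedListCategory.LC: 0.025,
}

# Upper-bound scenario: near-certain loss of threatened species and high
# loss rates even at low threat. A package default for sensitivity
# analysis, not taken from a published table.
_PESSIMISTIC = {
    RedListCategory.CR: 0.999,
    RedListCategory.EN: 0.99,
    RedListCategory.VU: 0.9,
    RedListCategory.NT: 0.5,
    RedListCategory.LC: 0.2,
}


@dataclass(frozen=True)
class PETransform:
    """A Red List category -> extinction probability mapping."""

    name: str
    mapping: dict
    horizon: int = 100

    def __post_init__(self):
        order = [
            RedListCategory.CR,
            RedListCategory.EN,
            RedListCategory.VU,
            RedListCategory.NT,
            RedListCategory.LC,
        ]
        vals = [self.mapping[c] for c in order]
        if any(not (0.0 <= v <= 1.0) for v in self.mapping.values()):
            raise ValueError("extinction probabilities must lie in [0, 1]")
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("PE must be monotone decreasing in threat order")

    @classmethod
    def iucn100(cls, dd: str = "midpoint") -> "PETransform":
        """The default transformation; ``dd`` in {"midpoint", "geometric"}
        picks how Data Deficient species are placed between LC and NT."""
        lc, nt = _IUCN100_BASE[RedListCategory.LC], _IUCN100_BASE[RedListCategory.NT]
        if dd == "midpoint":
            dd_val = (lc + nt) / 2.0
        elif dd == "geometric":
            dd_val = float(np.sqrt(lc * nt))
        else:
            raise ValueError(f"unknown DD rule {dd!r}")
        mapping = dict(_IUCN100_BASE)
        mapping[RedListCategory.DD] = dd_val
        return cls(name="IUCN100", mapping=mapping)

    @classmethod
    def isaac(cls) -> "PETransform":
        mapping = dict(_ISAAC)
        mapping[RedListCategory.DD] = float(
            np.sqrt(
                _ISAAC[RedListCategory.LC] * _ISAAC[RedListCategory.NT]
            )
        )
        return cls(name="Isaac", mapping=mapping)

    @classmethod
    def pessimistic(cls) -> "PETransform":
        mapping = dict(_PESSIMISTIC)
        mapping[RedListCategory.DD] = (
            _PESSIMISTIC[RedListCategory.LC] + _PESSIMISTIC[RedListCategory.NT]
        ) / 2.0
        return cls(name="Pessimistic", mapping=mapping)

    @classmethod
    def named(cls, name: str, **kwargs) -> "PETransform":
        key = name.lower()
        if key == "iucn100":
            return cls.iucn100(**kwargs)
        if key == "isaac":
            return cls.isaac()
        if key == "pessimistic":
            return cls.pessimistic()
        raise ValueError(f"unknown transform {name!r}")


@dataclass
class EdgeScore:
    species: str
    ed_mean: float
    ed_sd: float
    pe: float
    edge_mean: float
    edge_sd: float
    rank: int = 0


def evolutionary_distinctiveness(tree: PhyloTree) -> dict:
    """Fair-proportion ED per tip: each edge's length split equally among
    its descendant tips, summed along each tip's root path."""
    n_below: dict[int, int] = {}
    missing_lengths = 0
    for node in tree.postorder():
        if node.is_leaf:
            n_below[id(node)] = 1
        else:
            n_below[id(node)] = sum(n_below[id(c)] for c in node.children)
        if node.length is None and node.parent is not None:
            missing_lengths += 1
    if missing_lengths:
        warnings.warn(
            f"{missing_lengths} branch(es) lack length estimates; treated as 0"
        )
    ed: dict[str, float] = {}
    carry: dict[int, float] = {id(tree.root): (tree.root.length or 0.0) / n_below[id(tree.root)]}
    for node in tree.preorder():
        if node.parent is not None:
            carry[id(node)] = carry[id(node.parent)] + (node.length or 0.0) / n_below[
                id(node)
            ]
        if node.is_leaf:
            ed[node.label] = carry[id(node)]
    return ed


def pe_from_category(
    cat, transform: PETransform, strict_ne: bool = True
) -> float:
    """Extinction probability for a Red List category under a transform.

    Not Evaluated (NE) species raise in strict mode; otherwise they are
    treated like Data Deficient ones.
    """
    cat = RedListCategory.coerce(cat)
    if cat is RedListCategory.NE:
        if strict_ne:
            raise ValueError("species is Not Evaluated; no PE defined in strict mode")
        cat = RedListCategory.DD
    return float(transform.mapping[cat])


def edge_scores(
    resolutions: ResolutionSet,
    categories: dict,
    transform: PETransform | None = None,
    strict_ne: bool = True,
) -> list[EdgeScore]:
    """EDGE scores aggregated over polytomy resolutions.

    ED and EDGE are computed per resolved replicate, then summarized as mean
    and (sample) standard deviation per species. Species are ranked by mean
    EDGE descending; ties broken by mean ED, then label.
    """
    if transform is None:
        transform = PETransform.iucn100()
    tips = resolutions.base.leaf_labels()
    missing = [t for t in tips if t not in categories]
    if missing:
        raise ValueError(f"species without a Red List category: {sorted(missing)}")
    pe = np.array(
        [pe_from_category(categories[t], transform, strict_ne) for t in tips]
    )
    n_rep = len(resolutions.replicates)
    ed_mat = np.empty((len(tips), n_rep))
    for j, rep in enumerate(resolutions.replicates):
        ed = evolutionary_distinctiveness(rep)
        ed_mat[:, j] = [ed[t] for t in tips]
    edge_mat = ed_mat * pe[:, None]
    ddof = 1 if n_rep > 1 else 0
    ed_mean, ed_sd = ed_mat.mean(axis=1), ed_mat.std(axis=1, ddof=ddof)
    edge_mean, edge_sd = edge_mat.mean(axis=1), edge_mat.std(axis=1, ddof=ddof)
    scores = [
        EdgeScore(
            species=t,
            ed_mean=float(ed_mean[i]),
            ed_sd=float(ed_sd[i]),
            pe=float(pe[i]),
            edge_mean=float(edge_mean[i]),
            edge_sd=float(edge_sd[i]),
        )
        for i, t in enumerate(tips)
    ]
    scores.sort(key=lambda s: (-s.edge_mean, -s.ed_mean, s.species))
    for r, s in enumerate(scores, start=1):
        s.rank = r
    return scores


def rank_stability(
    full: list[EdgeScore], subset: list[EdgeScore], top_k: int
) -> tuple[float, float]:
    """Mean absolute rank change between a full and a reduced analysis.

    Both rankings are restricted to their shared species and densely
    re-ranked before comparison. Returns ``(mean |Δrank| over the top_k
    species of the full ranking, mean |Δrank| over all shared species)``.
    """
    full_species = {s.species for s in full}
    sub_species = {s.species for s in subset}
    if not sub_species <= full_species:
        raise ValueError("subset contains species absent from the full ranking")
    shared = sub_species
    if top_k > len(shared):
        raise ValueError("top_k exceeds the number of shared species")
    full_order = [s.species for s in sorted(full, key=lambda s: s.rank) if s.species in shared]
    sub_order = [s.species for s in sorted(subset, key=lambda s: s.rank) if s.species in shared]
    full_rank = {sp: i + 1 for i, sp in enumerate(full_order)}
    sub_rank = {sp: i + 1 for i, sp in enumerate(sub_order)}
    diffs = {sp: abs(full_rank[sp] - sub_rank[sp]) for sp in shared}
    top = full_order[:top_k]
    return (
        float(np.mean([diffs[sp] for sp in top])),
        float(np.mean(list(diffs.values()))),
    )
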