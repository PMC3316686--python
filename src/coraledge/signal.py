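"""Phylogenetic signal statistics and independent contrasts.

Three families of test:

* **Blomberg's K** for continuous traits — the ratio of observed to
  Brownian-expected (MSE0/MSE), where MSE0 is the trait variance about the
  phylogenetically corrected mean and MSE the generalized-least-squares
  variance under the tree's covariance. K ~ 1 under Brownian motion and
  falls toward 0 for traits shuffled across tips; significance comes from a
  tip-permutation randomization.

* **Fritz & Purvis' D** for binary traits — the observed sum of
  sister-clade differences in estimated nodal values, rescaled between the
  expectations under two simulated nulls: tip permutation (D = 1, no
  signal) and a threshold applied to a Brownian liability (D = 0,
  phylogenetically clumped). Two one-sided p-values are reported, one
  against each null.

* **Phylogenetically independent contrasts (PIC)** — standardized
  sister-clade differences used to test trait-trait association free of
  shared-ancestry pseudoreplication; the slope of a through-origin
  regression of y-contrasts on x-contrasts with a t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tree import PhyloTree, prune_to

__all__ = [
    "TraitVector",
    "SignalTestResult",
    "ContrastsResult",
    "blomberg_k",
    "k_randomization_test",
    "fritz_purvis_d",
    "independent_contrasts",
    "binary_contrast_correlation",
    "stratified_signal",
    "phylo_vcv",
    "simulate_brownian_tips",
    "sister_clade_difference_sum",
]


@dataclass
class TraitVector:
    values: dict
    trait_name: str = ""
    kind: str = "continuous"  # continuous | binary

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary":
            states = set(float(v) for v in self.values.values())
            if not states <= {0.0, 1.0}:
                raise ValueError("binary trait values must be 0/1")

    def vector(self, labels: list[str]) -> np.ndarray:
        missing = [l for l in labels if l not in self.values]
        if missing:
            raise ValueError(
                f"trait {self.trait_name!r} missing for: {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"trait {self.trait_name!r} missing for: {sorted(missing)}"
            )
        return np.array([float(self.values[l]) for l in labels])

    def restricted(self, labels) -> "TraitVector":
        labels = set(labels)
        return TraitVector(
            values={k: v for k, v in self.values.items() if k in labels},
            trait_name=self.trait_name,
            kind=self.kind,
        )


@dataclass
class SignalTestResult:
    statistic_name: str  # "K" or "D"
    observed: float
    p_vs_random: float
    null_random: np.ndarray
    n_replicates: int
    seed: int
    p_vs_clumped: float | None = None
    null_brownian: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ContrastsResult:
    contrasts_x: np.ndarray
    contrasts_y: np.ndarray
    slope: float
    p_value: float
    n_contrasts: int
    t_statistic: float = float("nan")
    correlation: float = float("nan")


# ----------------------------------------------------------------------
# tree -> arrays
# ----------------------------------------------------------------------

class _Indexed:
    """Postorder-indexed view of a tree for vectorized algorithms."""

    def __init__(self, tree: PhyloTree):
        self.nodes = list(tree.postorder())
        pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[pos[id(c)] for c in n.children] for n in self.nodes]
        self.lengths = np.array([n.length or 0.0 for n in self.nodes])
        self.is_tip = np.array([n.is_leaf for n in self.nodes])
        self.tip_labels = [n.label for n in self.nodes if n.is_leaf]
        self.tip_pos = np.flatnonzero(self.is_tip)
        self.n_tips = len(self.tip_labels)
        # depth from root (edge lengths accumulated tip-ward; the root's own
        # subtending length, conventionally 0, is included). Root is last in
        # postorder, so a reverse sweep visits parents before children.
        root = len(self.nodes) - 1
        depth = np.empty(len(self.nodes))
        depth[root] = self.lengths[root]
        for i in range(len(self.nodes) - 1, -1, -1):
            for c in self.children[i]:
                depth[c] = depth[i] + self.lengths[c]
        self.depth = depth
        # tips below each node
        self.tips_below: list[np.ndarray] = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                self.tips_below[i] = np.array(
                    [int(np.searchsorted(self.tip_pos, i))]
                )
            else:
                self.tips_below[i] = np.concatenate(
                    [self.tips_below[c] for c in self.children[i]]
                )


def phylo_vcv(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic variance-covariance matrix under Brownian motion.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j.
    Returns the matrix and the tip label order.
    """
    ix = _Indexed(tree)
    n = ix.n_tips
    C = np.zeros((n, n))
    for i in range(len(ix.nodes)):
        kids = ix.children[i]
        if not kids:
            continue
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ta, tb = ix.tips_below[kids[a]], ix.tips_below[kids[b]]
                C[np.ix_(ta, tb)] = ix.depth[i]
                C[np.ix_(tb, ta)] = ix.depth[i]
    tips = ix.tip_pos
    C[np.arange(n), np.arange(n)] = ix.depth[tips]
    return C, ix.tip_labels


def simulate_brownian_tips(
    tree: PhyloTree, n_replicates: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Simulate unit-rate Brownian motion on a tree.

    Returns an (n_tips, n_replicates) matrix of tip values and the tip
    label order (matching :func:`phylo_vcv`).
    """
    ix = _Indexed(tree)
    m = len(ix.nodes)
    vals = np.zeros((m, n_replicates))
    incr = rng.standard_normal((m, n_replicates)) * np.sqrt(ix.lengths)[:, None]
    root = m - 1
    vals[root] = incr[root]
    for i in range(m - 1, -1, -1):
        for c in ix.children[i]:
            vals[c] = vals[i] + incr[c]
    return vals[ix.tip_pos], ix.tip_labels


# ----------------------------------------------------------------------
# Blomberg's K
# ----------------------------------------------------------------------

def _k_machinery(C: np.ndarray):
    """Precompute the GLS pieces of K; regularize singular covariances.

    Trees with zero-length edges (polytomy resolutions, data-free
    terminals) can make C exactly singular; a tiny ridge on the diagonal
    keeps the GLS quantities defined without materially changing K.
    """
    n = C.shape[0]
    one = np.ones(n)
    ridge = 0.0
    base = np.trace(C) / n
    for attempt in range(8):
        try:
            Cinv = np.linalg.inv(C + ridge * np.eye(n) if ridge else C)
        except np.linalg.LinAlgError:
            Cinv = None
        if Cinv is not None:
            u = one @ Cinv
            s = float(u @ one)
            if np.isfinite(s) and s > 0:
                break
        new_ridge = base * 10.0 ** (-12 + 2 * attempt)
        if ridge == 0.0:
            warnings.warn(
                "singular phylogenetic covariance; adding a small ridge"
            )
        ridge = new_ridge
    else:
        raise np.linalg.LinAlgError("phylogenetic covariance is degenerate")
    expected = (np.trace(C) - n / s) / (n - 1)
    return Cinv, u, s, expected


def _k_values(X: np.ndarray, Cinv, u, s, expected) -> np.ndarray:
    """K for each column of X."""
    n = X.shape[0]
    ahat = (u @ X) / s
    R = X - ahat
    mse0 = (R * R).sum(axis=0) / (n - 1)
    mse = (R * (Cinv @ R)).sum(axis=0) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: PhyloTree, trait: TraitVector) -> float:
    """Blomberg et al.'s K statistic for a continuous trait."""
    if tree.n_leaves < 4:
        raise ValueError("K needs at least 4 tips")
    C, labels = phylo_vcv(tree)
    if np.trace(C) <= 0:
        raise ValueError("tree has zero total depth")
    x = trait.vector(labels)
    if np.var(x) == 0:
        raise ValueError("trait has zero variance")
    Cinv, u, s, expected = _k_machinery(C)
    return float(_k_values(x[:, None], Cinv, u, s, expected)[0])


def k_randomization_test(
    tree: PhyloTree,
    trait: TraitVector,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SignalTestResult:
    """Permutation test of phylogenetic signal via Blomberg's K.

    The trait is shuffled across tips ``n_permutations`` times;
    ``p_vs_random`` is the plus-one-corrected fraction of permuted K values
    at least as large as the observed one.
    """
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value")
    C, labels = phylo_vcv(tree)
    x = trait.vector(labels)
    if np.var(x) == 0:
        raise ValueError("trait has zero variance")
    Cinv, u, s, expected = _k_machinery(C)
    k_obs = float(_k_values(x[:, None], Cinv, u, s, expected)[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((len(x), n_permutations))
    for j in range(n_permutations):
        perms[:, j] = rng.permutation(x)
    k_null = _k_values(perms, Cinv, u, s, expected)
    p = (np.count_nonzero(k_null >= k_obs) + 1) / (n_permutations + 1)
    return SignalTestResult(
        statistic_name="K",
        observed=k_obs,
        p_vs_random=float(p),
        null_random=k_null,
        n_replicates=n_permutations,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Fritz & Purvis' D
# ----------------------------------------------------------------------

def sister_clade_difference_sum(tree_or_index, X: np.ndarray) -> np.ndarray:
    """Sum of sister-clade differences for each column of tip matrix X.

    Nodal values are estimated by equal-weight averaging of child values
    down the tree; each internal node contributes the summed absolute
    deviation of its children from their mean (for a bifurcation this is
    simply |left - right|).
    """
    ix = tree_or_index if isinstance(tree_or_index, _Indexed) else _Indexed(tree_or_index)
    m = X.shape[1] if X.ndim == 2 else 1
    X = X.reshape(ix.n_tips, m)
    vals = np.empty((len(ix.nodes), m))
    vals[ix.tip_pos] = X
    d = np.zeros(m)
    for i, kids in enumerate(ix.children):
        if not kids:
            continue
        child_vals = vals[kids]
        mean = child_vals.mean(axis=0)
        vals[i] = mean
        d += np.abs(child_vals - mean).sum(axis=0)
    return d


def _threshold_to_prevalence(liab: np.ndarray, n_ones: int) -> np.ndarray:
    """Binarize each column of a liability matrix so exactly ``n_ones`` tips
    get state 1 (the highest liabilities; ties broken by position)."""
    n, m = liab.shape
    out = np.zeros((n, m))
    order = np.argsort(-liab, axis=0, kind="stable")
    rows = order[:n_ones]
    cols = np.broadcast_to(np.arange(m), rows.shape)
    out[rows, cols] = 1.0
    return out


def fritz_purvis_d(
    tree: PhyloTree,
    trait: TraitVector,
    n_permutations: int = 1000,
    n_brownian: int = 1000,
    seed: int = 0,
) -> SignalTestResult:
    """Fritz & Purvis' D for a binary trait with its two simulated nulls.

    D = (Sd_obs - mean Sd_brownian) / (mean Sd_random - mean Sd_brownian),
    where Sd is the sum of sister-clade differences; the random null
    permutes tip states (preserving prevalence) and the Brownian null
    thresholds a unit-rate Brownian liability at the observed prevalence.

    ``p_vs_random`` (H0: D = 1) is the fraction of permutation-null sums at
    most the observed sum; ``p_vs_clumped`` (H0: D = 0) the fraction of
    Brownian-null sums at least the observed sum — each one-sided toward
    the alternative away from its null.
    """
    if trait.kind != "binary":
        raise ValueError("D is defined for binary traits")
    if tree.n_leaves < 10:
        warnings.warn("D is unreliable on fewer than 10 tips")
    ix = _Indexed(tree)
    x = trait.vector(ix.tip_labels)
    n_ones = int(round(x.sum()))
    if n_ones == 0 or n_ones == len(x):
        raise ValueError("monomorphic binary trait")
    rng = np.random.default_rng(seed)
    d_obs = float(sister_clade_difference_sum(ix, x[:, None])[0])
    perms = np.empty((len(x), n_permutations))
    for j in range(n_permutations):
        perms[:, j] = rng.permutation(x)
    d_rand = sister_clade_difference_sum(ix, perms)
    m = len(ix.nodes)
    incr = rng.standard_normal((m, n_brownian)) * np.sqrt(ix.lengths)[:, None]
    vals = np.zeros((m, n_brownian))
    vals[m - 1] = incr[m - 1]
    for i in range(m - 1, -1, -1):
        for c in ix.children[i]:
            vals[c] = vals[i] + incr[c]
    liab = vals[ix.tip_pos]
    bin_bm = _threshold_to_prevalence(liab, n_ones)
    d_brown = sister_clade_difference_sum(ix, bin_bm)
    denom = d_rand.mean() - d_brown.mean()
    D = (d_obs - d_brown.mean()) / denom if denom != 0 else float("nan")
    p_vs_random = (np.count_nonzero(d_rand <= d_obs) + 1) / (n_permutations + 1)
    p_vs_clumped = (np.count_nonzero(d_brown >= d_obs) + 1) / (n_brownian + 1)
    return SignalTestResult(
        statistic_name="D",
        observed=float(D),
        p_vs_random=float(p_vs_random),
        p_vs_clumped=float(p_vs_clumped),
        null_random=d_rand,
        null_brownian=d_brown,
        n_replicates=n_permutations,
        seed=seed,
        extra={"d_sum_observed": d_obs, "prevalence": n_ones / len(x)},
    )


# ----------------------------------------------------------------------
# independent contrasts
# ----------------------------------------------------------------------

def _contrasts(tree: PhyloTree, x: np.ndarray, labels: list[str], eps: float):
    """Felsenstein's pruning recursion; returns standardized contrasts."""
    value = {}
    vlen = {}
    contrasts = []
    lab_val = dict(zip(labels, x))
    for node in tree.postorder():
        bl = node.length if node.length is not None else 0.0
        if bl == 0.0 and node.parent is not None:
            bl = eps
        if node.is_leaf:
            value[id(node)] = lab_val[node.label]
            vlen[id(node)] = bl
        else:
            if len(node.children) != 2:
                raise ValueError(
                    "independent contrasts require a fully bifurcating tree; "
                    "resolve polytomies first"
                )
            a, b = node.children
            va, vb = vlen.pop(id(a)), vlen.pop(id(b))
            xa, xb = value.pop(id(a)), value.pop(id(b))
            contrasts.append((xa - xb) / np.sqrt(va + vb))
            value[id(node)] = (xa / va + xb / vb) / (1 / va + 1 / vb)
            vlen[id(node)] = bl + va * vb / (va + vb)
    return np.array(contrasts)


def independent_contrasts(
    tree: PhyloTree, x: TraitVector, y: TraitVector
) -> ContrastsResult:
    """Trait-trait association via phylogenetically independent contrasts.

    Standardized contrasts are computed for both traits by the pruning
    recursion (zero-length edges get a small epsilon, 1e-6 of tree depth,
    so standardization stays finite); the slope of the through-origin
    regression of y-contrasts on x-contrasts is tested with a t-statistic
    on n_contrasts - 1 degrees of freedom.
    """
    for n in tree.preorder():
        if n.length is not None and n.length < 0:
            raise ValueError("negative branch length")
    labels = tree.leaf_labels()
    ix = _Indexed(tree)
    depth = ix.depth[ix.tip_pos].max()
    eps = 1e-6 * depth if depth > 0 else 1e-6
    xv = x.vector(labels)
    yv = y.vector(labels)
    cx = _contrasts(tree, xv, labels, eps)
    cy = _contrasts(tree, yv, labels, eps)
    sxx = float(cx @ cx)
    sxy = float(cx @ cy)
    syy = float(cy @ cy)
    if sxx == 0:
        raise ValueError("x contrasts are all zero")
    slope = sxy / sxx
    df = len(cx) - 1
    rss = syy - slope * sxy
    if df > 0 and rss > 0:
        se = np.sqrt(rss / df / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), df)
    else:
        t, p = float("inf") * np.sign(slope), 0.0
    corr = sxy / np.sqrt(sxx * syy) if syy > 0 else float("nan")
    return ContrastsResult(
        contrasts_x=cx,
        contrasts_y=cy,
        slope=float(slope),
        p_value=float(p),
        n_contrasts=len(cx),
        t_statistic=float(t),
        correlation=float(corr),
    )


def binary_contrast_correlation(
    tree: PhyloTree, x: TraitVector, y: TraitVector
) -> ContrastsResult:
    """Independent contrasts on 0/1-coded binary traits.

    Identical machinery to :func:`independent_contrasts`; the slope's sign
    is the direction of the association.
    """
    if x.kind != "binary" or y.kind != "binary":
        raise ValueError("both traits must be binary")
    xc = TraitVector(values=x.values, trait_name=x.trait_name, kind="continuous")
    yc = TraitVector(values=y.values, trait_name=y.trait_name, kind="continuous")
    return independent_contrasts(tree, xc, yc)


# ----------------------------------------------------------------------
# stratified re-runs
# ----------------------------------------------------------------------

def stratified_signal(
    tree: PhyloTree,
    trait: TraitVector,
    strata: dict,
    n_permutations: int = 1000,
    n_brownian: int = 1000,
    seed: int = 0,
) -> dict:
    """Re-run the appropriate signal test within each stratum.

    The tree is pruned to each stratum's species and the K randomization
    (continuous trait) or D test (binary trait) repeated. Strata whose
    pruned trait is degenerate (monomorphic binary trait, zero variance, or
    fewer than 4 species) are skipped with a warning, mirroring how such
    subsets cannot be analysed.
    """
    tips = set(tree.leaf_labels())
    groups: dict[str, list[str]] = {}
    for sp, g in strata.items():
        if sp in tips:
            groups.setdefault(g, []).append(sp)
    results = {}
    for g, species in sorted(groups.items()):
        if len(species) < 4:
            warnings.warn(f"stratum {g!r} skipped: only {len(species)} species")
            continue
        sub = prune_to(tree, species)
        st = trait.restricted(species)
        vec = st.vector(sub.leaf_labels())
        if trait.kind == "binary":
            if vec.sum() in (0, len(vec)):
                warnings.warn(f"stratum {g!r} skipped: trait monomorphic")
                continue
            results[g] = fritz_purvis_d(
                sub, st, n_permutations, n_brownian, seed=seed
            )
        else:
            if np.var(vec) == 0:
                warnings.warn(f"stratum {g!r} skipped: zero trait variance")
                continue
            results[g] = k_randomization_test(
                sub, st, n_permutations, seed=seed
            )
    return results
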