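# Methods

`coraledge` implements a conservation-phylogenetics workflow for reef
corals (order Scleractinia): assemble a supertree from overlapping source
trees, rank species by expected loss of evolutionary history, test whether
extinction risk and threat traits track the phylogeny, and ask how much
phylogenetic diversity different extinction scenarios would erase. This
note records the models, the defaults and why they are what they are, and
the places where a genuine design choice had to be made.

## Tree model and conventions

Trees are rooted, with branch lengths attached to the edge subtending each
node (the root's own edge is 0 by convention). An *absent* length (`None`)
is distinct from an explicit 0: explicit zeros are meaningful — species
placed from taxonomy alone carry a terminal length of exactly 0, giving a
deliberate lower bound on their distinctiveness while their ancestral
branches still count. Absent lengths are treated as 0 with a warning
wherever a computation needs numbers.

Polytomies represent unresolved relationships (e.g. in a strict consensus
supertree). `resolve_polytomies` replaces each polytomy with a random
binary arrangement whose new internal edges have length 0, so total branch
length, the tip set and every clade of the base tree are invariant.
Replicate *i* draws from an RNG stream keyed by `(seed, i)` and is
therefore identical whatever the total number of replicates. Two sampling
schemes are provided:

* `sequential` (default): repeatedly join two uniformly chosen children.
  This samples *labeled histories*, which is exactly uniform over the 3
  topologies of a trichotomy but gives balanced shapes double weight for a
  4-way polytomy (measured 2:1 against the 12 caterpillar shapes).
* `uniform`: attach each child to a uniformly chosen edge of the growing
  local tree (including the root edge), which is exactly uniform over the
  (2k−3)!! rooted binary resolutions; this mode carries the uniformity
  property test at k = 4.

Pruning (`prune_to`) suppresses unbranched nodes, summing their lengths.
By default the path from the MRCA of the kept tips to the original root is
retained as subtending length on the returned root ("rooted PD"
convention): this keeps Faith's PD additive over nested subsets and makes
PD of the full tip set equal the total branch length exactly. The flag
`include_root_path=False` gives the MRCA-rooted alternative.

## MRP supertree assembly

Source-tree clades are coded Baum–Ragan style: one binary character per
non-trivial internal node (members 1, other taxa of that source 0, taxa
absent from the source missing), weighted by the node's bootstrap
percentage; taxonomy-derived trees get unit weights on every node, and
data-derived nodes lacking a support value fall back to weight 1 with a
log note. Identical characters from different sources are kept separate —
their weights add implicitly through the score.

Weighted parsimony length is computed by Hartigan's generalization of the
Fitch pass, which is exact on multifurcating trees; a missing state is the
full state set {0,1}, equivalent for binary characters to scoring each
character on the subtree induced by its non-missing taxa.

Parsimony length does not depend on root placement, so the search space is
effectively unrooted and a rooted supertree requires a rooting device. The
standard one is a hypothetical all-zero outgroup: `encode_mrp` can append
it (`add_root_taxon=True`) and `parsimony_search` then reroots every
minimum-length tree on it and drops it. The convenience `build_supertree`
wires this together; the low-level functions leave it off so the matrix
matches the sources exactly.

Two search strategies:

* `branch_and_bound` (≤ 15 taxa): stepwise addition over unrooted
  topologies with pruning on the partial score (a valid bound because
  adding taxa never decreases parsimony length), seeded with a
  random-addition tree. Returns *all* optimal topologies.
* `hill_climb`: random-addition starting trees refined by
  first-improvement NNI, followed by a breadth-first walk over the
  equal-score NNI plateau (capped at 500 topologies per start) so that the
  set of minimum-length trees — what a strict consensus needs — is
  collected rather than a single representative. A shared rearrangement
  budget (default 10⁵) bounds the work. NNI is the only rearrangement
  operator; desk-scale defaults (10–100 starts) replace the cluster-scale
  searches (10⁵ random additions, 10⁷–10⁸ rearrangements) such data were
  originally analysed with, since the algorithms rather than the compute
  are what this package reproduces.

A subtlety the tests encode: even with conflict-free sources and a perfect
search, the strict consensus on the *full* taxon set restricted to one
source's taxa can lack a clade of that source, because taxa unsampled by
that source have several equally parsimonious placements that the
consensus collapses. Recovery is therefore asserted per optimal tree
(each optimal tree restricted to a source's taxa displays all its clades)
together with consensus soundness (the consensus contains only clades of
the generating tree, restricted to the taxa present in at least one
source).

## EDGE scores

Evolutionary distinctiveness is the fair-proportion measure: each edge's
length is split equally among its descendant tips and summed along each
tip's root path. Summed over species this returns the total branch length
exactly — the conservation identity used as a correctness oracle
throughout.

Extinction probability over a 100-year horizon comes from the Red List
category through the IUCN100 transformation: LC = 0.001 (about one of the
~289 Least Concern corals lost per century), NT = 0.01, and Data Deficient
between the two (midpoint 0.0055 by default; geometric mean ≈ 0.0032 as an
option). CR = 0.999, EN = 0.667 and VU = 0.1 follow the standard IUCN100
table. The `Isaac` (risk doubling per category step) and `Pessimistic`
(upper-bound; a package default, not a published table) transformations
are available as alternatives but drive no default output.

EDGE = ED × PE is computed per polytomy resolution and then summarized
(mean, sample SD) per species; because PE is constant per species this
equals mean-ED × PE, but the per-replicate order is kept so the SDs are
right. Ranking is by mean EDGE, ties broken by mean ED then label.
`rank_stability` compares two rankings restricted to their shared species
(densely re-ranked) and reports the mean absolute rank change over the
top-k and over all shared species.

## Phylogenetic signal

**Blomberg's K** (continuous traits): the observed MSE₀/MSE ratio — trait
variance about the phylogenetically corrected mean over the generalized
least-squares variance under the tree's Brownian covariance — divided by
its Brownian-motion expectation, so K ≈ 1 under Brownian evolution and
falls toward 0 for tip-shuffled traits. Significance comes from permuting
the trait across tips (default 1000 permutations) with the plus-one rule,
so p-values are never 0. Zero-length edges (ubiquitous after polytomy
resolution and for data-free terminals) can make the covariance exactly
singular; a diagonal ridge starting at 10⁻¹² of the mean depth and grown
until the GLS quantities are finite keeps K defined without materially
changing it. Verified against picante's `Kcalc` to 10 decimal places on a
fixed 6-tip tree.

**Fritz & Purvis' D** (binary traits): nodal values are estimated by
equal-weight averaging of child values down the tree, and the observed sum
of sister-clade differences (at each node, the summed absolute deviation
of child values from their mean; |left − right| at a bifurcation) is
rescaled between the mean sums under two simulated nulls — tip permutation
(D = 1) and a unit-rate Brownian liability thresholded at exactly the
observed carrier count (D = 0). Two one-sided p-values are reported, one
against each null: P(D = 1) is the fraction of permutation sums at most
the observed sum, P(D = 0) the fraction of Brownian-threshold sums at
least it. Calibration on 64-tip pure-birth trees: mean D for permuted
traits ≈ 1 and for liability-threshold traits ≈ 0 at prevalences 0.1–0.5.

**Independent contrasts**: Felsenstein's pruning recursion with the usual
branch-length updating; association between two traits is the slope of the
through-origin regression of y-contrasts on x-contrasts with a t-test on
n − 1 degrees of freedom. Contrast standardization divides by branch
lengths, so zero-length edges receive a small ε (10⁻⁶ of tree depth) for
contrast computation only; K and D use the covariance with exact zeros.
Binary traits are analysed as 0/1 values, the slope's sign giving the
direction of association. Verified against ape's `pic` to 10 decimal
places.

`stratified_signal` prunes the tree to each stratum (abundance class,
source-tree representation, or any labelling) and reruns the appropriate
test, skipping — with a logged reason — strata whose trait is monomorphic
or that hold fewer than four species, which is how such subsets fail in
practice.

## PD loss and tree shape

Faith's PD of a taxon set is the branch length of the spanning subtree
(root path included by default, see above). An extinction scenario —
"every species at or above a Red List threshold" or an explicit set —
is compared against a null of removing the same *number* of species
uniformly at random (default 1000 draws): the surviving PD is tested
against the null sample with a one-sample t-test, and a direction
(greater/smaller loss than random) is reported at α = 0.05. Because the
t-test measures the distance of the observation from the null *mean* in
units of SE = SD/√n_null, it is extremely powerful by construction and
its p-value is not uniform even for a random scenario; a Monte-Carlo rank
p-value (position of the observed PD within the null sample, two-sided)
is reported alongside and is the quantity for which uniformity holds.
The same machinery tests the loss if the top-k EDGE species (default 30)
go extinct — these carry long branches, so the expected direction is a
greater-than-random loss.

Tree imbalance is the Colless index, Σ|L − R| over internal nodes of a
bifurcating tree. The null is the Yule (equal-rates-Markov) model,
simulated shape-only via the classic recursion — the root split of an
n-clade is uniform on 1..n−1 — with p the plus-one fraction of simulated
indices at least the observed one. Colless is integer-valued, so ties make
the test slightly conservative (measured type-I rate ≈ 0.04–0.05 at the
nominal 0.05).

## Synthetic data generator

The generator produces every input the pipeline needs, at the conditions
of the coral study by default:

* **Tree**: pure-birth (optionally birth–death), 837 extant species, via
  dendropy's simulator. The simulation stops at the n-th speciation,
  which leaves two zero-length terminals, so one further Exp(nλ) waiting
  time is added to all terminals. The tree is then degraded into a
  consensus-like supertree: a fraction of internal edges (default 0.3 —
  unstated in any source; chosen once as typical of strict consensus
  supertrees) is collapsed into polytomies, each collapsed edge's length
  pushed onto its children so root-to-tip distances are conserved; and a
  fraction of terminals (default (837−365)/837 ≈ 0.56, the share of
  species with no sequence data) is set to length 0.
* **Red List census**: exactly 4 CR, 23 EN, 198 VU, 174 NT, 289 LC and
  149 DD, scaled by largest remainder for other sizes. Counts are exact,
  never Bernoulli draws. `clustering="none"` (default) assigns categories
  by uniform permutation — the study's empirical finding of negligible
  signal in extinction risk — while `"brownian"` slices a Brownian
  liability ranking into category blocks for power analyses.
* **Binary traits**: eight threat/response traits at the study's
  prevalences; clumped traits threshold a unit-rate Brownian liability at
  the exact carrier count, random traits permute an exact-count vector.
  Traits in one liability group share a liability (bleaching and disease
  susceptibility by default), inducing the positive association the study
  reports between them. Liability rate is fixed at 1: D and threshold
  position are scale-free in the liability.
* **Source trees**: induced subtrees on random taxon subsets (default 15
  sources of 8–40 taxa), integer supports uniform on a configured range,
  optionally one taxonomy-flagged source with unit weights, and an
  optional per-source probability of one random NNI to inject conflict.
* **Abundance classes** (for stratified re-runs): equal thirds
  common/uncommon/rare assigned at random — a neutral default, no source
  states the real distribution. Source-tree representation counts are
  derived from the actual extracted sources.

What the generator does *not* emulate: non-Yule (imbalanced) tree shape —
so the imbalance test is expected non-significant on synthetic data,
unlike on real supertrees; correlation between data availability and
threat status; geographic structure; and any sequence-level process.
Passing calibration tests therefore demonstrates the statistics are
correctly implemented and calibrated under their defining models, not that
real coral data would show any particular signal.

## Pipeline defaults and problem sizes

`run_study` derives every stage seed from one top-level seed (via
`SeedSequence`, so stages are independent and reproducible). Defaults
follow the study where stated: 1000 polytomy resolutions, 1000 null
replicates for permutation/simulation tests and random prunings. The
signal stage estimates the mean ± SD of K and D over 100 of the 1000
resolutions by default (`n_signal_resolutions`): the between-resolution
SD is small (new edges have length 0) and 100 replicates estimate it
amply. Trait contrasts are computed on the first resolution. The
acceptance script runs the full 837-species study with these defaults and
100 resolutions, plus calibration studies of 200–300 datasets at 64 tips;
these sizes were chosen as the package's own desk-scale defaults and are
stated in its output.

## Known limitations

* Hill-climbing with NNI and a plateau cap does not guarantee that *all*
  minimum-length trees are found; the strict consensus can be
  over-resolved if optima are missed. Branch-and-bound is exact but
  limited to 15 taxa. TBR-style rearrangements are future work.
* D for polytomous nodes uses the summed deviation from the child mean,
  which reduces to the standard |left − right| only at bifurcations;
  analyses here resolve polytomies first.
* The Brownian-threshold null matches prevalence exactly by construction;
  traits whose real generating process conditions on prevalence
  differently would calibrate differently.
* PE transformations other than IUCN100 ship as conveniences; the
  Pessimistic table is a package default, not a literature value.
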