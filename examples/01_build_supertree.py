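"""Assemble an MRP supertree from overlapping source trees.

Three small rooted source trees with bootstrap supports are coded into a
bootstrap-weighted binary matrix (one character per clade), searched under
weighted parsimony with the all-zero hypothetical outgroup, and summarized
as the strict consensus of all minimum-length trees.
"""

from coraledge import read_newick, write_newick
from coraledge.mrp import SourceTree, build_supertree, encode_mrp

sources = [
    SourceTree(read_newick("(((A,B)90,C)70,D);"), name="molecular_1"),
    SourceTree(read_newick("((C,(D,E)85)60,F);"), name="molecular_2"),
    SourceTree(read_newick("((A,B),(E,F));"), provenance="taxonomic", name="taxonomy"),
]

matrix = encode_mrp(sources, add_root_taxon=True)
print(f"matrix: {matrix.n_taxa} taxa x {matrix.n_characters} characters")
print(f"character weights (bootstrap %, or 1 for taxonomy): {list(matrix.weights)}")

supertree, result = build_supertree(sources, strategy="branch_and_bound", seed=0)
print(f"best weighted parsimony score: {result.score:g} "
      f"({len(result.trees)} minimum-length tree(s))")
print(f"strict consensus supertree: {write_newick(supertree)}")
# The consensus keeps only groupings common to all optimal trees; taxa whose
# placement the sources do not determine appear in polytomies.
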