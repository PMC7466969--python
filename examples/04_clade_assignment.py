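"""Place query domains into named reference clades on a phylogeny.

A query tip belongs to the smallest named clade whose reference MRCA it
descends from; queries outside every named clade are "unassigned".  The
genome x clade abundance matrix is the input for the census heatmaps.
"""

import dendropy

from hgtcensus import sm_census as sm

newick = "(((sid_ref1,(sid_ref2,queryA)),((surf_ref1,(surf_ref2,queryB)),queryC)),outgroup);"
tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

clades = [
    sm.CladeDefinition("SIDE", frozenset({"sid_ref1", "sid_ref2"})),
    sm.CladeDefinition("surfactin-like", frozenset({"surf_ref1", "surf_ref2"})),
]
queries = ["queryA", "queryB", "queryC"]
assignments = sm.assign_clades(tree, clades, queries, outgroup_tips=["outgroup"])
for q, clade in assignments.items():
    print(f"{q} -> {clade}")

genome_of = {"queryA": "genome_1", "queryB": "genome_1", "queryC": "genome_2"}
matrix = sm.clade_abundance_matrix(assignments, genome_of)
print("\nabundance matrix (rows sum to per-genome query counts):")
print(matrix.to_string())
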