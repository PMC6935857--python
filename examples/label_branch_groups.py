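"""Partition a gene-tree into labeled branch groups.

Leaves take their species' group; an internal branch keeps a group label
iff every descendant branch shares it, otherwise it is 'nuisance'.  The
labeled tree (with {G} branch annotations) is the input of the group-level
selection test.
"""

from ciliaevol import LabeledTree, label_tree

newick = "((Loxodes:0.2,Remanella:0.25):0.1,((Stentor:0.2,Blepharisma:0.3):0.15,Frontonia:0.4):0.05);"
groups = {
    "Loxodes": "K",
    "Remanella": "K",
    "Stentor": "H",
    "Blepharisma": "H",
    "Frontonia": "NEF",
}

tree = LabeledTree.from_newick(newick)
label_tree(tree, groups)

print(tree.to_newick())
print()
print(tree.branch_table().to_string(index=False))
# The Karyorelictea and Heterotrichea cherries stay labeled K and H; the
# branch uniting Heterotrichea with Frontonia mixes groups and is nuisance.
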