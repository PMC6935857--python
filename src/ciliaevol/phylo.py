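"""Branch-group labeling of phylogenies.

The group-level selection tests partition tree branches into N+1
non-overlapping sets: the four focal groups (K, H, EF, NEF) plus the
"nuisance" set of unlabeled branches.  Leaves take their species' group;
internal branches are labeled bottom-up and receive a group label iff every
descendant branch shares it, otherwise they are nuisance.  Labels are
written in the ``{G}`` branch-annotation style used by selection-analysis
tools.
"""

from __future__ import annotations

import re
from typing import Mapping

import dendropy
import pandas as pd

NUISANCE = "nuisance"

_LABEL_RE = re.compile(r"\{([^{}]*)\}")


class LabeledTree:
    """A rooted dendropy tree whose nodes carry a ``group`` attribute.

    The label of a node describes the branch above it; the root (which has
    no branch) carries no label.  Leaf nodes additionally keep their
    ``species`` attribute (defaulting to the taxon label).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        for node in tree:
            if not hasattr(node, "group"):
                node.group = None
            if node.is_leaf() and not hasattr(node, "species"):
                node.species = node.taxon.label if node.taxon else None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        """Parse Newick; ``{G}`` suffixes on labels become branch groups."""
        # brace annotations are not standard Newick; shield them from the
        # tokenizer and decode after parsing
        shielded = _LABEL_RE.sub(lambda m: f"__GRP_{m.group(1)}__", newick)
        tree = dendropy.Tree.get(
            data=shielded,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        grp_re = re.compile(r"__GRP_([^_]*(?:_[^_]+)*?)__$")
        for node in tree:
            label = node.taxon.label if node.taxon else node.label
            if label:
                m = grp_re.search(label)
                if m:
                    node.group = m.group(1) or None
                    clean = grp_re.sub("", label)
                    if node.taxon:
                        node.taxon.label = clean
                    else:
                        node.label = clean or None
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "LabeledTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic accessors ----------------------------------------------

    def leaves(self):
        return self.tree.leaf_node_iter()

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.leaves()]

    def branch_labels(self) -> dict[str, str | None]:
        """Map of node key (leaf taxon or internal id) to branch label."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out[self.node_key(node)] = node.group
        return out

    @staticmethod
    def node_key(node) -> str:
        if node.is_leaf() and node.taxon:
            return node.taxon.label
        if getattr(node, "label", None):
            return node.label
        leaves = sorted(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon
        )
        return "|".join(leaves)

    # -- output --------------------------------------------------------

    def to_newick(self) -> str:
        """Newick with ``{G}`` label suffixes on labeled branches."""

        def rec(node) -> str:
            grp = getattr(node, "group", None)
            suffix = (
                ""
                if node.parent_node is None or grp in (None, NUISANCE)
                else "{%s}" % grp
            )
            bl = (
                f":{node.edge.length:g}"
                if node.parent_node is not None and node.edge.length is not None
                else ""
            )
            if node.is_leaf():
                name = node.taxon.label if node.taxon else (node.label or "")
                return f"{name}{suffix}{bl}"
            inner = ",".join(rec(c) for c in node.child_nodes())
            name = node.label or ""
            return f"({inner}){name}{suffix}{bl}"

        return rec(self.tree.seed_node) + ";"

    def branch_table(self) -> pd.DataFrame:
        """TSV-friendly table: branch id, parent, length, label."""
        rows = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            rows.append(
                {
                    "branch": self.node_key(node),
                    "parent": self.node_key(node.parent_node)
                    if node.parent_node.parent_node is not None
                    else "root",
                    "length": node.edge.length,
                    "label": node.group or NUISANCE,
                    "is_leaf": node.is_leaf(),
                }
            )
        return pd.DataFrame(rows)


def label_leaves(
    tree: LabeledTree, species_to_group: Mapping[str, str]
) -> LabeledTree:
    """Label each leaf branch with its species' group.

    Leaves whose species is missing from the map raise an error listing
    them; mapping a species explicitly to ``nuisance`` is allowed.
    """
    unmapped = []
    for leaf in tree.leaves():
        sp = getattr(leaf, "species", None) or (
            leaf.taxon.label if leaf.taxon else None
        )
        if sp not in species_to_group:
            unmapped.append(sp)
        else:
            leaf.group = species_to_group[sp]
    if unmapped:
        raise ValueError(f"species without group assignment: {sorted(unmapped)}")
    return tree


def label_internal(tree: LabeledTree) -> LabeledTree:
    """Propagate labels bottom-up: an internal branch gets group g iff all
    of its descendant branches are labeled g; otherwise it is nuisance."""
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            if node.group is None:
                raise ValueError(
                    f"unlabeled leaf {LabeledTree.node_key(node)!r}"
                )
            continue
        child_groups = {c.group for c in node.child_nodes()}
        if len(child_groups) == 1:
            (g,) = child_groups
            node.group = g if g != NUISANCE else NUISANCE
        else:
            node.group = NUISANCE
    return tree


def label_tree(
    tree: LabeledTree, species_to_group: Mapping[str, str]
) -> LabeledTree:
    """Leaf labeling followed by bottom-up internal labeling."""
    return label_internal(label_leaves(tree, species_to_group))
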