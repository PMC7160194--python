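"""Rooted phylogenies in Newick format.

A :class:`PhyloTree` is a thin, validated wrapper around a rooted
:class:`dendropy.Tree`: tips carry unique labels, internal labels are
optional, branch lengths are optional, and polytomies are permitted.
Underscores in labels are literal (no underscore-to-space translation),
matching the genus_species convention of the bundled fixtures.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Iterator

import dendropy

__all__ = [
    "PhyloTree",
    "TreeError",
    "NewickParseError",
    "DuplicateTipLabelError",
    "UnknownTaxonError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "read_newick_trees",
    "prune_to_taxa",
    "mrca",
    "attach_constraint_tip",
    "clade_key",
]


class TreeError(ValueError):
    """Base class for tree construction and query errors."""


class NewickParseError(TreeError):
    """Malformed Newick input; the message names the offending position."""


class DuplicateTipLabelError(TreeError):
    """Two tips in one tree share a label."""


class UnknownTaxonError(TreeError, KeyError):
    """A query named tip labels that are not in the tree."""

    def __init__(self, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(f"unknown tip label(s): {', '.join(self.missing)}")


def clade_key(node: dendropy.Node) -> tuple[str, ...]:
    """Stable identifier for a node: the sorted labels of its descendant tips.

    Used to key reconstruction results and branch reports, so that results
    survive tree copies and round-trips through Newick.
    """
    if node.is_leaf():
        return (node.taxon.label,)
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


class PhyloTree:
    """A rooted tree with uniquely labeled tips.

    Wraps a :class:`dendropy.Tree`; traversal methods yield raw dendropy
    nodes so downstream algorithms (parsimony, simulation) can walk the
    topology without reinventing a tree container.
    """

    __slots__ = ("_tree",)

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in tree.leaf_node_iter()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("every tip must carry a label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise DuplicateTipLabelError(
                f"duplicate tip label(s): {', '.join(sorted(dupes))}")
        self._tree = tree

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip()
        if not text.endswith(";"):
            raise NewickParseError(
                f"Newick statement must end with ';' (character offset {len(text)})")
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise DuplicateTipLabelError(str(exc)) from exc
        except Exception as exc:  # dendropy raises several reader subclasses
            raise NewickParseError(str(exc)) from exc
        return cls(tree)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic queries -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def postorder_nodes(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def preorder_nodes(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def leaves(self) -> Iterator[dendropy.Node]:
        return self._tree.leaf_node_iter()

    def __len__(self) -> int:
        return self.n_tips

    def __repr__(self) -> str:
        return f"<PhyloTree with {self.n_tips} tips>"

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Canonical Newick: unquoted underscores, no rooting token."""
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return out

    # -- manipulation ------------------------------------------------------

    def _require_known(self, labels: Iterable[str]) -> set[str]:
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise UnknownTaxonError(missing)
        return labels

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict to the tips in ``keep``.

        Degree-2 internal nodes created by the pruning are suppressed and
        their branch lengths summed, so pairwise path lengths among the
        kept tips are preserved.
        """
        keep = self._require_known(keep)
        if len(keep) < 2:
            raise TreeError("prune_to requires at least two tips to keep")
        pruned = self._tree.clone(depth=1)
        pruned.retain_taxa_with_labels(sorted(keep))
        # drop a leftover unifurcate root so the result is a clean rooted tree
        while len(pruned.seed_node.child_nodes()) == 1:
            child = pruned.seed_node.child_nodes()[0]
            if child.edge.length is not None and pruned.seed_node.edge.length:
                child.edge.length += pruned.seed_node.edge.length
            pruned.seed_node = child
            child.parent_node = None
        return PhyloTree(pruned)

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of the named tips."""
        tips = self._require_known(tips)
        if not tips:
            raise TreeError("mrca requires at least one tip label")
        if len(tips) == 1:
            (label,) = tips
            return next(leaf for leaf in self.leaves()
                        if leaf.taxon.label == label)
        return self._tree.mrca(taxon_labels=sorted(tips))

    def attach_constraint_tip(self, label: str) -> "PhyloTree":
        """Return a copy with a new root subtending the old root and a new
        tip named ``label`` on zero-length branches.

        This is the mechanism for imposing an outgroup state on an analysis:
        the added tip carries the constraining observation.
        """
        if label in self.tip_labels:
            raise DuplicateTipLabelError(f"tip label already present: {label}")
        augmented = self._tree.clone(depth=1)
        old_root = augmented.seed_node
        new_root = dendropy.Node()
        taxon = augmented.taxon_namespace.new_taxon(label)
        tip = dendropy.Node(taxon=taxon)
        new_root.add_child(old_root)
        new_root.add_child(tip)
        old_root.edge.length = 0.0
        tip.edge.length = 0.0
        augmented.seed_node = new_root
        return PhyloTree(augmented)


# -- module-level functional interface ------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    """Serialize; ``parse_newick(write_newick(t))`` preserves topology,
    labels, and branch lengths."""
    return tree.to_newick()


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_trees(source) -> list[PhyloTree]:
    """Read a multi-tree file: one Newick statement per line."""
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        fh = io.StringIO(str(source))
    else:
        fh = open(source)
    with fh:
        return [parse_newick(line) for line in fh if line.strip()]


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    return tree.prune_to(keep)


def mrca(tree: PhyloTree, tips: Iterable[str]) -> dendropy.Node:
    return tree.mrca(tips)


def attach_constraint_tip(tree: PhyloTree, label: str) -> PhyloTree:
    return tree.attach_constraint_tip(label)
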