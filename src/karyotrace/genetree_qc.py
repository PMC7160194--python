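"""Locus-level QC filters for phylogenomic datasets.

Two filters operating on per-locus alignments and their single-locus gene
trees: an occupancy threshold (discard loci sequenced for fewer than a
minimum number of core taxa) and a long-branch paralog/chimera filter
(discard loci whose gene tree has a longest branch at least five times the
second longest — the signature of an undetected paralog or chimeric
sequence isolating a few taxa on one very long branch).

The long-branch statistic treats the gene tree as unrooted: the two
branches adjacent to the root of a rooted binary representation describe
one unrooted branch and are merged (summed) before ranking, which makes
the ratio invariant to where the inference software happened to root the
tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .tree_io import PhyloTree, read_newick_file

__all__ = [
    "LocusRecord",
    "FilterResult",
    "locus_occupancy",
    "occupancy_filter",
    "longest_branch_ratio",
    "paralog_filter",
    "load_locus_set",
    "qc_report",
]

DEFAULT_MIN_OCCUPANCY = 7
DEFAULT_RATIO_THRESHOLD = 5.0


@dataclass(frozen=True)
class LocusRecord:
    """One locus: which taxa have sequence, and its gene tree if any."""

    locus_id: str
    taxa_present: frozenset
    alignment_length: int = 0
    gene_tree: PhyloTree | None = None

    def __post_init__(self):
        object.__setattr__(self, "taxa_present", frozenset(self.taxa_present))
        if self.gene_tree is not None:
            extra = set(self.gene_tree.tip_labels) - self.taxa_present
            if extra:
                raise ValueError(
                    f"{self.locus_id}: gene-tree tips not in alignment: "
                    f"{sorted(extra)}")


@dataclass
class FilterResult:
    kept: list[LocusRecord]
    discarded: list[LocusRecord]
    reasons: dict[str, str] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def locus_occupancy(locus: LocusRecord, core_taxa: Iterable[str]) -> int:
    """Number of core taxa with any sequence at the locus (any nonzero
    record counts as present; no length floor)."""
    core_taxa = set(core_taxa)
    if not core_taxa:
        raise ValueError("core_taxa must be nonempty")
    return len(locus.taxa_present & core_taxa)


def occupancy_filter(loci: Sequence[LocusRecord], core_taxa: Iterable[str],
                     min_count: int = DEFAULT_MIN_OCCUPANCY) -> FilterResult:
    """Keep loci with at least ``min_count`` core taxa present (loci with
    *fewer* are discarded)."""
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    core_taxa = set(core_taxa)
    result = FilterResult([], [])
    for locus in loci:
        occ = locus_occupancy(locus, core_taxa) if core_taxa else 0
        if occ >= min_count:
            result.kept.append(locus)
        else:
            result.discarded.append(locus)
            result.reasons[locus.locus_id] = (
                f"occupancy {occ} < {min_count} core taxa")
    return result


def longest_branch_ratio(tree: PhyloTree) -> float:
    """Ratio of the longest to the second-longest branch, over all
    terminal and internal branches of the unrooted tree.

    A zero second-longest branch under a positive longest yields
    ``inf`` (the degenerate star-with-one-long-branch case, which is
    exactly the paralog signature).  Ties produce a ratio of 1.
    """
    root = tree.root
    root_children = root.child_nodes()
    lengths = []
    for node in tree.postorder_nodes():
        if node is root or (len(root_children) == 2 and node in root_children):
            continue
        if node.edge.length is None:
            raise ValueError("longest_branch_ratio requires branch lengths "
                             "on every branch")
        lengths.append(float(node.edge.length))
    if len(root_children) == 2:
        a, b = (c.edge.length for c in root_children)
        if a is None or b is None:
            raise ValueError("longest_branch_ratio requires branch lengths "
                             "on every branch")
        lengths.append(float(a) + float(b))
    if len(lengths) < 2:
        raise ValueError("longest_branch_ratio requires at least two branches")
    lengths.sort(reverse=True)
    longest, second = lengths[0], lengths[1]
    if second == 0.0:
        if longest == 0.0:
            raise ValueError("all branch lengths are zero")
        return math.inf
    return longest / second


def paralog_filter(loci: Sequence[LocusRecord],
                   threshold: float = DEFAULT_RATIO_THRESHOLD) -> FilterResult:
    """Discard loci whose gene tree's longest-branch ratio is at least
    ``threshold`` ("at least five times longer" is inclusive), or
    infinite.  A locus without an evaluable gene tree is kept and
    flagged with a warning, never silently dropped."""
    result = FilterResult([], [])
    for locus in loci:
        if locus.gene_tree is None:
            result.kept.append(locus)
            result.warnings.append(
                f"{locus.locus_id}: no gene tree; unevaluable, kept")
            continue
        try:
            ratio = longest_branch_ratio(locus.gene_tree)
        except ValueError as exc:
            result.kept.append(locus)
            result.warnings.append(
                f"{locus.locus_id}: {exc}; unevaluable, kept")
            continue
        result.ratios[locus.locus_id] = ratio
        if ratio >= threshold:
            result.discarded.append(locus)
            result.reasons[locus.locus_id] = (
                f"longest-branch ratio {ratio:.3g} >= {threshold:g}")
        else:
            result.kept.append(locus)
    return result


def load_locus_set(alignments_dir, trees_dir=None,
                   alignment_suffixes=(".fasta", ".fa", ".fna")) -> list[LocusRecord]:
    """Build locus records from a directory of per-locus FASTA alignments
    (locus id = file stem) and, optionally, a matching directory of
    per-locus Newick gene trees."""
    alignments_dir = Path(alignments_dir)
    trees_dir = Path(trees_dir) if trees_dir is not None else None
    loci = []
    paths = sorted(p for p in alignments_dir.iterdir()
                   if p.suffix.lower() in alignment_suffixes)
    for path in paths:
        seqs = list(SeqIO.parse(str(path), "fasta"))
        taxa = frozenset(s.id for s in seqs)
        length = max((len(s.seq) for s in seqs), default=0)
        gene_tree = None
        if trees_dir is not None:
            for suffix in (".nwk", ".tre", ".treefile"):
                tree_path = trees_dir / (path.stem + suffix)
                if tree_path.exists():
                    gene_tree = read_newick_file(tree_path)
                    break
        loci.append(LocusRecord(path.stem, taxa, length, gene_tree))
    return loci


def qc_report(loci: Sequence[LocusRecord], core_taxa: Iterable[str],
              min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
              ratio_threshold: float = DEFAULT_RATIO_THRESHOLD) -> pd.DataFrame:
    """Run both filters in sequence (occupancy, then long-branch) and
    report one row per locus: occupancy, ratio, decision, reason."""
    core_taxa = set(core_taxa)
    occ_result = occupancy_filter(loci, core_taxa, min_occupancy)
    par_result = paralog_filter(occ_result.kept, ratio_threshold)
    discarded_par = {l.locus_id for l in par_result.discarded}
    discarded_occ = {l.locus_id for l in occ_result.discarded}
    unevaluable = {w.split(":")[0] for w in par_result.warnings}
    rows = []
    for locus in loci:
        occ = locus_occupancy(locus, core_taxa)
        ratio = par_result.ratios.get(locus.locus_id)
        if locus.locus_id in discarded_occ:
            decision, reason = "discard", occ_result.reasons[locus.locus_id]
        elif locus.locus_id in discarded_par:
            decision, reason = "discard", par_result.reasons[locus.locus_id]
        elif locus.locus_id in unevaluable:
            decision, reason = "keep", "gene tree unevaluable; kept with warning"
        else:
            decision, reason = "keep", ""
        rows.append({
            "locus_id": locus.locus_id,
            "occupancy": occ,
            "ratio": "" if ratio is None else f"{ratio:.6g}",
            "decision": decision,
            "reason": reason,
        })
    return pd.DataFrame(rows)
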