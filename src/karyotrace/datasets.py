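"""Bundled study fixtures.

``sitticini_karyotypes.tsv`` transcribes the male chromosome complements
observed for the 18 karyotyped sitticine species (multi-locality rows
collapsed; specimen/nucleus tallies summed).  ``sitticini_tree.nwk`` is
the 18-taxon karyotyped phylogeny the chromosome-evolution analysis runs
on (topology only, no branch lengths).
"""

from __future__ import annotations

from importlib.resources import files

from .karyotypes import KaryotypeRecord, parse_karyotype_table
from .tree_io import PhyloTree, parse_newick

__all__ = ["load_karyotype_table", "load_study_tree",
           "karyotype_table_path", "study_tree_path"]


def _data(name: str) -> str:
    return (files("karyotrace.data") / name).read_text()


def karyotype_table_path() -> str:
    return str(files("karyotrace.data") / "sitticini_karyotypes.tsv")


def study_tree_path() -> str:
    return str(files("karyotrace.data") / "sitticini_tree.nwk")


def load_karyotype_table() -> list[KaryotypeRecord]:
    """The 18 male karyotype records of the study species."""
    return parse_karyotype_table(_data("sitticini_karyotypes.tsv"))


def load_study_tree() -> PhyloTree:
    """The 18-taxon karyotyped phylogeny of the study species."""
    return parse_newick(_data("sitticini_tree.nwk"))
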