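"""Chromosome-evolution analyses on a karyotyped phylogeny.

Drivers that put the pieces together for the sitticine analysis: map the
neo-Y presence character and the base-autosome-number character from
karyotype records onto a tree, count minimum neo-Y origins (gains-only
model rooted in the ancestral X1X2O condition) versus minimum losses
(losses-only model rooted with a Y), reconstruct ancestral base numbers,
probe their sensitivity to deleting uncertain scores, and check whether
each neo-Y origin falls in a 28-autosome lineage.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .karyotypes import KaryotypeRecord, base_number, y_state
from .parsimony import (MISSING, CharacterMatrix, CostModel,
                        ReconstructionResult, fitch_reconstruct,
                        sankoff_reconstruct)
from .tree_io import PhyloTree, clade_key

__all__ = [
    "Y_ABSENT",
    "Y_PRESENT",
    "y_character",
    "base_number_character",
    "gains_only_model",
    "losses_only_model",
    "OriginContext",
    "OriginReport",
    "y_origin_analysis",
    "base_number_ancestry",
    "sensitivity_analysis",
    "origin_context_check",
    "named_clades",
    "root_condition_report",
]

Y_ABSENT, Y_PRESENT = "0", "1"


def y_character(records: Iterable[KaryotypeRecord]) -> CharacterMatrix:
    """Binary neo-Y presence character (1 = Y present)."""
    return CharacterMatrix(
        "neo_y", (Y_ABSENT, Y_PRESENT),
        {r.species: frozenset({str(y_state(r))}) for r in records})


def base_number_character(records: Iterable[KaryotypeRecord],
                          mode: str = "default",
                          drop_uncertain: bool = False) -> CharacterMatrix:
    """Base-autosome-number character from the counting rule.

    Unknown base numbers become MISSING; with ``drop_uncertain`` every
    '?'-flagged score is set MISSING as well (instead of its face value).
    """
    values: dict[str, object] = {}
    for r in records:
        b = base_number(r, mode=mode)
        if b.value is None or (drop_uncertain and b.uncertain):
            values[r.species] = MISSING
        else:
            values[r.species] = b.value
    return CharacterMatrix.from_values("base_number", values)


def gains_only_model() -> CostModel:
    """Y origins are counted: 0->1 costs 1, reversal forbidden, root XX0."""
    return CostModel.irreversible(Y_ABSENT, Y_PRESENT)


def losses_only_model() -> CostModel:
    """The alternative polarity: Y ancestral, only losses to XX0 allowed."""
    return CostModel.irreversible(Y_PRESENT, Y_ABSENT)


@dataclass(frozen=True)
class OriginContext:
    """Base-number context of one inferred neo-Y origin branch."""

    branch: tuple[str, ...]
    in_28_lineage: bool
    base_mpr_at_origin: frozenset
    nearest_26_tip: str | None
    nearest_26_has_y: bool | None


@dataclass
class OriginReport:
    gains_only_cost: int
    losses_only_cost: float
    origin_branches: list[tuple[str, ...]]
    gains_result: ReconstructionResult
    losses_result: ReconstructionResult
    origin_contexts: list[OriginContext] = field(default_factory=list)


def _check_coverage(tree: PhyloTree, records: Sequence[KaryotypeRecord]):
    have = {r.species for r in records}
    missing = set(tree.tip_labels) - have
    if missing:
        raise ValueError(f"no karyotype record for tip(s): {sorted(missing)}")


def y_origin_analysis(tree: PhyloTree,
                      records: Sequence[KaryotypeRecord],
                      with_context: bool = True,
                      mode: str = "default") -> OriginReport:
    """Count minimum neo-Y origins (gains-only, XX0 root) and minimum
    losses (losses-only, Y root), and locate the origin branches."""
    _check_coverage(tree, records)
    chars = y_character(records)
    gains = sankoff_reconstruct(tree, chars, gains_only_model())
    losses = sankoff_reconstruct(tree, chars, losses_only_model())
    origins = [branch for branch, a, b in gains.obligate_transitions()
               if (a, b) == (Y_ABSENT, Y_PRESENT)]
    report = OriginReport(
        gains_only_cost=int(gains.min_cost),
        losses_only_cost=losses.min_cost,
        origin_branches=sorted(origins),
        gains_result=gains,
        losses_result=losses,
    )
    assert report.gains_only_cost == len(report.origin_branches)
    if with_context:
        base_char = base_number_character(records, mode=mode)
        base_rec = fitch_reconstruct(tree, base_char)
        report.origin_contexts = origin_context_check(
            tree, report, base_rec, base_char)
    return report


def base_number_ancestry(tree: PhyloTree,
                         records: Sequence[KaryotypeRecord],
                         clade: Iterable[str],
                         mode: str = "default",
                         drop_uncertain: bool = False) -> frozenset:
    """MPR state set for the base autosome number at the MRCA of ``clade``
    under unordered symmetric (Fitch) parsimony."""
    _check_coverage(tree, records)
    chars = base_number_character(records, mode=mode,
                                  drop_uncertain=drop_uncertain)
    result = fitch_reconstruct(tree, chars)
    node = tree.mrca(clade)
    return result.node_mpr[clade_key(node)]


def named_clades(tree: PhyloTree,
                 ingroup_prefix: str = "Attulus") -> dict[str, tuple[str, ...]]:
    """The three ancestors the analysis reports on: the tree root, the
    MRCA of the ``ingroup_prefix`` tips (Attulus), and the MRCA of the
    remaining tips (the Jollas-Tomis clade)."""
    tips = tree.tip_labels
    ingroup = tuple(t for t in tips if t.startswith(ingroup_prefix))
    rest = tuple(t for t in tips if not t.startswith(ingroup_prefix))
    clades = {"sitticini_root": tips}
    if rest:
        clades["jollas_tomis_mrca"] = rest
    if ingroup:
        clades["attulus_mrca"] = ingroup
    return clades


def sensitivity_analysis(tree: PhyloTree,
                         records: Sequence[KaryotypeRecord],
                         scenarios: Mapping[str, Sequence[tuple[str, str]]],
                         mode: str = "default") -> pd.DataFrame:
    """Rerun the base-number reconstruction under per-scenario deletions.

    Each scenario is a list of ``(taxon, field)`` deletions with field
    ``"autosomes"`` (drop the autosome count, hence the base number) or
    ``"sex"`` (drop the sex-system score, hence both characters' use of
    it — conservatively the whole base number).  A ``"baseline"`` row
    with no deletions is always included.  Cells hold the sorted tuple
    of MPR states at the named ancestors.
    """
    _check_coverage(tree, records)
    by_species = {r.species: r for r in records}
    clades = named_clades(tree)
    # the state domain is fixed by the undeleted data, so MPR sets stay
    # comparable across scenarios (a data-free scenario spans the domain)
    domain = base_number_character(records, mode=mode).states
    all_scenarios: dict[str, Sequence[tuple[str, str]]] = {"baseline": ()}
    all_scenarios.update(scenarios)
    rows = {}
    for name, deletions in all_scenarios.items():
        values: dict[str, object] = {}
        deleted = set()
        for taxon, fld in deletions:
            if taxon not in by_species:
                raise ValueError(f"unknown taxon in deletion: {taxon!r}")
            if fld not in ("autosomes", "sex"):
                raise ValueError(f"unknown field in deletion: {fld!r}")
            deleted.add(taxon)
        for r in records:
            b = base_number(r, mode=mode)
            values[r.species] = MISSING if (r.species in deleted
                                            or b.value is None) else b.value
        chars = CharacterMatrix.from_values("base_number", values,
                                            states=domain)
        if all(v is MISSING for v in chars.assignments.values()):
            rows[name] = {c: tuple(sorted(domain)) for c in clades}
            continue
        result = fitch_reconstruct(tree, chars)
        rows[name] = {
            c: tuple(sorted(result.node_mpr[clade_key(tree.mrca(tips))]))
            for c, tips in clades.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def _node_by_key(tree: PhyloTree, key: tuple[str, ...]):
    for node in tree.postorder_nodes():
        if clade_key(node) == key:
            return node
    raise KeyError(f"no node with clade key {key}")


def origin_context_check(tree: PhyloTree, report: OriginReport,
                         base_result: ReconstructionResult,
                         base_char: CharacterMatrix,
                         context_state: str = "28",
                         contrast_state: str = "26") -> list[OriginContext]:
    """For each neo-Y origin, ask whether it sits in a 28-autosome lineage
    (28 in the MPR of the origin branch's child node, or observed in at
    least one descendant tip), and find the topologically nearest tip
    with base number 26 together with its Y state.

    Descriptive only — the underlying observation comes with no
    significance test attached.
    """
    y_by_tip = {}
    for key, mpr in report.gains_result.node_mpr.items():
        if len(key) == 1:
            y_by_tip[key[0]] = (Y_PRESENT in mpr)
    contexts = []
    for branch in report.origin_branches:
        child = _node_by_key(tree, branch)
        mpr = base_result.node_mpr.get(branch, frozenset())
        in_lineage = context_state in mpr
        if not in_lineage:
            for leaf in ([child] if child.is_leaf() else child.leaf_iter()):
                obs = base_char.assignments.get(leaf.taxon.label)
                if obs is not MISSING and context_state in obs:
                    in_lineage = True
                    break
        nearest, nearest_y = _nearest_tip_with_state(
            tree, child, base_char, contrast_state, y_by_tip)
        contexts.append(OriginContext(branch, in_lineage, mpr, nearest, nearest_y))
    return contexts


def _nearest_tip_with_state(tree: PhyloTree, start, base_char, state,
                            y_by_tip):
    """Breadth-first search over the topology (node hops; branch lengths
    are absent on the study fixture) for the closest tip observing
    ``state``.  Ties break alphabetically for determinism."""
    seen = {id(start)}
    frontier = deque([(start, 0)])
    best: tuple[int, str] | None = None
    while frontier:
        node, dist = frontier.popleft()
        if best is not None and dist > best[0]:
            break
        if node.is_leaf():
            obs = base_char.assignments.get(node.taxon.label)
            if obs is not MISSING and state in obs:
                cand = (dist, node.taxon.label)
                if best is None or cand < best:
                    best = cand
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            if id(nb) not in seen:
                seen.add(id(nb))
                frontier.append((nb, dist + 1))
    if best is None:
        return None, None
    return best[1], y_by_tip.get(best[1])


def root_condition_report(tree: PhyloTree,
                          records: Sequence[KaryotypeRecord],
                          outgroup_state: str = "26",
                          mode: str = "default") -> pd.DataFrame:
    """Ancestral base-number MPR sets with and without an imposed outgroup
    condition (a zero-length constraint tip observing ``outgroup_state``
    attached at the root), at the named ancestors.

    Whether the deep ancestors are ambiguous without the condition is
    reported, not asserted: it depends on how uncertain tips are scored.
    """
    _check_coverage(tree, records)
    chars = base_number_character(records, mode=mode)
    clades = named_clades(tree)
    rows = {}
    free = fitch_reconstruct(tree, chars)
    rows["unconstrained"] = {
        name: tuple(sorted(free.node_mpr[clade_key(tree.mrca(tips))]))
        for name, tips in clades.items()}
    out_label = "__outgroup__"
    constrained_tree = tree.attach_constraint_tip(out_label)
    assignments = dict(chars.assignments)
    assignments[out_label] = frozenset({outgroup_state})
    states = tuple(sorted(set(chars.states) | {outgroup_state}))
    chars2 = CharacterMatrix(chars.character_name, states, assignments)
    constrained = fitch_reconstruct(constrained_tree, chars2)
    rows[f"outgroup_{outgroup_state}"] = {
        name: tuple(sorted(
            constrained.node_mpr[clade_key(constrained_tree.mrca(tips))]))
        for name, tips in clades.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
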