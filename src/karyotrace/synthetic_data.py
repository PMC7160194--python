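"""Ground-truthed synthetic inputs for every other module.

Three generators, all pure functions of their arguments and a seed:

* Yule (pure-birth) trees, for topologies and ultrametric branch lengths;
* a continuous-time karyotype-evolution simulation on a tree — rare
  autosome pair gains/losses and irreversible X-autosome fusions
  (XX0 -> XXY -> XXXY, each fusion consuming one autosome pair) via a
  per-branch Gillespie algorithm, with a full event log so parsimony
  estimates can be compared against the true history;
* locus sets with controlled per-taxon occupancy and planted long-branch
  paralogs, for exercising the QC filters against known labels.

Fusion events conserve the base autosome number by construction (the
pair lost to the fusion is exactly the pair the counting rule adds
back), which is the invariant the karyotype module's rule must recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genetree_qc import LocusRecord
from .karyotypes import KaryotypeRecord, SexSystem
from .tree_io import PhyloTree, clade_key

__all__ = [
    "KaryoSimConfig",
    "Event",
    "simulate_yule_tree",
    "simulate_karyotype_evolution",
    "plant_paralog_branch",
    "generate_locus_set",
    "events_to_json",
]

#: Autosome floor: pair losses (and fusions, which also consume a pair)
#: are blocked from taking the diploid autosome count below this.
MIN_AUTOSOMES = 20

_SYSTEM_ORDER = (SexSystem.XX0, SexSystem.XXY, SexSystem.XXXY)


@dataclass(frozen=True)
class KaryoSimConfig:
    """Rates are events per unit branch length.

    ``fusion_rate_multiplier_at_28`` scales the fusion rate whenever the
    current autosome count is >= 28, letting simulations emulate (or, at
    1.0, break) an association between an extra autosome pair and neo-Y
    origins.
    """

    n_tips: int = 18
    seed: int = 0
    rate_pair_gain: float = 0.06
    rate_pair_loss: float = 0.06
    rate_fusion: float = 0.06
    fusion_rate_multiplier_at_28: float = 1.0
    root_autosomes: int = 26
    birth_rate: float = 1.0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        for name in ("rate_pair_gain", "rate_pair_loss", "rate_fusion",
                     "fusion_rate_multiplier_at_28", "birth_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite nonnegative real")
        if self.root_autosomes % 2 or self.root_autosomes < MIN_AUTOSOMES:
            raise ValueError(
                f"root autosome count must be even and >= {MIN_AUTOSOMES}")


@dataclass(frozen=True)
class Event:
    """One simulated change, recorded on the branch above ``branch``
    (the clade key of the branch's child node)."""

    branch: tuple[str, ...]
    time: float
    kind: str  # pair_gain | pair_loss | fusion1 | fusion2
    autosomes_before: int
    system_before: str
    autosomes_after: int
    system_after: str


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int = 0) -> PhyloTree:
    """Pure-birth tree with ``n_tips`` extant tips labeled ``t1..tn``.

    Standard Yule construction: with k lineages the next split waits an
    Exp(k * birth_rate) time and hits a uniformly chosen lineage; tips
    end contemporaneous (ultrametric).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth_rate > 0):
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.edge.length = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for lineage in active:
            lineage.edge.length += wait
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            split.add_child(child)
            active.append(child)
    final_wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for lineage in active:
        lineage.edge.length += final_wait
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tree.taxon_namespace.new_taxon(f"t{i + 1}")
    return PhyloTree(tree)


def _event_menu(autosomes: int, system: SexSystem,
                config: KaryoSimConfig) -> list[tuple[str, float]]:
    fusion_rate = config.rate_fusion * (
        config.fusion_rate_multiplier_at_28 if autosomes >= 28 else 1.0)
    menu = [("pair_gain", config.rate_pair_gain)]
    if autosomes - 2 >= MIN_AUTOSOMES:
        menu.append(("pair_loss", config.rate_pair_loss))
        if system is SexSystem.XX0:
            menu.append(("fusion1", fusion_rate))
        elif system is SexSystem.XXY:
            menu.append(("fusion2", fusion_rate))
    return [(kind, rate) for kind, rate in menu if rate > 0]


def _apply_event(kind: str, autosomes: int,
                 system: SexSystem) -> tuple[int, SexSystem]:
    if kind == "pair_gain":
        return autosomes + 2, system
    if kind == "pair_loss":
        return autosomes - 2, system
    if kind == "fusion1":
        return autosomes - 2, SexSystem.XXY
    if kind == "fusion2":
        return autosomes - 2, SexSystem.XXXY
    raise ValueError(kind)


def simulate_karyotype_evolution(
        tree: PhyloTree,
        config: KaryoSimConfig) -> tuple[list[KaryotypeRecord], list[Event]]:
    """Gillespie simulation of karyotype evolution along each branch.

    The root starts at ``(root_autosomes, XX0)``; events are pair gains
    (+2), pair losses (-2, blocked below the autosome floor), and the two
    irreversible fusions XX0->XXY and XXY->XXXY (each -2 autosomes).  Tips
    are emitted as all-acrocentric :class:`KaryotypeRecord`s together with
    the complete event log.
    """
    rng = np.random.default_rng(config.seed)
    state = {id(tree.root): (config.root_autosomes, SexSystem.XX0)}
    log: list[Event] = []
    for node in tree.preorder_nodes():
        if node is tree.root:
            continue
        if node.edge.length is None:
            raise ValueError("simulation requires branch lengths on every branch")
        autosomes, system = state[id(node.parent_node)]
        t, length = 0.0, float(node.edge.length)
        branch = clade_key(node)
        while True:
            menu = _event_menu(autosomes, system, config)
            total = sum(rate for _, rate in menu)
            if total == 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > length:
                break
            pick = rng.random() * total
            acc = 0.0
            for kind, rate in menu:
                acc += rate
                if pick <= acc:
                    break
            new_autosomes, new_system = _apply_event(kind, autosomes, system)
            log.append(Event(branch, t, kind, autosomes, system.value,
                             new_autosomes, new_system.value))
            autosomes, system = new_autosomes, new_system
        state[id(node)] = (autosomes, system)
    records = []
    for leaf in tree.leaves():
        autosomes, system = state[id(leaf)]
        records.append(KaryotypeRecord(
            species=leaf.taxon.label,
            diploid_autosomes=autosomes,
            acrocentric_autosomes=autosomes,
            metacentric_autosomes=0,
            sex_system=system,
            y_present=system.has_y,
            n_specimens=1,
            n_full_nuclei=1,
        ))
    return records, log


def events_to_json(events: Sequence[Event]) -> str:
    return json.dumps([asdict(e) | {"branch": list(e.branch)} for e in events],
                      indent=1)


def plant_paralog_branch(tree: PhyloTree, scale: float,
                         seed: int = 0) -> tuple[PhyloTree, tuple[str, ...]]:
    """Multiply one uniformly chosen (non-root) branch by ``scale``;
    returns the modified copy and the chosen branch's clade key."""
    if not (scale > 1):
        raise ValueError("scale must exceed 1")
    rng = np.random.default_rng(seed)
    planted = tree.clone()
    candidates = [n for n in planted.postorder_nodes()
                  if n is not planted.root]
    if any(n.edge.length is None for n in candidates):
        raise ValueError("plant_paralog_branch requires branch lengths")
    chosen = candidates[int(rng.integers(len(candidates)))]
    chosen.edge.length = float(chosen.edge.length) * scale
    return planted, clade_key(chosen)


_BASES = np.array(list("ACGT"))

# Gene-tree branch lengths are redrawn iid Uniform(0.8, 1.2): near-unit
# branches with mild jitter bound the background longest/second-longest
# ratio by 1.5, so a planted branch at scale >= 4 is always the unique
# exceedance and the truth labels are exact.
_BRANCH_LOW, _BRANCH_HIGH = 0.8, 1.2


def generate_locus_set(
        n_loci: int,
        core_taxa: Sequence[str],
        occupancy_dist: float | dict[str, float] = 0.8,
        paralog_fraction: float = 0.0,
        paralog_scale: float = 8.0,
        seed: int = 0,
        alignment_length_range: tuple[int, int] = (200, 800),
) -> tuple[list[LocusRecord], pd.DataFrame]:
    """Loci with random per-taxon presence, Yule gene trees on the
    present taxa, and a planted long-branch paralog in a labeled subset.

    ``occupancy_dist`` is a presence probability, scalar or per taxon.
    Exactly ``round(n_loci * paralog_fraction)`` loci (chosen without
    replacement) receive a planted branch scaled by ``paralog_scale``.
    Returns the loci and a ground-truth table (locus_id, occupancy,
    is_paralog, planted_branch).
    """
    if not 0 <= paralog_fraction <= 1:
        raise ValueError("paralog_fraction must be in [0, 1]")
    core_taxa = list(core_taxa)
    if isinstance(occupancy_dist, dict):
        probs = np.array([occupancy_dist[t] for t in core_taxa])
    else:
        probs = np.full(len(core_taxa), float(occupancy_dist))
    rng = np.random.default_rng(seed)
    n_paralog = round(n_loci * paralog_fraction)
    paralog_ids = set(rng.choice(n_loci, size=n_paralog, replace=False).tolist())
    loci, truth = [], []
    for i in range(n_loci):
        locus_id = f"locus{i:04d}"
        present = [t for t, p in zip(core_taxa, probs) if rng.random() < p]
        length = int(rng.integers(*alignment_length_range))
        gene_tree, planted_branch = None, None
        if len(present) >= 2:
            gene_tree = simulate_yule_tree(
                len(present), seed=int(rng.integers(2 ** 31)))
            _relabel_tips(gene_tree, present)
            _unroot(gene_tree)
            for node in gene_tree.postorder_nodes():
                if node is not gene_tree.root:
                    node.edge.length = float(
                        rng.uniform(_BRANCH_LOW, _BRANCH_HIGH))
            if i in paralog_ids and len(present) >= 3:
                gene_tree, planted_branch = plant_paralog_branch(
                    gene_tree, paralog_scale, seed=int(rng.integers(2 ** 31)))
        loci.append(LocusRecord(locus_id, frozenset(present), length, gene_tree))
        truth.append({
            "locus_id": locus_id,
            "occupancy": len(present),
            "is_paralog": i in paralog_ids and gene_tree is not None,
            "planted_branch": "" if planted_branch is None
                              else "|".join(planted_branch),
        })
    return loci, pd.DataFrame(truth)


def _relabel_tips(tree: PhyloTree, labels: Sequence[str]) -> None:
    for leaf, label in zip(tree.leaves(), labels):
        leaf.taxon.label = label


def _unroot(tree: PhyloTree) -> None:
    """Collapse a basal bifurcation to a trifurcation in place, the way
    single-search ML software writes gene trees.  The merged basal branch
    keeps the summed length; no-op on two-tip trees."""
    root = tree.root
    children = root.child_nodes()
    if len(children) != 2:
        return
    keep, fold = children
    if fold.is_leaf():
        keep, fold = fold, keep
    if fold.is_leaf():
        return
    for grandchild in list(fold.child_nodes()):
        fold.remove_child(grandchild)
        root.add_child(grandchild)
    root.remove_child(fold)
    if keep.edge.length is not None and fold.edge.length is not None:
        keep.edge.length += fold.edge.length


def random_alignment(taxa: Iterable[str], length: int, seed: int = 0) -> dict:
    """IID random DNA sequences, one per taxon (content is irrelevant to
    the QC filters; only presence and length matter)."""
    rng = np.random.default_rng(seed)
    return {t: "".join(rng.choice(_BASES, size=length)) for t in sorted(taxa)}
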