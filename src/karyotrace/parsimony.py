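"""Ancestral-state parsimony on rooted trees.

Implements the Sankoff dynamic program for arbitrary nonnegative cost
matrices with forbidden transitions and an optional root constraint, and
Fitch (unordered, symmetric unit-cost) parsimony as its special case —
which also gives polytomies a single, unambiguous semantics.

Beyond the minimum cost, the engine reports exact MPR (most parsimonious
reconstruction) state sets per node, obtained by combining the subtree
("down-pass") and rest-of-tree ("up-pass") cost vectors: a state belongs
to a node's MPR set iff fixing the node to that state still achieves the
global minimum.  Branches are classified by which ordered state pairs
occur in some (possible) or every (obligate) minimum-cost reconstruction.

A brute-force enumeration oracle over all ancestral labelings is provided
for validation on small instances.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .tree_io import PhyloTree, clade_key

__all__ = [
    "MISSING",
    "FORBIDDEN",
    "CharacterMatrix",
    "CostModel",
    "ReconstructionResult",
    "ParsimonyError",
    "fitch_reconstruct",
    "sankoff_reconstruct",
    "min_transition_count",
    "enumerate_assignments_oracle",
    "OracleResult",
]

#: Sentinel for a taxon with no observation (contributes no cost, no constraint).
MISSING = None

#: Absorbing sentinel for a disallowed transition (not a large finite cost,
#: so forbidden paths can never win by accumulation artifacts).
FORBIDDEN = math.inf

_EPS = 1e-9


class ParsimonyError(ValueError):
    """Invalid character matrix, cost model, or query."""


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxon -> observed state-set mapping for one character.

    ``assignments`` maps each taxon label to a nonempty frozenset of state
    labels (a singleton for a plain observation, larger for polymorphic or
    ambiguous scores) or to :data:`MISSING`.
    """

    character_name: str
    states: tuple[str, ...]
    assignments: Mapping[str, frozenset | None]

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ParsimonyError("duplicate state labels")
        domain = set(self.states)
        norm = {}
        for taxon, obs in self.assignments.items():
            if obs is MISSING:
                norm[taxon] = MISSING
                continue
            obs = frozenset(obs)
            if not obs:
                raise ParsimonyError(f"{taxon}: empty state set (use MISSING)")
            if not obs <= domain:
                raise ParsimonyError(
                    f"{taxon}: states {sorted(obs - domain)} outside domain")
            norm[taxon] = obs
        object.__setattr__(self, "assignments", norm)

    @classmethod
    def from_values(cls, name: str, values: Mapping[str, object],
                    states: Sequence[str] | None = None) -> "CharacterMatrix":
        """Build from per-taxon scalar values (``None`` = missing); the
        state domain defaults to the sorted distinct observed values."""
        assignments = {
            t: (MISSING if v is MISSING else frozenset({str(v)}))
            for t, v in values.items()
        }
        if states is None:
            states = sorted({s for a in assignments.values() if a for s in a})
        return cls(name, tuple(states), assignments)

    @classmethod
    def from_tsv(cls, text: str, name: str = "character") -> "CharacterMatrix":
        """Read rows ``taxon<TAB>state`` where state is a label, a
        ``|``-joined state set, or ``?`` for missing."""
        assignments: dict[str, frozenset | None] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, cell = line.split("\t")
            assignments[taxon] = (
                MISSING if cell.strip() == "?"
                else frozenset(cell.strip().split("|")))
        states = sorted({s for a in assignments.values() if a for s in a})
        return cls(name, tuple(states), assignments)


@dataclass(frozen=True, eq=False)
class CostModel:
    """State list plus transition-cost matrix (``cost[i, j]`` = cost of
    i -> j along a branch; :data:`FORBIDDEN` entries disallow it), with an
    optional hard root-state constraint."""

    states: tuple[str, ...]
    cost: np.ndarray
    root_constraint: str | None = None

    def __post_init__(self):
        cost = np.asarray(self.cost, dtype=float)
        k = len(self.states)
        if cost.shape != (k, k):
            raise ParsimonyError(f"cost matrix must be {k}x{k}")
        if np.any(np.diag(cost) != 0):
            raise ParsimonyError("diagonal costs must be zero")
        if np.any(cost < 0) or np.any(np.isnan(cost)):
            raise ParsimonyError("costs must be nonnegative reals (or FORBIDDEN)")
        if self.root_constraint is not None and \
                self.root_constraint not in self.states:
            raise ParsimonyError(
                f"root constraint {self.root_constraint!r} not a state")
        cost.setflags(write=False)
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "cost", cost)

    @classmethod
    def unit(cls, states: Sequence[str],
             root_constraint: str | None = None) -> "CostModel":
        """Symmetric unit costs (Fitch)."""
        k = len(states)
        return cls(tuple(states), np.ones((k, k)) - np.eye(k), root_constraint)

    @classmethod
    def irreversible(cls, from_state: str, to_state: str,
                     root_at_source: bool = True) -> "CostModel":
        """Two-state directional model: ``from_state -> to_state`` costs 1,
        the reversal is FORBIDDEN; by default the root is pinned to the
        source state (Camin-Sokal-style origin counting)."""
        states = (from_state, to_state)
        cost = np.array([[0.0, 1.0], [FORBIDDEN, 0.0]])
        return cls(states, cost, from_state if root_at_source else None)

    @classmethod
    def from_json(cls, text: str) -> "CostModel":
        doc = json.loads(text)
        cost = np.array(
            [[FORBIDDEN if c == "inf" else float(c) for c in row]
             for row in doc["cost"]])
        return cls(tuple(doc["states"]), cost, doc.get("root"))

    def to_json(self) -> str:
        rows = [["inf" if math.isinf(c) else c for c in row]
                for row in self.cost.tolist()]
        return json.dumps(
            {"states": list(self.states), "cost": rows,
             "root": self.root_constraint})


NodeKey = tuple[str, ...]


@dataclass
class ReconstructionResult:
    """Minimum cost, per-node MPR state sets, and per-branch transition
    classification.  Nodes and branches are keyed by the sorted tuple of
    descendant tip labels (a branch by its child node's key)."""

    character_name: str
    states: tuple[str, ...]
    min_cost: float
    node_mpr: dict[NodeKey, frozenset]
    branch_transitions: dict[NodeKey, dict[tuple[str, str], str]]

    @property
    def is_feasible(self) -> bool:
        return math.isfinite(self.min_cost)

    def obligate_transitions(self) -> list[tuple[NodeKey, str, str]]:
        return [(branch, a, b)
                for branch, pairs in self.branch_transitions.items()
                for (a, b), kind in pairs.items()
                if kind == "obligate" and a != b]


def _tip_vectors(tree: PhyloTree, chars: CharacterMatrix,
                 states: Sequence[str]) -> dict[int, np.ndarray]:
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    vectors = {}
    n_observed = 0
    for leaf in tree.leaves():
        label = leaf.taxon.label
        if label not in chars.assignments:
            raise ParsimonyError(f"tree tip {label!r} absent from character matrix")
        obs = chars.assignments[label]
        vec = np.full(k, FORBIDDEN)
        if obs is MISSING:
            vec[:] = 0.0
        else:
            n_observed += 1
            for s in obs:
                vec[index[s]] = 0.0
        vectors[id(leaf)] = vec
    if n_observed == 0:
        raise ParsimonyError("all tips missing: nothing to reconstruct")
    return vectors


def sankoff_reconstruct(tree: PhyloTree, chars: CharacterMatrix,
                        model: CostModel) -> ReconstructionResult:
    """Sankoff dynamic-programming reconstruction under ``model``.

    An infeasible model (no finite-cost labeling compatible with the tips)
    yields a result with ``min_cost == inf`` and empty MPR sets rather
    than an exception.
    """
    if not set(chars.states) <= set(model.states):
        raise ParsimonyError("character states outside cost-model domain")
    states = model.states
    k = len(states)
    cost = model.cost

    # down-pass: S[v][s] = min cost of v's subtree with v fixed to s
    S = _tip_vectors(tree, chars, states)
    M: dict[tuple[int, int], np.ndarray] = {}  # per (parent, child) message
    for node in tree.postorder_nodes():
        if node.is_leaf():
            continue
        total = np.zeros(k)
        for child in node.child_nodes():
            msg = np.min(cost + S[id(child)][np.newaxis, :], axis=1)
            M[(id(node), id(child))] = msg
            total = total + msg
        S[id(node)] = total

    root = tree.root
    root_pen = np.zeros(k)
    if model.root_constraint is not None:
        root_pen = np.full(k, FORBIDDEN)
        root_pen[states.index(model.root_constraint)] = 0.0
    min_cost = float(np.min(S[id(root)] + root_pen))
    if not math.isfinite(min_cost):
        return ReconstructionResult(chars.character_name, states,
                                    FORBIDDEN, {}, {})

    # up-pass: U[v][s] = min cost of everything outside v's subtree,
    # given v fixed to s (including the root penalty)
    U: dict[int, np.ndarray] = {id(root): root_pen}
    for node in tree.preorder_nodes():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            rest = U[id(node)].copy()
            for other in children:
                if other is not child:
                    rest = rest + M[(id(node), id(other))]
            U[id(child)] = np.min(rest[:, np.newaxis] + cost, axis=0)

    node_mpr: dict[NodeKey, frozenset] = {}
    branch_transitions: dict[NodeKey, dict[tuple[str, str], str]] = {}
    for node in tree.postorder_nodes():
        total = S[id(node)] + U[id(node)]
        node_mpr[clade_key(node)] = frozenset(
            states[i] for i in range(k) if total[i] <= min_cost + _EPS)
    for node in tree.preorder_nodes():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            rest = U[id(node)].copy()
            for other in children:
                if other is not child:
                    rest = rest + M[(id(node), id(other))]
            # B[t, s] = best total cost with parent=t and child=s
            B = rest[:, np.newaxis] + cost + S[id(child)][np.newaxis, :]
            achieving = list(zip(*np.where(B <= min_cost + _EPS)))
            pairs: dict[tuple[str, str], str] = {}
            for ti, si in achieving:
                pair = (states[ti], states[si])
                pairs[pair] = "obligate" if len(achieving) == 1 else "possible"
            branch_transitions[clade_key(child)] = pairs
    return ReconstructionResult(chars.character_name, states, min_cost,
                                node_mpr, branch_transitions)


def fitch_reconstruct(tree: PhyloTree,
                      chars: CharacterMatrix) -> ReconstructionResult:
    """Unordered symmetric unit-cost parsimony (Fitch), including on
    polytomies, implemented as unit-cost Sankoff."""
    if not chars.states:
        raise ParsimonyError("character has no states")
    return sankoff_reconstruct(tree, chars, CostModel.unit(chars.states))


def min_transition_count(result: ReconstructionResult, from_state: str,
                         to_state: str) -> int:
    """Number of branches on which ``from_state -> to_state`` is obligate
    (occurs in every minimum-cost reconstruction).  Under a directional
    unit-cost model this equals the model's minimum cost."""
    for s in (from_state, to_state):
        if s not in result.states:
            raise ParsimonyError(f"unknown state {s!r}")
    if not result.is_feasible:
        raise ParsimonyError("reconstruction is infeasible")
    return sum(
        1 for pairs in result.branch_transitions.values()
        if pairs.get((from_state, to_state)) == "obligate")


@dataclass
class OracleResult:
    min_cost: float
    assignments: list[dict[NodeKey, str]]
    node_mpr: dict[NodeKey, frozenset]


def enumerate_assignments_oracle(tree: PhyloTree, chars: CharacterMatrix,
                                 model: CostModel,
                                 guard: int = 10 ** 6) -> OracleResult:
    """Exhaustive ground truth: enumerate every ancestral labeling, score
    it, and collect all minimum-cost reconstructions.

    Intended for validation on small instances; refuses to enumerate more
    than ``guard`` labelings (use the dynamic program instead).
    """
    states = model.states
    k = len(states)
    nodes = list(tree.postorder_nodes())
    internal = [n for n in nodes if not n.is_leaf()]
    if k ** len(internal) > guard:
        raise ParsimonyError(
            f"{k}^{len(internal)} labelings exceed the oracle guard ({guard}); "
            "use sankoff_reconstruct")
    tip_vec = _tip_vectors(tree, chars, states)
    index = {id(n): i for i, n in enumerate(internal)}
    combos = np.array(list(itertools.product(range(k), repeat=len(internal))),
                      dtype=np.int64).reshape(-1, len(internal))
    total = np.zeros(len(combos))
    if model.root_constraint is not None:
        pen = np.full(k, FORBIDDEN)
        pen[states.index(model.root_constraint)] = 0.0
        total += pen[combos[:, index[id(tree.root)]]]
    # tip contribution: cheapest allowed tip state given the parent's state
    tip_cost = {}  # id(leaf) -> per-parent-state vector
    for node in nodes:
        if node.parent_node is None:
            continue
        p = combos[:, index[id(node.parent_node)]]
        if node.is_leaf():
            vec = np.min(model.cost + tip_vec[id(node)][np.newaxis, :], axis=1)
            tip_cost[id(node)] = vec
            total += vec[p]
        else:
            total += model.cost[p, combos[:, index[id(node)]]]
    min_cost = float(np.min(total))
    if not math.isfinite(min_cost):
        return OracleResult(FORBIDDEN, [], {})
    hits = combos[total <= min_cost + _EPS]
    assignments = [
        {clade_key(n): states[row[index[id(n)]]] for n in internal}
        for row in hits]
    node_mpr: dict[NodeKey, set] = {clade_key(n): set() for n in nodes}
    for row in hits:
        for n in internal:
            node_mpr[clade_key(n)].add(states[row[index[id(n)]]])
        for n in nodes:
            if n.is_leaf() and n.parent_node is not None:
                p = row[index[id(n.parent_node)]]
                vec = model.cost[p, :] + tip_vec[id(n)]
                best = vec.min()
                node_mpr[clade_key(n)].update(
                    states[i] for i in range(k) if vec[i] <= best + _EPS)
    return OracleResult(min_cost, assignments,
                        {key: frozenset(v) for key, v in node_mpr.items()})
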