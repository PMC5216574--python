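"""Intron gain/loss reconstruction on a rooted species tree.

Binary presence/absence characters (one per intron positional-homology
group) are mapped onto a rooted cladogram and ancestral states are
inferred by two small-parsimony criteria:

* **Fitch parsimony** — unconstrained minimum number of state changes
  (implemented as unit-cost Sankoff, which also counts co-optimal
  labelings);
* **Dollo parsimony** — at most one gain per character: the gain is
  placed on the branch above the most recent common ancestor of the
  present tips, and losses on the minimal set of branches covering the
  absent descendants.

Tips whose state is unknown (e.g. species whose 5' gene structure cannot
be resolved from the available annotation) are pruned per character
rather than imputed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

PRESENT, ABSENT, UNKNOWN = 1, 0, -1

_STATE_NAMES = {PRESENT: "present", ABSENT: "absent", UNKNOWN: "unknown"}


class PhyloError(ValueError):
    pass


def load_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Read a rooted Newick tree (path, Newick string or dendropy Tree)."""
    if isinstance(source, dendropy.Tree):
        return source
    else:
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    tree.is_rooted = True
    return tree


def _branch_label(node: dendropy.Node) -> str:
    """Stable branch identifier: the clade below the branch.

    Uses the taxon/internal label when present, otherwise a canonical
    ``clade(<smallest-leaf>+<n>)`` signature that is invariant under tip
    reordering.
    """
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter() if lf.taxon)
    return f"clade({leaves[0]}+{len(leaves)})"


@dataclass
class PresenceAbsenceMatrix:
    """Species × character matrix with entries present/absent/unknown."""

    data: pd.DataFrame  # int entries in {1, 0, -1}

    def __post_init__(self):
        bad = set(self.data.values.ravel()) - {PRESENT, ABSENT, UNKNOWN}
        if bad:
            raise PhyloError(f"invalid matrix entries: {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def states(self, character: str) -> dict[str, int]:
        return self.data[character].to_dict()

    def validate_against(self, tree: dendropy.Tree) -> None:
        tips = {t.label for t in tree.taxon_namespace}
        missing = sorted(set(self.data.index) - tips)
        if missing:
            raise PhyloError(f"species absent from tree: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


def build_presence_matrix(
    groups: Iterable,
    species: Iterable[str],
    unknown_flags: Mapping[str, object] | None = None,
) -> PresenceAbsenceMatrix:
    """Characters from intron homology groups: present iff the species
    contributes an intron to the group.

    ``unknown_flags`` maps a species either to ``True`` (all characters
    unknown) or to an iterable of character/group ids that are unknown for
    that species.
    """
    species = list(species)
    unknown_flags = unknown_flags or {}
    data = {}
    for g in groups:
        members = {m.species_id for m in g.members}
        col = []
        for s in species:
            flag = unknown_flags.get(s)
            if flag is True or (flag and g.group_id in flag):
                col.append(UNKNOWN)
            else:
                col.append(PRESENT if s in members else ABSENT)
        data[g.group_id] = col
    df = pd.DataFrame(data, index=species, dtype=int)
    return PresenceAbsenceMatrix(df)


@dataclass(frozen=True)
class Event:
    character: str
    branch: str  # identified by the node below the branch
    kind: str  # "gain" | "loss"


@dataclass
class CharacterReconstruction:
    character: str
    min_changes: int
    events: list[Event]
    node_states: dict[str, int]  # branch label -> state (pruned tips omitted)
    n_optimal_labelings: int = 1

    @property
    def n_gains(self) -> int:
        return sum(e.kind == "gain" for e in self.events)

    @property
    def n_losses(self) -> int:
        return sum(e.kind == "loss" for e in self.events)


@dataclass
class EventReconstruction:
    method: str  # "fitch" | "dollo"
    characters: dict[str, CharacterReconstruction] = field(default_factory=dict)

    @property
    def total_changes(self) -> int:
        return sum(c.min_changes for c in self.characters.values())

    def events_table(self) -> pd.DataFrame:
        rows = [
            {"character": e.character, "branch": e.branch, "event": e.kind}
            for c in self.characters.values()
            for e in c.events
        ]
        return pd.DataFrame(rows, columns=["character", "branch", "event"])


def _require_rooted(tree: dendropy.Tree) -> None:
    if not tree.is_rooted:
        raise PhyloError("rooting required: tree is unrooted")


def _known_leaf_states(tree, states: Mapping[str, int]) -> dict:
    out = {}
    for leaf in tree.leaf_node_iter():
        s = states.get(leaf.taxon.label, UNKNOWN)
        if s != UNKNOWN:
            out[leaf] = s
    return out


INF = float("inf")


def fitch_parsimony(
    tree: dendropy.Tree | str | Path, matrix: PresenceAbsenceMatrix
) -> EventReconstruction:
    """Minimum-change ancestral states for every character.

    Ties are broken deterministically: the root prefers "absent", and each
    descendant node prefers its parent's state.  The number of equally
    parsimonious labelings is counted exactly alongside.
    """
    tree = load_tree(tree)
    _require_rooted(tree)
    matrix.validate_against(tree)
    recon = EventReconstruction(method="fitch")
    for char in matrix.characters:
        recon.characters[char] = _fitch_one(tree, char, matrix.states(char))
    return recon


def _fitch_one(tree, char: str, states: Mapping[str, int]) -> CharacterReconstruction:
    known = _known_leaf_states(tree, states)
    if not known:
        return CharacterReconstruction(char, 0, [], {}, 1)

    cost: dict = {}
    count: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if node in known:
                s = known[node]
                cost[node] = {s: 0, 1 - s: INF}
                count[node] = {s: 1, 1 - s: 0}
            else:
                cost[node] = {0: 0, 1: 0}  # uninformative: pruned
                count[node] = {0: 1, 1: 1}
            continue
        c = {0: 0, 1: 0}
        n = {0: 1, 1: 1}
        for child in node.child_nodes():
            for s in (0, 1):
                opts = {t: cost[child][t] + (s != t) for t in (0, 1)}
                best = min(opts.values())
                c[s] += best
                n[s] *= sum(
                    count[child][t] for t in (0, 1) if opts[t] == best
                )
        cost[node] = c
        count[node] = n

    root = tree.seed_node
    min_changes = min(cost[root].values())
    if min_changes == INF:  # no known tips at all
        min_changes = 0
    n_opt = sum(count[root][s] for s in (0, 1) if cost[root][s] == min_changes)

    # deterministic labeling: prefer absent at root, parent's state below
    labels: dict = {}
    events: list[Event] = []
    order = [s for s in (ABSENT, PRESENT) if cost[root][s] == min_changes]
    labels[root] = order[0]
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.is_leaf() and node not in known:
            continue  # pruned tip: no state assigned
        parent_state = labels[node.parent_node]
        opts = {t: cost[node][t] + (t != parent_state) for t in (0, 1)}
        best = min(opts.values())
        if opts[parent_state] == best:
            state = parent_state
        else:
            state = ABSENT if opts[ABSENT] == best else PRESENT
        labels[node] = state
        if state != parent_state:
            kind = "gain" if state == PRESENT else "loss"
            events.append(Event(char, _branch_label(node), kind))

    node_states = {_branch_label(n): s for n, s in labels.items()}
    return CharacterReconstruction(
        character=char,
        min_changes=int(min_changes),
        events=events,
        node_states=node_states,
        n_optimal_labelings=int(n_opt),
    )


def dollo_parsimony(
    tree: dendropy.Tree | str | Path, matrix: PresenceAbsenceMatrix
) -> EventReconstruction:
    """Single-gain reconstruction for every character.

    The gain sits on the branch above the MRCA of the present tips (the
    root stem when the character is present across the whole tree; such a
    root-stem gain is reported as an event but contributes no state-change
    edge to ``min_changes``).  Losses are placed on the minimal set of
    branches whose subtrees contain only absent (or unknown) tips, with at
    least one known absent tip each.
    """
    tree = load_tree(tree)
    _require_rooted(tree)
    matrix.validate_against(tree)
    recon = EventReconstruction(method="dollo")
    for char in matrix.characters:
        recon.characters[char] = _dollo_one(tree, char, matrix.states(char))
    return recon


def _dollo_one(tree, char: str, states: Mapping[str, int]) -> CharacterReconstruction:
    known = _known_leaf_states(tree, states)
    present_leaves = [lf for lf, s in known.items() if s == PRESENT]

    if not present_leaves:
        warnings.warn(f"vacuous character {char}: no present tips", stacklevel=3)
        node_states = {
            _branch_label(n): ABSENT
            for n in tree.preorder_node_iter()
            if not (n.is_leaf() and n not in known)
        }
        return CharacterReconstruction(char, 0, [], node_states)

    if len(present_leaves) == 1:
        gain_node = present_leaves[0]
    else:
        gain_node = tree.mrca(taxa=[lf.taxon for lf in present_leaves])

    # per-node: does the subtree contain any known present / known absent tip?
    has_present: dict = {}
    has_absent: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_present[node] = known.get(node) == PRESENT
            has_absent[node] = known.get(node) == ABSENT
        else:
            kids = node.child_nodes()
            has_present[node] = any(has_present[k] for k in kids)
            has_absent[node] = any(has_absent[k] for k in kids)

    events = [Event(char, _branch_label(gain_node), "gain")]
    labels: dict = {}
    stack = [(gain_node, PRESENT)]
    while stack:
        node, state = stack.pop()
        if state == PRESENT and not has_present[node] and has_absent[node]:
            events.append(Event(char, _branch_label(node), "loss"))
            state = ABSENT
        labels[node] = state
        for child in node.child_nodes():
            stack.append((child, state))

    # everything outside the gained clade is ancestrally absent
    for node in tree.preorder_node_iter():
        if node not in labels:
            labels[node] = ABSENT

    n_losses = sum(e.kind == "loss" for e in events)
    gain_edges = 0 if gain_node is tree.seed_node else 1
    node_states = {
        _branch_label(n): s
        for n, s in labels.items()
        if not (n.is_leaf() and n not in known)
    }
    return CharacterReconstruction(
        character=char,
        min_changes=n_losses + gain_edges,
        events=events,
        node_states=node_states,
    )
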