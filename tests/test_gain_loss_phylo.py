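"""Fitch/Dollo reconstruction against exhaustive-enumeration oracles."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from intronarch.gain_loss_phylo import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    PhyloError,
    PresenceAbsenceMatrix,
    build_presence_matrix,
    dollo_parsimony,
    fitch_parsimony,
    load_tree,
)
from intronarch.synthetic_data import species_tree

SIX_LEAF_TREES = [
    "((a,b),((c,d),(e,f)));",
    "(((a,b),c),((d,e),f));",
    "((((a,b),c),d),(e,f));",
    "(((((a,b),c),d),e),f);",
]
LEAVES = list("abcdef")


def _matrix(states: dict, char="c1"):
    return PresenceAbsenceMatrix(pd.DataFrame({char: states}).astype(int))


def _exhaustive(newick, states, dollo=False):
    """Enumerate all internal labelings (unknown tips free); return the
    minimal number of state-change edges, and how many labelings achieve
    it.  Under the Dollo constraint at most one origin is allowed (a
    present root counts as the origin)."""
    tree = load_tree(newick)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    free = [
        n
        for n in tree.leaf_node_iter()
        if states.get(n.taxon.label, UNKNOWN) == UNKNOWN
    ]
    nodes = internals + free
    best, count = None, 0
    for assign in itertools.product((0, 1), repeat=len(nodes)):
        lab = dict(zip(nodes, assign))
        for leaf in tree.leaf_node_iter():
            lab.setdefault(leaf, states[leaf.taxon.label])
        changes = gains = 0
        for n in tree.preorder_node_iter():
            if n.parent_node and lab[n] != lab[n.parent_node]:
                changes += 1
                if lab[n] == 1:
                    gains += 1
        origins = gains + (1 if lab[tree.seed_node] == 1 else 0)
        if dollo and origins > 1:
            continue
        if best is None or changes < best:
            best, count = changes, 1
        elif changes == best:
            count += 1
    return best, count


def _random_characters(n, rng):
    for _ in range(n):
        newick = SIX_LEAF_TREES[rng.integers(0, len(SIX_LEAF_TREES))]
        states = {lf: int(rng.integers(0, 2)) for lf in LEAVES}
        yield newick, states


def test_fitch_equals_exhaustive_oracle_on_200_random_characters():
    rng = np.random.default_rng(42)
    for newick, states in _random_characters(200, rng):
        recon = fitch_parsimony(newick, _matrix(states)).characters["c1"]
        want, n_opt = _exhaustive(newick, states)
        assert recon.min_changes == want
        assert recon.n_optimal_labelings == n_opt
        assert len(recon.events) == want  # the reported labeling is optimal


def test_dollo_equals_constrained_exhaustive_oracle():
    rng = np.random.default_rng(43)
    for newick, states in _random_characters(200, rng):
        if not any(states.values()):
            continue
        recon = dollo_parsimony(newick, _matrix(states)).characters["c1"]
        want, _ = _exhaustive(newick, states, dollo=True)
        assert recon.min_changes == want


def test_fitch_never_exceeds_dollo():
    rng = np.random.default_rng(44)
    for newick, states in _random_characters(100, rng):
        if not any(states.values()):
            continue
        f = fitch_parsimony(newick, _matrix(states)).characters["c1"]
        d = dollo_parsimony(newick, _matrix(states)).characters["c1"]
        assert f.min_changes <= d.min_changes


def test_unknown_tips_are_pruned_not_imputed():
    rng = np.random.default_rng(45)
    for newick, states in _random_characters(50, rng):
        states["c"] = UNKNOWN
        recon = fitch_parsimony(newick, _matrix(states)).characters["c1"]
        want, _ = _exhaustive(newick, states)
        assert recon.min_changes == want


def test_all_present_character_has_no_changes():
    states = {lf: PRESENT for lf in LEAVES}
    f = fitch_parsimony(SIX_LEAF_TREES[0], _matrix(states)).characters["c1"]
    assert f.min_changes == 0 and f.events == []
    d = dollo_parsimony(SIX_LEAF_TREES[0], _matrix(states)).characters["c1"]
    assert d.min_changes == 0 and d.n_losses == 0
    # origin reported on the root stem
    assert d.events[0].kind == "gain"


def test_single_present_tip_is_one_terminal_gain():
    states = {lf: ABSENT for lf in LEAVES}
    states["d"] = PRESENT
    for recon in (
        fitch_parsimony(SIX_LEAF_TREES[0], _matrix(states)),
        dollo_parsimony(SIX_LEAF_TREES[0], _matrix(states)),
    ):
        c = recon.characters["c1"]
        assert c.min_changes == 1
        assert [(e.branch, e.kind) for e in c.events if e.kind == "gain"] == [
            ("d", "gain")
        ]


def test_vacuous_character_warns_with_zero_events():
    states = {lf: ABSENT for lf in LEAVES}
    with pytest.warns(UserWarning, match="vacuous"):
        d = dollo_parsimony(SIX_LEAF_TREES[0], _matrix(states)).characters["c1"]
    assert d.min_changes == 0 and d.events == []


def test_unrooted_tree_rejected():
    tree = load_tree(SIX_LEAF_TREES[0])
    tree.is_rooted = False
    with pytest.raises(PhyloError, match="rooting required"):
        fitch_parsimony(tree, _matrix({lf: PRESENT for lf in LEAVES}))


def test_species_missing_from_tree_rejected():
    m = _matrix({**{lf: PRESENT for lf in LEAVES}, "zz": PRESENT})
    with pytest.raises(PhyloError, match="zz"):
        fitch_parsimony(SIX_LEAF_TREES[0], m)


# ---------------------------------------------------------------------------
# the packaged metazoan tree
# ---------------------------------------------------------------------------

ECDYSOZOANS = ["Ce", "Cr", "Dm", "Tc", "Dpu", "Is"]


def test_ecdysozoan_character_gains_on_ecdysozoan_stem():
    """A character present only in nematode + arthropod tips places its
    single Dollo gain on the ecdysozoan stem branch, with no losses."""
    tree = species_tree()
    tips = [t.label for t in tree.taxon_namespace]
    states = {t: PRESENT if t in ECDYSOZOANS else ABSENT for t in tips}
    d = dollo_parsimony(tree, _matrix(states)).characters["c1"]
    assert [(e.branch, e.kind) for e in d.events] == [("Ecdysozoa", "gain")]
    assert d.min_changes == 1


def test_universal_character_is_ancestral_on_packaged_tree():
    tree = species_tree()
    states = {t.label: PRESENT for t in tree.taxon_namespace}
    d = dollo_parsimony(tree, _matrix(states)).characters["c1"]
    assert d.events == [type(d.events[0])("c1", "Metazoa", "gain")]
    assert d.min_changes == 0
    f = fitch_parsimony(tree, _matrix(states)).characters["c1"]
    assert f.min_changes == 0


def test_reconstruction_invariant_under_tip_reordering():
    """Rotating clades in the Newick leaves events and counts unchanged."""
    a = "((a,b)X,((c,d)Y,(e,f)Z)W);"
    b = "(((f,e)Z,(d,c)Y)W,(b,a)X);"
    states = {"a": 1, "b": 0, "c": 1, "d": 1, "e": 0, "f": 0}
    for method in (fitch_parsimony, dollo_parsimony):
        ra = method(a, _matrix(states)).characters["c1"]
        rb = method(b, _matrix(states)).characters["c1"]
        assert ra.min_changes == rb.min_changes
        assert {(e.branch, e.kind) for e in ra.events} == {
            (e.branch, e.kind) for e in rb.events
        }


# ---------------------------------------------------------------------------
# presence matrix construction
# ---------------------------------------------------------------------------


class _G:
    def __init__(self, gid, species):
        self.group_id = gid
        self.members = [type("M", (), {"species_id": s})() for s in species]


def test_build_presence_matrix_matches_membership_oracle():
    rng = np.random.default_rng(3)
    species = [f"s{i}" for i in range(12)]
    groups = []
    for g in range(6):
        members = [s for s in species if rng.random() < 0.5]
        groups.append(_G(f"g{g}", members))
    m = build_presence_matrix(groups, species)
    for g in groups:
        members = {x.species_id for x in g.members}
        for s in species:
            assert m.data.loc[s, g.group_id] == (PRESENT if s in members else ABSENT)


def test_build_presence_matrix_unknown_flags():
    groups = [_G("g1", ["a", "b"]), _G("g2", ["a"])]
    m = build_presence_matrix(
        groups, ["a", "b", "c"], unknown_flags={"c": True, "b": ["g2"]}
    )
    assert m.data.loc["c", "g1"] == UNKNOWN and m.data.loc["c", "g2"] == UNKNOWN
    assert m.data.loc["b", "g2"] == UNKNOWN and m.data.loc["b", "g1"] == PRESENT


def test_empty_group_list_gives_zero_characters():
    m = build_presence_matrix([], ["a", "b"])
    assert m.data.shape == (2, 0)
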