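"""Intron phase/protein mapping, domain register, MSA projection, clustering."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from intronarch.intron_protein_mapping import (
    DomainAnnotation,
    MappingError,
    ProjectedIntron,
    cds_introns,
    cluster_homologous_introns,
    domain_register,
    intron_cds_position,
    project_to_alignment,
    read_domains,
)
from intronarch.synthetic_data import build_anchor_msa, packaged_domain_table


def test_human_first_cds_intron_between_95_and_96(parsed_fixtures):
    """The 116-nt 5'UTR offset puts the insertion between residues 95/96,
    phase 0."""
    model, _, _ = parsed_fixtures["Hs"]
    rec = cds_introns(model)[0]
    assert (rec.residue_before, rec.residue_after) == (95, 96)
    assert rec.phase == 0 and not rec.codon_split


def test_phase_and_residues_match_translation_oracle(parsed_fixtures):
    """Brute-force oracle: translate the CDS prefix 5' of each intron and
    compare residue counts and phase."""
    for code in ("Hs", "Ci", "Ce", "Dm", "Gm2", "Tr2", "Aq"):
        model, _, _ = parsed_fixtures[code]
        cds = model.cds_sequence()
        protein = str(Seq(cds).translate())
        for rec in cds_introns(model):
            assert rec.phase == rec.cds_offset % 3
            # residues fully encoded 5' of the intron
            prefix = cds[: rec.cds_offset - rec.phase]
            assert len(prefix) % 3 == 0
            n_res = len(str(Seq(prefix).translate()))
            assert rec.residue_before == n_res
            assert rec.residue_after == n_res + 1
            assert protein.startswith(str(Seq(prefix).translate()))


def test_utr_intron_is_not_a_cds_intron(parsed_fixtures):
    model, _, _ = parsed_fixtures["Hs"]  # intron 0 separates pre-ATG exon
    with pytest.raises(MappingError, match="not a CDS intron"):
        intron_cds_position(model, 0)
    with pytest.raises(MappingError, match="out of range"):
        intron_cds_position(model, 99)


# ---------------------------------------------------------------------------
# domain register
# ---------------------------------------------------------------------------


def _fake_intron(residue_before):
    from intronarch.intron_protein_mapping import IntronRecord

    return IntronRecord(
        species_id="x",
        gene_id="x",
        intron_index=1,
        genomic_span=(0, 10),
        length=10,
        cds_offset=residue_before * 3,
        phase=0,
        residue_before=residue_before,
        residue_after=residue_before + 1,
        codon_split=False,
    )


def test_human_insertion_within_ig1_mid_strand(parsed_fixtures):
    """The 95/96 site falls inside IG1 (and mid third beta-strand), away
    from domain boundaries."""
    model, _, _ = parsed_fixtures["Hs"]
    rec = cds_introns(model)[0]
    table = read_domains(packaged_domain_table(), "Hs_DG")
    domain_level = [d for d in table if not d.feature.startswith("beta")]
    call = domain_register(rec, domain_level, boundary_tolerance=2)
    assert (call.kind, call.feature) == ("within", "IG1")
    strands = [d for d in table if d.feature.startswith("beta")]
    assert domain_register(rec, strands).feature == "beta3"


def test_insertion_at_domain_start_is_boundary():
    dom = [DomainAnnotation("p", "D", 10, 40)]
    call = domain_register(_fake_intron(9), dom, boundary_tolerance=0)
    assert call.kind == "at_boundary" and call.feature == "D"


def test_register_matches_interval_scan_oracle():
    """1000 random insertions against an exhaustive interval scan."""
    rng = np.random.default_rng(7)
    domains = [
        DomainAnnotation("p", "A", 10, 50),
        DomainAnnotation("p", "B", 60, 90),
        DomainAnnotation("p", "C", 95, 200),
    ]
    tol = 2
    for _ in range(1000):
        rb = int(rng.integers(0, 210))
        call = domain_register(_fake_intron(rb), domains, boundary_tolerance=tol)
        p = rb + 0.5
        near = [
            d
            for d in domains
            if min(abs(p - (d.start - 0.5)), abs(p - (d.end + 0.5))) <= tol
        ]
        inside = [d for d in domains if d.start - 0.5 < p < d.end + 0.5]
        if near:
            want = ("at_boundary", min(near, key=lambda d: d.end - d.start).feature)
        elif inside:
            want = ("within", min(inside, key=lambda d: d.end - d.start).feature)
        else:
            want = ("inter_domain", None)
        assert (call.kind, call.feature) == want, rb


def test_empty_domain_table_rejected():
    with pytest.raises(MappingError, match="no annotation"):
        domain_register(_fake_intron(5), [])


# ---------------------------------------------------------------------------
# MSA projection
# ---------------------------------------------------------------------------


def _msa(tmp_path, rows):
    p = tmp_path / "m.fa"
    p.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
    return p


def test_projection_examples(tmp_path):
    p = _msa(tmp_path, {"a": "MKVLWA", "b": "MK--VL"})
    assert project_to_alignment(p, "a", 3) == 3  # gapless row
    assert project_to_alignment(p, "b", 3) == 5  # "MK--VL", residue 3 = V
    with pytest.raises(MappingError, match="out of range"):
        project_to_alignment(p, "b", 5)
    with pytest.raises(MappingError, match="absent"):
        project_to_alignment(p, "zz", 1)


@given(st.text(alphabet="MKVA-", min_size=3, max_size=40))
def test_projection_is_monotone(row):
    ungapped = sum(c != "-" for c in row)
    if ungapped < 2:
        return
    msa = {"r": row}
    cols = [project_to_alignment_dict(msa, i) for i in range(1, ungapped + 1)]
    assert cols == sorted(cols) and len(set(cols)) == len(cols)


def project_to_alignment_dict(rows, residue):
    # adapter: feed a dict through the Bio.AlignIO-free path
    class _Rec:
        def __init__(self, i, s):
            self.id, self.seq = i, s

    return project_to_alignment([_Rec(k, v) for k, v in rows.items()], "r", residue)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _proj(sid, col):
    return ProjectedIntron(species_id=sid, intron=None, column=col)


def test_two_distant_introns_form_two_groups():
    groups = cluster_homologous_introns([_proj("a", 10), _proj("b", 20)], 2)
    assert len(groups) == 2
    assert [g.group_id for g in groups] == ["g10", "g20"]


def test_incompatible_msas_rejected():
    p1 = ProjectedIntron("a", None, 5, msa_id="m1")
    p2 = ProjectedIntron("b", None, 6, msa_id="m2")
    with pytest.raises(MappingError, match="incompatible"):
        cluster_homologous_introns([p1, p2])


@given(
    st.lists(st.integers(min_value=0, max_value=120), min_size=1, max_size=25),
    st.integers(min_value=0, max_value=5),
)
def test_clustering_matches_graph_component_oracle(cols, tol):
    """Single-linkage groups equal connected components of the
    |ci - cj| <= tol graph, and are permutation-invariant."""
    import networkx as g

    projs = [_proj(f"s{i}", c) for i, c in enumerate(cols)]
    groups = cluster_homologous_introns(projs, tol)
    # each intron in exactly one group
    seen = sorted(m.species_id for grp in groups for m in grp.members)
    assert seen == sorted(p.species_id for p in projs)
    graph = g.Graph()
    graph.add_nodes_from(range(len(cols)))
    for i, j in itertools.combinations(range(len(cols)), 2):
        if abs(cols[i] - cols[j]) <= tol:
            graph.add_edge(i, j)
    oracle = {
        frozenset(f"s{i}" for i in comp) for comp in g.connected_components(graph)
    }
    ours = {frozenset(m.species_id for m in grp.members) for grp in groups}
    assert ours == oracle
    # permutation invariance
    rng = np.random.default_rng(0)
    shuffled = [projs[i] for i in rng.permutation(len(projs))]
    again = cluster_homologous_introns(shuffled, tol)
    assert {frozenset(m.species_id for m in grp.members) for grp in again} == ours
    assert [grp.group_id for grp in again] == [grp.group_id for grp in groups]


def test_all_first_introns_cluster_into_one_group(parsed_fixtures, tmp_path):
    """Anchor-aligned proteins project every recorded first-intron site
    into a single positional-homology group across all species."""
    proteins = {}
    for code, (model, arch, fp) in parsed_fixtures.items():
        recs = cds_introns(model)
        anchor = recs[fp.realized.printed_ig1_ordinal]
        protein = str(Seq(model.cds_sequence()).translate()).rstrip("*")
        if anchor.residue_before < 1:
            continue
        proteins[code] = (protein, anchor.residue_before)
    msa = build_anchor_msa(proteins, tmp_path / "anchor.fa")
    projs = [
        ProjectedIntron(code, None, project_to_alignment(msa, code, res))
        for code, (_, res) in proteins.items()
    ]
    groups = cluster_homologous_introns(projs, 2)
    assert len(groups) == 1
    assert len(groups[0].members) == len(proteins) >= 35
    assert groups[0].column_spread == 0
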