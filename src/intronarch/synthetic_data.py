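"""Synthetic genomes, gene models and evolutionary histories with known truth.

Three generators live here:

* :func:`build_fixture_models` realises the packaged machine-readable
  transcription of the 39 dystroglycan gene records (35 species plus 4
  paralogues) as per-species genome FASTA + GFF3 files whose extracted
  architectures reproduce the recorded element lengths exactly.  Filler
  sequence is seeded-random at GC 0.5; coding sequence is built from
  non-stop codons so the gene translates cleanly; introns carry canonical
  GT..AG ends unless a violation rate is requested.
* :func:`simulate_gene_evolution` evolves intron presence along a rooted
  tree (Poisson gains at uniform coding positions, per-branch losses) and
  returns the true event log and presence/absence matrix against which a
  reconstruction can be scored.
* :func:`simulate_intron_sizes` draws intron sizes from a semi-log model
  ``size = intercept + slope * log10(genome size) + noise`` floored at
  30 bp (just below the smallest observed intron).

Conventions the records cannot pin down are fixed here once: 5'UTR
offsets inside ATG exons default to 0 (human: 116 nt, the offset implied
by a phase-0 insertion between residues 95 and 96 inside a 401-bp ATG
exon), 3'UTR lengths and the individual sizes of exon pieces summed in
the combined columns are deterministic functions of the seed.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .gain_loss_phylo import (
    ABSENT,
    PRESENT,
    PresenceAbsenceMatrix,
    _branch_label,
    load_tree,
)
from .gene_models import _revcomp
from .scaling_analysis import SizeRecord
from .splice_boundaries import BoundaryWindow

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]
_NON_GT = [d for d in ("".join(p) for p in itertools.product("ACGT", repeat=2)) if d != "GT"]
_NON_AG = [d for d in ("".join(p) for p in itertools.product("ACGT", repeat=2)) if d != "AG"]

HUMAN_UTR5_OFFSET = 116  # nt of 5'UTR inside the human ATG exon
MIN_INTRON_SIZE_FLOOR = 30

_DATA = importlib.resources.files("intronarch") / "data"


def _species_seed(seed: int, code: str) -> int:
    h = hashlib.sha256(f"{seed}:{code}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_coding(rng: np.random.Generator, n_codons: int, first: str, last: str = "TAA") -> str:
    body = [
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=max(n_codons - 2, 0))
    ]
    return first + "".join(body) + (last if n_codons >= 2 else "")


# ---------------------------------------------------------------------------
# Packaged table records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureRecord:
    """One recorded gene: printed element lengths + interpretation metadata."""

    code: str
    species: str
    group: str
    clade: str
    table: int
    tree_tip: str
    pre_atg_exon: int | None
    pre_atg_intron: int | None
    atg_exon: int | None
    ig1_intron: int | None
    exon3: int
    mini_intron: int | None
    exon4: int | None
    n_add_5p: int
    n_add_3p: int
    flags: frozenset[str]
    low_confidence: bool
    notes: str

    @property
    def ends_at_stop(self) -> bool:
        return "ends_at_stop" in self.flags

    @property
    def starts_after_atg(self) -> bool:
        return "starts_after_atg" in self.flags


def _opt(value) -> int | None:
    return None if pd.isna(value) or value == "." else int(value)


def load_fixture_records() -> list[FixtureRecord]:
    """The packaged machine-readable gene-architecture table (39 records)."""
    df = pd.read_csv(_DATA / "dg_gene_table.tsv", sep="\t")
    records = []
    for r in df.itertuples(index=False):
        flags = frozenset() if r.flags == "." else frozenset(r.flags.split(","))
        records.append(
            FixtureRecord(
                code=r.code,
                species=r.species,
                group=r.group,
                clade=r.clade,
                table=int(r.table),
                tree_tip=r.tree_tip,
                pre_atg_exon=_opt(r.pre_atg_exon),
                pre_atg_intron=_opt(r.pre_atg_intron),
                atg_exon=_opt(r.atg_exon),
                ig1_intron=_opt(r.ig1_intron),
                exon3=int(r.exon3),
                mini_intron=_opt(r.mini_intron),
                exon4=_opt(r.exon4),
                n_add_5p=int(r.n_add_5p),
                n_add_3p=int(r.n_add_3p),
                flags=flags,
                low_confidence=bool(r.low_confidence),
                notes="" if r.notes == "." else r.notes,
            )
        )
    return records


def species_tree() -> dendropy.Tree:
    """The packaged rooted cladogram of the 35 species (phylum backbone)."""
    return load_tree(str(_DATA / "species_tree.nwk"))


def packaged_domain_table() -> Path:
    """Path to the packaged (synthetic-convention) human domain table."""
    return Path(str(_DATA / "human_dg_domains_synthetic.tsv"))


# ---------------------------------------------------------------------------
# Element realisation
# ---------------------------------------------------------------------------


@dataclass
class Element:
    kind: str  # "exon" | "intron"
    length: int
    intron_class: str | None = None  # "pre_atg" | "add_5p" | "ig1" | "add_3p" | "mini"


@dataclass
class RealizedGene:
    """Deterministic elaboration of a record into explicit gene geometry."""

    record: FixtureRecord
    elements: list[Element]
    utr5: int  # 5'UTR nt inside the first coding exon
    utr3: int  # 3'UTR nt inside the last exon
    coding_len: int

    @property
    def printed_ig1_ordinal(self) -> int:
        """Index (among CDS introns, tx order) of the recorded IG1/mini intron."""
        return self.record.n_add_5p


def _split_even(total: int, n_pieces: int) -> list[int]:
    """Deterministic near-even split of ``total`` into ``n_pieces`` >= 1 parts."""
    base = [total // n_pieces] * n_pieces
    for i in range(total % n_pieces):
        base[i] += 1
    return base


def realize_record(record: FixtureRecord, seed: int = 0) -> RealizedGene:
    """Fix every free length in a record (UTRs, exon-piece splits,
    unprinted additional-intron sizes) deterministically from the seed."""
    rng = np.random.default_rng(_species_seed(seed, record.code))
    elements: list[Element] = []

    if record.pre_atg_exon is not None:
        elements.append(Element("exon", record.pre_atg_exon))
    if record.pre_atg_intron is not None:
        elements.append(Element("intron", record.pre_atg_intron, "pre_atg"))

    # -- ATG-side exon(s) ---------------------------------------------------
    if record.atg_exon is not None:
        if record.code == "Hs":
            utr5 = HUMAN_UTR5_OFFSET
        elif record.ends_at_stop:
            # whole downstream exon set is coding: absorb the mod-3 remainder
            # into a (conventional) tiny 5'UTR so the CDS translates cleanly
            tail = record.exon3 + (record.exon4 or 0)
            utr5 = (record.atg_exon + tail) % 3
        else:
            utr5 = 0
        coding_e2 = record.atg_exon - utr5
        if record.n_add_5p:
            pieces = _split_even(coding_e2, record.n_add_5p + 1)
            pieces[0] += utr5
            lo, hi = (2000, 5001) if "large" in record.notes else (80, 301)
            for i, p in enumerate(pieces):
                elements.append(Element("exon", p))
                if i < record.n_add_5p:
                    elements.append(
                        Element("intron", int(rng.integers(lo, hi)), "add_5p")
                    )
        else:
            elements.append(Element("exon", record.atg_exon))
        elements.append(Element("intron", record.ig1_intron, "ig1"))
    else:
        # paralogue with unannotated 5' half: first annotated exon is exon3
        utr5 = (record.exon3 + (record.exon4 or 0)) % 3
        coding_e2 = 0

    # -- downstream exons ---------------------------------------------------
    if record.table == 1:
        utr3 = 0
        coding_e3 = record.exon3
        if not record.ends_at_stop:
            # convention: ~quarter of the final combined exon is 3'UTR,
            # nudged so the CDS length is a codon multiple
            base = max(record.exon3 // 4, 9)
            utr3 = base + ((coding_e2 + record.exon3 - base) % 3)
            coding_e3 = record.exon3 - utr3
        pieces = _split_even(coding_e3, record.n_add_3p + 1)
        pieces[-1] += utr3
        for i, p in enumerate(pieces):
            elements.append(Element("exon", p))
            if i < record.n_add_3p:
                elements.append(Element("intron", int(rng.integers(80, 301)), "add_3p"))
        coding_len = coding_e2 + coding_e3
    else:
        elements.append(Element("exon", record.exon3))
        elements.append(Element("intron", record.mini_intron, "mini"))
        elements.append(Element("exon", record.exon4))
        utr3 = 0
        coding_len = coding_e2 + record.exon3 + record.exon4 - (
            utr5 if record.atg_exon is None else 0
        )

    assert coding_len % 3 == 0, f"{record.code}: CDS length {coding_len} not codon multiple"
    return RealizedGene(record, elements, utr5, utr3, coding_len)


# ---------------------------------------------------------------------------
# FASTA + GFF3 writing
# ---------------------------------------------------------------------------

FLANK = 100


@dataclass
class FixturePaths:
    species_id: str
    gene_id: str
    fasta: Path
    gff3: Path
    realized: RealizedGene | None
    violations: list[int] = field(default_factory=list)  # CDS-intron ordinals


def _intron_seq(rng, length: int, violate: bool) -> tuple[str, bool]:
    donor, acceptor = "GT", "AG"
    if violate:
        if rng.random() < 0.5:
            donor = _NON_GT[rng.integers(0, len(_NON_GT))]
        else:
            acceptor = _NON_AG[rng.integers(0, len(_NON_AG))]
    return donor + _random_dna(rng, length - 4) + acceptor, violate


def write_gene_files(
    out_dir: str | Path,
    species_id: str,
    gene_id: str,
    elements: Sequence[Element],
    utr5: int,
    utr3: int,
    seed: int = 0,
    strand: str = "+",
    violation_rate: float = 0.0,
    start_codon: str = "ATG",
) -> FixturePaths:
    """Assemble a gene from its element list and write FASTA + GFF3.

    The coding sequence starts at ``utr5`` within the first coding exon and
    ends ``utr3`` before the end of the last exon; it is built from
    non-stop codons, opened with ``start_codon`` and closed with TAA.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_species_seed(seed, species_id))

    total_exonic = sum(e.length for e in elements if e.kind == "exon")
    # exons preceding a "pre_atg" intron are wholly 5'UTR; utr5 then applies
    # within the first coding exon
    idx_pre_atg = next(
        (i for i, el in enumerate(elements) if el.intron_class == "pre_atg"), None
    )
    utr_exon_total = (
        0
        if idx_pre_atg is None
        else sum(el.length for el in elements[:idx_pre_atg] if el.kind == "exon")
    )
    cds_tx_start = utr_exon_total + utr5
    cds_tx_end = total_exonic - utr3
    coding_len = cds_tx_end - cds_tx_start
    n_codons = coding_len // 3
    coding = _random_coding(rng, n_codons, first=start_codon)
    if len(coding) != coding_len:
        raise ValueError(f"coding length mismatch for {species_id}")
    transcript = _random_dna(rng, cds_tx_start) + coding + _random_dna(rng, utr3)

    # assemble contig and features
    contig_parts = [_random_dna(rng, FLANK)]
    pos = FLANK  # forward genomic cursor (0-based)
    tx_cursor = 0
    exon_feats: list[tuple[int, int]] = []
    cds_feats: list[tuple[int, int]] = []
    violations: list[int] = []
    cds_intron_ordinal = 0
    for el in elements:
        if el.kind == "exon":
            chunk = transcript[tx_cursor : tx_cursor + el.length]
            contig_parts.append(chunk)
            exon_feats.append((pos, pos + el.length))
            a = max(tx_cursor, cds_tx_start)
            b = min(tx_cursor + el.length, cds_tx_end)
            if a < b:
                cds_feats.append((pos + (a - tx_cursor), pos + (b - tx_cursor)))
            tx_cursor += el.length
            pos += el.length
        else:
            in_cds = cds_tx_start < tx_cursor < cds_tx_end
            violate = bool(in_cds and rng.random() < violation_rate)
            seq, v = _intron_seq(rng, el.length, violate)
            if in_cds:
                if v:
                    violations.append(cds_intron_ordinal)
                cds_intron_ordinal += 1
            contig_parts.append(seq)
            pos += el.length
    contig_parts.append(_random_dna(rng, FLANK))
    contig = "".join(contig_parts)

    if strand == "-":
        L = len(contig)
        contig = _revcomp(contig)
        exon_feats = [(L - e, L - s) for s, e in exon_feats][::-1]
        cds_feats = [(L - e, L - s) for s, e in cds_feats][::-1]

    contig_id = f"{species_id}_locus"
    fasta_path = out_dir / f"{species_id}.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig_id}\n")
        for i in range(0, len(contig), 80):
            fh.write(contig[i : i + 80] + "\n")

    gff_path = out_dir / f"{species_id}.gff3"
    gene_start = min(s for s, _ in exon_feats) + 1
    gene_end = max(e for _, e in exon_feats)
    lines = ["##gff-version 3"]

    def feat(ftype, s, e, attrs, phase="."):
        lines.append(
            "\t".join(
                [
                    contig_id,
                    "intronarch",
                    ftype,
                    str(s + 1),
                    str(e),
                    ".",
                    strand,
                    phase,
                    attrs,
                ]
            )
        )

    lines.append(
        "\t".join(
            [
                contig_id,
                "intronarch",
                "gene",
                str(gene_start),
                str(gene_end),
                ".",
                strand,
                ".",
                f"ID={gene_id}",
            ]
        )
    )
    mrna_id = f"{gene_id}.t1"
    feat("mRNA", gene_start - 1, gene_end, f"ID={mrna_id};Parent={gene_id}")
    for i, (s, e) in enumerate(sorted(exon_feats), 1):
        feat("exon", s, e, f"ID={mrna_id}.exon{i};Parent={mrna_id}")
    # GFF3 phase: number of bases to remove to reach the next codon start
    ordered_cds = sorted(cds_feats, reverse=(strand == "-"))
    acc = 0
    phases = []
    for s, e in ordered_cds:
        phases.append((3 - acc % 3) % 3)
        acc += e - s
    for (s, e), ph in sorted(zip(ordered_cds, phases)):
        feat("CDS", s, e, f"ID={mrna_id}.cds;Parent={mrna_id}", phase=str(ph))
    gff_path.write_text("\n".join(lines) + "\n")

    return FixturePaths(
        species_id=species_id,
        gene_id=gene_id,
        fasta=fasta_path,
        gff3=gff_path,
        realized=None,  # filled by callers that have a record
        violations=violations,
    )


def build_fixture_models(
    out_dir: str | Path,
    records: Sequence[FixtureRecord] | None = None,
    seed: int = 0,
    strand_map: Mapping[str, str] | None = None,
    violation_rate: float = 0.0,
) -> dict[str, FixturePaths]:
    """Write genome FASTA + GFF3 for every record; keyed by record code."""
    records = list(records) if records is not None else load_fixture_records()
    strand_map = strand_map or {}
    out = {}
    for rec in records:
        rg = realize_record(rec, seed=seed)
        start = "CTG" if rec.starts_after_atg else "ATG"
        paths = write_gene_files(
            out_dir,
            species_id=rec.code,
            gene_id=f"{rec.code}_DG",
            elements=rg.elements,
            utr5=rg.utr5,
            utr3=rg.utr3,
            seed=seed,
            strand=strand_map.get(rec.code, "+"),
            violation_rate=violation_rate,
            start_codon=start,
        )
        paths.realized = rg
        out[rec.code] = paths
    return out


def printed_row_from_architecture(arch, record: FixtureRecord) -> dict:
    """Recover the recorded table columns from an extracted architecture.

    Species with additional 5' CDS introns print the *combined* ATG-side
    exon length and list the first CDS intron after those additions as the
    IG1-intron; the record's additional-5' count drives that mapping.
    """
    k = record.n_add_5p
    down = arch.downstream_exon_lens
    introns = arch.cds_intron_lens
    if record.atg_exon is None:  # 5'-truncated paralogue (first exon = exon3)
        return {
            "pre_atg_exon": None,
            "pre_atg_intron": None,
            "atg_exon": None,
            "ig1_intron": None,
            "exon3": arch.atg_exon_len,
            "mini_intron": introns[0] if introns else None,
            "exon4": down[0] if down else None,
        }
    row = {
        "pre_atg_exon": arch.pre_atg_exon_len,
        "pre_atg_intron": arch.pre_atg_intron_len,
        "atg_exon": arch.atg_exon_len + sum(down[:k]),
        "ig1_intron": introns[k] if len(introns) > k else None,
    }
    if record.table == 1:
        row["exon3"] = sum(down[k:])
        row["mini_intron"] = None
        row["exon4"] = None
    else:
        row["exon3"] = down[k]
        row["mini_intron"] = introns[k + 1]
        row["exon4"] = down[k + 1]
    return row


def build_anchor_msa(
    proteins: Mapping[str, tuple[str, int]], path: str | Path
) -> Path:
    """Write an aligned FASTA in which one anchor residue per row shares a
    column.

    ``proteins`` maps a row id to ``(protein_sequence, anchor_residue)``
    (1-based).  Rows are left-padded with gaps so every anchor lands in the
    same column and right-padded to equal length — a stand-in for a real
    alignment when only the junction register matters.
    """
    path = Path(path)
    anchor_col = max(r for _, r in proteins.values())
    rows = {}
    for sid, (seq, res) in proteins.items():
        padded = "-" * (anchor_col - res) + seq
        rows[sid] = padded
    width = max(len(s) for s in rows.values())
    with open(path, "w") as fh:
        for sid in sorted(rows):
            fh.write(f">{sid}\n{rows[sid].ljust(width, '-')}\n")
    return path


# ---------------------------------------------------------------------------
# Boundary-window simulator
# ---------------------------------------------------------------------------


def simulate_splice_windows(
    n: int,
    violation_rate: float,
    seed: int = 0,
    width: int = 50,
) -> tuple[list[tuple[BoundaryWindow, BoundaryWindow]], list[bool]]:
    """Donor/acceptor window pairs for ``n`` introns, a fraction of which
    violate the canonical GT..AG ends.  Returns the windows and the truth."""
    rng = np.random.default_rng(seed)
    half = width // 2
    pairs, truth = [], []
    for i in range(n):
        violate = bool(rng.random() < violation_rate)
        intron, _ = _intron_seq(rng, max(width, 60), violate)
        sid = f"sim{i:04d}"
        donor = BoundaryWindow(
            species_id=sid,
            gene_id=sid,
            intron_index=0,
            side="donor",
            seq=_random_dna(rng, half) + intron[: width - half],
            exonic_len=half,
            intronic_len=width - half,
        )
        acceptor = BoundaryWindow(
            species_id=sid,
            gene_id=sid,
            intron_index=0,
            side="acceptor",
            seq=intron[-(width - half):] + _random_dna(rng, half),
            exonic_len=half,
            intronic_len=width - half,
        )
        pairs.append((donor, acceptor))
        truth.append(violate)
    return pairs, truth


# ---------------------------------------------------------------------------
# Evolution simulator
# ---------------------------------------------------------------------------


@dataclass
class EvolutionParams:
    """Generative model of intron gain/loss on a rooted tree.

    Rates are per unit branch length (length 1 assumed where the tree has
    none).  Intron lengths follow a log-normal whose median scales with
    genome size as ``a * g**b``.
    """

    tree: object  # Newick path/string or dendropy.Tree
    gain_rate: float = 0.3
    loss_rate: float = 0.0
    seed: int = 0
    cds_len: int = 1800
    root_intron_offsets: tuple[int, ...] = (285,)
    genome_sizes: Mapping[str, float] | None = None
    length_a: float = 0.02
    length_b: float = 0.7
    length_sigma: float = 0.4
    boundary_violation_rate: float = 0.0

    def __post_init__(self):
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.cds_len % 3:
            raise ValueError("cds_len must be a codon multiple")


@dataclass
class SimulatedEvolution:
    params: EvolutionParams
    tree: dendropy.Tree
    matrix: PresenceAbsenceMatrix
    events: list[tuple[str, str, str]]  # (branch, kind, intron_id)
    intron_offsets: dict[str, int]
    tip_sets: dict[str, frozenset[str]]

    def true_gain_branch(self, intron_id: str) -> str:
        for branch, kind, iid in self.events:
            if iid == intron_id and kind == "gain":
                return branch
        raise KeyError(intron_id)


def simulate_gene_evolution(params: EvolutionParams) -> SimulatedEvolution:
    """Evolve intron presence along the tree and log every event.

    Gains are Poisson along each branch at fresh uniform coding offsets
    (so each gained intron is a unique positional character: no
    homoplasy of insertion sites); losses remove whole introns
    independently with probability ``1 - exp(-loss_rate * bl)``.
    """
    tree = load_tree(params.tree)
    rng = np.random.default_rng(params.seed)
    offsets: dict[str, int] = {}
    used = set()
    counter = itertools.count()

    def new_intron(branch_label: str) -> str:
        iid = f"i{next(counter)}"
        while True:
            off = int(rng.integers(3, params.cds_len - 2))
            if off not in used:
                used.add(off)
                break
        offsets[iid] = off
        return iid

    root_set = set()
    for off in params.root_intron_offsets:
        iid = f"i{next(counter)}"
        offsets[iid] = off
        used.add(off)
        root_set.add(iid)

    events: list[tuple[str, str, str]] = []
    tip_sets: dict[str, frozenset[str]] = {}
    state: dict = {tree.seed_node: frozenset(root_set)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = state[node]
        else:
            bl = node.edge.length if node.edge.length is not None else 1.0
            label = _branch_label(node)
            current = set(state[node.parent_node])
            p_loss = 1.0 - math.exp(-params.loss_rate * bl)
            for iid in sorted(current):
                if p_loss and rng.random() < p_loss:
                    current.discard(iid)
                    events.append((label, "loss", iid))
            for _ in range(rng.poisson(params.gain_rate * bl)):
                iid = new_intron(label)
                current.add(iid)
                events.append((label, "gain", iid))
            current = frozenset(current)
            state[node] = current
        if node.is_leaf():
            tip_sets[node.taxon.label] = state[node]

    all_introns = sorted(offsets, key=lambda i: int(i[1:]))
    tips = sorted(tip_sets)
    df = pd.DataFrame(
        {
            iid: [PRESENT if iid in tip_sets[t] else ABSENT for t in tips]
            for iid in all_introns
        },
        index=tips,
        dtype=int,
    )
    return SimulatedEvolution(
        params=params,
        tree=tree,
        matrix=PresenceAbsenceMatrix(df),
        events=events,
        intron_offsets=offsets,
        tip_sets=tip_sets,
    )


def write_simulated_tip_genes(
    sim: SimulatedEvolution, out_dir: str | Path, seed: int = 0
) -> dict[str, FixturePaths]:
    """Realise each tip's architecture as FASTA + GFF3 files.

    Intron lengths are log-normal with median ``a * genome_size**b``.
    """
    p = sim.params
    out = {}
    rng = np.random.default_rng(seed)
    genome_sizes = p.genome_sizes or {}
    for tip, introns in sorted(sim.tip_sets.items()):
        g = float(genome_sizes.get(tip, 1e8))
        median = p.length_a * g**p.length_b
        offs = sorted(sim.intron_offsets[i] for i in introns)
        elements = []
        prev = 0
        for off in offs:
            elements.append(Element("exon", off - prev))
            ln = max(
                MIN_INTRON_SIZE_FLOOR,
                int(round(float(rng.lognormal(math.log(median), p.length_sigma)))),
            )
            elements.append(Element("intron", ln, "ig1" if prev == 0 else "add_3p"))
            prev = off
        elements.append(Element("exon", p.cds_len - prev))
        out[tip] = write_gene_files(
            out_dir,
            species_id=tip,
            gene_id=f"{tip}_sim",
            elements=elements,
            utr5=0,
            utr3=0,
            seed=seed,
            violation_rate=p.boundary_violation_rate,
        )
    return out


# ---------------------------------------------------------------------------
# Intron-size simulator
# ---------------------------------------------------------------------------


def simulate_intron_sizes(
    genome_sizes: Mapping[str, float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
    exonic_budget: float = 3000.0,
) -> list[SizeRecord]:
    """Semi-log intron-size model: ``intercept + slope*log10(g) + N(0, sd)``,
    floored at 30 bp.  ``gene_span`` is the intron plus a fixed exonic
    budget so that gene-size regressions are also exercised."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for sp, g in sorted(genome_sizes.items()):
        if g <= 0:
            raise ValueError(f"genome size must be positive for {sp}")
        y = intercept + slope * math.log10(g) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        y = max(float(MIN_INTRON_SIZE_FLOOR), float(y))
        out.append(
            SizeRecord(
                species_id=sp,
                ig1_intron_len=y,
                gene_span=y + exonic_budget,
                genome_size=float(g),
            )
        )
    return out
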