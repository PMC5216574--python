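"""Intron phase / protein-coordinate mapping and cross-species positional homology.

Each CDS-interrupting intron is described by the number of coding
nucleotides 5' of it (``cds_offset``), its phase (``cds_offset mod 3``:
the nucleotides of the interrupted codon preceding the intron) and the
flanking protein residues.  A phase-0 intron falls cleanly between two
codons — e.g. the human dystroglycan IG1-intron inserts between residues
95 and 96 — while phase 1/2 introns split a codon (``codon_split``).

Insertion residues can be tested for register against protein
domain/feature intervals (:func:`domain_register`), projected onto the
columns of a protein multiple sequence alignment
(:func:`project_to_alignment`) and clustered into positional-homology
groups across species (:func:`cluster_homologous_introns`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

from .gene_models import GeneModel, GeneModelError

GAP_CHARS = frozenset("-.")

DEFAULT_BOUNDARY_TOLERANCE = 2  # residues
DEFAULT_COLUMN_TOLERANCE = 2  # alignment columns


class MappingError(GeneModelError):
    pass


@dataclass(frozen=True)
class IntronRecord:
    """One CDS intron with coding-sequence and protein coordinates."""

    species_id: str
    gene_id: str
    intron_index: int  # ordinal over *all* introns, transcription order
    genomic_span: tuple[int, int]
    length: int
    cds_offset: int
    phase: int
    residue_before: int  # 1-based position of last complete codon's residue
    residue_after: int
    codon_split: bool


def cds_introns(model: GeneModel) -> list[IntronRecord]:
    """All CDS-interrupting introns of a model, transcription order."""
    out = []
    for idx in range(len(model.introns)):
        try:
            out.append(intron_cds_position(model, idx))
        except MappingError:
            continue
    return out


def intron_cds_position(model: GeneModel, intron_index: int) -> IntronRecord:
    """Coding offset, phase and flanking residues of one intron.

    ``intron_index`` is the ordinal of the intron in transcription order
    (0-based, counting UTR introns too).  Raises :class:`MappingError` for
    introns that do not interrupt the CDS.
    """
    introns = model.introns
    if not 0 <= intron_index < len(introns):
        raise MappingError(
            f"{model.gene_id} has {len(introns)} introns; index {intron_index} "
            "out of range"
        )
    cds_lo, cds_hi = model.cds_tx_range()
    exon_lens = [e - s for s, e in model.exons]
    tx_starts = model._tx_starts()
    junction = tx_starts[intron_index] + exon_lens[intron_index]
    if junction <= cds_lo or junction >= cds_hi:
        raise MappingError(
            f"not a CDS intron: intron {intron_index} of {model.gene_id}"
        )
    offset = junction - cds_lo
    phase = offset % 3
    residue_before = offset // 3
    span = introns[intron_index]
    return IntronRecord(
        species_id=model.species_id,
        gene_id=model.gene_id,
        intron_index=intron_index,
        genomic_span=span,
        length=span[1] - span[0],
        cds_offset=offset,
        phase=phase,
        residue_before=residue_before,
        residue_after=residue_before + 1,
        codon_split=phase != 0,
    )


# ---------------------------------------------------------------------------
# Domain register
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainAnnotation:
    """One protein feature interval, 1-based inclusive residue coordinates."""

    protein_id: str
    feature: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval for {self.feature}")


def read_domains(tsv_path: str | Path, protein_id: str | None = None) -> list[DomainAnnotation]:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    out = [
        DomainAnnotation(r.protein_id, r.feature, int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    if protein_id is not None:
        out = [d for d in out if d.protein_id == protein_id]
    return out


@dataclass(frozen=True)
class RegisterCall:
    kind: str  # "within" | "at_boundary" | "inter_domain"
    feature: str | None


def domain_register(
    intron: IntronRecord,
    domains: Sequence[DomainAnnotation],
    boundary_tolerance: int = DEFAULT_BOUNDARY_TOLERANCE,
) -> RegisterCall:
    """Classify an insertion site against protein feature intervals.

    The insertion point sits between ``residue_before`` and
    ``residue_after``; a feature spanning residues ``[s, e]`` has its
    boundaries at s-0.5 and e+0.5 in that coordinate.  ``at_boundary`` wins
    over ``within`` when the point lies within ``boundary_tolerance``
    residues of a feature end; with several qualifying features the
    shortest (most specific) is reported.
    """
    if not domains:
        raise MappingError("no annotation: empty domain table")
    p = intron.residue_before + 0.5
    boundary_hits: list[DomainAnnotation] = []
    within_hits: list[DomainAnnotation] = []
    for d in domains:
        lo, hi = d.start - 0.5, d.end + 0.5
        if min(abs(p - lo), abs(p - hi)) <= boundary_tolerance:
            boundary_hits.append(d)
        elif lo < p < hi:
            within_hits.append(d)
    for hits, kind in ((boundary_hits, "at_boundary"), (within_hits, "within")):
        if hits:
            best = min(hits, key=lambda d: (d.end - d.start, d.start, d.feature))
            return RegisterCall(kind, best.feature)
    return RegisterCall("inter_domain", None)


# ---------------------------------------------------------------------------
# MSA projection and positional homology
# ---------------------------------------------------------------------------


def _msa_rows(msa) -> dict[str, str]:
    if isinstance(msa, (str, Path)):
        msa = AlignIO.read(str(msa), "fasta")
    return {rec.id: str(rec.seq) for rec in msa}


def project_to_alignment(msa, species_id: str, residue_index: int) -> int:
    """Alignment column (1-based) of a residue of one MSA row.

    The column is the one at which the count of non-gap characters of the
    row equals ``residue_index``.
    """
    rows = _msa_rows(msa)
    if species_id not in rows:
        raise MappingError(f"{species_id} absent from alignment")
    if residue_index < 1:
        raise MappingError(f"residue index must be >= 1, got {residue_index}")
    seen = 0
    for col, ch in enumerate(rows[species_id], start=1):
        if ch not in GAP_CHARS:
            seen += 1
            if seen == residue_index:
                return col
    raise MappingError(
        f"out of range: residue {residue_index} beyond ungapped length "
        f"({seen}) of {species_id}"
    )


@dataclass(frozen=True)
class ProjectedIntron:
    species_id: str
    intron: IntronRecord | None
    column: int
    msa_id: str = "msa"


@dataclass
class IntronHomologyGroup:
    """Cross-species cluster of introns sharing an alignment-column position."""

    group_id: str
    members: list[ProjectedIntron]
    consensus_column: int
    column_spread: int
    member_columns: dict[str, int] = field(default_factory=dict)


def cluster_homologous_introns(
    projections: Iterable[ProjectedIntron],
    column_tolerance: int = DEFAULT_COLUMN_TOLERANCE,
) -> list[IntronHomologyGroup]:
    """Single-linkage clustering of projected insertion columns.

    Two projections join the same group when a chain of member columns
    exists in which consecutive sorted columns differ by at most
    ``column_tolerance``.  Group ids are deterministic, derived from each
    group's leftmost column.
    """
    projs = sorted(projections, key=lambda p: (p.column, p.species_id))
    if not projs:
        return []
    msa_ids = {p.msa_id for p in projs}
    if len(msa_ids) > 1:
        raise MappingError(f"incompatible projections: multiple MSAs {sorted(msa_ids)}")

    groups: list[list[ProjectedIntron]] = [[projs[0]]]
    for p in projs[1:]:
        if p.column - groups[-1][-1].column <= column_tolerance:
            groups[-1].append(p)
        else:
            groups.append([p])

    out = []
    for members in groups:
        cols = [m.column for m in members]
        lo, hi = min(cols), max(cols)
        mid = sorted(cols)[(len(cols) - 1) // 2]
        out.append(
            IntronHomologyGroup(
                group_id=f"g{lo}",
                members=members,
                consensus_column=mid,
                column_spread=hi - lo,
                member_columns={m.species_id: m.column for m in members},
            )
        )
    return out


def intron_map_table(
    records: Iterable[IntronRecord],
    registers: dict[tuple[str, int], RegisterCall] | None = None,
    columns: dict[tuple[str, int], int] | None = None,
    groups: dict[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """Per-intron summary table (offset, phase, residues, register, column, group)."""
    rows = []
    for r in records:
        key = (r.species_id, r.intron_index)
        reg = registers.get(key) if registers else None
        rows.append(
            {
                "species_id": r.species_id,
                "gene_id": r.gene_id,
                "intron_index": r.intron_index,
                "length": r.length,
                "cds_offset": r.cds_offset,
                "phase": r.phase,
                "residue_before": r.residue_before,
                "residue_after": r.residue_after,
                "codon_split": r.codon_split,
                "register": f"{reg.kind}({reg.feature})" if reg else None,
                "column": columns.get(key) if columns else None,
                "group": groups.get(key) if groups else None,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["species_id", "intron_index"], kind="stable")
        .reset_index(drop=True)
    )
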