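"""Gene-model ingestion and exon–intron architecture classification.

A :class:`GeneModel` holds one gene's exons and CDS segments on a genomic
contig, strand-aware, with coordinates stored 0-based half-open (GFF3 I/O
converts from 1-based inclusive).  :func:`extract_architecture` classifies
the gene's elements into the vocabulary used throughout this package:

* **pre-ATG exon(s)** — exons lying wholly 5' of the first coding base
  (non-coding leader exons);
* **pre-ATG intron** — the UTR intron immediately upstream of the first
  coding exon;
* **ATG exon** — the exon containing the translation start;
* **IG1-intron** — the *first* intron that interrupts the coding sequence.
  The name records where this intron falls in dystroglycan (inside the
  region encoding the first immunoglobulin-like domain), but the
  definition is purely positional so that genes which have lost the domain
  yet kept the intron are classified identically;
* **additional CDS introns** — every subsequent CDS-interrupting intron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class GeneModelError(ValueError):
    """Base class for gene-model parsing/classification failures."""


class GeneNotFoundError(GeneModelError):
    pass


class InconsistentAnnotationError(GeneModelError):
    pass


class CoordinateOverflowError(GeneModelError):
    pass


class NonCodingGeneError(GeneModelError):
    pass


class DegenerateIntronError(GeneModelError):
    pass


Interval = tuple[int, int]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneModel:
    """One gene's exon/CDS layout on a genomic sequence.

    ``exons`` and ``cds_segments`` are genomic 0-based half-open intervals
    listed in *transcription* order (ascending coordinates on '+', descending
    on '-').  ``seq`` is the forward-strand contig slice covering the gene
    span, starting at genomic coordinate ``span_start``.
    """

    species_id: str
    gene_id: str
    contig_id: str
    seq: str
    span_start: int
    strand: str
    exons: list[Interval]
    cds_segments: list[Interval]
    flags: set[str] = field(default_factory=set)

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def gene_span(self) -> int:
        s, e = self.span
        return e - s

    @property
    def introns(self) -> list[Interval]:
        """Genomic intervals between consecutive exons, transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                iv = (e1, s2)
            else:
                iv = (e2, s1)
            if iv[1] - iv[0] <= 0:
                raise DegenerateIntronError(
                    f"degenerate intron between exons in {self.gene_id}"
                )
            out.append(iv)
        return out

    def slice(self, start: int, end: int) -> tuple[str, int, int]:
        """Forward-strand genomic slice, clipped to the stored sequence.

        Returns ``(sequence, actual_start, actual_end)``.
        """
        lo = self.span_start
        hi = self.span_start + len(self.seq)
        a, b = max(start, lo), min(end, hi)
        if a >= b:
            return "", a, a
        return self.seq[a - lo : b - lo], a, b

    def _tx_starts(self) -> list[int]:
        """Cumulative transcript offset of each exon's first (tx) base."""
        offs, total = [], 0
        for s, e in self.exons:
            offs.append(total)
            total += e - s
        return offs

    def spliced_sequence(self) -> str:
        """mRNA-oriented concatenation of exon sequences."""
        parts = []
        for s, e in self.exons:
            chunk, a, b = self.slice(s, e)
            if (a, b) != (s, e):
                raise CoordinateOverflowError(
                    f"coordinate overflow: exon {s}-{e} outside sequence of "
                    f"{self.gene_id}"
                )
            parts.append(chunk if self.strand == "+" else _revcomp(chunk))
        return "".join(parts)

    def cds_tx_range(self) -> Interval:
        """Coding range in transcript coordinates (0-based half-open)."""
        if not self.cds_segments:
            raise NonCodingGeneError(f"non-coding gene: {self.gene_id}")
        tx_starts = self._tx_starts()
        positions = []
        for cs, ce in self.cds_segments:
            placed = False
            for (es, ee), off in zip(self.exons, tx_starts):
                if cs >= es and ce <= ee:
                    if self.strand == "+":
                        positions.append((off + (cs - es), off + (ce - es)))
                    else:
                        positions.append((off + (ee - ce), off + (ee - cs)))
                    placed = True
                    break
            if not placed:
                raise InconsistentAnnotationError(
                    f"inconsistent annotation: CDS {cs}-{ce} outside exons of "
                    f"{self.gene_id}"
                )
        return min(p[0] for p in positions), max(p[1] for p in positions)

    def cds_sequence(self) -> str:
        a, b = self.cds_tx_range()
        return self.spliced_sequence()[a:b]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


def _cds_span_of(db, feature) -> int:
    return sum(f.end - f.start + 1 for f in db.children(feature, featuretype="CDS"))


def read_gene_model(
    gff3_path: str | Path,
    fasta_path: str | Path,
    gene_id: str,
    species_id: str | None = None,
) -> GeneModel:
    """Parse one gene from a GFF3 file + genome FASTA into a :class:`GeneModel`.

    When the gene has several mRNAs the transcript with the longest CDS is
    selected (ties broken by coordinate).  Exons are returned in
    transcription order; for minus-strand genes this means descending
    genomic coordinates.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError:
        raise GeneNotFoundError(f"gene not found: {gene_id}") from None

    mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
    if mrnas:
        parent = max(mrnas, key=lambda m: (_cds_span_of(db, m), -m.start))
    else:
        parent = gene

    exons = sorted(
        (f.start - 1, f.end) for f in db.children(parent, featuretype="exon")
    )
    cds = sorted((f.start - 1, f.end) for f in db.children(parent, featuretype="CDS"))
    if not exons:
        exons = list(cds)
    if not exons:
        raise InconsistentAnnotationError(
            f"inconsistent annotation: no exon/CDS features under {gene_id}"
        )
    for cs, ce in cds:
        if not any(cs >= es and ce <= ee for es, ee in exons):
            raise InconsistentAnnotationError(
                f"inconsistent annotation: CDS {cs + 1}-{ce} of {gene_id} not "
                "contained in any exon"
            )

    seqs = SeqIO.to_dict(SeqIO.parse(str(fasta_path), "fasta"))
    if gene.seqid not in seqs:
        raise GeneNotFoundError(
            f"gene not found: sequence {gene.seqid} absent from FASTA"
        )
    contig = str(seqs[gene.seqid].seq).upper()
    span_start = min(s for s, _ in exons)
    span_end = max(e for _, e in exons)
    if span_end > len(contig):
        raise CoordinateOverflowError(
            f"coordinate overflow: {gene_id} span ends at {span_end} but "
            f"{gene.seqid} is {len(contig)} bp"
        )

    strand = gene.strand if gene.strand in {"+", "-"} else "+"
    if strand == "-":
        exons = exons[::-1]
        cds = cds[::-1]

    flags: set[str] = set()
    model = GeneModel(
        species_id=species_id or gene.seqid,
        gene_id=gene_id,
        contig_id=gene.seqid,
        seq=contig[span_start:span_end],
        span_start=span_start,
        strand=strand,
        exons=exons,
        cds_segments=cds,
        flags=flags,
    )
    if cds and model.cds_length % 3 != 0:
        flags.add("truncated_annotation")
    return model


@dataclass
class ArchitectureRecord:
    """Classified element lengths of one gene (one table row's content)."""

    species_id: str
    gene_id: str
    pre_atg_exon_len: int | None
    pre_atg_intron_len: int | None
    additional_5p_intron_lens: list[int]
    atg_exon_len: int
    ig1_intron_len: int | None
    additional_3p_intron_lens: list[int]
    downstream_exon_lens: list[int]
    cds_intron_lens: list[int]
    cds_intron_offsets: list[int]
    n_coding_exons: int
    gene_span: int
    completeness_flags: set[str]

    @property
    def downstream_exon_combined(self) -> int:
        """Combined downstream exon size (the table's E3 convention)."""
        return sum(self.downstream_exon_lens)

    @property
    def element_lengths(self) -> list[int]:
        """All element lengths 5'->3' (exons and introns interleaved)."""
        out: list[int] = []
        if self.pre_atg_exon_len is not None:
            out.append(self.pre_atg_exon_len)
        for iv in self.additional_5p_intron_lens:
            out.append(iv)
        if self.pre_atg_intron_len is not None:
            out.append(self.pre_atg_intron_len)
        out.append(self.atg_exon_len)
        for intron, exon in zip(self.cds_intron_lens, self.downstream_exon_lens):
            out.extend((intron, exon))
        return out


def extract_architecture(model: GeneModel) -> ArchitectureRecord:
    """Classify a gene model's exons and introns.

    Raises :class:`NonCodingGeneError` when the model has no CDS and
    :class:`DegenerateIntronError` when abutting exons imply a zero-length
    intron.
    """
    if not model.cds_segments:
        raise NonCodingGeneError(f"non-coding gene: {model.gene_id}")
    cds_lo, cds_hi = model.cds_tx_range()

    exon_lens = [e - s for s, e in model.exons]
    tx_starts = model._tx_starts()
    introns = model.introns  # raises DegenerateIntronError on abutting exons
    intron_lens = [e - s for s, e in introns]

    # transcript coordinate of the junction 5' of each intron
    junctions = [tx_starts[i] + exon_lens[i] for i in range(len(introns))]

    utr5_introns: list[int] = []      # indices of introns wholly 5' of CDS
    cds_introns: list[int] = []
    utr3_introns: list[int] = []
    for i, j in enumerate(junctions):
        if j <= cds_lo:
            utr5_introns.append(i)
        elif j >= cds_hi:
            utr3_introns.append(i)
        else:
            cds_introns.append(i)
    if utr3_introns:
        warnings.warn(
            f"{model.gene_id}: {len(utr3_introns)} intron(s) wholly within the "
            "3'UTR are not classified as CDS introns",
            stacklevel=2,
        )

    coding_exons = [
        i
        for i in range(len(model.exons))
        if tx_starts[i] < cds_hi and tx_starts[i] + exon_lens[i] > cds_lo
    ]
    first_coding = coding_exons[0]
    pre_atg_exons = [i for i in range(first_coding)]

    flags = set(model.flags)

    pre_atg_exon_len = sum(exon_lens[i] for i in pre_atg_exons) or None
    # The UTR intron immediately preceding the first coding exon is *the*
    # pre-ATG intron; any further-upstream UTR introns are additional 5'.
    pre_atg_intron_len = None
    additional_5p: list[int] = []
    if utr5_introns:
        pre_atg_intron_len = intron_lens[utr5_introns[-1]]
        additional_5p = [intron_lens[i] for i in utr5_introns[:-1]]

    if tx_starts[first_coding] == cds_lo:
        # First exon starts exactly at the CDS start: a 5' UTR (and hence a
        # pre-ATG exon) cannot be distinguished from one lost to annotation.
        flags.add("utr5_unannotated")

    cds_intron_lens = [intron_lens[i] for i in cds_introns]
    coding_before = _coding_nt_before(junctions, cds_introns, cds_lo)
    ig1_len = cds_intron_lens[0] if cds_intron_lens else None

    downstream = [exon_lens[i] for i in range(first_coding + 1, len(model.exons))]

    return ArchitectureRecord(
        species_id=model.species_id,
        gene_id=model.gene_id,
        pre_atg_exon_len=pre_atg_exon_len,
        pre_atg_intron_len=pre_atg_intron_len,
        additional_5p_intron_lens=additional_5p,
        atg_exon_len=exon_lens[first_coding],
        ig1_intron_len=ig1_len,
        additional_3p_intron_lens=cds_intron_lens[1:],
        downstream_exon_lens=downstream,
        cds_intron_lens=cds_intron_lens,
        cds_intron_offsets=coding_before,
        n_coding_exons=len(coding_exons),
        gene_span=model.gene_span,
        completeness_flags=flags,
    )


def _coding_nt_before(
    junctions: Sequence[int], cds_intron_idx: Sequence[int], cds_lo: int
) -> list[int]:
    """Coding-nucleotide offset of each CDS intron (UTR excluded).

    Only exact for genes whose CDS is contiguous in transcript coordinates
    between its first and last base, which holds for every model produced in
    this package (single-transcript protein-coding genes).
    """
    return [junctions[i] - cds_lo for i in cds_intron_idx]


def architecture_table(records: Iterable[ArchitectureRecord]) -> pd.DataFrame:
    """Tabulate records with one row per gene (table-style column semantics)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "gene_id": r.gene_id,
                "pre_atg_exon": r.pre_atg_exon_len,
                "pre_atg_intron": r.pre_atg_intron_len,
                "atg_exon": r.atg_exon_len,
                "ig1_intron": r.ig1_intron_len,
                "downstream_exons_combined": r.downstream_exon_combined,
                "n_additional_cds_introns": len(r.additional_3p_intron_lens),
                "n_coding_exons": r.n_coding_exons,
                "gene_span": r.gene_span,
                "flags": ",".join(sorted(r.completeness_flags)),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("species_id", kind="stable").reset_index(drop=True)
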