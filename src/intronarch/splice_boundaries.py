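"""Splice-junction windows, canonical AGGT/GT–AG classification, seed scans.

Windows of fixed width (50 nt by default, matching the flank width used to
compare junctions across species) are cut from the genome across each
donor (exon→intron) and acceptor (intron→exon) junction, in mRNA
orientation.  Classification follows the canonical junction consensus:
the intron starts ``GT`` and ends ``AG``; the stricter "AGGT rule"
additionally requires the exon to end ``AG`` before the donor site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .gene_models import GeneModel, GeneModelError, _revcomp

DEFAULT_WINDOW_WIDTH = 50


class BoundaryError(GeneModelError):
    pass


@dataclass(frozen=True)
class BoundaryWindow:
    """Fixed-width genomic window spanning one splice junction (mRNA sense)."""

    species_id: str
    gene_id: str
    intron_index: int
    side: str  # "donor" | "acceptor"
    seq: str
    exonic_len: int
    intronic_len: int
    clipped: bool = False

    @property
    def junction_offset(self) -> int:
        """Offset of the junction within ``seq``: donor windows place the
        exon 5' of it, acceptor windows the intron."""
        return self.exonic_len if self.side == "donor" else self.intronic_len

    @property
    def width(self) -> int:
        return len(self.seq)


def boundary_windows(
    model: GeneModel,
    intron_index: int,
    width: int = DEFAULT_WINDOW_WIDTH,
    split: int | None = None,
) -> tuple[BoundaryWindow, BoundaryWindow]:
    """Donor and acceptor windows of one intron.

    ``split`` is the number of exonic nucleotides in each window (the rest
    is intronic); by default the window is centred on the junction.
    Windows are contiguous genomic slices, so a short flanking exon simply
    contributes upstream intron sequence to the "exonic" side, exactly as
    a genomic 50-mer spanning the junction would.  Windows running past a
    contig end are clipped and flagged.
    """
    introns = model.introns
    if not 0 <= intron_index < len(introns):
        raise BoundaryError(
            f"{model.gene_id} has {len(introns)} introns; index {intron_index} "
            "out of range"
        )
    if split is None:
        split = width // 2
    if not 0 <= split <= width:
        raise BoundaryError(f"window split {split} outside width {width}")
    ex, inn = split, width - split
    g0, g1 = introns[intron_index]  # genomic, forward coords

    def cut(start: int, end: int, junction: int, side: str, exonic: int, intronic: int):
        chunk, a, b = model.slice(start, end)
        if model.strand == "-":
            chunk = _revcomp(chunk)
            lost5, lost3 = end - b, a - start
        else:
            lost5, lost3 = a - start, end - b
        clipped = (lost5 + lost3) > 0
        if side == "donor":
            exonic -= lost5
            intronic -= lost3
        else:
            intronic -= lost5
            exonic -= lost3
        return BoundaryWindow(
            species_id=model.species_id,
            gene_id=model.gene_id,
            intron_index=intron_index,
            side=side,
            seq=chunk,
            exonic_len=max(exonic, 0),
            intronic_len=max(intronic, 0),
            clipped=clipped,
        )

    if model.strand == "+":
        donor = cut(g0 - ex, g0 + inn, g0, "donor", ex, inn)
        acceptor = cut(g1 - inn, g1 + ex, g1, "acceptor", ex, inn)
    else:
        # transcription runs right-to-left: donor junction at genomic g1
        donor = cut(g1 - inn, g1 + ex, g1, "donor", ex, inn)
        acceptor = cut(g0 - ex, g0 + inn, g0, "acceptor", ex, inn)
    return donor, acceptor


@dataclass(frozen=True)
class CanonicalCall:
    """Canonical-junction flags of one intron; ``None`` = indeterminate (N)."""

    donor_gt: bool | None
    acceptor_ag: bool | None
    exonic_ag: bool | None

    @property
    def aggt_compliant(self) -> bool | None:
        if self.exonic_ag is None or self.donor_gt is None:
            return None
        return self.exonic_ag and self.donor_gt

    @property
    def gt_ag_compliant(self) -> bool | None:
        if self.donor_gt is None or self.acceptor_ag is None:
            return None
        return self.donor_gt and self.acceptor_ag


def _dinuc_eq(dinuc: str, expected: str) -> bool | None:
    if len(dinuc) < 2 or any(c not in "ACGT" for c in dinuc):
        return None
    return dinuc == expected


def classify_canonical(donor: BoundaryWindow, acceptor: BoundaryWindow) -> CanonicalCall:
    """Flags for intron-initial GT, intron-terminal AG and exon-terminal AG.

    Requires at least 2 nt on each side of both junctions; ambiguous bases
    at the diagnostic positions yield indeterminate (``None``) flags.
    """
    if min(donor.exonic_len, donor.intronic_len) < 2 or min(
        acceptor.exonic_len, acceptor.intronic_len
    ) < 2:
        raise BoundaryError("window too short: need >= 2 nt each side of junction")
    j = donor.junction_offset
    exon_last2 = donor.seq[j - 2 : j].upper()
    intron_first2 = donor.seq[j : j + 2].upper()
    k = acceptor.junction_offset
    intron_last2 = acceptor.seq[k - 2 : k].upper()
    return CanonicalCall(
        donor_gt=_dinuc_eq(intron_first2, "GT"),
        acceptor_ag=_dinuc_eq(intron_last2, "AG"),
        exonic_ag=_dinuc_eq(exon_last2, "AG"),
    )


def compliance_summary(calls: Mapping[str, CanonicalCall]) -> dict:
    """Compliance fractions and per-rule exception species over a gene set.

    Indeterminate calls are excluded from the denominators.  Exceptions are
    reported separately for the exon–intron side (AGGT) and the intron–exon
    side (terminal AG), mirroring how junction exceptions are usually
    listed per side.
    """

    def _frac(flags):
        known = [f for f in flags if f is not None]
        return (sum(known) / len(known)) if known else float("nan")

    items = sorted(calls.items())
    return {
        "n": len(items),
        "gt_ag_fraction": _frac([c.gt_ag_compliant for _, c in items]),
        "aggt_fraction": _frac([c.aggt_compliant for _, c in items]),
        "donor_gt_fraction": _frac([c.donor_gt for _, c in items]),
        "acceptor_ag_fraction": _frac([c.acceptor_ag for _, c in items]),
        "donor_exceptions": [s for s, c in items if c.aggt_compliant is False],
        "acceptor_exceptions": [s for s, c in items if c.acceptor_ag is False],
        "indeterminate": [
            s for s, c in items if c.gt_ag_compliant is None or c.aggt_compliant is None
        ],
    }


def calls_table(calls: Mapping[str, CanonicalCall]) -> pd.DataFrame:
    rows = [
        {
            "species_id": s,
            "donor_gt": c.donor_gt,
            "acceptor_ag": c.acceptor_ag,
            "exonic_ag": c.exonic_ag,
            "aggt_compliant": c.aggt_compliant,
            "gt_ag_compliant": c.gt_ag_compliant,
        }
        for s, c in sorted(calls.items())
    ]
    return pd.DataFrame(rows)


def windows_to_fasta(windows: Iterable[BoundaryWindow], path) -> None:
    """Write windows as FASTA for external alignment; headers encode
    species, side and junction offset."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f">{w.species_id}|{w.gene_id}|intron{w.intron_index}|{w.side}"
                f"|junction={w.junction_offset}\n{w.seq}\n"
            )


# ---------------------------------------------------------------------------
# miRNA seed matching
# ---------------------------------------------------------------------------

SEED_LENGTH = 7


def seed_match_scan(
    seq: str, seed: str, max_mismatch: int = 1
) -> list[tuple[int, int]]:
    """All windows of ``seq`` within Hamming distance ``max_mismatch`` of a
    7-nt seed.

    RNA and DNA alphabets are normalised (U↔T), so miRNA seeds scan genomic
    or mRNA sequence directly.  Returns ``(position, mismatches)`` pairs
    (0-based positions), sorted by position then distance.  Seeds containing
    ambiguous bases are rejected.
    """
    seed_n = seed.upper().replace("U", "T")
    if len(seed_n) != SEED_LENGTH:
        raise ValueError(f"seed must be {SEED_LENGTH} nt, got {len(seed_n)}")
    if any(c not in "ACGT" for c in seed_n):
        raise ValueError(f"seed contains ambiguous base: {seed}")
    seq_n = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(seq_n) - SEED_LENGTH + 1):
        window = seq_n[i : i + SEED_LENGTH]
        d = sum(a != b for a, b in zip(window, seed_n))
        if d <= max_mismatch:
            hits.append((i, d))
    return hits
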