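"""Sequence/annotation I/O and promoter-window extraction.

Coordinate conventions used throughout the package:

* Genomic coordinates follow GFF3: 1-based, inclusive on both ends.
* Gene-frame ("promoter") coordinates number the first base of the
  annotated start codon +1 and the base immediately upstream -1; there
  is no position 0.  The default scanning window covers -150..+25,
  i.e. 175 bases when the contig does not truncate it.
* Promoter windows are always reported 5'->3' on the gene's coding
  strand, so on the minus strand the window sequence is the reverse
  complement of the genomic slice.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("carhscan")

__all__ = [
    "SeqEntry",
    "GeneFeature",
    "PromoterWindow",
    "FastaParseError",
    "GffParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "extract_promoter_window",
    "reverse_complement",
]


class FastaParseError(ValueError):
    """Raised when a FASTA record is malformed (names the offending record)."""


class GffParseError(ValueError):
    """Raised when a GFF3 line cannot be interpreted as a gene feature."""


@dataclass(frozen=True)
class SeqEntry:
    """A named sequence (nucleotide or amino acid), upper-cased."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene/CDS feature with 1-based inclusive genomic coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise GffParseError(
                f"feature {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GffParseError(
                f"feature {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """A -150..+25 (default) window around a translation start, in gene frame.

    ``sequence`` runs 5'->3' on the coding strand; ``offset_of_plus1`` is
    the 0-based index within ``sequence`` of the first base of the start
    codon (gene-frame position +1).
    """

    gene_id: str
    contig_id: str
    window_start: int
    window_end: int
    strand: str
    sequence: str
    offset_of_plus1: int
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_frame_position(self, index: int) -> int:
        """Gene-frame coordinate (no zero) of a 0-based index in ``sequence``."""
        delta = index - self.offset_of_plus1
        return delta + 1 if delta >= 0 else delta


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqEntry]:
    """Read a FASTA file into a list of :class:`SeqEntry`, order preserved.

    Sequences are upper-cased and whitespace-stripped.  An empty file
    yields an empty list (with a warning); a record with an empty
    sequence raises :class:`FastaParseError` naming the record.
    """
    path = Path(path)
    entries: list[SeqEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        entries.append(SeqEntry(id=rec.id, sequence=seq, description=rec.description))
    if not entries:
        log.warning("no FASTA records found in %s", path)
    return entries


def write_fasta(entries: Iterable[SeqEntry], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description=e.description or "")
        for e in entries
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene", "CDS")) -> list[GeneFeature]:
    """Extract gene features from a GFF3 file.

    Coordinates are kept 1-based inclusive as in the file.  If both
    ``gene`` and ``CDS`` rows describe a locus only the requested types
    are returned (default: both, callers typically pass one).  Features
    whose ID attribute is absent fall back to a positional identifier.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
                "Name", [None]
            )[0] or f"{feat.seqid}:{feat.start}-{feat.end}"
            features.append(
                GeneFeature(
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    gene_id=gene_id,
                )
            )
    return features


def extract_promoter_window(
    genome: SeqEntry,
    feature: GeneFeature,
    upstream: int = 150,
    downstream: int = 25,
) -> PromoterWindow:
    """Extract the -upstream..+downstream window around a start codon.

    The window spans gene-frame positions -upstream..-1 and
    +1..+downstream (no position 0), so the full-length window has
    ``upstream + downstream`` bases (175 at the defaults).  Windows that
    run off a contig edge are clipped and flagged ``truncated`` rather
    than rejected, since draft-genome annotations frequently start near
    contig boundaries.
    """
    n = len(genome.sequence)
    if feature.end > n:
        raise ValueError(
            f"feature {feature.gene_id!r} ({feature.start}..{feature.end}) "
            f"lies outside contig {genome.id!r} of length {n}"
        )
    if feature.strand == "+":
        # +1 is feature.start; upstream genomic [start-upstream, start-1]
        lo = feature.start - upstream
        hi = feature.start + downstream - 1
        clip_lo, clip_hi = max(lo, 1), min(hi, n)
        seq = genome.sequence[clip_lo - 1 : clip_hi]
        offset_plus1 = feature.start - clip_lo
    else:
        # +1 is feature.end on the genome; upstream genomic [end+1, end+upstream]
        lo = feature.end - downstream + 1
        hi = feature.end + upstream
        clip_lo, clip_hi = max(lo, 1), min(hi, n)
        seq = reverse_complement(genome.sequence[clip_lo - 1 : clip_hi])
        offset_plus1 = clip_hi - feature.end
    truncated = (clip_lo != lo) or (clip_hi != hi)
    if truncated:
        log.debug(
            "window for %s truncated at contig edge (%d nt)", feature.gene_id, len(seq)
        )
    return PromoterWindow(
        gene_id=feature.gene_id,
        contig_id=feature.contig_id,
        window_start=clip_lo,
        window_end=clip_hi,
        strand=feature.strand,
        sequence=seq,
        offset_of_plus1=offset_plus1,
        truncated=truncated,
    )
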