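"""Annotated-genome input: transcript models and sense-strand introns.

Genomes arrive either as GenBank flat files or as GFF3 + FASTA pairs.  Both
are reduced to the same in-memory model: :class:`GenomeRecord` (one contig),
:class:`TranscriptModel` (one annotated transcript, exons in reference
coordinates) and :class:`IntronRecord` (one intron, with its sequence read
5'->3' on the transcript strand).

Coordinates are 1-based inclusive throughout, the native convention of both
input formats.  Minus-strand introns carry the reverse complement of the
reference slice so downstream window arithmetic is always done in transcript
sense.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "GenomeRecord",
    "TranscriptModel",
    "IntronRecord",
    "parse_genbank",
    "parse_gff3_fasta",
    "derive_introns",
    "write_intron_bed",
    "write_intron_tsv",
]

_ALPHABET = set("ACGTN")

#: introns shorter than this cannot hold the terminal AG plus any scan window
MIN_INTRON_LENGTH = 4


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: id, uppercased sequence restricted to {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            # IUPAC ambiguity codes other than N are collapsed to N
            seq = "".join(c if c in _ALPHABET else "N" for c in seq)
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript; exons sorted by reference coordinate."""

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        if not exons:
            raise ValueError("transcript with no exons")
        for (a, b) in exons:
            if a > b:
                raise ValueError(f"inverted exon interval ({a},{b})")
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c <= b:
                raise ValueError(
                    f"overlapping exons ({a},{b}) and ({c},{d}) "
                    f"in {self.transcript_id}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class IntronRecord:
    """One intron in transcript sense.

    ``acceptor_key`` identifies the 3' end (acceptor) of the intron in
    reference space: for '+' introns it is the reference ``end``, for '-'
    introns the reference ``start`` (the last sense base in both cases).
    ``downstream_exon`` is the exon that follows the intron in transcript
    sense, in reference coordinates.
    """

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    sense_sequence: str
    downstream_exon: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def terminal_dinucleotide(self) -> str:
        return self.sense_sequence[-2:]

    @property
    def acceptor_coordinate(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_key(self) -> tuple[str, str, int]:
        return (self.contig_id, self.strand, self.acceptor_coordinate)


# ---------------------------------------------------------------------------
# parsing


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_genbank(path: str | Path) -> list[tuple[GenomeRecord, list[TranscriptModel]]]:
    """Read a GenBank flat file into (contig, transcripts) pairs.

    mRNA features are the transcript source; genes without any mRNA feature
    fall back to their CDS joins.  complement() locations yield strand '-'.
    Features extending beyond the contig are skipped with a warning.
    """
    out: list[tuple[GenomeRecord, list[TranscriptModel]]] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "genbank"):
            genome = GenomeRecord(rec.id, str(rec.seq))
            mrnas: list[TranscriptModel] = []
            cds: list[TranscriptModel] = []
            counters: dict[str, int] = {}
            for feat in rec.features:
                if feat.type not in ("mRNA", "CDS"):
                    continue
                gene_id = _first(feat.qualifiers, "gene", "locus_tag", "gene_id")
                if gene_id is None:
                    gene_id = f"gene_at_{int(feat.location.start) + 1}"
                tx_id = _first(
                    feat.qualifiers, "transcript_id", "standard_name", "protein_id"
                )
                if tx_id is None:
                    counters[gene_id] = counters.get(gene_id, 0) + 1
                    tx_id = f"{gene_id}.t{counters[gene_id]}"
                exons = [
                    (int(p.start) + 1, int(p.end)) for p in feat.location.parts
                ]
                if any(b > genome.length or a < 1 for a, b in exons):
                    warnings.warn(
                        f"feature {tx_id} exceeds contig {genome.contig_id} "
                        "bounds; skipped"
                    )
                    continue
                strand = "-" if feat.location.strand == -1 else "+"
                model = TranscriptModel(gene_id, tx_id, genome.contig_id, strand,
                                        tuple(exons))
                (mrnas if feat.type == "mRNA" else cds).append(model)
            genes_with_mrna = {t.gene_id for t in mrnas}
            transcripts = mrnas + [t for t in cds if t.gene_id not in genes_with_mrna]
            out.append((genome, transcripts))
    return out


def _first(qualifiers: dict, *keys: str) -> str | None:
    for k in keys:
        if k in qualifiers and qualifiers[k]:
            return qualifiers[k][0]
    return None


def parse_gff3_fasta(
    gff: str | Path, fasta: str | Path
) -> list[tuple[GenomeRecord, list[TranscriptModel]]]:
    """Read a GFF3 + FASTA pair into the same model as :func:`parse_genbank`.

    The gene -> mRNA/transcript -> exon hierarchy is followed through Parent
    attributes (via an in-memory gffutils database).  Exon phase and CDS
    features are ignored.  A GFF3 seqid absent from the FASTA is an error.
    """
    with _open_text(fasta) as fh:
        genomes = {rec.id: GenomeRecord(rec.id, str(rec.seq))
                   for rec in SeqIO.parse(fh, "fasta")}
    db = gffutils.create_db(
        str(gff), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    tx_types = [t for t in ("mRNA", "transcript") if t in set(db.featuretypes())]
    by_contig: dict[str, list[TranscriptModel]] = {g: [] for g in genomes}
    for tx_type in tx_types:
        for tx in db.features_of_type(tx_type):
            if tx.seqid not in genomes:
                raise ValueError(f"GFF3 seqid {tx.seqid!r} absent from FASTA")
            exons = []
            for ex in db.children(tx, featuretype="exon", order_by="start"):
                exons.append((ex.start, ex.end))
            if not exons:
                continue
            parents = list(db.parents(tx, featuretype="gene"))
            gene_id = parents[0].id if parents else tx.attributes.get(
                "Parent", [tx.id])[0]
            biotype = (tx.attributes.get("biotype") or
                       tx.attributes.get("transcript_biotype") or [None])[0]
            by_contig[tx.seqid].append(
                TranscriptModel(gene_id, tx.id, tx.seqid,
                                tx.strand if tx.strand in "+-" else "+",
                                tuple(exons), biotype=biotype)
            )
    return [(genomes[c], by_contig[c]) for c in genomes]


# ---------------------------------------------------------------------------
# introns


def derive_introns(
    transcript: TranscriptModel, genome: GenomeRecord
) -> list[IntronRecord]:
    """One intron per gap between reference-adjacent exons, in transcript sense.

    Introns shorter than :data:`MIN_INTRON_LENGTH` and zero-length gaps are
    dropped.  For '-' transcripts the sense sequence is the reverse
    complement of the reference slice and the transcript-sense downstream
    exon is the reference-previous one.
    """
    if transcript.contig_id != genome.contig_id:
        raise ValueError("transcript/genome contig mismatch")
    exons = transcript.exons
    introns: list[IntronRecord] = []
    for i in range(len(exons) - 1):
        gap_start = exons[i][1] + 1
        gap_end = exons[i + 1][0] - 1
        if gap_end < gap_start:  # zero-length gap (abutting exons)
            warnings.warn(
                f"zero-length intron in {transcript.transcript_id}; dropped"
            )
            continue
        if gap_end - gap_start + 1 < MIN_INTRON_LENGTH:
            continue
        ref_slice = genome.sequence[gap_start - 1 : gap_end]
        if transcript.strand == "+":
            sense = ref_slice
            downstream = exons[i + 1]
        else:
            sense = reverse_complement(ref_slice)
            downstream = exons[i]
        introns.append(
            IntronRecord(
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                contig_id=transcript.contig_id,
                strand=transcript.strand,
                start=gap_start,
                end=gap_end,
                sense_sequence=sense,
                downstream_exon=downstream,
            )
        )
    if transcript.strand == "-":
        introns.reverse()  # transcript-sense order
    return introns


def ag_introns(introns: Iterable[IntronRecord]) -> tuple[list[IntronRecord], int]:
    """Split off AG-terminal introns; returns (kept, n_rejected)."""
    kept, rejected = [], 0
    for it in introns:
        if it.terminal_dinucleotide == "AG":
            kept.append(it)
        else:
            rejected += 1
    return kept, rejected


# ---------------------------------------------------------------------------
# writers


def write_intron_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """BED6: 0-based half-open, name = gene|transcript, score = intron length."""
    with open(path, "w") as fh:
        for it in introns:
            fh.write(
                f"{it.contig_id}\t{it.start - 1}\t{it.end}\t"
                f"{it.gene_id}|{it.transcript_id}\t{it.length}\t{it.strand}\n"
            )


def write_intron_tsv(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """TSV with sense sequence; columns fixed for diffability."""
    cols = ("contig", "strand", "start", "end", "gene", "transcript",
            "terminal_dinucleotide", "sense_sequence")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for it in introns:
            fh.write(
                f"{it.contig_id}\t{it.strand}\t{it.start}\t{it.end}\t"
                f"{it.gene_id}\t{it.transcript_id}\t"
                f"{it.terminal_dinucleotide}\t{it.sense_sequence}\n"
            )
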