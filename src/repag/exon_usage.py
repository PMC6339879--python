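"""Constitutive vs non-constitutive exon classification and enrichment.

An exon is identified by its exact reference coordinate pair.  Within a gene
annotated with two or more transcripts, an exon present (both coordinates
matched) in every transcript is constitutive; any other exon — skipped in
some transcript, or with a shifted 5'/3' boundary — is non-constitutive
(alternative).  Single-transcript genes cannot be classified and are
excluded from both numerator and denominator.

The enrichment question: are the exons immediately downstream of G-tract
(REPAG) acceptors alternative more often than exons at large?  Quantified
Table-style as

    a = % alternative among all classified exons
    b = number of REPAG acceptors with a classified downstream exon
    c = % alternative among those REPAG-downstream exons
    d = c / a  (fold, 2 decimals)
    p = upper-tail hypergeometric (population = classified exons,
        successes = non-constitutive ones, draws = b)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .enrichment_stats import hypergeometric_tail
from .genome_io import TranscriptModel
from .splice_sites import ThreePrimeSS

__all__ = [
    "ExonUsageRecord",
    "AltExonEnrichment",
    "classify_exons",
    "downstream_exon",
    "alt_exon_enrichment",
]


@dataclass(frozen=True)
class ExonUsageRecord:
    gene_id: str
    exon: tuple[int, int]
    n_transcripts_of_gene: int
    n_transcripts_containing: int

    @property
    def is_constitutive(self) -> bool:
        return self.n_transcripts_containing == self.n_transcripts_of_gene


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    return genes


def classify_exons(
    transcripts_by_gene: Mapping[str, Sequence[TranscriptModel]],
    include_single_transcript: bool = False,
) -> list[ExonUsageRecord]:
    """One record per distinct exon coordinate pair of each multi-transcript gene.

    ``include_single_transcript`` is a sensitivity switch that classifies the
    exons of single-transcript genes as constitutive instead of skipping them.
    """
    records: list[ExonUsageRecord] = []
    for gene_id, txs in transcripts_by_gene.items():
        if len(txs) < 2 and not include_single_transcript:
            continue
        containing: dict[tuple[int, int], int] = {}
        for tx in txs:
            for exon in tx.exons:
                containing[exon] = containing.get(exon, 0) + 1
        for exon, n in sorted(containing.items()):
            records.append(ExonUsageRecord(gene_id, exon, len(txs), n))
    return records


def downstream_exon(
    site: ThreePrimeSS,
    transcripts_by_gene: Mapping[str, Sequence[TranscriptModel]] | None = None,
) -> list[tuple[int, int]]:
    """Candidate exons fed by an acceptor, in reference coordinates.

    The candidates were collected while the site was extracted and merged at
    deduplication; when a transcript grouping is supplied they are
    re-derived from the annotation instead (acceptor at the exon's
    transcript-sense start).  An acceptor with no downstream exon in any
    transcript raises ``ValueError``.
    """
    if transcripts_by_gene is not None:
        contig, strand, coord = site.acceptor_key
        candidates: list[tuple[int, int]] = []
        for txs in transcripts_by_gene.values():
            for tx in txs:
                if tx.contig_id != contig or tx.strand != strand:
                    continue
                for exon in tx.exons:
                    sense_start = exon[0] if strand == "+" else exon[1]
                    boundary = coord + 1 if strand == "+" else coord - 1
                    if sense_start == boundary and exon not in candidates:
                        candidates.append(exon)
        if not candidates:
            raise ValueError(f"no downstream exon found for acceptor {site.acceptor_key}")
        return candidates
    if not site.downstream_exons:
        raise ValueError(f"acceptor {site.acceptor_key} carries no downstream exon")
    return list(site.downstream_exons)


@dataclass(frozen=True)
class AltExonEnrichment:
    a: float  # % alternative among all classified exons
    b: int    # REPAG acceptors entering the test
    c: float  # % alternative among REPAG-downstream exons
    p: float

    @property
    def d(self) -> float:
        """Fold enrichment c/a at 2 decimals (table convention)."""
        return round(self.c / self.a, 2)


def alt_exon_enrichment(
    records: Sequence[ExonUsageRecord],
    repag_sites: Sequence[ThreePrimeSS],
) -> AltExonEnrichment:
    """Alternative-exon enrichment downstream of REPAG acceptors.

    A REPAG acceptor enters the test when at least one of its downstream
    exon candidates was classified; it counts as alternative when any
    candidate is non-constitutive or when the candidates disagree (an
    acceptor feeding several exon forms is alternatively used by
    definition).
    """
    if not records:
        raise ValueError("no classified exons")
    if not repag_sites:
        raise ValueError("empty REPAG site set")
    usage = {(r.gene_id, r.exon): r.is_constitutive for r in records}
    by_exon = {r.exon: r.is_constitutive for r in records}
    n_total = len(records)
    n_alt = sum(not r.is_constitutive for r in records)

    b = 0
    k_alt = 0
    for site in repag_sites:
        candidates = site.downstream_exons
        classified = [
            usage.get((site.gene_id, e), by_exon.get(e))
            for e in candidates
        ]
        classified = [c for c in classified if c is not None]
        if not classified:
            continue
        b += 1
        if len(classified) > 1 or not classified[0]:
            k_alt += 1
    if b == 0:
        raise ValueError("no REPAG acceptor has a classified downstream exon")
    a = 100.0 * n_alt / n_total
    c = 100.0 * k_alt / b
    p = hypergeometric_tail(k_alt, b, n_alt, n_total)
    return AltExonEnrichment(a=a, b=b, c=c, p=p)
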