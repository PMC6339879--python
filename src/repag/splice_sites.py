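"""3' splice-site windows, purine-rich / REPAG classification, matrices.

A 3' splice site (acceptor) window covers the last ``L`` intron bases and the
first ``M`` exon bases, in transcript sense.  Positions are indexed the way
splice-site biology writes them: -1 is the last intron base (the G of the
terminal AG), -2 the A, 0 is the intron-exon junction marker (never a base),
+1 the first exon base.

Two predicates drive the survey:

* *purine-rich*: more than 4 purines (A/G) at positions -10..-3, i.e. at
  least 5 of the 8 bases between the polypyrimidine tract and the 3' AG;
* *REPAG*: a GGG triplet wholly contained in -15..-3 (legal starts
  -15..-5), separating the polypyrimidine tract from the 3' AG.

N bases never satisfy either predicate and are excluded from the percentage
denominators of position matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, IntronRecord
from Bio.Seq import reverse_complement

__all__ = [
    "ThreePrimeSS",
    "PositionMatrix",
    "extract_3ss",
    "classify_purine_rich",
    "detect_repag",
    "deduplicate",
    "build_position_matrix",
    "genome_composition",
]

PURINES = frozenset("AG")

#: purine-rich scan window (inclusive sense positions)
PURINE_WINDOW = (-10, -3)
#: G-tract containment window; the triplet must lie wholly inside
REPAG_WINDOW = (-15, -3)


@dataclass
class ThreePrimeSS:
    """One acceptor with its position-indexed window and classification.

    ``window`` has length L+M; index 0..L-1 maps to sense positions -L..-1,
    index L..L+M-1 to +1..+M.  ``downstream_exons`` accumulates the exon
    intervals (with gene id) fed by this acceptor; deduplication merges the
    links of transcripts sharing the acceptor.
    """

    acceptor_key: tuple[str, str, int]
    window: str
    L: int
    M: int
    gene_id: str | None = None
    downstream_exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.window) != self.L + self.M:
            raise ValueError("window length != L + M")

    def index(self, pos: int) -> int:
        """Map a sense position (-L..-1, +1..+M; 0 illegal) to a window index."""
        if pos == 0 or pos < -self.L or pos > self.M:
            raise IndexError(f"position {pos} outside window -{self.L}..+{self.M}")
        return self.L + pos if pos < 0 else self.L + pos - 1

    def base(self, pos: int) -> str:
        return self.window[self.index(pos)]

    def slice(self, start: int, end: int) -> str:
        """Inclusive slice between two sense positions on the same side of 0."""
        return "".join(self.base(p) for p in range(start, end + 1) if p != 0)

    # classification ------------------------------------------------------

    @property
    def purine_count_10_3(self) -> int:
        return sum(c in PURINES for c in self.slice(*PURINE_WINDOW))

    @property
    def is_purine_rich(self) -> bool:
        return classify_purine_rich(self)

    @property
    def ggg_starts(self) -> list[int]:
        return detect_repag(self)

    @property
    def is_repag(self) -> bool:
        return bool(self.ggg_starts)


def extract_3ss(
    intron: IntronRecord,
    genome: GenomeRecord | None = None,
    L: int = 100,
    M: int = 3,
    exon_downstream: tuple[int, int] | None = None,
) -> ThreePrimeSS:
    """Anchor a 3' SS window at an AG-terminal intron end.

    Introns shorter than ``L`` are N-padded on the 5' side.  The +1..+M exon
    bases come from ``genome`` and the downstream exon interval (defaulting
    to the one recorded on the intron); without a genome or exon they are N.

    Raises ``ValueError`` for a non-AG intron — callers count these
    rejections, they are not part of the scanned set.
    """
    if intron.terminal_dinucleotide != "AG":
        raise ValueError(
            f"intron at {intron.acceptor_key} does not end in AG "
            f"({intron.terminal_dinucleotide})"
        )
    tail = intron.sense_sequence[-L:]
    if len(tail) < L:
        tail = "N" * (L - len(tail)) + tail
    exon = exon_downstream if exon_downstream is not None else intron.downstream_exon
    exon_part = "N" * M
    if genome is not None and exon is not None:
        s, e = exon
        if intron.strand == "+":
            raw = genome.sequence[s - 1 : s - 1 + M]
        else:
            raw = reverse_complement(genome.sequence[max(e - M, 0) : e])
        exon_part = (raw + "N" * M)[:M]
    site = ThreePrimeSS(
        acceptor_key=intron.acceptor_key,
        window=tail + exon_part,
        L=L,
        M=M,
        gene_id=intron.gene_id,
    )
    if exon is not None:
        site.downstream_exons.append(exon)
    return site


def classify_purine_rich(site: ThreePrimeSS) -> bool:
    """More than 4 purines at -10..-3 (boundary: 4 is False, 5 is True)."""
    return site.purine_count_10_3 >= 5


def detect_repag(site: ThreePrimeSS) -> list[int]:
    """All starts p with window[p..p+2] == GGG wholly inside -15..-3.

    Containment is enforced arithmetically (p in -15..-5); overlapping runs
    (GGGG) report every valid start.
    """
    lo, hi = REPAG_WINDOW
    return [
        p
        for p in range(lo, hi - 1)  # p, p+1, p+2 <= hi  =>  p <= hi - 2
        if site.slice(p, p + 2) == "GGG"
    ]


def deduplicate(sites: Iterable[ThreePrimeSS]) -> list[ThreePrimeSS]:
    """One site per acceptor_key, merging downstream-exon links.

    Acceptors shared by several transcripts collapse to a single site; when
    the transcripts disagree on the downstream exon (alternative 3' exons)
    every candidate interval is kept on the retained site.
    """
    by_key: dict[tuple, ThreePrimeSS] = {}
    for site in sites:
        kept = by_key.get(site.acceptor_key)
        if kept is None:
            by_key[site.acceptor_key] = site
        else:
            for exon in site.downstream_exons:
                if exon not in kept.downstream_exons:
                    kept.downstream_exons.append(exon)
    return list(by_key.values())


@dataclass
class PositionMatrix:
    """Per-position A/C/G/T counts and percentages for a set of 3' SS."""

    positions: list[int]
    counts: pd.DataFrame      # index = positions, columns = A,C,G,T
    n_sites: int

    @property
    def percentages(self) -> pd.DataFrame:
        denom = self.counts.sum(axis=1)  # N excluded: only ACGT counted
        return self.counts.div(denom.replace(0, np.nan), axis=0) * 100.0

    @property
    def purine_percentages(self) -> pd.Series:
        pct = self.percentages
        return pct["A"] + pct["G"]

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        pct = self.percentages
        for b in "ACGT":
            df[f"{b}_pct"] = pct[b].round(1)
        df.index.name = "position"
        df.to_csv(path, sep="\t")


def build_position_matrix(
    sites: Sequence[ThreePrimeSS], positions: Sequence[int] | None = None
) -> PositionMatrix:
    """Count A/C/G/T per position over a site set (default range -20..+3)."""
    sites = list(sites)
    if not sites:
        raise ValueError("cannot build a position matrix from zero sites")
    if positions is None:
        positions = [p for p in range(-20, 4) if p != 0]
    positions = [p for p in positions if p != 0]
    counts = pd.DataFrame(0, index=positions, columns=list("ACGT"))
    lengths = {(s.L, s.M) for s in sites}
    if len(lengths) == 1:
        # uniform window shape: vectorized per-position tally
        idx = [sites[0].index(p) for p in positions]
        chars = np.frombuffer(
            "".join(s.window for s in sites).encode(), dtype="S1"
        ).reshape(len(sites), -1)[:, idx]
        for b in "ACGT":
            counts[b] = (chars == b.encode()).sum(axis=0)
    else:
        for site in sites:
            for p in positions:
                c = site.base(p)
                if c in "ACGT":
                    counts.loc[p, c] += 1
    return PositionMatrix(list(positions), counts, len(sites))


def genome_composition(
    genome: GenomeRecord | Iterable[GenomeRecord],
) -> dict[str, float]:
    """Base fractions over {A,C,G,T}, N ignored; fractions sum to 1."""
    records = [genome] if isinstance(genome, GenomeRecord) else list(genome)
    if not records:
        raise ValueError("empty genome")
    totals = {b: 0 for b in "ACGT"}
    for rec in records:
        for b in "ACGT":
            totals[b] += rec.sequence.count(b)
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("genome contains no unambiguous bases")
    return {b: totals[b] / grand for b in "ACGT"}


# ---------------------------------------------------------------------------
# exports


def write_site_table(sites: Iterable[ThreePrimeSS], path: str | Path) -> None:
    cols = ("contig", "strand", "acceptor_coord", "gene", "purine_count",
            "is_purine_rich", "is_repag", "ggg_starts", "window")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            contig, strand, coord = s.acceptor_key
            fh.write(
                f"{contig}\t{strand}\t{coord}\t{s.gene_id or '.'}\t"
                f"{s.purine_count_10_3}\t{int(s.is_purine_rich)}\t"
                f"{int(s.is_repag)}\t{','.join(map(str, s.ggg_starts)) or '.'}\t"
                f"{s.window}\n"
            )


def write_repag_fasta(sites: Iterable[ThreePrimeSS], path: str | Path) -> None:
    """FASTA export of REPAG windows (id = contig:strand:coordinate)."""
    with open(path, "w") as fh:
        for s in sites:
            if s.is_repag:
                contig, strand, coord = s.acceptor_key
                fh.write(f">{contig}:{strand}:{coord}\n{s.window}\n")
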