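"""Synthetic annotated genomes with planted 3' splice-site features.

Every pipeline stage is testable against ground truth: the generator emits a
FASTA + GFF3 pair together with a truth table recording, for every intron
acceptor, whether a purine-rich -10..-3 block was planted, whether and where
a GGG tract was planted in -15..-3, which B-box pentamer was planted and
where its branch adenosine sits, and whether the exon downstream of the
acceptor was made non-constitutive (dropped from a subset of the gene's
transcripts).

Planting is literal and exclusive: background sequence around each acceptor
is rejection-sampled so that non-planted sites never satisfy the purine-rich
predicate, never contain a GGG inside -15..-3, and the last 100 intron bases
contain no incidental B-box pentamer.  Detector output on the emitted genome
therefore equals the truth table exactly (recall and precision 1.0), while
the detected *fractions* remain binomial draws around the configured rates.

Non-planted acceptors receive a pyrimidine-biased -20..-3 block so synthetic
position matrices reproduce the pyrimidine-tract-dominated genome-average
profile of real acceptors.  Exon dropping is the only alternative-splicing
mechanism simulated; the coordinate-pair-based classifier needs no other.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .branchpoint import BBOX_MOTIFS
from .genome_io import GenomeRecord, TranscriptModel

__all__ = [
    "SimulationConfig",
    "AberrantSetConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_aberrant_sets",
]

_MAX_ATTEMPTS = 500


@dataclass
class SimulationConfig:
    """Ground-truth generation parameters.

    Defaults plant a 20% purine-rich acceptor rate with half of those
    carrying a G tract, alternative-exon probabilities of 0.87 downstream of
    G-tract acceptors vs 0.62 elsewhere (the fold observed in the most
    enriched primate genomes), and distal-only branch points for G-tract
    acceptors versus mostly proximal ones elsewhere.
    """

    seed: int = 0
    n_genes: int = 200
    transcripts_per_gene: tuple[int, int] = (2, 4)      # uniform inclusive
    exons_per_transcript: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (60, 180)
    intron_length: tuple[int, int] = (140, 400)          # min >= 120
    base_fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
    )
    pyrimidine_bias: float = 0.8      # C/T share of non-planted -20..-3 bases
    purine_rich_fraction: float = 0.2
    repag_prob_given_purine_rich: float = 0.5
    bbox_prob: float = 0.9            # probability an acceptor gets a B-box
    bbox_motif_weights: dict[str, float] = field(
        default_factory=lambda: {"CTAAC": 0.35, "CTGAC": 0.25, "CTCAC": 0.18,
                                 "TTAAC": 0.12, "CTGAT": 0.10}
    )
    bbox_proximal_weight: float = 0.85        # non-G-tract acceptors
    bbox_proximal_weight_repag: float = 0.0   # G-tract acceptors: distal only
    # BP-A placement windows; proximal capped at -17 so the pentamer
    # (BP-A-3 .. BP-A+1) never enters the engineered -15..-3 region
    proximal_bp_window: tuple[int, int] = (-24, -17)
    distal_bp_window: tuple[int, int] = (-97, -25)
    alt_prob_repag: float = 0.87
    alt_prob_other: float = 0.62
    minus_strand_prob: float = 0.5
    spacer_length: int = 100
    genes_per_contig: int = 100
    contig_prefix: str = "chrS"

    def validate(self) -> None:
        probs = [self.pyrimidine_bias, self.purine_rich_fraction,
                 self.repag_prob_given_purine_rich, self.bbox_prob,
                 self.bbox_proximal_weight, self.bbox_proximal_weight_repag,
                 self.alt_prob_repag, self.alt_prob_other,
                 self.minus_strand_prob]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.base_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("base fractions must sum to 1")
        if self.intron_length[0] < 120:
            raise ValueError("minimum intron length must be >= 120")
        if self.intron_length[0] < -self.distal_bp_window[0] + 4:
            raise ValueError("introns too short for the distal B-box window")
        if set(self.bbox_motif_weights) - set(BBOX_MOTIFS):
            raise ValueError("unknown B-box motif in weights")


@dataclass
class SimulatedGenome:
    genomes: list[GenomeRecord]
    transcripts: list[TranscriptModel]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gff = outdir / "annotation.gff3"
        truth = outdir / "truth.tsv"
        with open(fasta, "w") as fh:
            for g in self.genomes:
                fh.write(f">{g.contig_id}\n")
                for i in range(0, g.length, 70):
                    fh.write(g.sequence[i : i + 70] + "\n")
        _write_gff3(self.transcripts, self.genomes, gff)
        self.truth.to_csv(truth, sep="\t", index=False)
        return {"fasta": fasta, "gff3": gff, "truth": truth}

    def file_hashes(self, outdir: str | Path) -> dict[str, str]:
        paths = self.write(outdir)
        return {k: hashlib.sha256(p.read_bytes()).hexdigest()
                for k, p in paths.items()}


def _write_gff3(
    transcripts: Sequence[TranscriptModel],
    genomes: Sequence[GenomeRecord],
    path: Path,
) -> None:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.contig_id} 1 {g.length}\n")
        for gene_id, txs in by_gene.items():
            start = min(tx.exons[0][0] for tx in txs)
            end = max(tx.exons[-1][1] for tx in txs)
            contig, strand = txs[0].contig_id, txs[0].strand
            fh.write(f"{contig}\trepag_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={gene_id}\n")
            for tx in txs:
                ts, te = tx.exons[0][0], tx.exons[-1][1]
                fh.write(f"{contig}\trepag_sim\tmRNA\t{ts}\t{te}\t.\t{strand}\t.\t"
                         f"ID={tx.transcript_id};Parent={gene_id}\n")
                for i, (a, b) in enumerate(tx.exons, 1):
                    fh.write(
                        f"{contig}\trepag_sim\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                        f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# sequence engineering


def _draw(rng: np.random.Generator, n: int, fractions: dict[str, float]) -> list[str]:
    bases = list("ACGT")
    p = np.array([fractions[b] for b in bases])
    return list(rng.choice(bases, size=n, p=p / p.sum()))


def _draw_biased(
    rng: np.random.Generator, n: int, fractions: dict[str, float],
    py_share: float,
) -> list[str]:
    """Bases with a fixed pyrimidine share, C:T and A:G in background ratio."""
    out = []
    c, t = fractions["C"], fractions["T"]
    a, g = fractions["A"], fractions["G"]
    for _ in range(n):
        if rng.random() < py_share:
            out.append("C" if rng.random() < c / (c + t) else "T")
        else:
            out.append("A" if rng.random() < a / (a + g) else "G")
    return out


def _engineer_tail(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    is_pr: bool,
    ggg_start: int | None,
    bbox: tuple[str, int] | None,  # (motif, bp_a sense position)
) -> str:
    """Last 100 intron bases satisfying the planted truth exactly."""
    fr = cfg.base_fractions
    for _ in range(_MAX_ATTEMPTS):
        tail = _draw(rng, 100, fr)
        # pyrimidine-tract background over -20..-3
        tail[80:98] = _draw_biased(rng, 18, fr, cfg.pyrimidine_bias)
        if is_pr:
            # purine block at -10..-3, >=5 purines enforced by verification
            tail[90:98] = _draw_biased(rng, 8, fr, 1.0 - 0.85)
        tail[98:100] = ["A", "G"]
        if ggg_start is not None:
            i = 100 + ggg_start
            tail[i : i + 3] = ["G", "G", "G"]
        if bbox is not None:
            motif, bp_a = bbox
            i = 100 + bp_a - 3
            tail[i : i + 5] = list(motif)
        s = "".join(tail)
        # verification: detector output must equal the planted truth
        purines = sum(c in "AG" for c in s[90:98])
        if (purines >= 5) != is_pr:
            continue
        ggg = [p for p in range(-15, -4) if s[100 + p : 100 + p + 3] == "GGG"]
        if ggg != ([ggg_start] if ggg_start is not None else []):
            continue
        hits = [
            (s[i : i + 5], i - 100)
            for i in range(96)
            if s[i : i + 5] in BBOX_MOTIFS
        ]
        want = [(bbox[0], bbox[1] - 3)] if bbox is not None else []
        if hits != want:
            continue
        return s
    raise RuntimeError("tail engineering failed to converge; check config")


# ---------------------------------------------------------------------------
# genome assembly


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate a synthetic annotated genome with a per-acceptor truth table.

    Identical seed + config give byte-identical output files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fr = config.base_fractions

    contig_parts: list[str] = []
    contig_seqs: list[str] = []
    contig_id = f"{config.contig_prefix}1"
    contig_index = 1
    genes_on_contig = 0
    offset = 0
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    genomes: list[GenomeRecord] = []

    def flush_contig() -> None:
        nonlocal contig_parts, offset, genes_on_contig, contig_index, contig_id
        if contig_parts:
            genomes.append(GenomeRecord(contig_id, "".join(contig_parts)))
        contig_parts = []
        offset = 0
        genes_on_contig = 0
        contig_index += 1
        contig_id = f"{config.contig_prefix}{contig_index}"

    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        n_tx = int(rng.integers(config.transcripts_per_gene[0],
                                config.transcripts_per_gene[1] + 1))
        n_ex = int(rng.integers(config.exons_per_transcript[0],
                                config.exons_per_transcript[1] + 1))
        exon_lens = [int(rng.integers(*config.exon_length)) for _ in range(n_ex)]
        intron_lens = [int(rng.integers(*config.intron_length))
                       for _ in range(n_ex - 1)]
        strand = "-" if rng.random() < config.minus_strand_prob else "+"

        # per-intron planted features
        intron_truth = []
        intron_seqs = []
        for li in intron_lens:
            is_pr = rng.random() < config.purine_rich_fraction
            ggg_start = None
            if is_pr and rng.random() < config.repag_prob_given_purine_rich:
                ggg_start = int(rng.integers(-15, -4))  # -15..-5
            bbox = None
            if rng.random() < config.bbox_prob:
                motifs = list(config.bbox_motif_weights)
                w = np.array([config.bbox_motif_weights[m] for m in motifs])
                motif = str(rng.choice(motifs, p=w / w.sum()))
                prox_w = (config.bbox_proximal_weight_repag
                          if ggg_start is not None
                          else config.bbox_proximal_weight)
                win = (config.proximal_bp_window
                       if rng.random() < prox_w else config.distal_bp_window)
                bp_a = int(rng.integers(win[0], win[1] + 1))
                bbox = (motif, bp_a)
            tail = _engineer_tail(rng, config, is_pr, ggg_start, bbox)
            head = "".join(_draw(rng, li - 100, fr))
            intron_seqs.append(head + tail)
            intron_truth.append(
                {"is_purine_rich": is_pr, "ggg_start": ggg_start, "bbox": bbox}
            )

        # sense-space layout
        exon_seqs = ["".join(_draw(rng, n, fr)) for n in exon_lens]
        sense_parts = []
        exon_sense: list[tuple[int, int]] = []
        pos = 1
        for j in range(n_ex):
            exon_sense.append((pos, pos + exon_lens[j] - 1))
            sense_parts.append(exon_seqs[j])
            pos += exon_lens[j]
            if j < n_ex - 1:
                sense_parts.append(intron_seqs[j])
                pos += intron_lens[j]
        sense_seq = "".join(sense_parts)
        B = len(sense_seq)

        # alternative-exon decisions (non-first exons only; realization
        # drops the exon from a proper subset of transcripts)
        alt = [False] * n_ex
        for j in range(1, n_ex):
            upstream = intron_truth[j - 1]
            p_alt = (config.alt_prob_repag if upstream["ggg_start"] is not None
                     else config.alt_prob_other)
            if n_tx >= 2 and rng.random() < p_alt:
                alt[j] = True

        # placement
        if genes_on_contig >= config.genes_per_contig:
            flush_contig()
        spacer = "".join(_draw(rng, config.spacer_length, fr))
        contig_parts.append(spacer)
        offset += config.spacer_length
        block = sense_seq if strand == "+" else reverse_complement(sense_seq)
        gene_offset = offset
        contig_parts.append(block)
        offset += B
        genes_on_contig += 1

        def to_ref(s1: int, s2: int) -> tuple[int, int]:
            if strand == "+":
                return (gene_offset + s1, gene_offset + s2)
            return (gene_offset + B - s2 + 1, gene_offset + B - s1 + 1)

        exon_ref = [to_ref(a, b) for (a, b) in exon_sense]

        # transcripts: drop each alternative exon from a proper random subset
        keep = np.ones((n_tx, n_ex), dtype=bool)
        for j in range(1, n_ex):
            if alt[j]:
                m = int(rng.integers(1, n_tx))  # 1 .. n_tx-1 transcripts drop it
                drop = rng.choice(n_tx, size=m, replace=False)
                keep[drop, j] = False
        for ti in range(n_tx):
            exons = tuple(exon_ref[j] for j in range(n_ex) if keep[ti, j])
            transcripts.append(
                TranscriptModel(gene_id, f"{gene_id}.t{ti + 1}", contig_id,
                                strand, exons)
            )

        # truth rows, one per acceptor (intron j feeds exon j+1)
        for j, info in enumerate(intron_truth):
            acceptor_sense = exon_sense[j + 1][0] - 1  # last intron base
            coord = to_ref(acceptor_sense, acceptor_sense)[0]
            bbox = info["bbox"]
            truth_rows.append(
                {"contig": contig_id, "strand": strand,
                 "acceptor_coord": coord, "gene_id": gene_id,
                 "is_purine_rich": info["is_purine_rich"],
                 "is_repag": info["ggg_start"] is not None,
                 "ggg_start": info["ggg_start"] if info["ggg_start"] is not None
                              else pd.NA,
                 "bbox_motif": bbox[0] if bbox else pd.NA,
                 "bp_a_position": bbox[1] if bbox else pd.NA,
                 "downstream_exon_start": exon_ref[j + 1][0],
                 "downstream_exon_end": exon_ref[j + 1][1],
                 "downstream_constitutive": not alt[j + 1]}
            )

    flush_contig()
    truth = pd.DataFrame(truth_rows)
    return SimulatedGenome(genomes, transcripts, truth, config)


# ---------------------------------------------------------------------------
# aberrant / canonical acceptor window sets


@dataclass
class AberrantSetConfig:
    """Planted triplet rates for paired aberrant vs canonical acceptor sets.

    Default rates emulate the composition reported for splicing-factor
    mutant tumours: G tracts near 5% of aberrant sites at roughly twice the
    canonical rate, other purine triplets enriched, pyrimidine triplets
    depleted, and two purine triplets absent from the canonical set
    entirely (their fold is then undefined).
    """

    seed: int = 0
    n_aberrant: int = 860
    n_canonical: int = 860
    window_length: int = 20
    pyrimidine_bias: float = 0.8
    base_fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
    )
    rates_aberrant: dict[str, float] = field(
        default_factory=lambda: {
            "GGG": 0.048, "AAA": 0.06, "GAA": 0.05, "GAG": 0.04, "AGA": 0.04,
            "GGA": 0.03, "AGG": 0.01, "AAG": 0.01,
            "CCC": 0.03, "TTT": 0.04, "CTT": 0.03, "TCT": 0.03,
        }
    )
    rates_canonical: dict[str, float] = field(
        default_factory=lambda: {
            "GGG": 0.022, "AAA": 0.02, "GAA": 0.015, "GAG": 0.012, "AGA": 0.012,
            "GGA": 0.01, "AGG": 0.0, "AAG": 0.0,
            "CCC": 0.06, "TTT": 0.09, "CTT": 0.07, "TCT": 0.06,
        }
    )


def _homoclass_triplets(s: str) -> set[str]:
    """Homopurine/homopyrimidine triplets wholly inside -15..-3 of a window."""
    region = s[len(s) - 15 : len(s) - 2]
    out = set()
    for i in range(len(region) - 2):
        t = region[i : i + 3]
        if set(t) <= set("AG") or set(t) <= set("CT"):
            out.add(t)
    return out


def _class_constrained(
    rng: np.random.Generator, n: int, fractions: dict[str, float]
) -> list[str]:
    """Bases with no 3 consecutive same-class (purine/pyrimidine) characters.

    Used for the background -15..-3 region of the aberrant/canonical window
    sets so that homoclass triplets there are exactly the planted ones.
    """
    c, t = fractions["C"], fractions["T"]
    a, g = fractions["A"], fractions["G"]
    classes: list[bool] = []  # True = pyrimidine
    out: list[str] = []
    for _ in range(n):
        py = bool(rng.random() < 0.5)
        if len(classes) >= 2 and classes[-1] == classes[-2]:
            py = not classes[-1]
        classes.append(py)
        if py:
            out.append("C" if rng.random() < c / (c + t) else "T")
        else:
            out.append("A" if rng.random() < a / (a + g) else "G")
    return out


def _sample_window(
    rng: np.random.Generator, cfg: AberrantSetConfig, rates: dict[str, float]
) -> tuple[str, str | None]:
    triplets = list(rates)
    p = np.array([rates[t] for t in triplets], dtype=float)
    if p.sum() > 1:
        raise ValueError("triplet planting rates sum to more than 1")
    L = cfg.window_length
    for _ in range(_MAX_ATTEMPTS):
        w = _draw_biased(rng, L, cfg.base_fractions, cfg.pyrimidine_bias)
        w[L - 15 : L - 2] = _class_constrained(rng, 13, cfg.base_fractions)
        w[-2:] = ["A", "G"]
        u = rng.random()
        planted = None
        acc = 0.0
        for t, r in zip(triplets, p):
            acc += r
            if u < acc:
                planted = t
                break
        if planted is None:
            return "".join(w), None
        start = int(rng.integers(-15, -4))  # -15..-5
        w[L + start : L + start + 3] = list(planted)
        s = "".join(w)
        if _homoclass_triplets(s) == {planted}:
            return s, planted
    raise RuntimeError("window sampling failed to converge")


def simulate_aberrant_sets(
    config: AberrantSetConfig,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Paired aberrant/canonical window sets with known per-triplet truth.

    Windows are fixed-length strings whose last character is position -1.
    Each site carries at most one planted triplet type; background windows
    are rejection-sampled free of homopurine/homopyrimidine triplets in
    -15..-3, so the recovered per-triplet ratios estimate the configured
    rate ratios binomially.  The truth frame lists both rates and their
    ratio (NaN where the canonical rate is zero).
    """
    rng = np.random.default_rng(config.seed)
    aberrant = [
        _sample_window(rng, config, config.rates_aberrant)[0]
        for _ in range(config.n_aberrant)
    ]
    canonical = [
        _sample_window(rng, config, config.rates_canonical)[0]
        for _ in range(config.n_canonical)
    ]
    triplets = sorted(set(config.rates_aberrant) | set(config.rates_canonical))
    truth = pd.DataFrame(
        {
            "triplet": triplets,
            "rate_aberrant": [config.rates_aberrant.get(t, 0.0) for t in triplets],
            "rate_canonical": [config.rates_canonical.get(t, 0.0) for t in triplets],
        }
    )
    truth["true_ratio"] = truth.rate_aberrant / truth.rate_canonical.replace(
        0.0, np.nan
    )
    return aberrant, canonical, truth
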