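"""Per-species survey orchestration and the cross-species cohort stage.

``run_species`` executes the whole single-genome analysis: intron
derivation, AG filtering, acceptor-window extraction and deduplication,
purine-rich and G-tract classification, position matrices, exon-usage
classification with the alternative-exon enrichment test, and the
branch-point positional analysis.  ``run_cohort`` combines many species
summaries into the trendline-normalized enrichment index.

Every run emits a :class:`RunManifest` (inputs, parameters, per-stage row
counts) so deterministic stages can be reproduced byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import branchpoint as bp
from . import enrichment_stats as es
from . import exon_usage as eu
from . import genome_io as gio
from . import splice_sites as ss

__all__ = ["RunManifest", "SpeciesBundle", "run_species", "run_cohort"]


def _version() -> str:
    try:
        return _pkg_version("repag")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


@dataclass
class RunManifest:
    inputs: dict[str, str]
    parameters: dict[str, object]
    seed: int | None
    stage_counts: dict[str, int] = field(default_factory=dict)
    tool_version: str = field(default_factory=_version)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


@dataclass
class SpeciesBundle:
    """All per-species outputs of one survey run."""

    species: str
    summary: es.SpeciesSummary
    sites: list[ss.ThreePrimeSS]
    purine_rich: list[ss.ThreePrimeSS]
    repag: list[ss.ThreePrimeSS]
    matrix_all: ss.PositionMatrix
    matrix_purine_rich: ss.PositionMatrix | None
    matrix_repag: ss.PositionMatrix | None
    exon_records: list[eu.ExonUsageRecord]
    alt_enrichment: eu.AltExonEnrichment | None
    bbox_occupancy: bp.WindowOccupancy | None
    manifest: RunManifest

    def summary_row(self) -> dict[str, object]:
        s = self.summary
        row = {
            "species": s.species, "group": s.group,
            "total_3ss": s.total_3ss,
            "purine_rich": s.purine_rich_count,
            "purine_rich_pct": round(s.purine_rich_pct, 1),
            "repag": s.repag_count,
            "repag_pct_of_purine_rich": round(s.repag_pct_of_purine_rich, 1),
            "genome_g_pct": round(s.genome_g_pct, 1),
        }
        if self.alt_enrichment is not None:
            e = self.alt_enrichment
            row.update({"a": round(e.a, 1), "b": e.b, "c": round(e.c, 1),
                        "d": f"{e.d:.2f}", "p": f"{e.p:.2e}"})
        return row

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ss.write_site_table(self.sites, outdir / "sites.tsv")
        ss.write_repag_fasta(self.repag, outdir / "repag_windows.fa")
        self.matrix_all.to_tsv(outdir / "matrix_all.tsv")
        if self.matrix_purine_rich is not None:
            self.matrix_purine_rich.to_tsv(outdir / "matrix_purine_rich.tsv")
        if self.matrix_repag is not None:
            self.matrix_repag.to_tsv(outdir / "matrix_repag.tsv")
        pd.DataFrame(
            [{"gene": r.gene_id, "start": r.exon[0], "end": r.exon[1],
              "n_transcripts": r.n_transcripts_of_gene,
              "n_containing": r.n_transcripts_containing,
              "constitutive": int(r.is_constitutive)}
             for r in self.exon_records]
        ).to_csv(outdir / "exon_usage.tsv", sep="\t", index=False)
        pd.DataFrame([self.summary_row()]).to_csv(
            outdir / "summary.tsv", sep="\t", index=False
        )
        if self.bbox_occupancy is not None:
            self.bbox_occupancy.table.to_csv(outdir / "bbox_occupancy.tsv", sep="\t")
        self.manifest.write(outdir / "manifest.json")


def run_species(
    parsed: Sequence[tuple[gio.GenomeRecord, Sequence[gio.TranscriptModel]]],
    species: str = "species",
    group: str = "unassigned",
    L: int = 100,
    M: int = 3,
    repag_within_purine_rich: bool = True,
    input_paths: Mapping[str, str] | None = None,
) -> SpeciesBundle:
    """Single-genome survey over parsed (contig, transcripts) pairs.

    ``repag_within_purine_rich`` reproduces the two-stage search (G tracts
    looked for in the purine-rich output only); disabling it scans every AG
    acceptor for sensitivity analysis.
    """
    genomes = [g for g, _ in parsed]
    if not any(txs for _, txs in parsed):
        raise ValueError("no annotated transcripts in input")
    all_sites: list[ss.ThreePrimeSS] = []
    n_introns = 0
    n_non_ag = 0
    transcripts: list[gio.TranscriptModel] = []
    for genome, txs in parsed:
        for tx in txs:
            transcripts.append(tx)
            if tx.n_exons < 2:
                continue
            introns = gio.derive_introns(tx, genome)
            n_introns += len(introns)
            kept, rejected = gio.ag_introns(introns)
            n_non_ag += rejected
            for it in kept:
                all_sites.append(ss.extract_3ss(it, genome, L=L, M=M))
    if not all_sites:
        raise ValueError("no AG-terminal introns found")
    sites = ss.deduplicate(all_sites)
    purine_rich = [s for s in sites if s.is_purine_rich]
    repag_pool = purine_rich if repag_within_purine_rich else sites
    repag = [s for s in repag_pool if s.is_repag]

    comp = ss.genome_composition(genomes)
    summary = es.SpeciesSummary(
        species=species, group=group, total_3ss=len(sites),
        purine_rich_count=len(purine_rich), repag_count=len(repag),
        genome_g_pct=100.0 * comp["G"],
    )

    matrix_all = ss.build_position_matrix(sites)
    matrix_pr = ss.build_position_matrix(purine_rich) if purine_rich else None
    matrix_repag = ss.build_position_matrix(repag) if repag else None

    by_gene = eu.group_by_gene(transcripts)
    exon_records = eu.classify_exons(by_gene)
    alt = None
    if repag and exon_records:
        try:
            alt = eu.alt_exon_enrichment(exon_records, repag)
        except ValueError:
            alt = None

    occupancy = None
    control = [s for s in sites if not s.is_repag]
    if repag and control:
        occupancy = bp.window_occupancy(
            bp.positional_distribution(repag, label="repag"),
            bp.positional_distribution(control, label="control"),
        )

    manifest = RunManifest(
        inputs=dict(input_paths or {}),
        parameters={"L": L, "M": M, "species": species,
                    "repag_within_purine_rich": repag_within_purine_rich,
                    "purine_window": ss.PURINE_WINDOW,
                    "repag_window": ss.REPAG_WINDOW},
        seed=None,
        stage_counts={
            "transcripts": len(transcripts),
            "introns": n_introns,
            "non_ag_introns_excluded": n_non_ag,
            "unique_acceptors": len(sites),
            "purine_rich": len(purine_rich),
            "repag": len(repag),
            "classified_exons": len(exon_records),
        },
    )
    return SpeciesBundle(
        species=species, summary=summary, sites=sites,
        purine_rich=purine_rich, repag=repag,
        matrix_all=matrix_all, matrix_purine_rich=matrix_pr,
        matrix_repag=matrix_repag, exon_records=exon_records,
        alt_enrichment=alt, bbox_occupancy=occupancy, manifest=manifest,
    )


def run_cohort(
    summaries: Sequence[es.SpeciesSummary],
    fungal_group: str = "fungi",
    min_purine_rich: int = 100,
) -> tuple[pd.DataFrame, es.TrendlineFit, pd.DataFrame]:
    """Cross-species normalization: trendline fit and enrichment indices.

    Species at or below ``min_purine_rich`` purine-rich acceptors are
    filtered out (strict >).  Returns (per-species index table, fit,
    per-group mean +/- SEM).
    """
    kept = [s for s in summaries if s.purine_rich_count > min_purine_rich]
    if len(kept) < 3:
        raise ValueError("cohort needs at least 3 species above the threshold")
    fungal = [s.species for s in kept if s.group == fungal_group]
    if not fungal:
        raise ValueError(f"no species in the reference group {fungal_group!r}")
    fit = es.fit_trendline(
        [(s.genome_g_pct, s.repag_pct_of_purine_rich) for s in kept]
    )
    indices = es.enrichment_index(kept, fit, fungal)
    table = pd.DataFrame(
        [{"species": i.species, "group": i.group,
          "raw": i.raw, "normalized": i.normalized} for i in indices]
    )
    groups = es.group_index_stats(indices)
    return table, fit, groups
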