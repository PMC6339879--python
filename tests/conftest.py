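"""Shared fixtures: toy acceptor windows and a small simulated genome."""

from __future__ import annotations

import pytest

from repag import genome_io as gio
from repag import pipeline as pl
from repag.simulate import SimulationConfig, simulate_genome
from repag.splice_sites import ThreePrimeSS


def make_site(intron_tail: str, exon: str = "GTT", key=("c", "+", 100)) -> ThreePrimeSS:
    """Acceptor window from an intron-tail string (last base = position -1)."""
    return ThreePrimeSS(
        acceptor_key=key, window=intron_tail + exon,
        L=len(intron_tail), M=len(exon),
    )


def make_bp_site(bp_positions, key=("c", "+", 100), motif="CTGAC") -> ThreePrimeSS:
    """100-nt intron tail, all-C background, pentamers planted at given BP-As."""
    tail = ["C"] * 100
    for bp in bp_positions:
        i = 100 + bp - 3
        tail[i : i + 5] = list(motif)
    tail[98:100] = ["A", "G"]
    return make_site("".join(tail), key=key)


@pytest.fixture(scope="session")
def sim_genome():
    """Small synthetic genome with planted ground truth (fixed seed)."""
    return simulate_genome(SimulationConfig(seed=7, n_genes=80))


@pytest.fixture(scope="session")
def sim_files(sim_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return sim_genome.write(outdir)


@pytest.fixture(scope="session")
def sim_parsed(sim_files):
    return gio.parse_gff3_fasta(sim_files["gff3"], sim_files["fasta"])


@pytest.fixture(scope="session")
def sim_bundle(sim_parsed):
    return pl.run_species(sim_parsed, species="sim", group="test")
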