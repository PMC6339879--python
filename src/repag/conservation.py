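"""Cross-species conservation of G tracts relative to the 3' AG.

Conservation of a REPAG is estimated from a multiple alignment of the 3'
splice-site region (e.g. a Multiz extract): the fraction of aligned species
whose row still contains a GGG within the columns aligned to the reference
-15..-3 window, normalized to the fraction retaining the 3' AG itself
(level = 1.0).  Presence is scored anywhere in the aligned window rather
than column-exact, because a conserved G tract may sit in shifted context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from scipy import stats

__all__ = [
    "AlignedSSBlock",
    "motif_conservation",
    "compare_species_sets",
]


@dataclass
class AlignedSSBlock:
    """One aligned 3' SS region: equal-length gapped rows keyed by species.

    ``junction_col`` is the alignment column holding the reference row's -1
    base (the G of the terminal AG).  By default the reference row's last
    ungapped column — the natural anchor for blocks extracted to end at the
    acceptor.
    """

    reference: str
    rows: dict[str, str]
    junction_col: int | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("aligned rows differ in length")
        if self.reference not in self.rows:
            raise ValueError(f"reference species {self.reference!r} absent")
        self.rows = {k: v.upper() for k, v in self.rows.items()}
        if self.junction_col is None:
            ref = self.rows[self.reference]
            ungapped = [i for i, c in enumerate(ref) if c != "-"]
            if not ungapped:
                raise ValueError("reference row is all gaps")
            self.junction_col = ungapped[-1]
        if self.rows[self.reference][self.junction_col] == "-":
            raise ValueError("reference row gapped at the junction column")

    @classmethod
    def from_fasta(cls, path: str | Path, reference: str,
                   junction_col: int | None = None) -> "AlignedSSBlock":
        aln = AlignIO.read(str(path), "fasta")
        return cls(reference, {r.id: str(r.seq) for r in aln}, junction_col)

    @classmethod
    def from_maf(cls, path: str | Path, reference: str) -> list["AlignedSSBlock"]:
        blocks = []
        for aln in AlignIO.parse(str(path), "maf"):
            rows = {r.id.split(".")[0]: str(r.seq) for r in aln}
            blocks.append(cls(reference, rows))
        return blocks

    # column arithmetic ---------------------------------------------------

    def reference_columns(self, start: int, end: int) -> list[int]:
        """Alignment columns of reference sense positions start..end (< 0).

        Position -1 is the junction column; counting walks left over the
        reference row's ungapped columns, so reference gaps never enter the
        window.
        """
        ref = self.rows[self.reference]
        ungapped = [i for i in range(self.junction_col + 1) if ref[i] != "-"]
        # ungapped[-1] is position -1, ungapped[-2] is -2, ...
        cols = []
        for pos in range(start, end + 1):
            if pos >= 0:
                raise ValueError("only intron-side (negative) positions are anchored")
            if -pos > len(ungapped):
                raise ValueError(f"reference row too short for position {pos}")
            cols.append(ungapped[len(ungapped) + pos])
        return cols


def motif_conservation(
    block: AlignedSSBlock,
    window: tuple[int, int] = (-15, -3),
) -> tuple[float, float, float]:
    """(repag_freq, ag_freq, normalized) over the species of one block.

    repag_freq: fraction of species whose row contains GGG anywhere within
    the column span aligned to the reference window (gaps dropped before
    matching, so a motif shifted by gap columns still scores).
    ag_freq: fraction with AG column-exact at the junction (-2, -1).
    normalized = repag_freq / ag_freq; NaN (unavailable) when ag_freq = 0.
    """
    if len(block.rows) < 2:
        raise ValueError("need at least 2 species rows")
    win_cols = block.reference_columns(*window)
    lo, hi = min(win_cols), max(win_cols)
    ag_cols = block.reference_columns(-2, -1)
    n = len(block.rows)
    n_ggg = 0
    n_ag = 0
    for row in block.rows.values():
        segment = row[lo : hi + 1].replace("-", "")
        if "GGG" in segment:
            n_ggg += 1
        if row[ag_cols[0]] + row[ag_cols[1]] == "AG":
            n_ag += 1
    repag_freq = n_ggg / n
    ag_freq = n_ag / n
    normalized = repag_freq / ag_freq if ag_freq > 0 else float("nan")
    return repag_freq, ag_freq, normalized


def compare_species_sets(
    set_a: Sequence[float],
    set_b: Sequence[float],
    paired: bool = False,
) -> float:
    """Two-sided t-test p between two lists of normalized conservation levels.

    Paired when the caller supplies true pairing (requires equal sizes),
    unpaired Student's t otherwise.  Degenerate zero-variance inputs resolve
    to p=1 for identical sets and p=0 for fully separated constants.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both sets")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal sizes")
        d = a - b
        if np.all(d == d[0]):
            return 1.0 if d[0] == 0 else 0.0
        return float(stats.ttest_rel(a, b).pvalue)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
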