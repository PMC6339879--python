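"""Branch-point (B-box) pentamer scanning and positional analysis.

The branch-point adenosine sits inside a pentamer ("B-box") that base-pairs
with U2 snRNA.  The five highest-affinity/most-abundant pentamers are
scanned in the last 100 nt of each intron:

    CTAAC  CTGAC  CTCAC  TTAAC  CTGAT

All five carry the branch adenosine as their fourth base, so a hit starting
at sense position p has its BP-A at p+3.

Positional analyses compare G-tract (REPAG) acceptors against a control set
(by default all non-REPAG AG acceptors): per-position BP-A distributions,
occupancy of the proximal (-24..-4), AG-exclusion (-7..-5) and distal
(-97..-25) windows, per-motif over-representation, and the association of
BP distance with alternative downstream exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import hypergeometric_lower_tail, hypergeometric_tail
from .splice_sites import ThreePrimeSS

__all__ = [
    "BBOX_MOTIFS",
    "BBoxHit",
    "PositionalDistribution",
    "WindowOccupancy",
    "scan_bboxes",
    "positional_distribution",
    "window_occupancy",
    "motif_overrepresentation",
    "bp_distance_vs_alt_exon",
]

BBOX_MOTIFS = ("CTAAC", "CTGAC", "CTCAC", "TTAAC", "CTGAT")

#: scan region (sense positions, inclusive)
SCAN_WINDOW = (-100, -1)
PROXIMAL_WINDOW = (-24, -4)
EXCLUSION_WINDOW = (-7, -5)
DISTAL_WINDOW = (-97, -25)


@dataclass(frozen=True)
class BBoxHit:
    acceptor_key: tuple[str, str, int]
    motif: str
    start: int  # sense position of the pentamer's first base

    def __post_init__(self) -> None:
        if self.motif not in BBOX_MOTIFS:
            raise ValueError(f"{self.motif} is not one of the five B-box pentamers")

    @property
    def bp_a_position(self) -> int:
        """The branch adenosine: fourth base of every pentamer."""
        return self.start + 3


def scan_bboxes(
    site: ThreePrimeSS, motifs: Sequence[str] = BBOX_MOTIFS
) -> list[BBoxHit]:
    """All pentamer occurrences wholly inside the last 100 intron bases."""
    lo, hi = SCAN_WINDOW
    lo = max(lo, -site.L)
    region = site.slice(lo, hi)
    hits = []
    for i in range(len(region) - 4):
        penta = region[i : i + 5]
        if penta in motifs:
            hits.append(BBoxHit(site.acceptor_key, penta, lo + i))
    return hits


def _select_bp(hits: list[BBoxHit], selection: str) -> list[int]:
    """BP-A positions to credit for one site under the configured rule."""
    if not hits:
        return []
    if selection == "nearest":
        # lariat-proximal convention: the hit closest to the 3' AG
        return [max(h.bp_a_position for h in hits)]
    if selection == "all":
        return [h.bp_a_position for h in hits]
    raise ValueError(f"unknown selection rule {selection!r}")


@dataclass
class PositionalDistribution:
    """Per-position BP-A counts/fractions over sense positions -100..-1."""

    positions: np.ndarray           # -100..-1
    counts: np.ndarray              # BP-A credited per position
    n_sites: int                    # all sites in the set
    n_sites_with_hit: int
    label: str = ""

    def fractions(self, denominator: str = "all_sites") -> np.ndarray:
        if denominator == "all_sites":
            return self.counts / max(self.n_sites, 1)
        if denominator == "with_hit":
            return self.counts / max(self.n_sites_with_hit, 1)
        raise ValueError(f"unknown denominator {denominator!r}")

    def window_count(self, window: tuple[int, int]) -> int:
        lo, hi = window
        mask = (self.positions >= lo) & (self.positions <= hi)
        return int(self.counts[mask].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "count": self.counts,
             "fraction_all_sites": self.fractions("all_sites"),
             "fraction_with_hit": self.fractions("with_hit")}
        )


def positional_distribution(
    sites: Sequence[ThreePrimeSS],
    selection: str = "nearest",
    label: str = "",
) -> PositionalDistribution:
    """Distribution of BP-A positions over a site set.

    ``selection='nearest'`` credits each site's lariat-proximal hit only
    (per-position fractions then sum to <= 1); ``'all'`` credits every hit.
    Sites with no hit still count in the ``all_sites`` denominator.
    """
    if not sites:
        raise ValueError("empty site set")
    positions = np.arange(SCAN_WINDOW[0], SCAN_WINDOW[1] + 1)
    counts = np.zeros(positions.size, dtype=int)
    with_hit = 0
    for site in sites:
        hits = scan_bboxes(site)
        if hits:
            with_hit += 1
        for bp in _select_bp(hits, selection):
            counts[bp - SCAN_WINDOW[0]] += 1
    return PositionalDistribution(positions, counts, len(sites), with_hit, label)


@dataclass
class WindowOccupancy:
    """Occupancy of the proximal/exclusion/distal BP windows, set vs control."""

    table: pd.DataFrame  # rows = windows; occupancy fractions and p-values

    def occupancy(self, window: str, which: str = "set") -> float:
        return float(self.table.loc[window, f"{which}_occupancy"])


def window_occupancy(
    repag_dist: PositionalDistribution,
    control_dist: PositionalDistribution,
    windows: Mapping[str, tuple[int, int]] | None = None,
) -> WindowOccupancy:
    """Per-window BP-A occupancy and hypergeometric p vs the control set.

    Depletion (lower tail) is tested in the proximal and exclusion windows,
    enrichment (upper tail) in the distal window, matching the direction of
    the biological question; both tails are reported.
    """
    if windows is None:
        windows = {"proximal": PROXIMAL_WINDOW, "exclusion": EXCLUSION_WINDOW,
                   "distal": DISTAL_WINDOW}
    rows = {}
    for name, win in windows.items():
        k_set = repag_dist.window_count(win)
        k_ctl = control_dist.window_count(win)
        n_set, n_ctl = repag_dist.n_sites, control_dist.n_sites
        p_enrich = hypergeometric_tail(k_set, n_set, k_set + k_ctl, n_set + n_ctl)
        p_deplete = hypergeometric_lower_tail(
            k_set, n_set, k_set + k_ctl, n_set + n_ctl
        )
        rows[name] = {
            "set_occupancy": k_set / n_set,
            "control_occupancy": k_ctl / n_ctl,
            "p_enrichment": p_enrich,
            "p_depletion": p_deplete,
        }
    return WindowOccupancy(pd.DataFrame(rows).T)


def motif_overrepresentation(
    site_set: Sequence[ThreePrimeSS],
    background_set: Sequence[ThreePrimeSS],
) -> pd.DataFrame:
    """Abundance ratio (background = 1.0) per B-box motif and key nucleotides.

    Features: presence of each of the five pentamers in the last 100 intron
    bases, G at +1 and T at -3.  The background (whole-genome unique
    acceptors) is the sampling population for the hypergeometric p.  A
    feature absent from the background is flagged unavailable.
    """
    if not site_set or not background_set:
        raise ValueError("both site sets must be non-empty")

    def features(site: ThreePrimeSS) -> set[str]:
        out = {h.motif for h in scan_bboxes(site)}
        if site.M >= 1 and site.base(+1) == "G":
            out.add("G+1")
        if site.base(-3) == "T":
            out.add("T-3")
        return out

    names = list(BBOX_MOTIFS) + ["G+1", "T-3"]
    set_feats = [features(s) for s in site_set]
    bg_feats = [features(s) for s in background_set]
    rows = {}
    for name in names:
        k = sum(name in f for f in set_feats)
        K = sum(name in f for f in bg_feats)
        n, N = len(site_set), len(background_set)
        if K == 0:
            rows[name] = {"set_fraction": k / n, "background_fraction": 0.0,
                          "ratio": float("nan"), "available": False, "p": float("nan")}
            continue
        ratio = (k / n) / (K / N)
        # the set is drawn from the background population when it is a
        # subset of it; otherwise fall back to the pooled 2x2
        args = (k, n, K, N) if (k <= K and n <= N) else (k, n, K + k, N + n)
        p = (hypergeometric_tail(*args) if ratio >= 1
             else hypergeometric_lower_tail(*args))
        rows[name] = {"set_fraction": k / n, "background_fraction": K / N,
                      "ratio": ratio, "available": True, "p": p}
    return pd.DataFrame(rows).T


def bp_distance_vs_alt_exon(
    sites_with_usage: Sequence[tuple[ThreePrimeSS, bool]],
    selection: str = "nearest",
    proximal: tuple[int, int] = PROXIMAL_WINDOW,
    distal: tuple[int, int] = DISTAL_WINDOW,
) -> pd.DataFrame | None:
    """Alternative-exon share for distal- vs proximal-BP acceptors.

    Input pairs are (site, downstream exon is constitutive).  Sites are
    grouped by the window their selected BP-A falls in; the one-sided
    hypergeometric tests whether the distal group carries more alternative
    exons.  Returns None (unavailable) when either group is empty.
    """
    groups: dict[str, list[bool]] = {"proximal": [], "distal": []}
    for site, constitutive in sites_with_usage:
        bps = _select_bp(scan_bboxes(site), selection)
        if not bps:
            continue
        bp = bps[0]
        if proximal[0] <= bp <= proximal[1]:
            groups["proximal"].append(not constitutive)
        elif distal[0] <= bp <= distal[1]:
            groups["distal"].append(not constitutive)
    if not groups["proximal"] or not groups["distal"]:
        return None
    n_prox, n_dist = len(groups["proximal"]), len(groups["distal"])
    k_prox, k_dist = sum(groups["proximal"]), sum(groups["distal"])
    p = hypergeometric_tail(k_dist, n_dist, k_prox + k_dist, n_prox + n_dist)
    return pd.DataFrame(
        {"n": [n_prox, n_dist],
         "alt_pct": [100.0 * k_prox / n_prox, 100.0 * k_dist / n_dist],
         "p_distal_enriched": [float("nan"), p]},
        index=["proximal", "distal"],
    )
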