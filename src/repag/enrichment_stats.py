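"""Cross-species enrichment normalization and shared statistics.

Covers four analyses that share the same statistical machinery:

* per-species summaries of purine-rich and G-tract (REPAG) acceptor counts;
* the G%-trendline normalization that turns each species' REPAG share of
  purine-rich 3' SS into an *enrichment index* (fungal mean fixed at 1.0);
* homopurine/homopyrimidine triplet composition of 3' SS sets (e.g. sites
  aberrantly used in splicing-factor-mutant tumours vs the disrupted
  canonical sites they replace);
* relative splice-site strength from externally computed scores, compared
  by Student's paired t-test.

The enrichment test throughout is the one-tailed upper hypergeometric
(depletion via the complementary lower tail); raw p-values are reported
alongside Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpeciesSummary",
    "TrendlineFit",
    "EnrichmentIndex",
    "TripletCountTable",
    "StrengthComparison",
    "PURINE_TRIPLETS",
    "PYRIMIDINE_TRIPLETS",
    "hypergeometric_tail",
    "hypergeometric_lower_tail",
    "fit_trendline",
    "enrichment_index",
    "triplet_enrichment",
    "relative_strength",
    "paired_t_test",
]

PURINE_TRIPLETS = ("AAA", "AAG", "AGA", "AGG", "GAA", "GAG", "GGA", "GGG")
PYRIMIDINE_TRIPLETS = ("CCC", "CCT", "CTC", "CTT", "TCC", "TCT", "TTC", "TTT")
ALL_TRIPLETS = PURINE_TRIPLETS + PYRIMIDINE_TRIPLETS


# ---------------------------------------------------------------------------
# hypergeometric


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) drawing n from N containing K successes."""
    _check_hypergeom(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_lower_tail(k: int, n: int, K: int, N: int) -> float:
    """Lower (depletion) tail P(X <= k)."""
    _check_hypergeom(k, n, K, N)
    return float(stats.hypergeom.cdf(k, N, K, n))


def _check_hypergeom(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"impossible hypergeometric parameters k={k} n={n} K={K} N={N}")


# ---------------------------------------------------------------------------
# species summaries and the enrichment index


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species acceptor counts (one row of the cross-species table)."""

    species: str
    group: str
    total_3ss: int
    purine_rich_count: int
    repag_count: int
    genome_g_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.repag_count <= self.purine_rich_count <= self.total_3ss:
            raise ValueError(
                f"{self.species}: inconsistent counts "
                f"{self.repag_count} <= {self.purine_rich_count} <= {self.total_3ss}"
            )

    @property
    def purine_rich_pct(self) -> float:
        return 100.0 * self.purine_rich_count / self.total_3ss

    @property
    def repag_pct_of_purine_rich(self) -> float:
        if self.purine_rich_count == 0:
            return float("nan")
        return 100.0 * self.repag_count / self.purine_rich_count


@dataclass(frozen=True)
class TrendlineFit:
    """Linear least-squares fit of REPAG%-of-purine-rich on genome G%."""

    slope: float
    intercept: float
    r_squared: float
    form: str = "linear"

    def predict(self, g_pct: float) -> float:
        return self.slope * g_pct + self.intercept


def fit_trendline(points: Sequence[tuple[float, float]]) -> TrendlineFit:
    """Least-squares line through (genome G%, REPAG% of purine-rich) points."""
    if len(points) < 3:
        raise ValueError("trendline needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate x values: all genome G% identical")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rvalue**2)
    return TrendlineFit(float(res.slope), float(res.intercept), r2)


@dataclass(frozen=True)
class EnrichmentIndex:
    species: str
    group: str
    raw: float          # REPAG% of purine-rich / trendline prediction at G%
    normalized: float   # raw / mean raw over the fungal reference species


def enrichment_index(
    summaries: Sequence[SpeciesSummary],
    fit: TrendlineFit,
    fungal_set: Iterable[str],
) -> list[EnrichmentIndex]:
    """Trendline-normalized REPAG enrichment, fungal mean pinned to 1.0.

    Species whose trendline prediction is not positive are excluded with a
    warning (the index would be meaningless there).
    """
    fungal = set(fungal_set)
    if not fungal:
        raise ValueError("empty fungal reference set")
    raws: dict[str, float] = {}
    kept: list[SpeciesSummary] = []
    for s in summaries:
        pred = fit.predict(s.genome_g_pct)
        if pred <= 0:
            import warnings

            warnings.warn(f"{s.species}: non-positive trendline prediction; excluded")
            continue
        raws[s.species] = s.repag_pct_of_purine_rich / pred
        kept.append(s)
    fungal_raws = [raws[s.species] for s in kept if s.species in fungal]
    if not fungal_raws:
        raise ValueError("no fungal reference species survived the fit")
    fungal_mean = float(np.mean(fungal_raws))
    return [
        EnrichmentIndex(s.species, s.group, raws[s.species],
                        raws[s.species] / fungal_mean)
        for s in kept
    ]


def group_index_stats(indices: Sequence[EnrichmentIndex]) -> pd.DataFrame:
    """Mean +/- SEM of the normalized index per group label."""
    df = pd.DataFrame(
        {"group": [i.group for i in indices],
         "normalized": [i.normalized for i in indices]}
    )
    out = df.groupby("group")["normalized"].agg(["mean", "sem", "count"])
    return out.rename(columns={"count": "n"})


# ---------------------------------------------------------------------------
# triplet composition


@dataclass
class TripletCountTable:
    """Counts of 3' SS containing each homopurine/homopyrimidine triplet.

    ``counts[t]`` is the number of sites (presence/absence by default) with
    at least one occurrence of triplet ``t`` wholly inside sense positions
    -15..-3 of the window; mixed purine/pyrimidine triplets are out of the
    alphabet by construction.
    """

    counts: dict[str, int]
    n: int
    mode: str = "presence"

    def __post_init__(self) -> None:
        for t, c in self.counts.items():
            if t not in ALL_TRIPLETS:
                raise ValueError(f"{t} is not a homopurine/homopyrimidine triplet")
            if self.mode == "presence" and c > self.n:
                raise ValueError(f"count for {t} exceeds set size")

    @classmethod
    def from_windows(
        cls,
        windows: Sequence[str],
        start: int = -15,
        end: int = -3,
        mode: str = "presence",
    ) -> "TripletCountTable":
        """Count triplets in windows whose last character is position -1."""
        counts = {t: 0 for t in ALL_TRIPLETS}
        for w in windows:
            region = w[len(w) + start : len(w) + end + 1]  # inclusive -15..-3
            found = (
                {region[i : i + 3] for i in range(len(region) - 2)}
                if mode == "presence"
                else [region[i : i + 3] for i in range(len(region) - 2)]
            )
            for t in ALL_TRIPLETS:
                if mode == "presence":
                    counts[t] += t in found
                else:
                    counts[t] += sum(1 for f in found if f == t)
        return cls(counts, len(windows), mode)


def triplet_enrichment(
    aberrant: TripletCountTable, canonical: TripletCountTable
) -> pd.DataFrame:
    """Per-triplet percentage ratio (canonical baseline = 1) and exact p.

    ratio = (aberrant%)/(canonical%); reported as NaN ("not available") when
    the canonical set contains no such triplet.  p is the upper-tail
    hypergeometric on the pooled 2x2 (population = both sets, successes =
    sites with the triplet, draws = the aberrant set).  Benjamini-Hochberg
    q-values are appended over the triplets with defined p.
    """
    if aberrant.n == 0 or canonical.n == 0:
        raise ValueError("both triplet tables must be non-empty")
    rows = []
    for t in ALL_TRIPLETS:
        ka, kc = aberrant.counts.get(t, 0), canonical.counts.get(t, 0)
        ratio = (
            float("nan")
            if kc == 0
            else (ka / aberrant.n) / (kc / canonical.n)
        )
        p = hypergeometric_tail(ka, aberrant.n, ka + kc, aberrant.n + canonical.n)
        rows.append(
            {"triplet": t,
             "class": "purine" if t in PURINE_TRIPLETS else "pyrimidine",
             "aberrant_count": ka, "canonical_count": kc,
             "ratio": ratio, "available": kc > 0, "p": p}
        )
    df = pd.DataFrame(rows).set_index("triplet")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# splice-site strength (external scores)


@dataclass
class StrengthComparison:
    ratios: pd.Series      # per-pair aberrant/canonical score ratio
    mean_ratio: float
    t_statistic: float
    p: float
    n_pairs: int
    n_unpaired_dropped: int


def relative_strength(
    aberrant_scores: Mapping[str, float],
    canonical_scores: Mapping[str, float],
    pairing: Mapping[str, str],
) -> StrengthComparison:
    """Per-pair score ratios (canonical baseline 1) and the paired t-test.

    ``pairing`` maps each aberrant site id to the id of the disrupted
    canonical site it replaced; sites without a scored partner are dropped
    with a warning count.
    """
    pairs = []
    dropped = 0
    for ab_id, can_id in pairing.items():
        if ab_id in aberrant_scores and can_id in canonical_scores:
            pairs.append((ab_id, aberrant_scores[ab_id], canonical_scores[can_id]))
        else:
            dropped += 1
    if not pairs:
        raise ValueError("no scored pairs")
    ab = np.array([p[1] for p in pairs], dtype=float)
    can = np.array([p[2] for p in pairs], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = pd.Series(ab / can, index=[p[0] for p in pairs], name="ratio")
    if len(pairs) >= 2:
        t, p = paired_t_test(ab.tolist(), can.tolist())
    else:  # a single pair carries no within-pair variance to test
        t, p = float("nan"), float("nan")
    return StrengthComparison(
        ratios=ratios,
        mean_ratio=float(np.mean(ratios)),
        t_statistic=t,
        p=p,
        n_pairs=len(pairs),
        n_unpaired_dropped=dropped,
    )


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Student's paired t-test; returns (statistic, p).

    Degenerate cases are resolved explicitly: identical samples give
    (0.0, 1.0); constant non-zero differences give (+/-inf, 0.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
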