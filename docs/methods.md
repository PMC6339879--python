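# Methods

## Acceptor model and coordinate conventions

All coordinates are 1-based inclusive (the native convention of GenBank and
GFF3), and all window arithmetic is done in transcript-sense positions:
−1 is the last intron base (the G of the terminal AG), −2 the A, 0 the
junction marker (never a base), +1 the first exon base. Minus-strand
introns carry the reverse complement of the reference slice, so every
downstream predicate is strand-agnostic. Acceptors are identified by
`(contig, strand, reference coordinate of the −1 base)`; transcripts
sharing an acceptor collapse to one site at deduplication, with all their
downstream-exon links retained.

Only AG-terminal introns enter the survey; others are counted and
excluded. Introns shorter than the scan window are N-padded on the 5′
side: N never satisfies a predicate and is excluded from matrix
percentage denominators, so short introns contribute what they can without
biasing compositions.

Predicates:

* **purine-rich** — strictly more than 4 purines (A/G) at −10..−3
  (boundary: 4 → no, 5 → yes);
* **REPAG** — at least one GGG wholly inside −15..−3; legal start
  positions are therefore −15..−5, enforced arithmetically, and
  overlapping runs (GGGG) report every valid start;
* by default G tracts are searched within the purine-rich output
  (two-stage, matching the survey the reference tables describe); a flag
  widens the search to all AG acceptors.

## Statistics

Enrichment and depletion are tested with the exact hypergeometric
distribution (upper tail for enrichment, lower tail for depletion),
delegated to `scipy.stats.hypergeom` and verified in the tests against
exhaustive enumeration of all draw outcomes up to N = 12. Where two
disjoint site sets are compared (aberrant vs canonical windows) the 2×2 is
pooled; where a set is a subset of its background (motif
over-representation against whole-genome acceptors) the background is the
sampling population. Raw p-values are reported alongside
Benjamini–Hochberg q-values, clearly labelled, so the raw numbers remain
comparable with the published ones.

The cross-species trendline is an ordinary least-squares line of REPAG%
(of purine-rich acceptors) on genomic G%; a single monotone predictor is
all the normalization requires, and the fitted form is recorded in the
output. The enrichment index divides each species' REPAG% by the
trendline prediction at its G% and renormalizes so the fungal mean is
exactly 1.0 (an algebraic identity, asserted in the tests). Species whose
trendline prediction is non-positive are excluded with a warning. Cohorts
keep only species with more than 100 purine-rich acceptors (strict
inequality at the boundary).

Score comparisons use Student's paired *t*-test with explicit degenerate
cases: identical samples give (0, 1); constant non-zero differences give
(±∞, 0); a single pair reports NaN. Conservation-level comparisons use the
two-sided *t*-test, paired only when the caller supplies true pairing.

## Exon usage

Exon identity is the exact coordinate pair; partially overlapping exons
are distinct records, which is precisely what makes shifted 5′/3′
boundaries register as alternative. Genes with a single annotated
transcript cannot be classified and are excluded from numerator and
denominator (a flag includes them as constitutive for sensitivity
checks). An acceptor feeding several exon forms is alternative by
definition. The enrichment row reports `a`, `b`, `c`, `d = c/a` (2
decimals, the convention of the published table) and the upper-tail
hypergeometric p with population = all classified exons, successes =
alternative ones, draws = REPAG acceptors with a classified downstream
exon; `b` counts exactly those acceptors, logged next to the total REPAG
count.

## Branch points

The B-box list is fixed to the five pentamers CTAAC, CTGAC, CTCAC, TTAAC,
CTGAT (configurable), all carrying the branch adenosine as their fourth
base — stated explicitly and asserted structurally in the tests. Scans
cover the last 100 intron nt. When a site has several hits the default
per-site selection is the hit nearest the 3′ AG (lariat-proximal
convention); an all-hits mode is available, and positional distributions
emit both the all-sites and the with-hit denominator since either
normalization is defensible. The control set defaults to all non-REPAG AG
acceptors of the same species; whole-genome mode is selectable. Window
boundaries default to proximal −24..−4, exclusion −7..−5, distal −97..−25,
all configurable.

## Synthetic genomes

The generator emulates exactly the statistical structure the analyses
assume: multi-transcript genes (2–4 transcripts, 4–7 exons of 60–180 nt,
introns of 140–400 nt, minimum 120 so a distal branch point always fits),
AG-terminal introns, configurable background base composition
(A/T-rich 29.5/20.5 by default), and per-acceptor planted features:

* purine-rich rewrite of −10..−3 at rate 0.2 (G-tract at rate 0.5 within
  those, uniform start in −15..−5) — rates sized so a ~1,150-gene genome
  yields the ~5,000 introns and ~1,000 purine-rich acceptors the recovery
  analyses use;
* non-planted acceptors get a pyrimidine-biased −20..−3 (80% C/T), so
  synthetic matrices reproduce the Py-dominated genome-average profile;
* one B-box pentamer per acceptor (rate 0.9), distal-only for REPAG
  acceptors and mostly proximal (0.85) otherwise, emulating the observed
  branch-point displacement;
* the exon downstream of an acceptor is made alternative with probability
  0.87 after a G-tract acceptor vs 0.62 otherwise — the fold observed in
  the most enriched primate genomes — realized by dropping the exon from a
  proper, non-empty subset of the gene's transcripts. Exon dropping is the
  only alternative-splicing mechanism simulated; the coordinate-pair
  classifier needs no other.

Backgrounds are rejection-sampled so that non-planted acceptors never
satisfy the purine-rich predicate, never contain GGG inside −15..−3, and
the last 100 intron nt contain no incidental B-box. Planted features are
therefore the *complete* ground truth: detector output equals the truth
table site by site (recall and precision 1.0), while detected fractions
remain binomial draws around the configured rates — that is what the
recovery tests assert, at 3 binomial standard deviations. The proximal
branch-point placement window is capped at BP-A = −17 so a planted
pentamer never overlaps the engineered −15..−3 region. Identical seed and
configuration give byte-identical output files.

The aberrant/canonical window sets plant at most one homoclass triplet
per site (categorical draw over the configured per-triplet rates, uniform
start in −15..−5) on a background whose −15..−3 region is built with no
three consecutive same-class bases, so recovered ratios estimate the
configured rate ratios binomially. Default rates emulate the reported
composition of splicing-factor-mutant tumour acceptors, including two
purine triplets absent from the canonical set (their fold is then
reported unavailable).

What the generator does **not** emulate: realistic gene density or length
distributions, splice-site donor structure, minor-spliceosome (AC)
introns, expression weighting, sequencing noise, or evolutionary
relatedness between genes. Passing recovery tests therefore demonstrate
correctness of the detectors and tests under the assumed statistical
model, not performance on real annotation artifacts (mis-annotated
boundaries, partial transcripts), which the AG filter and warning counters
only partially address.

## Numerical and reporting choices

Percentages print at 1 decimal, folds at 2 (the published convention),
p-values in scientific notation with 2 significant digits; p-values that
underflow double precision are reported via the log survival function.
Position-matrix percentages exclude N from denominators and every row sums
to 100 ± 0.1 over observed bases. The synthetic problem sizes used by the
test suite and the acceptance script (≈5,000 introns for recovery,
≈2,500 G-tract acceptors for the fold test, 860-window aberrant sets)
were chosen to match the scales at which the corresponding published
quantities are reported while keeping a full run in seconds.

## Known limitations

* The two-stage REPAG search reproduces the published semantics; the
  survey's "authenticity" qualifier for G-tract acceptors has no
  operational definition and no filter is applied.
* The exact 2×2 construction behind some published p-values (triplet
  enrichment site-vs-occurrence counting; the distal-vs-proximal
  alternative-exon comparison) is not stated in the source material; both
  counting modes are provided, and the tests freeze enumeration-oracle
  values rather than the prose claims.
* MaxEnt (or any) splice-strength scoring is consumed from TSV, never
  computed; alignment blocks are inputs, never computed.
* Trans-splicing, joins across contigs, and non-AG acceptors are out of
  scope.
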