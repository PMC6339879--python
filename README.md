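# repag

Survey of purine-rich and G-tract (**REPAG**) 3′ splice sites in annotated
genomes.

## The problem

The canonical metazoan acceptor ends in `(Y)₂₀NCAG|gt`: a polypyrimidine
tract (Py) running almost up to the terminal AG. In a sizeable class of
introns, however, the Py and the 3′ AG are separated by purine-rich
regulatory elements — most prominently G tracts (GGG) — which recruit
hnRNP H/F, interfere with U2AF65 binding, weaken the acceptor, and are
associated with alternative and aberrant splicing. This package implements
the genome-scale survey of that acceptor class:

* **Detection.** An acceptor is *purine-rich* when more than 4 of the 8
  bases at positions −10..−3 are purines (A/G); a purine-rich acceptor is a
  *REPAG* when it carries a GGG wholly inside −15..−3. Positions are
  transcript-sense: −1 is the G of the terminal AG, 0 the junction, +1 the
  first exon base.
* **Cross-species enrichment.** Per-species REPAG share of purine-rich
  acceptors is regressed on genomic G% (linear least squares); each
  species' ratio to the trendline prediction, normalized so the fungal
  mean is 1.0, is its *enrichment index*.
* **Alternative exons.** An exon is constitutive when its exact coordinate
  pair occurs in every transcript of its (multi-transcript) gene, otherwise
  alternative. Enrichment of alternative exons immediately downstream of
  REPAG acceptors is tested with the upper-tail hypergeometric:
  `a` = % alternative transcriptome-wide, `b` = REPAG acceptors tested,
  `c` = % alternative downstream of REPAGs, `d = c/a`.
* **Branch points.** The five high-affinity B-box pentamers (CTAAC, CTGAC,
  CTCAC, TTAAC, CTGAT; branch adenosine = 4th base) are scanned in the last
  100 intron nt; occupancy of the proximal (−24..−4), AG-exclusion (−7..−5)
  and distal (−97..−25) windows is compared between REPAG and control
  acceptors.
* **Aberrant acceptors and conservation.** Homopurine/homopyrimidine
  triplet composition of aberrantly used vs disrupted canonical acceptors
  (splicing-factor-mutant tumours), relative splice-site strength from
  externally computed scores (paired *t*-test), and G-tract conservation
  relative to the 3′ AG in aligned blocks.

A synthetic-genome generator (`repag.simulate`) plants all of these
features with known ground truth, so every stage is testable without any
download.

## Worked example

```python
from repag.simulate import SimulationConfig, simulate_genome
from repag import genome_io, pipeline

cfg = SimulationConfig(seed=42, n_genes=300)      # ~1,400 introns
paths = simulate_genome(cfg).write("demo")
parsed = genome_io.parse_gff3_fasta(paths["gff3"], paths["fasta"])
bundle = pipeline.run_species(parsed, species="demo", group="synthetic")
print(bundle.summary_row())
print(bundle.bbox_occupancy.table.round(4))
```

prints

```
{'species': 'demo', 'group': 'synthetic', 'total_3ss': 1370,
 'purine_rich': 236, 'purine_rich_pct': 17.2, 'repag': 127,
 'repag_pct_of_purine_rich': 53.8, 'genome_g_pct': 20.6,
 'a': 53.4, 'b': 127, 'c': 84.3, 'd': '1.58', 'p': '2.66e-14'}
           set_occupancy  control_occupancy  p_enrichment  p_depletion
proximal           0.000             0.7667           1.0          0.0
exclusion          0.000             0.0000           1.0          1.0
distal             0.937             0.1279           0.0          1.0
```

Of the 1,370 unique acceptors, 17.2% were detected purine-rich and 53.8%
of those carry a G tract (the generator planted 20% and 50%; the detected
fractions are binomial draws around them). Exons downstream of the 127
REPAG acceptors are alternative in 84.3% of cases against 53.4%
transcriptome-wide — a 1.58-fold enrichment at p ≈ 3e−14. REPAG branch
points sit almost entirely in the distal window (planted distal-only),
while control acceptors keep proximal branch points.

The same stages are available as subcommands of the `repag` CLI
(`simulate`, `scan`, `matrix`, `exon-usage`, `bbox`, `cohort`, `triplets`,
`strength`, `conserve`); every run writes a `manifest.json` with
parameters and per-stage counts.

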