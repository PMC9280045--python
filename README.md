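# woxkit

Comparative-genomics toolkit for plant transcription-factor gene families,
built around the kind of multi-species characterization studies performed on
the WUSCHEL-related homeobox (WOX) family: codon-usage bias and heterologous
expression-host choice, protein physicochemistry, neighbor-joining phylogeny
with ancient / intermediate / modern-WUS clade assignment, gene-structure
statistics, promoter cis-element scanning, and relative expression analysis.
It is aimed at researchers who have curated a gene family (CDS, proteins, an
alignment, gene models) and want the downstream statistics as tested,
scriptable functions rather than a chain of web servers.

## What it computes

**Codon-usage bias.** For each synonymous family of size *k* with codon
counts *X<sub>i</sub>*:

- RSCU<sub>i</sub> = *X<sub>i</sub>* · *k* / Σ*X* — relative synonymous codon
  usage (>1 positive bias, <1 negative, =1 none);
- RFSC<sub>i</sub> = 100 · *X<sub>i</sub>* / Σ*X* — the codon's percent share
  of its family, with the *high-frequency* rule RFSC > 60 or
  RFSC ≥ 1.5 · (100/*k*) (families with *k* = 1 are never classified);
- per-codon frequency ratios (occurrences per 1,000 codons) between a gene
  set and candidate host genomes, with ratios ≤ 0.50 or ≥ 2.00 classed
  *divergent* and hosts ranked by divergent-codon count.

**Protein physicochemistry.** Average molecular weight, theoretical pI
(bisection root of the Henderson–Hasselbalch net charge with a
Bjellqvist-style pKa set), Guruprasad instability index (unstable at ≥ 40),
Ikai aliphatic index, and Kyte–Doolittle GRAVY.

**Phylogeny.** p- or Poisson-corrected protein distances with pairwise gap
deletion, Saitou–Nei neighbor joining (deterministic tie-breaking, negative
branch lengths clamped), column-bootstrap supports, and nearest-anchor clade
assignment with an ambiguity margin.

**Annotation.** Exon/intron/UTR statistics from GFF3 (genes over 3 kb
flagged), extraction of promoters up to 2,000 bp upstream of the start
codon, and IUPAC-consensus scanning of stress / hormone / growth cis-elements
on both strands.

**Expression.** log2(x+1) and row-z heatmap transforms, per-gene peak-stage
and monotone-decrease calls, and 2^−ΔΔCt fold changes with two reference
genes and a replicate-level Student's t-test (α = 0.01) against the
calibrator sample.

A seeded `synthetic_data` module generates every input type with
machine-readable ground truth, so the full pipeline is exercisable and
testable without any downloads.

## Worked example

The package ships transcriptions of the published per-species RSCU/RFSC
table and codon-frequency-ratio table for the WOX genes of four
Euphorbiaceae species (*Hevea brasiliensis*, *Jatropha curcas*,
*Manihot esculenta*, *Ricinus communis*). Re-running the classification
rules on those tables:

```python
from woxkit import codon_usage as cu

usage = cu.load_fixture_usage_tables()          # four CodonUsageTables
print(cu.bias_partition(list(usage.values())))
print(sorted(cu.consensus_high_frequency(list(usage.values()))))
ratios = cu.load_fixture_ratio_tables()
print(ratios["JcWOX/At"].n_divergent, sorted(ratios["JcWOX/At"].divergent_set()))
```

prints

```
(19, 23, 2, 20)
['AGA', 'CCA', 'GAU', 'GCA']
6 ['CGC', 'GCU', 'UAA', 'UAG', 'UCG', 'UGA']
```

meaning: across the four species 19 codons share positive bias, 23 share
negative bias, 2 are unbiased everywhere and 20 differ between species;
exactly four codons (GCA, GAU, CCA, AGA) are high-frequency in all four
sets; and six codons of the *J. curcas* WOX set diverge from the
*A. thaliana* genome's usage. The same checks are available from the shell
as `woxkit verify`, which prints a pass/fail table of all of these counts
plus the clade-proportion summary (38/12/9 of 59 genes → 64.4% / 20.3% /
15.3%).

An end-to-end run on synthetic data:

```bash
woxkit simulate annotation --seed 4 --out demo/
woxkit structure --gff demo/genes.gff3 --out demo/structure.tsv
```

`structure.tsv` then lists one row per generated gene, e.g.
`gene001  4 exons, 3 introns, span 2204 bp, long_gene False`, matching the
generator's truth JSON. See `woxkit --help` for the remaining subcommands
(`codon`, `protparam`, `tree`, `promoters`, `expression`, `qpcr`, `run`).

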