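# tierscan

A toolkit for finding and characterizing palindromic dihexamer response
elements (consensus `AGAACAnnnTGTTCT`) in DNA sequence: position-specific
scoring-matrix construction, exact-p-value motif scanning under a
zero-order background, 5-tier degeneracy classification, genomic
annotation, spaced-motif co-occurrence analysis, region-density statistics,
and integration with a differential-expression table. A fully seeded
synthetic-fixture module makes every stage testable without external data.

## The five tiers

| Tier | Definition |
|------|------------|
| 1 | perfect full site (0 mismatches over the 12 informative positions) |
| 2 | 1 mismatch |
| 3 | 2 mismatches |
| 4 | 3 mismatches |
| 5 | isolated perfect hexamer (`AGAACA` / `TGTTCT`) not part of a full site |

The 3-bp spacer is fully degenerate and never counts toward mismatches.
Overlaps are resolved so each locus is reported once, at the lowest
(most specific) tier available.

## Library overview

- `tierscan.motif_models` — `MotifModel` (probabilities, background,
  base-2 log-odds, IUPAC consensus, informative mask), built from a
  consensus string or aligned sites; MEME-minimal and JSON I/O.
- `tierscan.scanner` — exact score distribution by dynamic programming on
  a discretized integer lattice; both-strand scanning with exact p-values;
  palindromic models are scanned once and reported on the plus strand.
- `tierscan.tier_classifier` — Hamming-based full-site classification,
  exact half-site detection, lowest-tier overlap resolution, tier summaries.
- `tierscan.genome_annotation` — BED12/GTF gene models; category priority
  TSS > TTS > 5'UTR > 3'UTR > exon > intron > non-coding > intergenic with
  strand-aware promoter/terminator windows; nearest-gene assignment.
- `tierscan.cooperation` — spacing histograms (±160 bp window, 5-bp bins by
  default) between anchor sites and a secondary motif, per-bin binomial
  enrichment with Bonferroni correction, full-vs-half anchor comparison.
- `tierscan.downstream_stats` — sites/Mbp inside a region set vs its
  complement with an exact two-sided binomial test (plus a permutation
  cross-check), and per-tier transcriptional hit rates against a
  gene → up/down/ns response table.
- `tierscan.synthetic` — seeded background sequence, planted tiered sites
  (with rejection sampling so planted tiers are provably recoverable),
  cooperating motifs at controlled spacings, gene models, response tables.

## Command line

```bash
tierscan build-model --consensus AGAACANNNTGTTCT --match-prob 0.997 --out ideal.meme
tierscan scan      --fasta genome.fa --motif ideal.meme --pvalue 4.94e-5 --out-bed hits.bed
tierscan classify  --fasta genome.fa --out tiered           # -> tiered.bed / tiered.tsv
tierscan annotate  --hits tiered.tsv --genes genes.bed --format BED12 --out annotated.tsv
tierscan spacing   --anchors tiered.tsv --fasta genome.fa --secondary klf.meme --out spacing.tsv
tierscan density   --hits tiered.tsv --regions amplified.bed --chrom-sizes chrom.sizes
tierscan hitrate   --annotated annotated.tsv --responses responses.tsv
tierscan simulate  --preset tiers --seed 1 --out simdir     # synthetic data + truth
tierscan run       --config config.yaml                     # full pipeline + manifest
```

All BED/TSV outputs are 0-based half-open and declare the convention in a
header comment. BED scores are `min(1000, round(-10*log10 p))`.

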