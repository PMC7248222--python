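# methylstab

Motif-landscape statistics and cross-replicate m6A methylation-stability
analysis for the GATC/CATG restriction-modification target sites of a
chlorovirus-scale genome, driven by PacBio-style per-site base-modification
calls.

The pipeline covers:

* **genome_motifs** — FASTA ingestion, palindromic motif scanning on both
  strands, mean-spacing and index-of-dispersion statistics, motif-free gap
  detection, and the random-composition expected recurrence interval
  (278 bp for a 2×S/2×W 4-mer at 40% GC).
* **enrichment** — step-1 sliding-window motif enrichment (ME = observed
  loci / expected 2 per 278-bp window), merged significant regions,
  gap-based fold depletion (139/length), GFF3 gene-overlap annotation and a
  per-gene motif-density vs transcription-class Pearson correlation.
* **modcalls** — readers for the two PacBio-style dialects (modifications
  GFF3 with QV score + `coverage;IPDRatio;frac` attributes; per-strand-position
  modifications CSV with 0/1 strand encoding), the genome-wide
  ipdRatio > 2 census, QV↔p-value transforms, and per-motif methylation
  call fractions at a QV threshold.
* **stability** — cross-replicate mean/SD of methylFrac per motif
  strand-site (absent call ⇒ 0.0 in this stage only), binarisation at 0.5
  per replicate, and the four k-of-n stability classes.
* **palindromes** — two-strand classification of each locus as fully
  methylated / hemimethylated / stochastic at the strict > 0.75 threshold,
  stably non-methylated flagging, and per-gene palindrome reports.
* **synthetic_data** — a seeded generator of genomes (target GC, optional
  planted motif-free gaps / enriched windows) and three-replicate
  modification GFF3+CSV files under a binomial read-sampling model at 30×
  coverage, with planted ground truth for recovery tests.

## The reference genome

Landscape statistics on the real reference need the NC_000852 FASTA
(~0.3 MB). This repository ships no data and the code never downloads
anything; to enable the reference-dependent tests and acceptance targets,
save the FASTA to `data/NC_000852.fasta` (or point `METHYLSTAB_REFERENCE`
at it). Without it, those tests fail with a clear diagnostic and the
acceptance report omits the corresponding targets.

## CLI

```sh
methylstab simulate --outdir sim/ [--config sim.yaml] [--seed 7]
methylstab scan --fasta sim/genome.fa --out loci.bed
methylstab enrich --fasta sim/genome.fa --window 278 --min-me 3.5 --out regions.tsv
methylstab summarize-mods --fasta sim/genome.fa \
    --gff sim/rep1.modifications.gff --csv sim/rep1.modifications.csv
methylstab stability --fasta sim/genome.fa \
    --reps sim/rep1.modifications.gff,sim/rep2.modifications.gff,sim/rep3.modifications.gff \
    --out stab.tsv
methylstab palindromes --stability stab.tsv --threshold 0.75 --out pal.tsv
```

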