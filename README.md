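# gbskaryo

Karyotyping of allopolyploid plants from genotyping-by-sequencing (GBS)
read coverage.

Newly synthesized wheat x rye amphidiploids (AABBDDRR, 2n = 56) stabilize
their hybrid genomes through large-scale chromosome rearrangements:
whole-chromosome losses and gains (nullisomy, monosomy, trisomy,
tetrasomy), elimination of single chromosome arms (telocentric
chromosomes), and terminal, interstitial or pericentric deletions.
`gbskaryo` detects these events from low-cost GBS data: it counts
uniquely mapped reads in fixed genomic bins, normalizes them against
euploid control samples, segments the resulting log2-ratio profiles into
integer copy-number states, classifies the events into the standard
cytogenetic vocabulary, and reports each plant's somatic chromosome
number and the dosage of named loci (such as the incompatibility alleles
on 6AL and 6RL whose elimination restores fertility).

The core statistic, for sample *s* and bin *b*:

    r_sb = log2( (cpm_sb + p) / (mean of control cpm_b + p) )

where `cpm = counts / sample_total x 1e6`. A disomic region sits near 0, a
monosomic one near −1, an eliminated one at the ratio floor; a copy-number
state *k* sits near log2(*k*/2). Profiles are segmented by exact penalized
least-squares changepoint detection and each segment is assigned
CN = round(2·2^r) ∈ {0..4}. The somatic chromosome number is
2n = Σ max(CN_S, CN_L) over chromosomes — telocentric bodies count as
chromosomes. A negative-binomial GBS count simulator with planted events
(shared target-density profile, per-sample library size, cross-mapping
floor) makes every stage verifiable without external data. See
`docs/methods.md` for the full model.

## Worked example

```python
from gbskaryo import (demo_config, simulate_cohort, normalize_counts,
                      call_cohort, summarize)

config = demo_config(seed=1)              # 30 genotypes, 28 chromosomes
matrix, sheet, truth = simulate_cohort(config)
norm = normalize_counts(matrix, sheet)
calls = call_cohort(norm, sheet, config.genome)
reports = summarize(calls, config.genome, sheet)
for name in ("ctrl01", "rye_elim", "dt4BS"):
    print(reports[name].describe())
```

prints

```
sample ctrl01 (control): 2n = 56
  euploid, no major rearrangements
sample rye_elim (test): 2n = 42
  1R: nullisomic (CN 0, arms S=0/L=0, 0-52000000)
  ... (all seven rye chromosomes nullisomic)
sample dt4BS (test): 2n = 56
  4B: ditelosomic:S (CN 0, arms S=2/L=0, 22000000-48000000)
```

The control keeps the euploid complement (2n = 56). The plant that lost
the entire rye subgenome retains only the 42 wheat chromosomes. The
ditelosomic plant lost the long arm of 4B on both homologs, yet still
counts 56 chromosome bodies because the retained short arms persist as
telocentric chromosomes. On this demo cohort the caller recovers 32/32
planted chromosome/arm events at their exact copy number and the correct
2n for 30/30 genotypes.

The `examples/` directory has one short script per capability
(simulation, normalization, calling, locus queries, the end-to-end
pipeline); each prints what it computes and what the numbers mean. The
same stages are available from the shell:

```sh
gbskaryo simulate --seed 1 --out sim/
gbskaryo normalize --counts sim/counts.tsv --samplesheet sim/samplesheet.tsv \
    --genome sim/genome.tsv --out normalized.tsv
gbskaryo call --normalized normalized.tsv --samplesheet sim/samplesheet.tsv \
    --genome sim/genome.tsv --out calls/
gbskaryo report --normalized normalized.tsv --samplesheet sim/samplesheet.tsv \
    --genome sim/genome.tsv --out report/
```

Real data enter as per-sample BED4 bin-count TSVs (or one wide matrix
TSV), a genome model TSV (chrom, subgenome, length, centromere), and a
sample sheet designating the euploid controls; an optional adapter counts
reads directly from SAM records (MAPQ-filtered, primary alignments only).

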