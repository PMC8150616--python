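# lcshap — phasing-free long haplotypes from homozygosity tracts

`lcshap` mines **experimentally confirmed haplotypes** from population
genotype data (a VCF such as the 1000 Genomes Project Phase 3 callset)
without any computational phasing.  It targets researchers in
transfusion medicine and population genetics who need long, error-free
reference sequences for a gene — the motivating case is the *ACKR1*
gene carrying the Duffy (FY) blood-group system.

## The idea

Computational genotype phasing is error-prone for rare and novel
variants.  But a diploid individual who is homozygous at *every* variant
site of a window carries two identical chromosomes there, so the
haplotype can be read directly from the genotypes.  For a focal gene
*G* inside a region *R*:

1. **Screen**: keep samples with ≤ 1 heterozygous site inside *G*
   (complete homozygosity, or heterozygosity at a single site — both
   chromosomes' gene sequences are then still unambiguous).
2. **Extend**: grow the window 5′ and 3′ from *G* until the first
   heterozygous variant outside the gene; the span strictly between the
   two terminating variants (their REF footprints excluded) is maximal
   and unambiguous.
3. **Realise**: splice the carried alleles into the reference window to
   obtain each chromosome's full nucleotide sequence (indels shift the
   realised length relative to the span width).
4. **Catalogue**: deduplicate by (span, sequence), count chromosome
   observations (two per qualifying sample), attach population and
   super-population breakdowns, and summarise the length distribution
   (distinct-haplotype quartiles; observation-weighted histogram).
5. **Classify**: name each haplotype by its bases at configured
   diagnostic exonic positions (the Duffy FY\*01 / FY\*02 / FY\*02N.01
   motifs ship as the default config).
6. **Compare**: rank haplotypes by IUPAC-aware mismatches against
   external base profiles, e.g. the bundled Neanderthal *ACKR1*
   consensus profiles.

The VCF phase separators (`|` vs `/`) are parsed but never used —
independence from phasing is the point.

## Worked example

Everything is testable offline: the built-in simulator emits a cohort
(VCF + reference FASTA + panel + ground truth).  The `ackr1` profile
simulates the real GRCh38 window chr1:159,203,314–159,283,887 around
*ACKR1* with a planted Duffy-null sample:

```sh
lcshap simulate --out demo --seed 3 --samples 12 --profile ackr1
lcshap extract \
    --vcf demo/cohort.vcf --reference demo/reference.fa --panel demo/cohort.panel \
    --region chr1:159203314-159283887 --gene chr1:159204875-159206500 \
    --out results
cat results/run_report.txt
```

```
samples=12
variant_sites=12
gene_variant_sites=4
qualifying_samples=7
observations=14
distinct_haplotypes=12
```

Seven of the 12 samples have ≤ 1 heterozygous site inside the 1,626-nt
gene, contributing 14 chromosomes that collapse into 12 distinct
haplotypes.  `results/haplotypes.tsv` lists each haplotype's span,
length, observation count, population counts and Duffy allele call
(`results/haplotypes.fasta` holds the sequences):

```
id    contig start     end       length observations allele
HAP1  chr1   159203314 159255401 52088  2            FY*01
HAP2  chr1   159204121 159210003 5883   2            FY*02N.01
HAP3  chr1   159203314 159210003 6690   1            unclassified
...
```

`lcshap compare` (same inputs, `--out cmp`) ranks the catalogue against
the bundled Neanderthal profiles; in this small Hardy-Weinberg cohort an
exact match to the archaic profile happens to exist — in real data the
interesting output is the mismatch count of the closest haplotype:

```
      query  rank haplotype  mismatches  exact_match  length allele
Chagyrskaya     1      HAP7           0         True    5883  FY*02
Chagyrskaya     2      HAP5           1        False   34504  FY*01
```

`lcshap classify` writes per-allele length statistics, and
`lcshap summarize` recomputes the length histogram from written
catalogue files.  For real data, point `--vcf` at a genotype VCF slice,
`--reference` at the matching FASTA (a full contig or a
`samtools faidx`-style `contig:start-end` window) and `--panel` at a
1000GP-style `sample pop super_pop` table; use `--keep-samples` to drop
related individuals.

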