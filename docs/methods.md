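# Methods

## Model and procedure

A diploid sample that is homozygous at every variant site of a window
carries two chromosomes with identical sequence over that window; the
haplotype is then determined by the genotypes alone.  One heterozygous
site still leaves both chromosomes determined (each carries one of the
two alleles at that site, everything else being shared), so the
screening rule is: **at most one heterozygous site inside the focal
gene**.  Extension outward stops at the first heterozygous variant on
either side; the haplotype span is the closed interval strictly between
the two terminating variants' REF footprints (or the region edge).  Each
qualifying sample contributes exactly two chromosome observations; a
fully homozygous sample contributes two identical ones.

All coordinates are 1-based inclusive (VCF convention); readers convert
any half-open arithmetic internally.  Phase separators in GT are parsed
and carried but never consulted.

### Membership and boundary rules

* A variant belongs to the gene when its REF footprint **overlaps** the
  gene interval.  Overlap (not containment) is the only choice that
  keeps spans well-formed for deletions straddling the gene boundary.
* Extension likewise treats a window as invalidated as soon as it
  overlaps any part of a flanking heterozygous footprint, so the span
  starts at `footprint_end + 1` of the nearest left het (symmetrically
  on the right).  Sequence splicing, by contrast, applies only variants
  whose footprint is fully contained in the span; a homozygous
  non-reference footprint that straddles a span edge (possible only
  with overlapping VCF records) is represented by reference bases.
* Multi-allelic records are kept as single sites with allele indices;
  splitting them would double-count heterozygosity.
* Records with symbolic or non-ACGT alleles, without ALT, with
  footprints crossing the region edge, or duplicating a position are
  skipped and tallied, not errors: population callsets routinely carry
  structural-variant records the method does not consume.

### Missing genotypes

Callsets like 1000GP Phase 3 are essentially complete, but the policy
matters for generality.  Default (`MissingPolicy.AS_HET`): a missing
call is ambiguity, so it terminates extension and counts toward the
one-heterozygote limit; if the single permitted in-gene "het" is itself
a missing call the sample is excluded outright, because no allele pair
can be assigned.  `AS_REF` (optional) reads missing as homozygous
reference.  The conservative default preserves the "experimentally
confirmed" guarantee at the cost of discarding rare ambiguous samples.

### Lengths and statistics

Haplotype **length** is the length of the realised sequence, not the
span width — insertions add and deletions remove bases
(`length = span_width + Σ(len(alt) − len(ref))`).  Distinct-haplotype
identity is the (span, sequence) pair; identical strings over different
spans are different physical claims.  Median/quartiles/combined length
are computed over **distinct** haplotypes (linear-interpolation "type 7"
quartiles, the numpy and spreadsheet default; a ±few-nt discrepancy
against other quartile conventions is possible).  The length histogram
is weighted by **chromosome observations**, with percentages rounded
half-up to two decimals (spreadsheet convention, not banker's
rounding).  The length-vs-observations association uses Spearman rank
correlation (scipy), undefined-on-constant signalled as an error.

### Allele classification

Classification is config-driven: an ordered list of diagnostic
positions (genomic coordinate, CDS-style label, reference base) plus
named allele motifs.  A haplotype's motif is its base at each position,
read through applied indels; exact motif match assigns the name,
anything else is `unclassified`, and a haplotype whose span misses a
position (or whose deletion removes it) is `uncallable` and excluded
from per-allele statistics.  Classified + unclassified + uncallable
always partitions the catalogue.  Per-allele standard deviations use
the sample (n−1) denominator.

The bundled Duffy config carries the three common motifs (FY\*01,
FY\*02, FY\*02N.01) over 15 exonic positions.  Two coordinates are
anchored to dbSNP GRCh38: the GATA-box promoter site c.-67
(rs2814778, chr1:159,204,893) and the Fy(a/b) site c.125 (rs12075,
chr1:159,205,564).  The other 13 positions carry the reference bases
shared by all three motifs; their coordinates are self-consistent
placeholders inside the exon bounds (offsets from c.125), pending
curation.  Because those bases are invariant across the configured
motifs, the placeholder coordinates affect only which incidental
variation could render a haplotype `unclassified`, not how the three
alleles separate.  Rare weak alleles (Fy(a+w)/Fy(b+w)) are deliberately
absent from the default config and surface as `unclassified`; they can
be added as extra `allele` rows.

### Archaic comparison

External samples enter as per-position base profiles (archaic consensus
bases are often IUPAC-ambiguous, e.g. Y = C or T).  Two bases match
when their IUPAC sets intersect, so ambiguity can only reduce
mismatches.  Ranking is by ascending mismatches, ties by descending
length then id.  Comparison is restricted to configured positions (the
bundled set: c.-67, c.21+115, c.21+235, c.125 — the positions at which
published Neanderthal consensus differs from or matches the Duffy-null
haplotype); full-sequence comparison against an alignment-derived
archaic consensus is out of scope, and the position set is a parameter.

## The simulator

`lcshap.simulate` draws a uniform-random reference window, places
variant sites (SNVs, left-aligned-by-construction insertions and
deletions), and samples genotypes under Hardy-Weinberg equilibrium:
two independent allele draws per sample per site at the configured
alt frequencies.  Sites are independent — no linkage disequilibrium,
recombination map or coalescent history.  The method never consults
any of those, so HWE-independent sites exercise every code path, but
passing tests therefore say nothing about realistic haplotype-block
structure, allele-frequency spectra or population differentiation;
with independent common variants, long spans are rarer than in real
data, and exact matches to an external profile can arise by chance
where real cohorts show none.

Ground truth (who qualifies, each span, the expected catalogue,
expected allele calls) is computed inside the simulator by an
exhaustive single-base window scan plus a standalone splicer —
deliberately separate code from the extraction and sequence modules,
so generator and extractor cannot share a bug silently.  Output is
deterministic per seed, and the seed is recorded in the VCF header.

Default study conditions: the randomized property-test cohorts use 10
samples × 15 sites over a 240-nt region (gene 90–150) with alt
frequencies uniform in 0.05–0.5 and occasional missing calls; the
Hardy-Weinberg calibration check uses n = 2,000 samples and five
in-gene sites at alt frequency 0.1, where the qualifying fraction has
the closed form Π(1−hᵢ) + Σⱼ hⱼ Π₍ᵢ≠ⱼ₎(1−hᵢ) with hᵢ = 2pᵢ(1−pᵢ);
the bundled regression fixture is 30 samples × 25 sites (one insertion,
one deletion, three populations) at a fixed seed with its catalogue
frozen as golden files.  The `ackr1` demo profile simulates the real
80,574-nt GRCh38 window with pinned reference bases at the diagnostic
positions, plausible Duffy allele frequencies, and one sample planted
homozygous for the Duffy-null promoter profile.  These sizes keep the
whole suite in the seconds range while covering every operation.

## Command-line interface

`extract`, `classify` and `compare` all start from the raw inputs
(VCF + reference + panel) rather than from a written catalogue: motif
lookup through indels needs the applied-variant offsets, which the
catalogue TSV/FASTA deliberately does not serialise.  `summarize`
alone re-reads catalogue files, since it needs only lengths and
counts.  Remote callset fetching is out of scope; inputs are local
files.

## Known limitations

* No re-normalisation of variants: the VCF is trusted to be
  left-aligned; overlapping footprints within one haplotype are a hard
  error at splice time.
* Duplicate-position records are kept first-come; real multi-record
  sites (SNV + indel at one position) would need pre-merging.
* The 13 placeholder coordinates in the Duffy config (above).
* Catalogue files do not round-trip the applied-variant structure, so
  classification cannot be re-run from files alone.
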