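# tevar

Discovery of transposable-element (TE) presence/absence variants from
paired-end DNA sequencing, with the population-scale analyses that turn
per-sample calls into biology: allele-frequency classification, TE–SNP
linkage profiling, differential expression, rare-variant burden tests and
a genome-wide methylation association scan.

## Who this is for

TEs are mobile genetic elements whose presence or absence differs between
individuals of a species. Short reads are normally mapped to a single
reference genome, which hides exactly this kind of structural difference:
a TE present in your sample but missing from the reference produces no
alignment at its own locus, only indirect mapping anomalies. `tevar` is
for population-genomics studies (its defaults are tuned to
*Arabidopsis*-scale genomes) that need to recover those anomalies as
explicit TE variant genotypes across tens to hundreds of resequenced
accessions, and to relate them to expression and DNA-methylation data.

## The method

**Discovery (per sample).** From a coordinate-sorted alignment file the
caller estimates the library insert model (mean μ and standard deviation
σ of proper-pair template lengths, 1% tails trimmed) and the genome-wide
mean coverage *c*. Two evidence classes are extracted:

* *discordant pairs* — mates mapping more than μ + 4σ apart, or to
  different chromosomes;
* *split reads* — reads aligning in two segments ≥ 5 kb apart (closer
  splits are small indels, not TE variants) with MAPQ ≥ 5.

A **TE insertion** is called where evidence reads cluster at a breakpoint
while their mates or second segments fall ≥ 80% inside one annotated TE
elsewhere; the required read count is max(2, ⌊c/10⌋), doubled when no
discordant pairs face each other across the breakpoint. A **TE absence**
is called where split/discordant reads span ≥ 80% of an annotated TE and
the internal read depth falls below 10% of the depth in the 2 kb flanks
(at intermediate depth ratios < 1, twice as many spanning reads are
required). Spans over 20 kb are discarded as unrelated structural
variation.

**Refinement (per population).** Insertion sites are merged across
samples; every sample is re-genotyped at every merged site with a relaxed
threshold (a single TE-linked split read), yielding 1/0/NA genotypes — NA
whenever a zero-coverage base makes the site unassessable. This rescues
false negatives in low-coverage samples.

**Population statistics.** On the genotype matrix: minor allele frequency
(MAF) per variant; re-expression of reference-relative calls as true
insertions (variant allele at MAF ≤ 20% frequency, or absences shared by
≥ 80% of accessions) versus deletions, with MAF > 20% unclassifiable;
rare = MAF < 3% and fewer than 7 carriers. TE–SNP linkage is profiled by
ranking squared genotype correlations (r²) of the TE against its 300
flanking SNPs per side and counting ranks where the TE exceeds the
median SNP–SNP value (< 200 wins: low LD; 200–400: mid; > 400: high).
Expression effects use two-sided Mann–Whitney U tests with Storey
q-values (significant at q < 0.01 and > 2-fold change); rare variants are
aggregated in a burden test (quadratic fit to carriers' pooled phenotype
ranks). Methylation analyses correlate DMR levels with the nearest
variant's genotype, and a permutation scan labels a variant–DMR pair
significant only when its |r| beats all 500 accession-label permutations.

**Simulator.** A built-in generator creates random genomes with annotated
TE families, plants copy-paste/cut-paste transpositions and deletions,
simulates paired reads (configurable coverage, read length, insert-size
normal distribution, error rate), and — because every read's true origin
is known — writes the *ideal alignments* those reads would have on the
reference. That makes the entire caller testable hermetically, with exact
truth for sensitivity/FDR accounting.

## Worked example

Simulate a 1 Mb two-chromosome genome carrying 50 TEs, plant 10
insertions (5 copy-paste, 5 cut-paste) and 10 deletions, sequence it at
20×, call variants, and score them against the planted truth:

```sh
$ tevar --seed 5 simulate --out-dir demo --chrom-length 500000 --n-tes 50 \
        --copy-paste 5 --cut-paste 5 --deletions 10 --coverage 20
simulated 1000000 bp genome, 50 TEs, 10 insertions, 10 deletions, 99720 read pairs -> demo

$ tevar discover --bam demo/ideal.sam --te-bed demo/tes.bed \
        --genome demo/reference.fa --accession demo1 --out-prefix demo/demo1
demo1: 10 presence, 11 absence calls (coverage 19.9x, insert 400+/-47)

$ tevar evaluate --calls demo/demo1.all.tsv --truth demo/truth.tsv
insertion: TP=10 FP=0 FN=0 sensitivity=1.000 FDR=0.000
absence: TP=10 FP=0 FN=0 sensitivity=1.000 FDR=0.000
```

The discover step reports the estimated library model (insert 400 ± 47 bp,
19.9× coverage) and writes BED-like TSVs. All 10 planted insertions are
recovered with the correct TE family and breakpoints within 100 bp; the
11th absence call sits at a cut-paste donor site — a locus genuinely
excised in the sample, scored separately from the 10 planted deletions.
A presence call row looks like:

```
chrom  start   end     variant_id                variant_type  te_ids   accession  n_split  n_discordant
chr1   259025  259025  ins_chr1_259025_TE00005   presence      TE00005  demo1      30       61
```

i.e. a breakpoint at chr1:259,025 supported by 30 split and 61 discordant
reads, all linked to the annotated element TE00005.

The same operations are available as library functions
(`tevar.discover_sample`, `tevar.merge_insertions`,
`tevar.popgen.classify_matrix`, `tevar.ld.rank_profile`,
`tevar.assoc.permutation_scan`, …) for notebook use.

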