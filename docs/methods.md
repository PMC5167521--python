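# Methods

## The caller's model of a TE variant

A paired-end library is summarised by the insert-size distribution of
properly mapped pairs. `tevar` models it by the trimmed sample mean μ and
standard deviation σ (top and bottom 1% of template lengths removed —
real libraries have heavy chimeric tails that would otherwise inflate σ;
on clean simulated data the trim biases σ down by ~6%, which is
immaterial because every comparison against the model uses the same
statistic). A pair is *discordant* when its mates map more than μ + 4σ
apart or to different chromosomes; at 4σ, fewer than ~10⁻⁴ of genuine
pairs are mislabelled. A *split read* maps in two segments; segments
closer than 5 kb are attributed to small indels and ignored, and MAPQ < 5
segments are too ambiguous to use.

A non-reference TE insertion leaves a characteristic signature: reads
whose one end maps at the breakpoint while the other end (mate, or
second split segment) maps inside the donor element's annotated copy.
Evidence reads are linked to a TE when the TE-side mapping overlaps an
annotated element by at least 80% of the read's mapped span; the 80%
rather than 100% absorbs annotation boundary error and TE footprints.
Breakpoint-side mappings ("anchors") are clustered along the genome with
a merge distance of μ + 4σ — the spatial scale over which one insertion
scatters its evidence — requiring cluster members to share a candidate
TE. A cluster is called when its split + discordant read count reaches
the depth-scaled threshold

    T(c) = max(2, floor(c / 10))   (c = genome-wide mean coverage),

or twice that when the cluster lacks *facing pairs*: at a real insertion,
forward-strand anchors accumulate left of the breakpoint and
reverse-strand anchors right of it, mates on the same element.
"Facing" is implemented as at least one discordant anchor on each side,
inner edges converging within one read length, sharing a TE — the
minimal reading of "independent read pairs facing one another"; the
breakpoint is the interval between the innermost facing edges, collapsed
to a point whenever a split read crosses it (split junctions are
base-precise). A `--strict` mode doubles all thresholds for sets of
nearly identical samples.

An absence (the sample lacking a reference TE) is the mirror image:
split/discordant reads *span* the element — the gap between a split
read's segments, or between the inner edges of a facing discordant pair,
covers ≥ 80% of the TE — while internal depth collapses. The call
requires internal mean depth below 10% of the mean depth in the 2 kb
flanks (flank bases inside other annotated TEs are excluded, since those
may themselves be absent), with the same threshold T(c) on spanning
reads; when the depth ratio is between 0.1 and 1 the evidence is
ambiguous (partial deletion, mismapping) and twice the spanning reads
are demanded. Spanning evidence wider than 20 kb is discarded: in
Arabidopsis 99.9% of TEs are shorter, so wider spans indicate unrelated
structural variation. All TEs inside one spanned region can be reported;
candidate TEs at one site are ranked by supporting-read count.

Cut-paste donor sites deserve a note: the moved copy's reads still map
back to the donor locus (it is the only copy in the reference), so the
internal-depth signature of a clean deletion is absent there. The
evaluator therefore scores absence calls against planted deletions only
and treats donor-site calls as neither true nor false positives.

## Refinement across a population

Per-sample insertion calls are merged into population sites (breakpoints
within 100 bp sharing a TE collapse; the consensus interval is the
intersection of member intervals, or their union when disjoint). Every
sample is then re-genotyped at every site: carriers keep 1; a
non-carrier with a zero-coverage base anywhere within the site ± one
read length is NA (the data cannot distinguish presence from absence);
otherwise a single TE-linked split read suffices for 1, else 0. One
read is the minimal nonzero evidence — the point of refinement is that a
site already established by other samples needs far less support than a
de novo discovery. Absences are not refined. Refinement is additive:
no discovery call is ever demoted.

## The simulator and what it does (not) show

`simulate_genome` builds random-sequence chromosomes (random sequence is
maximally mappable at read-length scale) carrying TE copies drawn from
family consensus sequences with 2% per-copy substitutions, placed ≥ 1 kb
apart and ≥ 3 kb from chromosome ends. The ≥ 1 kb spacing keeps the 2 kb
depth flanks informative and prevents a deletion's spanning mates from
landing inside a neighbouring element; real genomes violate this in
pericentromeric TE nests, where the caller's accuracy will be lower than
any number measured here. `apply_variants` excises deletion and
cut-paste TEs and inserts copies at background sites ≥ 6 kb from other
events and ≥ 25 kb from their own donor (so insertion split reads pass
the 5 kb filter and donor/target signatures never overlap — dispersed
transposition, the typical case, not tandem movement).

`generate_reads` draws round(c·G/2L) pairs (coverage c, genome length G,
read length L = 100 bp default) with inserts ~ Normal(400, 50) bp and
i.i.d. substitution errors (default 1%, config-exposed). Because read
names encode true origins, `emit_ideal_alignments` can write the exact
alignments a perfect mapper would produce: reads inside unchanged
sequence become concordant records, reads crossing planted junctions
become soft-clipped split records (segments under 20 bp are clipped,
matching a split mapper's seed limit), and mates are lifted through the
event map so pairs straddling events become discordant. MAPQ is a
uniform high value. This path contains *no mapping noise*: repeats,
multimapping, and alignment errors are absent, so round-trip
sensitivities near 1.0 are a statement about the calling logic, not
about real-data performance (the ~9-10% error rates reported for real
resequencing data are dominated by mapping, not calling). It is also why
the low-coverage refinement scenario genotypes a 4× sample at sites
discovered in deeper samples rather than relying on discovery misses: under
ideal alignments a discovery miss occurs almost only at a local coverage
hole, which refinement must report as NA, not rescue.

Matrix generators produce the downstream inputs: genotype matrices with
Beta(0.4, 2.5) presence frequencies (a rare-skewed site-frequency
spectrum), SNP haplotype blocks built as a per-accession Markov chain
(flip rate 0.002/SNP by default, keeping the focal marker correlated
across a large share of a 600-SNP window — the long haplotypes of a
highly selfing species; short-haplotype panels should raise it),
phenotypes with rare carriers drawn uniformly or with probability rising
quadratically toward the phenotype extremes (a graded U-shaped burden),
and DMR methylation matrices with plantable genotype effects.

## Statistical procedures

* **MAF and classification.** Frequencies are computed over non-NA calls
  only. With the minor allele assumed derived: an absence shared by
  ≥ 80% of accessions is a TE insertion private to the reference lineage;
  a presence shared by ≥ 80% is a deletion in the reference; MAF > 20%
  is unclassifiable (NA). Thresholds are taken literally at equality.
  Rare requires both MAF < 3% *and* < 7 carriers (the stricter
  conjunctive reading; both are config-exposed).
* **Window enrichment.** Empirical p = (1 + #{null ≥ observed}) /
  (n + 1) over uniformly placed windows — the +1 keeps finite resampling
  from reporting p = 0.
* **Rank LD.** Pairwise r² over pairwise-complete cases (zero-variance
  or < 2-case pairs are NA and dropped before sorting). The SNP–SNP
  median at rank k is taken over the flanking SNPs' own sorted vectors.
  Edge variants with fewer than 600 flanking SNPs are profiled over what
  exists, with the 200/400 category cut-offs prorated by
  n_ranks/600.
* **Differential expression.** Two-sided Mann–Whitney U; exact
  enumeration when both groups have ≤ 8 members and no ties (where the
  normal approximation is worst), tie-corrected asymptotic otherwise.
  Fold change = (mean+ε)/(mean+ε) with ε = 0.01 FPKM guarding empty
  expression. Storey q-values: π₀(λ) on λ ∈ {0, 0.05, …, 0.6} smoothed
  by a least-squares cubic (four coefficients — the closest polynomial
  analogue of a 4-df smoothing spline, which no installed library
  provides) evaluated at λ = 0.6, clipped to (0, 1].
* **Burden.** Accessions ranked per phenotype (average ranks on ties,
  normalised to [0, 1]); carriers' ranks pooled, binned into 20
  equal-width bins, and fitted with a quadratic by OLS; R², the x²
  coefficient (curvature) and the F-test p are reported.
* **Methylation.** Weighted methylation level = methylated / total
  cytosine calls per 200 bp bin; bins with no covered cytosines are NA;
  bases inside the variant's own TE interval are excluded so internal TE
  methylation cannot masquerade as flanking signal. Pericentromeric
  means within 3 Mb of the centromere midpoint. The permutation scan
  permutes whole accession labels of the methylation matrix (preserving
  within-accession correlation across DMRs), drops DMRs missing in
  > 15% of accessions, tests common variants (MAF > 3%) two-sidedly on
  |r|, and calls a pair significant only when the observed value beats
  all permutations — the attainable p floor is 1/(n_perm + 1).

## Problem sizes used in the tests

The acceptance-style checks run the full published simulation design —
a 5 Mb genome (2 × 2.5 Mb), 200 TEs, 50 copy-paste + 50 cut-paste
insertions and 100 deletions, called from ideal alignments at 5×, 10×,
20× and 40× — plus a 6-sample refinement scenario (five 12× samples and
one 4×), a 600-SNP/187-accession LD panel, a 400-phenotype burden
simulation and a 100 × 100-pair null permutation scan. Unit tests use
smaller seeded instances of the same generators. All simulations are
deterministic given their seeds.

## Known limitations

* Ideal alignments bound calling-logic error only; with real aligners
  sensitivity drops for nested, fragmented or low-complexity TEs.
* The classifier polarises by frequency; a true deletion that swept the
  population is misread as a reference insertion (acknowledged
  impossibility of distinguishing these without outgroups).
* The q-value π₀ smoother is a cubic fit, not R's spline; on typical
  p-value sets the difference is far below the q < 0.01 decision scale.
* `refine` trusts the merged site list; a false-positive site in one
  sample can propagate 0/1 genotypes (not NA) to others.
* The simulator plants neither nested insertions, tandem duplications,
  TE footprints (configurable but default 0), nor bisulfite reads;
  methylation matrices are consumed as processed levels.
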