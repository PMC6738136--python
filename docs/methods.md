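# Methods

This note documents the models behind `straindiverge`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real data.

## Variant filtering

Variant records (VCF v4.2 with `GT:AD:DP`, up to four alleles per site from
a caller run with a ploidy-4 upper bound) pass two filters before any
analysis: site depth DP ≥ 8, and per-alternate fraction AD/DP ≥ 0.10. The
fraction rule is applied per alternate allele against site depth, and the
boundary is inclusive ("fewer than 10%" is what gets excluded): an allele
at exactly 10% survives. Alternates failing the rule are projected out of
an otherwise surviving record; records missing AD or DP are rejected and
counted separately. Filtering is a pure subset/projection and therefore
idempotent.

Allele-balance observations y = AD_alt/(AD_ref + AD_alt) are taken from
biallelic SNP records with both alleles observed (0 < y < 1). Records that
remain multiallelic after filtering are excluded from the ploidy model —
the mixture is defined on biallelic fractions — but still count in gene
variant profiles, one contribution per alternate.

## Ploidy from allele balance

For ploidy m, heterozygous fractions cluster near j/m (j = 1..m−1 carrier
haplotypes). Each hypothesis m ∈ {2, 3, 4} is a Gaussian mixture on (0,1)
with means fixed at j/m and per-component standard deviations fitted by EM
(σ floored at 1e-3; convergence at ΔlogL < 1e-6 or 500 iterations; logL is
non-decreasing by construction). The observation model is Gaussian on y;
depth is used only by the filter. The Gaussian is a documented, swappable
choice — a beta-binomial on counts would use depth directly but the
fraction-space mixture is what the ploidy literature fits, and at depth
≥ 8 the difference is immaterial for model choice.

**Weights are fixed uniform at 1/(m−1) by default.** A ploidy-m hypothesis
here asserts that every carrier-multiplicity class occurs in comparable
proportion, which matches variants arising independently on random
haplotype subsets. The alternative — free weights — makes the hypothesis
family nested: the tetraploid model can zero its 1/4 and 3/4 components
and reproduce the diploid fit exactly, so likelihoods cannot separate a
diploid from a weight-degenerate tetraploid and any margin rule becomes
vacuous. That degeneracy is real in published strain comparisons (a
"tetraploid or diploid" call is exactly this shape); `weights="free"`
reproduces it when wanted.

**Supports and the margin rule.** Hypothesis supports are posterior model
probabilities under equal priors, i.e. a softmax of the total
log-likelihoods. A per-site (geometric-mean) transform was considered and
rejected: the per-site logL gap between the triploid and tetraploid
hypotheses on clean tetraploid data at depth ~50 is only ≈ 0.12 nat, so
any bounded per-site transform pins the support gap near zero no matter
how many sites agree; the total-likelihood posterior instead accumulates
evidence over sites and is decisive exactly when the data are. A ploidy is
called only when the top support exceeds the runner-up by ≥ 0.10
(configurable); ties and weak separations report "ambiguous", and fewer
than 50 usable sites report "no call".

**Denoising.** Before fitting, a free 3-component mixture (means
initialized at 1/4, 1/2, 3/4; means, σ and weights free) augmented with a
Uniform(0,1) component is fitted, and every site whose posterior
responsibility is highest for the uniform component is dropped. On pure
uniform input this removes essentially everything and the downstream call
is "no call"; uniform contamination hiding under a genuine mode (within
roughly ±2σ of a component mean) is not removable by construction.

**Free-mixture ceiling.** The unconstrained 3-component fit is also used
as a likelihood ceiling in tests (logL_free ≥ logL_m for every m). Because
EM only finds local optima, the free fit is multi-started from the
canonical init and from each fixed-hypothesis solution expanded to three
components, which guarantees the nesting inequality up to EM tolerance.

**Per-contig calls.** Contigs longer than 10,000 bp with ≥ 50 sites are
called independently (denoised per contig); the genome summary reports,
per ploidy level, the summed length of contigs called that level divided
by the summed length of all called contigs, plus the fraction of tested
contigs passing the margin rule.

## Ploidy from k-mer pairs

Canonical 21-mers (lexicographic minimum of k-mer and reverse complement;
k configurable odd 15–31) are bucketed, for every position p, by the
string with p wildcarded, in both orientations. A bucket with exactly two
distinct canonical k-mers yields a pair; buckets with more members are
repeat-ambiguous loci and yield nothing. Pairing at any position (not the
middle base only) maximizes pair yield on small genomes while the
two-member rule excludes ambiguous loci. Counts below ci = 1 are ignored
and pairs with summed coverage above cs = 10,000 dropped.

With haploid (per-copy) coverage n, genotype centers in
(log total coverage, minor fraction) are AB (2n, 1/2), AAB (3n, 1/3),
AAAB (4n, 1/4) and AABB (4n, 1/2). Pairs are assigned to the nearest
center, each axis standardized by its spread over the observed pairs
(floors 0.2 in log-coverage and 0.05 in fraction keep degenerate inputs
classifiable); a nearest-center rule is deterministic and testable where a
density plot would need a human reader. Pairs whose two best candidates
are AB and AABB at nearly equal distance (within 5%) are genuinely
unresolved at fraction 1/2 and are excluded from the modal vote. The
ploidy call is the copy number of the modal genotype.

**Haploid coverage.** n̂ is estimated from the dominant peak T* of the
smoothed total-coverage histogram by scoring the candidate grids
n̂ = T*/p for p ∈ {2, 3, 4} on mean nearest-center distance and taking the
smallest p within 5% of the best fit. Parsimony matters because minor
fractions fold at 1/2: a diploid's AB smudge is reproduced exactly by the
AABB center of the p = 4 grid, and the fold's lower tail leaks into the
richer grids' AAB/AAAB centers, so the p = 4 grid always fits a diploid at
least as well as p = 2. One further consistency rule: a grid whose implied
call is tetraploid must put at least 10% of pairs in the quarter-fraction
AAAB smudge — a genuine tetraploid with all carrier classes does, while a
diploid misread at twice its coverage does not and falls back to the
diploid anchor. A window-anchored estimate (peak of totals restricted to
fractions 0.4–0.5) was rejected for exactly this reason: the AABB smudge
of a tetraploid sits inside that window at 4n and halves the estimate.
Limitation: a tetraploid whose heterozygous sites are exclusively
AABB-type is indistinguishable from a diploid at the k-mer level.

## Gene complement

Pooled genes are clustered greedily, longest first (cd-hit style): a gene
joins the first cluster whose representative it matches at global-alignment
identity ≥ 0.8 (edlib edit distance over the longer length) with length
ratio ≥ 0.8, which for a global alignment also enforces ≥ 0.8 mutual
coverage; otherwise it founds a cluster. Equal lengths are ordered by gene
id, so the partition is stable under input permutation. Consensus is
column-majority over representative-anchored alignments (insertions
relative to the representative do not vote; ties go to the representative).

Placement is seed-and-extend: exact 21-bp seeds every 50 bp (both strands)
nominate windows, the full gene is infix-aligned into each window with
edlib, and the best placement with identity ≥ 0.9 is kept (full query
coverage by construction). At the 0.9 identity floor a clean seed is
missed with probability ~4e-6 per gene. The built-in aligner serves the
intron-free synthetic genomes; spliced placements computed externally can
be substituted for real genomes since merging and classification only
consume placement intervals.

Same-contig, same-strand placements overlapping by at least 10% of the
**shorter** placement merge transitively (union-find) into one locus; the
shorter-gene denominator is the conservative reading of "10% of the gene
length" and is configurable. Clusters sharing a merged locus in any strain
become one family; a family's presence set is the set of strains where it
placed, partitioned into core (all strains) / shared / exclusive. Gene
density is n / Σ(contig lengths > 500 bp) × 1e6, truncated to an integer —
truncation, not half-up rounding, is what reproduces the published density
table from its printed inputs.

## Allele-aware divergence

Two strains' gene copies are aligned globally (match +1, mismatch −1, gap
open −2, extend −0.5; Biopython `PairwiseAligner`). Per column, a strain's
symbol set is its aligned base (or gap) plus any filtered alternate
alleles at that position: SNP and MNP alleles contribute substituted
bases, a deletion allele contributes the gap symbol at each deleted
position, and an insertion allele contributes its bases into following gap
columns. Columns are independent — the caller's genotypes are unphased, so
an allele may be used at one column regardless of choices at another; the
brute-force test oracle enumerates assignments under the same assumption.
A mutation is a column where the two sets are disjoint; the rate divides
by alignment length (configuration point: the published normalization
"length of the gene" is ambiguous between the two copies; alignment length
is symmetric and never shorter than either). Zero mutations defines an
identical gene pair; identical pairs are counted per strain pair.

## Category statistics

Within a functional category, per-gene rates (counts/length) of each
variant type are compared across strains by one-way ANOVA; per-family
between-strain mutation rates are compared across strain pairs by
Kruskal–Wallis (those rates are zero-inflated and long-tailed). Both flag
significance at raw P < 0.01 with no multiple-testing correction by
default (Holm available behind a flag), matching how such thresholds are
conventionally reported. Degenerate inputs (zero variance) report P = 1
with a flag rather than NaN. Wilcoxon signed-rank post-hocs compare groups
pairwise on items matched by identifier (gene families present in both
groups); unmatched items are dropped. Categories with fewer than three
genes per group are reported as insufficient data. A KEGG module is
complete when a two-gene module is fully present, or a larger module
misses at most one gene; genes with several KO assignments keep their
lowest-e-value category.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's shape: three strains at ploidy 3/2/4
derived from one ancestor; ~68.5% of gene families core, ~10% in exactly
two strains, the rest exclusive (ancestral genes lost per strain plus
de-novo exclusive genes appended); category-specific heterozygosity
(defaults 0.002–0.012/bp, lowest for energy metabolism, highest for
genetic information processing) and fixed inter-strain substitution rates
(0.004–0.014/bp, ~97–98% pairwise identity); heterozygous variants (90%
SNPs, 10% indels ≤ 10 bp) assigned to uniform subsets of non-reference
haplotypes; haplotype 0 written as the collapsed assembly so VCF
coordinates and the j/m allele fractions are exact; contigs cut only at
intergenic positions, with a configurable share of <500 bp gene-free
fragments; site depths negative binomial (mean 50, overdispersion 0.3 by
default, Poisson at 0), alternate depths Binomial(DP, j/m), plus a
configurable fraction of uniform-fraction error sites; k-mer counts
Poisson around multiplicity × per-copy coverage.

Not emulated: read-level errors and mapping artifacts, repeats and
transposons (so k-mer pairing sees no repeat-ambiguity beyond chance),
introns/splicing, structural variants, GC or coverage bias along the
genome, and linkage between heterozygous sites. Passing tests therefore
demonstrate the estimators' correctness under the stated sampling models
and the pipeline's internal consistency — not robustness to repeat-rich or
error-rich real libraries, where the external-placement hook and the
denoising stage would carry more weight.

Desk scales: the default preset (3 strains, 1 Mb haploid, 600 genes,
coverage 50) generates in well under a minute; recovery experiments use
5,000-site allele-balance draws and 1 Mb strain simulations, and the
integrated pipeline test runs at 120 kb / 60 genes so that repeated
end-to-end runs stay cheap. All randomness flows from explicit integer
seeds; equal seeds give byte-identical outputs.

## Numerical conventions

Internal coordinates are 0-based half-open; emitted GFF3/VCF are 1-based
per their standards. Report tables round half-up (one decimal for
percentages and Mb; densities truncate as above). EM tolerances and the
σ floor are as stated; axis-standardization floors for the smudge
classifier are 0.2 (log-coverage) and 0.05 (fraction). Ties in the support
argmax yield margin 0 and hence "ambiguous"; ties in consensus voting go
to the representative base.
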