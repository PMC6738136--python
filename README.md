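# straindiverge

Intraspecific genome variation of conspecific polyploid protist strains:
a tested pipeline for ploidy estimation, gene-complement comparison and
allele-aware gene divergence, built around the kind of study design in which
two or three strains of one species are sequenced, assembled and compared —
for example chrysophyte isolates that turn out to be diploid, triploid and
tetraploid despite belonging to the same species.

## What it computes

**Ploidy from allele balance.** At a heterozygous site in a ploidy-*m*
genome carried by *j* haplotypes, the alternate-read fraction
*y* = AD<sub>alt</sub>/(AD<sub>ref</sub>+AD<sub>alt</sub>) concentrates near
*j/m*. After filtering (depth ≥ 8, variant fraction ≥ 10%) and denoising
with a uniform error component, each hypothesis *m* ∈ {2, 3, 4} is scored by
a Gaussian mixture with means fixed at *j/m* (*j* = 1..*m*−1) fitted by EM.
Supports are posterior model probabilities; a ploidy is called when the best
support beats the runner-up by ≥ 10%, genome-wide and per contig
(> 10 kb), with per-contig calls aggregated by contig length.

**Ploidy from k-mer pairs.** Heterozygous SNPs produce canonical k-mer
pairs (k = 21) differing at one position. In the plane of (summed pair
coverage, minor fraction), pairs cluster at genotype-specific positions:
AB (2n̂, 1/2), AAB (3n̂, 1/3), AAAB (4n̂, 1/4), AABB (4n̂, 1/2), where n̂ is
the haploid k-mer coverage. The modal genotype gives an assembly-free
second ploidy estimate.

**Gene complement.** Predicted genes of all strains are pooled, clustered
(identity ≥ 0.8, mutual coverage ≥ 0.8, length ratio ≥ 0.8), merged by
consensus, placed back onto every genome, and same-strand placements
overlapping ≥ 10% of the shorter gene are merged into one locus. Families
are classified core / shared / exclusive, and gene density is
*d* = *n* / Σ(contig lengths > 500 bp) × 10⁶ genes/Mb.

**Allele-aware divergence.** Two strains' copies of a gene are compared
per alignment column; a mutation is counted only where no combination of
called alleles can produce a match, normalized by alignment length. A
strain's haploid genome size is its total DNA content divided by the called
ploidy.

**Category statistics.** Per-gene SNP/insertion/deletion rates are
stratified by KEGG-style functional category and compared across strains
(one-way ANOVA) and across strain pairs (Kruskal–Wallis), with Wilcoxon
signed-rank post-hocs, at P < 0.01. KEGG modules count as complete when a
two-gene module is fully present or a larger module misses at most one gene.

Because the study's raw data cannot ship, a first-class synthetic generator
(`straindiverge.simulate`) produces study-shaped inputs — three strains at
ploidy 3/2/4 sharing ~68.5% core families, category-specific
heterozygosity, binomial allele depths, fragmented contigs and Poisson
k-mer coverage — with full ground truth, in the standard formats (FASTA,
GFF3, VCF v4.2, TSV).

## Worked example

```sh
straindiverge simulate --out demo --seed 1 --haploid-bp 200000 --n-genes 100
straindiverge ploidy-ab --vcf demo/alpha.vcf --fasta demo/alpha.contigs.fasta
straindiverge ploidy-kmer --kmers demo/alpha.kmers.tsv
```

prints (strain `alpha` is simulated triploid):

```
genome call: 3 (margin 1.000, supports {2: 0.0, 3: 1.0, 4: 0.0}, 1454 sites after denoising removed 0)
call: 3 (haploid coverage 16.5, genotypes {'AB': 2910, 'AAB': 21261, 'AAAB': 3332, 'AABB': 1330}, unresolved 63)
```

The allele-balance model puts all posterior support on triploidy, and the
k-mer pairs pile up in the AAB smudge at minor fraction 1/3 with haploid
coverage ≈ 50/3 — the two independent estimators agree on ploidy 3. The
full pipeline (`straindiverge run --config run.cfg`) writes `report.tsv`,
per-contig `*.ploidy.tsv`, `venn.tsv`, `rates.tsv` and `stats.tsv`.

Python API equivalents live in `straindiverge.allele_balance`,
`straindiverge.smudge`, `straindiverge.geneset`, `straindiverge.divergence`,
`straindiverge.stats` and `straindiverge.pipeline`; see `docs/methods.md`
for the models and their assumptions.

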