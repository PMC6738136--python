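"""Synthetic multi-strain polyploid genome generator.

Emulates the study design this package targets: a small number of conspecific
protist strains (default three, at ploidy 2 / 3 / 4) that share a large core
gene complement plus strain-exclusive genes. Each strain is represented as
``ploidy`` haplotype copies of a strain reference derived from a common
ancestor by fixed inter-strain substitutions; heterozygous SNPs and short
indels are injected at functional-category-specific rates and assigned to a
random subset of the non-reference haplotypes. Haplotype 0 is written out as
the (collapsed) assembly, so emitted VCF records are expressed against it and
the alternate-read fraction at a site carried by j of m haplotypes is j/m.

Outputs use the standard text formats the analysis modules consume: contig
FASTA, gene FASTA, GFF3, VCF v4.2 (GT:AD:DP) and a k-mer count TSV. All
randomness flows from explicit integer seeds; identical seeds give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kmers import BASES, canonical_kmers, decode_bases, decode_kmers, kmer_array, revcomp

# KEGG-style top-level functional groups plus the two catch-all labels used
# downstream. Weights are the ancestral assignment probabilities.
CATEGORIES = (
    "genetic_information_processing",
    "cellular_processes",
    "energy_metabolism",
    "carbohydrate_metabolism",
    "lipid_metabolism",
    "amino_acid_metabolism",
    "secondary_metabolism",
    "environmental_information_processing",
    "organelle_targeted",
    "unannotated",
)

DEFAULT_CATEGORY_WEIGHTS = {
    "genetic_information_processing": 0.14,
    "cellular_processes": 0.12,
    "energy_metabolism": 0.08,
    "carbohydrate_metabolism": 0.10,
    "lipid_metabolism": 0.08,
    "amino_acid_metabolism": 0.10,
    "secondary_metabolism": 0.06,
    "environmental_information_processing": 0.08,
    "organelle_targeted": 0.08,
    "unannotated": 0.16,
}

# Per-bp heterozygosity by category; energy metabolism is the most conserved
# group, genetic information processing the most variable.
DEFAULT_HET_RATES = {
    "genetic_information_processing": 0.012,
    "cellular_processes": 0.008,
    "energy_metabolism": 0.002,
    "carbohydrate_metabolism": 0.006,
    "lipid_metabolism": 0.006,
    "amino_acid_metabolism": 0.006,
    "secondary_metabolism": 0.008,
    "environmental_information_processing": 0.006,
    "organelle_targeted": 0.004,
    "unannotated": 0.008,
    "intergenic": 0.006,
}

# Fixed inter-strain substitution rates vs. the ancestor (ANI between two
# strains is roughly one minus the sum of their rates; defaults land near the
# 97-98% identity typical of conspecific isolates).
DEFAULT_DIVERGENCE_RATES = {
    "genetic_information_processing": 0.014,
    "cellular_processes": 0.012,
    "energy_metabolism": 0.004,
    "carbohydrate_metabolism": 0.010,
    "lipid_metabolism": 0.010,
    "amino_acid_metabolism": 0.010,
    "secondary_metabolism": 0.012,
    "environmental_information_processing": 0.010,
    "organelle_targeted": 0.008,
    "unannotated": 0.012,
    "intergenic": 0.012,
}

SNP, INSERTION, DELETION = "SNP", "insertion", "deletion"


class PlacementError(RuntimeError):
    """Raised when genes cannot be placed on the requested sequence length."""


@dataclass(frozen=True)
class StrainSpec:
    """Design of one simulated strain."""

    name: str
    ploidy: int
    het_rate: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HET_RATES))
    divergence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE_RATES)
    )
    n_exclusive_genes: int = 25
    mean_coverage: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3, 4):
            raise ValueError(f"ploidy must be 2, 3 or 4, got {self.ploidy}")
        for rates in (self.het_rate, self.divergence):
            for cat, r in rates.items():
                if not 0.0 <= r <= 0.2:
                    raise ValueError(f"rate for {cat} out of [0, 0.2]: {r}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass
class Gene:
    """A gene interval on the strain (or ancestral) reference, 0-based half-open."""

    gene_id: str
    start: int
    end: int
    strand: str
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Ancestor:
    seq: np.ndarray  # uint8 base codes
    genes: list[Gene]

    @property
    def length(self) -> int:
        return int(self.seq.size)


@dataclass
class HetVariant:
    """One injected heterozygous variant on the strain reference (0-based pos)."""

    pos: int
    ref: str
    alt: str
    carriers: tuple[int, ...]  # non-reference haplotype indices (1..ploidy-1)
    vtype: str
    gene_id: str | None
    category: str


@dataclass
class StrainGenome:
    spec: StrainSpec
    seq: np.ndarray  # reference (= haplotype 0) base codes
    genes: list[Gene]  # genes present in this strain (incl. exclusive)
    variants: list[HetVariant]
    n_fixed_substitutions: int

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def ploidy(self) -> int:
        return self.spec.ploidy

    def het_counts_by_gene(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {
            g.gene_id: {SNP: 0, INSERTION: 0, DELETION: 0} for g in self.genes
        }
        for v in self.variants:
            if v.gene_id is not None:
                out[v.gene_id][v.vtype] += 1
        return out

    def haplotypes(self) -> list[str]:
        """Materialize the ploidy haplotype sequences (haplotype 0 first)."""
        ref = decode_bases(self.seq)
        haps = [ref]
        by_pos = sorted(self.variants, key=lambda v: v.pos)
        for h in range(1, self.ploidy):
            pieces: list[str] = []
            cursor = 0
            for v in by_pos:
                if h not in v.carriers:
                    continue
                pieces.append(ref[cursor : v.pos])
                pieces.append(v.alt)
                cursor = v.pos + len(v.ref)
            pieces.append(ref[cursor:])
            haps.append("".join(pieces))
        return haps

    def gene_sequence(self, gene: Gene) -> str:
        s = decode_bases(self.seq[gene.start : gene.end])
        return s if gene.strand == "+" else revcomp(s)


@dataclass
class Contig:
    name: str
    start: int  # on the strain reference, 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Assembly:
    strain: str
    contigs: list[Contig]

    def locate(self, pos: int) -> tuple[str, int]:
        """Reference position -> (contig name, 0-based offset on contig)."""
        for c in self.contigs:
            if c.start <= pos < c.end:
                return c.name, pos - c.start
        raise ValueError(f"position {pos} outside all contigs")

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.contigs}


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    ploidy: dict[str, int]
    family_presence: dict[str, frozenset[str]]  # family id -> strains carrying it
    het_counts: dict[str, dict[str, dict[str, int]]]  # strain -> gene -> vtype -> n
    haploid_length: int

    @property
    def n_families(self) -> int:
        return len(self.family_presence)

    def core_fraction(self) -> float:
        n_strains = len(self.ploidy)
        core = sum(
            1 for p in self.family_presence.values() if len(p) == n_strains
        )
        return core / len(self.family_presence)


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

def make_ancestor(
    length_bp: int,
    n_genes: int,
    gene_length_dist: tuple[float, float] = (1500.0, 300.0),
    seed: int = 0,
    category_weights: dict[str, float] | None = None,
    min_gap: int = 50,
    max_tries: int = 20,
) -> Ancestor:
    """Random ancestral reference with non-overlapping genes on both strands.

    Gene lengths are drawn from a normal distribution (floored at 200 bp) and
    intervals are laid out left to right with Dirichlet-distributed intergenic
    gaps of at least ``min_gap`` bp, which guarantees non-overlap whenever the
    genes fit at all.
    """
    rng = np.random.default_rng(seed)
    weights = category_weights or DEFAULT_CATEGORY_WEIGHTS
    cats = sorted(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    lens = None
    for _ in range(max_tries):
        cand = np.maximum(
            np.round(rng.normal(gene_length_dist[0], gene_length_dist[1], n_genes)),
            200,
        ).astype(int)
        if cand.sum() + min_gap * (n_genes + 1) <= length_bp:
            lens = cand
            break
    if lens is None:
        raise PlacementError(
            f"cannot place {n_genes} genes of ~{gene_length_dist[0]} bp "
            f"on {length_bp} bp"
        )

    slack = length_bp - int(lens.sum()) - min_gap * (n_genes + 1)
    gaps = min_gap + np.floor(rng.dirichlet(np.ones(n_genes + 1)) * slack).astype(int)
    genes: list[Gene] = []
    cursor = 0
    cat_idx = rng.choice(len(cats), size=n_genes, p=probs)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    for i in range(n_genes):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lens[i])
        genes.append(
            Gene(f"g{i + 1:05d}", start, end, str(strands[i]), cats[int(cat_idx[i])])
        )
        cursor = end
    seq = rng.integers(0, 4, size=length_bp, dtype=np.uint8)
    return Ancestor(seq=seq, genes=genes)


# ---------------------------------------------------------------------------
# strain derivation
# ---------------------------------------------------------------------------

def _rate_arrays(
    length: int, genes: list[Gene], rates: dict[str, float]
) -> np.ndarray:
    """Per-base rate array; intergenic bases get rates['intergenic'] (or the
    mean of the category rates if absent)."""
    default = rates.get("intergenic", float(np.mean(list(rates.values()))))
    arr = np.full(length, default, dtype=float)
    for g in genes:
        arr[g.start : g.end] = rates.get(g.category, default)
    return arr


def _gene_index_arrays(length: int, genes: list[Gene]) -> np.ndarray:
    idx = np.full(length, -1, dtype=np.int32)
    for i, g in enumerate(genes):
        idx[g.start : g.end] = i
    return idx


def derive_strain(
    ancestor: Ancestor,
    spec: StrainSpec,
    absent_genes: frozenset[str] | set[str] = frozenset(),
    gene_length_dist: tuple[float, float] = (1500.0, 300.0),
    category_weights: dict[str, float] | None = None,
    snp_fraction: float = 0.9,
    exclusive_spacer: int = 200,
) -> StrainGenome:
    """Derive one strain from the ancestor.

    Genes in ``absent_genes`` are overwritten with random sequence (the strain
    lost them; coordinates of the remaining genes are preserved). Exclusive
    genes are appended after the ancestral region. Fixed inter-strain
    substitutions go onto all haplotypes (i.e. into the strain reference);
    heterozygous variants are recorded against it and assigned to 1..ploidy-1
    of the non-reference haplotypes.
    """
    rng = np.random.default_rng(spec.seed)
    weights = category_weights or DEFAULT_CATEGORY_WEIGHTS
    cats = sorted(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    seq = ancestor.seq.copy()
    genes: list[Gene] = []
    for g in ancestor.genes:
        if g.gene_id in absent_genes:
            seq[g.start : g.end] = rng.integers(0, 4, size=g.length, dtype=np.uint8)
        else:
            genes.append(dataclasses.replace(g))

    # exclusive genes appended on a tail segment
    tail: list[np.ndarray] = []
    cursor = seq.size
    for i in range(spec.n_exclusive_genes):
        spacer = rng.integers(0, 4, size=exclusive_spacer, dtype=np.uint8)
        glen = int(
            max(200, round(rng.normal(gene_length_dist[0], gene_length_dist[1])))
        )
        gseq = rng.integers(0, 4, size=glen, dtype=np.uint8)
        tail.extend([spacer, gseq])
        start = cursor + exclusive_spacer
        genes.append(
            Gene(
                f"{spec.name}_x{i + 1:04d}",
                start,
                start + glen,
                str(rng.choice(np.array(["+", "-"]))),
                cats[int(rng.choice(len(cats), p=probs))],
            )
        )
        cursor = start + glen
    if tail:
        seq = np.concatenate([seq] + tail)
    length = seq.size

    # fixed inter-strain substitutions
    div_rate = _rate_arrays(length, genes, spec.divergence)
    sub_mask = rng.random(length) < div_rate
    sub_pos = np.nonzero(sub_mask)[0]
    seq[sub_pos] = (seq[sub_pos] + rng.integers(1, 4, size=sub_pos.size)) % 4

    # heterozygous variants
    het_rate = _rate_arrays(length, genes, spec.het_rate)
    het_pos = np.nonzero(rng.random(length) < het_rate)[0]
    gene_idx = _gene_index_arrays(length, genes)
    m = spec.ploidy
    ref_str = decode_bases(seq)

    variants: list[HetVariant] = []
    blocked_until = -1
    for p in het_pos:
        p = int(p)
        if p <= blocked_until or p >= length - 12:
            continue
        gi = int(gene_idx[p])
        gene = genes[gi] if gi >= 0 else None
        j = int(rng.integers(1, m))  # carrier count 1..m-1
        carriers = tuple(
            sorted(int(c) for c in rng.choice(np.arange(1, m), size=j, replace=False))
        )
        u = rng.random()
        if u < snp_fraction:
            ref = ref_str[p]
            alt = BASES[(seq[p] + int(rng.integers(1, 4))) % 4]
            vtype = SNP
        elif u < snp_fraction + (1 - snp_fraction) / 2:
            ins_len = min(10, 1 + int(rng.geometric(0.5)))
            ref = ref_str[p]
            alt = ref + "".join(
                BASES[b] for b in rng.integers(0, 4, size=ins_len)
            )
            vtype = INSERTION
        else:
            del_len = min(10, 1 + int(rng.geometric(0.5)))
            if gene is not None and p + del_len + 1 > gene.end:
                del_len = max(1, gene.end - p - 1)
            ref = ref_str[p : p + del_len + 1]
            alt = ref_str[p]
            vtype = DELETION
            blocked_until = p + del_len
        variants.append(
            HetVariant(
                pos=p,
                ref=ref,
                alt=alt,
                carriers=carriers,
                vtype=vtype,
                gene_id=gene.gene_id if gene else None,
                category=gene.category if gene else "intergenic",
            )
        )
        blocked_until = max(blocked_until, p)

    return StrainGenome(
        spec=spec,
        seq=seq,
        genes=genes,
        variants=variants,
        n_fixed_substitutions=int(sub_pos.size),
    )


# ---------------------------------------------------------------------------
# fragmentation + writers
# ---------------------------------------------------------------------------

def fragment_genome(
    strain: StrainGenome,
    n_contigs: int = 50,
    short_contig_fraction: float = 0.1,
    short_len_range: tuple[int, int] = (150, 450),
    seed: int | None = None,
) -> Assembly:
    """Cut the strain reference into contigs at intergenic positions.

    A ``short_contig_fraction`` share of the contigs are small (< 500 bp)
    gene-free fragments carved out of large intergenic gaps, to exercise the
    assembly-size filter downstream. Gene intervals are never split.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(strain.spec.seed + 7919 if seed is None else seed)
    length = strain.seq.size
    genes = sorted(strain.genes, key=lambda g: g.start)
    # intergenic gaps
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for g in genes:
        if g.start > cursor:
            gaps.append((cursor, g.start))
        cursor = max(cursor, g.end)
    if cursor < length:
        gaps.append((cursor, length))

    n_short = int(round(short_contig_fraction * n_contigs))
    n_plain_cuts = n_contigs - 1 - 2 * n_short
    if n_plain_cuts < 0:
        raise ValueError("n_contigs too small for requested short_contig_fraction")

    cuts: list[int] = []
    big_gaps = [g for g in gaps if g[1] - g[0] >= short_len_range[1] + 20]
    if n_short > 0 and not big_gaps:
        raise PlacementError("no intergenic gap large enough for short contigs")
    used_gaps: set[tuple[int, int]] = set()
    for i in range(n_short):
        lo, hi = big_gaps[int(rng.integers(0, len(big_gaps)))]
        ell = int(rng.integers(short_len_range[0], short_len_range[1]))
        x = int(rng.integers(lo + 5, hi - ell - 5))
        cuts.extend([x, x + ell])
        used_gaps.add((lo, hi))
    # one plain cut per distinct gap so cuts cannot carve accidental short
    # fragments out of a single intergenic stretch
    candidates = [g for g in gaps if g not in used_gaps and g[1] - g[0] >= 3]
    if n_plain_cuts > len(candidates):
        raise PlacementError("not enough intergenic gaps for requested contigs")
    chosen = rng.choice(len(candidates), size=n_plain_cuts, replace=False)
    for gi in chosen:
        lo, hi = candidates[int(gi)]
        cuts.append(int(rng.integers(lo + 1, hi - 1)))
    bounds = [0] + sorted(set(cuts)) + [length]
    contigs = [
        Contig(f"{strain.name}_ctg{i + 1:04d}", bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
        if bounds[i + 1] > bounds[i]
    ]
    return Assembly(strain=strain.name, contigs=contigs)


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{_wrap_fasta(seq)}\n")


def write_assembly(
    strain: StrainGenome, assembly: Assembly, fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write contig FASTA plus a GFF3 of genes in contig coordinates."""
    ref = decode_bases(strain.seq)
    write_fasta(fasta_path, [(c.name, ref[c.start : c.end]) for c in assembly.contigs])
    genes = sorted(strain.genes, key=lambda g: g.start)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ctg, off = assembly.locate(g.start)
            fh.write(
                f"{ctg}\tstraindiverge\tgene\t{off + 1}\t{off + g.length}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};category={g.category}\n"
            )


def write_gene_fasta(strain: StrainGenome, path: str | Path) -> None:
    write_fasta(
        path,
        [(g.gene_id, strain.gene_sequence(g)) for g in sorted(strain.genes, key=lambda g: g.start)],
    )


# ---------------------------------------------------------------------------
# read-level observations
# ---------------------------------------------------------------------------

def simulate_allele_depths(
    strain: StrainGenome,
    assembly: Assembly,
    mean_coverage: float | None = None,
    overdispersion: float = 0.3,
    error_sites_fraction: float = 0.02,
    seed: int = 0,
    vcf_path: str | Path | None = None,
) -> list[tuple[str, int, str, str, str, int, int]]:
    """Simulate per-site depths for every injected het variant and write a VCF.

    Site depth is negative binomial with the requested mean (Poisson when
    ``overdispersion`` is 0); the alternate-allele depth is Binomial(depth,
    j/m) for a variant carried by j of m haplotypes. An extra
    ``error_sites_fraction`` share of sites gets a Uniform(0,1) alternate
    fraction to exercise the denoising stage. Genotypes are padded to four
    alleles, mirroring a caller run with a ploidy-4 upper bound.

    Returns the records as tuples (contig, pos1, ref, alt, gt, alt_depth, dp).
    """
    mu = strain.spec.mean_coverage if mean_coverage is None else mean_coverage
    rng = np.random.default_rng(seed)
    m = strain.ploidy
    ref_str = decode_bases(strain.seq)

    def draw_depth() -> int:
        if overdispersion <= 0:
            return int(rng.poisson(mu))
        r = 1.0 / overdispersion
        return int(rng.negative_binomial(r, r / (r + mu)))

    records: list[tuple[str, int, str, str, str, int, int]] = []
    for v in strain.variants:
        dp = draw_depth()
        alt_dp = int(rng.binomial(dp, len(v.carriers) / m)) if dp > 0 else 0
        n_alt = min(3, max(1, round(4 * len(v.carriers) / m)))
        gt = "/".join(["0"] * (4 - n_alt) + ["1"] * n_alt)
        ctg, off = assembly.locate(v.pos)
        records.append((ctg, off + 1, v.ref, v.alt, gt, alt_dp, dp))

    n_err = int(round(error_sites_fraction * len(strain.variants)))
    used = {v.pos for v in strain.variants}
    for _ in range(n_err):
        p = int(rng.integers(0, strain.seq.size))
        if p in used:
            continue
        used.add(p)
        dp = draw_depth()
        frac = rng.random()
        alt_dp = int(np.clip(round(dp * frac), 0, dp))
        ref = ref_str[p]
        alt = BASES[(strain.seq[p] + int(rng.integers(1, 4))) % 4]
        ctg, off = assembly.locate(p)
        records.append((ctg, off + 1, ref, alt, "0/0/0/1", alt_dp, dp))

    order = {c.name: i for i, c in enumerate(assembly.contigs)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    if vcf_path is not None:
        write_vcf(vcf_path, strain.name, assembly, records)
    return records


def write_vcf(
    path: str | Path,
    sample: str,
    assembly: Assembly,
    records: list[tuple[str, int, str, str, str, int, int]],
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=straindiverge-simulate\n")
        for c in assembly.contigs:
            fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for ctg, pos, ref, alt, gt, alt_dp, dp in records:
            ref_dp = max(dp - alt_dp, 0)
            fh.write(
                f"{ctg}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ref_dp},{alt_dp}:{dp}\n"
            )


# ---------------------------------------------------------------------------
# k-mer coverage
# ---------------------------------------------------------------------------

@dataclass
class KmerCounts:
    """Canonical k-mer count table (packed 2-bit representation, sorted)."""

    kmers: np.ndarray  # int64, sorted ascending
    counts: np.ndarray  # int64
    k: int

    def to_tsv(self, path: str | Path) -> None:
        strings = decode_kmers(self.kmers, self.k)
        with open(path, "w") as fh:
            for s, c in zip(strings, self.counts):
                fh.write(f"{s}\t{int(c)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCounts":
        kmers: list[int] = []
        counts: list[int] = []
        k = None
        with open(path) as fh:
            for line in fh:
                s, c = line.split("\t")
                if k is None:
                    k = len(s)
                elif len(s) != k:
                    raise ValueError("mixed k-mer lengths in TSV")
                kmers.append(int(kmer_array(s, k)[0]))
                counts.append(int(c))
        if k is None:
            raise ValueError("empty k-mer TSV")
        km = np.array(kmers, dtype=np.int64)
        ct = np.array(counts, dtype=np.int64)
        km = canonical_kmers(km, k)
        order = np.argsort(km, kind="stable")
        return cls(kmers=km[order], counts=ct[order], k=k)

    def to_dict(self) -> dict[str, int]:
        return dict(zip(decode_kmers(self.kmers, self.k), (int(c) for c in self.counts)))


def simulate_kmer_counts(
    strain: StrainGenome,
    mean_coverage: float | None = None,
    k: int = 21,
    seed: int = 0,
    tsv_path: str | Path | None = None,
) -> KmerCounts:
    """Poisson-noised canonical k-mer counts over all haplotype copies.

    Each haplotype contributes per-copy coverage mean_coverage/ploidy, so a
    k-mer present on j copies has expected count j*mean_coverage/ploidy.
    """
    if k % 2 == 0 or not 1 <= k <= 31:
        raise ValueError("k must be odd and <= 31")
    mu = strain.spec.mean_coverage if mean_coverage is None else mean_coverage
    per_copy = mu / strain.ploidy
    rng = np.random.default_rng(seed)
    parts = [canonical_kmers(kmer_array(h, k), k) for h in strain.haplotypes()]
    allk = np.concatenate(parts)
    uniq, mult = np.unique(allk, return_counts=True)
    obs = rng.poisson(mult * per_copy)
    keep = obs > 0
    result = KmerCounts(kmers=uniq[keep], counts=obs[keep].astype(np.int64), k=k)
    if tsv_path is not None:
        result.to_tsv(tsv_path)
    return result


# ---------------------------------------------------------------------------
# multi-strain preset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    ancestor: Ancestor
    strains: dict[str, StrainGenome]
    assemblies: dict[str, Assembly]
    truth: GroundTruth


def default_strain_specs(seed: int = 0, mean_coverage: float = 50.0) -> list[StrainSpec]:
    """Three strains at ploidy 3 / 2 / 4, mirroring the study layout."""
    return [
        StrainSpec(name="alpha", ploidy=3, mean_coverage=mean_coverage, seed=seed * 1000 + 11),
        StrainSpec(name="beta", ploidy=2, mean_coverage=mean_coverage, seed=seed * 1000 + 23),
        StrainSpec(name="gamma", ploidy=4, mean_coverage=mean_coverage, seed=seed * 1000 + 37),
    ]


def simulate_strain_set(
    haploid_bp: int = 1_000_000,
    n_genes: int = 600,
    specs: list[StrainSpec] | None = None,
    seed: int = 0,
    core_fraction: float = 0.685,
    pair_fraction: float = 0.10,
    gene_length_dist: tuple[float, float] = (1500.0, 300.0),
    n_contigs: int | None = None,
) -> SimulatedDataset:
    """Generate the full multi-strain dataset with ground truth.

    Ancestral genes are assigned presence patterns so that roughly
    ``core_fraction`` of all gene families (ancestral plus exclusive) are
    present in every strain, ``pair_fraction`` in exactly two, and the rest in
    one strain only.
    """
    rng = np.random.default_rng(seed)
    specs = specs if specs is not None else default_strain_specs(seed)
    names = [s.name for s in specs]
    ancestor = make_ancestor(
        haploid_bp, n_genes, gene_length_dist, seed=seed * 7 + 1
    )

    n_excl_total = sum(s.n_exclusive_genes for s in specs)
    n_families = n_genes + n_excl_total
    n_core = int(round(core_fraction * n_families))
    n_pair = int(round(pair_fraction * n_families)) if len(names) >= 2 else 0
    n_core = min(n_core, n_genes)
    n_pair = min(n_pair, n_genes - n_core)

    gene_ids = [g.gene_id for g in ancestor.genes]
    perm = rng.permutation(n_genes)
    presence: dict[str, frozenset[str]] = {}
    for rank, gi in enumerate(perm):
        gid = gene_ids[gi]
        if rank < n_core:
            presence[gid] = frozenset(names)
        elif rank < n_core + n_pair:
            pair = rng.choice(len(names), size=2, replace=False)
            presence[gid] = frozenset(names[int(i)] for i in pair)
        else:
            presence[gid] = frozenset([names[int(rng.integers(0, len(names)))]])

    strains: dict[str, StrainGenome] = {}
    assemblies: dict[str, Assembly] = {}
    het_counts: dict[str, dict[str, dict[str, int]]] = {}
    for spec in specs:
        absent = frozenset(
            gid for gid, pres in presence.items() if spec.name not in pres
        )
        sg = derive_strain(
            ancestor, spec, absent_genes=absent, gene_length_dist=gene_length_dist
        )
        strains[spec.name] = sg
        nc = n_contigs if n_contigs is not None else max(4, min(50, haploid_bp // 20_000))
        assemblies[spec.name] = fragment_genome(sg, n_contigs=nc)
        het_counts[spec.name] = sg.het_counts_by_gene()
        for g in sg.genes:
            if g.gene_id not in presence:  # exclusive gene
                presence[g.gene_id] = frozenset([spec.name])

    truth = GroundTruth(
        ploidy={s.name: s.ploidy for s in specs},
        family_presence=presence,
        het_counts=het_counts,
        haploid_length=haploid_bp,
    )
    return SimulatedDataset(
        ancestor=ancestor, strains=strains, assemblies=assemblies, truth=truth
    )


def write_dataset(
    dataset: SimulatedDataset,
    out_dir: str | Path,
    vcf_seed: int = 0,
    kmer_seed: int = 0,
    mean_coverage: float | None = None,
    k: int = 21,
    write_kmers: bool = True,
) -> dict[str, dict[str, Path]]:
    """Write every strain's FASTA/GFF3/gene FASTA/VCF/k-mer TSV plus a
    gene-category table; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for i, (name, sg) in enumerate(sorted(dataset.strains.items())):
        asm = dataset.assemblies[name]
        p = {
            "contigs": out / f"{name}.contigs.fasta",
            "gff": out / f"{name}.genes.gff3",
            "genes": out / f"{name}.genes.fasta",
            "vcf": out / f"{name}.vcf",
            "kmers": out / f"{name}.kmers.tsv",
        }
        write_assembly(sg, asm, p["contigs"], p["gff"])
        write_gene_fasta(sg, p["genes"])
        simulate_allele_depths(sg, asm, seed=vcf_seed * 100 + i, vcf_path=p["vcf"])
        if write_kmers:
            simulate_kmer_counts(
                sg, mean_coverage, k=k, seed=kmer_seed * 100 + i, tsv_path=p["kmers"]
            )
        else:
            del p["kmers"]
        paths[name] = p
    with open(out / "categories.tsv", "w") as fh:
        fh.write("gene_id\tcategory\n")
        seen: set[str] = set()
        for sg in dataset.strains.values():
            for g in sorted(sg.genes, key=lambda g: g.gene_id):
                if g.gene_id not in seen:
                    seen.add(g.gene_id)
                    fh.write(f"{g.gene_id}\t{g.category}\n")
    return paths
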