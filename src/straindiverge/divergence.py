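"""Per-gene variant profiles and allele-aware pairwise divergence.

Within a strain, every gene gets counts of SNPs, insertions and deletions
among the filtered variants falling inside its interval, normalized by gene
length into per-bp rates.

Between strains, two copies of a shared gene are compared column by column
on a global alignment of their reference sequences. At each column the set
of symbols a strain can present is its aligned base (or gap) plus any
alternate alleles called at that position — an unphased allele may be used
at one column independently of choices at other columns. A mutation is
recorded only where the two symbol sets are disjoint: a mismatch that some
allelic variant could reconcile does not count. The mutation count divided
by the alignment length is the mutation rate of the allele; genes with zero
mutations are identical.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align
from intervaltree import IntervalTree

from .variants import DELETION, INSERTION, MNP, SNP, VariantRecord, classify_variant

GAP = "-"


@dataclass
class GeneInterval:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    category: str = "unannotated"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneVariantProfile:
    gene_id: str
    strain: str
    length: int
    counts: dict[str, int]
    category: str = "unannotated"

    def rate(self, vtype: str) -> float:
        return self.counts.get(vtype, 0) / self.length


@dataclass
class AlleleSet:
    """A gene's reference sequence plus its called alternate alleles.

    ``variants`` maps 0-based position within the gene sequence to the list
    of (ref, alt) allele strings anchored there.
    """

    gene_id: str
    strain: str
    seq: str
    variants: dict[int, list[tuple[str, str]]] = field(default_factory=dict)


@dataclass
class PairwiseGeneComparison:
    family_id: str
    strain_a: str
    strain_b: str
    mutations: int
    aligned_length: int

    @property
    def rate(self) -> float:
        return self.mutations / self.aligned_length if self.aligned_length else 0.0

    @property
    def identical(self) -> bool:
        return self.mutations == 0


def profile_gene_variants(
    genes: list[GeneInterval],
    records: list[VariantRecord],
    strain: str = "",
    categories: dict[str, str] | None = None,
) -> list[GeneVariantProfile]:
    """Count filtered variants per gene by type.

    A variant belongs to a gene iff its anchor position (POS, 0-based) lies
    inside the gene's half-open interval; a variant inside two overlapping
    genes counts in both. MNP alleles contribute one SNP per substituted
    base.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.contig][g.start : g.end] = g
    counts: dict[str, dict[str, int]] = {
        g.gene_id: {SNP: 0, INSERTION: 0, DELETION: 0} for g in genes
    }
    for rec in records:
        pos0 = rec.pos - 1
        hits = trees[rec.contig][pos0] if rec.contig in trees else ()
        if not hits:
            continue
        for alt in rec.alts:
            try:
                vtype = classify_variant(rec.ref, alt)
            except ValueError:
                continue
            for hit in hits:
                gene: GeneInterval = hit.data
                if vtype == MNP:
                    counts[gene.gene_id][SNP] += sum(
                        1 for a, b in zip(rec.ref, alt) if a != b
                    )
                else:
                    counts[gene.gene_id][vtype] += 1
    cats = categories or {}
    return [
        GeneVariantProfile(
            gene_id=g.gene_id,
            strain=strain,
            length=g.length,
            counts=counts[g.gene_id],
            category=cats.get(g.gene_id, g.category),
        )
        for g in genes
    ]


def default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def _column_sets(allele_set: AlleleSet, aligned: str) -> list[set[str]]:
    """Per-column symbol sets for one strain given its gapped aligned string.

    Base columns get {aligned base} plus SNP/MNP alternates at that position
    and a gap symbol where a deletion allele covers the position. Gap columns
    get {-} plus bases from insertion alleles anchored just before the gap
    run, consumed left to right.
    """
    sets: list[set[str]] = []
    pos = -1  # last consumed sequence position
    ins_remaining: list[tuple[str, int]] = []  # (inserted seq, offset consumed)
    # deletion coverage and per-position extra symbols
    del_cover: set[int] = set()
    snp_extra: dict[int, set[str]] = defaultdict(set)
    ins_at: dict[int, list[str]] = defaultdict(list)
    for p, alleles in allele_set.variants.items():
        for ref, alt in alleles:
            vtype = classify_variant(ref, alt)
            if vtype == SNP:
                snp_extra[p].add(alt)
            elif vtype == MNP:
                for i, (a, b) in enumerate(zip(ref, alt)):
                    if a != b:
                        snp_extra[p + i].add(b)
            elif vtype == DELETION:
                for i in range(len(alt), len(ref)):
                    del_cover.add(p + i)
            elif vtype == INSERTION:
                ins_at[p].append(alt[len(ref) :])
    for ch in aligned:
        if ch == GAP:
            symbols = {GAP}
            for seq_ins, off in ins_remaining:
                if off < len(seq_ins):
                    symbols.add(seq_ins[off])
            ins_remaining = [
                (s, off + 1) for s, off in ins_remaining if off + 1 <= len(s)
            ]
            sets.append(symbols)
        else:
            pos += 1
            symbols = {ch} | snp_extra.get(pos, set())
            if pos in del_cover:
                symbols.add(GAP)
            sets.append(symbols)
            ins_remaining = [(s, 0) for s in ins_at.get(pos, [])]
    return sets


def compare_gene_pair(
    a: AlleleSet,
    b: AlleleSet,
    family_id: str = "",
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseGeneComparison:
    """Allele-aware mutation count between two strains' copies of a gene."""
    aligner = aligner or default_aligner()
    if a.seq == b.seq:
        cols_a = _column_sets(a, a.seq)
        cols_b = _column_sets(b, b.seq)
        n_cols = len(a.seq)
    else:
        alignment = aligner.align(a.seq, b.seq)[0]
        sa, sb = str(alignment[0]), str(alignment[1])
        cols_a = _column_sets(a, sa)
        cols_b = _column_sets(b, sb)
        n_cols = len(sa)
    mutations = sum(
        1 for x, y in zip(cols_a, cols_b) if not (x & y)
    )
    return PairwiseGeneComparison(
        family_id=family_id,
        strain_a=a.strain,
        strain_b=b.strain,
        mutations=mutations,
        aligned_length=n_cols,
    )


def count_identical(
    comparisons: list[PairwiseGeneComparison],
) -> dict[tuple[str, str], int]:
    """Per unordered strain pair, the number of identical gene families."""
    out: dict[tuple[str, str], int] = defaultdict(int)
    for c in comparisons:
        key = tuple(sorted((c.strain_a, c.strain_b)))
        out[key] += 0
        if c.identical:
            out[key] += 1
    return dict(out)
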