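"""Per-gene variant profiles and allele-aware pairwise mutation counting."""

from itertools import product

import pytest

from straindiverge import divergence as dv
from straindiverge import variants as vr


def vrec(pos, ref="A", alts=("T",), contig="c"):
    return vr.VariantRecord(contig, pos, ref, tuple(alts), 50, (25,) + (25,) * len(alts))


class TestProfiles:
    def test_counts_and_rates(self):
        genes = [dv.GeneInterval("g1", "c", 100, 1100)]
        records = [
            vrec(151),            # SNP inside (0-based 150)
            vrec(901),            # SNP inside
            vrec(501, ref="ACG", alts=("A",)),  # deletion inside
            vrec(1101),           # 0-based 1100 = half-open end -> outside
            vrec(50),             # before gene
        ]
        profiles = dv.profile_gene_variants(genes, records)
        p = profiles[0]
        assert p.counts == {vr.SNP: 2, vr.INSERTION: 0, vr.DELETION: 1}
        assert p.rate(vr.SNP) == pytest.approx(0.002)

    def test_gene_without_variants_is_identical_allele(self):
        profiles = dv.profile_gene_variants([dv.GeneInterval("g1", "c", 0, 500)], [])
        assert profiles[0].counts == {vr.SNP: 0, vr.INSERTION: 0, vr.DELETION: 0}

    def test_overlapping_genes_both_counted(self):
        genes = [dv.GeneInterval("g1", "c", 0, 600), dv.GeneInterval("g2", "c", 400, 900)]
        profiles = dv.profile_gene_variants(genes, [vrec(501)])
        assert all(p.counts[vr.SNP] == 1 for p in profiles)

    def test_mnp_counts_substitutions(self):
        profiles = dv.profile_gene_variants(
            [dv.GeneInterval("g1", "c", 0, 100)], [vrec(10, ref="AC", alts=("TG",))]
        )
        assert profiles[0].counts[vr.SNP] == 2


def brute_force_mutations(a: dv.AlleleSet, b: dv.AlleleSet) -> int:
    """Oracle: enumerate every per-strain assignment of SNP alleles and count
    columns where all assignment pairs mismatch (sequences equal length)."""
    assert len(a.seq) == len(b.seq)

    def realizations(s: dv.AlleleSet):
        positions = sorted(s.variants)
        choices = []
        for p in positions:
            alts = [alt for ref, alt in s.variants[p]]
            choices.append([s.seq[p]] + alts)
        seqs = []
        for combo in product(*choices):
            seq = list(s.seq)
            for p, base in zip(positions, combo):
                seq[p] = base
            seqs.append("".join(seq))
        return seqs

    sa, sb = realizations(a), realizations(b)
    n_mut = 0
    for col in range(len(a.seq)):
        if all(x[col] != y[col] for x in sa for y in sb):
            n_mut += 1
    return n_mut


class TestComparison:
    def test_allelic_variation_induces_match(self):
        a = dv.AlleleSet("g", "A", "ACGT", {3: [("T", "A")]})
        b = dv.AlleleSet("g", "B", "ACGA")
        assert dv.compare_gene_pair(a, b).mutations == 0
        assert dv.compare_gene_pair(a, b).identical

    def test_plain_mismatch_counts(self):
        a = dv.AlleleSet("g", "A", "ACGT")
        b = dv.AlleleSet("g", "B", "ACGA")
        c = dv.compare_gene_pair(a, b)
        assert c.mutations == 1 and not c.identical
        assert c.rate == pytest.approx(1 / 4)

    def test_disjoint_allele_sets_count(self):
        a = dv.AlleleSet("g", "A", "ACGT", {3: [("T", "C")]})
        b = dv.AlleleSet("g", "B", "ACGA", {3: [("A", "G")]})
        assert dv.compare_gene_pair(a, b).mutations == 1

    def test_deletion_allele_matches_gap(self):
        # b lacks one base; a has a deletion allele spanning it
        a = dv.AlleleSet("g", "A", "ACGTACGT", {2: [("GT", "G")]})
        b = dv.AlleleSet("g", "B", "ACGACGT")
        assert dv.compare_gene_pair(a, b).mutations == 0

    def test_insertion_allele_fills_gap(self):
        a = dv.AlleleSet("g", "A", "ACGACGT", {2: [("G", "GT")]})
        b = dv.AlleleSet("g", "B", "ACGTACGT")
        assert dv.compare_gene_pair(a, b).mutations == 0

    def test_symmetry(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            other = list(seq)
            for pos in rng.choice(n, size=3, replace=False):
                other[pos] = "ACGT"[("ACGT".index(other[pos]) + 1) % 4]
            a = dv.AlleleSet("g", "A", seq, {int(rng.integers(0, n)): [(seq[0], "G")]})
            b = dv.AlleleSet("g", "B", "".join(other))
            ab = dv.compare_gene_pair(a, b)
            ba = dv.compare_gene_pair(b, a)
            assert ab.mutations == ba.mutations
            assert ab.identical == ba.identical

    def test_extra_allele_never_increases_count(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=40))
        other = list(seq)
        for pos in (5, 15, 25):
            other[pos] = "ACGT"[("ACGT".index(other[pos]) + 1) % 4]
        b = dv.AlleleSet("g", "B", "".join(other))
        base = dv.compare_gene_pair(dv.AlleleSet("g", "A", seq), b).mutations
        widened = dv.compare_gene_pair(
            dv.AlleleSet("g", "A", seq, {15: [(seq[15], "".join(other)[15])]}), b
        ).mutations
        assert widened <= base

    def test_matches_brute_force_oracle(self, rng):
        for case in range(60):
            n = int(rng.integers(15, 40))
            seq_a = "".join(rng.choice(list("ACGT"), size=n))
            seq_b = list(seq_a)
            for pos in rng.choice(n, size=int(rng.integers(0, 5)), replace=False):
                seq_b[pos] = "ACGT"[("ACGT".index(seq_b[pos]) + 1) % 4]
            seq_b = "".join(seq_b)

            def random_alleles(seq):
                out = {}
                for pos in rng.choice(n, size=int(rng.integers(0, 6)), replace=False):
                    n_alt = int(rng.integers(1, 3))
                    alts = set()
                    while len(alts) < n_alt:
                        c = "ACGT"[int(rng.integers(0, 4))]
                        if c != seq[pos]:
                            alts.add(c)
                    out[int(pos)] = [(seq[pos], alt) for alt in sorted(alts)]
                return out

            a = dv.AlleleSet("g", "A", seq_a, random_alleles(seq_a))
            b = dv.AlleleSet("g", "B", seq_b, random_alleles(seq_b))
            got = dv.compare_gene_pair(a, b).mutations
            assert got == brute_force_mutations(a, b), f"case {case}"


class TestIdenticalCounts:
    def test_grouped_by_pair(self):
        comps = [
            dv.PairwiseGeneComparison("f1", "A", "B", 0, 100),
            dv.PairwiseGeneComparison("f2", "B", "A", 2, 100),
            dv.PairwiseGeneComparison("f3", "A", "C", 0, 100),
        ]
        counts = dv.count_identical(comps)
        assert counts == {("A", "B"): 1, ("A", "C"): 1}

    def test_zero_divergence_pair_all_identical(self):
        comps = [dv.PairwiseGeneComparison(f"f{i}", "A", "B", 0, 500) for i in range(5)]
        assert dv.count_identical(comps) == {("A", "B"): 5}

    def test_no_comparisons(self):
        assert dv.count_identical([]) == {}
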