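"""Generator correctness: placement, determinism, truth/emission consistency."""

import numpy as np
import pytest

from straindiverge import simulate as sim
from straindiverge import variants as vr
from straindiverge._kmers import revcomp


def _intervals_disjoint(genes):
    ordered = sorted(genes, key=lambda g: g.start)
    return all(a.end <= b.start for a, b in zip(ordered, ordered[1:]))


class TestMakeAncestor:
    def test_placement_and_determinism(self):
        a1 = sim.make_ancestor(100_000, 20, (1500, 300), seed=1)
        a2 = sim.make_ancestor(100_000, 20, (1500, 300), seed=1)
        assert len(a1.genes) == 20
        assert all(0 <= g.start < g.end <= 100_000 for g in a1.genes)
        assert _intervals_disjoint(a1.genes)
        assert np.array_equal(a1.seq, a2.seq)
        assert a1.genes == a2.genes
        assert all(g.category in sim.CATEGORIES for g in a1.genes)

    def test_two_fixed_length_genes(self):
        anc = sim.make_ancestor(3000, 2, (1000, 0), seed=7)
        g1, g2 = sorted(anc.genes, key=lambda g: g.start)
        assert g1.length == g2.length == 1000
        assert g1.end <= g2.start

    def test_impossible_placement_raises(self):
        with pytest.raises(sim.PlacementError):
            sim.make_ancestor(5000, 10, (1000, 0), seed=0)


class TestDeriveStrain:
    def test_zero_het_rate_haplotypes_identical(self):
        anc = sim.make_ancestor(20_000, 8, seed=2)
        zero = {c: 0.0 for c in list(sim.CATEGORIES) + ["intergenic"]}
        spec = sim.StrainSpec(
            name="s", ploidy=2, het_rate=zero, n_exclusive_genes=0, seed=4
        )
        sg = sim.derive_strain(anc, spec)
        h = sg.haplotypes()
        assert len(h) == 2 and h[0] == h[1]
        assert sg.variants == []
        assert sg.n_fixed_substitutions > 0  # divergence still applied

    def test_zero_divergence_keeps_ancestor(self):
        anc = sim.make_ancestor(20_000, 8, seed=2)
        zero = {c: 0.0 for c in list(sim.CATEGORIES) + ["intergenic"]}
        spec = sim.StrainSpec(
            name="s", ploidy=3, het_rate=zero, divergence=zero,
            n_exclusive_genes=0, seed=4,
        )
        sg = sim.derive_strain(anc, spec)
        assert np.array_equal(sg.seq, anc.seq)

    def test_truth_counts_match_emitted_vcf(self, tmp_path):
        anc = sim.make_ancestor(60_000, 30, seed=5)
        spec = sim.StrainSpec(name="s", ploidy=3, n_exclusive_genes=2, seed=6)
        sg = sim.derive_strain(anc, spec)
        asm = sim.fragment_genome(sg, n_contigs=5, short_contig_fraction=0.0)
        vcf = tmp_path / "s.vcf"
        sim.simulate_allele_depths(
            sg, asm, error_sites_fraction=0.0, seed=1, vcf_path=vcf
        )
        records = vr.read_vcf(vcf)
        # map contig coordinates back to gene ids via the truth gene table
        per_gene: dict[str, int] = {}
        for rec in records:
            contig = next(c for c in asm.contigs if c.name == rec.contig)
            pos = contig.start + rec.pos - 1
            for g in sg.genes:
                if g.start <= pos < g.end:
                    per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + 1
        truth = sg.het_counts_by_gene()
        truth_totals = {g: sum(c.values()) for g, c in truth.items() if sum(c.values())}
        assert per_gene == truth_totals

    def test_carriers_never_include_reference_haplotype(self):
        anc = sim.make_ancestor(30_000, 10, seed=9)
        sg = sim.derive_strain(anc, sim.StrainSpec(name="s", ploidy=4, seed=8))
        assert all(0 not in v.carriers for v in sg.variants)
        assert all(1 <= len(v.carriers) <= 3 for v in sg.variants)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sim.StrainSpec(name="s", ploidy=5)
        with pytest.raises(ValueError):
            sim.StrainSpec(name="s", ploidy=2, het_rate={"unannotated": 0.5})
        with pytest.raises(ValueError):
            sim.StrainSpec(name="s", ploidy=2, mean_coverage=0)


class TestFragmentAndWrite:
    def test_short_contig_fraction(self):
        anc = sim.make_ancestor(500_000, 200, seed=3)
        sg = sim.derive_strain(anc, sim.StrainSpec(name="s", ploidy=2, seed=3))
        asm = sim.fragment_genome(sg, n_contigs=50, short_contig_fraction=0.1)
        short = [c for c in asm.contigs if c.length < 500]
        assert 3 <= len(short) <= 7  # aimed at ~5
        assert sum(c.length for c in asm.contigs) == sg.seq.size

    def test_genes_never_split(self, small_dataset):
        for name, sg in small_dataset.strains.items():
            asm = small_dataset.assemblies[name]
            for g in sg.genes:
                ctg_start, _ = asm.locate(g.start)
                ctg_end, _ = asm.locate(g.end - 1)
                assert ctg_start == ctg_end

    def test_fasta_gff_roundtrip(self, tmp_path, small_dataset):
        name = "beta"
        sg = small_dataset.strains[name]
        asm = small_dataset.assemblies[name]
        fa, gff = tmp_path / "c.fa", tmp_path / "g.gff3"
        sim.write_assembly(sg, asm, fa, gff)
        contigs = {}
        with open(fa) as fh:
            cname = None
            for line in fh:
                if line.startswith(">"):
                    cname = line[1:].strip()
                    contigs[cname] = []
                else:
                    contigs[cname].append(line.strip())
        contigs = {k: "".join(v) for k, v in contigs.items()}
        truth_seqs = {g.gene_id: sg.gene_sequence(g) for g in sg.genes}
        n = 0
        with open(gff) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                ctg, _, _, start, end, _, strand, _, attrs = line.split("\t")
                gid = attrs.split("ID=")[1].split(";")[0]
                seq = contigs[ctg][int(start) - 1 : int(end)]
                if strand == "-":
                    seq = revcomp(seq)
                assert seq == truth_seqs[gid]
                n += 1
        assert n == len(sg.genes)


class TestAlleleDepths:
    def test_fractions_concentrate_at_carrier_ratio(self, tmp_path):
        anc = sim.make_ancestor(150_000, 60, seed=4)
        sg = sim.derive_strain(anc, sim.StrainSpec(name="s", ploidy=4, seed=5))
        asm = sim.fragment_genome(sg, n_contigs=3, short_contig_fraction=0.0)
        recs = sim.simulate_allele_depths(
            sg, asm, overdispersion=0.0, error_sites_fraction=0.0, seed=2
        )
        assert len(recs) == len(sg.variants)
        within = 0
        for v, (_, _, _, _, _, alt_dp, dp) in zip(sg.variants, recs):
            p = len(v.carriers) / 4
            sd = max(np.sqrt(p * (1 - p) / max(dp, 1)), 1e-6)
            within += abs(alt_dp / max(dp, 1) - p) <= 4.5 * sd + 1 / max(dp, 1)
        assert within / len(recs) >= 0.99

    def test_error_sites_added(self):
        anc = sim.make_ancestor(80_000, 30, seed=4)
        sg = sim.derive_strain(anc, sim.StrainSpec(name="s", ploidy=2, seed=5))
        asm = sim.fragment_genome(sg, n_contigs=2, short_contig_fraction=0.0)
        recs = sim.simulate_allele_depths(
            sg, asm, error_sites_fraction=0.10, seed=2
        )
        extra = len(recs) - len(sg.variants)
        assert extra == pytest.approx(0.10 * len(sg.variants), abs=3)


class TestKmerCounts:
    def test_determinism_and_tsv_roundtrip(self, tmp_path):
        anc = sim.make_ancestor(10_000, 4, seed=6)
        sg = sim.derive_strain(anc, sim.StrainSpec(name="s", ploidy=2, seed=7))
        a = sim.simulate_kmer_counts(sg, seed=9, tsv_path=tmp_path / "a.tsv")
        b = sim.simulate_kmer_counts(sg, seed=9, tsv_path=tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        back = sim.KmerCounts.from_tsv(tmp_path / "a.tsv")
        assert np.array_equal(back.kmers, a.kmers)
        assert np.array_equal(back.counts, a.counts)

    def test_het_kmer_pair_coverage(self):
        # one heterozygous SNP in a diploid: the two SNP-spanning k-mers each
        # sit near half the total coverage
        from straindiverge import smudge as sm

        anc = sim.make_ancestor(3000, 1, (800, 0), seed=8)
        zero = {c: 0.0 for c in list(sim.CATEGORIES) + ["intergenic"]}
        spec = sim.StrainSpec(
            name="s", ploidy=2, het_rate=zero, divergence=zero,
            n_exclusive_genes=0, mean_coverage=60, seed=9,
        )
        sg = sim.derive_strain(anc, spec)
        g = sg.genes[0]
        sg.variants.append(
            sim.HetVariant(
                pos=g.start + 400,
                ref=sim.decode_bases(sg.seq[g.start + 400 : g.start + 401]),
                alt="ACGT"[(sg.seq[g.start + 400] + 1) % 4],
                carriers=(1,),
                vtype=sim.SNP,
                gene_id=g.gene_id,
                category=g.category,
            )
        )
        counts = sim.simulate_kmer_counts(sg, seed=11)
        pairs = sm.find_het_pairs(counts)
        assert len(pairs) >= 1
        good = [p for p in pairs if abs(p.cov_a - 30) < 20 and abs(p.cov_b - 30) < 20]
        assert good


class TestStrainSet:
    def test_core_fraction_and_presence(self, small_dataset):
        truth = small_dataset.truth
        assert truth.ploidy == {"alpha": 3, "beta": 2, "gamma": 4}
        assert truth.core_fraction() == pytest.approx(0.685, abs=0.02)
        for sg in small_dataset.strains.values():
            for g in sg.genes:
                assert sg.name in truth.family_presence[g.gene_id]

    def test_write_dataset_deterministic(self, tmp_path):
        specs = [sim.StrainSpec(name="a", ploidy=2, n_exclusive_genes=2, seed=1)]
        for d in ("d1", "d2"):
            ds = sim.simulate_strain_set(
                haploid_bp=40_000, n_genes=15, specs=specs, seed=5
            )
            sim.write_dataset(ds, tmp_path / d, vcf_seed=1, kmer_seed=1)
        for f in sorted((tmp_path / "d1").iterdir()):
            assert f.read_bytes() == (tmp_path / "d2" / f.name).read_bytes()
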