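"""Clustering, consensus, placement, locus merging, Venn partition, density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from straindiverge import geneset as gs
from straindiverge import simulate as sim
from straindiverge._kmers import revcomp


def gene(gid, seq, strain="s"):
    return gs.GeneRecord(gid, strain, "", "+", 0, len(seq), seq)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestClustering:
    def test_identical_genes_one_cluster(self, rng):
        s = random_seq(rng, 1000)
        clusters = gs.cluster_genes([gene("a", s), gene("b", s)])
        assert len(clusters) == 1
        assert sorted(m.gene_id for m in clusters[0].members) == ["a", "b"]

    def test_short_fragment_fails_length_ratio(self, rng):
        s = random_seq(rng, 1000)
        clusters = gs.cluster_genes([gene("a", s), gene("b", s[:700])])
        assert len(clusters) == 2  # 0.7 < 0.8 length ratio

    def test_unrelated_genes_stay_singletons(self, rng):
        genes = [gene(f"g{i}", random_seq(rng, 900)) for i in range(20)]
        clusters = gs.cluster_genes(genes)
        assert len(clusters) == 20

    def test_divergent_copy_joins(self, rng):
        s = list(random_seq(rng, 1000))
        mutated = s.copy()
        for pos in rng.choice(1000, size=50, replace=False):  # 5% divergence
            mutated[pos] = "ACGT"[(("ACGT".index(mutated[pos])) + 1) % 4]
        clusters = gs.cluster_genes([gene("a", "".join(s)), gene("b", "".join(mutated))])
        assert len(clusters) == 1

    def test_order_stable(self, rng):
        seqs = [random_seq(rng, 800) for _ in range(6)]
        genes = [gene(f"g{i}", s) for i, s in enumerate(seqs + seqs)]
        shuffled = list(genes)
        rng.shuffle(shuffled)
        part1 = sorted(
            tuple(sorted(m.gene_id for m in c.members))
            for c in gs.cluster_genes(genes)
        )
        part2 = sorted(
            tuple(sorted(m.gene_id for m in c.members))
            for c in gs.cluster_genes(shuffled)
        )
        assert part1 == part2


class TestConsensus:
    def test_singleton_identity(self, rng):
        s = random_seq(rng, 500)
        cl = gs.GeneCluster("c1", gene("a", s), [gene("a", s)])
        assert gs.consensus_sequence(cl) == s

    def test_majority_wins(self, rng):
        s = random_seq(rng, 300)
        variant = s[:100] + ("T" if s[100] != "T" else "A") + s[101:]
        rep = gene("a", s)
        cl = gs.GeneCluster("c1", rep, [rep, gene("b", variant), gene("c", variant)])
        assert gs.consensus_sequence(cl) == variant

    def test_tie_goes_to_representative(self, rng):
        s = random_seq(rng, 300)
        variant = s[:100] + ("T" if s[100] != "T" else "A") + s[101:]
        rep = gene("a", s)
        cl = gs.GeneCluster("c1", rep, [rep, gene("b", variant)])
        assert gs.consensus_sequence(cl) == s


class TestPlacement:
    def test_roundtrip_exact(self, rng):
        contig = random_seq(rng, 20_000)
        piece = contig[5000:6500]
        index = gs.GenomeIndex({"c1": contig})
        p = gs.place_gene(piece, index, query_id="q")
        assert (p.contig, p.start, p.end) == ("c1", 5000, 6500)
        assert p.identity == 1.0 and p.strand == "+"

    def test_reverse_strand(self, rng):
        contig = random_seq(rng, 10_000)
        piece = revcomp(contig[2000:3200])
        p = gs.place_gene(piece, gs.GenomeIndex({"c1": contig}), query_id="q")
        assert p is not None and p.strand == "-"
        assert (p.start, p.end) == (2000, 3200)

    def test_absent_gene_unplaced(self, rng):
        contig = random_seq(rng, 10_000)
        foreign = random_seq(rng, 1200)
        assert gs.place_gene(foreign, gs.GenomeIndex({"c1": contig})) is None

    def test_divergent_gene_identity(self, rng):
        contig = random_seq(rng, 20_000)
        piece = list(contig[4000:5500])
        for pos in rng.choice(len(piece), size=len(piece) // 20, replace=False):
            piece[pos] = "ACGT"[("ACGT".index(piece[pos]) + 1) % 4]
        p = gs.place_gene("".join(piece), gs.GenomeIndex({"c1": contig}), query_id="q")
        assert p is not None
        assert p.identity == pytest.approx(0.95, abs=0.02)


class TestMerging:
    def place(self, qid, start, end, strand="+", contig="c"):
        return gs.Placement(qid, contig, strand, start, end, 1.0)

    def test_ten_percent_boundary_inclusive(self):
        merged = gs.merge_overlapping(
            [self.place("a", 0, 1000), self.place("b", 900, 1900)]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 1900)

    def test_below_boundary_not_merged(self):
        merged = gs.merge_overlapping(
            [self.place("a", 0, 1000), self.place("b", 950, 1950)]
        )
        assert len(merged) == 2

    def test_opposite_strands_not_merged(self):
        merged = gs.merge_overlapping(
            [self.place("a", 0, 1000), self.place("b", 0, 1000, strand="-")]
        )
        assert len(merged) == 2

    def test_shorter_length_rule(self):
        # overlap 60 = 12% of the 500 bp placement but 6% of the 1000 bp one
        merged = gs.merge_overlapping(
            [self.place("a", 0, 1000), self.place("b", 940, 1440)]
        )
        assert len(merged) == 1

    def test_transitive_merging(self):
        merged = gs.merge_overlapping(
            [
                self.place("a", 0, 1000),
                self.place("b", 900, 1900),
                self.place("c", 1800, 2800),
            ]
        )
        assert len(merged) == 1
        assert merged[0].member_ids == ["a", "b", "c"]

    @settings(max_examples=25, deadline=None)
    @given(st.permutations(range(5)), st.data())
    def test_idempotent_and_order_free(self, perm, data):
        iv = data.draw(
            st.lists(
                st.tuples(st.integers(0, 3000), st.integers(100, 1200)),
                min_size=5,
                max_size=5,
            )
        )
        placements = [
            self.place(f"g{i}", s, s + l) for i, (s, l) in enumerate(iv)
        ]
        base = gs.merge_overlapping(placements)
        shuffled = gs.merge_overlapping([placements[i] for i in perm])
        key = lambda loci: sorted((m.start, m.end, tuple(m.member_ids)) for m in loci)
        assert key(base) == key(shuffled)
        again = gs.merge_overlapping(
            [self.place(",".join(m.member_ids), m.start, m.end) for m in base]
        )
        assert len(again) == len(base)


class TestClassifyAndDensity:
    def test_family_recovery_on_synthetic_truth(self, small_dataset):
        ds = small_dataset
        pooled = [
            gs.GeneRecord(g.gene_id, n, "", "+", 0, g.length, ds.strains[n].gene_sequence(g))
            for n in sorted(ds.strains)
            for g in ds.strains[n].genes
        ]
        clusters = gs.cluster_genes(pooled)
        queries = {c.cluster_id: c.consensus for c in clusters}
        genomes = {
            n: {
                c.name: sim.decode_bases(ds.strains[n].seq[c.start : c.end])
                for c in ds.assemblies[n].contigs
            }
            for n in ds.strains
        }
        placements = gs.place_genes(queries, genomes)
        families, summary = gs.classify_shared(placements)
        truth_core = ds.truth.core_fraction()
        assert summary.core_fraction == pytest.approx(truth_core, abs=0.03)
        # partition recovery: pooled genes grouped into predicted families
        # must match the truth partition (genes sharing an ancestral id)
        from sklearn.metrics import adjusted_rand_score

        fam_of_cluster = {
            cid: fam.family_id for fam in families for cid in fam.cluster_ids
        }
        labels_true, labels_pred = [], []
        for cl in clusters:
            for member in cl.members:
                labels_true.append(member.gene_id)
                labels_pred.append(fam_of_cluster.get(cl.cluster_id, cl.cluster_id))
        assert adjusted_rand_score(labels_true, labels_pred) >= 0.95
        # Venn identity: per-strain count = core + its pairwise-shared + exclusive
        for s in ds.strains:
            shared_with_some = sum(
                n for pres, n in summary.venn.items() if s in pres and 1 < len(pres) < 3
            )
            assert summary.per_strain_genes[s] == (
                summary.n_core + shared_with_some + summary.n_exclusive[s]
            )

    def test_presence_classes(self):
        placements = {
            "s1": {"q1": gs.Placement("q1", "c", "+", 0, 100, 1.0)},
            "s2": {"q1": gs.Placement("q1", "c", "+", 0, 100, 1.0)},
            "s3": {},
        }
        families, summary = gs.classify_shared(placements)
        assert summary.n_families == 1
        assert families[0].presence == frozenset({"s1", "s2"})
        assert summary.n_core == 0

    @pytest.mark.parametrize(
        "n,total_bp,expected",
        [
            (17_315, 49.4e6, 350),
            (16_915, 54.7e6, 309),
            (19_494, 52.8e6, 369),
            (0, 1e6, 0),
        ],
    )
    def test_density_values(self, n, total_bp, expected):
        assert gs.gene_density(n, [total_bp]) == expected

    def test_density_contig_filter_strict(self):
        # 500 bp contigs are excluded ("> 500 bp" strict)
        assert gs.gene_density(100, [500_000, 500, 499]) == 200

    def test_density_undefined(self):
        with pytest.raises(ValueError):
            gs.gene_density(10, [400, 300])
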