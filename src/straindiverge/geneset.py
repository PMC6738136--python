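"""Multi-strain gene-complement comparison.

Predicted genes from all strains are pooled and clustered greedily by length
(cd-hit style: a gene joins the first longer representative it matches at
>= 80% identity with >= 80% mutual coverage and >= 0.8 length ratio,
otherwise it founds a new cluster). Cluster consensus sequences are aligned
back onto every strain assembly with a seed-and-extend aligner; placements
on the same contig and strand overlapping by at least 10% of the shorter
placement are merged into one locus (transitively). Gene families present in
every strain are core, in several strains shared, in one strain exclusive.

Gene density d = n / sum(contig lengths > 500 bp) * 1e6 genes per Mb,
truncated to an integer for reporting.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from ._kmers import kmer_array, revcomp

CLUSTER_IDENTITY = 0.8
CLUSTER_LENGTH_RATIO = 0.8
CLUSTER_COVERAGE = 0.8
PLACE_IDENTITY = 0.9
PLACE_COVERAGE = 0.8
MERGE_OVERLAP = 0.10
DENSITY_MIN_CONTIG = 500
# 21 bp seeds every 50 bp: a gene at 5% divergence (the placement identity
# floor is 0.9) still yields a clean exact seed with probability ~1-4e-6
SEED_LEN = 21
SEED_STEP = 50


@dataclass
class GeneRecord:
    gene_id: str
    strain: str
    contig: str
    strand: str
    start: int  # 0-based half-open on the contig
    end: int
    seq: str


@dataclass
class GeneCluster:
    cluster_id: str
    representative: GeneRecord
    members: list[GeneRecord]
    consensus: str = ""


@dataclass
class Placement:
    query_id: str
    contig: str
    strand: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MergedLocus:
    contig: str
    strand: str
    start: int
    end: int
    member_ids: list[str]


@dataclass
class GeneFamily:
    family_id: str
    cluster_ids: list[str]
    presence: frozenset[str]
    placements: dict[str, list[Placement]]


@dataclass
class GeneSetSummary:
    n_families: int
    n_core: int
    n_exclusive: dict[str, int]
    venn: dict[frozenset, int]
    per_strain_genes: dict[str, int]

    @property
    def core_fraction(self) -> float:
        return self.n_core / self.n_families if self.n_families else 0.0


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _global_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def cluster_genes(
    genes: list[GeneRecord],
    identity: float = CLUSTER_IDENTITY,
    length_ratio: float = CLUSTER_LENGTH_RATIO,
    coverage: float = CLUSTER_COVERAGE,
) -> list[GeneCluster]:
    """Greedy incremental clustering, longest gene first.

    A candidate joins the first cluster whose representative it matches with
    global-alignment identity >= ``identity``; the length-ratio screen
    (member/representative >= ``length_ratio``) also enforces the mutual
    coverage bound for a global alignment. Ties in length are broken by gene
    id, so the partition is stable under input permutation.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    ordered = sorted(genes, key=lambda g: (-len(g.seq), g.gene_id))
    clusters: list[GeneCluster] = []
    for g in ordered:
        placed = False
        for cl in clusters:
            rep = cl.representative.seq
            ratio = len(g.seq) / len(rep)
            if ratio < max(length_ratio, coverage):
                continue
            if _global_identity(g.seq, rep) >= identity:
                cl.members.append(g)
                placed = True
                break
        if not placed:
            clusters.append(
                GeneCluster(f"c{len(clusters) + 1:05d}", representative=g, members=[g])
            )
    for cl in clusters:
        cl.consensus = consensus_sequence(cl)
    return clusters


def consensus_sequence(cluster: GeneCluster) -> str:
    """Column-majority consensus over a representative-anchored alignment.

    Every member is aligned globally to the representative; votes are tallied
    per representative column (insertions relative to the representative do
    not vote). Ties go to the representative's base.
    """
    rep = cluster.representative.seq
    if len(cluster.members) == 1:
        return rep
    votes = [defaultdict(int) for _ in rep]
    for g in cluster.members:
        if g.seq == rep:
            for i, b in enumerate(rep):
                votes[i][b] += 1
            continue
        res = edlib.align(g.seq, rep, mode="NW", task="path")
        qi = ri = 0
        for n_str, op in _cigar_ops(res["cigar"]):
            n = int(n_str)
            if op in "=XM":
                for t in range(n):
                    votes[ri + t][g.seq[qi + t]] += 1
                qi += n
                ri += n
            elif op == "I":  # present in member, absent in representative
                qi += n
            elif op == "D":  # gap in member
                for t in range(n):
                    votes[ri + t]["-"] += 1
                ri += n
    out = []
    for i, b in enumerate(rep):
        best = max(votes[i].items(), key=lambda kv: (kv[1], kv[0] == b))
        top = best[1]
        winners = [s for s, c in votes[i].items() if c == top]
        sym = b if b in winners else sorted(winners)[0]
        if sym != "-":
            out.append(sym)
    return "".join(out)


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact-seed index over a set of contigs (packed seed k-mers, sorted)."""

    def __init__(self, contigs: dict[str, str], seed_len: int = SEED_LEN):
        self.contigs = contigs
        self.seed_len = seed_len
        names = sorted(contigs)
        kms, positions, ctg_ids = [], [], []
        for i, name in enumerate(names):
            arr = kmer_array(contigs[name], seed_len)
            kms.append(arr)
            positions.append(np.arange(arr.size))
            ctg_ids.append(np.full(arr.size, i))
        self.names = names
        if kms:
            km = np.concatenate(kms)
            order = np.argsort(km, kind="stable")
            self.kmers = km[order]
            self.positions = np.concatenate(positions)[order]
            self.ctg_ids = np.concatenate(ctg_ids)[order]
        else:
            self.kmers = np.empty(0, dtype=np.int64)
            self.positions = np.empty(0, dtype=np.int64)
            self.ctg_ids = np.empty(0, dtype=np.int64)

    def lookup(self, seed_code: int, max_hits: int = 50) -> list[tuple[str, int]]:
        lo = int(np.searchsorted(self.kmers, seed_code, side="left"))
        hi = int(np.searchsorted(self.kmers, seed_code, side="right"))
        hits = []
        for i in range(lo, min(hi, lo + max_hits)):
            hits.append((self.names[int(self.ctg_ids[i])], int(self.positions[i])))
        return hits


def place_gene(
    seq: str,
    index: GenomeIndex,
    min_identity: float = PLACE_IDENTITY,
    query_id: str = "",
    seed_step: int = SEED_STEP,
) -> Placement | None:
    """Best placement of one gene on one genome (both strands), or None.

    Exact seed matches nominate candidate windows; the full gene is then
    aligned into each window with an infix alignment, so query coverage is
    complete by construction and identity = 1 - edits/len(gene).
    """
    k = index.seed_len
    best: tuple[float, str, str, int, int] | None = None
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        if len(q) < k:
            continue
        offsets = list(range(0, len(q) - k + 1, seed_step)) or [0]
        windows: set[tuple[str, int]] = set()
        for off in offsets:
            arr = kmer_array(q[off : off + k], k)
            if arr.size != 1:
                continue
            for ctg, pos in index.lookup(int(arr[0])):
                margin = 30 + len(q) // 10
                w_start = max(0, pos - off - margin)
                windows.add((ctg, w_start))
        for ctg, w_start in windows:
            target = index.contigs[ctg][w_start : w_start + len(q) + 2 * (30 + len(q) // 10)]
            if len(target) < k:
                continue
            res = edlib.align(q, target, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(q)
            if ident < min_identity:
                continue
            loc = res["locations"][0]
            start, end = w_start + loc[0], w_start + loc[1] + 1
            if best is None or ident > best[0]:
                best = (ident, ctg, strand, start, end)
    if best is None:
        return None
    ident, ctg, strand, start, end = best
    return Placement(
        query_id=query_id, contig=ctg, strand=strand, start=start, end=end, identity=ident
    )


def place_genes(
    queries: dict[str, str],
    genomes: dict[str, dict[str, str]],
    min_identity: float = PLACE_IDENTITY,
) -> dict[str, dict[str, Placement]]:
    """Best placement of each query on each genome: strain -> gene -> Placement."""
    out: dict[str, dict[str, Placement]] = {}
    for strain, contigs in sorted(genomes.items()):
        index = GenomeIndex(contigs)
        placed: dict[str, Placement] = {}
        for qid in sorted(queries):
            p = place_gene(queries[qid], index, min_identity=min_identity, query_id=qid)
            if p is not None:
                placed[qid] = p
        out[strain] = placed
    return out


# ---------------------------------------------------------------------------
# merging and classification
# ---------------------------------------------------------------------------

def merge_overlapping(
    placements: list[Placement], min_overlap: float = MERGE_OVERLAP
) -> list[MergedLocus]:
    """Merge same-contig same-strand placements overlapping by at least
    ``min_overlap`` of the shorter placement (transitive; order-independent)."""
    groups: dict[tuple[str, str], list[Placement]] = defaultdict(list)
    for p in placements:
        groups[(p.contig, p.strand)].append(p)

    loci: list[MergedLocus] = []
    for (contig, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda p: (p.start, p.end, p.query_id))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        active: list[int] = []
        for i, p in enumerate(group):
            active = [j for j in active if group[j].end > p.start]
            for j in active:
                q = group[j]
                ov = min(p.end, q.end) - max(p.start, q.start)
                if ov >= min_overlap * min(p.length, q.length):
                    parent[find(i)] = find(j)
            active.append(i)
        comps: dict[int, list[Placement]] = defaultdict(list)
        for i, p in enumerate(group):
            comps[find(i)].append(p)
        for members in comps.values():
            loci.append(
                MergedLocus(
                    contig=contig,
                    strand=strand,
                    start=min(p.start for p in members),
                    end=max(p.end for p in members),
                    member_ids=sorted(p.query_id for p in members),
                )
            )
    loci.sort(key=lambda m: (m.contig, m.strand, m.start))
    return loci


def classify_shared(
    placements: dict[str, dict[str, Placement]],
    min_overlap: float = MERGE_OVERLAP,
) -> tuple[list[GeneFamily], GeneSetSummary]:
    """Build gene families from per-strain placements.

    Clusters whose placements land in one merged locus on any strain are the
    same family (union-find across strains); a family's presence set is the
    set of strains where any of its clusters placed.
    """
    strains = sorted(placements)
    all_ids = sorted({qid for pl in placements.values() for qid in pl})
    idx = {qid: i for i, qid in enumerate(all_ids)}
    parent = list(range(len(all_ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    merged_by_strain: dict[str, list[MergedLocus]] = {}
    for strain in strains:
        loci = merge_overlapping(list(placements[strain].values()), min_overlap)
        merged_by_strain[strain] = loci
        for locus in loci:
            first = idx[locus.member_ids[0]]
            for qid in locus.member_ids[1:]:
                parent[find(idx[qid])] = find(first)

    comps: dict[int, list[str]] = defaultdict(list)
    for qid in all_ids:
        comps[find(idx[qid])].append(qid)

    families: list[GeneFamily] = []
    for i, (_, members) in enumerate(sorted(comps.items(), key=lambda kv: kv[1][0])):
        pres = frozenset(
            s for s in strains if any(q in placements[s] for q in members)
        )
        fam_placements = {
            s: [placements[s][q] for q in members if q in placements[s]]
            for s in strains
            if s in pres
        }
        families.append(
            GeneFamily(
                family_id=f"f{i + 1:05d}",
                cluster_ids=sorted(members),
                presence=pres,
                placements=fam_placements,
            )
        )

    venn: dict[frozenset, int] = defaultdict(int)
    for fam in families:
        venn[fam.presence] += 1
    n_core = venn.get(frozenset(strains), 0)
    n_excl = {
        s: venn.get(frozenset([s]), 0) for s in strains
    }
    per_strain = {
        s: sum(1 for fam in families if s in fam.presence) for s in strains
    }
    summary = GeneSetSummary(
        n_families=len(families),
        n_core=n_core,
        n_exclusive=n_excl,
        venn=dict(venn),
        per_strain_genes=per_strain,
    )
    return families, summary


def gene_density(n_genes: int, contig_lengths) -> int:
    """Genes per Mb over contigs longer than 500 bp, truncated to integer."""
    if n_genes < 0:
        raise ValueError("negative gene count")
    total = sum(l for l in contig_lengths if l > DENSITY_MIN_CONTIG)
    if total == 0:
        raise ValueError("no contig longer than 500 bp; density undefined")
    return math.floor(n_genes / total * 1e6)


def read_gene_fasta(path: str | Path, strain: str) -> list[GeneRecord]:
    """Load gene sequences from FASTA (coordinates unknown -> zeros)."""
    records: list[GeneRecord] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seq = "".join(chunks)
                    records.append(GeneRecord(name, strain, "", "+", 0, len(seq), seq))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seq = "".join(chunks)
        records.append(GeneRecord(name, strain, "", "+", 0, len(seq), seq))
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
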