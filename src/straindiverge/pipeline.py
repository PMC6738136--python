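"""End-to-end orchestration and report metrics.

Runs variant filtering, both ploidy estimators, gene clustering/placement,
pairwise divergence and category statistics on a set of strains — either
freshly simulated or loaded from files — and writes every intermediate as
TSV. Also houses the small report arithmetic: haploid genome size from
total DNA content and called ploidy, and the core-genome percentage.
Report values round half-up (densities are truncated to integers by
``geneset.gene_density``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path

import numpy as np

from . import allele_balance as ab
from . import divergence as dv
from . import geneset as gs
from . import simulate as sim
from . import smudge as sm
from . import stats as st
from . import variants as vr

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def haploid_size(total_size_mb: float, ploidy: int | str) -> float | None:
    """Haploid genome size (Mb) from total DNA content and called ploidy."""
    if not isinstance(ploidy, int):
        log.warning("ploidy ambiguous; haploid size not recalculated")
        return None
    if total_size_mb <= 0 or ploidy not in (2, 3, 4):
        raise ValueError("need total size > 0 and ploidy in {2,3,4}")
    return round_half_up(total_size_mb / ploidy, 1)


def shared_fraction(core: int, total: int) -> float:
    """Core-genome percentage, one decimal."""
    if not 0 <= core <= total or total <= 0:
        raise ValueError("need 0 <= core <= total, total > 0")
    return round_half_up(100.0 * core / total, 1)


@dataclass
class RunConfig:
    out_dir: str = "straindiverge_out"
    seed: int = 0
    simulate: bool = True
    haploid_bp: int = 1_000_000
    n_genes: int = 600
    mean_coverage: float = 50.0
    min_depth: int = 8
    min_alt_fraction: float = 0.10
    margin: float = 0.10
    min_contig_len: int = 10_000
    cluster_identity: float = 0.8
    cluster_length_ratio: float = 0.8
    merge_overlap: float = 0.10
    alpha: float = 0.01
    k: int = 21
    total_size_mb: dict[str, float] = field(default_factory=dict)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, dict):
                    v = ",".join(f"{k}:{x}" for k, x in sorted(v.items()))
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str, "bool": lambda s: s == "True"}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if key == "total_size_mb":
                kwargs[key] = (
                    {p.split(":")[0]: float(p.split(":")[1]) for p in raw.split(",") if p}
                    if raw
                    else {}
                )
            else:
                kwargs[key] = casts[types[key]](raw)
        return cls(**kwargs)


@dataclass
class StrainReport:
    strain: str
    ploidy_ab: int | str
    ploidy_kmer: int | None
    n_genes: int
    density: int
    haploid_size_mb: float | None


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run(config: RunConfig) -> dict:
    """Execute the full pipeline on a simulated dataset; returns the report
    dictionary and writes report/ploidy/venn/rates/stats TSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    log.info("run config: %s", config)
    config.to_file(out / "run.cfg")

    if not config.simulate:
        raise StageError("inputs", "file-based inputs: use the module CLIs per stage")
    dataset = sim.simulate_strain_set(
        haploid_bp=config.haploid_bp,
        n_genes=config.n_genes,
        specs=sim.default_strain_specs(config.seed, config.mean_coverage),
        seed=config.seed,
    )
    paths = sim.write_dataset(dataset, out / "data", vcf_seed=config.seed, kmer_seed=config.seed, k=config.k)

    reports: dict[str, StrainReport] = {}
    profiles_by_strain: dict[str, list[dv.GeneVariantProfile]] = {}
    filtered_by_strain: dict[str, list[vr.VariantRecord]] = {}
    categories = st.read_category_table(out / "data" / "categories.tsv")

    for name in sorted(dataset.strains):
        sg = dataset.strains[name]
        asm = dataset.assemblies[name]
        try:
            records = vr.read_vcf(paths[name]["vcf"])
            filtered = vr.filter_variants(
                records, config.min_depth, config.min_alt_fraction
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("variants", f"{name}: {e}") from e
        filtered_by_strain[name] = filtered
        sites, _ = vr.extract_allele_balance(filtered)
        den_sites, _ = ab.denoise(sites)
        genome_call = ab.call_ploidy(den_sites, margin_threshold=config.margin)
        summary = ab.contig_ploidy(
            sites, asm.lengths, min_contig_len=config.min_contig_len,
            margin_threshold=config.margin,
        )
        ab.write_ploidy_tsv(out / f"{name}.ploidy.tsv", summary, genome_call, asm.lengths)

        kmer_counts = sim.KmerCounts.from_tsv(paths[name]["kmers"])
        try:
            smres = sm.smudge_ploidy(kmer_counts)
            kcall = smres.call
            smres.to_json(out / f"{name}.smudge.json")
        except sm.InsufficientPairs:
            kcall = None

        genes = [
            dv.GeneInterval(
                g.gene_id,
                asm.locate(g.start)[0],
                asm.locate(g.start)[1],
                asm.locate(g.start)[1] + g.length,
                g.category,
            )
            for g in sg.genes
        ]
        profiles_by_strain[name] = dv.profile_gene_variants(
            genes, filtered, strain=name, categories=categories
        )
        density = gs.gene_density(len(sg.genes), asm.lengths.values())
        hap = None
        if name in config.total_size_mb and isinstance(genome_call.call, int):
            hap = haploid_size(config.total_size_mb[name], genome_call.call)
        reports[name] = StrainReport(
            strain=name,
            ploidy_ab=genome_call.call,
            ploidy_kmer=kcall,
            n_genes=len(sg.genes),
            density=density,
            haploid_size_mb=hap,
        )

    # gene families across strains
    try:
        pooled = [
            gs.GeneRecord(g.gene_id, name, "", "+", 0, g.length, dataset.strains[name].gene_sequence(g))
            for name, sgen in sorted(dataset.strains.items())
            for g in sgen.genes
        ]
        clusters = gs.cluster_genes(pooled)
        queries = {c.cluster_id: c.consensus for c in clusters}
        genomes = {
            name: {
                c.name: sim.decode_bases(dataset.strains[name].seq[c.start : c.end])
                for c in dataset.assemblies[name].contigs
            }
            for name in sorted(dataset.strains)
        }
        placements = gs.place_genes(queries, genomes)
        families, summary = gs.classify_shared(placements, config.merge_overlap)
    except Exception as e:  # noqa: BLE001
        raise StageError("geneset", str(e)) from e

    with open(out / "venn.tsv", "w") as f:
        f.write("strains\tfamilies\n")
        for pres, n in sorted(summary.venn.items(), key=lambda kv: sorted(kv[0])):
            f.write("+".join(sorted(pres)) + f"\t{n}\n")

    core_pct = shared_fraction(summary.n_core, summary.n_families)

    # divergence on shared families (via truth gene ids for the simulated path)
    comparisons: list[dv.PairwiseGeneComparison] = []
    names = sorted(dataset.strains)
    allele_sets = {
        name: _strain_allele_sets(dataset.strains[name], dataset.assemblies[name], filtered_by_strain[name])
        for name in names
    }
    for fam_id, pres in sorted(dataset.truth.family_presence.items()):
        for a, b in combinations(sorted(pres), 2):
            if fam_id in allele_sets[a] and fam_id in allele_sets[b]:
                comparisons.append(
                    dv.compare_gene_pair(allele_sets[a][fam_id], allele_sets[b][fam_id], fam_id)
                )
    identical = dv.count_identical(comparisons)
    with open(out / "rates.tsv", "w") as f:
        f.write("family\tstrain_a\tstrain_b\tmutations\taligned_len\trate\tidentical\n")
        for c in comparisons:
            f.write(
                f"{c.family_id}\t{c.strain_a}\t{c.strain_b}\t{c.mutations}\t"
                f"{c.aligned_length}\t{c.rate:.6f}\t{int(c.identical)}\n"
            )

    stat_rows: list[st.StatResult] = []
    for cat in sorted({p.category for ps in profiles_by_strain.values() for p in ps}):
        for vtype in (vr.SNP, vr.INSERTION, vr.DELETION):
            rates = {
                name: np.array([p.rate(vtype) for p in ps if p.category == cat])
                for name, ps in profiles_by_strain.items()
            }
            try:
                stat_rows.append(
                    st.allelic_variation_tests(rates, grouping=f"{cat}/{vtype}", alpha=config.alpha)
                )
            except st.InsufficientGroups:
                continue
    with open(out / "stats.tsv", "w") as f:
        f.write("test\tgrouping\tstatistic\tpvalue\tsignificant\tn\n")
        for r in stat_rows:
            f.write(
                f"{r.test}\t{r.grouping}\t{r.statistic:.4f}\t{r.pvalue:.6g}\t"
                f"{int(r.significant)}\t{r.n}\n"
            )

    with open(out / "report.tsv", "w") as f:
        f.write("strain\tploidy_ab\tploidy_kmer\tn_genes\tdensity\thaploid_size_mb\n")
        for name in names:
            r = reports[name]
            f.write(
                f"{r.strain}\t{r.ploidy_ab}\t{r.ploidy_kmer}\t{r.n_genes}\t"
                f"{r.density}\t{r.haploid_size_mb}\n"
            )

    log.removeHandler(fh)
    fh.close()
    return {
        "strains": reports,
        "summary": summary,
        "core_percent": core_pct,
        "identical": identical,
        "truth": dataset.truth,
    }


def _strain_allele_sets(
    strain: sim.StrainGenome,
    assembly: sim.Assembly,
    filtered: list[vr.VariantRecord],
) -> dict[str, dv.AlleleSet]:
    """AlleleSet per gene id from the strain's filtered variant records."""
    by_contig: dict[str, list[vr.VariantRecord]] = {}
    for rec in filtered:
        by_contig.setdefault(rec.contig, []).append(rec)
    out: dict[str, dv.AlleleSet] = {}
    for g in strain.genes:
        ctg, off = assembly.locate(g.start)
        variants: dict[int, list[tuple[str, str]]] = {}
        for rec in by_contig.get(ctg, []):
            p0 = rec.pos - 1
            if off <= p0 < off + g.length:
                gpos = p0 - off
                if g.strand == "-":
                    # express on the oriented gene sequence
                    alleles = [
                        (sim.revcomp(rec.ref), sim.revcomp(alt)) for alt in rec.alts
                    ]
                    gpos = g.length - 1 - gpos - (len(rec.ref) - 1)
                    if gpos < 0:
                        continue
                else:
                    alleles = [(rec.ref, alt) for alt in rec.alts]
                variants.setdefault(gpos, []).extend(alleles)
        out[g.gene_id] = dv.AlleleSet(
            gene_id=g.gene_id,
            strain=strain.name,
            seq=strain.gene_sequence(g),
            variants=variants,
        )
    return out
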