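"""VCF reading, site filters and allele-balance extraction.

The study's variant set was produced by a haplotype caller run with a ploidy
upper bound of four; records therefore carry up to four alleles and unphased
genotypes. Two filters define the working set everywhere downstream:

* minimum read depth: sites with DP < 8 are excluded;
* minimum variant fraction: an alternate allele observed in fewer than 10% of
  the reads at its site is dropped ("<10%" is strict, so exactly 10% is kept).

Allele-balance observations for ploidy estimation are the alternate-read
fractions y = AD_alt / (AD_ref + AD_alt) of biallelic SNPs with heterozygous
evidence (0 < y < 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

log = logging.getLogger(__name__)

SNP, INSERTION, DELETION, MNP = "SNP", "insertion", "deletion", "MNP"

MIN_DEPTH = 8
MIN_ALT_FRACTION = 0.10


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    depth: int
    allele_depths: tuple[int, ...]  # ref first, then alts

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class AlleleBalanceSite:
    """One biallelic heterozygous SNP observation for the ploidy model."""

    contig: str
    pos: int
    depth: int
    alt_fraction: float


@dataclass
class FilterStats:
    n_input: int = 0
    n_low_depth: int = 0
    n_low_fraction: int = 0
    n_missing_fields: int = 0
    n_kept: int = 0
    dropped_alts: int = 0


def classify_variant(ref: str, alt: str) -> str:
    """SNP / insertion / deletion / MNP by allele lengths.

    Symbolic alleles (``<DEL>``, breakends, ``*``) are not sequence-resolved
    and raise ValueError.
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    if alt.startswith("<") or "*" in alt or "[" in alt or "]" in alt:
        raise ValueError(f"symbolic allele {alt!r}")
    if len(ref) == len(alt):
        return SNP if len(ref) == 1 else MNP
    return INSERTION if len(alt) > len(ref) else DELETION


def n_substitutions(ref: str, alt: str) -> int:
    """Number of substitution events an allele represents (MNP = its length)."""
    vtype = classify_variant(ref, alt)
    if vtype == SNP:
        return 1
    if vtype == MNP:
        return sum(1 for a, b in zip(ref, alt) if a != b)
    return 0


def read_vcf(path: str | Path, sample: str | None = None) -> list[VariantRecord]:
    """Read a VCF (plain text or bgzipped) into VariantRecords.

    AD/DP are taken from the FORMAT fields of ``sample`` (first sample by
    default); records without them get depth -1 and are rejected by the
    filter with a logged warning.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_name = sample or next(iter(vf.header.samples), None)
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            if not alts:
                continue
            dp = -1
            ad: tuple[int, ...] = ()
            if sample_name is not None:
                fmt = rec.samples[sample_name]
                raw_ad = fmt.get("AD")
                raw_dp = fmt.get("DP")
                if raw_ad is not None and all(x is not None for x in raw_ad):
                    ad = tuple(int(x) for x in raw_ad)
                if raw_dp is not None:
                    dp = int(raw_dp)
            records.append(
                VariantRecord(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=alts,
                    depth=dp,
                    allele_depths=ad,
                )
            )
    return records


def filter_variants(
    records: list[VariantRecord],
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
    stats: FilterStats | None = None,
) -> list[VariantRecord]:
    """Apply the depth and variant-fraction filters.

    A record survives iff DP >= ``min_depth`` and at least one alternate
    allele has AD/DP >= ``min_alt_fraction``; alternates individually below
    the fraction are dropped from the surviving record. The operation is a
    pure subset/projection, hence idempotent.
    """
    st = stats if stats is not None else FilterStats()
    out: list[VariantRecord] = []
    for rec in records:
        st.n_input += 1
        if rec.depth < 0 or len(rec.allele_depths) != 1 + len(rec.alts):
            st.n_missing_fields += 1
            log.warning("record %s:%d missing DP/AD; rejected", rec.contig, rec.pos)
            continue
        if rec.depth < min_depth:
            st.n_low_depth += 1
            continue
        kept_alts = []
        kept_ad = [rec.allele_depths[0]]
        for alt, ad in zip(rec.alts, rec.allele_depths[1:]):
            if rec.depth > 0 and ad / rec.depth >= min_alt_fraction:
                kept_alts.append(alt)
                kept_ad.append(ad)
            else:
                st.dropped_alts += 1
        if not kept_alts:
            st.n_low_fraction += 1
            continue
        st.n_kept += 1
        out.append(
            VariantRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(kept_alts),
                depth=rec.depth,
                allele_depths=tuple(kept_ad),
            )
        )
    return out


def extract_allele_balance(
    records: list[VariantRecord],
) -> tuple[list[AlleleBalanceSite], int]:
    """Allele-balance observations from filtered, biallelic SNP records.

    Returns the sites plus the number of records skipped as multiallelic.
    Sites where either allele has zero depth (homozygous evidence) yield no
    observation.
    """
    sites: list[AlleleBalanceSite] = []
    n_multi = 0
    for rec in records:
        if not rec.is_biallelic:
            n_multi += 1
            continue
        try:
            if classify_variant(rec.ref, rec.alts[0]) != SNP:
                continue
        except ValueError:
            continue
        if len(rec.allele_depths) != 2:
            continue
        ref_dp, alt_dp = rec.allele_depths
        total = ref_dp + alt_dp
        if total <= 0 or alt_dp == 0 or ref_dp == 0:
            continue
        sites.append(
            AlleleBalanceSite(
                contig=rec.contig,
                pos=rec.pos,
                depth=rec.depth,
                alt_fraction=alt_dp / total,
            )
        )
    return sites, n_multi


def write_allele_balance_tsv(path: str | Path, sites: list[AlleleBalanceSite]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tdepth\talt_fraction\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.pos}\t{s.depth}\t{s.alt_fraction:.6f}\n")
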