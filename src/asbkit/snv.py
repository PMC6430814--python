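"""Allele counting at candidate SNVs and heterozygous-SNV calling.

Heterozygosity is called from the pooled SMInput libraries of a cell line: a
bi-allelic candidate is heterozygous when its pooled coverage is at least 10
and the reference-allele ratio lies in [0.25, 0.75] (bounds inclusive,
configurable).  A user-supplied VCF of known heterozygous genotypes can be
merged in; on conflict the user record wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pysam

from .io import is_usable_read, DEFAULT_MIN_MAPQ

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CandidateSNV:
    """A bi-allelic candidate SNV (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = "user"

    def __post_init__(self) -> None:
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class AllelicCount:
    """Raw (y) and bias-normalized (x) allele counts for one sample."""

    snv: CandidateSNV
    sample: str
    y_ref: int
    y_alt: int
    y_other: int = 0
    x_ref: float | None = None
    x_alt: float | None = None

    def __post_init__(self) -> None:
        if min(self.y_ref, self.y_alt, self.y_other) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        """Ref + alt coverage; third-allele reads are excluded from ratios."""
        return self.y_ref + self.y_alt

    @property
    def ref_ratio(self) -> float:
        cov = self.coverage
        return self.y_ref / cov if cov else float("nan")


def count_alleles(
    snv: CandidateSNV,
    alignments: pysam.AlignmentFile,
    sample: str = "sample",
    min_base_quality: int = 10,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    single_end: bool = False,
) -> AllelicCount:
    """Count ref/alt/other bases at an SNV from a pileup.

    Base calls below ``min_base_quality`` are excluded (base qualities are
    taken as stored in the BAM: if upstream processing wrote
    realignment-adjusted qualities those are what is thresholded), as are
    deletions and reference skips.  Reads pass the same usable-read filters
    as everywhere else (mapped, primary, MAPQ, read-2 only unless
    ``single_end``).
    """
    lengths = dict(zip(alignments.references, alignments.lengths))
    if snv.chrom not in lengths or not (0 <= snv.pos < lengths[snv.chrom]):
        raise ValueError(f"position {snv.chrom}:{snv.pos} outside chromosome bounds")
    y_ref = y_alt = y_other = 0
    for read in alignments.fetch(snv.chrom, snv.pos, snv.pos + 1):
        if not is_usable_read(read, min_mapq, single_end):
            continue
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=True):
            if r == snv.pos:
                qpos = q
                break
        if qpos is None:  # deletion or reference skip over the SNV
            continue
        if read.query_qualities is not None and \
                read.query_qualities[qpos] < min_base_quality:
            continue
        base = read.query_sequence[qpos].upper()
        if base == snv.ref:
            y_ref += 1
        elif base == snv.alt:
            y_alt += 1
        elif base in _VALID_BASES:
            y_other += 1
    return AllelicCount(snv=snv, sample=sample, y_ref=y_ref, y_alt=y_alt, y_other=y_other)


def pool_counts(counts: Iterable[AllelicCount], sample: str = "pooled") -> AllelicCount:
    """Sum allelic counts of the same SNV across data sets."""
    counts = list(counts)
    if not counts:
        raise ValueError("nothing to pool")
    snv = counts[0].snv
    if any(c.snv != snv for c in counts):
        raise ValueError("cannot pool counts of different SNVs")
    return AllelicCount(
        snv=snv, sample=sample,
        y_ref=sum(c.y_ref for c in counts),
        y_alt=sum(c.y_alt for c in counts),
        y_other=sum(c.y_other for c in counts),
    )


def call_heterozygous(
    pooled: AllelicCount,
    min_cov: int = 10,
    ratio_low: float = 0.25,
    ratio_high: float = 0.75,
) -> bool:
    """Heterozygous iff pooled coverage >= min_cov and ref ratio in bounds."""
    cov = pooled.coverage
    if cov < min_cov:
        return False
    ratio = pooled.y_ref / cov
    return ratio_low <= ratio <= ratio_high


def load_candidate_snvs(vcf_path: str | Path, source: str | None = None) -> list[CandidateSNV]:
    """Load bi-allelic SNVs from a VCF; multi-allelic/indel records skipped."""
    out: list[CandidateSNV] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("%s:%d skipped: not bi-allelic", rec.chrom, rec.pos)
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
                continue
            out.append(CandidateSNV(rec.chrom, rec.pos - 1, ref, alt,
                                    source=source or "candidate"))
    return out


def _is_het_genotype(gt) -> bool:
    if gt is None or len(gt) != 2 or None in gt:
        return False
    return sorted(gt) == [0, 1]


def load_user_heterozygous_snvs(vcf_path: str | Path) -> list[CandidateSNV]:
    """Load user-provided heterozygous SNVs (GT 0/1, 0|1 or 1|0 only)."""
    out: list[CandidateSNV] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        has_samples = len(vcf.header.samples) > 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("%s:%d skipped: not bi-allelic", rec.chrom, rec.pos)
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
                continue
            if has_samples:
                gt = rec.samples[0].get("GT")
                if not _is_het_genotype(gt):
                    continue
            out.append(CandidateSNV(rec.chrom, rec.pos - 1, ref, alt, source="user"))
    return out


def merge_with_user_snvs(
    called: Iterable[CandidateSNV],
    user: Iterable[CandidateSNV],
) -> list[CandidateSNV]:
    """Union of called and user-provided heterozygous SNVs, keyed by position.

    Where both lists carry the same position the user record wins (with a
    warning if the alleles disagree).
    """
    merged: dict[tuple[str, int], CandidateSNV] = {
        (s.chrom, s.pos): s for s in called
    }
    for s in user:
        key = (s.chrom, s.pos)
        prev = merged.get(key)
        if prev is not None and (prev.ref, prev.alt) != (s.ref, s.alt):
            logger.warning(
                "allele conflict at %s:%d (%s/%s called vs %s/%s user); user record wins",
                s.chrom, s.pos + 1, prev.ref, prev.alt, s.ref, s.alt,
            )
        merged[key] = replace(s, source="user")
    return sorted(merged.values(), key=lambda s: (s.chrom, s.pos))
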