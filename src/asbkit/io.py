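"""Reading and writing the genomic formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions (VCF, the printed position column of the ASB table) are converted
at the boundary.  Peaks are strand-specific intervals carrying per-replicate
and size-matched-input (SMInput) coverage, and the peak-retention rule keeps a
peak when at least one eCLIP replicate is enriched at least ``fold``-fold over
the SMInput after per-million library normalization.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# SAM flag filters defining "usable" reads.  Deduplication and unique mapping
# are assumed upstream; here we additionally drop unmapped, secondary,
# supplementary and QC-fail records, and (configurable) low-MAPQ reads.
DEFAULT_MIN_MAPQ = 10
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800  # unmapped/secondary/qcfail/dup/suppl


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Peak:
    """An eCLIP peak with replicate and SMInput coverage.

    ``rep_library_sizes`` and ``input_library_size`` are usable-read totals in
    millions (the per-replicate R_j used throughout normalization).
    """

    interval: GenomicInterval
    rep_coverage: Sequence[float]
    input_coverage: float
    rep_library_sizes: Sequence[float]
    input_library_size: float

    def __post_init__(self) -> None:
        if len(self.rep_coverage) != len(self.rep_library_sizes):
            raise ValueError("one library size per replicate coverage required")
        if len(self.rep_coverage) < 2:
            raise ValueError("at least two eCLIP replicates required")
        if any(c < 0 for c in self.rep_coverage) or self.input_coverage < 0:
            raise ValueError("coverages must be non-negative")
        if any(s <= 0 for s in self.rep_library_sizes) or self.input_library_size <= 0:
            raise ValueError("library sizes must be positive")


def load_peaks(path: str | Path) -> list[GenomicInterval]:
    """Load peak intervals from a BED6 (or narrowPeak) file.

    Only the first six columns are used.  Lines violating start < end are
    rejected with a logged error naming the line number; a missing strand
    column is a hard error because eCLIP is strand-specific.
    """
    intervals: list[GenomicInterval] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: fewer than 6 columns; a strand column is "
                    "required (eCLIP peaks are strand-specific)"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand, name)
            except ValueError as exc:
                logger.error("%s:%d: rejected line: %s", path, lineno, exc)
                n_rejected += 1
                continue
            intervals.append(iv)
    if not intervals:
        logger.warning("%s: no peaks loaded", path)
    if n_rejected:
        logger.warning("%s: rejected %d malformed line(s)", path, n_rejected)
    return intervals


def is_usable_read(read, min_mapq: int = DEFAULT_MIN_MAPQ, single_end: bool = False) -> bool:
    """Usable-read predicate shared by coverage, read-start and allele counting.

    Only second-in-pair mates carry the crosslink-truncation signal in
    paired-end eCLIP, so read 1 is dropped unless ``single_end`` is set (then
    every read is treated as the informative mate).
    """
    if read.flag & _EXCLUDE_FLAGS:
        return False
    if read.mapping_quality < min_mapq:
        return False
    if not single_end and not read.is_read2:
        return False
    return True


def library_size_millions(
    alignments,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    single_end: bool = False,
) -> float:
    """Total number of usable reads in millions (R_j).

    ``alignments`` may be a pysam.AlignmentFile, an iterable of reads, or an
    integer count of already-filtered usable reads.
    """
    if isinstance(alignments, (int, np.integer)):
        n = int(alignments)
    else:
        it = alignments.fetch(until_eof=True) if hasattr(alignments, "fetch") else alignments
        n = sum(1 for r in it if is_usable_read(r, min_mapq, single_end))
    if n <= 0:
        raise ValueError("zero usable reads: library-size normalization undefined")
    return n / 1e6


@dataclass
class AttritionReport:
    """Bookkeeping for the peak-retention step."""

    n_input: int
    n_retained: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_retained


def peak_rpm(count: float, library_size_millions_: float) -> float:
    return count / library_size_millions_


def retain_peaks(
    peaks: Iterable[Peak], fold: float = 4.0
) -> tuple[list[Peak], AttritionReport]:
    """Keep peaks where >=1 replicate's RPM is >= fold x the SMInput RPM.

    The threshold is inclusive.  A peak with zero SMInput coverage passes as
    long as some replicate has coverage (the fold change is effectively
    infinite there).
    """
    peaks = list(peaks)
    retained = []
    for pk in peaks:
        input_rpm = peak_rpm(pk.input_coverage, pk.input_library_size)
        keep = False
        for cov, lib in zip(pk.rep_coverage, pk.rep_library_sizes):
            rpm = peak_rpm(cov, lib)
            if input_rpm == 0.0:
                if rpm > 0.0:
                    keep = True
                    break
            elif rpm >= fold * input_rpm:
                keep = True
                break
        if keep:
            retained.append(pk)
    report = AttritionReport(n_input=len(peaks), n_retained=len(retained))
    logger.info(
        "peak retention (fold >= %g): %d of %d retained, %d dropped",
        fold, report.n_retained, report.n_input, report.n_dropped,
    )
    return retained, report


# --- ASB result table -------------------------------------------------------

#: Stable column order of the ASB table (documented in the README).
ASB_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rbp", "major_allele",
    "mu_major", "mu_minor", "var_major", "k",
    "pvalue", "fdr", "filters_failed", "significant",
]

_FLOAT_COLUMNS = ("mu_major", "mu_minor", "var_major", "pvalue", "fdr")


def write_asb_table(records, path: str | Path) -> None:
    """Write ASB records to TSV, 1-based positions, deterministic row order.

    Row order is (chrom, pos, rbp); floats are printed with 12 significant
    digits so a write/read round trip is lossless at that precision.
    """
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
        rows.append({
            "chrom": d["chrom"],
            "pos": int(d["pos"]) + 1,  # printed 1-based
            "ref": d["ref"],
            "alt": d["alt"],
            "rbp": d["rbp"],
            "major_allele": d["major_allele"],
            "mu_major": d["mu_major"],
            "mu_minor": d["mu_minor"],
            "var_major": d["var_major"],
            "k": int(d["k"]),
            "pvalue": d["pvalue"],
            "fdr": d["fdr"],
            "filters_failed": d.get("filters_failed", "") or "",
            "significant": bool(d["significant"]),
        })
    df = pd.DataFrame(rows, columns=ASB_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "pos", "rbp"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("\t".join(ASB_TABLE_COLUMNS) + "\n")
        for _, row in df.iterrows():
            out = []
            for col in ASB_TABLE_COLUMNS:
                v = row[col]
                if col in _FLOAT_COLUMNS:
                    out.append(f"{float(v):.12g}")
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


def read_asb_table(path: str | Path) -> pd.DataFrame:
    """Read an ASB table back; positions converted to internal 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "filters_failed": str},
                     keep_default_na=False, na_values=[""])
    if len(df):
        df["pos"] = df["pos"].astype(int) - 1
        df["significant"] = df["significant"].astype(str).str.lower().isin(("true", "1"))
        df["filters_failed"] = df["filters_failed"].fillna("")
    return df
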