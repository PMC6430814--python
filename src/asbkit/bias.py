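"""Crosslink-site detection and crosslinking-induced sequence-bias correction.

In eCLIP, reverse transcription usually truncates at the protein-RNA
crosslink, so the 5' ends of read-2 alignments pile up at crosslinking sites.
Sites are called per peak by comparing read-start pileups against a
permutation null (read starts redistributed uniformly within the peak) at an
empirical FDR <= 0.001.  UV crosslinking prefers particular nucleotides
(uridines above all), which distorts allelic read counts at SNVs near
crosslink sites.  The distortion is estimated from the SMInput sample as the
relative abundance q(a, d) of each nucleotide a at each offset d in [-25, 25]
from a crosslink site, and raw allelic counts y are corrected as

    x = y / (q(a, d) * R)

with R the library size in millions and q = 0.25 outside the +/-25 window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import is_usable_read, DEFAULT_MIN_MAPQ, GenomicInterval

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
FLANK = 25
OFFSETS = np.arange(-FLANK, FLANK + 1)
UNIFORM_Q = 0.25
DEFAULT_Q_FLOOR = 0.005

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrosslinkSite:
    """A called crosslinking site within a peak."""

    chrom: str
    position: int  # 0-based genomic coordinate
    strand: str
    m: int  # number of R2 reads whose 5' end coincides with the position
    fdr: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("a crosslink site needs at least one read start")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("fdr must be in [0, 1]")


class BiasTable:
    """Crosslinking sequence propensity q(a, d), a in {A,C,G,T}, d in [-25, 25].

    Stored as a 4 x 51 matrix whose columns each sum to one.  ``q_of`` returns
    0.25 for offsets outside the window (or ``d=None``, meaning the SNV has no
    crosslink site in its peak).  T stands in for U internally; RNA-facing
    output may render U.
    """

    def __init__(self, q: np.ndarray, n_sites: int = 0):
        q = np.asarray(q, dtype=float)
        if q.shape != (4, len(OFFSETS)):
            raise ValueError(f"q must be 4 x {len(OFFSETS)}, got {q.shape}")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("q entries must lie in [0, 1]")
        sums = q.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each offset column of q must sum to 1")
        self.q = q
        self.n_sites = int(n_sites)

    @classmethod
    def uniform(cls) -> "BiasTable":
        return cls(np.full((4, len(OFFSETS)), UNIFORM_Q), n_sites=0)

    def q_of(self, allele: str, d: int | None) -> float:
        if d is None or d < -FLANK or d > FLANK:
            return UNIFORM_Q
        return float(self.q[_BASE_INDEX[allele.upper()], d + FLANK])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("base\t" + "\t".join(str(d) for d in OFFSETS) + "\n")
            for i, b in enumerate(BASES):
                fh.write(b + "\t" + "\t".join(f"{v:.12g}" for v in self.q[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasTable":
        rows = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            offsets = [int(x) for x in header[1:]]
            if offsets != list(OFFSETS):
                raise ValueError("bias table header must list offsets -25..25")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows[fields[0]] = [float(x) for x in fields[1:]]
        q = np.array([rows[b] for b in BASES])
        return cls(q)


def collect_read_starts(
    peak: GenomicInterval,
    alignments,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    single_end: bool = False,
) -> dict[int, int]:
    """Count biological-5'-end positions of usable R2 reads within a peak.

    The 5' end is the leftmost aligned base for reads on the + strand and the
    rightmost for -; only reads whose strand matches the peak strand count.
    Positions with zero starts are omitted.
    """
    counts: dict[int, int] = {}
    for read in alignments.fetch(peak.chrom, peak.start, peak.end):
        if not is_usable_read(read, min_mapq, single_end):
            continue
        read_strand = "-" if read.is_reverse else "+"
        if read_strand != peak.strand:
            continue
        start = read.reference_end - 1 if read.is_reverse else read.reference_start
        if peak.contains(start):
            counts[start] = counts.get(start, 0) + 1
    return counts


def crosslink_fdr_curve(
    start_counts: Mapping[int, int],
    peak_length: int,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """Empirical FDR for each candidate read-start threshold m.

    The null redistributes the peak's read starts i.i.d. uniformly over its
    positions; FDR(m) = E_perm[#positions with count >= m] / #observed
    positions with count >= m, clipped to [0, 1] and made monotone
    non-increasing in m.
    """
    if peak_length < 1:
        raise ValueError("peak_length must be >= 1")
    if not start_counts:
        return {}
    rng = np.random.default_rng() if rng is None else rng
    obs = np.fromiter(start_counts.values(), dtype=np.int64)
    n_reads = int(obs.sum())
    max_m = int(obs.max())
    thresholds = np.arange(1, max_m + 1)

    # Tally, across permutations, how many positions reach each count.
    tail_sum = np.zeros(max_m, dtype=np.float64)  # index m-1 -> sum over perms of #pos>=m
    for _ in range(n_perm):
        pos = rng.integers(0, peak_length, size=n_reads)
        cnt = np.bincount(pos, minlength=peak_length)
        cnt = cnt[cnt > 0]
        cnt = np.minimum(cnt, max_m)
        hist = np.bincount(cnt, minlength=max_m + 1)[1:]
        tail_sum += np.cumsum(hist[::-1])[::-1]
    expected_tail = tail_sum / n_perm

    obs_sorted = np.sort(obs)
    obs_tail = len(obs) - np.searchsorted(obs_sorted, thresholds, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_tail > 0, expected_tail / obs_tail, 0.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    # enforce monotone non-increasing FDR in m
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    return {int(m): float(f) for m, f in zip(thresholds, fdr)}


def call_crosslink_sites(
    start_counts: Mapping[int, int],
    peak_length: int,
    n_perm: int = 1000,
    max_fdr: float = 0.001,
    rng: np.random.Generator | int | None = None,
    chrom: str = ".",
    strand: str = "+",
) -> list[CrosslinkSite]:
    """Call crosslinking sites in one peak at empirical FDR <= max_fdr.

    Multiple sites per peak are allowed (reverse transcription can read
    through a 3' crosslink and stall at an upstream one).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    fdr_by_m = crosslink_fdr_curve(start_counts, peak_length, n_perm, rng)
    sites = [
        CrosslinkSite(chrom=chrom, position=pos, strand=strand, m=m, fdr=fdr_by_m[m])
        for pos, m in start_counts.items()
        if fdr_by_m[m] <= max_fdr
    ]
    sites.sort(key=lambda s: s.position)
    return sites


def _site_context(genome, chrom: str, position: int, strand: str) -> str | None:
    """Strand-oriented 51-mer centred on a crosslink site, or None at edges."""
    start = position - FLANK
    end = position + FLANK + 1
    if start < 0:
        return None
    seq = str(genome[chrom][start:end]).upper()
    if len(seq) != 2 * FLANK + 1:
        return None
    if strand == "-":
        seq = reverse_complement(seq)
    return seq


def estimate_bias_table(
    sites: Iterable[CrosslinkSite | tuple],
    genome,
) -> BiasTable:
    """Estimate q(a, d) from the sequence contexts of SMInput crosslink sites.

    ``genome`` is any mapping of chromosome name to sliceable sequence
    (e.g. pyfaidx.Fasta).  Sites whose 51-nt window runs off the chromosome
    are skipped and counted; ambiguous bases (N) are excluded per offset.
    """
    counts = np.zeros((4, len(OFFSETS)), dtype=np.int64)
    n_used = 0
    n_skipped = 0
    for site in sites:
        if isinstance(site, CrosslinkSite):
            chrom, pos, strand = site.chrom, site.position, site.strand
        else:
            chrom, pos, strand = site
        ctx = _site_context(genome, chrom, pos, strand)
        if ctx is None:
            n_skipped += 1
            continue
        n_used += 1
        for d, base in zip(OFFSETS, ctx):
            i = _BASE_INDEX.get(base)
            if i is not None:
                counts[i, d + FLANK] += 1
    if n_used == 0:
        raise ValueError("no usable crosslink sites: cannot estimate bias table")
    if n_skipped:
        logger.info("bias estimation: skipped %d site(s) too close to a chromosome edge",
                    n_skipped)
    colsums = counts.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError("an offset column received no unambiguous bases")
    q = counts / colsums
    return BiasTable(q, n_sites=n_used)


def assign_offset(
    snv_position: int,
    sites: Sequence[CrosslinkSite | int],
    strand: str = "+",
    flank: int = FLANK,
) -> int | None:
    """Strand-oriented offset of an SNV to the nearest crosslink site.

    Ties are broken toward the 5' site.  Returns None ("outside") when the
    peak has no called site or the nearest one is farther than ``flank``.
    """
    positions = [s.position if isinstance(s, CrosslinkSite) else int(s) for s in sites]
    if not positions:
        return None
    best = None
    for p in positions:
        dist = abs(snv_position - p)
        if best is None or dist < best[0]:
            best = (dist, p)
        elif dist == best[0]:
            # 5' on + strand is the smaller coordinate; on -, the larger.
            if (strand == "+" and p < best[1]) or (strand == "-" and p > best[1]):
                best = (dist, p)
    site = best[1]
    d = snv_position - site if strand == "+" else site - snv_position
    if abs(d) > flank:
        return None
    return int(d)


def normalize_allelic_count(
    y: float,
    allele: str,
    d: int | None,
    bias: BiasTable,
    R: float,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> float:
    """Bias- and library-normalize a raw allelic count: x = y / (q(a, d) * R).

    q is floored at ``q_floor`` when the allele base was (almost) never seen
    at that offset in the SMInput -- a finite-sample zero, not a true
    impossibility -- since dividing by 0 would blow up.
    """
    if y < 0:
        raise ValueError("raw count must be non-negative")
    if R <= 0:
        raise ValueError("library size must be positive")
    q = bias.q_of(allele, d)
    if q < q_floor:
        if y > 0:
            logger.warning(
                "q(%s, %s) = %.3g below floor %.3g; flooring (allele observed %g times)",
                allele, d, q, q_floor, y,
            )
        q = q_floor
    return y / (q * R)
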