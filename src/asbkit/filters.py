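"""Posterior quality filters for ASB candidates on real data.

Allelic imbalance at single nucleotides inherits the artifact modes of
RNA-editing analysis, so candidates are screened after testing: homopolymer
runs, annotated microsatellites, multi-mapping regions, whole-gene
allele-specific expression (an imbalance of transcription, not binding),
reference-mapping bias, and multi-RBP "hotspot" windows.  The chain applies
the filters in that fixed order and reports per-step attrition; a candidate
failing several filters is charged to the first.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import bh_adjust

logger = logging.getLogger(__name__)

FILTER_ORDER = (
    "homopolymer", "microsatellite", "mappability", "ase", "reference_bias", "hotspot",
)


@dataclass
class FilterReport:
    """Per-filter attrition, ordered as applied."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_removed: int) -> None:
        self.steps.append({
            "filter": name,
            "n_before": n_before,
            "n_removed": n_removed,
            "n_remaining": n_before - n_removed,
            "pct_removed": 100.0 * n_removed / n_before if n_before else 0.0,
        })

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["filter", "n_before", "n_removed", "n_remaining", "pct_removed"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# --- individual filters (pure predicates: True = keep) ----------------------

def homopolymer_filter(chrom: str, pos: int, genome, min_run: int = 5) -> bool:
    """Keep unless the reference position sits inside a run of >= min_run
    identical bases (the run includes the reference base at the SNV)."""
    chrom_seq = genome[chrom]
    chrom_len = len(chrom_seq)
    start = max(0, pos - (min_run - 1))
    end = min(chrom_len, pos + min_run)
    seq = str(chrom_seq[start:end]).upper()
    centre = pos - start
    base = seq[centre]
    run = 1
    i = centre - 1
    while i >= 0 and seq[i] == base:
        run += 1
        i -= 1
    i = centre + 1
    while i < len(seq) and seq[i] == base:
        run += 1
        i += 1
    return run < min_run


class IntervalSet:
    """Half-open interval overlap lookup per chromosome (for BED masks)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            # merge overlaps so a single bisect suffices
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]


def microsatellite_filter(chrom: str, pos: int, microsatellites: IntervalSet) -> bool:
    """Keep unless the position overlaps an annotated microsatellite
    (0-based half-open overlap)."""
    return not microsatellites.contains(chrom, pos)


def mappability_filter(
    chrom: str,
    pos: int,
    similarity: Mapping[tuple[str, int], float],
    max_identity: float = 0.95,
    strict: bool = False,
) -> bool:
    """Keep unless the best off-target identity of the 101-mer centred at the
    SNV is >= max_identity (inclusive).

    ``similarity`` is a precomputed table (e.g. from an external aligner over
    the 101-nt windows); a missing SNV is kept with a warning unless
    ``strict``.
    """
    ident = similarity.get((chrom, pos))
    if ident is None:
        if strict:
            return False
        logger.warning("no mappability entry for %s:%d; keeping", chrom, pos + 1)
        return True
    return ident < max_identity


def load_similarity_table(path: str | Path) -> dict[tuple[str, int], float]:
    """TSV (chrom, pos 1-based, best_offtarget_identity) -> lookup table."""
    table: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, ident = line.split("\t")[:3]
            table[(chrom, int(pos) - 1)] = float(ident)
    return table


def detect_ase_genes(
    gene_allelic_tables: Mapping[str, pd.DataFrame],
    n_datasets_required: int = 2,
    min_cov: int = 10,
    min_testable_snvs: int = 2,
    fdr_threshold: float = 0.05,
    ratio_low: float = 0.40,
    ratio_high: float = 0.60,
) -> set[str]:
    """Genes with whole-gene allele-specific expression in RNA-Seq.

    Each table (one per RNA-Seq data set) has columns gene, ref, alt (one
    row per heterozygous SNV).  Within a data set a gene is ASE when it has
    >= 2 testable SNVs (coverage >= 10) and every one is biased at BH
    FDR < 0.05 (exact binomial test against 0.5; the BH family is all
    testable SNVs of the data set).  A gene is confirmed when it is ASE in
    >= n_datasets_required data sets and, in each of those, every testable
    SNV's reference-allele frequency is < 0.40 or > 0.60.
    """
    ase_votes: dict[str, int] = {}
    freq_ok: dict[str, bool] = {}
    for name, df in gene_allelic_tables.items():
        df = df.copy()
        df["cov"] = df["ref"] + df["alt"]
        testable = df[df["cov"] >= min_cov].copy()
        if testable.empty:
            continue
        testable["p"] = [
            stats.binomtest(int(r), int(n), 0.5).pvalue
            for r, n in zip(testable["ref"], testable["cov"])
        ]
        testable["fdr"] = bh_adjust(testable["p"].to_numpy())
        testable["ratio"] = testable["ref"] / testable["cov"]
        for gene, sub in testable.groupby("gene"):
            if len(sub) < min_testable_snvs:
                continue
            if not (sub["fdr"] < fdr_threshold).all():
                continue
            ase_votes[gene] = ase_votes.get(gene, 0) + 1
            extreme = ((sub["ratio"] < ratio_low) | (sub["ratio"] > ratio_high)).all()
            freq_ok[gene] = freq_ok.get(gene, True) and bool(extreme)
    return {
        g for g, votes in ase_votes.items()
        if votes >= n_datasets_required and freq_ok.get(g, False)
    }


def reference_bias_filter(
    theta_i: float, theta_mean: float, theta_sd: float, min_z: float = 1.0
) -> bool:
    """Keep unless the candidate's allelic ratio is within ``min_z`` SMInput
    standard deviations of the SMInput mean ratio (z = |θᵢ − θ| / σ < 1 would
    be consistent with reference-mapping bias alone)."""
    if theta_sd <= 0:
        raise ValueError("degenerate SMInput allelic-ratio distribution (sd = 0)")
    z = abs(theta_i - theta_mean) / theta_sd
    return z >= min_z


def find_hotspot_windows(
    candidates: pd.DataFrame,
    window: int = 2000,
    rbp_threshold: int = 4,
    fdr_threshold: float = 0.01,
    min_count: int = 3,
) -> set[tuple[str, int]]:
    """Windows where candidates shared by > rbp_threshold RBPs pile up.

    The genome is binned into non-overlapping ``window``-nt windows; in each,
    the number of candidates at positions that are ASB candidates for
    strictly more than ``rbp_threshold`` distinct RBPs is counted.  Windows
    whose count significantly exceeds the background (Poisson upper tail
    against the mean over non-empty windows, BH FDR < 0.01) and reaches the
    hard floor ``min_count`` are flagged.
    """
    if candidates.empty:
        return set()
    rbp_per_pos = candidates.groupby(["chrom", "pos"])["rbp"].nunique()
    multi = set(rbp_per_pos[rbp_per_pos > rbp_threshold].index)
    if not multi:
        return set()
    is_multi = [
        (c, p) in multi for c, p in zip(candidates["chrom"], candidates["pos"])
    ]
    cand_multi = candidates[np.asarray(is_multi)]
    win_counts = (
        cand_multi.assign(win=cand_multi["pos"] // window)
        .groupby(["chrom", "win"]).size()
    )
    # background: mean multi-RBP count over every window that holds any
    # candidate at all, so a lone crowded window is judged against the
    # genome-wide rate rather than against itself
    n_bg_windows = (
        candidates.assign(win=candidates["pos"] // window)
        .groupby(["chrom", "win"]).ngroups
    )
    background = float(win_counts.sum()) / n_bg_windows
    pvals = stats.poisson.sf(win_counts.values - 1, background)
    fdr = bh_adjust(pvals)
    flagged = {
        (chrom, int(win))
        for (chrom, win), f, n in zip(win_counts.index, fdr, win_counts.values)
        if f < fdr_threshold and n >= min_count
    }
    return flagged


def hotspot_filter_mask(
    candidates: pd.DataFrame,
    window: int = 2000,
    rbp_threshold: int = 4,
    fdr_threshold: float = 0.01,
    min_count: int = 3,
) -> np.ndarray:
    """Boolean keep-mask removing every candidate inside a flagged window."""
    flagged = find_hotspot_windows(candidates, window, rbp_threshold,
                                   fdr_threshold, min_count)
    if not flagged:
        return np.ones(len(candidates), dtype=bool)
    keep = np.array([
        (chrom, pos // window) not in flagged
        for chrom, pos in zip(candidates["chrom"], candidates["pos"])
    ])
    return keep


@dataclass
class FilterConfig:
    """Resources and toggles for the posterior filter chain.

    A filter whose resource is absent is skipped (with a prominent warning
    for the ASE filter, which silently passing would make misleading).
    """

    genome: object | None = None
    microsatellites: IntervalSet | None = None
    similarity: Mapping[tuple[str, int], float] | None = None
    rnaseq_tables: Mapping[str, pd.DataFrame] | None = None
    snv_to_gene: Mapping[tuple[str, int], str] | None = None
    sminput_ratio_mean: float | None = None
    sminput_ratio_sd: float | None = None
    enabled: Sequence[str] = FILTER_ORDER
    min_run: int = 5
    max_identity: float = 0.95
    mappability_strict: bool = False
    ase_datasets_required: int = 2
    min_z: float = 1.0
    hotspot_window: int = 2000
    hotspot_rbp_threshold: int = 4
    hotspot_fdr: float = 0.01
    hotspot_min_count: int = 3


def apply_filter_chain(
    candidates: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the six filters in fixed order; returns survivors and the report.

    ``candidates`` needs columns chrom, pos (0-based), rbp and, for the
    reference-bias step, ratio (major-allele or reference ratio as
    configured upstream).  The result is independent of input row order: each
    step's mask is computed on the step's survivors only, and every step is a
    pure per-candidate predicate except the hotspot step, whose window
    statistics are order-free aggregates.
    """
    report = FilterReport()
    current = candidates.copy()

    def _run(name: str, mask_fn: Callable[[pd.DataFrame], np.ndarray]) -> None:
        nonlocal current
        n_before = len(current)
        if name not in config.enabled or n_before == 0:
            report.add(name, n_before, 0)
            return
        mask = np.asarray(mask_fn(current), dtype=bool)
        report.add(name, n_before, int((~mask).sum()))
        current = current[mask]

    def _homopolymer(df):
        if config.genome is None:
            return np.ones(len(df), dtype=bool)
        return np.array([
            homopolymer_filter(c, p, config.genome, config.min_run)
            for c, p in zip(df["chrom"], df["pos"])
        ])

    def _microsat(df):
        if config.microsatellites is None:
            return np.ones(len(df), dtype=bool)
        return np.array([
            microsatellite_filter(c, p, config.microsatellites)
            for c, p in zip(df["chrom"], df["pos"])
        ])

    def _mappability(df):
        if config.similarity is None:
            return np.ones(len(df), dtype=bool)
        return np.array([
            mappability_filter(c, p, config.similarity, config.max_identity,
                               config.mappability_strict)
            for c, p in zip(df["chrom"], df["pos"])
        ])

    def _ase(df):
        if not config.rnaseq_tables:
            logger.warning(
                "ASE filter skipped: no RNA-Seq allelic tables supplied; "
                "allele-specific expression may masquerade as binding"
            )
            return np.ones(len(df), dtype=bool)
        if config.snv_to_gene is None:
            logger.warning("ASE filter skipped: no SNV-to-gene map supplied")
            return np.ones(len(df), dtype=bool)
        ase_genes = detect_ase_genes(
            config.rnaseq_tables, n_datasets_required=config.ase_datasets_required
        )
        return np.array([
            config.snv_to_gene.get((c, p)) not in ase_genes
            for c, p in zip(df["chrom"], df["pos"])
        ])

    def _refbias(df):
        if config.sminput_ratio_sd is None or config.sminput_ratio_mean is None:
            return np.ones(len(df), dtype=bool)
        return np.array([
            reference_bias_filter(r, config.sminput_ratio_mean,
                                  config.sminput_ratio_sd, config.min_z)
            for r in df["ratio"]
        ])

    def _hotspot(df):
        return hotspot_filter_mask(
            df, config.hotspot_window, config.hotspot_rbp_threshold,
            config.hotspot_fdr, config.hotspot_min_count,
        )

    _run("homopolymer", _homopolymer)
    _run("microsatellite", _microsat)
    _run("mappability", _mappability)
    _run("ase", _ase)
    _run("reference_bias", _refbias)
    _run("hotspot", _hotspot)
    return current, report
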