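"""End-to-end orchestration of the ASB pipeline over real alignment data.

Stages: peak retention → crosslink-site calling (eCLIP reads for offsets,
SMInput reads for bias estimation) → heterozygous-SNV calling from pooled
SMInput → allelic counting and bias normalization per replicate → variance
trend + empirical Gaussian test + BH → posterior filters.  Every stage's
output is persisted so a run is auditable; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
import yaml
from pyfaidx import Fasta

from . import bias as bias_mod
from . import filters as filt_mod
from . import io as io_mod
from . import snv as snv_mod
from .model import EmpiricalGaussianASB, ASBRecord

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """A pipeline stage failed on the input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """One auditable home for every pipeline threshold.

    Thresholds default to the published operating points: 4-fold peak
    enrichment, crosslink-site FDR 0.001, heterozygote coverage ≥ 10 with
    reference ratio in [0.25, 0.75], ASB FDR < 0.10.
    """

    peaks: str = ""
    replicates: list = field(default_factory=list)  # eCLIP BAM paths
    sminput: str = ""
    genome: str = ""
    candidate_snvs: str = ""
    rbp: str = "RBP"
    out_dir: str = "asbkit_out"
    user_snvs: str | None = None
    microsatellite_bed: str | None = None
    similarity_table: str | None = None

    peak_fold: float = 4.0
    crosslink_fdr: float = 0.001
    crosslink_permutations: int = 1000
    het_min_coverage: int = 10
    het_ratio_low: float = 0.25
    het_ratio_high: float = 0.75
    min_base_quality: int = 10
    min_mapq: int = 10
    asb_fdr: float = 0.10
    loess_span: float = 0.75
    q_floor: float = 0.005
    min_trend_points: int = 30
    single_end: bool = False
    filters_enabled: list = field(default_factory=lambda: list(filt_mod.FILTER_ORDER))
    seed: int = 0

    def validate(self) -> None:
        if len(self.replicates) < 2:
            raise ConfigError("need at least two eCLIP replicate alignments")
        for name, lo, hi in [
            ("peak_fold", 0, np.inf), ("crosslink_fdr", 0, 1),
            ("het_ratio_low", 0, 1), ("het_ratio_high", 0, 1),
            ("asb_fdr", 0, 1), ("loess_span", 0, 1), ("q_floor", 0, 0.25),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.het_ratio_low > self.het_ratio_high:
            raise ConfigError("het_ratio_low must be <= het_ratio_high")
        if self.crosslink_permutations < 100:
            raise ConfigError("crosslink_permutations must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, DataError):
                raise
            except Exception as exc:
                raise DataError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _peak_coverage(aln: pysam.AlignmentFile, iv: io_mod.GenomicInterval,
                   min_mapq: int, single_end: bool) -> int:
    n = 0
    for read in aln.fetch(iv.chrom, iv.start, iv.end):
        if not io_mod.is_usable_read(read, min_mapq, single_end):
            continue
        if ("-" if read.is_reverse else "+") != iv.strand:
            continue
        n += 1
    return n


def run_call(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Outputs: asb_table.tsv, crosslink_sites.bed, bias_table.tsv, trend.tsv,
    filter_report.tsv, attrition.tsv, config_used.yaml.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    rng = np.random.default_rng(config.seed)

    for label, p in [("peaks", config.peaks), ("genome", config.genome),
                     ("candidate_snvs", config.candidate_snvs),
                     ("sminput", config.sminput),
                     *[(f"replicate[{i}]", r) for i, r in enumerate(config.replicates)]]:
        if not p or not Path(p).exists():
            raise ConfigError(f"missing input for stage inputs: {label} ({p!r})")

    intervals = io_mod.load_peaks(config.peaks)
    if not intervals:
        raise DataError("stage 'peaks': no peaks in input")

    reps = [pysam.AlignmentFile(p) for p in config.replicates]
    smi = pysam.AlignmentFile(config.sminput)
    try:
        return _run_call_open(config, out, intervals, reps, smi, rng)
    finally:
        for a in reps:
            a.close()
        smi.close()


def _run_call_open(config, out, intervals, reps, smi, rng):
    se = config.single_end
    mq = config.min_mapq
    rep_R = [io_mod.library_size_millions(a, mq, se) for a in reps]
    for a in reps:
        a.reset()
    smi_R = io_mod.library_size_millions(smi, mq, se)
    smi.reset()
    logger.info("library sizes (millions): replicates %s, SMInput %.6g", rep_R, smi_R)

    # stage: peak retention
    peaks = []
    for iv in intervals:
        peaks.append(io_mod.Peak(
            interval=iv,
            rep_coverage=[_peak_coverage(a, iv, mq, se) for a in reps],
            input_coverage=_peak_coverage(smi, iv, mq, se),
            rep_library_sizes=rep_R,
            input_library_size=smi_R,
        ))
    retained, attrition = io_mod.retain_peaks(peaks, config.peak_fold)
    with open(out / "attrition.tsv", "w") as fh:
        fh.write("n_input\tn_retained\tn_dropped\n")
        fh.write(f"{attrition.n_input}\t{attrition.n_retained}\t{attrition.n_dropped}\n")
    if not retained:
        raise DataError("stage 'peak retention': no peak passed the enrichment filter")

    # stage: crosslink sites (eCLIP, pooled replicates -> offsets;
    # SMInput -> bias estimation)
    try:
        genome = Fasta(config.genome)
    except Exception as exc:
        raise DataError(f"stage 'bias estimation': cannot open genome FASTA: {exc}")

    eclip_sites: dict[int, list[bias_mod.CrosslinkSite]] = {}
    smi_sites: list[bias_mod.CrosslinkSite] = []
    for idx, pk in enumerate(retained):
        iv = pk.interval
        starts: dict[int, int] = {}
        for a in reps:
            for pos, cnt in bias_mod.collect_read_starts(iv, a, mq, se).items():
                starts[pos] = starts.get(pos, 0) + cnt
        eclip_sites[idx] = bias_mod.call_crosslink_sites(
            starts, len(iv), n_perm=config.crosslink_permutations,
            max_fdr=config.crosslink_fdr, rng=rng, chrom=iv.chrom, strand=iv.strand,
        )
        smi_starts = bias_mod.collect_read_starts(iv, smi, mq, se)
        smi_sites.extend(bias_mod.call_crosslink_sites(
            smi_starts, len(iv), n_perm=config.crosslink_permutations,
            max_fdr=config.crosslink_fdr, rng=rng, chrom=iv.chrom, strand=iv.strand,
        ))
    with open(out / "crosslink_sites.bed", "w") as fh:
        for idx, sites in sorted(eclip_sites.items()):
            for s in sites:
                fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}"
                         f"\tpeak{idx}\t{s.m}\t{s.strand}\n")
    if not smi_sites:
        raise DataError("stage 'bias estimation': no SMInput crosslink sites called; "
                        "cannot estimate the propensity table")
    bias_table = bias_mod.estimate_bias_table(smi_sites, genome)
    bias_table.to_tsv(out / "bias_table.tsv")

    # stage: heterozygous SNVs from pooled SMInput (+ optional user VCF)
    candidates = snv_mod.load_candidate_snvs(config.candidate_snvs)
    het: list[snv_mod.CandidateSNV] = []
    for cand in candidates:
        pooled = snv_mod.count_alleles(cand, smi, sample="sminput",
                                       min_base_quality=config.min_base_quality,
                                       min_mapq=mq, single_end=se)
        if snv_mod.call_heterozygous(pooled, config.het_min_coverage,
                                     config.het_ratio_low, config.het_ratio_high):
            het.append(dataclasses.replace(cand, source="eclip"))
    if config.user_snvs:
        het = snv_mod.merge_with_user_snvs(
            het, snv_mod.load_user_heterozygous_snvs(config.user_snvs))
    logger.info("heterozygous SNVs: %d of %d candidates", len(het), len(candidates))

    # stage: allelic counts + normalization for het SNVs inside retained peaks
    rows = []
    for cand in het:
        hit = None
        for idx, pk in enumerate(retained):
            if pk.interval.chrom == cand.chrom and pk.interval.contains(cand.pos):
                hit = idx
                break
        if hit is None:
            continue
        iv = retained[hit].interval
        d = bias_mod.assign_offset(cand.pos, eclip_sites[hit], iv.strand)
        x_ref, x_alt = [], []
        for a, R in zip(reps, rep_R):
            ac = snv_mod.count_alleles(cand, a, min_base_quality=config.min_base_quality,
                                       min_mapq=mq, single_end=se)
            # bases on the - strand peak are complemented for the bias lookup
            ref_b, alt_b = cand.ref, cand.alt
            if iv.strand == "-":
                ref_b = bias_mod.reverse_complement(ref_b)
                alt_b = bias_mod.reverse_complement(alt_b)
            x_ref.append(bias_mod.normalize_allelic_count(
                ac.y_ref, ref_b, d, bias_table, R, config.q_floor))
            x_alt.append(bias_mod.normalize_allelic_count(
                ac.y_alt, alt_b, d, bias_table, R, config.q_floor))
        rows.append((cand, np.array(x_ref), np.array(x_alt)))
    if not rows:
        raise DataError("stage 'allelic counting': no heterozygous SNV inside "
                        "a retained peak")

    # stage: variance trend + test + BH
    x_ref = np.vstack([r[1] for r in rows])
    x_alt = np.vstack([r[2] for r in rows])
    est = EmpiricalGaussianASB(span=config.loess_span,
                               fdr_threshold=config.asb_fdr,
                               min_trend_points=min(config.min_trend_points,
                                                    2 * len(rows)))
    est.fit(x_ref, x_alt)
    est.trend_.to_tsv(out / "trend.tsv")

    records = []
    for i, (cand, _, _) in enumerate(rows):
        if not est.testable_[i]:
            continue
        records.append(ASBRecord(
            chrom=cand.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
            rbp=config.rbp,
            major_allele="ref" if est.major_is_ref_[i] else "alt",
            mu_major=float(est.mu_major_[i]), mu_minor=float(est.mu_minor_[i]),
            var_major=float(est.var_major_[i]), k=est.k_,
            pvalue=float(est.pvalues_[i]), fdr=float(est.fdr_[i]),
            significant=bool(est.significant_[i]),
        ))

    # stage: posterior filters on significant candidates
    import pandas as pd

    sig = [r for r in records if r.significant]
    fconf = filt_mod.FilterConfig(
        genome=genome,
        microsatellites=(filt_mod.IntervalSet.from_bed(config.microsatellite_bed)
                         if config.microsatellite_bed else None),
        similarity=(filt_mod.load_similarity_table(config.similarity_table)
                    if config.similarity_table else None),
        enabled=config.filters_enabled,
    )
    if sig:
        df = pd.DataFrame({
            "chrom": [r.chrom for r in sig], "pos": [r.pos for r in sig],
            "rbp": [r.rbp for r in sig],
            "ratio": [r.mu_major / (r.mu_major + r.mu_minor) for r in sig],
        })
        surviving, report = filt_mod.apply_filter_chain(df, fconf)
        survived_keys = set(zip(surviving["chrom"], surviving["pos"]))
        for r in records:
            if r.significant and (r.chrom, r.pos) not in survived_keys:
                r.significant = False
                r.filters_failed = "posterior"
    else:
        report = filt_mod.FilterReport()
        for name in filt_mod.FILTER_ORDER:
            report.add(name, 0, 0)
    report.to_tsv(out / "filter_report.tsv")

    io_mod.write_asb_table(records, out / "asb_table.tsv")
    logger.info("wrote %d ASB record(s) to %s", len(records), out / "asb_table.tsv")
    return out
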