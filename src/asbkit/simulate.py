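"""Synthetic allelic read-count generation for testing and benchmarking.

Each simulated experiment mimics the count structure of a two-replicate eCLIP
assay at heterozygous SNVs: a per-SNV total coverage drawn from a broad
(log-normal by default, or empirical) distribution, a shared per-replicate
depth factor capturing replicate-level depth/IP-efficiency variability, and
per-allele counts drawn from a zero-truncated negative binomial (ZTNB) whose
variance follows a mean–variance target with a CV² plateau.  A configurable
fraction of SNVs carries true allele-specific binding with major-allele
ratio r; optionally, counts are distorted by a crosslinking-bias table the
way real counts are, so bias correction can be exercised end to end.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bias import BASES, BiasTable, FLANK, OFFSETS, UNIFORM_Q

logger = logging.getLogger(__name__)

#: Sentinel offset for SNVs outside any crosslink window.
OUTSIDE = 127


def default_variance_target(mean: np.ndarray, cv2_plateau: float = 0.05) -> np.ndarray:
    """Mean–variance target v(m) = m + cv2_plateau · m².

    The linear term is Poisson counting noise; the quadratic term is the
    high-count CV² plateau seen in replicated eCLIP allelic counts.
    """
    mean = np.asarray(mean, dtype=float)
    return mean + cv2_plateau * mean**2


@dataclass
class SimConfig:
    """Study conditions for simulated allelic counts.

    Defaults are the benchmark conditions used throughout: 5000 SNVs per
    experiment, 10% true-ASB fraction at major-allele ratio 0.8, two
    replicates, log-normal coverage with median 55 (floored at 10), CV²
    plateau 0.05, and a shared between-replicate depth factor with ~25% CV.
    """

    n_experiments: int = 1
    n_snvs: int = 5000
    frac_asb: float = 0.10
    r_true: float = 0.8
    k: int = 2
    coverage_file: str | None = None
    coverage_log_median: float = 55.0
    coverage_log_sigma: float = 1.0
    min_coverage: int = 10
    cv2_plateau: float = 0.05
    rep_log_sigma: float = 0.25
    coverage_mode: str = "per_snv"  # per_snv | shared | independent
    bias: BiasTable | None = None
    high_variance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_asb < 1.0):
            # 0 is allowed: an all-null study is how calibration is checked
            raise ValueError("frac_asb must be in [0, 1)")
        if not (0.5 < self.r_true < 1.0):
            raise ValueError("r_true must be in (0.5, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.coverage_mode not in ("per_snv", "shared", "independent"):
            raise ValueError("coverage_mode must be per_snv, shared or independent")
        if self.n_snvs < 1 or self.n_experiments < 0:
            raise ValueError("n_snvs >= 1 and n_experiments >= 0 required")

    def variance_target(self) -> Callable[[np.ndarray], np.ndarray]:
        return lambda m: default_variance_target(m, self.cv2_plateau)


@dataclass
class SimDataset:
    """One simulated experiment with embedded truth labels."""

    major: np.ndarray  # (n_snvs, k) counts of the major allele
    minor: np.ndarray  # (n_snvs, k)
    is_asb: np.ndarray  # (n_snvs,) bool truth labels
    r: np.ndarray  # (n_snvs,) true major-allele ratio
    offset: np.ndarray  # (n_snvs,) int8-ish; OUTSIDE when no crosslink window
    major_base: np.ndarray  # (n_snvs,) allele nucleotides
    minor_base: np.ndarray
    coverage: np.ndarray  # (n_snvs,) the sampled per-SNV total coverage
    seed: int = 0

    @property
    def n_snvs(self) -> int:
        return self.major.shape[0]

    @property
    def k(self) -> int:
        return self.major.shape[1]

    def mean_coverage(self) -> np.ndarray:
        """Average observed total (major+minor) coverage across replicates."""
        return (self.major + self.minor).mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            cols = ["snv_id", "replicate", "major", "minor", "offset",
                    "major_base", "minor_base", "label", "r"]
            fh.write("\t".join(cols) + "\n")
            for i in range(self.n_snvs):
                label = "ASB" if self.is_asb[i] else "null"
                off = "outside" if self.offset[i] == OUTSIDE else str(int(self.offset[i]))
                for j in range(self.k):
                    fh.write("\t".join([
                        f"snv{i}", str(j + 1),
                        str(int(self.major[i, j])), str(int(self.minor[i, j])),
                        off, self.major_base[i], self.minor_base[i],
                        label, f"{self.r[i]:g}",
                    ]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimDataset":
        seed = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# seed="):
                seed = int(first.strip().split("=", 1)[1])
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        snvs = df["snv_id"].unique()
        k = df["replicate"].nunique()
        n = len(snvs)
        major = df["major"].to_numpy().reshape(n, k)
        minor = df["minor"].to_numpy().reshape(n, k)
        per_snv = df.drop_duplicates("snv_id")
        offs = np.array([
            OUTSIDE if o == "outside" else int(o) for o in per_snv["offset"]
        ], dtype=np.int16)
        return cls(
            major=major, minor=minor,
            is_asb=(per_snv["label"] == "ASB").to_numpy(),
            r=per_snv["r"].to_numpy(dtype=float),
            offset=offs,
            major_base=per_snv["major_base"].to_numpy(dtype=object),
            minor_base=per_snv["minor_base"].to_numpy(dtype=object),
            coverage=(major + minor).mean(axis=1),
            seed=seed,
        )


def sample_total_coverage(
    source,
    rng: np.random.Generator,
    size: int = 1,
    min_coverage: int = 10,
    log_median: float = 55.0,
    log_sigma: float = 1.0,
) -> np.ndarray:
    """Per-SNV total read coverage, resampled until >= min_coverage.

    ``source`` is either an array/file of empirical coverages (one per line)
    to resample from, or None for the parametric log-normal fallback.
    """
    if isinstance(source, (str, Path)):
        values = np.loadtxt(source, dtype=float, ndmin=1)
        if values.size == 0:
            raise ValueError(f"empty empirical coverage file: {source}")
        source = values
    out = np.empty(size, dtype=np.int64)
    need = np.ones(size, dtype=bool)
    while need.any():
        n = int(need.sum())
        if source is None:
            draw = np.rint(
                np.exp(rng.normal(np.log(log_median), log_sigma, size=n))
            ).astype(np.int64)
        else:
            draw = np.asarray(rng.choice(np.asarray(source), size=n)).astype(np.int64)
        out[need] = draw
        need = out < min_coverage
        if source is not None and np.all(np.asarray(source) < min_coverage):
            raise ValueError("empirical coverage source has no values >= min_coverage")
    return out


def ztnb_sample(
    mean,
    variance,
    rng: np.random.Generator,
    max_rejections: int = 1000,
) -> np.ndarray:
    """Zero-truncated counts with pre-truncation NB(mean, variance).

    The NB is parameterized by (mean m, size s) with s = m²/(v − m); where
    v <= m (no overdispersion left to model) a Poisson is used instead, with
    a warning.  Zeros are rejection-resampled, which realizes the truncated
    distribution exactly.
    """
    mean = np.broadcast_arrays(np.asarray(mean, dtype=float))[0].copy()
    variance = np.broadcast_to(np.asarray(variance, dtype=float), mean.shape).copy()
    if np.any(mean <= 0):
        raise ValueError("ZTNB means must be positive")
    out = np.empty(mean.shape, dtype=np.int64)
    nb = variance > mean
    if not np.all(nb):
        warnings.warn("variance <= mean for some draws; falling back to "
                      "zero-truncated Poisson there", stacklevel=2)

    flat_mean = mean.ravel()
    flat_var = variance.ravel()
    flat_nb = nb.ravel()
    flat = np.empty(flat_mean.shape, dtype=np.int64)
    size = np.where(flat_nb, flat_mean**2 / np.where(flat_nb, flat_var - flat_mean, 1.0), 1.0)
    p = size / (size + flat_mean)
    need = np.ones(flat.shape, dtype=bool)
    for _ in range(max_rejections):
        idx = np.nonzero(need)[0]
        if idx.size == 0:
            break
        draw = np.empty(idx.size, dtype=np.int64)
        sel_nb = flat_nb[idx]
        if sel_nb.any():
            draw[sel_nb] = rng.negative_binomial(size[idx][sel_nb], p[idx][sel_nb])
        if (~sel_nb).any():
            draw[~sel_nb] = rng.poisson(flat_mean[idx][~sel_nb])
        flat[idx] = draw
        need[idx] = draw == 0
    if need.any():
        # means this small make zeros overwhelming; land on the floor
        flat[need] = 1
    out = flat.reshape(mean.shape)
    return out


def sample_allelic_counts_ztnb(
    C,
    r: float,
    var_target: Callable[[np.ndarray], np.ndarray],
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """k replicate (major, minor) count pairs for one SNV.

    ``C`` is the total coverage: a scalar (same mean for every replicate) or
    a length-k vector of per-replicate effective coverages.  Major and minor
    counts are independent ZTNB draws with means r·C and (1−r)·C.
    """
    C = np.broadcast_to(np.asarray(C, dtype=float), (k,))
    if np.any(C < 2):
        raise ValueError("total coverage must be >= 2")
    if not (0.5 <= r < 1.0):
        raise ValueError("r must be in [0.5, 1)")
    m_major = r * C
    m_minor = (1.0 - r) * C
    major = ztnb_sample(m_major, var_target(m_major), rng)
    minor = ztnb_sample(m_minor, var_target(m_minor), rng)
    return major, minor


_ALLELE_PAIRS = [(a, b) for a in BASES for b in BASES if a != b]


def inject_crosslink_bias(
    dataset: SimDataset,
    bias: BiasTable,
    rng: np.random.Generator,
    assign: bool = True,
) -> SimDataset:
    """Distort counts by crosslinking sequence propensity.

    Each SNV within the ±25-nt window (offset drawn uniformly unless already
    assigned) has each allele's counts rescaled by q(base, d)/0.25, rounded
    to the nearest integer with a floor of 1.  SNVs outside the window are
    untouched.
    """
    ds = dataclasses.replace(
        dataset,
        major=dataset.major.copy(), minor=dataset.minor.copy(),
        offset=dataset.offset.copy(),
        major_base=dataset.major_base.copy(), minor_base=dataset.minor_base.copy(),
    )
    n = ds.n_snvs
    if assign:
        ds.offset = rng.integers(-FLANK, FLANK + 1, size=n).astype(np.int16)
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
        ds.major_base = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
        ds.minor_base = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    inside = ds.offset != OUTSIDE
    q_major = np.array([
        bias.q_of(b, int(d)) for b, d in zip(ds.major_base, ds.offset)
    ])
    q_minor = np.array([
        bias.q_of(b, int(d)) for b, d in zip(ds.minor_base, ds.offset)
    ])
    scale_major = np.where(inside, q_major / UNIFORM_Q, 1.0)
    scale_minor = np.where(inside, q_minor / UNIFORM_Q, 1.0)
    ds.major = np.maximum(1, np.rint(ds.major * scale_major[:, None])).astype(np.int64)
    ds.minor = np.maximum(1, np.rint(ds.minor * scale_minor[:, None])).astype(np.int64)
    return ds


def make_high_variance(
    dataset: SimDataset,
    reference_sds: np.ndarray,
    rng: np.random.Generator,
    mean_tolerance: float = 0.10,
    max_tries: int = 50,
) -> SimDataset:
    """Re-draw each SNV's replicate counts into the high-variance regime.

    Replicate deviations from the SNV mean are scaled up until the
    between-replicate standard deviation exceeds the 95th percentile of
    ``reference_sds`` while the mean stays within ``mean_tolerance``; SNVs
    where integer counts cannot reach the target are dropped (with a count
    logged).
    """
    target = float(np.percentile(np.asarray(reference_sds, dtype=float), 95.0))
    keep_rows = []
    major = dataset.major.astype(float).copy()
    minor = dataset.minor.astype(float).copy()
    k = dataset.k
    signs = np.resize([1.0, -1.0], k)
    for i in range(dataset.n_snvs):
        ok = True
        for arr in (major, minor):
            x = arr[i]
            m = x.mean()
            achieved = False
            for _ in range(max_tries):
                dev = x - m
                if np.allclose(dev, 0):
                    dev = signs * max(1.0, 0.1 * m)
                scale = 1.5
                x = m + dev * scale
                x = np.maximum(1, np.rint(x))
                sd = x.std(ddof=1)
                if sd > target:
                    if abs(x.mean() - m) <= mean_tolerance * max(m, 1.0):
                        achieved = True
                    break
            if not achieved:
                ok = False
                break
            arr[i] = x
        if ok:
            keep_rows.append(i)
    n_dropped = dataset.n_snvs - len(keep_rows)
    if n_dropped:
        logger.warning("high-variance regime: dropped %d SNV(s) whose counts "
                       "could not reach the target SD", n_dropped)
    idx = np.asarray(keep_rows, dtype=int)
    return SimDataset(
        major=major[idx].astype(np.int64), minor=minor[idx].astype(np.int64),
        is_asb=dataset.is_asb[idx], r=dataset.r[idx], offset=dataset.offset[idx],
        major_base=dataset.major_base[idx], minor_base=dataset.minor_base[idx],
        coverage=dataset.coverage[idx], seed=dataset.seed,
    )


def _simulate_one(config: SimConfig, rng: np.random.Generator, seed: int) -> SimDataset:
    n, k = config.n_snvs, config.k
    n_asb = int(round(config.frac_asb * n))
    is_asb = np.zeros(n, dtype=bool)
    is_asb[rng.choice(n, size=n_asb, replace=False)] = True
    r = np.where(is_asb, config.r_true, 0.5)

    C = sample_total_coverage(
        config.coverage_file, rng, size=n,
        min_coverage=config.min_coverage,
        log_median=config.coverage_log_median,
        log_sigma=config.coverage_log_sigma,
    ).astype(float)

    if config.coverage_mode == "independent":
        C_rep = np.column_stack([
            sample_total_coverage(
                config.coverage_file, rng, size=n,
                min_coverage=config.min_coverage,
                log_median=config.coverage_log_median,
                log_sigma=config.coverage_log_sigma,
            ).astype(float)
            for _ in range(k)
        ])
    elif config.coverage_mode == "shared":
        C_rep = np.repeat(C[:, None], k, axis=1)
    else:  # per_snv: shared SNV coverage x replicate-level depth factor
        sig = config.rep_log_sigma
        factors = np.exp(rng.normal(-0.5 * sig**2, sig, size=(n, k)))
        C_rep = C[:, None] * factors

    var_target = config.variance_target()
    m_major = r[:, None] * C_rep
    m_minor = (1.0 - r)[:, None] * C_rep
    major = ztnb_sample(m_major, var_target(m_major), rng)
    minor = ztnb_sample(m_minor, var_target(m_minor), rng)

    ds = SimDataset(
        major=major, minor=minor, is_asb=is_asb, r=r,
        offset=np.full(n, OUTSIDE, dtype=np.int16),
        major_base=np.full(n, "T", dtype=object),
        minor_base=np.full(n, "C", dtype=object),
        coverage=C, seed=seed,
    )
    if config.bias is not None:
        ds = inject_crosslink_bias(ds, config.bias, rng, assign=True)
    if config.high_variance:
        baseline_sds = (np.stack([ds.major, ds.minor]) \
                        .astype(float).std(axis=2, ddof=1)).ravel()
        ds = make_high_variance(ds, baseline_sds, rng)
    return ds


def simulate_study(config: SimConfig) -> list[SimDataset]:
    """Generate ``config.n_experiments`` independent labelled data sets.

    Bit-reproducible from ``config.seed``; each experiment gets its own
    deterministic child seed.
    """
    root = np.random.SeedSequence(config.seed)
    datasets = []
    for child in root.spawn(config.n_experiments):
        seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(seed)
        datasets.append(_simulate_one(config, rng, seed))
    return datasets


def example_bias_table(strength: float = 0.45, width: float = 4.0) -> BiasTable:
    """A synthetic crosslinking-propensity table for simulations.

    Uridine (stored as T) is enriched in a peak centred on the crosslink
    site, q(T, 0) = 0.25 + strength, decaying exponentially with |d|; the
    other three bases share the remainder equally.  Mimics the shape of
    SMInput-derived propensity profiles.
    """
    q = np.full((4, len(OFFSETS)), UNIFORM_Q)
    t_idx = BASES.index("T")
    bump = strength * np.exp(-np.abs(OFFSETS) / width)
    q[t_idx] = UNIFORM_Q + bump
    rest = (1.0 - q[t_idx]) / 3.0
    for i in range(4):
        if i != t_idx:
            q[i] = rest
    return BiasTable(q, n_sites=0)
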