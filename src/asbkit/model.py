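"""The allelic-imbalance test: CV²-LOESS variance moderation and the
empirical Gaussian posterior.

With only k ≈ 2 eCLIP replicates the per-SNV sample variance is useless on
its own, so the expected variance of normalized allelic counts is moderated
globally: for every allele of every SNV the squared coefficient of variation
ω = σ²/μ² is regressed on log₂ μ with LOESS, and the moderated value ω̂(μ)
gives the expected variance σ̂² = ω̂ μ².  The test then asks whether the minor
allele's mean count is plausible under the major allele's posterior mean
distribution: with a flat prior the posterior of the major-allele mean is
N(μ_M, σ̂²_M / k), and the two-sided p-value is

    p = min(1, 2 Φ((μ_m − μ_M) / sqrt(σ̂²_M / k))).

Benjamini–Hochberg FDR < 10% calls significant events.  The estimators follow
the scikit-learn fit/predict idiom so they compose with sklearn tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CV2_FLOOR = 1e-6


@dataclass(frozen=True)
class AlleleSummary:
    """Across-replicate summary of one allele's normalized counts."""

    mu: float
    var: float
    cv2: float
    k: int


def summarize_allele(x, ddof: int = 1) -> AlleleSummary:
    """Mean, variance (unbiased by default) and CV² across replicates."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need counts from at least two replicates")
    if np.any(x < 0):
        raise ValueError("normalized counts must be non-negative")
    mu = float(x.mean())
    var = float(x.var(ddof=ddof))
    cv2 = var / mu**2 if mu > 0 else 0.0
    return AlleleSummary(mu=mu, var=var, cv2=cv2, k=x.size)


class LoessVarianceTrend(BaseEstimator, RegressorMixin):
    """LOESS trend of CV² against log₂ mean normalized count.

    Degree-1 local fits with tricube weights and no robustness iterations
    (the statsmodels defaults), span 0.75.  Predictions interpolate the
    fitted curve, clamp to the boundary fitted values outside the training
    range, and are floored at ``floor`` so expected variances stay positive.

    Parameters
    ----------
    span : fraction of the data used per local fit.
    floor : lower bound on the returned CV².
    min_points : minimum number of training alleles with μ > 0; below this
        ``fit`` raises and suggests pooling experiments or the parametric
        fallback ω̂ = a + b/μ (``ParametricVarianceTrend``).
    delta_frac : statsmodels ``delta`` as a fraction of the x-range
        (linear-interpolation shortcut between close x values; large speedup,
        negligible change at these sample sizes).
    """

    def __init__(self, span: float = 0.75, floor: float = CV2_FLOOR,
                 min_points: int = 30, delta_frac: float = 0.01):
        self.span = span
        self.floor = floor
        self.min_points = min_points
        self.delta_frac = delta_frac

    def fit(self, mu, cv2=None):
        """Fit the trend on per-allele (μ, ω) pairs; μ ≤ 0 points are dropped."""
        mu = np.asarray(mu, dtype=float)
        if cv2 is None and mu.ndim == 2 and mu.shape[1] == 2:
            mu, cv2 = mu[:, 0], mu[:, 1]
        cv2 = np.asarray(cv2, dtype=float)
        keep = mu > 0
        mu, cv2 = mu[keep], cv2[keep]
        if mu.size < self.min_points:
            raise ValueError(
                f"only {mu.size} training alleles with positive mean "
                f"(< {self.min_points}); pool more SNVs/experiments or use "
                "ParametricVarianceTrend"
            )
        x = np.log2(mu)
        delta = self.delta_frac * (x.max() - x.min())
        # it=0: no robustness iterations -- the CV2 response is strongly
        # right-skewed at small k and robust reweighting would bias the trend
        # toward the median CV2 rather than its mean.
        fitted = lowess(cv2, x, frac=self.span, it=0, delta=delta, return_sorted=True)
        gx, gy = fitted[:, 0], fitted[:, 1]
        # collapse duplicate x for interpolation
        gx, idx = np.unique(gx, return_index=True)
        gy = gy[idx]
        self.x_grid_ = gx
        self.y_grid_ = np.maximum(gy, self.floor)
        self.n_training_ = int(mu.size)
        return self

    def predict(self, mu) -> np.ndarray:
        """Moderated CV² ω̂ for mean counts ``mu`` (> 0), clamped and floored."""
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        if np.any(mu <= 0):
            raise ValueError("mean counts must be positive")
        # np.interp clamps to boundary values outside the training range
        return np.interp(np.log2(mu), self.x_grid_, self.y_grid_)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize the fitted grid (log₂ μ vs ω̂) for diagnostics."""
        with open(path, "w") as fh:
            fh.write("log2_mu\tcv2_hat\n")
            for x, y in zip(self.x_grid_, self.y_grid_):
                fh.write(f"{x:.12g}\t{y:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, **params) -> "LoessVarianceTrend":
        df = pd.read_csv(path, sep="\t")
        trend = cls(**params)
        trend.x_grid_ = df["log2_mu"].to_numpy(dtype=float)
        trend.y_grid_ = df["cv2_hat"].to_numpy(dtype=float)
        trend.n_training_ = len(df)
        return trend


class ParametricVarianceTrend(BaseEstimator, RegressorMixin):
    """Fallback mean–CV² model ω̂ = a + b/μ for data too sparse for LOESS.

    ``a`` captures the high-count CV² plateau, ``b/μ`` the Poisson-like
    counting term; fitted by least squares on (1/μ, ω).
    """

    def __init__(self, floor: float = CV2_FLOOR):
        self.floor = floor

    def fit(self, mu, cv2):
        mu = np.asarray(mu, dtype=float)
        cv2 = np.asarray(cv2, dtype=float)
        keep = mu > 0
        mu, cv2 = mu[keep], cv2[keep]
        if mu.size < 2:
            raise ValueError("need at least two alleles with positive mean")
        A = np.column_stack([np.ones_like(mu), 1.0 / mu])
        (self.a_, self.b_), *_ = np.linalg.lstsq(A, cv2, rcond=None)
        return self

    def predict(self, mu) -> np.ndarray:
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        if np.any(mu <= 0):
            raise ValueError("mean counts must be positive")
        return np.maximum(self.a_ + self.b_ / mu, self.floor)


def fit_variance_trend(summaries, span: float = 0.75, **params) -> LoessVarianceTrend:
    """Fit the LOESS trend from AlleleSummary objects (or (μ, ω) pairs)."""
    mus, cv2s = [], []
    for s in summaries:
        if isinstance(s, AlleleSummary):
            mus.append(s.mu)
            cv2s.append(s.cv2)
        else:
            mus.append(s[0])
            cv2s.append(s[1])
    return LoessVarianceTrend(span=span, **params).fit(np.array(mus), np.array(cv2s))


def expected_variance(mu, trend) -> np.ndarray | float:
    """Moderated expected variance σ̂² = ω̂(μ) × μ²."""
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu_arr <= 0):
        raise ValueError("mean count must be positive")
    out = trend.predict(mu_arr) * mu_arr**2
    return float(out[0]) if np.isscalar(mu) or np.ndim(mu) == 0 else out


def asb_test_arrays(x_ref: np.ndarray, x_alt: np.ndarray, trend) -> dict[str, np.ndarray]:
    """Vectorized allelic-imbalance test over many SNVs.

    ``x_ref`` and ``x_alt`` have shape (n_snvs, k).  SNVs where either allele
    has zero mean are untestable (p = NaN).  The major allele is the one with
    the higher mean normalized count; exact ties give p = 1 with the
    reference allele as major (deterministic).
    """
    x_ref = np.asarray(x_ref, dtype=float)
    x_alt = np.asarray(x_alt, dtype=float)
    if x_ref.shape != x_alt.shape or x_ref.ndim != 2 or x_ref.shape[1] < 2:
        raise ValueError("x_ref and x_alt must both be (n_snvs, k) with k >= 2")
    k = x_ref.shape[1]
    mu_ref = x_ref.mean(axis=1)
    mu_alt = x_alt.mean(axis=1)
    testable = (mu_ref > 0) & (mu_alt > 0)

    ref_major = mu_ref >= mu_alt  # tie -> ref is major
    mu_major = np.where(ref_major, mu_ref, mu_alt)
    mu_minor = np.where(ref_major, mu_alt, mu_ref)

    p = np.full(x_ref.shape[0], np.nan)
    var_major = np.full(x_ref.shape[0], np.nan)
    if np.any(testable):
        vm = expected_variance(mu_major[testable], trend)
        var_major[testable] = vm
        z = (mu_minor[testable] - mu_major[testable]) / np.sqrt(vm / k)
        p[testable] = np.minimum(1.0, 2.0 * stats.norm.cdf(z))
    return {
        "pvalue": p,
        "testable": testable,
        "major_is_ref": ref_major,
        "mu_major": mu_major,
        "mu_minor": mu_minor,
        "var_major": var_major,
        "k": k,
    }


def asb_pvalue(x_ref, x_alt, trend) -> tuple[float, str, float, float, float]:
    """Single-SNV allelic-imbalance test.

    Returns (p, major_allele, μ_M, μ_m, σ̂²_M) where major_allele is "ref" or
    "alt".  Raises if either allele is untestable (zero mean).
    """
    res = asb_test_arrays(np.asarray(x_ref, dtype=float)[None, :],
                          np.asarray(x_alt, dtype=float)[None, :], trend)
    if not res["testable"][0]:
        raise ValueError("untestable SNV: an allele has zero mean normalized count")
    major = "ref" if res["major_is_ref"][0] else "alt"
    return (float(res["pvalue"][0]), major, float(res["mu_major"][0]),
            float(res["mu_minor"][0]), float(res["var_major"][0]))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any(ok):
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class ASBRecord:
    """One per-(SNV, RBP) allelic-binding test result."""

    chrom: str
    pos: int  # 0-based internally
    ref: str
    alt: str
    rbp: str
    major_allele: str  # "ref" or "alt"
    mu_major: float
    mu_minor: float
    var_major: float
    k: int
    pvalue: float
    fdr: float
    significant: bool
    filters_failed: str = ""


class EmpiricalGaussianASB(BaseEstimator):
    """Allelic-imbalance detector over an experiment's normalized counts.

    ``fit(x_ref, x_alt)`` takes the (n_snvs, k) normalized allelic count
    matrices of one eCLIP experiment, fits the CV²-LOESS trend on all alleles
    of all SNVs, runs the empirical Gaussian test and BH adjustment, and
    stores per-SNV results in trailing-underscore attributes.

    Parameters
    ----------
    span : LOESS span for the variance trend.
    fdr_threshold : BH FDR below which an SNV is flagged significant (the
        multiple-testing family is the experiment passed to ``fit``).
    ddof : delta degrees of freedom of the across-replicate variance.
    min_trend_points, cv2_floor : passed to the trend.
    """

    def __init__(self, span: float = 0.75, fdr_threshold: float = 0.10,
                 ddof: int = 1, min_trend_points: int = 30,
                 cv2_floor: float = CV2_FLOOR):
        self.span = span
        self.fdr_threshold = fdr_threshold
        self.ddof = ddof
        self.min_trend_points = min_trend_points
        self.cv2_floor = cv2_floor

    def fit(self, x_ref, x_alt):
        x_ref = np.asarray(x_ref, dtype=float)
        x_alt = np.asarray(x_alt, dtype=float)
        if x_ref.shape != x_alt.shape or x_ref.ndim != 2:
            raise ValueError("x_ref and x_alt must both be (n_snvs, k)")
        k = x_ref.shape[1]
        if k < 2:
            raise ValueError("need at least two replicates")

        mus = np.concatenate([x_ref.mean(axis=1), x_alt.mean(axis=1)])
        variances = np.concatenate([x_ref.var(axis=1, ddof=self.ddof),
                                    x_alt.var(axis=1, ddof=self.ddof)])
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(mus > 0, variances / mus**2, 0.0)
        self.trend_ = LoessVarianceTrend(
            span=self.span, floor=self.cv2_floor, min_points=self.min_trend_points
        ).fit(mus, cv2)

        res = asb_test_arrays(x_ref, x_alt, self.trend_)
        self.k_ = k
        self.pvalues_ = res["pvalue"]
        self.testable_ = res["testable"]
        self.major_is_ref_ = res["major_is_ref"]
        self.mu_major_ = res["mu_major"]
        self.mu_minor_ = res["mu_minor"]
        self.var_major_ = res["var_major"]
        self.fdr_ = bh_adjust(self.pvalues_)
        self.significant_ = np.where(
            np.isnan(self.fdr_), False, self.fdr_ < self.fdr_threshold
        ).astype(bool)
        n_sig = int(self.significant_.sum())
        logger.info(
            "allelic-imbalance test: %d SNVs, %d testable, %d significant at FDR < %g",
            x_ref.shape[0], int(self.testable_.sum()), n_sig, self.fdr_threshold,
        )
        return self

    def results_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pvalue": self.pvalues_,
            "fdr": self.fdr_,
            "testable": self.testable_,
            "major_is_ref": self.major_is_ref_,
            "mu_major": self.mu_major_,
            "mu_minor": self.mu_minor_,
            "var_major": self.var_major_,
            "significant": self.significant_,
        })
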