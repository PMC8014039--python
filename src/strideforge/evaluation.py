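"""Error metrics, agreement analysis and report generation.

Per subject: bias (mean error), precision (sample STD of the error), RMSE
and the Pearson correlation between estimate and reference; inter-subject
aggregates are the mean, STD, min and max of the per-subject values.  A
Lilliefors normality test (Kolmogorov-Smirnov against a normal with
estimated parameters, Monte-Carlo null) guards the mean/STD summaries --
non-normal error distributions switch to median/IQR.  Agreement is
summarized Bland-Altman style (mean difference, 1.96-STD limits and the
least-squares trend of difference versus mean), and the empirical CDF of
absolute errors is reported per subject and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "error_metrics",
    "lilliefors_mc",
    "normality_guard",
    "bland_altman",
    "error_cdf",
]


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_intercept: float

    def as_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff, "loa_low": self.loa_low,
            "loa_high": self.loa_high, "trend_slope": self.trend_slope,
            "trend_intercept": self.trend_intercept,
        }


@dataclass
class EvaluationReport:
    """Per-subject and aggregate speed-estimation performance."""

    per_subject: pd.DataFrame  # bias, precision, rmse, pearson_r, normal, n
    aggregates: pd.DataFrame  # mean/std/min/max of each per-subject metric
    pooled: dict  # pooled-over-steps bias/precision/rmse
    bland_altman: BlandAltman | None = None
    cdf: pd.DataFrame | None = None
    excluded_subjects: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Speed estimation report", "  inter-subject aggregates:"]
        for metric in ("bias", "precision", "rmse"):
            row = self.aggregates.loc[metric]
            lines.append(
                f"    {metric:<9s} {row['mean']:+.3f} ± {row['std']:.3f} "
                f"(min {row['min']:+.3f}, max {row['max']:+.3f}) m/s"
            )
        r = self.aggregates.loc["pearson_r"]
        lines.append(f"    pearson r {r['mean']:.3f} ± {r['std']:.3f}")
        if self.bland_altman is not None:
            ba = self.bland_altman
            lines.append(
                f"  Bland-Altman: diff {ba.mean_diff:+.3f} m/s, "
                f"LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}], "
                f"trend y = {ba.trend_slope:.4f}x{ba.trend_intercept:+.3f}"
            )
        return "\n".join(lines)


from functools import lru_cache


@lru_cache(maxsize=16)
def _lilliefors_null(n: int, n_resamples: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic at size n."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_resamples, n))
    mu = draws.mean(axis=1, keepdims=True)
    sd = draws.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((draws - mu) / sd, axis=1)
    grid = stats.norm.cdf(z)
    k = np.arange(1, n + 1)
    return np.maximum(k / n - grid, grid - (k - 1) / n).max(axis=1)


def lilliefors_mc(
    x: np.ndarray, n_resamples: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors statistic and Monte-Carlo p-value.

    KS distance of the sample against a normal with the sample's own mean
    and STD; the null distribution of the statistic is simulated by
    drawing Gaussian samples of the same size and re-estimating (the null
    depends only on the sample size, so it is cached).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    s = x.std(ddof=1)
    if s == 0:
        return np.inf, 0.0
    d_obs = stats.kstest(x, "norm", args=(x.mean(), s)).statistic
    d_null = _lilliefors_null(n, n_resamples, seed)
    p = float((d_null >= d_obs).mean())
    return float(d_obs), p


def normality_guard(
    errors: np.ndarray, alpha: float = 0.05, n_resamples: int = 2000, seed: int = 0
) -> dict:
    """Choose mean/STD or median/IQR summaries based on Lilliefors.

    Requires n >= 20.  Returns the chosen convention and both summaries.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 20:
        raise ValueError("normality guard needs at least 20 samples")
    d, p = lilliefors_mc(errors, n_resamples=n_resamples, seed=seed)
    normal = p > alpha
    q75, q25 = np.percentile(errors, [75, 25])
    return {
        "normal": bool(normal), "statistic": d, "p_value": p,
        "location": float(np.mean(errors) if normal else np.median(errors)),
        "scale": float(errors.std(ddof=1) if normal else q75 - q25),
        "mean": float(errors.mean()), "std": float(errors.std(ddof=1)),
        "median": float(np.median(errors)), "iqr": float(q75 - q25),
    }


def bland_altman(v_est: np.ndarray, v_ref: np.ndarray) -> BlandAltman:
    """Agreement summary: mean difference, 1.96-STD limits, linear trend."""
    v_est = np.asarray(v_est, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    diff = v_est - v_ref
    mean = 0.5 * (v_est + v_ref)
    md = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    if np.ptp(mean) > 0:
        slope, intercept = np.polyfit(mean, diff, 1)
    else:
        slope, intercept = 0.0, md
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd, float(slope),
                       float(intercept))


def error_cdf(
    abs_errors: np.ndarray,
    groups: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Empirical CDF of absolute errors, pooled and per group.

    Returns a frame indexed by threshold with a ``pooled`` column and one
    column per group.  Queryable at arbitrary thresholds.
    """
    abs_errors = np.asarray(abs_errors, dtype=float)
    if np.any(abs_errors < 0):
        raise ValueError("absolute errors must be non-negative")
    if thresholds is None:
        thresholds = np.linspace(0.0, max(abs_errors.max(), 1e-9), 101)
    out = {"pooled": [float((abs_errors <= t).mean()) for t in thresholds]}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            e = abs_errors[groups == g]
            out[str(g)] = [float((e <= t).mean()) for t in thresholds]
    return pd.DataFrame(out, index=pd.Index(thresholds, name="threshold"))


def error_metrics(
    v_est: np.ndarray,
    v_ref: np.ndarray,
    subjects: np.ndarray,
    with_bland_altman: bool = True,
    with_cdf: bool = True,
    normality_seed: int = 0,
    n_resamples: int = 500,
) -> EvaluationReport:
    """Per-subject bias/precision/RMSE/Pearson-r plus aggregates.

    Subjects with fewer than 2 paired samples are excluded (listed in the
    report).  Both the mean of per-subject biases and the pooled
    over-all-steps bias are reported; they differ on unbalanced data.
    """
    v_est = np.asarray(v_est, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    subjects = np.asarray(subjects)
    rows, excluded = [], []
    for s in pd.unique(subjects):
        m = subjects == s
        if m.sum() < 2:
            excluded.append(s)
            continue
        err = v_est[m] - v_ref[m]
        if np.std(v_est[m]) > 0 and np.std(v_ref[m]) > 0:
            r = float(stats.pearsonr(v_est[m], v_ref[m]).statistic)
        else:
            r = np.nan  # undefined for constant series
        normal = True
        if err.size >= 20:
            guard = normality_guard(err, n_resamples=n_resamples, seed=normality_seed)
            normal = guard["normal"]
        rows.append(dict(
            subject=s, n=int(m.sum()), bias=float(err.mean()),
            precision=float(err.std(ddof=1)),
            rmse=float(np.sqrt(np.mean(err**2))), pearson_r=r, normal=normal,
            median_bias=float(np.median(err)),
            iqr_precision=float(np.subtract(*np.percentile(err, [75, 25]))),
        ))
    per_subject = pd.DataFrame(rows).set_index("subject")
    metrics = ["bias", "precision", "rmse", "pearson_r"]
    aggregates = pd.DataFrame({
        "mean": per_subject[metrics].mean(),
        "std": per_subject[metrics].std(ddof=1),
        "min": per_subject[metrics].min(),
        "max": per_subject[metrics].max(),
    })
    err_all = v_est - v_ref
    pooled = {
        "bias": float(err_all.mean()),
        "precision": float(err_all.std(ddof=1)),
        "rmse": float(np.sqrt(np.mean(err_all**2))),
        "n": int(err_all.size),
    }
    ba = bland_altman(v_est, v_ref) if with_bland_altman else None
    cdf = error_cdf(np.abs(err_all), subjects) if with_cdf else None
    return EvaluationReport(per_subject=per_subject, aggregates=aggregates,
                            pooled=pooled, bland_altman=ba, cdf=cdf,
                            excluded_subjects=excluded)
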