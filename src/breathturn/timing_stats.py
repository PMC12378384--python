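"""Statistical characterization of the speech-breathing lag Delta-t.

The cleaned lag distribution is summarized by: MAD-based outlier rejection
(more than k = 3 median absolute deviations from the median), a
Kolmogorov-Smirnov (Lilliefors) test of normality, a skewness test, the mode
of a Gaussian kernel density estimate, and a two-sample comparison between
conditions (human vs robot interlocutor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

log = logging.getLogger(__name__)

#: multiplier that makes the MAD a consistent estimator of a normal sigma
MAD_NORMAL_SCALE = 1.4826


@dataclass
class TTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_student: float
    dof_student: float
    p_student: float
    t_welch: float
    dof_welch: float
    p_welch: float


@dataclass
class DeltaTSummary:
    n_total: int
    n_removed: int
    pct_removed: float
    mean: float
    sd: float
    skewness: float
    skew_p: float
    mode: Optional[float]
    ks_p: Optional[float] = None
    resp_plus_fraction_pct: Optional[float] = None
    group_test: Optional[TTestResult] = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_removed <= 100:
            raise ValueError("pct_removed out of [0, 100]")

    def to_dict(self) -> dict:
        out = {
            "n_total": self.n_total,
            "n_removed": self.n_removed,
            "pct_removed": self.pct_removed,
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness,
            "skew_p": self.skew_p,
            "mode": self.mode,
            "ks_p": self.ks_p,
            "resp_plus_fraction_pct": self.resp_plus_fraction_pct,
        }
        if self.group_test is not None:
            out["group_test"] = vars(self.group_test)
        return out


def remove_outliers_mad(
    deltas: Sequence[float], k: float = 3.0, scale: str = "normal"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass MAD outlier filter.

    Removes every ``x`` with ``|x - median| > k * c * MAD`` where
    ``MAD = median(|x - median|)``.  ``scale='normal'`` uses c = 1.4826 (the
    consistency constant for a normal sigma, matching common outlier
    routines); ``scale='raw'`` uses c = 1.  If the MAD is zero but values
    differ, every value different from the median is removed.
    """
    x = np.asarray(deltas, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if scale not in ("normal", "raw"):
        raise ValueError("scale must be 'normal' or 'raw'")
    c = MAD_NORMAL_SCALE if scale == "normal" else 1.0
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0 and np.any(x != med):
        log.warning("MAD is zero with non-identical values; removing x != median")
        keep = x == med
    else:
        keep = np.abs(x - med) <= k * c * mad
    return x[keep], x[~keep]


def ks_normality(deltas: Sequence[float]) -> float:
    """Lilliefors-corrected KS test of normality (parameters estimated from
    the sample); returns the p-value."""
    x = np.asarray(deltas, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    if np.std(x) == 0.0:
        log.warning("zero-variance sample: degenerate, reporting p = 0")
        return 0.0
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def skewness_test(deltas: Sequence[float]) -> tuple[float, float]:
    """Adjusted Fisher-Pearson sample skewness g1 and a two-sided test of
    zero skewness (D'Agostino)."""
    x = np.asarray(deltas, dtype=float)
    if len(x) < 8:
        raise ValueError("skewness test needs at least 8 values")
    if np.std(x) == 0.0:
        raise ValueError("skewness undefined for a zero-variance sample")
    g1 = float(stats.skew(x, bias=False))
    _, p = stats.skewtest(x)
    return g1, float(p)


def density_mode(deltas: Sequence[float], bandwidth: Optional[float] = None) -> float:
    """Mode of a Gaussian KDE evaluated on a 1 ms grid over the data range.

    ``bandwidth`` is in data units (seconds); by default Silverman's rule is
    used.
    """
    x = np.asarray(deltas, dtype=float)
    if len(x) < 50:
        raise ValueError("density mode needs at least 50 values")
    span = x.max() - x.min()
    if span == 0.0:
        return float(x[0])
    if bandwidth is None:
        kde = stats.gaussian_kde(x, bw_method="silverman")
    else:
        kde = stats.gaussian_kde(x, bw_method=bandwidth / x.std(ddof=1))
    grid = np.arange(x.min(), x.max() + 5e-4, 1e-3)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def compare_conditions(
    deltas_a: Sequence[float], deltas_b: Sequence[float]
) -> TTestResult:
    """Two-sample comparison of mean lags between conditions.

    Reports both the pooled-variance (Student) and unequal-variance (Welch)
    versions, with per-group means and standard deviations.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return TTestResult(
            float(np.mean(a)), 0.0, float(np.mean(b)), 0.0,
            0.0, len(a) + len(b) - 2, 1.0, 0.0, len(a) + len(b) - 2, 1.0,
        )
    t_s, p_s = stats.ttest_ind(a, b, equal_var=True)
    t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
    dof_s = len(a) + len(b) - 2
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    dof_w = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return TTestResult(
        mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)),
        t_student=float(t_s), dof_student=float(dof_s), p_student=float(p_s),
        t_welch=float(t_w), dof_welch=float(dof_w), p_welch=float(p_w),
    )


def cumulative_density(values: Sequence[float]) -> pd.DataFrame:
    """Empirical cumulative density table, monotone from >0 to 1."""
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValueError("empty sample")
    cdf = np.arange(1, len(x) + 1) / len(x)
    return pd.DataFrame({"delta_t": x, "cumulative_density": cdf})


def summarize(
    deltas: Sequence[float],
    mad_k: float = 3.0,
    mad_scale: str = "normal",
    bandwidth: Optional[float] = None,
    n_peaks: Optional[int] = None,
    n_resp_plus: Optional[int] = None,
    deltas_by_condition: Optional[dict[str, Sequence[float]]] = None,
) -> tuple[DeltaTSummary, pd.DataFrame]:
    """Full descriptive summary of a Delta-t sample.

    Outlier rejection is applied first (following the analysis order); the
    KS, skewness, and density-mode statistics are computed on the cleaned
    values.  When peak counts are given, the Resp+ fraction
    ``100 * n_resp_plus / n_peaks`` is reported.  When per-condition samples
    are given, the two-sample comparison is included.  Returns the summary
    and the cumulative-density table of the cleaned values.
    """
    x = np.asarray(deltas, dtype=float)
    kept, removed = remove_outliers_mad(x, k=mad_k, scale=mad_scale)
    pct_removed = 100.0 * len(removed) / len(x)
    g1, skew_p = skewness_test(kept)
    summary = DeltaTSummary(
        n_total=len(x),
        n_removed=len(removed),
        pct_removed=pct_removed,
        mean=float(np.mean(kept)),
        sd=float(np.std(kept, ddof=1)),
        skewness=g1,
        skew_p=skew_p,
        mode=density_mode(kept, bandwidth=bandwidth) if len(kept) >= 50 else None,
        ks_p=ks_normality(kept) if len(kept) >= 5 else None,
    )
    if n_peaks is not None and n_resp_plus is not None:
        if n_peaks <= 0:
            raise ValueError("n_peaks must be positive")
        summary.resp_plus_fraction_pct = 100.0 * n_resp_plus / n_peaks
    if deltas_by_condition is not None and len(deltas_by_condition) == 2:
        # group comparison on the cleaned sample: apply the global MAD cutoff
        c = MAD_NORMAL_SCALE if mad_scale == "normal" else 1.0
        med = np.median(x)
        cutoff = mad_k * c * np.median(np.abs(x - med))
        (ka, va), (kb, vb) = sorted(deltas_by_condition.items())
        va = np.asarray(va, dtype=float)
        vb = np.asarray(vb, dtype=float)
        va = va[np.abs(va - med) <= cutoff]
        vb = vb[np.abs(vb - med) <= cutoff]
        if len(va) >= 2 and len(vb) >= 2:
            summary.group_test = compare_conditions(va, vb)
    return summary, cumulative_density(kept)
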