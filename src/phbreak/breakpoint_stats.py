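"""Distribution statistics for breakpoint coordinates.

Three screens used for breakpoint-cluster-region analyses:

* uniformity within a region — Pearson chi-squared against the equal-bin
  uniform expectation,
* two-sample comparison between cohorts (e.g. CML vs ALL breakpoints in the
  same region) — Kolmogorov-Smirnov, which is binning-free,
* single-covariate screening — logistic regression of a binary patient
  class on the min-max-normalized breakpoint position, tested by the
  likelihood-ratio test against the intercept-only model.

Auto-binning for the chi-squared test picks the largest equal-width bin
count keeping every expected count >= 5, capped at 100 bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "DistTestResult",
    "uniformity_test",
    "ks_compare",
    "covariate_logit",
    "density_profile",
]


@dataclass
class DistTestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _check_in_region(positions: np.ndarray, region) -> None:
    if len(positions) and (positions.min() < region.start or positions.max() >= region.end):
        raise ValueError(
            f"positions outside region {region.name} "
            f"[{region.start}, {region.end})"
        )


def uniformity_test(positions, region, bin_width="auto") -> DistTestResult:
    """Chi-squared test of positional uniformity within a region.

    ``bin_width="auto"`` chooses the largest number of equal-width bins with
    expected count >= 5 (capped at 100); an explicit ``bin_width`` in bases
    is honoured if every bin keeps expected count >= 1, otherwise the call
    refuses with guidance.  df = bins - 1.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 20:
        raise ValueError(f"uniformity test needs n >= 20 positions, got {n}")
    _check_in_region(positions, region)
    if bin_width == "auto":
        n_bins = int(min(100, n // 5))
    else:
        n_bins = int(np.ceil(len(region) / float(bin_width)))
        if n / n_bins < 1.0:
            raise ValueError(
                f"bin width {bin_width} gives {n_bins} bins with expected "
                f"count {n / n_bins:.2f} < 1; widen the bins (expected >= 5 "
                "is the conventional floor) or use bin_width='auto'"
            )
    edges = np.linspace(region.start, region.end, n_bins + 1)
    counts, _ = np.histogram(positions, bins=edges)
    statistic, p = stats.chisquare(counts)
    return DistTestResult(
        "chisq_uniformity",
        float(statistic),
        float(p),
        (n,),
        {"n_bins": n_bins, "df": n_bins - 1, "expected_per_bin": n / n_bins},
    )


def ks_compare(groupA, groupB, method: str = "asymp") -> DistTestResult:
    """Two-sample Kolmogorov-Smirnov comparison of coordinate samples.

    Default p-value is asymptotic (standard practice for cohort-scale
    samples); ``method="exact"`` is available and ``method="auto"`` switches
    to the exact computation when nA*nB <= 10,000.  Ties are allowed.
    A group below 5 observations triggers a reliability warning.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(a), len(b)) < 5:
        warnings.warn(
            "a group has fewer than 5 observations; the asymptotic KS "
            "p-value is unreliable",
            UserWarning,
            stacklevel=2,
        )
    if method == "auto":
        method = "exact" if len(a) * len(b) <= 10_000 else "asymp"
    if method not in ("asymp", "exact"):
        raise ValueError("method must be 'asymp', 'exact' or 'auto'")
    res = stats.ks_2samp(a, b, method=method)
    return DistTestResult(
        "ks_two_sample",
        float(res.statistic),
        float(res.pvalue),
        (len(a), len(b)),
        {"method": method, "effective_n": len(a) * len(b) / (len(a) + len(b))},
    )


def covariate_logit(positions, region, covariate) -> DistTestResult:
    """Screen one binary covariate against breakpoint position.

    Logistic model: covariate class ~ intercept + normalized position
    (min-max over the region).  The p-value is the likelihood-ratio test
    against the intercept-only model (equivalent, for a single-predictor
    logit, to testing whether position influences the class distribution).
    Complete separation is reported via ``params["separation"]`` with the
    LRT statistic taken at the saturated bound.
    """
    positions = np.asarray(positions, dtype=float)
    _check_in_region(positions, region)
    y = np.asarray(covariate)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"covariate must be binary, got classes {classes!r}")
    if len(positions) < 30:
        raise ValueError("covariate screen needs n >= 30")
    if len(positions) != len(y):
        raise ValueError("positions and covariate must have equal length")
    ybin = (y == classes[1]).astype(float)
    x = (positions - region.start) / (region.end - region.start)
    X = sm.add_constant(x)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(ybin, X).fit(disp=0, maxiter=200)
            llf, llnull = fit.llf, fit.llnull
            coef = float(fit.params[1])
            if not np.isfinite(coef) or abs(coef) > 1e3:
                separation = True
        except Exception:  # PerfectSeparation or convergence failure
            separation = True
            coef = np.inf
            llnull = sm.Logit(ybin, np.ones((len(ybin), 1))).fit(disp=0).llf
            llf = 0.0  # saturated bound under complete separation
    lrt = max(0.0, 2.0 * (llf - llnull))
    p = float(stats.chi2.sf(lrt, df=1))
    return DistTestResult(
        "logit_covariate",
        float(lrt),
        p,
        (int(ybin.sum()), int(len(ybin) - ybin.sum())),
        {"coef_position": coef, "separation": separation, "df": 1},
    )


def density_profile(positions, region, bin_width: int) -> pd.DataFrame:
    """Binned breakpoint counts tiling the region exactly.

    Returns a DataFrame with 0-based half-open ``bin_start``/``bin_end``
    columns and a ``count`` column summing to n; the final bin is shortened
    when the region length is not a multiple of ``bin_width``.
    """
    positions = np.asarray(positions, dtype=float)
    _check_in_region(positions, region)
    edges = np.arange(region.start, region.end, bin_width, dtype=float)
    edges = np.append(edges, region.end)
    counts, _ = np.histogram(positions, bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "bin_end": edges[1:].astype(int),
            "count": counts,
        }
    )
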