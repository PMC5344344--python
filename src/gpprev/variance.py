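"""Cluster-design variance for weighted prevalence estimates.

The sample has a single-stage cluster design: each GP contributes a cluster
of ~30 consecutive patients. All estimates are ratios R = Y/X of weighted
totals (numerator C*F*G * indicator over denominator C*F), so the primary
variance method is the Taylor-linearised ratio estimator over cluster
totals, with a t reference distribution on (#clusters - 1) degrees of
freedom — the standard survey-procedure treatment of such designs. A
cluster (GP-resampling) bootstrap is provided as a cross-check.

G and the population shares D are treated as known constants (they come
from administrative sources, not the sample) and contribute no variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class VarianceError(ValueError):
    pass


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence point estimate with its cluster-design 95% CI."""

    target: str
    method: str  # encounter | population_old | population_new
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.estimate <= self.ci_high <= 1):
            raise VarianceError(
                f"{self.target}/{self.method}: CI ordering violated: "
                f"[{self.ci_low}, {self.estimate}, {self.ci_high}]"
            )

    def as_row(self) -> dict:
        return {
            "target": self.target,
            "method": self.method,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "n_clusters": self.n_clusters,
        }


def _cluster_totals(num, den, clusters):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    codes, _ = pd.factorize(np.asarray(clusters))
    g = codes.max() + 1
    y = np.bincount(codes, weights=num, minlength=g)
    x = np.bincount(codes, weights=den, minlength=g)
    return y, x


def cluster_ratio_ci(num, den, clusters, level: float = 0.95):
    """Ratio estimate sum(num)/sum(den) with linearised cluster variance.

    ``num`` is typically weight * indicator and ``den`` the weight; with
    unit weights this reduces to a cluster-robust CI for a proportion.
    Returns ``(estimate, ci_low, ci_high, n_clusters)``; the CI is truncated
    to [0, 1].

    Linearisation: with cluster totals y_g, x_g, X = sum x_g and
    R = Y/X, the residuals e_g = (y_g - R x_g)/X sum to zero and
    var(R) = G/(G-1) * sum e_g^2 (with-replacement first-stage
    approximation). The CI uses t on G-1 degrees of freedom.
    """
    y, x = _cluster_totals(num, den, clusters)
    g = len(y)
    if g < 2:
        raise VarianceError("cluster variance needs at least 2 clusters")
    X = x.sum()
    if X <= 0:
        raise VarianceError("zero denominator total")
    r = y.sum() / X
    e = (y - r * x) / X
    var = g / (g - 1) * np.sum(e**2)
    t = stats.t.ppf(0.5 + level / 2, df=g - 1)
    half = t * np.sqrt(var)
    lo = min(max(r - half, 0.0), r)
    hi = max(min(r + half, 1.0), r)
    return float(r), float(lo), float(hi), g


def cluster_bootstrap_ci(
    num, den, clusters, reps: int = 2000, seed: int = 0, level: float = 0.95
):
    """Percentile CI from resampling whole clusters (GPs) with replacement."""
    y, x = _cluster_totals(num, den, clusters)
    g = len(y)
    if g < 2:
        raise VarianceError("cluster bootstrap needs at least 2 clusters")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, g, size=(reps, g))
    ys = y[idx].sum(axis=1)
    xs = x[idx].sum(axis=1)
    ok = xs > 0
    r = ys[ok] / xs[ok]
    alpha = 1 - level
    lo, hi = np.quantile(r, [alpha / 2, 1 - alpha / 2])
    est = y.sum() / x.sum()
    return float(est), float(max(min(lo, est), 0.0)), float(min(max(hi, est), 1.0)), g


def significant_difference(e1: PrevalenceEstimate, e2: PrevalenceEstimate) -> bool:
    """True iff the two 95% CIs do not overlap (a conservative test)."""
    return e1.ci_high < e2.ci_low or e2.ci_high < e1.ci_low
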