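"""Group-level nonparametric and estimation statistics.

Repeated-measures contrasts use the Wilcoxon signed-rank test with an exact
sign-flip permutation distribution at small n (all 2^n sign assignments,
computed by generating-function convolution so mid-ranked ties are handled),
a normal approximation above. Effect sizes are reported as the mean paired
difference with a bias-corrected and accelerated (BCa) bootstrap confidence
interval. All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "EffectSize",
    "wilcoxon_exact",
    "bca_mean_diff",
    "weighted_linfit",
    "mann_whitney",
    "friedman",
]

EXACT_N_MAX = 25


@dataclass
class PairedSample:
    a: np.ndarray
    b: np.ndarray
    units: list[str] | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired samples must be equal-length vectors")
        if np.any(np.isnan(self.a)) or np.any(np.isnan(self.b)):
            raise ValueError("missing pairs are not allowed")

    def diff(self) -> np.ndarray:
        return self.b - self.a


@dataclass
class WilcoxonResult:
    p: float
    w_plus: float
    n_used: int  # pairs after dropping zero differences
    method: str  # "exact" or "normal"
    degenerate: bool = False  # all differences were zero


@dataclass
class EffectSize:
    mean_difference: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int | None


def _as_paired(paired, b=None) -> PairedSample:
    if isinstance(paired, PairedSample):
        return paired
    return PairedSample(np.asarray(paired), np.asarray(b))


def wilcoxon_exact(paired, b=None) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped before ranking; ties receive mid-ranks.
    For n <= 25 the p value is exact over all 2^n sign assignments; larger
    samples use the tie-corrected normal approximation.
    """
    d = _as_paired(paired, b).diff()
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(p=1.0, w_plus=0.0, n_used=0, method="exact", degenerate=True)
    if n < 2:
        return WilcoxonResult(p=1.0, w_plus=float(d[0] > 0), n_used=n,
                              method="exact", degenerate=False)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        # distribution of 2*W+ over all sign flips; doubled ranks are integers
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        dist /= 2.0**n
        w2 = int(np.rint(2 * w_plus))
        p_low = dist[: w2 + 1].sum()
        p_high = dist[w2:].sum()
        p = min(1.0, 2 * min(p_low, p_high))
        return WilcoxonResult(p=float(p), w_plus=w_plus, n_used=n, method="exact")
    mean = n * (n + 1) / 4
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (counts**3 - counts).sum() / 48
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return WilcoxonResult(p=p, w_plus=w_plus, n_used=n, method="normal")


def bca_mean_diff(paired, b=None, n_resamples: int = 5000,
                  seed: int | None = None) -> EffectSize:
    """Mean paired difference with a BCa 95% bootstrap confidence interval."""
    d = _as_paired(paired, b).diff()
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    mean = float(d.mean())
    if np.ptp(d) == 0:
        return EffectSize(mean, mean, mean, n_resamples, seed)
    res = sps.bootstrap(
        (d,), np.mean, n_resamples=n_resamples, confidence_level=0.95,
        method="BCa", random_state=np.random.default_rng(seed), vectorized=True,
        axis=-1,
    )
    return EffectSize(mean, float(res.confidence_interval.low),
                      float(res.confidence_interval.high), n_resamples, seed)


def weighted_linfit(x, y, weights=None):
    """Weighted least-squares line fit.

    Returns ``(slope, intercept, r_squared, p_slope)``; *weights* follow the
    WLS convention (inverse-variance, e.g. 1/SEM^2 when fitting averages
    with error bars). Uniform or absent weights reduce to OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x values are collinear")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return (
        float(model.params[1]),
        float(model.params[0]),
        float(model.rsquared),
        float(model.pvalues[1]),
    )


def mann_whitney(u1, u2) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test (exact where scipy can, else asymptotic)."""
    u1, u2 = np.asarray(u1, dtype=float), np.asarray(u2, dtype=float)
    if u1.size < 1 or u2.size < 1:
        raise ValueError("both groups must be nonempty")
    res = sps.mannwhitneyu(u1, u2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def friedman(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman test on a blocks x treatments matrix."""
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2 or blocks.shape[1] < 3:
        raise ValueError("need a blocks x treatments matrix with >= 3 treatments")
    if np.all(blocks == blocks[:, :1]):
        return 0.0, 1.0  # identical treatments: no effect by construction
    res = sps.friedmanchisquare(*(blocks[:, j] for j in range(blocks.shape[1])))
    return float(res.statistic), float(res.pvalue)
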