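"""Statistics over detected convergent-promoter structures.

Spearman correlation with two-tailed significance (exact permutation null
for n <= 10, t-approximation otherwise), OLS fits with a 95% confidence
band for the mean response, sign-discordance of log2FC pairs, Wilcoxon
rank-sum group comparison, Benjamini-Hochberg adjustment, the Tau
tissue-specificity index, and scale-adjusted metaprofiles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval, per_base_signal


@dataclass
class CorrelationReport:
    n: int
    rho: float
    p_two_sided: float
    slope: float | None = None
    intercept: float | None = None
    group: str | None = None


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with two-sided p value.

    For n <= 10 the p value is an exact permutation probability over all
    n! rank assignments; for larger n the usual t-approximation with
    n - 2 degrees of freedom is used.  A constant input leaves rho
    undefined: (nan, nan) is returned with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("spearman requires finite values")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant input: Spearman rho undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 10:
        # exact permutation null: rho is monotone in sum(rx * perm(ry))
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        s_all = ry[perms] @ rx  # (n!,) inner products of rx with permuted ry
        mu = rx.mean() * ry.mean() * n
        denom = n * sx * sy
        rho_all = (s_all - mu) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return rho, p

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class LinearFit:
    slope: float
    intercept: float
    _results: object

    def band(self, x_new) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Mean response and pointwise 95% confidence band at x_new."""
        x_new = np.asarray(x_new, dtype=np.float64)
        design = sm.add_constant(x_new, has_constant="add")
        pred = self._results.get_prediction(design)
        frame = pred.summary_frame(alpha=0.05)
        return (
            frame["mean"].to_numpy(),
            frame["mean_ci_lower"].to_numpy(),
            frame["mean_ci_upper"].to_numpy(),
        )


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y ~ x with a 95% CI band for the mean."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("linear_fit requires equal-length inputs, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    design = sm.add_constant(x)
    results = sm.OLS(y, design).fit()
    intercept, slope = results.params
    return LinearFit(float(slope), float(intercept), results)


def sign_discordance(log2fc_a, log2fc_b) -> float:
    """Fraction of pairs with opposite-signed log2FCs (zeros concordant)."""
    a = np.asarray(log2fc_a, dtype=np.float64)
    b = np.asarray(log2fc_b, dtype=np.float64)
    if a.size == 0 or a.size != b.size:
        raise ValueError("sign_discordance requires equal-length non-empty inputs")
    return float(np.mean(a * b < 0))


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns (U of the first group, two-sided p) using the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_groups requires non-empty groups")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tau_index(expression) -> float:
    """Tau tissue-specificity index of a per-tissue expression vector.

    tau = sum_i (1 - x_i / x_max) / (n - 1); 0 for uniform expression,
    1 for expression confined to a single tissue.
    """
    x = np.asarray(expression, dtype=np.float64)
    if x.size < 2:
        raise ValueError("tau_index requires at least 2 tissues")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("expression must be finite and non-negative")
    x_max = x.max()
    if x_max == 0:
        raise ValueError("tau undefined for an all-zero expression vector")
    return float(np.sum(1.0 - x / x_max) / (x.size - 1))


def _region_profile(track, region: GenomicInterval, n_bins: int) -> np.ndarray:
    """Mean per-base signal in n_bins equal fractions of one region,
    oriented 5' -> 3' (− strand regions are reversed)."""
    signal = per_base_signal(
        track, region.chrom, region.strand, region.start, region.end
    )
    length = signal.size
    # fractional binning via the cumulative integral, exact for any
    # length-to-bin ratio (regions shorter than n_bins included)
    cum = np.concatenate([[0.0], np.cumsum(signal)])
    edges = np.linspace(0.0, float(length), n_bins + 1)
    integral = np.interp(edges, np.arange(length + 1, dtype=np.float64), cum)
    widths = np.diff(edges)
    means = np.diff(integral) / widths
    if region.strand == "-":
        means = means[::-1]
    return means


def metaprofile(regions: list[GenomicInterval], track, n_bins: int,
                mode: str = "scaled", flank: int = 500) -> np.ndarray:
    """Average signal profile over regions.

    ``scaled``: each region is rescaled to ``n_bins`` equal fractions so
    that anchors align across loci regardless of length; bin 1 is always
    the 5' anchor (− strand regions are reversed).  ``anchored``: a fixed
    ±``flank`` window around each region's 5' anchor, binned into
    ``n_bins`` equal-width bins.
    """
    if not regions:
        raise ValueError("metaprofile requires at least one region")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if mode == "scaled":
        profiles = [_region_profile(track, r, n_bins) for r in regions]
    elif mode == "anchored":
        profiles = []
        for r in regions:
            anchor = r.start if r.strand == "+" else r.end - 1
            window = GenomicInterval(
                r.chrom, max(anchor - flank, 0), anchor + flank + 1, r.strand
            )
            profiles.append(_region_profile(track, window, n_bins))
    else:
        raise ValueError("mode must be 'scaled' or 'anchored'")
    return np.mean(np.vstack(profiles), axis=0)
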