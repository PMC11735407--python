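"""Peak-level quantification, normalization and log2 fold changes.

Counting is strand-aware end-tag summation within feature intervals.
Normalization uses median-of-ratios size factors; condition effects are
summarized as pseudocounted log2 fold changes of normalized condition
means, together with the base mean (mean normalized count over all
samples).  No per-feature dispersion model or test statistic is fitted:
the downstream co-regulation analyses consume the log2FC values only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval, StrandedEndTrack


@dataclass
class SampleInfo:
    sample_id: str
    condition: str
    replicate: int = 1


@dataclass
class CountMatrix:
    """Feature-by-sample end-tag counts with size factors."""

    feature_ids: list[str]
    features: list[GenomicInterval]
    samples: list[SampleInfo]
    counts: np.ndarray  # shape (n_features, n_samples), non-negative ints
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("counts shape does not match features x samples")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def normalized(self) -> np.ndarray:
        sf = self.size_factors
        if sf is None:
            sf = size_factors(self)
            self.size_factors = sf
        return self.counts / sf[np.newaxis, :]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([s.condition == condition for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.feature_ids, name="feature_id"),
            columns=[s.sample_id for s in self.samples],
        )
        return df.reset_index()


def count_in_features(track: StrandedEndTrack,
                      features: list[GenomicInterval]) -> np.ndarray:
    """End-tags of one sample falling within each stranded feature.

    Features overlapping on the same strand are each counted independently
    (tags in the overlap contribute to both; no double-count correction).
    """
    return np.array(
        [track.count_in(f.chrom, f.strand, f.start, f.end) for f in features],
        dtype=np.int64,
    )


def build_count_matrix(tracks: list[StrandedEndTrack],
                       sample_info: list[SampleInfo],
                       feature_ids: list[str],
                       features: list[GenomicInterval]) -> CountMatrix:
    if len(tracks) != len(sample_info):
        raise ValueError("one SampleInfo per track required")
    counts = np.column_stack(
        [count_in_features(t, features) for t in tracks]
    ) if tracks else np.zeros((len(features), 0), dtype=np.int64)
    cm = CountMatrix(list(feature_ids), list(features), list(sample_info), counts)
    cm.size_factors = size_factors(cm)
    return cm


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For each feature row with all-positive counts, the per-sample ratio to
    the row's geometric mean is formed; a sample's factor is the median of
    its ratios.  Without any all-positive row the estimator is undefined
    and total-count scaling (normalized to geometric mean 1) is used, with
    a warning.
    """
    counts = cm.counts.astype(np.float64)
    n_features, n_samples = counts.shape
    if n_samples == 1:
        return np.ones(1)
    positive = np.all(counts > 0, axis=1)
    if not np.any(positive):
        warnings.warn(
            "no feature detected in every sample; "
            "falling back to total-count size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            return np.ones(n_samples)
        log_totals = np.log(totals)
        return np.exp(log_totals - log_totals.mean())
    sub = counts[positive]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geomean)[:, np.newaxis]
    return np.median(ratios, axis=0)


def log2fc(cm: CountMatrix, treated: str, control: str,
           pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-feature base mean and log2 fold change (treated vs control).

    log2FC = log2((mean_norm_treated + eps) / (mean_norm_control + eps));
    base_mean = mean normalized count over all samples.  The pseudocount
    keeps every log2FC finite.
    """
    mask_t = cm.condition_mask(treated)
    mask_c = cm.condition_mask(control)
    if not mask_t.any():
        raise ValueError(f"no samples with condition {treated!r}")
    if not mask_c.any():
        raise ValueError(f"no samples with condition {control!r}")
    norm = cm.normalized
    mean_t = norm[:, mask_t].mean(axis=1)
    mean_c = norm[:, mask_c].mean(axis=1)
    lfc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    return pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
        }
    )


def tertiles(values) -> np.ndarray:
    """Equal-count low/medium/high groups by rank; ties go to the lower group.

    A value's group is decided by the number of values strictly smaller
    than it, so tied values always share the lowest applicable group (all
    equal values -> all 'low').
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 3:
        raise ValueError("tertiles require at least 3 values")
    if np.any(~np.isfinite(values)):
        raise ValueError("tertiles require finite values")
    sorted_vals = np.sort(values)
    min_rank = np.searchsorted(sorted_vals, values, side="left")
    labels = np.where(
        min_rank < n / 3, "low", np.where(min_rank < 2 * n / 3, "medium", "high")
    )
    return labels
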