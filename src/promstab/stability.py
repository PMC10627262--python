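"""Expression-stability statistics from tissue-atlas count matrices.

A gene's expression stability across a tissue atlas is summarized by the
coefficient of variation (CV) of its normalized counts: low CV means
uniform (constitutive-like) expression, high CV means conditional or
tissue-specific expression.  Counts are normalized with the
median-of-ratios size-factor estimator, CVs and geometric means are
converted to percentile ranks so they can be compared across species,
and very weakly expressed transcripts (mean raw count below a read
threshold) are flagged and excluded from ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SizeFactorError",
    "size_factors",
    "normalize",
    "cv",
    "percentile_rank",
    "geometric_mean",
    "low_expression_filter",
    "stability_table",
    "read_counts",
    "read_metadata",
    "read_stability",
    "write_stability",
]

STABILITY_COLUMNS = [
    "cv",
    "cv_percentile",
    "geo_mean",
    "geo_mean_percentile",
    "mean_raw",
    "passes_filter",
]


class SizeFactorError(ValueError):
    """No usable reference transcripts for median-of-ratios estimation."""


def _validate_counts(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not counts.index.is_unique or not counts.columns.is_unique:
        raise ValueError("transcript and sample ids must be unique")
    return x


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference transcripts are those with strictly positive counts in every
    sample.  For sample ``s``, the factor is the median over reference
    transcripts of ``count(g, s) / geomean_samples(count(g, .))``.  The
    factor vector is rescaled to geometric mean 1 (the raw estimator is
    only defined up to a common scalar), which makes normalization a
    fixed point: re-estimating on normalized counts gives all 1.0.
    """
    x = _validate_counts(counts)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise SizeFactorError(
            "no transcript has strictly positive counts in every sample; "
            "median-of-ratios size factors cannot be estimated"
        )
    logx = np.log(x[ref])
    log_geo = logx.mean(axis=1)
    log_factors = np.median(logx - log_geo[:, None], axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | np.ndarray) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.shape[1],):
        raise ValueError(
            f"expected {counts.shape[1]} size factors, got shape {factors.shape}"
        )
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return counts / factors


def cv(values) -> float:
    """Sample coefficient of variation: sd (n-1 denominator) over mean.

    Returns NaN when fewer than 2 values are present or the mean is 0,
    in which case the transcript is excluded from percentile ranking.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def percentile_rank(values) -> pd.Series | np.ndarray:
    """Fraction of values less than or equal to each value, in (0, 1].

    NaN inputs are excluded from the ranking and map to NaN.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n:
        # rankdata(method="max") counts values <= v, including ties
        out[ok] = rankdata(v[ok], method="max") / n
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name="percentile")
    return out


def geometric_mean(values) -> float:
    """n-th root of the product; exactly 0 when any value is 0."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("geometric mean requires non-negative values")
    if v.size == 0:
        return float("nan")
    if (v == 0).any():
        return 0.0
    return float(np.exp(np.log(v).mean()))


def low_expression_filter(raw: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Keep transcripts whose mean RAW count across samples is >= threshold."""
    return raw.mean(axis=1) >= threshold


def stability_table(
    raw: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    min_mean_reads: float = 1.0,
) -> pd.DataFrame:
    """Full per-transcript stability summary from a raw count matrix.

    Normalizes by median-of-ratios size factors, computes CV and geometric
    mean of the normalized counts, applies the mean-raw-read filter, and
    percentile-ranks CV and geometric mean over the transcripts that pass
    the filter (and have a defined CV).  Filtered-out transcripts keep
    their statistics but get NaN percentiles, so their CV distribution can
    still be compared with the kept set.
    """
    _validate_counts(raw)
    if metadata is not None:
        missing = set(raw.columns) - set(metadata.index)
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)}")
    factors = size_factors(raw)
    norm = normalize(raw, factors)
    x = norm.to_numpy(dtype=float)

    tab = pd.DataFrame(index=raw.index.copy())
    tab.index.name = "transcript"
    tab["cv"] = [cv(row) for row in x]
    tab["geo_mean"] = [geometric_mean(row) for row in x]
    tab["mean_raw"] = raw.mean(axis=1)
    tab["passes_filter"] = low_expression_filter(raw, threshold=min_mean_reads)

    rankable = tab["passes_filter"] & tab["cv"].notna()
    tab["cv_percentile"] = np.nan
    tab["geo_mean_percentile"] = np.nan
    tab.loc[rankable, "cv_percentile"] = percentile_rank(tab.loc[rankable, "cv"])
    tab.loc[rankable, "geo_mean_percentile"] = percentile_rank(
        tab.loc[rankable, "geo_mean"]
    )
    return tab[STABILITY_COLUMNS]


# -- TSV round-trip -----------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a transcripts x samples TSV count matrix (first column = id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "transcript"
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata TSV (sample, tissue, stage)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_stability(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t")


def read_stability(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    tab["passes_filter"] = tab["passes_filter"].astype(bool)
    return tab
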