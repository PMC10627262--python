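"""Summary tables: CV distributions by promoter class, ortholog recovery
rates with ANOVA/Tukey, and percentile tertile binning.

All outputs are numeric tables rather than figures so downstream checks
can assert on the numbers directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ClassDistribution",
    "subsample_transcripts",
    "cv_distribution_by_class",
    "class_distribution_table",
    "ortholog_recovery",
    "anova_tukey",
    "tertile_bins",
    "tertile_summary",
]


@dataclass
class ClassDistribution:
    """Normalized histogram of CV percentiles for one promoter class."""

    promoter_class: str
    bin_edges: np.ndarray  # on [0, 1]
    densities: np.ndarray  # integrate to 1 for nonempty classes
    n: int
    mean_percentile: float


def subsample_transcripts(ids, fraction: float = 0.4, seed: int = 0) -> list[str]:
    """Uniform sample without replacement of round(fraction * n) ids."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = sorted(ids)
    k = round(fraction * len(ids))
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(ids, size=k, replace=False))


def cv_distribution_by_class(
    labels: pd.DataFrame, stab: pd.DataFrame, bins: int = 20
) -> dict[str, ClassDistribution]:
    """Per-class normalized histogram of CV percentile ranks.

    Joins scan labels with the stability table on transcript id and keeps
    only transcripts that pass the read filter and are scannable.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    merged = labels.merge(
        stab.reset_index(), left_on="transcript", right_on="transcript", how="inner"
    )
    merged = merged[
        merged["passes_filter"] & merged["scannable"] & merged["cv_percentile"].notna()
    ]
    out: dict[str, ClassDistribution] = {}
    for cls, sub in merged.groupby("class", sort=True):
        vals = sub["cv_percentile"].to_numpy()
        if len(vals):
            dens, _ = np.histogram(vals, bins=edges, density=True)
            mean = float(vals.mean())
        else:
            dens, mean = np.zeros(bins), float("nan")
        out[cls] = ClassDistribution(cls, edges, dens, len(vals), mean)
    return out


def class_distribution_table(dists: dict[str, ClassDistribution]) -> pd.DataFrame:
    rows = []
    for cls in sorted(dists):
        d = dists[cls]
        for i in range(len(d.densities)):
            rows.append(
                {
                    "class": cls,
                    "bin_left": round(float(d.bin_edges[i]), 6),
                    "bin_right": round(float(d.bin_edges[i + 1]), 6),
                    "density": round(float(d.densities[i]), 6),
                    "n": d.n,
                    "mean_cv_percentile": round(d.mean_percentile, 6),
                }
            )
    return pd.DataFrame(rows)


def ortholog_recovery(
    query_sets: dict[str, list[str]],
    table: pd.DataFrame,
    species: list[str],
) -> pd.DataFrame:
    """Fraction of each query set with >=1 ortholog row per target species."""
    found = {
        sp: set(sub["query_transcript"]) for sp, sub in table.groupby("species")
    }
    rows = []
    for name in sorted(query_sets):
        ids = query_sets[name]
        for sp in species:
            hits = sum(1 for q in ids if q in found.get(sp, set()))
            rows.append(
                {
                    "species": sp,
                    "gene_set": name,
                    "n_queries": len(ids),
                    "rate": hits / len(ids) if ids else 0.0,
                }
            )
    return pd.DataFrame(rows)


def anova_tukey(rates: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across gene sets (species as observations) + Tukey HSD.

    ``rates`` needs columns ``gene_set`` and ``rate``.  Returns the F
    statistic, its p-value and a tidy Tukey HSD table.
    """
    counts = rates.groupby("gene_set")["rate"].count()
    if len(counts) < 2:
        raise ValueError("ANOVA needs at least 2 gene-set groups")
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"gene set(s) with <2 observations: {sorted(bad.index)}")
    model = ols("rate ~ C(gene_set)", data=rates).fit()
    table = sm.stats.anova_lm(model, typ=1)
    f_stat = float(table["F"].iloc[0])
    p_value = float(table["PR(>F)"].iloc[0])
    tukey = pairwise_tukeyhsd(rates["rate"], rates["gene_set"])
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return f_stat, p_value, tukey_df


def tertile_bins(percentile: float) -> str:
    """low for [0, 0.33], mid for (0.33, 0.66], high for (0.66, 1.00]."""
    if pd.isna(percentile) or not 0 <= percentile <= 1:
        raise ValueError(f"percentile {percentile!r} outside [0, 1]")
    if percentile <= 0.33:
        return "low"
    if percentile <= 0.66:
        return "mid"
    return "high"


def tertile_summary(labels: pd.DataFrame, stab: pd.DataFrame) -> pd.DataFrame:
    """Counts of promoters per (class, CV tertile, expression tertile)."""
    merged = labels.merge(stab.reset_index(), on="transcript", how="inner")
    merged = merged[
        merged["passes_filter"]
        & merged["scannable"]
        & merged["cv_percentile"].notna()
        & merged["geo_mean_percentile"].notna()
    ]
    merged = merged.assign(
        cv_tertile=merged["cv_percentile"].map(tertile_bins),
        exp_tertile=merged["geo_mean_percentile"].map(tertile_bins),
    )
    out = (
        merged.groupby(["class", "cv_tertile", "exp_tertile"])
        .size()
        .rename("n")
        .reset_index()
        .sort_values(["class", "cv_tertile", "exp_tertile"], kind="stable")
        .reset_index(drop=True)
    )
    return out


# scipy.stats.f_oneway serves as an independent cross-check of the OLS-based
# ANOVA in tests; re-exported here for convenience.
f_oneway = scipy.stats.f_oneway
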