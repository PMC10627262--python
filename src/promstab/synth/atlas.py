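"""Synthetic tissue-atlas count matrices with designed expression classes.

Each gene is designated *uniform* (same expected expression in every
sample) or *conditional* (expressing in a chosen number of tissues, a
low "leak" mean elsewhere).  Counts are negative-binomial draws around
the per-gene, per-sample means after multiplying in per-sample library
size distortions; dispersion 0 is the documented noise-free limit in
which counts equal the rounded means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneClass", "AtlasSpec", "AtlasSim", "simulate_counts"]


@dataclass(frozen=True)
class GeneClass:
    """Designed expression class for one gene.

    ``name`` is "uniform" or "conditional"; conditional genes express in
    ``n_expressing`` tissues (drawn per gene) at the atlas base mean and
    at ``AtlasSpec.off_mean`` elsewhere.
    """

    name: str
    n_expressing: int | None = None

    def __post_init__(self) -> None:
        if self.name not in {"uniform", "conditional"}:
            raise ValueError(f"unknown gene class {self.name!r}")
        if self.name == "conditional" and (self.n_expressing is None or self.n_expressing < 1):
            raise ValueError("conditional genes need n_expressing >= 1")


@dataclass
class AtlasSpec:
    """Design of one species' tissue atlas (>=10 tissues, >=2 stages)."""

    gene_classes: list[GeneClass]
    n_tissues: int = 12
    n_stages: int = 3
    base_mean: float = 100.0
    dispersion: float = 0.05  # NB dispersion alpha; var = mu + alpha * mu^2
    off_mean: float = 0.1  # leak mean of conditional genes outside their tissues
    library_size_factors: list[float] | None = None  # None: lognormal draws
    size_factor_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 10:
            raise ValueError("an atlas needs at least 10 tissue samples")
        if self.n_stages < 2:
            raise ValueError("an atlas needs at least 2 developmental stages")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0 (0 is the noise-free limit)")
        if self.off_mean < 0:
            raise ValueError("off_mean must be >= 0")
        for gc in self.gene_classes:
            if gc.n_expressing is not None and gc.n_expressing > self.n_tissues:
                raise ValueError("n_expressing cannot exceed n_tissues")
        if self.library_size_factors is not None:
            f = np.asarray(self.library_size_factors, dtype=float)
            if f.shape != (self.n_tissues,):
                raise ValueError("need one library size factor per sample")
            if (f <= 0).any():
                raise ValueError("library size factors must be strictly positive")


@dataclass
class AtlasSim:
    counts: pd.DataFrame  # transcripts x samples, raw counts
    metadata: pd.DataFrame  # sample -> tissue, stage
    truth: pd.DataFrame  # transcript -> gene_class, n_expressing, expressing tissues
    size_factors: np.ndarray  # the planted library-size distortions

    def write(self, outdir, prefix: str = "") -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": str(outdir / f"{prefix}counts.tsv"),
            "metadata": str(outdir / f"{prefix}samples.tsv"),
            "truth": str(outdir / f"{prefix}gene_classes.tsv"),
        }
        self.counts.to_csv(paths["counts"], sep="\t")
        self.metadata.to_csv(paths["metadata"], sep="\t")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    spec: AtlasSpec,
    transcript_ids: list[str] | None = None,
    n_genes: int | None = None,
) -> AtlasSim:
    """Draw a raw count matrix and its class truth table.

    One sample per tissue; developmental stages are assigned to tissues
    round-robin.  ``transcript_ids`` (or ``n_genes`` with generated ids)
    must match the length of ``spec.gene_classes``.
    """
    if transcript_ids is None:
        if n_genes is None:
            n_genes = len(spec.gene_classes)
        transcript_ids = [f"g{i + 1:05d}.t1" for i in range(n_genes)]
    if len(transcript_ids) != len(spec.gene_classes):
        raise ValueError(
            f"{len(transcript_ids)} transcripts but {len(spec.gene_classes)} gene classes"
        )
    rng = np.random.default_rng(spec.seed)
    T = spec.n_tissues
    samples = [f"T{t + 1:02d}" for t in range(T)]
    metadata = pd.DataFrame(
        {
            "tissue": [f"tissue{t + 1:02d}" for t in range(T)],
            "stage": [f"stage{t % spec.n_stages + 1}" for t in range(T)],
        },
        index=pd.Index(samples, name="sample"),
    )

    if spec.library_size_factors is None:
        factors = np.exp(rng.normal(0.0, spec.size_factor_sigma, size=T))
    else:
        factors = np.asarray(spec.library_size_factors, dtype=float)

    means = np.empty((len(transcript_ids), T), dtype=float)
    truth_rows = []
    for i, gc in enumerate(spec.gene_classes):
        if gc.name == "uniform":
            means[i, :] = spec.base_mean
            expressing: list[int] = list(range(T))
        else:
            on = rng.choice(T, size=gc.n_expressing, replace=False)
            means[i, :] = spec.off_mean
            means[i, on] = spec.base_mean
            expressing = sorted(int(t) for t in on)
        truth_rows.append(
            {
                "transcript": transcript_ids[i],
                "gene_class": gc.name,
                "n_expressing": gc.n_expressing if gc.name == "conditional" else T,
                "expressing_tissues": ";".join(samples[t] for t in expressing),
            }
        )

    counts = _nb_draw(rng, means * factors[None, :], spec.dispersion)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(transcript_ids, name="transcript"), columns=samples
    )
    return AtlasSim(counts_df, metadata, pd.DataFrame(truth_rows), factors)


def uniform_conditional_classes(
    n_uniform: int, n_conditional: int, n_expressing: int = 3
) -> list[GeneClass]:
    """Convenience: a block of uniform genes followed by conditional ones."""
    return [GeneClass("uniform")] * n_uniform + [
        GeneClass("conditional", n_expressing)
    ] * n_conditional
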