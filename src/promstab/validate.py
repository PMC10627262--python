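"""Ground-truth validation routines run against the synthetic generators.

Each function builds a synthetic dataset with known truth, runs the
corresponding pipeline stage, and measures how well the truth is
recovered.  They back both the test suite and the reproducibility
script.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import scan as sc
from . import stability as stab
from .orthologs import load_tree, switch_cascade
from .promoters import extract_promoters
from .synth import (
    AtlasSpec,
    FamilySpec,
    GenomeSpec,
    mirror_genome,
    plant,
    simulate_counts,
    simulate_family,
    simulate_genome,
    uniform_conditional_classes,
)

__all__ = [
    "auroc",
    "planted_tata_recovery",
    "stability_auroc",
    "size_factor_recovery",
    "switch_recovery",
    "strand_symmetry",
    "run_all_determinism",
]


def auroc(positives, negatives) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _tata_genome(n_genes: int, gc: float, seed: int) -> tuple:
    """Genome with the TATA consensus planted in the first half of genes."""
    n_planted = n_genes // 2
    element_plan = {i: [plant("TATA")] for i in range(n_planted)}
    spec = GenomeSpec(
        n_genes=n_genes, gc_background=gc, element_plan=element_plan, seed=seed
    )
    return simulate_genome(spec), n_planted


def planted_tata_recovery(
    n_genes: int = 500,
    gc: float = 0.36,
    seeds=(0, 1, 2),
    threshold: float = 0.85,
    workdir=None,
) -> pd.DataFrame:
    """Scan synthetic genomes with consensus TATA plants in half the genes.

    Returns one row per seed with the fraction of planted promoters
    labeled TATA and the false-TATA rate on the element-free half.
    """
    import tempfile

    pwms = sc.default_pwms()
    octamers = sc.default_octamers()
    rows = []
    for seed in seeds:
        genome, n_planted = _tata_genome(n_genes, gc, seed)
        with tempfile.TemporaryDirectory(dir=workdir) as td:
            paths = genome.write(td)
            promoters = extract_promoters(paths["fasta"], paths["gff3"])
        labels = sc.scan_promoters(promoters, pwms, octamers, threshold=threshold)
        planted_ids = set(genome.truth["transcript"])
        is_planted = labels["transcript"].isin(planted_ids)
        is_tata = labels["class"] == "TATA"
        rows.append(
            {
                "seed": seed,
                "n_planted": int(is_planted.sum()),
                "recovery": float(is_tata[is_planted].mean()),
                "false_positive_rate": float(is_tata[~is_planted].mean()),
            }
        )
    return pd.DataFrame(rows)


def stability_auroc(
    n_uniform: int = 500,
    n_conditional: int = 500,
    n_tissues: int = 12,
    n_expressing: int = 3,
    dispersion: float = 0.05,
    seeds=range(5),
) -> pd.DataFrame:
    """AUROC of CV-percentile ranking for designed conditional vs uniform genes."""
    rows = []
    for seed in seeds:
        spec = AtlasSpec(
            gene_classes=uniform_conditional_classes(n_uniform, n_conditional, n_expressing),
            n_tissues=n_tissues,
            dispersion=dispersion,
            seed=seed,
        )
        sim = simulate_counts(spec)
        table = stab.stability_table(sim.counts, sim.metadata)
        merged = table.join(sim.truth.set_index("transcript"))
        merged = merged[merged["cv_percentile"].notna()]
        pos = merged.loc[merged["gene_class"] == "conditional", "cv_percentile"]
        neg = merged.loc[merged["gene_class"] == "uniform", "cv_percentile"]
        rows.append({"seed": seed, "auroc": auroc(pos, neg)})
    return pd.DataFrame(rows)


def size_factor_recovery(
    n_genes: int = 1000, n_tissues: int = 12, dispersion: float = 0.05, seed: int = 0
) -> float:
    """CV of (estimated / planted) size factors; small means the planted
    library-size distortions are recovered up to a common scalar."""
    spec = AtlasSpec(
        gene_classes=uniform_conditional_classes(n_genes // 2, n_genes - n_genes // 2),
        n_tissues=n_tissues,
        dispersion=dispersion,
        seed=seed,
    )
    sim = simulate_counts(spec)
    est = stab.size_factors(sim.counts).to_numpy()
    ratio = est / sim.size_factors
    return float(ratio.std(ddof=1) / ratio.mean())


def switch_recovery(seeds=(0, 1, 2), dispersion: float = 0.02) -> pd.DataFrame:
    """Exact planted-switch-group recovery through the full cascade.

    One row per seed: the retained query set, the clade-concentrated
    truth set, and whether they are exactly equal.
    """
    from .synth import FamilyAtlasParams

    rows = []
    for seed in seeds:
        fspec = FamilySpec(
            atlas=FamilyAtlasParams(dispersion=dispersion), seed=seed
        )
        fam = simulate_family(fspec)
        stability_by_species = {
            sp: stab.stability_table(sim.counts, sim.metadata)
            for sp, sim in fam.atlases.items()
        }
        groups, _ = switch_cascade(
            fam.ortholog_table,
            stability_by_species,
            load_tree(fam.tree_newick),
            fam.query_species,
            member_counts=fam.member_counts,
        )
        retained = set(groups.loc[groups["retained"], "query_transcript"])
        truth = set(
            fam.groups.loc[fam.groups["clade_concentrated"], "query_transcript"]
        )
        rows.append(
            {
                "seed": seed,
                "n_retained": len(retained),
                "n_truth": len(truth),
                "exact": retained == truth,
                "n_overlap": len(retained & truth),
            }
        )
    return pd.DataFrame(rows)


def strand_symmetry(n_genes: int = 60, seed: int = 0, workdir=None) -> float:
    """Fraction of promoters labeled identically on a genome and its
    reverse complement (with coordinates remapped); 1.0 means the
    extraction + scan stack is strand-correct."""
    import tempfile

    element_plan = {}
    elements = ["TATA", "YPatch", "Inr", "CA", "GA"]
    for i in range(n_genes):
        if i % 3 != 2:
            element_plan[i] = [plant(elements[i % len(elements)])]
    spec = GenomeSpec(
        n_genes=n_genes, strand_fraction=0.5, element_plan=element_plan, seed=seed
    )
    genome = simulate_genome(spec)
    mirrored = mirror_genome(genome)
    pwms = sc.default_pwms()
    octamers = sc.default_octamers()
    frames = []
    for sim in (genome, mirrored):
        with tempfile.TemporaryDirectory(dir=workdir) as td:
            paths = sim.write(td)
            promoters = extract_promoters(paths["fasta"], paths["gff3"])
        frames.append(
            sc.scan_promoters(promoters, pwms, octamers).set_index("transcript")
        )
    a, b = frames
    same = (a["class"] == b.loc[a.index, "class"])
    return float(same.mean())


def run_all_determinism(config: dict | None = None, seed: int = 0, workdir=None) -> float:
    """Run the pipeline twice with one config/seed and compare all output
    files byte for byte; returns the fraction of identical files."""
    import tempfile

    from .pipeline import run_all

    with tempfile.TemporaryDirectory(dir=workdir) as td:
        out1, out2 = Path(td) / "run1", Path(td) / "run2"
        run_all(config, seed=seed, outdir=out1)
        run_all(config, seed=seed, outdir=out2)
        files = sorted(p.relative_to(out1) for p in out1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(out2) for p in out2.rglob("*") if p.is_file())
        if files != files2 or not files:
            return 0.0
        same = sum(
            filecmp.cmp(out1 / f, out2 / f, shallow=False) for f in files
        )
        return same / len(files)
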