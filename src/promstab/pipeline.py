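"""End-to-end orchestration: simulate -> stability -> extract -> scan ->
orthologs -> report, from one config and one seed.

Every stage writes its artifacts as TSV/JSON under the output directory
and logs its timing to stderr.  Two runs from the same config and seed
produce byte-identical outputs: all randomness is derived from one seed
sequence and no timestamps are written into files.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import orthologs as orth
from . import report as rep
from . import scan as sc
from . import stability as stab
from .promoters import extract_promoters, write_promoters
from .synth import (
    FamilyAtlasParams,
    FamilySpec,
    ScenarioSpec,
    build_scenario,
    simulate_counts,
    simulate_family,
    simulate_genome,
)

log = logging.getLogger("promstab")

__all__ = ["default_config", "load_config", "run_all"]


def default_config() -> dict:
    return {
        "scenario": {
            "n_genes": 300,
            "conditional_fraction": 0.5,
            "n_expressing": 3,
            "element_rates": {
                "TATA": {"conditional": 0.7, "uniform": 0.2},
                "YPatch": {"conditional": 0.1, "uniform": 0.3},
            },
            "gc_background": 0.36,
            "strand_fraction": 0.3,
            "n_tissues": 12,
            "n_stages": 3,
            "base_mean": 100.0,
            "dispersion": 0.05,
        },
        "stability": {"min_mean_reads": 1.0},
        "extract": {"max_upstream": 2000, "subsample_fraction": 0.4},
        "scan": {"threshold": 0.85, "min_intergenic": 100},
        "family": {
            "n_species": 8,
            "n_groups": 40,
            "n_clade_switched": 10,
            "n_scattered_switched": 10,
            "n_background": 200,
            "dispersion": 0.02,
            "ortholog_presence": {"uniform": 0.9, "conditional": 0.5},
        },
        "orthologs": {
            "min_switched": 2,
            "boundary": 0.5,
            "consistency_threshold": 0.5,
        },
        "report": {"bins": 20},
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, *exc):
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def run_all(config: dict | None = None, seed: int = 0, outdir="promstab_out") -> dict:
    """Run the whole pipeline; returns a summary dict (also written as JSON)."""
    cfg = _merge(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_scenario, s_subsample, s_family, s_sets = ss.spawn(4)
    summary: dict = {"seed": seed}

    # -- simulate the query species genome + atlas ---------------------------
    with _Stage("simulate"):
        scen = ScenarioSpec(**cfg["scenario"], seed=_seed_of(s_scenario))
        genome_spec, atlas_spec = build_scenario(scen)
        genome = simulate_genome(genome_spec)
        sim_paths = genome.write(outdir / "sim")
        transcript_ids = [g.transcript_id for g in genome.genes]
        atlas = simulate_counts(atlas_spec, transcript_ids=transcript_ids)
        atlas.write(outdir / "sim")

    # -- stability ------------------------------------------------------------
    with _Stage("stability"):
        table = stab.stability_table(
            atlas.counts, atlas.metadata, min_mean_reads=cfg["stability"]["min_mean_reads"]
        )
        (outdir / "stability").mkdir(exist_ok=True)
        stab.write_stability(table, outdir / "stability" / "stability.tsv")

    # -- promoter extraction (with transcript subsampling) --------------------
    with _Stage("extract"):
        chosen = rep.subsample_transcripts(
            transcript_ids,
            fraction=cfg["extract"]["subsample_fraction"],
            seed=_seed_of(s_subsample),
        )
        promoters = extract_promoters(
            sim_paths["fasta"],
            sim_paths["gff3"],
            max_upstream=cfg["extract"]["max_upstream"],
            transcript_ids=chosen,
        )
        (outdir / "promoters").mkdir(exist_ok=True)
        write_promoters(promoters, outdir / "promoters" / "promoters.tsv")

    # -- core promoter scan ----------------------------------------------------
    with _Stage("scan"):
        pwms = sc.default_pwms()
        octamers = sc.default_octamers()
        labels = sc.scan_promoters(
            promoters,
            pwms,
            octamers,
            threshold=cfg["scan"]["threshold"],
            min_intergenic=cfg["scan"]["min_intergenic"],
        )
        (outdir / "scan").mkdir(exist_ok=True)
        sc.write_labels(labels, outdir / "scan" / "labels.tsv")

    # -- synthetic ortholog family --------------------------------------------
    with _Stage("family"):
        fam_cfg = cfg["family"]
        from .synth.family import default_tree

        fspec = FamilySpec(
            tree_newick=default_tree(fam_cfg["n_species"]),
            n_groups=fam_cfg["n_groups"],
            n_clade_switched=fam_cfg["n_clade_switched"],
            n_scattered_switched=fam_cfg["n_scattered_switched"],
            n_background=fam_cfg["n_background"],
            ortholog_presence=fam_cfg.get("ortholog_presence", {}),
            atlas=FamilyAtlasParams(dispersion=fam_cfg["dispersion"]),
            seed=_seed_of(s_family),
        )
        family = simulate_family(fspec)
        family.write(outdir / "family")
        stability_by_species = {}
        for sp, sim in family.atlases.items():
            t = stab.stability_table(sim.counts, sim.metadata)
            stab.write_stability(t, outdir / "family" / sp / "stability.tsv")
            stability_by_species[sp] = t

    # -- ortholog cascade -------------------------------------------------------
    with _Stage("orthologs"):
        tree = orth.load_tree(family.tree_newick)
        ocfg = cfg["orthologs"]
        groups, reports = orth.switch_cascade(
            family.ortholog_table,
            stability_by_species,
            tree,
            family.query_species,
            member_counts=family.member_counts,
            min_switched=ocfg["min_switched"],
            boundary=ocfg["boundary"],
            consistency_threshold=ocfg["consistency_threshold"],
        )
        (outdir / "orthologs").mkdir(exist_ok=True)
        groups.to_csv(outdir / "orthologs" / "groups.tsv", sep="\t", index=False)
        orth.write_reports(reports, outdir / "orthologs" / "retained_groups.json")

    # -- report -----------------------------------------------------------------
    with _Stage("report"):
        rdir = outdir / "report"
        rdir.mkdir(exist_ok=True)
        dists = rep.cv_distribution_by_class(labels, table, bins=cfg["report"]["bins"])
        rep.class_distribution_table(dists).to_csv(
            rdir / "class_distributions.tsv", sep="\t", index=False
        )
        rep.tertile_summary(labels, table).to_csv(
            rdir / "tertiles.tsv", sep="\t", index=False
        )

        truth = family.groups
        by_class = {
            name: truth.loc[truth["query_class"] == name, "query_transcript"].tolist()
            for name in ("uniform", "conditional")
        }
        rng = np.random.default_rng(_seed_of(s_sets))
        all_q = sorted(truth["query_transcript"])
        k = max(1, len(all_q) // 2)
        by_class["random"] = sorted(rng.choice(all_q, size=k, replace=False))
        targets = [s for s in family.species if s != family.query_species]
        rates = rep.ortholog_recovery(by_class, family.ortholog_table, targets)
        rates.to_csv(rdir / "recovery.tsv", sep="\t", index=False)
        f_stat, p_value, tukey = rep.anova_tukey(rates)
        tukey.to_csv(rdir / "tukey.tsv", sep="\t", index=False)

        class_means = {
            cls: round(d.mean_percentile, 6) for cls, d in dists.items() if d.n
        }
        summary.update(
            {
                "n_genes": len(transcript_ids),
                "n_promoters_scanned": int(len(labels)),
                "class_counts": {
                    cls: int((labels["class"] == cls).sum())
                    for cls in sorted(labels["class"].unique())
                },
                "mean_cv_percentile_by_class": class_means,
                "n_groups": int(len(truth)),
                "n_retained_groups": int(groups["retained"].sum()),
                "recovery_rate_by_set": {
                    name: round(float(rates.loc[rates["gene_set"] == name, "rate"].mean()), 6)
                    for name in sorted(by_class)
                },
                "anova_F": round(f_stat, 6),
                "anova_p": float(f"{p_value:.6g}"),
            }
        )
        (rdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary
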