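"""Coupled genome + atlas designs for end-to-end runs.

A scenario ties the planted promoter elements of a synthetic genome to
the designed expression classes of its tissue atlas — e.g. planting a
TATA-box into 70% of conditional genes but only 20% of uniform genes —
so the downstream class-vs-CV report has a known direction of effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasSpec, GeneClass
from .genome import GenomeSpec, plant

__all__ = ["ScenarioSpec", "build_scenario"]


@dataclass
class ScenarioSpec:
    """One-species end-to-end design (genome + atlas + element planting)."""

    n_genes: int = 300
    conditional_fraction: float = 0.5
    n_expressing: int = 3
    element_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TATA": {"conditional": 0.7, "uniform": 0.2},
            "YPatch": {"conditional": 0.1, "uniform": 0.3},
        }
    )
    # genome settings
    strand_fraction: float = 0.3
    gc_background: float = 0.36
    intergenic_min: int = 300
    intergenic_max: int = 1500
    utr5_min: int = 50
    utr5_max: int = 200
    # atlas settings
    n_tissues: int = 12
    n_stages: int = 3
    base_mean: float = 100.0
    dispersion: float = 0.05
    seed: int = 0


def build_scenario(spec: ScenarioSpec) -> tuple[GenomeSpec, AtlasSpec]:
    """Draw per-gene classes and element plants; return coupled specs.

    The same seed sequence drives class assignment, planting, genome
    layout and count sampling, so a scenario is fully reproducible from
    (spec, seed).
    """
    ss = np.random.SeedSequence(spec.seed)
    design_seed, genome_seed, atlas_seed = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(3)
    )
    rng = np.random.default_rng(design_seed)

    classes: list[GeneClass] = []
    element_plan: dict[int, list] = {}
    for i in range(spec.n_genes):
        cls = "conditional" if rng.random() < spec.conditional_fraction else "uniform"
        classes.append(
            GeneClass(cls, spec.n_expressing if cls == "conditional" else None)
        )
        plants = []
        for element in sorted(spec.element_rates):
            if rng.random() < spec.element_rates[element].get(cls, 0.0):
                plants.append(plant(element))
        if plants:
            element_plan[i] = plants

    genome_spec = GenomeSpec(
        n_genes=spec.n_genes,
        strand_fraction=spec.strand_fraction,
        gc_background=spec.gc_background,
        intergenic_min=spec.intergenic_min,
        intergenic_max=spec.intergenic_max,
        utr5_min=spec.utr5_min,
        utr5_max=spec.utr5_max,
        element_plan=element_plan,
        seed=genome_seed,
    )
    atlas_spec = AtlasSpec(
        gene_classes=classes,
        n_tissues=spec.n_tissues,
        n_stages=spec.n_stages,
        base_mean=spec.base_mean,
        dispersion=spec.dispersion,
        seed=atlas_seed,
    )
    return genome_spec, atlas_spec
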