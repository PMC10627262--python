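"""Synthetic multi-species ortholog families with planted expression switches.

A family simulation couples a species phylogeny, one tissue atlas per
species, and an ortholog table linking each query-species transcript to
one gene per target species.  Every ortholog group has a designed
expression class in the query species; *switched* species receive the
opposite class (uniform <-> conditional).  Switch sets are planted
either clade-concentrated (the full leaf set of one clade, so the
switches are perfectly consistent with the tree) or scattered across
the tree (so they are not), giving the ortholog-switch cascade an exact
ground truth to recover.

Each species' atlas also carries background genes in fixed proportions
(40% uniform, 20% intermediate, 40% conditional of the total), so that
every uniform gene ranks below the 50th CV percentile and every
conditional gene above it, with intermediate background genes filling
the band around the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .atlas import AtlasSim, AtlasSpec, GeneClass, simulate_counts

__all__ = [
    "FamilySpec",
    "FamilyAtlasParams",
    "FamilySim",
    "simulate_family",
    "default_tree",
]

UNIFORM_FRACTION = 0.4  # of each species' total genes
MID_FRACTION = 0.2  # intermediate background genes straddling the CV boundary


def default_tree(n_species: int = 8) -> str:
    """A balanced-ish rooted Newick tree over sp1..spN."""
    names = [f"sp{i + 1}" for i in range(n_species)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return names[lo]
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)})"

    return build(0, n_species) + ";"


@dataclass
class FamilyAtlasParams:
    """Per-species atlas settings used by the family generator."""

    n_tissues: int = 12
    n_stages: int = 3
    base_mean: float = 100.0
    dispersion: float = 0.02
    off_mean: float = 0.1
    n_expressing_conditional: int = 3
    n_expressing_mid: int | None = None  # default: 2/3 of the tissues
    size_factor_sigma: float = 0.25

    def mid_k(self) -> int:
        if self.n_expressing_mid is not None:
            return self.n_expressing_mid
        return max(self.n_expressing_conditional + 1, round(2 * self.n_tissues / 3))


@dataclass
class FamilySpec:
    """Design of a planted ortholog family experiment."""

    tree_newick: str = field(default_factory=default_tree)
    n_groups: int = 40
    n_clade_switched: int = 10
    n_scattered_switched: int = 10
    n_background: int = 200
    query_species: str | None = None  # default: first leaf of the tree
    switch_plan: list[dict] | None = None  # explicit per-group plans (see below)
    duplications: list[tuple[int, str]] = field(default_factory=list)
    multi_member: list[tuple[int, str]] = field(default_factory=list)
    ortholog_presence: dict[str, float] = field(default_factory=dict)
    atlas: FamilyAtlasParams = field(default_factory=FamilyAtlasParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clade_switched + self.n_scattered_switched > self.n_groups:
            raise ValueError("more switched groups than groups")
        for cls, p in self.ortholog_presence.items():
            if cls not in {"uniform", "conditional"}:
                raise ValueError(f"unknown query class {cls!r} in ortholog_presence")
            if not 0 <= p <= 1:
                raise ValueError("presence probabilities must be in [0, 1]")


@dataclass
class FamilySim:
    tree_newick: str
    species: list[str]
    query_species: str
    ortholog_table: pd.DataFrame  # query_transcript, species, gene_id, transcript_id
    member_counts: pd.DataFrame  # query_transcript, species, n_members
    atlases: dict[str, AtlasSim]
    groups: pd.DataFrame  # per-group truth table

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": str(outdir / "tree.nwk"),
            "orthologs": str(outdir / "ortholog_table.tsv"),
            "member_counts": str(outdir / "member_counts.tsv"),
            "groups": str(outdir / "groups_truth.tsv"),
        }
        Path(paths["tree"]).write_text(self.tree_newick + "\n")
        self.ortholog_table.to_csv(paths["orthologs"], sep="\t", index=False)
        self.member_counts.to_csv(paths["member_counts"], sep="\t", index=False)
        self.groups.to_csv(paths["groups"], sep="\t", index=False)
        for sp, sim in self.atlases.items():
            sim.write(outdir / sp)
        return paths


def _tree_structures(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    clades = []
    for node in tree.preorder_internal_node_iter():
        labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.append(labels)
    root_children = []
    for child in tree.seed_node.child_nodes():
        root_children.append(frozenset(lf.taxon.label for lf in child.leaf_iter()))
    return leaves, clades, root_children


def _mrca_leafset(clades: list[frozenset], targets: set[str]) -> frozenset:
    containing = [c for c in clades if targets <= c]
    return min(containing, key=len)


def _flip(cls: str) -> str:
    return "conditional" if cls == "uniform" else "uniform"


def _make_switch_plan(spec: FamilySpec, leaves, clades, root_children, query, rng):
    """Per-group dicts: query_class, switched (set), clade_concentrated."""
    targets = [s for s in leaves if s != query]
    n = len(leaves)
    clade_options = [
        sorted(c) for c in clades
        if query not in c and 2 <= len(c) < n
    ]
    if spec.n_clade_switched and not clade_options:
        raise ValueError("tree has no clade of >=2 leaves excluding the query species")

    plans = []
    for _ in range(spec.n_clade_switched):
        chosen = clade_options[int(rng.integers(len(clade_options)))]
        plans.append({"switched": set(chosen), "clade_concentrated": True})
    for _ in range(spec.n_scattered_switched):
        # one leaf from each of two different root subtrees -> MRCA is the
        # whole tree, so the consistency score is |switched| / n < 0.5
        for _attempt in range(100):
            k = int(rng.integers(2, 4))  # 2 or 3 switched species
            picked: list[str] = []
            for sub in root_children:
                cand = sorted(sub - {query})
                if cand:
                    picked.append(cand[int(rng.integers(len(cand)))])
            while len(picked) < k:
                extra = targets[int(rng.integers(len(targets)))]
                if extra not in picked:
                    picked.append(extra)
            picked = picked[:k]
            score = len(picked) / len(_mrca_leafset(clades, set(picked)))
            if score < 0.5:
                plans.append({"switched": set(picked), "clade_concentrated": False})
                break
        else:
            raise ValueError("could not plant a scattered (clade-inconsistent) switch set")
    for _ in range(spec.n_groups - len(plans)):
        plans.append({"switched": set(), "clade_concentrated": False})
    for plan in plans:
        unknown = plan["switched"] - set(leaves)
        if unknown:
            raise ValueError(f"switch plan references unknown species: {sorted(unknown)}")
        plan["query_class"] = "uniform" if rng.random() < 0.5 else "conditional"
    return plans


def _species_classes(plans, species, query, ap: FamilyAtlasParams, n_background):
    """Gene-class list for one species: family genes then background fill."""
    fam = []
    for plan in plans:
        cls = plan["query_class"]
        if species != query and species in plan["switched"]:
            cls = _flip(cls)
        fam.append(cls)
    n_total = len(plans) + n_background
    want_uniform = round(UNIFORM_FRACTION * n_total)
    want_mid = round(MID_FRACTION * n_total)
    bg_uniform = max(0, want_uniform - sum(c == "uniform" for c in fam))
    bg_mid = want_mid
    bg_conditional = max(0, n_background - bg_uniform - bg_mid)

    classes = [
        GeneClass("uniform") if c == "uniform"
        else GeneClass("conditional", ap.n_expressing_conditional)
        for c in fam
    ]
    classes += [GeneClass("uniform")] * bg_uniform
    classes += [GeneClass("conditional", ap.mid_k())] * bg_mid
    classes += [GeneClass("conditional", ap.n_expressing_conditional)] * bg_conditional
    return classes, fam


def simulate_family(spec: FamilySpec) -> FamilySim:
    """Generate the full planted-family dataset (atlases, table, truth)."""
    leaves, clades, root_children = _tree_structures(spec.tree_newick)
    query = spec.query_species or leaves[0]
    if query not in leaves:
        raise ValueError(f"query species {query!r} is not a leaf of the tree")

    ss = np.random.SeedSequence(spec.seed)
    plan_rng = np.random.default_rng(ss.spawn(1)[0])
    if spec.switch_plan is not None:
        plans = [dict(p) for p in spec.switch_plan]
        for plan in plans:
            plan["switched"] = set(plan.get("switched", set()))
            unknown = plan["switched"] - set(leaves)
            if unknown:
                raise ValueError(f"switch plan references unknown species: {sorted(unknown)}")
            plan.setdefault("clade_concentrated", False)
            plan.setdefault("query_class", "uniform")
        if len(plans) != spec.n_groups:
            raise ValueError("switch_plan length must equal n_groups")
    else:
        plans = _make_switch_plan(spec, leaves, clades, root_children, query, plan_rng)

    ap = spec.atlas
    species_seeds = {sp: s for sp, s in zip(leaves, ss.spawn(len(leaves)))}
    table_rng = np.random.default_rng(ss.spawn(1)[0])

    atlases: dict[str, AtlasSim] = {}
    fam_classes: dict[str, list[str]] = {}
    extra_genes: dict[str, list[str]] = {sp: [] for sp in leaves}
    dup_by_species: dict[str, list[int]] = {}
    for gi, sp in spec.duplications:
        dup_by_species.setdefault(sp, []).append(gi)

    for sp in leaves:
        classes, fam = _species_classes(plans, sp, query, ap, spec.n_background)
        ids = [f"{sp}_g{k + 1:04d}.t1" for k in range(len(plans))]
        ids += [f"{sp}_bg{k + 1:04d}.t1" for k in range(len(classes) - len(plans))]
        for gi in dup_by_species.get(sp, []):
            dup_id = f"{sp}_g{gi + 1:04d}b.t1"
            ids.append(dup_id)
            classes.append(GeneClass("uniform"))
            extra_genes[sp].append(dup_id)
        aspec = AtlasSpec(
            gene_classes=classes,
            n_tissues=ap.n_tissues,
            n_stages=ap.n_stages,
            base_mean=ap.base_mean,
            dispersion=ap.dispersion,
            off_mean=ap.off_mean,
            size_factor_sigma=ap.size_factor_sigma,
            seed=int(species_seeds[sp].generate_state(1)[0] & 0x7FFFFFFF),
        )
        atlases[sp] = simulate_counts(aspec, transcript_ids=ids)
        fam_classes[sp] = fam

    presence = {"uniform": 1.0, "conditional": 1.0} | spec.ortholog_presence
    rows = []
    for k, plan in enumerate(plans):
        qt = f"{query}_g{k + 1:04d}.t1"
        for sp in leaves:
            if sp == query:
                continue
            if table_rng.random() >= presence[plan["query_class"]]:
                continue
            gene = f"{sp}_g{k + 1:04d}"
            rows.append((qt, sp, gene, f"{gene}.t1"))
            if k in dup_by_species.get(sp, []):
                rows.append((qt, sp, f"{gene}b", f"{gene}b.t1"))
    table = pd.DataFrame(
        rows, columns=["query_transcript", "species", "gene_id", "transcript_id"]
    )

    mm = {(gi, sp) for gi, sp in spec.multi_member}
    mc_rows = [
        (
            f"{query}_g{k + 1:04d}.t1",
            sp,
            2 if (k, sp) in mm else 1,
        )
        for k in range(len(plans))
        for sp in leaves
        if sp != query
    ]
    member_counts = pd.DataFrame(
        mc_rows, columns=["query_transcript", "species", "n_members"]
    )

    groups = pd.DataFrame(
        {
            "query_transcript": [f"{query}_g{k + 1:04d}.t1" for k in range(len(plans))],
            "query_class": [p["query_class"] for p in plans],
            "switched_species": [";".join(sorted(p["switched"])) for p in plans],
            "n_switched": [len(p["switched"]) for p in plans],
            "clade_concentrated": [bool(p["clade_concentrated"]) for p in plans],
        }
    )
    return FamilySim(
        spec.tree_newick.strip(),
        leaves,
        query,
        table,
        member_counts,
        atlases,
        groups,
    )
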