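"""Ortholog expression-pattern switch analysis on a species phylogeny.

Starting from per-species stability tables and an ortholog table mapping
query-species transcripts to target-species genes, the cascade:

1. keeps only the highest-expressing transcript of each target gene;
2. removes every (query, species) pair that retrieved more than one
   target gene (no 1:many orthology);
3. flags members whose CV percentile lies on the opposite side of the
   50th percentile from the query ("expression-pattern switch");
4. keeps groups switched in at least ``min_switched`` target species;
5. removes species with more than one gene-tree member, enforcing 1:1
   orthology across the group; and
6. scores how concentrated the switched species are within one clade of
   the phylogeny, retaining groups whose score reaches a threshold.

The clade-consistency score is ``|switched| / |leaves under the MRCA of
the switched species that are present in the group|``: 1.0 when the
switched species form exactly one clade (restricted to the present
species), small when they are scattered across the tree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "gene_set_size",
    "select_gene_sets",
    "pick_highest_expressing",
    "drop_multi_orthologs",
    "detect_switch",
    "filter_switch_groups",
    "clade_consistency",
    "enforce_one_to_one",
    "OrthologGroup",
    "build_groups",
    "switch_cascade",
    "load_tree",
    "read_ortholog_table",
]

ORTHOLOG_COLUMNS = ["query_transcript", "species", "gene_id", "transcript_id"]


def gene_set_size(n: int, fraction: float = 0.05) -> int:
    """ceiling(fraction * n): members per gene set (e.g. top/bottom 5%)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return math.ceil(fraction * n)


def select_gene_sets(
    stab: pd.DataFrame, fraction: float = 0.05, seed: int = 0
) -> dict[str, list[str]]:
    """Lowest-CV, highest-CV and random control transcript sets.

    Only transcripts passing the read filter (with a defined CV) are
    eligible; each set has ``ceiling(fraction * n)`` members.  Ties are
    broken by transcript id for determinism.
    """
    eligible = stab[stab["passes_filter"] & stab["cv"].notna()]
    n = len(eligible)
    k = gene_set_size(n, fraction)
    ordered = eligible.assign(_tid=eligible.index.astype(str)).sort_values(
        ["cv", "_tid"], kind="stable"
    )
    by_cv = ordered.index.to_list()
    rng = np.random.default_rng(seed)
    control = sorted(rng.choice(sorted(eligible.index), size=k, replace=False))
    return {
        "uniform": by_cv[:k],
        "conditional": by_cv[-k:][::-1],
        "random": list(control),
    }


def pick_highest_expressing(candidates: list[str], stab: pd.DataFrame) -> str:
    """Transcript with the greatest geometric-mean expression.

    Exact ties break toward the lexicographically smaller id; candidates
    without expression data are ignored, and an empty usable set raises.
    """
    usable = [c for c in candidates if c in stab.index and pd.notna(stab.at[c, "geo_mean"])]
    if not usable:
        raise KeyError(f"no expression data for any of {sorted(candidates)}")
    return min(usable, key=lambda c: (-stab.at[c, "geo_mean"], c))


def drop_multi_orthologs(table: pd.DataFrame) -> pd.DataFrame:
    """Remove ALL rows of every (query, species) pair with >1 target gene."""
    genes_per_pair = table.groupby(["query_transcript", "species"])["gene_id"].transform(
        "nunique"
    )
    return table[genes_per_pair == 1].reset_index(drop=True)


def detect_switch(
    query_percentile: float, target_percentile: float, boundary: float = 0.5
) -> bool:
    """True iff the two percentiles lie strictly on opposite sides of the
    boundary; a value exactly at the boundary never switches."""
    if pd.isna(query_percentile) or pd.isna(target_percentile):
        raise ValueError("both percentiles must be defined")
    return (query_percentile - boundary) * (target_percentile - boundary) < 0


@dataclass
class OrthologGroup:
    query_transcript: str
    query_percentile: float
    members: dict[str, str]  # species -> chosen transcript
    percentiles: dict[str, float]
    switched: set[str] = field(default_factory=set)
    consistency: float = float("nan")
    consistent: bool = False
    retained: bool = False

    @property
    def present(self) -> set[str]:
        return set(self.members)


def filter_switch_groups(
    groups: list[OrthologGroup], min_switched: int = 2
) -> list[OrthologGroup]:
    """Keep groups with at least ``min_switched`` switched target species."""
    return [g for g in groups if len(g.switched) >= min_switched]


def load_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or string."""
    text = source if str(source).strip().endswith(";") else Path(source).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree leaf names must be unique")
    return tree


def clade_consistency(
    tree: dendropy.Tree,
    switched: set[str],
    present: set[str],
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Concentration of switched species within one clade.

    Score = |switched| / |leaves(MRCA(switched)) intersect present|.
    A singleton switched set scores 1; an empty one is undefined (NaN,
    flag False).
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not switched <= present:
        raise ValueError("switched species must be a subset of present species")
    if not present <= leaf_labels:
        raise ValueError("present species must be leaves of the tree")
    if not switched:
        return float("nan"), False
    if len(switched) == 1:
        return 1.0, 1.0 >= threshold
    mrca = tree.mrca(taxon_labels=sorted(switched))
    under = {lf.taxon.label for lf in mrca.leaf_iter()}
    score = len(switched) / len(under & present)
    return score, score >= threshold


def enforce_one_to_one(
    group: OrthologGroup,
    member_counts: dict[str, int],
    min_switched: int = 2,
) -> OrthologGroup | None:
    """Drop species with >1 gene-tree member; drop the whole group when the
    remaining switched species fall below ``min_switched``."""
    multi = {sp for sp, n in member_counts.items() if n > 1}
    if multi:
        group.members = {sp: t for sp, t in group.members.items() if sp not in multi}
        group.percentiles = {
            sp: p for sp, p in group.percentiles.items() if sp not in multi
        }
        group.switched = group.switched - multi
    if len(group.switched) < min_switched:
        return None
    return group


def read_ortholog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ORTHOLOG_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    if "transcript_id" not in df.columns:
        df["transcript_id"] = pd.NA
    return df[ORTHOLOG_COLUMNS]


def _resolve_transcripts(
    table: pd.DataFrame, stability: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """One row per (query, species, gene): the highest-expressing transcript."""
    rows = []
    for (qt, sp, gene), sub in table.groupby(
        ["query_transcript", "species", "gene_id"], sort=True
    ):
        if sp not in stability:
            continue
        cands = [t for t in sub["transcript_id"] if pd.notna(t)]
        if not cands:
            continue
        try:
            chosen = pick_highest_expressing(sorted(set(cands)), stability[sp])
        except KeyError:
            continue
        rows.append((qt, sp, gene, chosen))
    return pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)


def build_groups(
    table: pd.DataFrame,
    stability: dict[str, pd.DataFrame],
    query_species: str,
    boundary: float = 0.5,
) -> list[OrthologGroup]:
    """Resolve, de-duplicate and switch-annotate one group per query.

    Species whose chosen transcript has no defined CV percentile are
    excluded from both the present and switched sets.
    """
    qstab = stability[query_species]
    resolved = _resolve_transcripts(table, stability)
    resolved = drop_multi_orthologs(resolved)
    groups = []
    for qt, sub in resolved.groupby("query_transcript", sort=True):
        if qt not in qstab.index:
            continue
        qp = qstab.at[qt, "cv_percentile"]
        if pd.isna(qp):
            continue
        members, percentiles, switched = {}, {}, set()
        for r in sub.itertuples():
            st = stability[r.species]
            if r.transcript_id not in st.index:
                continue
            tp = st.at[r.transcript_id, "cv_percentile"]
            if pd.isna(tp):
                continue
            members[r.species] = r.transcript_id
            percentiles[r.species] = float(tp)
            if detect_switch(qp, tp, boundary):
                switched.add(r.species)
        groups.append(
            OrthologGroup(qt, float(qp), members, percentiles, switched)
        )
    return groups


def switch_cascade(
    table: pd.DataFrame,
    stability: dict[str, pd.DataFrame],
    tree: dendropy.Tree,
    query_species: str,
    member_counts: pd.DataFrame | None = None,
    labels: dict[str, pd.DataFrame] | None = None,
    min_switched: int = 2,
    boundary: float = 0.5,
    consistency_threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full filtering cascade; return a summary table and per-group
    report dicts (suitable for JSON) for the retained groups."""
    groups = build_groups(table, stability, query_species, boundary)
    groups = filter_switch_groups(groups, min_switched)
    if member_counts is not None:
        mc = {
            (r.query_transcript, r.species): int(r.n_members)
            for r in member_counts.itertuples()
        }
        kept = []
        for g in groups:
            counts = {sp: mc.get((g.query_transcript, sp), 1) for sp in g.members}
            g2 = enforce_one_to_one(g, counts, min_switched)
            if g2 is not None:
                kept.append(g2)
        groups = kept

    rows, reports = [], []
    for g in groups:
        present = g.present | {query_species}
        g.consistency, g.consistent = clade_consistency(
            tree, g.switched, present, consistency_threshold
        )
        g.retained = g.consistent
        rows.append(
            {
                "query_transcript": g.query_transcript,
                "query_percentile": round(g.query_percentile, 6),
                "n_members": len(g.members),
                "n_switched": len(g.switched),
                "switched_species": ";".join(sorted(g.switched)),
                "consistency": round(g.consistency, 6),
                "retained": g.retained,
            }
        )
        if g.retained:
            report = {
                "query_transcript": g.query_transcript,
                "query_percentile": round(g.query_percentile, 6),
                "members": {
                    sp: {
                        "transcript": g.members[sp],
                        "cv_percentile": round(g.percentiles[sp], 6),
                    }
                    for sp in sorted(g.members)
                },
                "switched_species": sorted(g.switched),
                "consistency_score": round(g.consistency, 6),
                "consistency_note": (
                    "score reconstructs the manual tree-inspection step as "
                    "|switched| / |present leaves under their MRCA|"
                ),
            }
            if labels is not None:
                for sp in report["members"]:
                    lab = labels.get(sp)
                    t = g.members[sp]
                    if lab is not None and t in lab.index:
                        report["members"][sp]["promoter_class"] = str(
                            lab.at[t, "class"]
                        )
            reports.append(report)

    summary = pd.DataFrame(
        rows,
        columns=[
            "query_transcript",
            "query_percentile",
            "n_members",
            "n_switched",
            "switched_species",
            "consistency",
            "retained",
        ],
    )
    return summary, reports


def write_reports(reports: list[dict], path) -> None:
    Path(path).write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")
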