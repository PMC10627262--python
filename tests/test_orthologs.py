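"""Ortholog switch cascade: set selection, filters, clade consistency."""

import math

import numpy as np
import pandas as pd
import pytest

from promstab import stability as st
from promstab.orthologs import (
    OrthologGroup,
    clade_consistency,
    detect_switch,
    drop_multi_orthologs,
    enforce_one_to_one,
    filter_switch_groups,
    gene_set_size,
    load_tree,
    pick_highest_expressing,
    select_gene_sets,
    switch_cascade,
)
from promstab.synth import FamilyAtlasParams, FamilySpec, default_tree, simulate_family


@pytest.fixture(scope="module")
def toy_tree():
    return load_tree(default_tree(8))


def _stab(cv_values, geo=None, ids=None):
    ids = ids or [f"t{i:03d}" for i in range(len(cv_values))]
    df = pd.DataFrame(
        {
            "cv": cv_values,
            "geo_mean": geo if geo is not None else np.ones(len(ids)),
            "mean_raw": 10.0,
            "passes_filter": True,
        },
        index=pd.Index(ids, name="transcript"),
    )
    df["cv_percentile"] = st.percentile_rank(df["cv"])
    df["geo_mean_percentile"] = st.percentile_rank(df["geo_mean"])
    return df


class TestGeneSetSelection:
    def test_five_percent_of_26842_is_1343(self):
        assert gene_set_size(26842, 0.05) == 1343

    def test_small_n(self):
        assert gene_set_size(100, 0.05) == 5

    def test_fraction_must_be_a_proper_fraction(self):
        with pytest.raises(ValueError):
            gene_set_size(10, 1.5)

    def test_sets_have_expected_members_and_are_deterministic(self):
        rng = np.random.default_rng(0)
        tab = _stab(rng.uniform(0.1, 2.0, size=100))
        sets1 = select_gene_sets(tab, fraction=0.05, seed=4)
        sets2 = select_gene_sets(tab, fraction=0.05, seed=4)
        assert sets1 == sets2
        assert all(len(v) == 5 for v in sets1.values())
        cv = tab["cv"]
        assert max(cv[sets1["uniform"]]) <= min(cv[sets1["conditional"]])


class TestPickHighestExpressing:
    def test_greater_geometric_mean_wins(self):
        tab = _stab([0.1, 0.2], geo=[5.0, 7.5], ids=["a", "b"])
        assert pick_highest_expressing(["a", "b"], tab) == "b"

    def test_singleton(self):
        tab = _stab([0.1], geo=[5.0], ids=["only"])
        assert pick_highest_expressing(["only"], tab) == "only"

    def test_exact_tie_breaks_lexicographically(self):
        tab = _stab([0.1, 0.2], geo=[5.0, 5.0], ids=["zz", "aa"])
        assert pick_highest_expressing(["zz", "aa"], tab) == "aa"

    def test_no_data_raises(self):
        tab = _stab([0.1], ids=["x"])
        with pytest.raises(KeyError):
            pick_highest_expressing(["missing"], tab)


class TestDropMultiOrthologs:
    def test_quoted_rule(self):
        table = pd.DataFrame(
            {
                "query_transcript": ["q", "q", "q"],
                "species": ["s", "s", "t"],
                "gene_id": ["g1", "g2", "g3"],
                "transcript_id": ["g1.t1", "g2.t1", "g3.t1"],
            }
        )
        out = drop_multi_orthologs(table)
        assert out["species"].tolist() == ["t"]

    def test_unique_table_unchanged(self):
        table = pd.DataFrame(
            {
                "query_transcript": ["q1", "q2"],
                "species": ["s", "s"],
                "gene_id": ["g1", "g2"],
                "transcript_id": ["g1.t1", "g2.t1"],
            }
        )
        pd.testing.assert_frame_equal(drop_multi_orthologs(table), table)


class TestDetectSwitch:
    @pytest.mark.parametrize(
        "q,t,expected",
        [(0.03, 0.62, True), (0.97, 0.40, True), (0.03, 0.20, False),
         (0.6, 0.5, False), (0.5, 0.6, False)],
    )
    def test_crossing_the_median(self, q, t, expected):
        assert detect_switch(q, t) is expected

    def test_undefined_percentile_rejected(self):
        with pytest.raises(ValueError):
            detect_switch(float("nan"), 0.3)


class TestFilterSwitchGroups:
    def _group(self, n_switched):
        return OrthologGroup(
            "q", 0.1, {f"s{i}": f"t{i}" for i in range(5)},
            {f"s{i}": 0.9 for i in range(5)},
            switched={f"s{i}" for i in range(n_switched)},
        )

    def test_threshold_of_two(self):
        groups = [self._group(1), self._group(2), self._group(3)]
        kept = filter_switch_groups(groups)
        assert [len(g.switched) for g in kept] == [2, 3]

    def test_zero_threshold_keeps_all(self):
        groups = [self._group(0), self._group(1)]
        assert len(filter_switch_groups(groups, min_switched=0)) == 2


class TestCladeConsistency:
    def test_cherry_is_perfect(self, toy_tree):
        score, flag = clade_consistency(toy_tree, {"sp1", "sp2"}, set(f"sp{i}" for i in range(1, 9)))
        assert score == 1.0 and flag

    def test_scattered_pair_scores_quarter(self, toy_tree):
        present = {f"sp{i}" for i in range(1, 9)}
        score, flag = clade_consistency(toy_tree, {"sp1", "sp8"}, present)
        assert score == pytest.approx(0.25) and not flag

    def test_all_present_switched_is_one(self, toy_tree):
        present = {f"sp{i}" for i in range(1, 9)}
        score, flag = clade_consistency(toy_tree, present, present)
        assert score == 1.0 and flag

    def test_empty_switched_undefined(self, toy_tree):
        score, flag = clade_consistency(toy_tree, set(), {"sp1"})
        assert math.isnan(score) and not flag

    def test_singleton_scores_one(self, toy_tree):
        score, flag = clade_consistency(toy_tree, {"sp5"}, {"sp5", "sp1"})
        assert score == 1.0 and flag

    def test_absent_species_shrink_the_denominator(self, toy_tree):
        # MRCA(sp1, sp4) covers sp1..sp4, but only 3 of them are present
        present = {"sp1", "sp2", "sp4"}
        score, _ = clade_consistency(toy_tree, {"sp1", "sp4"}, present)
        assert score == pytest.approx(2 / 3)


class TestEnforceOneToOne:
    def _group(self):
        return OrthologGroup(
            "q", 0.1,
            {"sp2": "a", "sp3": "b", "sp4": "c"},
            {"sp2": 0.9, "sp3": 0.8, "sp4": 0.7},
            switched={"sp2", "sp3"},
        )

    def test_multi_member_species_removed(self):
        out = enforce_one_to_one(self._group(), {"sp2": 1, "sp3": 1, "sp4": 2})
        assert "sp4" not in out.members and out.switched == {"sp2", "sp3"}

    def test_all_single_members_unchanged(self):
        g = self._group()
        out = enforce_one_to_one(g, {"sp2": 1, "sp3": 1, "sp4": 1})
        assert out is g and len(out.members) == 3

    def test_dropping_switched_species_can_drop_group(self):
        out = enforce_one_to_one(self._group(), {"sp2": 2, "sp3": 1, "sp4": 1})
        assert out is None


@pytest.fixture(scope="module")
def family_run():
    spec = FamilySpec(
        n_groups=20,
        n_clade_switched=5,
        n_scattered_switched=5,
        n_background=150,
        duplications=[(15, "sp5")],
        atlas=FamilyAtlasParams(dispersion=0.02),
        seed=77,
    )
    fam = simulate_family(spec)
    stability = {
        sp: st.stability_table(sim.counts, sim.metadata)
        for sp, sim in fam.atlases.items()
    }
    groups, reports = switch_cascade(
        fam.ortholog_table,
        stability,
        load_tree(fam.tree_newick),
        fam.query_species,
        member_counts=fam.member_counts,
    )
    return fam, stability, groups, reports


class TestCascadeEndToEnd:

    def test_retained_equals_clade_concentrated_truth(self, family_run):
        fam, _, groups, _ = family_run
        retained = set(groups.loc[groups["retained"], "query_transcript"])
        truth = set(fam.groups.loc[fam.groups["clade_concentrated"], "query_transcript"])
        assert retained == truth

    def test_every_retained_group_satisfies_contract(self, family_run):
        _, _, groups, reports = family_run
        retained = groups[groups["retained"]]
        assert (retained["n_switched"] >= 2).all()
        assert (retained["consistency"] >= 0.5).all()
        for rep in reports:
            species = list(rep["members"])
            assert len(species) == len(set(species))

    def test_duplicated_pair_absent_downstream(self, family_run):
        from promstab.orthologs import build_groups

        fam, stability, _, _ = family_run
        qt = f"{fam.query_species}_g0016.t1"  # group 15 carries the 1:many plant
        groups = build_groups(fam.ortholog_table, stability, fam.query_species)
        g = next(x for x in groups if x.query_transcript == qt)
        assert "sp5" not in g.members
        assert set(g.members) == {f"sp{i}" for i in range(2, 9)} - {"sp5"}
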