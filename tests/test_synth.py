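"""Ground-truth guarantees of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from promstab import stability as st
from promstab.synth import (
    AtlasSpec,
    FamilyAtlasParams,
    FamilySpec,
    GeneClass,
    GenomeSizingError,
    GenomeSpec,
    default_tree,
    plant,
    simulate_counts,
    simulate_family,
    simulate_genome,
    uniform_conditional_classes,
)


class TestSimulateGenome:
    def test_empty_spec_gives_pure_background(self, tmp_path):
        genome = simulate_genome(GenomeSpec(n_genes=0, chrom_length=500, seed=0))
        assert genome.genes == [] and genome.truth.empty
        assert len(genome.sequence) == 500
        paths = genome.write(tmp_path)
        gff = open(paths["gff3"]).read()
        assert gff.startswith("##gff-version 3") and "gene" not in gff.split("\n", 2)[2]

    def test_gene_intervals_strictly_ordered_and_disjoint(self):
        genome = simulate_genome(GenomeSpec(n_genes=30, seed=2))
        spans = [(g.start, g.end) for g in genome.genes]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2 and s1 <= e1

    def test_equal_seeds_byte_identical_outputs(self, tmp_path):
        spec = GenomeSpec(n_genes=10, strand_fraction=0.5,
                          element_plan={0: [plant("TATA")]}, seed=9)
        a = simulate_genome(spec).write(tmp_path / "a")
        b = simulate_genome(spec).write(tmp_path / "b")
        for key in ("fasta", "gff3"):
            assert open(a[key], "rb").read() == open(b[key], "rb").read()

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(GenomeSizingError):
            simulate_genome(GenomeSpec(n_genes=50, chrom_length=5000, seed=0))

    def test_background_gc_close_to_requested(self):
        genome = simulate_genome(GenomeSpec(n_genes=0, chrom_length=200_000,
                                            gc_background=0.36, seed=4))
        gc = sum(genome.sequence.count(b) for b in "GC") / len(genome.sequence)
        assert gc == pytest.approx(0.36, abs=0.01)


class TestSimulateCounts:
    def test_noise_free_limit_reproduces_means(self):
        spec = AtlasSpec(
            gene_classes=[GeneClass("uniform")] * 3,
            dispersion=0.0,
            library_size_factors=[1.0] * 12,
            base_mean=100.0,
            seed=0,
        )
        sim = simulate_counts(spec)
        assert (sim.counts.to_numpy() == 100).all()
        assert all(st.cv(row) == 0.0 for row in sim.counts.to_numpy())

    def test_conditional_gene_mostly_silent(self):
        spec = AtlasSpec(
            gene_classes=[GeneClass("conditional", 2)], n_tissues=12, seed=1
        )
        sim = simulate_counts(spec)
        near_zero = (sim.counts.to_numpy()[0] <= 2).sum()
        assert near_zero >= 10

    def test_equal_seeds_identical_matrices(self):
        spec = AtlasSpec(gene_classes=uniform_conditional_classes(5, 5), seed=3)
        pd.testing.assert_frame_equal(
            simulate_counts(spec).counts, simulate_counts(spec).counts
        )

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(base_mean=0.0), "base_mean"),
            (dict(dispersion=-0.1), "dispersion"),
            (dict(n_tissues=5), "10 tissue"),
            (dict(n_stages=1), "2 developmental"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs, msg):
        base = dict(gene_classes=[GeneClass("uniform")])
        with pytest.raises(ValueError, match=msg):
            AtlasSpec(**{**base, **kwargs})

    def test_row_cv_monotone_in_expressing_tissue_count(self):
        """Mean CV over replicates grows as conditional genes express in
        fewer tissues (k/T shrinks)."""
        mean_cv = {}
        for k in (2, 4, 8):
            cvs = []
            for rep in range(20):
                spec = AtlasSpec(
                    gene_classes=[GeneClass("conditional", k)] * 5,
                    n_tissues=12,
                    seed=1000 * k + rep,
                )
                sim = simulate_counts(spec)
                cvs += [st.cv(r) for r in sim.counts.to_numpy()]
            mean_cv[k] = np.mean(cvs)
        assert mean_cv[2] > mean_cv[4] > mean_cv[8]

    def test_counts_roundtrip_through_readers(self, tmp_path):
        spec = AtlasSpec(gene_classes=uniform_conditional_classes(4, 4), seed=5)
        sim = simulate_counts(spec)
        paths = sim.write(tmp_path)
        back = st.read_counts(paths["counts"])
        pd.testing.assert_frame_equal(back, sim.counts)
        meta = st.read_metadata(paths["metadata"])
        pd.testing.assert_frame_equal(meta, sim.metadata)


@pytest.fixture(scope="module")
def small_family():
    spec = FamilySpec(
        n_groups=8,
        n_clade_switched=2,
        n_scattered_switched=2,
        n_background=100,
        duplications=[(0, "sp3")],
        multi_member=[(1, "sp4")],
        seed=21,
    )
    return spec, simulate_family(spec)


class TestSimulateFamily:

    def test_unswitched_groups_share_query_class(self, small_family):
        _, fam = small_family
        unswitched = fam.groups[fam.groups["n_switched"] == 0]
        assert len(unswitched) == 4
        for row in unswitched.itertuples():
            k = int(row.query_transcript.split("_g")[1].split(".")[0])
            for sp in fam.species:
                truth = fam.atlases[sp].truth
                cls = truth.loc[
                    truth["transcript"] == f"{sp}_g{k:04d}.t1", "gene_class"
                ].item()
                assert cls == row.query_class

    def test_switched_species_have_opposite_class(self, small_family):
        _, fam = small_family
        for row in fam.groups[fam.groups["n_switched"] > 0].itertuples():
            k = int(row.query_transcript.split("_g")[1].split(".")[0])
            for sp in row.switched_species.split(";"):
                truth = fam.atlases[sp].truth
                cls = truth.loc[
                    truth["transcript"] == f"{sp}_g{k:04d}.t1", "gene_class"
                ].item()
                assert cls != row.query_class

    def test_cherry_switches_marked_clade_concentrated(self, small_family):
        _, fam = small_family
        concentrated = fam.groups[fam.groups["clade_concentrated"]]
        assert len(concentrated) == 2
        assert (concentrated["n_switched"] >= 2).all()

    def test_planted_duplication_yields_two_rows(self, small_family):
        _, fam = small_family
        qt = f"{fam.query_species}_g0001.t1"
        sub = fam.ortholog_table.query("query_transcript == @qt and species == 'sp3'")
        assert len(sub) == 2 and set(sub["gene_id"]) == {"sp3_g0001", "sp3_g0001b"}

    def test_multi_member_counts_recorded(self, small_family):
        _, fam = small_family
        qt = f"{fam.query_species}_g0002.t1"
        row = fam.member_counts.query("query_transcript == @qt and species == 'sp4'")
        assert row["n_members"].item() == 2

    def test_unknown_switch_species_rejected(self):
        spec = FamilySpec(
            n_groups=2,
            n_clade_switched=0,
            n_scattered_switched=0,
            switch_plan=[
                {"switched": {"nosuch"}, "query_class": "uniform"},
                {"switched": set(), "query_class": "uniform"},
            ],
            seed=0,
        )
        with pytest.raises(ValueError, match="unknown species"):
            simulate_family(spec)

    def test_default_tree_is_balanced_newick(self):
        nwk = default_tree(8)
        assert nwk.count("sp") == 8 and nwk.endswith(";")
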