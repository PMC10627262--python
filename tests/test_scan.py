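"""PWM relative scoring, octamer containment and label combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from promstab.promoters import PromoterSequence
from promstab.scan import (
    OctamerSet,
    ScanWindows,
    combine_labels,
    load_octamers,
    load_pwm,
    motif_scan,
    octamer_scan,
    pwm_relative_score,
    scan_promoter,
    scan_promoters,
)

from _oracles import (
    BASES,
    brute_force_octamer,
    brute_force_relative_score,
    random_promoter,
    random_pwm,
)


class TestPWMRelativeScore:
    def test_consensus_scores_one(self, pwms):
        for pwm in pwms.values():
            score, off = pwm_relative_score(pwm, pwm.consensus)
            assert score == pytest.approx(1.0) and off == 0

    def test_anticonsensus_scores_zero(self, pwms):
        pwm = pwms["TATA"]
        worst = "".join(BASES[i] for i in pwm.weights.argmin(axis=1))
        assert pwm_relative_score(pwm, worst)[0] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            pwm = random_pwm(rng, int(rng.integers(2, 9)))
            n = int(rng.integers(pwm.length, 40))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            ours = pwm_relative_score(pwm, seq)
            oracle = brute_force_relative_score(pwm, seq)
            if oracle[0] is None:
                assert ours == (None, None)
            else:
                assert ours[0] == pytest.approx(oracle[0], abs=1e-12)
                assert ours[1] == oracle[1]

    def test_short_sequence_undefined(self, pwms):
        assert pwm_relative_score(pwms["TATA"], "ACG") == (None, None)

    @given(seed=st_.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_score_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, int(rng.integers(2, 7)))
        seq = "".join(rng.choice(list(BASES), size=25))
        score, _ = pwm_relative_score(pwm, seq)
        assert 0.0 <= score <= 1.0


class TestMotifScan:
    def test_planted_tata_detected(self, planted_promoters, planted_genome, pwms):
        genome, _ = planted_genome
        tata_ids = genome.truth.loc[genome.truth["element"] == "TATA", "transcript"]
        for tid in tata_ids:
            hits = motif_scan(planted_promoters[tid], pwms)
            assert hits["TATA"].flag and hits["TATA"].best_score == pytest.approx(1.0)

    def test_unattainable_threshold_flags_nothing(self, planted_promoters, pwms):
        for p in list(planted_promoters.values())[:5]:
            hits = motif_scan(p, pwms, threshold=1.01)
            assert not any(h.flag for h in hits.values())

    def test_threshold_monotonicity(self, planted_promoters, pwms):
        """Raising the threshold never turns a flag true."""
        for p in list(planted_promoters.values())[:10]:
            low = motif_scan(p, pwms, threshold=0.6)
            high = motif_scan(p, pwms, threshold=0.9)
            for e in high:
                assert not (high[e].flag and not low[e].flag)

    def test_false_tata_rate_stable_across_seeds(self):
        """The background false-TATA rate varies by at most 2 percentage
        points around its mean over 5 genome seeds."""
        from promstab.validate import planted_tata_recovery

        results = planted_tata_recovery(n_genes=500, seeds=(10, 11, 12, 13, 14))
        fp = results["false_positive_rate"]
        assert (fp - fp.mean()).abs().max() <= 0.02


class TestOctamerScan:
    def test_planted_octamer_found_in_window(self):
        sets = {"TATA": OctamerSet("TATA", frozenset({"TATAAATA"}))}
        up = "C" * 70 + "TATAAATA" + "C" * 22  # occupies -30..-23
        p = PromoterSequence("x", up, "G" * 20)
        hits = octamer_scan(p, sets)
        assert hits["TATA"].flag and hits["TATA"].matches == [("TATAAATA", -30)]

    def test_octamer_outside_window_ignored(self):
        sets = {"TATA": OctamerSet("TATA", frozenset({"TATAAATA"}))}
        up = "C" * 90 + "TATAAATA" + "CC"  # occupies -10..-3, outside (-45,-18)
        p = PromoterSequence("x", up, "G" * 20)
        assert not octamer_scan(p, sets)["TATA"].flag

    def test_empty_set_never_flags(self):
        sets = {"TATA": OctamerSet("TATA", frozenset())}
        p = PromoterSequence("x", "TATAAATA" * 10, "")
        assert not octamer_scan(p, sets)["TATA"].flag

    def test_matches_naive_windowed_search(self, octamers):
        rng = np.random.default_rng(13)
        windows = ScanWindows()
        for _ in range(300):
            p = random_promoter(rng, up_len=int(rng.integers(0, 130)),
                                utr_len=int(rng.integers(0, 90)))
            hits = octamer_scan(p, octamers, windows)
            for elem, (frm, to) in windows.octamer.items():
                oracle = brute_force_octamer(p, octamers[elem].octamers, frm, to)
                assert hits[elem].matches == oracle

    def test_malformed_octamer_rejected_at_load(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("TATAAAT\n")
        with pytest.raises(ValueError, match="8-mer"):
            load_octamers(bad)


class TestCombineLabels:
    def test_either_method_suffices(self):
        from promstab.scan import MotifHit, OctamerHit

        lab = combine_labels(
            "t",
            {"TATA": MotifHit(True, 0.9, -30)},
            {"TATA": OctamerHit(False, [])},
            scannable=True,
        )
        assert lab.combined["TATA"] and lab.promoter_class == "TATA"

    def test_all_negative_is_coreless(self):
        from promstab.scan import MotifHit, OctamerHit

        lab = combine_labels(
            "t",
            {"TATA": MotifHit(False, 0.2, -50), "YPatch": MotifHit(False, 0.1, 0)},
            {"TATA": OctamerHit(False, [])},
            scannable=True,
        )
        assert lab.promoter_class == "Coreless"

    def test_tata_precedence_keeps_both_flags(self):
        from promstab.scan import MotifHit

        lab = combine_labels(
            "t",
            {"TATA": MotifHit(True, 0.95, -30), "YPatch": MotifHit(True, 0.9, -10)},
            {},
            scannable=True,
        )
        assert lab.promoter_class == "TATA"
        assert lab.combined["TATA"] and lab.combined["YPatch"]

    def test_unscannable_overrides(self):
        lab = combine_labels("t", {}, {}, scannable=False)
        assert lab.promoter_class == "Unscannable"


class TestScanPromoters:
    def test_short_intergenic_region_unscannable(self, pwms, octamers):
        p = PromoterSequence("x", "TATAAATA", "G" * 150)  # 8 bp intergenic
        lab = scan_promoter(p, pwms, octamers)
        assert lab.promoter_class == "Unscannable"

    def test_scannable_promoters_partition_into_three_classes(
        self, planted_promoters, pwms, octamers
    ):
        df = scan_promoters(list(planted_promoters.values()), pwms, octamers)
        scannable = df[df["scannable"]]
        assert set(scannable["class"]) <= {"TATA", "YPatch", "Coreless"}
        # exactly one class per promoter by construction of the class column
        assert scannable["class"].notna().all()

    def test_planted_labels_match_truth(self, planted_genome, planted_promoters, pwms, octamers):
        genome, _ = planted_genome
        df = scan_promoters(list(planted_promoters.values()), pwms, octamers)
        df = df.set_index("transcript")
        for row in genome.truth.itertuples():
            if row.element in ("TATA", "YPatch"):
                assert df.at[row.transcript, f"combined_{row.element}"]


class TestPWMLoading:
    def test_frequency_matrix_converted_to_log_odds(self, tmp_path):
        f = tmp_path / "toy.pwm"
        f.write_text(">toy\nA [ 90 5 ]\nC [ 5 5 ]\nG [ 0 85 ]\nT [ 5 5 ]\n")
        pwm = load_pwm(f)
        assert pwm.name == "toy" and pwm.length == 2
        assert pwm.consensus == "AG"
        assert (pwm.weights <= np.log2(1 / 0.25) + 0.1).all()

    def test_negative_matrix_used_as_scores(self, tmp_path):
        f = tmp_path / "raw.pwm"
        f.write_text("A 1.0 -1.0\nC -1.0 1.0\nG -1.0 -1.0\nT -1.0 -1.0\n")
        pwm = load_pwm(f)
        assert pwm.consensus == "AC"
        assert pwm.weights[0, 0] == 1.0
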