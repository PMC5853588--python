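"""Synthetic-data generator: site layout, truth construction, count sampling."""

import numpy as np
import pandas as pd
import pytest

import orgedit as oe
from orgedit.annotation import SampleDesign, sites_to_frame
from orgedit.errors import ArgumentError, DesignError
from orgedit.simulate import _round_half_away


class TestGenSites:
    def test_reference_design_counts(self):
        sites = oe.gen_sites(576, 36, 24, seed=1)
        assert len(sites) == 612
        assert sum(s.organelle == "mito" for s in sites) == 576
        assert sum(s.organelle == "plastid" for s in sites) == 36
        frame = sites_to_frame(sites)
        mito_tx = frame.loc[frame["organelle"] == "mito", "transcript"]
        assert mito_tx.nunique() == 24

    def test_empty_request(self):
        assert oe.gen_sites(0, 0, 1, seed=1) == []

    def test_seeded_determinism(self):
        a = [s.site_id for s in oe.gen_sites(50, 10, 6, seed=7)]
        b = [s.site_id for s in oe.gen_sites(50, 10, 6, seed=7)]
        assert a == b
        c = [s.site_id for s in oe.gen_sites(50, 10, 6, seed=8)]
        assert a != c

    def test_site_ids_unique_and_positions_valid(self):
        frame = sites_to_frame(oe.gen_sites(200, 20, 15, seed=3))
        assert frame.index.is_unique
        assert (frame["tx_position"] >= 1).all()
        assert (frame["genome_position"] >= 1).all()

    @pytest.mark.parametrize("nm,np_,nt", [(-1, 0, 1), (0, -2, 1), (5, 5, 0)])
    def test_invalid_arguments(self, nm, np_, nt):
        with pytest.raises(ArgumentError):
            oe.gen_sites(nm, np_, nt, seed=1)


class TestGenTruth:
    def test_class_counts_round_half_away(self):
        frame = sites_to_frame(oe.gen_sites(576, 0, 24, seed=2))
        truth = oe.gen_truth(frame, frac_increased=0.14, frac_decreased=0.03,
                             seed=3)
        counts = truth.effect_class.value_counts()
        assert counts["increased"] == 81  # round(0.14 * 576)
        assert counts["decreased"] == 17  # round(0.03 * 576)

    def test_all_invariant(self, small_frame):
        truth = oe.gen_truth(small_frame, frac_increased=0.0,
                             frac_decreased=0.0, seed=4)
        assert (truth.effect_class == "invariant").all()
        assert (truth.delta_true == 0).all()
        assert truth.extents["wildtype"].equals(truth.extents["mutant"])

    def test_effect_floor_by_construction(self, small_truth):
        non_inv = small_truth.effect_class != "invariant"
        realized = (small_truth.extents["mutant"]
                    - small_truth.extents["wildtype"])[non_inv]
        assert (realized.abs() >= 0.1 - 1e-12).all()
        signs = np.sign(realized)
        expect = small_truth.effect_class[non_inv].map(
            {"increased": 1.0, "decreased": -1.0})
        assert (signs == expect).all()

    def test_extents_stay_in_unit_interval(self, small_truth):
        assert ((small_truth.extents >= 0) & (small_truth.extents <= 1)).all().all()

    def test_effect_sites_restriction(self, small_frame):
        mito = list(small_frame.index[small_frame["organelle"] == "mito"])
        truth = oe.gen_truth(small_frame, frac_increased=0.5,
                             frac_decreased=0.25, seed=5, effect_sites=mito)
        plastid = small_frame.index[small_frame["organelle"] == "plastid"]
        assert (truth.effect_class[plastid] == "invariant").all()

    def test_rejects_delta_below_floor(self, small_frame):
        with pytest.raises(ArgumentError):
            oe.gen_truth(small_frame, delta_range=(0.05, 0.2), seed=1)

    def test_sidecar_round_trip(self, small_truth, tmp_path):
        path = tmp_path / "truth.tsv"
        small_truth.to_tsv(path)
        back = oe.TruthTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.extents, small_truth.extents)
        assert (back.effect_class == small_truth.effect_class).all()


class TestGenCounts:
    def test_conservation(self, small_truth):
        m = oe.gen_counts(small_truth, oe.default_design(), depth=500, seed=6)
        total = m.edited + m.unedited + m.other
        assert (total == 500).all().all()
        assert (m.other == 0).all().all()

    def test_zero_depth_undefined_extent(self, small_truth):
        m = oe.gen_counts(small_truth, oe.default_design(), depth=0, seed=6)
        assert (m.edited == 0).all().all()
        assert m.extent().isna().all().all()

    def test_degenerate_full_editing(self, small_frame):
        truth = oe.gen_truth(small_frame, frac_increased=0, frac_decreased=0,
                             base_extent_range=(0.999999, 1.0), seed=7)
        truth.extents[:] = 1.0
        m = oe.gen_counts(truth, oe.default_design(replicates=1),
                          depth=500, seed=8)
        assert (m.edited == 500).all().all()

    def test_binomial_mean_recovery(self, small_frame):
        # mean observed extent over 1000 replicate draws at depth 1000
        truth = oe.gen_truth(small_frame.iloc[:1], frac_increased=0,
                             frac_decreased=0, seed=9)
        truth.extents[:] = 0.6
        design = [SampleDesign(f"s{i}", "wildtype", i, "wildtype")
                  for i in range(1, 1001)]
        m = oe.gen_counts(truth, design, depth=1000, seed=10)
        assert abs(m.extent().to_numpy().mean() - 0.6) < 0.01

    def test_unknown_genotype_raises(self, small_truth):
        bad = [SampleDesign("x", "nosuch", 1, "mutant")]
        with pytest.raises(DesignError):
            oe.gen_counts(small_truth, bad, depth=100, seed=1)

    def test_error_rate_produces_other_calls(self, small_truth):
        m = oe.gen_counts(small_truth, oe.default_design(replicates=1),
                          depth=1000, seed=11, error_rate=0.05)
        assert m.other.to_numpy().sum() > 0
        assert ((m.edited + m.unedited + m.other) == 1000).all().all()

    def test_beta_binomial_overdispersion(self, small_frame):
        truth = oe.gen_truth(small_frame, frac_increased=0, frac_decreased=0,
                             seed=12)
        truth.extents[:] = 0.5
        design = [SampleDesign(f"s{i}", "wildtype", i, "wildtype")
                  for i in range(1, 201)]
        tight = oe.gen_counts(truth, design, depth=500, seed=13)
        wide = oe.gen_counts(truth, design, depth=500, seed=13, dispersion=0.05)
        assert wide.extent().to_numpy().var() > 2 * tight.extent().to_numpy().var()

    def test_seeded_determinism(self, small_truth):
        a = oe.gen_counts(small_truth, oe.default_design(), depth=300, seed=14)
        b = oe.gen_counts(small_truth, oe.default_design(), depth=300, seed=14)
        pd.testing.assert_frame_equal(a.edited, b.edited)


class TestGenReads:
    def test_byte_identical_for_fixed_seed(self, small_truth, tmp_path):
        intron = oe.default_intron()
        design = oe.default_design(replicates=1)
        p1 = oe.gen_reads(small_truth, design, intron, 200, site_depth=20,
                          seed=15, out_dir=tmp_path / "a")
        p2 = oe.gen_reads(small_truth, design, intron, 200, site_depth=20,
                          seed=15, out_dir=tmp_path / "b")
        for s in p1:
            assert p1[s].read_bytes() == p2[s].read_bytes()

    def test_degenerate_splicing_extremes(self, small_truth, tmp_path):
        design = oe.default_design(replicates=1,
                                   genotypes=("wildtype", "mutant"))
        intron = oe.default_intron({"wildtype": 1.0, "mutant": 0.0})
        paths = oe.gen_reads(small_truth, design, intron, 500, seed=16,
                             out_dir=tmp_path)
        s_wt, u_wt = oe.junction_counts(paths["wildtype-1"], intron)
        s_mut, u_mut = oe.junction_counts(paths["mutant-1"], intron)
        assert (s_wt, u_wt) == (500, 0)
        assert (s_mut, u_mut) == (0, 500)

    def test_truth_sidecars_written(self, small_truth, tmp_path):
        intron = oe.default_intron()
        oe.gen_reads(small_truth, oe.default_design(replicates=1), intron,
                     10, seed=17, out_dir=tmp_path)
        assert (tmp_path / "sites_truth.tsv").exists()
        intron_truth = pd.read_csv(tmp_path / "intron_truth.tsv", sep="\t")
        assert set(intron_truth["genotype"]) == {"wildtype", "mutant"}


def test_round_half_away_from_zero():
    assert _round_half_away(80.64) == 81
    assert _round_half_away(17.28) == 17
    assert _round_half_away(96.5) == 97
    assert _round_half_away(-2.5) == -3
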