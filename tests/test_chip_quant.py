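"""Spike-in normalization and fold-change grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfdelta import chip_quant as cq
from zfdelta import simgen
from zfdelta.chip_quant import ScaledTrack


def flat_track(value, nbins=100, bin_size=10, state="raw"):
    return ScaledTrack({"c": np.full(nbins, float(value))},
                       bin_size=bin_size, norm_state=state)


class TestRPGC:
    def test_constant_track_becomes_unit_mean(self):
        out = cq.normalize_rpgc(flat_track(3.0), effective_genome_size=1000)
        assert np.allclose(out.data["c"], 1.0)
        assert out.norm_state == "rpgc"

    def test_state_machine_rejects_reapplication(self):
        out = cq.normalize_rpgc(flat_track(3.0), 1000)
        with pytest.raises(ValueError, match="raw"):
            cq.normalize_rpgc(out, 1000)

    def test_random_track_mean_per_bp_is_one(self):
        rng = np.random.default_rng(0)
        track = ScaledTrack({"a": rng.random(500) * 7,
                             "b": rng.random(300) * 2}, bin_size=10)
        egs = 8000
        out = cq.normalize_rpgc(track, egs)
        mean_per_bp = out.total() * out.bin_size / egs
        assert mean_per_bp == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cq.normalize_rpgc(flat_track(0.0), 1000)


class TestSpikeProfileAndFactor:
    def test_single_peak_profile_equals_window(self):
        cov = np.zeros(200)
        cov[90:110] = np.arange(20)
        track = ScaledTrack({"spike": cov}, bin_size=10)
        prof = cq.spikein_meta_profile(track, "spike", [(900, 1100)],
                                       half_width=50)
        summit = 90 + int(np.argmax(cov[90:110]))
        np.testing.assert_array_equal(prof, cov[summit - 5:summit + 6])

    def test_two_identical_peaks_average_to_one_window(self):
        cov = np.zeros(400)
        for s in (100, 300):
            cov[s - 3:s + 4] = [1, 3, 7, 9, 7, 3, 1]
        track = ScaledTrack({"spike": cov}, bin_size=10)
        prof = cq.spikein_meta_profile(
            track, "spike", [(950, 1050), (2950, 3050)], half_width=50)
        np.testing.assert_array_equal(prof, cov[95:106])

    def test_profile_maximum_at_center_bin(self, default_sim):
        """Averaged over 200 simulated spike peaks, the summit sits at the
        window center (construction places summits at peak centers)."""
        cfg = default_sim["cfg"]
        prof = cq.spikein_meta_profile(
            default_sim["track_ref"], cfg.spike_contig,
            simgen.spike_peak_intervals(default_sim["truth"]),
            half_width=500)
        assert int(np.argmax(prof)) == len(prof) // 2

    def test_identical_profiles_give_unit_factor(self):
        prof = np.array([1.0, 5.0, 2.0])
        f = cq.compute_scale_factor(prof, prof)
        assert f.factors["ref"] == 1.0
        assert f.factors["alt"] == pytest.approx(1.0)

    def test_factor_is_summit_ratio(self):
        f = cq.compute_scale_factor(np.array([10.0, 100.0]),
                                    np.array([50.0, 20.0]))
        assert f.factors["alt"] == pytest.approx(2.0)

    def test_zero_summit_rejected(self):
        with pytest.raises(ValueError):
            cq.compute_scale_factor(np.zeros(3), np.ones(3))


class TestApplyScale:
    def test_factor_two_doubles_every_bin(self):
        track = flat_track(2.5, state="rpgc")
        f = cq.compute_scale_factor(np.array([100.0]), np.array([50.0]))
        out = cq.apply_scale(track, f, "alt")
        assert np.allclose(out.data["c"], 5.0)
        assert out.norm_state == "rpgc+scaled"
        assert out.applied_factor == 2.0

    def test_requires_rpgc_state(self):
        f = cq.compute_scale_factor(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            cq.apply_scale(flat_track(1.0, state="raw"), f, "alt")
        with pytest.raises(KeyError):
            cq.apply_scale(flat_track(1.0, state="rpgc"), f, "nope")

    def test_scale_factor_idempotent_after_scaling(self, default_sim,
                                                   chip_chain):
        """Recomputing spike factors on already-scaled tracks gives ~1."""
        cfg = default_sim["cfg"]
        spikes = simgen.spike_peak_intervals(default_sim["truth"])
        prof_ref = cq.spikein_meta_profile(chip_chain["scaled_ref"],
                                           cfg.spike_contig, spikes, 500)
        prof_alt = cq.spikein_meta_profile(chip_chain["scaled_alt"],
                                           cfg.spike_contig, spikes, 500)
        f = cq.compute_scale_factor(prof_ref, prof_alt)
        assert f.factors["alt"] == pytest.approx(1.0, rel=0.05)


class TestQuantify:
    def make_tracks(self, ref_vals, alt_vals):
        return (ScaledTrack({"c": np.asarray(ref_vals, float)}, bin_size=10,
                            norm_state="rpgc+scaled"),
                ScaledTrack({"c": np.asarray(alt_vals, float)}, bin_size=10,
                            norm_state="rpgc+scaled"))

    def test_flat_peak_leftmost_summit(self):
        tr, ta = self.make_tracks([5.0] * 20, [5.0] * 20)
        peaks = pd.DataFrame([{"contig": "c", "start": 40, "end": 120}])
        t = cq.quantify_site_strength(tr, ta, peaks, epsilon=1e-6)
        assert t.loc[0, "strength_ref"] == 5.0
        assert t.loc[0, "strength_alt"] == 5.0
        assert t.loc[0, "summit"] == 0  # leftmost bin of the peak

    def test_quarter_coverage_gives_log2fc_two(self):
        ref = np.zeros(20); ref[10] = 8.0
        alt = np.zeros(20); alt[10] = 2.0
        tr, ta = self.make_tracks(ref, alt)
        peaks = pd.DataFrame([{"contig": "c", "start": 80, "end": 130}])
        t = cq.quantify_site_strength(tr, ta, peaks, epsilon=1e-9)
        assert t.loc[0, "log2fc"] == pytest.approx(2.0, abs=1e-6)

    def test_peak_outside_track_rejected(self):
        tr, ta = self.make_tracks([1.0] * 10, [1.0] * 10)
        peaks = pd.DataFrame([{"contig": "c", "start": 90, "end": 200}])
        with pytest.raises(ValueError, match="outside"):
            cq.quantify_site_strength(tr, ta, peaks)

    def test_simulated_u_site_log2fc_near_log2_five(self, default_sim,
                                                    chip_chain):
        """delta = 0.8 at U sites with equal depths: median U-site log2fc
        should sit near log2(5) = 2.32 after spike-in normalization."""
        table = chip_chain["table"]
        u = default_sim["truth"].sites["has_u"].values
        med = float(np.median(table["log2fc"].values[u]))
        assert med == pytest.approx(np.log2(5), abs=0.35)


class TestClassify:
    def test_hand_enumerated_quartiles(self):
        """8 sites split into rank quartiles of 2; downregulated = fc > 1."""
        fc = [-2, -1, 0, 0.2, 0.6, 0.9, 1.2, 2]
        t = pd.DataFrame({"contig": "c", "start": range(8),
                          "end": range(1, 9), "log2fc": fc})
        out = cq.classify_fc_groups(t)
        assert list(out["group"]) == [1, 1, 2, 2, 3, 3, 4, 4]
        assert list(out.loc[out["downregulated"], "log2fc"]) == [1.2, 2]

    def test_downregulation_threshold_is_strict(self):
        t = pd.DataFrame({"contig": "c", "start": range(4),
                          "end": range(1, 5),
                          "log2fc": [1.5, 0.0, 1.0, -1.0]})
        out = cq.classify_fc_groups(t)
        assert list(out["downregulated"]) == [True, False, False, False]

    def test_quartile_needs_four_sites(self):
        t = pd.DataFrame({"contig": "c", "start": [0, 1, 2],
                          "end": [1, 2, 3], "log2fc": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            cq.classify_fc_groups(t)

    def test_fixed_mode_thresholds(self):
        t = pd.DataFrame({"contig": "c", "start": range(4),
                          "end": range(1, 5),
                          "log2fc": [-1.0, 0.3, 0.8, 3.0]})
        out = cq.classify_fc_groups(t, mode="fixed",
                                    thresholds=[0.0, 0.5, 1.0])
        assert list(out["group"]) == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            cq.classify_fc_groups(t, mode="fixed", thresholds=[1.0, 0.5, 0.0])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=8,
                    max_size=40), st.randoms(use_true_random=False))
    def test_partition_and_order_invariance(self, fcs, rnd):
        """Groups partition the sites with sizes differing by <= 1, and
        permuting the input order never changes any site's group."""
        t = pd.DataFrame({"contig": "c", "start": range(len(fcs)),
                          "end": range(1, len(fcs) + 1), "log2fc": fcs})
        out = cq.classify_fc_groups(t)
        sizes = out["group"].value_counts()
        assert sizes.sum() == len(fcs)
        assert sizes.max() - sizes.min() <= 1
        perm = list(range(len(fcs)))
        rnd.shuffle(perm)
        out_perm = cq.classify_fc_groups(t.iloc[perm].reset_index(drop=True))
        merged = out_perm.set_index("start")["group"]
        for _, row in out.iterrows():
            assert merged[row["start"]] == row["group"]

    def test_recovery_of_planted_downregulation(self, default_sim,
                                                chip_chain):
        """{log2fc > 1} recovers the planted U-site set with precision and
        recall >= 0.9 at default noise."""
        table = chip_chain["table"]
        truth = default_sim["truth"]
        pred = table["log2fc"].values > 1
        true = truth.sites["has_u"].values
        tp = (pred & true).sum()
        assert tp / pred.sum() >= 0.9
        assert tp / true.sum() >= 0.9
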