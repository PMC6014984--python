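"""Statistical structure and determinism of the synthetic event generator."""

import numpy as np
import pytest
from scipy import stats

from mirsensor.fit import bin_events, default_bin_edges
from mirsensor.model import MiRNAActivity
from mirsensor.simulate import (CellLineProfile, DesignInput, NoiseModel,
                                SensorDesign, sample_plasmid_counts,
                                simulate_coculture, simulate_sensor_events)

HIGH = MiRNAActivity("miR-X", "line", M=600.0, K_m=30.0)
PROFILE = CellLineProfile("line", {"miR-X": HIGH})
SINGLE = SensorDesign((DesignInput("miR-X", "three_prime"),), "single")
NEG = SensorDesign((), "neg")


class TestPlasmidCounts:
    def test_degenerate_spread_gives_constant(self):
        counts = sample_plasmid_counts(100, 50.0, 1.0, seed=0)
        np.testing.assert_allclose(counts, 50.0)

    def test_geometric_sd_is_log_sd(self):
        counts = sample_plasmid_counts(100_000, 100.0, 2.8, seed=1)
        assert np.std(np.log(counts)) == pytest.approx(np.log(2.8), rel=0.02)
        assert np.median(counts) == pytest.approx(100.0, rel=0.05)

    def test_seed_determinism(self):
        np.testing.assert_array_equal(
            sample_plasmid_counts(1000, 100.0, 2.8, seed=7),
            sample_plasmid_counts(1000, 100.0, 2.8, seed=7))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_plasmid_counts(0, 100.0, 2.8, seed=0)
        with pytest.raises(ValueError):
            sample_plasmid_counts(10, 100.0, 0.9, seed=0)


class TestSensorEvents:
    def test_byte_identical_for_same_seed(self, rates):
        a = simulate_sensor_events(SINGLE, PROFILE, rates, NoiseModel(),
                                   1000, 3)
        b = simulate_sensor_events(SINGLE, PROFILE, rates, NoiseModel(),
                                   1000, 3)
        assert a.to_csv() == b.to_csv()

    def test_zero_input_design_matches_negative_control(self, rates):
        ev0 = simulate_sensor_events(SensorDesign((), "null"), PROFILE, rates,
                                     NoiseModel(), 10_000, 11)
        evn = simulate_sensor_events(NEG, PROFILE, rates, NoiseModel(),
                                     10_000, 12)
        _, p = stats.mannwhitneyu(np.log(ev0["mkate2"]), np.log(evn["mkate2"]))
        assert p > 0.01

    def test_marker_channel_ignores_mirna_activity(self, rates):
        # same seed, wildly different activity: EBFP2 draws are identical
        ev_rep = simulate_sensor_events(SINGLE, PROFILE, rates, NoiseModel(),
                                        2000, 21)
        ev_neg = simulate_sensor_events(NEG, PROFILE, rates, NoiseModel(),
                                        2000, 21)
        np.testing.assert_array_equal(ev_rep["ebfp2"], ev_neg["ebfp2"])
        assert not np.allclose(ev_rep["mkate2"], ev_neg["mkate2"])

    def test_antagonistic_duplicate_inputs_match_single_input(self, rates):
        duo = SensorDesign((DesignInput("miR-X", "three_prime"),
                            DesignInput("miR-X", "three_prime")), "duo")
        ev1 = simulate_sensor_events(SINGLE, PROFILE, rates, NoiseModel(),
                                     50_000, 31, truth_rule="antagonistic")
        ev2 = simulate_sensor_events(duo, PROFILE, rates, NoiseModel(),
                                     50_000, 31, truth_rule="antagonistic")
        edges = default_bin_edges(ev1)
        c1 = bin_events(ev1, edges)
        c2 = bin_events(ev2, edges)
        shared, i1, i2 = np.intersect1d(c1.bin_index, c2.bin_index,
                                        return_indices=True)
        np.testing.assert_allclose(c1.mkate2[i1], c2.mkate2[i2], rtol=1e-9)

    def test_ant_syn_one_per_utr_multiplies_fold_repressions(self, rates):
        both = SensorDesign((DesignInput("miR-X", "five_prime"),
                             DesignInput("miR-X", "three_prime")), "both")
        ev_neg = simulate_sensor_events(NEG, PROFILE, rates, NoiseModel(),
                                        50_000, 41)
        ev_one = simulate_sensor_events(SINGLE, PROFILE, rates, NoiseModel(),
                                        50_000, 42)
        ev_two = simulate_sensor_events(both, PROFILE, rates, NoiseModel(),
                                        50_000, 43)
        edges = default_bin_edges(ev_neg)
        cn = bin_events(ev_neg, edges)
        c1 = bin_events(ev_one, edges)
        c2 = bin_events(ev_two, edges)
        shared = np.intersect1d(np.intersect1d(cn.bin_index, c1.bin_index),
                                c2.bin_index)
        # restrict to bins with clear signal above background
        sel_n = np.isin(cn.bin_index, shared)
        sel_1 = np.isin(c1.bin_index, shared)
        sel_2 = np.isin(c2.bin_index, shared)
        bg = 5.0
        neg = cn.mkate2[sel_n] - bg
        one = c1.mkate2[sel_1] - bg
        two = c2.mkate2[sel_2] - bg
        ok = (two > 5.0) & (one > 5.0)
        fold_one = neg[ok] / one[ok]
        fold_two = neg[ok] / two[ok]
        np.testing.assert_allclose(np.log10(fold_two),
                                   np.log10(fold_one ** 2), atol=0.15)

    def test_missing_activity_names_the_mirna(self, rates):
        design = SensorDesign((DesignInput("miR-absent", "three_prime"),), "x")
        with pytest.raises(KeyError, match="miR-absent"):
            simulate_sensor_events(design, PROFILE, rates, NoiseModel(),
                                   100, 0)


class TestCoculture:
    def make_profiles(self):
        weak = CellLineProfile(
            "weak", {"miR-X": MiRNAActivity("miR-X", "weak", M=600.0,
                                            K_m=6000.0)},
            lineage_marker_on=True)
        return [(weak, 5000), (CellLineProfile(
            "strong", {"miR-X": HIGH}), 5000)]

    def test_single_profile_equals_plain_simulation(self, rates):
        table = simulate_coculture([(PROFILE, 1000)], SINGLE, rates,
                                   NoiseModel(), 5)
        assert set(table["lineage_label"]) == {"line"}
        assert len(table) == 1000

    def test_mixture_proportions(self, rates):
        table = simulate_coculture(self.make_profiles(), SINGLE, rates,
                                   NoiseModel(), 6)
        frac = np.mean(table["lineage_label"] == "weak")
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_high_activity_line_is_repressed_at_matched_bins(self, rates):
        table = simulate_coculture(self.make_profiles(), SINGLE, rates,
                                   NoiseModel(), 7)
        weak = table[table["lineage_label"] == "weak"]
        strong = table[table["lineage_label"] == "strong"]
        edges = default_bin_edges(table)
        cw = bin_events(weak, edges, min_count=50)
        cs = bin_events(strong, edges, min_count=50)
        shared, iw, is_ = np.intersect1d(cw.bin_index, cs.bin_index,
                                         return_indices=True)
        assert np.all(cs.mkate2[is_] < cw.mkate2[iw])

    def test_lineage_marker_separates_lines(self, rates):
        table = simulate_coculture(self.make_profiles(), SINGLE, rates,
                                   NoiseModel(), 8)
        on = table[table["lineage_label"] == "weak"]["eyfp"]
        off = table[table["lineage_label"] == "strong"]["eyfp"]
        assert np.median(on) > 100 * np.median(off)

    def test_coculture_determinism(self, rates):
        a = simulate_coculture(self.make_profiles(), SINGLE, rates,
                               NoiseModel(), 9)
        b = simulate_coculture(self.make_profiles(), SINGLE, rates,
                               NoiseModel(), 9)
        assert a.to_csv() == b.to_csv()
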