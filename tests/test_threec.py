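"""3C digestion, BAC normalization, relative profiles and loop calling."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locuspipe import simulate as sim
from locuspipe import threec as c3


class TestDigestion:
    def test_single_site_manual_enumeration(self):
        fmap = c3.digest_sequence("AAACCATGGTTT")
        assert [f.length for f in fmap.fragments] == [4, 8]
        assert (fmap.fragments[0].start, fmap.fragments[0].end) == (0, 4)

    def test_no_site_gives_whole_sequence(self):
        fmap = c3.digest_sequence("ACGTACGTACGT")
        assert len(fmap) == 1
        assert fmap.fragments[0].length == 12

    def test_ambiguous_bases_do_not_match(self):
        # an N inside the motif breaks strict matching
        assert len(c3.digest_sequence("AAACCNTGGTTT")) == 1

    def test_concatenation_doubles_sites(self):
        unit = "ACGTCCATGGAAATTTCCATGGCCC"
        single = c3.digest_sequence(unit)
        double = c3.digest_sequence(unit * 2)
        assert len(double) == 2 * len(single) - 1

    @given(st.text(alphabet="ACGT", min_size=10, max_size=2000))
    @settings(derandomize=True, max_examples=200)
    def test_matches_regex_oracle_and_reconstructs(self, seq):
        fmap = c3.digest_sequence(seq)
        oracle_cuts = [m.start() + 1 for m in re.finditer("(?=CCATGG)", seq)]
        assert [f.start for f in fmap.fragments[1:]] == oracle_cuts
        assert len(fmap) == len(oracle_cuts) + 1
        # fragment intervals reconstruct the sequence exactly
        assert "".join(seq[f.start:f.end] for f in fmap.fragments) == seq

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            c3.digest_sequence("")

    def test_fasta_path_input(self, tmp_path):
        fa = tmp_path / "locus.fa"
        fa.write_text(">toy synthetic locus\nAAACCATGGTTT\n")
        assert [f.length for f in c3.digest_sequence(fa).fragments] == [4, 8]


class TestRestrictionEfficiency:
    def test_arithmetic(self):
        eff = c3.restriction_efficiency(
            {"s1": 0.0, "s2": 10.0, "s3": 3.5}, reference_pg=10.0)
        assert eff["s1"] == pytest.approx(1.0)
        assert eff["s2"] == pytest.approx(0.0)
        assert eff["s3"] == pytest.approx(0.65)  # inside the typical 60-70% band

    def test_excess_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            eff = c3.restriction_efficiency({"s": 12.0}, reference_pg=10.0)
        assert eff["s"] == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            c3.restriction_efficiency({"s": 1.0}, reference_pg=0.0)


class TestNormalization:
    def test_primer_bias_cancels_exactly(self, locus_fragment_map):
        bias = {"f002": 4.0, "f005": 0.25, "f009": 2.0}
        base = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                  anchor="f003", seed=0)
        biased = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                    anchor="f003", primer_bias=bias, seed=0)
        noise = sim.QpcrNoiseModel(ct_sd=0.0)
        norm_base = c3.normalize_junctions(*sim.make_3c_tables(base, noise))
        norm_bias = c3.normalize_junctions(*sim.make_3c_tables(biased, noise))
        np.testing.assert_allclose(norm_bias["normalized"],
                                   norm_base["normalized"], rtol=1e-6)

    def test_sample_equal_to_bac_is_flat(self, locus_fragment_map):
        scen = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                  anchor="f003", seed=0)
        _, bac, dil = sim.make_3c_tables(scen, sim.QpcrNoiseModel(ct_sd=0.0))
        sample = bac.assign(sample="sample")
        norm = c3.normalize_junctions(sample, bac, dil)
        np.testing.assert_allclose(norm["normalized"], 1.0, rtol=1e-9)

    def test_mismatched_fragments_rejected(self, locus_fragment_map):
        scen = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                  anchor="f003", seed=0)
        sp, bp, dl = sim.make_3c_tables(scen, sim.QpcrNoiseModel())
        with pytest.raises(ValueError, match="not shared"):
            c3.normalize_junctions(sp[sp["fragment"] != "f007"], bp, dl)


class TestRelativeProfile:
    def test_uniform_frequencies_are_all_one(self, locus_fragment_map):
        freq = {f.id: 3.7 for f in locus_fragment_map.fragments
                if f.id != "f003"}
        prof = c3.relative_profile(freq, locus_fragment_map, "f003")
        np.testing.assert_allclose(prof.table["relative"], 1.0)

    def test_reference_is_closest_3prime_and_unity(self, locus_fragment_map):
        scen = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                  anchor="f003", seed=0)
        norm = c3.normalize_junctions(
            *sim.make_3c_tables(scen, sim.QpcrNoiseModel(ct_sd=0.0)))
        prof = c3.relative_profile(norm, locus_fragment_map, "f003")
        assert prof.reference == "f004"
        ref_rel = prof.table.loc[prof.table["fragment"] == "f004", "relative"]
        assert float(ref_rel.iloc[0]) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, locus_fragment_map):
        freq = {f.id: 1.0 / (1 + i)
                for i, f in enumerate(locus_fragment_map.fragments)
                if f.id != "f003"}
        a = c3.relative_profile(freq, locus_fragment_map, "f003")
        b = c3.relative_profile({k: 100.0 * v for k, v in freq.items()},
                                locus_fragment_map, "f003")
        np.testing.assert_allclose(a.table["relative"], b.table["relative"],
                                   rtol=1e-12)

    def test_pure_decay_is_monotone_beyond_reference(self, locus_fragment_map):
        scen = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                  anchor="f003", background_alpha=1.3, seed=0)
        norm = c3.normalize_junctions(
            *sim.make_3c_tables(scen, sim.QpcrNoiseModel(ct_sd=0.0)))
        t = c3.relative_profile(norm, locus_fragment_map, "f003").table
        downstream = t[t["distance"] > 0].sort_values("distance")
        assert downstream["relative"].is_monotonic_decreasing

    def test_3prime_most_anchor_rejected(self, locus_fragment_map):
        last = locus_fragment_map.fragments[-1].id
        freq = {f.id: 1.0 for f in locus_fragment_map.fragments if f.id != last}
        with pytest.raises(ValueError, match="3' side"):
            c3.relative_profile(freq, locus_fragment_map, last)


class TestPeakCalling:
    def profile_for(self, scenario, ct_sd=0.0):
        norm = c3.normalize_junctions(
            *sim.make_3c_tables(scenario, sim.QpcrNoiseModel(ct_sd=ct_sd)))
        return c3.relative_profile(norm, scenario.fragment_map,
                                   scenario.anchor)

    def test_loop_partner_recovered_noise_free(self, locus_fragment_map):
        scen = sim.ThreeCScenario(
            fragment_map=locus_fragment_map, anchor="f003",
            loops=[("f003", "f009", 5.0)], primer_bias={"f009": 0.5}, seed=0)
        peaks = c3.detect_interaction_peaks(self.profile_for(scen))
        assert peaks == [["f009"]]

    def test_two_disjoint_loops_give_two_regions(self, locus_fragment_map):
        scen = sim.ThreeCScenario(
            fragment_map=locus_fragment_map, anchor="f003",
            loops=[("f003", "f007", 6.0), ("f003", "f012", 6.0)], seed=0)
        peaks = c3.detect_interaction_peaks(self.profile_for(scen))
        assert [r[0] for r in peaks] == ["f007", "f012"]

    def test_noisy_loop_recovery_rate(self, locus_fragment_map):
        # fold-3 loop, 0.3-cycle noise: partner called in >= 90% of seeds
        hits = 0
        for seed in range(200):
            scen = sim.ThreeCScenario(
                fragment_map=locus_fragment_map, anchor="f003",
                loops=[("f003", "f009", 3.0)], seed=seed)
            peaks = c3.detect_interaction_peaks(
                self.profile_for(scen, ct_sd=0.3))
            hits += any("f009" in region for region in peaks)
        assert hits >= 180

    def test_no_loop_rarely_calls_anything(self, locus_fragment_map):
        false_calls = 0
        for seed in range(100):
            scen = sim.ThreeCScenario(fragment_map=locus_fragment_map,
                                      anchor="f003", seed=seed)
            if c3.detect_interaction_peaks(self.profile_for(scen, ct_sd=0.3)):
                false_calls += 1
        assert false_calls <= 5
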