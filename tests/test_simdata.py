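"""Simulator tests: motif truth against a regex oracle, noise-free limits,
Monte-Carlo shift recovery, distributional WGA equivalence, and fixture
round-trips."""

import re

import numpy as np
import pytest
from scipy import stats

from smrtkin import kinetics_io
from smrtkin.simdata import (IUPAC, GroundTruthKinetics, MethylationTruth,
                             SimConfig, find_motif_sites, generate_genome,
                             read_truth_bed, reverse_complement,
                             simulate_dataset, simulate_kinetics, write_fixture)


def _iupac_regex(motif: str) -> str:
    return "".join("[" + "".join(sorted(IUPAC[c])) + "]" for c in motif)


class TestGenerateGenome:
    def test_motif_truth_matches_regex_oracle(self):
        cfg = SimConfig(genome_length=8000, motif="CCWGG", mod_offset=1,
                        methyl_fraction=1.0, seed=2)
        seq, truth = generate_genome(cfg)
        plus = {m.start() + 1 for m in
                re.finditer("(?=" + _iupac_regex("CCWGG") + ")", seq)}
        minus = {m.start() + 3 for m in
                 re.finditer("(?=" + _iupac_regex(reverse_complement("CCWGG")) + ")", seq)}
        got_plus = {s.pos for s in truth.sites if s.strand == "+"}
        got_minus = {s.pos for s in truth.sites if s.strand == "-"}
        assert got_plus == plus
        assert got_minus == minus

    def test_gatc_modified_base_is_the_adenine(self):
        cfg = SimConfig(genome_length=5000, motif="GATC", mod_offset=1, seed=3)
        seq, truth = generate_genome(cfg)
        assert len(truth) > 0
        for s in truth.sites:
            base = seq[s.pos] if s.strand == "+" else reverse_complement(seq[s.pos])
            assert base == "A"

    def test_zero_methyl_fraction_yields_empty_truth(self):
        cfg = SimConfig(genome_length=5000, methyl_fraction=0.0, seed=1)
        _, truth = generate_genome(cfg)
        assert len(truth) == 0

    def test_methyl_fraction_site_count(self):
        cfg = SimConfig(genome_length=8000, motif="GATC", mod_offset=1,
                        methyl_fraction=0.5, seed=4)
        seq, truth = generate_genome(cfg)
        n_all = len(find_motif_sites(seq, "GATC", 1))
        assert len(truth) == round(0.5 * n_all)

    def test_determinism_per_seed(self):
        cfg = SimConfig(genome_length=3000, seed=9)
        a = generate_genome(cfg)
        b = generate_genome(cfg)
        assert a[0] == b[0]
        assert a[1].sites == b[1].sites

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(motif="CXWGG")
        with pytest.raises(ValueError):
            SimConfig(mod_offset=9)
        with pytest.raises(ValueError):
            SimConfig(context_k=4)
        with pytest.raises(ValueError):
            SimConfig(coverage_mean=0.5)
        with pytest.raises(ValueError):
            SimConfig(genome_length=3, motif="CCWGG")


class TestGroundTruthKinetics:
    def test_same_kmer_same_value_and_determinism(self):
        gt1 = GroundTruthKinetics(5, seed=11)
        gt2 = GroundTruthKinetics(5, seed=11)
        assert gt1.lookup("ACGTA") == gt2.lookup("ACGTA")
        assert gt1.lookup("ACGTA") == gt1.lookup("ACGTA")
        assert gt1.lookup("ACGTA") != GroundTruthKinetics(5, seed=12).lookup("ACGTA")

    def test_values_positive(self):
        gt = GroundTruthKinetics(5, seed=13)
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, size=(500, 5))
        ipd, pw = gt.values_for_codes(codes)
        assert np.all(ipd > 0) and np.all(pw > 0)


class TestSimulateKinetics:
    def test_wga_mode_noiseless_equals_table(self):
        cfg = SimConfig(genome_length=500, methyl_fraction=0.0, context_k=5,
                        subread_noise_sigma=0.0, coverage_mean=1, seed=5)
        seq, truth, kin = simulate_dataset(cfg)
        gt = GroundTruthKinetics.from_config(cfg)
        p = 137
        kmer = seq[p - 2: p + 3]
        ipd, pw = gt.lookup(kmer)
        assert kin.ipd_noiseless["+"][p] == pytest.approx(ipd)
        assert kin.ipd["+"][p] == pytest.approx(ipd)  # noise-free limit
        assert kin.pw["+"][p] == pytest.approx(pw)
        # minus strand uses the reverse-complement context
        ipd_m, _ = gt.lookup(reverse_complement(kmer))
        assert kin.ipd["-"][p] == pytest.approx(ipd_m)

    def test_edge_positions_flagged_invalid(self):
        cfg = SimConfig(genome_length=200, context_k=7, seed=6)
        _, _, kin = simulate_dataset(cfg)
        assert not kin.valid[:3].any() and not kin.valid[-3:].any()
        assert kin.valid[3:-3].all()
        assert np.isnan(kin.ipd["+"][0]) and np.isnan(kin.ipd["+"][-1])

    def test_shift_locality_exact(self):
        """Positions beyond the largest configured offset are unshifted."""
        cfg = SimConfig(genome_length=4000, motif="GATC", mod_offset=1,
                        methyl_fraction=1.0, context_k=5, seed=7,
                        subread_noise_sigma=0.0, coverage_mean=1,
                        ipd_shift={0: 2.0, 1: 1.5}, pw_shift={0: 1.3})
        seq, truth, kin = simulate_dataset(cfg)
        wga = SimConfig(**{**cfg.to_dict(), "methyl_fraction": 0.0})
        kin0 = simulate_kinetics(seq, MethylationTruth([]), wga)
        for strand in "+-":
            ratio = kin.ipd_noiseless[strand] / kin0.ipd_noiseless[strand]
            shifted = {s.pos + off if strand == "+" else s.pos - off
                       for s in truth.sites if s.strand == strand
                       for off in (0, 1)}
            for p in range(3, cfg.genome_length - 3):
                if p not in shifted:
                    assert ratio[p] == pytest.approx(1.0, abs=1e-12)
                else:
                    assert ratio[p] > 1.0

    def test_monte_carlo_shift_recovery(self):
        """Mean of ~10k subread draws at a methylated site over a matched
        unmethylated same-context site recovers the multiplicative shift."""
        unit = "AACGGATCGTCCTTAG"  # one GATC per repeat unit
        seq = unit * 40
        cfg = SimConfig(genome_length=len(seq), motif="GATC", mod_offset=1,
                        context_k=5, subread_noise_sigma=0.2,
                        coverage_mean=10000, seed=8, ipd_shift={0: 2.0},
                        pw_shift={})
        sites = find_motif_sites(seq, "GATC", 1)
        plus_sites = [s for s in sites if s.strand == "+"]
        # methylate alternate units only
        truth = MethylationTruth(plus_sites[::2])
        kin = simulate_kinetics(seq, truth, cfg)
        met = np.array([kin.ipd["+"][s.pos] for s in plus_sites[::2]])
        unmet = np.array([kin.ipd["+"][s.pos] for s in plus_sites[1::2]])
        ratio = met.mean() / unmet.mean()
        # relative s.e. of each mean ~ sigma/sqrt(n_draws_total)
        n_total = 10000 * len(met)
        se = 2.0 * 0.2 * np.sqrt(2.0 / n_total)
        assert abs(ratio - 2.0) < 3 * se + 1e-3

    def test_wga_distributional_equivalence_at_fixed_context(self):
        """At a fixed k-mer context, unmethylated sites of a methylated
        genome and WGA sites share the generating distribution (KS test)."""
        unit = "AACGGATCGTCCTTAG"
        seq = unit * 70
        base = dict(genome_length=len(seq), motif="GATC", mod_offset=1,
                    context_k=5, subread_noise_sigma=0.25, coverage_mean=3,
                    chemistry_seed=55, ipd_shift={0: 2.5}, pw_shift={0: 1.4})
        plus_sites = [s for s in find_motif_sites(seq, "GATC", 1)
                      if s.strand == "+"]
        native_cfg = SimConfig(**base, seed=20)
        wga_cfg = SimConfig(**base, seed=21)
        native = simulate_kinetics(seq, MethylationTruth(plus_sites[::2]), native_cfg)
        wga = simulate_kinetics(seq, MethylationTruth([]), wga_cfg)
        unmet_native = np.array([native.ipd["+"][s.pos] for s in plus_sites[1::2]])
        wga_vals = np.array([wga.ipd["+"][s.pos] for s in plus_sites[1::2]])
        assert stats.ks_2samp(unmet_native, wga_vals).pvalue > 0.001

    def test_determinism(self):
        cfg = SimConfig(genome_length=1500, seed=30)
        a = simulate_dataset(cfg)[2]
        b = simulate_dataset(cfg)[2]
        np.testing.assert_array_equal(a.ipd["+"], b.ipd["+"])
        np.testing.assert_array_equal(a.n_subreads["-"], b.n_subreads["-"])


class TestFixtureRoundTrip:
    def test_write_then_read_is_lossless_to_printed_precision(self, tmp_path):
        cfg = SimConfig(genome_length=2000, motif="GATC", mod_offset=1,
                        methyl_fraction=0.7, seed=31)
        seq, truth, kin = simulate_dataset(cfg)
        paths = write_fixture(tmp_path, seq, truth, kin, cfg)
        genome = kinetics_io.read_genome(paths["fasta"])
        assert genome[cfg.contig] == seq
        table = kinetics_io.read_kinetics(paths["kinetics"])
        orig = kin.to_table()
        assert len(table) == len(orig)
        np.testing.assert_array_equal(table["pos0"], orig["pos0"])
        np.testing.assert_allclose(table["ipd_mean"], orig["ipd_mean"], atol=1e-6)
        np.testing.assert_allclose(table["pw_mean"], orig["pw_mean"], atol=1e-6)
        truth2 = read_truth_bed(paths["bed"])
        assert truth2.site_keys() == truth.site_keys()
        assert len(truth2) == len(truth)

    def test_bed_intervals_are_width_one_half_open(self, tmp_path):
        cfg = SimConfig(genome_length=2000, motif="GATC", mod_offset=1, seed=32)
        seq, truth, kin = simulate_dataset(cfg)
        paths = write_fixture(tmp_path, seq, truth, kin, cfg)
        for line in open(paths["bed"]):
            _, start, end, _, _, strand = line.split("\t")
            assert int(end) - int(start) == 1
            assert strand.strip() in "+-"

    def test_byte_identical_fixtures_for_identical_config(self, tmp_path):
        cfg = SimConfig(genome_length=1200, seed=33)
        for d in ("a", "b"):
            seq, truth, kin = simulate_dataset(cfg)
            write_fixture(tmp_path / d, seq, truth, kin, cfg)
        for name in ("genome.fasta", "kinetics.tsv", "truth.bed", "sim_config.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
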