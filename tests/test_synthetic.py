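import math

import numpy as np
import pandas as pd
import pytest

from rbpkit import kmers, synthetic
from rbpkit.synthetic import (
    BindingModel,
    ConfigurationError,
    SelectionConfig,
    generate_input_pool,
    read_binding_probability,
    simulate_array_table,
    simulate_blot_table,
    simulate_selection,
)


class TestBindingModel:
    def test_rejects_mixed_lengths(self):
        with pytest.raises(ConfigurationError):
            BindingModel({"ACGU": 2.0, "ACGUA": 2.0})

    def test_rejects_background_above_motifs(self):
        with pytest.raises(ConfigurationError):
            BindingModel({"ACGU": 2.0}, background_affinity=3.0)

    def test_rejects_nonpositive_affinity(self):
        with pytest.raises(ConfigurationError):
            BindingModel({"ACGU": 0.0})

    def test_normalizes_dna_dialect_keys(self):
        model = BindingModel({"ACGT": 2.0})
        assert "ACGU" in model.motif_affinities

    def test_read_affinity_background(self, planted_model):
        assert planted_model.read_affinity("A" * 40) == 1.0

    def test_read_affinity_motif(self, planted_model, planted_kmer):
        read = "A" * 10 + planted_kmer + "A" * 22
        assert planted_model.read_affinity(read) == 100.0

    def test_combine_rule_sum(self, planted_kmer):
        model = BindingModel({planted_kmer: 100.0}, combine_rule="sum")
        read = planted_kmer + "AAAA" + planted_kmer
        assert model.read_affinity(read) == 200.0

    def test_combine_rule_max(self, planted_kmer):
        model = BindingModel({planted_kmer: 100.0}, combine_rule="max")
        read = planted_kmer + "AAAA" + planted_kmer
        assert model.read_affinity(read) == 100.0

    def test_graded_model_is_monotone(self, planted_kmer):
        model = synthetic.graded_binding_model(planted_kmer)
        affs = list(model.motif_affinities.values())
        assert affs[0] == max(affs)
        assert model.motif_affinities[planted_kmer] == affs[0]
        assert min(affs) >= model.background_affinity


class TestSelectionConfig:
    def test_requires_zero_control(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(protein_concentrations=(100.0,))

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(n_input_reads=0)

    def test_read_length_must_fit_motif(self, planted_model):
        cfg = SelectionConfig(read_length=4)
        with pytest.raises(ConfigurationError):
            cfg.validate_model(planted_model)


class TestGenerateInputPool:
    def test_length_and_alphabet_contract(self):
        cfg = SelectionConfig(n_input_reads=1, read_length=4, seed=3)
        pool = generate_input_pool(cfg)
        assert len(pool) == 1
        assert len(pool.reads[0]) == 4
        assert set(pool.reads[0]) <= set("ACGU")

    def test_base_composition_uniform(self):
        # binomial CI at n = 100_000 * 40 positions: each base in [0.24, 0.26]
        cfg = SelectionConfig(n_input_reads=100_000, read_length=40, seed=11)
        pool = generate_input_pool(cfg)
        freqs = np.bincount(pool.codes.ravel(), minlength=4) / pool.codes.size
        assert freqs.min() > 0.24 and freqs.max() < 0.26

    def test_determinism(self):
        cfg = SelectionConfig(n_input_reads=50, read_length=10, seed=9)
        a, b = generate_input_pool(cfg), generate_input_pool(cfg)
        assert np.array_equal(a.codes, b.codes)


class TestReadBindingProbability:
    def test_zero_protein_gives_zero(self, planted_model):
        assert read_binding_probability("A" * 40, planted_model, 0.0) == 0.0

    def test_langmuir_half_occupancy(self):
        # background affinity 1 at the 100 nM reference: x = 1 -> p = 0.5
        model = BindingModel({"ACGUACGU": 2.0}, background_affinity=1.0)
        assert read_binding_probability("A" * 40, model, 100.0) == pytest.approx(0.5)

    def test_ratio_decreases_with_concentration(self, planted_model, planted_kmer):
        motif_read = planted_kmer + "A" * 32
        bg_read = "A" * 40
        ratios = [
            read_binding_probability(motif_read, planted_model, c)
            / read_binding_probability(bg_read, planted_model, c)
            for c in (10.0, 50.0, 100.0, 500.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_monotone_in_concentration(self, planted_model):
        ps = [read_binding_probability("A" * 40, planted_model, c) for c in (1, 10, 100, 1000)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1.0

    def test_rejects_bad_characters(self, planted_model):
        with pytest.raises(ValueError):
            read_binding_probability("ACGN" * 10, planted_model, 100.0)


class TestSimulateSelection:
    def test_neutral_model_preserves_frequencies(self, small_input_pool):
        neutral = BindingModel({"ACGUACGU": 1.0}, background_affinity=1.0)
        out = simulate_selection(small_input_pool, neutral, 100.0, 5000, seed=5)
        f_in = kmers.count_kmers(small_input_pool, 1).frequencies()
        f_out = kmers.count_kmers(out, 1).frequencies()
        assert np.abs(f_in - f_out).max() < 0.02

    def test_planted_kmer_enriched(self, small_input_pool, planted_model, planted_kmer):
        out = simulate_selection(small_input_pool, planted_model, 100.0, 5000, seed=6)
        k = len(planted_kmer)
        f_in = kmers.count_kmers(small_input_pool, k).frequencies()
        f_out = kmers.count_kmers(out, k).frequencies()
        from rbpkit.sequtils import kmer_to_index

        idx = kmer_to_index(planted_kmer)
        assert f_out[idx] > f_in[idx]

    def test_zero_protein_is_uniform_background(self, small_input_pool, planted_model):
        out = simulate_selection(small_input_pool, planted_model, 0.0, 5000, seed=7)
        f_in = kmers.count_kmers(small_input_pool, 1).frequencies()
        f_out = kmers.count_kmers(out, 1).frequencies()
        assert np.abs(f_in - f_out).max() < 0.02

    def test_determinism(self, small_input_pool, planted_model):
        a = simulate_selection(small_input_pool, planted_model, 100.0, 1000, seed=8)
        b = simulate_selection(small_input_pool, planted_model, 100.0, 1000, seed=8)
        assert np.array_equal(a.codes, b.codes)
        assert a.label == "100nM"


class TestZeroProteinNeutrality:
    def test_r_values_within_binomial_bound(self, planted_model):
        # expected R = 1 for every k-mer at 0 nM; |R - 1| <= 5 binomial SEs
        cfg = SelectionConfig(n_input_reads=50_000, n_pulldown_reads=50_000, seed=21)
        inp = generate_input_pool(cfg)
        out = simulate_selection(inp, planted_model, 0.0, cfg.n_pulldown_reads, seed=22)
        k = 6
        t_in = kmers.count_kmers(inp, k)
        t_out = kmers.count_kmers(out, k)
        table = kmers.compute_enrichment(t_out, t_in, pseudocount=1.0)
        p = 4.0**-k
        se = np.sqrt((1 - p) / (p * t_out.total_positions) + (1 - p) / (p * t_in.total_positions))
        assert np.abs(table.R - 1).max() <= 5 * se


class TestFastqFasta:
    def test_single_read_record(self, tmp_path):
        pool = synthetic.ReadPool.from_strings("x", ["ACGU"])
        path = tmp_path / "x.fastq"
        synthetic.write_fastq(pool, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == "@read_0"
        assert lines[1] == "ACGU"
        assert lines[3] == "IIII"  # constant per-base quality

    def test_roundtrip_preserves_order(self, tmp_path, small_input_pool):
        path = tmp_path / "pool.fastq"
        synthetic.write_fastq(small_input_pool, path)
        back = synthetic.read_pool(path)
        assert back.reads == small_input_pool.reads

    def test_dna_flag_maps_u_to_t(self, tmp_path):
        pool = synthetic.ReadPool.from_strings("x", ["ACGU"])
        path = tmp_path / "x.fasta"
        synthetic.write_fasta(pool, path, dna=True)
        assert "ACGT" in path.read_text()
        assert synthetic.read_pool(path).reads == ["ACGU"]


class TestSimulateArrayTable:
    PROBES = [
        ("p1", 0, 1000, "geneA", False),
        ("p2", 1000, 2000, "geneB", False),
        ("p3", 2000, 3000, "rrn", True),
    ]

    def test_noise_free_factor_one_gives_equality(self):
        wt, ctl = simulate_array_table(3000, self.PROBES, [], [], n_replicates=2, noise_sd=0.0, seed=1)
        assert np.allclose(wt["F635"], wt["F532"])
        assert np.allclose(ctl["F635"], ctl["F532"])

    def test_noise_free_planted_factor_exact(self):
        wt, ctl = simulate_array_table(
            3000, self.PROBES, [(0, 1000)], [10.0], n_replicates=2, noise_sd=0.0, seed=2
        )
        p1 = wt[wt["probe_id"] == "p1"]
        assert np.allclose(p1["F635"], 10.0 * p1["F532"])
        # control always has factor 1
        c1 = ctl[ctl["probe_id"] == "p1"]
        assert np.allclose(c1["F635"], c1["F532"])

    def test_probe_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_array_table(500, self.PROBES, [], [], seed=3)

    def test_enrichment_ranking_recovered(self):
        from rbpkit import ripchip

        regions = [(0, 1000), (1000, 2000)]
        factors = [8.0, 3.0]
        wt, ctl = simulate_array_table(
            3000, self.PROBES, regions, factors, n_replicates=3, noise_sd=0.2, seed=4
        )
        enr = ripchip.probe_enrichment(wt).set_index("probe_id")
        assert enr.loc["p1", "median_ratio"] > enr.loc["p2", "median_ratio"] > enr.loc["p3", "median_ratio"]


class TestSimulateBlotTable:
    def test_fraction_half_no_background(self):
        df = simulate_blot_table(["t"], [0.5], [100.0], background=0.0, seed=1)
        wt = df[df["genotype"] == "wt"].set_index("fraction_label")
        assert wt.loc["P", "signal"] == wt.loc["S", "signal"]

    def test_fraction_zero_is_background_only(self):
        df = simulate_blot_table(["t"], [0.0], [100.0], background=0.5, seed=2)
        wt = df[df["genotype"] == "wt"].set_index("fraction_label")
        assert wt.loc["P", "signal"] < 5.0  # exponential background, scale 0.5
        assert wt.loc["S", "signal"] > 90.0

    def test_fraction_recovery_with_small_background(self):
        from rbpkit import quant

        df = simulate_blot_table(["t"], [0.9], [1000.0], background=10.0, seed=3)
        metrics = quant.blot_metrics(df)
        assert metrics.loc[0, "fraction_bound"] == pytest.approx(0.9, abs=0.05)


def test_load_config_roundtrip(tmp_path):
    cfg_text = """
binding_model:
  motif_affinities: {UGGUUGGU: 100.0}
  background_affinity: 1.0
selection:
  n_input_reads: 100
  n_pulldown_reads: 100
  seed: 5
"""
    path = tmp_path / "sim.yaml"
    path.write_text(cfg_text)
    config, model = synthetic.load_config(path)
    assert config.n_input_reads == 100
    assert config.protein_concentrations == (0.0, 100.0, 1000.0)
    assert model.motif_affinities == {"UGGUUGGU": 100.0}
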