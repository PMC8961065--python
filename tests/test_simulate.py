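"""Synthetic CDS generator: validity, determinism, calibration, divergence."""

import numpy as np
import pytest

from cubkit import (
    SimulationConfig,
    aggregate_counts,
    codon_index_table,
    count_codons,
    filter_cds,
    generate_cds_set,
    generate_reference_genome_pair,
    genome_composition,
    neutrality_fit,
    positional_gc,
    rscu_distance_matrix,
    rscu_matrix,
    write_cds_fasta,
)


def test_all_generated_genes_pass_filter():
    recs, _ = generate_cds_set(SimulationConfig(seed=11))
    kept, report = filter_cds(recs)
    assert report.n_retained == report.n_input == 57
    assert report.rejected_ids == []


def test_fixed_seed_is_byte_identical(tmp_path):
    paths = []
    for i in (1, 2):
        recs, _ = generate_cds_set(SimulationConfig(seed=99, n_genes=10))
        p = tmp_path / f"run{i}.fasta"
        write_cds_fasta(recs, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]
    recs_other, _ = generate_cds_set(SimulationConfig(seed=100, n_genes=10))
    assert any(a.seq != b.seq for a, b in zip(recs, recs_other))


def test_default_genome_is_chloroplast_like(code):
    recs, _ = generate_cds_set(SimulationConfig(seed=5))
    comp = genome_composition(recs, code)
    assert 0.30 <= comp.gc <= 0.45
    lengths = [len(r.seq) for r in recs]
    assert min(lengths) >= 300 and all(n % 3 == 0 for n in lengths)


def test_unbiased_config_gives_uniform_rscu(code):
    """theta = 0 with no GC3 targeting: pooled RSCU ~ 1 at ~1e5 codons."""
    cfg = SimulationConfig(n_genes=300, length_range=(320, 360), bias_theta=0.0,
                          gc3_targets=None, seed=21)
    recs, _ = generate_cds_set(cfg)
    counts = aggregate_counts([count_codons(r, code=code) for r in recs])
    assert counts.L > 9e4
    table = codon_index_table(counts, code)
    multi = table[table.family_size >= 2]
    assert float((multi["rscu"] - 1).abs().max()) < 0.1


def test_biased_config_prefers_at_ending_codons(code):
    recs, _ = generate_cds_set(SimulationConfig(seed=3, bias_theta=1.0))
    counts = aggregate_counts([count_codons(r, code=code) for r in recs])
    table = codon_index_table(counts, code)
    preferred = table[(table.family_size >= 2) & (table.rscu > 1)]
    at_ending = preferred.index.str[2].isin(["A", "T"]).mean()
    assert at_ending > 0.9


def test_gc3_targets_are_met_in_expectation():
    targets = [0.25, 0.35, 0.45]
    cfg = SimulationConfig(n_genes=3, gc3_targets=targets, seed=7,
                          length_range=(400, 400))
    _, truth = generate_cds_set(cfg)
    for gene, t in zip(truth.genes, targets):
        assert gene.expected_gc3 == pytest.approx(t, abs=0.01)
        assert gene.flags == []


def test_infeasible_gc3_target_clamped_and_flagged():
    # GC3 = 0 is unreachable: Met (ATG) and Trp (TGG) force G-ending codons
    _, truth = generate_cds_set(
        SimulationConfig(n_genes=1, gc3_targets=[0.0], seed=1))
    assert "gc3_target_clamped" in truth.genes[0].flags
    assert truth.genes[0].expected_gc3 > 0.0


def test_neutrality_structure_recovered_over_seeds(code):
    """Generating slope 0.3 (noise sd 0.02, n=57) is recovered by the fit."""
    slopes = []
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, gc3_targets=(0.3, 0.25, 0.02),
                              gc3_range=(0.15, 0.55))
        recs, _ = generate_cds_set(cfg)
        comps = [positional_gc(r, code) for r in recs]
        slopes.append(neutrality_fit(comps).slope)
    assert np.mean(slopes) == pytest.approx(0.3, abs=0.05)
    assert all(abs(s - 0.3) < 0.2 for s in slopes)


def test_divergence_zero_pair_distance_vanishes_with_length(code):
    """At divergence 0 both genomes share every sampling distribution, so the
    RSCU distance is pure multinomial noise and shrinks as codons accumulate."""
    dist_by_n = {}
    for n_genes in (15, 240):
        cfg = SimulationConfig(seed=13, n_genes=n_genes, length_range=(300, 400))
        (a, _), (b, _) = generate_reference_genome_pair(cfg, divergence=0.0)
        mats = rscu_matrix({
            "a": aggregate_counts([count_codons(r, code=code) for r in a]),
            "b": aggregate_counts([count_codons(r, code=code) for r in b]),
        }, code)
        dist_by_n[n_genes] = rscu_distance_matrix(mats).d[0, 1]
        if n_genes == 240:
            # identical profiles -> exactly zero
            assert rscu_distance_matrix(mats.iloc[[0, 0]]).d[0, 1] == 0.0
    assert dist_by_n[240] < dist_by_n[15]
    assert dist_by_n[240] < 0.15


def test_distance_increases_with_divergence(code):
    wins = 0
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, n_genes=25, length_range=(200, 300),
                              bias_theta=1.2)
        dists = {}
        for div in (0.5, 1.0):
            (a, _), (b, _) = generate_reference_genome_pair(cfg, divergence=div)
            mats = rscu_matrix({
                "a": aggregate_counts([count_codons(r, code=code) for r in a]),
                "b": aggregate_counts([count_codons(r, code=code) for r in b]),
            }, code)
            dists[div] = rscu_distance_matrix(mats).d[0, 1]
        wins += dists[1.0] > dists[0.5]
    assert wins >= 16  # Monte-Carlo monotonicity


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        generate_cds_set(SimulationConfig(length_range=(50, 80)))
    with pytest.raises(ValueError):
        generate_cds_set(SimulationConfig(gc3_targets=[0.3, 0.4], n_genes=3))
    with pytest.raises(ValueError):
        generate_reference_genome_pair(SimulationConfig(), divergence=1.5)
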