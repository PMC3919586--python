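"""Simulator: geometry, determinism, condition effects, sampling."""

import numpy as np
import pytest

from slicerscan.simulate import (SimulationConfig, build_toy_genome,
                                 emit_raw_reads, expected_species,
                                 simulate_library, slicer_product_length)


def _locus_counts(lib, locus):
    return {s.species_id: s.count for s in lib.mapped_species()
            if s.species_id.startswith(locus.id + ":")}


@pytest.mark.parametrize("L,o,expected", [(42, 2, 30), (60, 2, 48), (54, 4, 40)])
def test_slicer_product_length(L, o, expected):
    assert slicer_product_length(L, o) == expected


def test_slicer_rejects_too_short_hairpin():
    with pytest.raises(ValueError, match="too short to slice"):
        slicer_product_length(14, 2)


def test_short_hairpin_precursor_geometry():
    cfg = SimulationConfig(seed=1, sh_arm_len=18, sh_loop_len=4, overhang=2)
    _, loci = build_toy_genome(cfg)
    sh = [l for l in loci if l.locus_class == "short_hairpin"]
    assert sh and all(l.precursor_len == 42 for l in sh)
    assert all(l.end - l.start == l.precursor_len for l in sh)


def test_genome_and_library_are_deterministic():
    cfg = SimulationConfig(seed=42)
    g1, l1 = build_toy_genome(cfg)
    g2, l2 = build_toy_genome(SimulationConfig(seed=42))
    assert g1 == g2 and [l.id for l in l1] == [l.id for l in l2]
    lib1 = simulate_library(g1, l1, "gfp_kd", cfg)
    lib2 = simulate_library(g2, l2, "gfp_kd", SimulationConfig(seed=42))
    assert [(s.species_id, s.count) for s in lib1.species] == \
           [(s.species_id, s.count) for s in lib2.species]
    r1 = list(emit_raw_reads(lib1, seed=42))
    r2 = list(emit_raw_reads(lib2, seed=42))
    assert r1 == r2


def test_empty_config_gives_background_only_genome():
    cfg = SimulationConfig(seed=0, n_canonical=0, n_short_hairpin=0, n_hpRNA=0,
                           n_decoy_low_coverage=0, n_decoy_mixed_strand=0,
                           n_decoy_unstructured=0, genome_len=2000,
                           n_background=0)
    genome, loci = build_toy_genome(cfg)
    assert loci == []
    assert len(genome[cfg.chrom]) == 2000


def test_placement_error_names_overflowing_class():
    cfg = SimulationConfig(seed=0, genome_len=700)
    with pytest.raises(ValueError, match="too small"):
        build_toy_genome(cfg)


def test_unknown_condition_rejected(default_sim):
    cfg, genome, loci, _, _ = default_sim
    with pytest.raises(ValueError, match="unknown condition"):
        simulate_library(genome, loci, "mock_kd", cfg)


def test_trimmed_to_acpre_ratio_equals_routing_split():
    cfg = SimulationConfig(seed=2)
    genome, loci = build_toy_genome(cfg)
    lib = simulate_library(genome, loci, "gfp_kd", cfg, expectation_mode=True)
    sh = next(l for l in loci if l.locus_class == "short_hairpin")
    counts = _locus_counts(lib, sh)
    trimmed = sum(c for sid, c in counts.items() if ":trimmed" in sid)
    acpre = sum(c for sid, c in counts.items() if ":ac_pre" in sid)
    r = cfg.ago1_routing_fraction
    assert trimmed / acpre == pytest.approx(r / (1 - r), rel=0.02)


def test_expectation_mode_recovers_configured_fold():
    cfg = SimulationConfig(seed=3)
    genome, loci = build_toy_genome(cfg)
    gfp = simulate_library(genome, loci, "gfp_kd", cfg, expectation_mode=True)
    dcr1 = simulate_library(genome, loci, "dcr1_kd", cfg, expectation_mode=True)
    assert gfp.total_mapped == dcr1.total_mapped == cfg.library_depth
    for sh in (l for l in loci if l.locus_class == "short_hairpin"):
        c_g = sum(_locus_counts(gfp, sh).values())
        c_d = sum(_locus_counts(dcr1, sh).values())
        rpm_ratio = (c_d / dcr1.total_mapped) / (c_g / gfp.total_mapped)
        assert rpm_ratio == pytest.approx(cfg.dcr1_shorthairpin_fold, abs=0.03)


def test_resection_lengths_and_shared_five_prime(default_sim):
    cfg, genome, loci, gfp, dcr1 = default_sim
    lo, hi = cfg.resection_len_range
    for lib in (gfp, dcr1):
        for sh in (l for l in loci if l.locus_class == "short_hairpin"):
            sps = [s for s in lib.mapped_species()
                   if s.species_id.startswith(sh.id + ":")]
            five = {s.five_prime for s in sps}
            assert len(five) == 1  # pre, ac_pre and trimmed share one 5' end
            for s in sps:
                if s.species_class == "trimmed":
                    assert lo <= s.length <= hi
                    assert not s.methylated3p
                elif s.species_class == "ac_pre":
                    assert s.length == slicer_product_length(
                        sh.precursor_len, sh.overhang)
                    assert s.methylated3p  # AGO2-arrested, Hen1-modified


def test_full_ago2_routing_arrests_all_trimming():
    cfg = SimulationConfig(seed=4, ago1_routing_fraction=0.0)
    genome, loci = build_toy_genome(cfg)
    lib = simulate_library(genome, loci, "gfp_kd", cfg)
    assert not any(s.species_class == "trimmed" for s in lib.species)
    cfg_all = SimulationConfig(seed=4, ago1_routing_fraction=1.0)
    lib_all = simulate_library(genome, loci, "gfp_kd", cfg_all)
    assert not any(s.species_class == "ac_pre" for s in lib_all.species)


def test_sampled_counts_conserve_depth(default_sim):
    cfg, _, _, gfp, dcr1 = default_sim
    for lib in (gfp, dcr1):
        assert sum(s.count for s in lib.mapped_species()) == cfg.library_depth
        assert lib.total_mapped == cfg.library_depth


def test_sampled_counts_within_binomial_envelope():
    """Per-locus totals stay within 4 sigma of the multinomial expectation."""
    base = SimulationConfig(seed=0)
    genome, loci = build_toy_genome(base)
    pairs = expected_species(genome, loci, "gfp_kd", base)
    weights = {}
    for sp, w in pairs:
        locus = sp.species_id.split(":")[0]
        weights[locus] = weights.get(locus, 0.0) + w
    total_w = sum(w for _, w in pairs)
    for seed in range(10):
        # same genome and locus weights; only the sampling RNG varies
        lib = simulate_library(genome, loci, "gfp_kd", _reseeded(base, seed))
        counts = {}
        for sp in lib.mapped_species():
            locus = sp.species_id.split(":")[0]
            counts[locus] = counts.get(locus, 0) + sp.count
        n = base.library_depth
        for locus, w in weights.items():
            if locus.startswith("background"):
                continue
            p = w / total_w
            mu = n * p
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(locus, 0) - mu) <= 4 * sigma, (seed, locus)


def _reseeded(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    import dataclasses
    return dataclasses.replace(cfg, seed=seed)


def test_spike_ins_present_at_fixed_counts(default_sim):
    cfg, _, _, gfp, _ = default_sim
    spikes = [s for s in gfp.species if s.species_class == "spike"]
    assert len(spikes) == cfg.spike_in_count
    assert {s.count for s in spikes} == \
        {cfg.spike_base_count * (k + 1) for k in range(cfg.spike_in_count)}
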