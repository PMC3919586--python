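"""Genome scan: coverage, region calling, fold filter, classification."""

import dataclasses

import numpy as np

from slicerscan.fold import FoldResult
from slicerscan.records import Library, ReadSpecies, revcomp
from slicerscan.scan import (CandidateRegion, ScanParams, classify_candidate,
                             coverage_profile, find_candidate_regions,
                             fold_filter, scan_genome)
from slicerscan.annotate import truth_annotation


def _sp(start, end, strand="+", count=1, chrom="c1"):
    return ReadSpecies("", chrom, start, end, strand, count,
                       species_id=f"{start}:{end}:{strand}")


def test_coverage_profile_single_species():
    plus, minus = coverage_profile([_sp(10, 32, count=40)], "c1", 100)
    assert plus[9] == 0 and plus[10] == 40 and plus[31] == 40 and plus[32] == 0
    assert minus.sum() == 0


def test_coverage_profile_empty():
    plus, minus = coverage_profile([], "c1", 50)
    assert plus.sum() == 0 and minus.sum() == 0


def test_coverage_profile_matches_brute_force():
    rng = np.random.default_rng(3)
    species = [_sp(int(s), int(s) + int(rng.integers(18, 43)),
                   "+-"[int(rng.integers(2))], int(rng.integers(1, 50)))
               for s in rng.integers(0, 950, size=500)]
    plus, minus = coverage_profile(species, "c1", 1000)
    for x in rng.integers(0, 1000, size=200):
        want_p = sum(s.count for s in species
                     if s.strand == "+" and s.start <= x < s.end)
        want_m = sum(s.count for s in species
                     if s.strand == "-" and s.start <= x < s.end)
        assert plus[x] == want_p and minus[x] == want_m


def test_region_called_when_criteria_met():
    species = [_sp(100, 125, count=50)]
    plus, minus = coverage_profile(species, "c1", 300)
    regions = find_candidate_regions(plus, minus, species, "c1", ScanParams())
    assert len(regions) == 1
    (r,) = regions
    assert (r.start, r.end, r.strand) == (100, 125, "+")
    assert r.strand_fraction == 1.0


def test_nineteen_nt_run_rejected_even_at_high_coverage():
    species = [_sp(100, 119, count=1000)]
    plus, minus = coverage_profile(species, "c1", 300)
    assert find_candidate_regions(plus, minus, species, "c1", ScanParams()) == []


def test_mixed_strand_run_dropped_below_75_percent():
    species = [_sp(100, 125, "+", count=70), _sp(100, 125, "-", count=30)]
    plus, minus = coverage_profile(species, "c1", 300)
    assert find_candidate_regions(plus, minus, species, "c1", ScanParams()) == []
    species = [_sp(100, 125, "+", count=75), _sp(100, 125, "-", count=25)]
    plus, minus = coverage_profile(species, "c1", 300)
    assert len(find_candidate_regions(plus, minus, species, "c1", ScanParams())) == 1


def test_fold_filter_threshold_is_inclusive():
    genome = {"c1": "A" * 300}
    region = CandidateRegion("c1", 100, 140, "+")

    def folder_at(dg):
        def folder(seq):
            return FoldResult(seq, "." * len(seq), dg)
        return folder

    kept = fold_filter(dataclasses.replace(region), genome, ScanParams(),
                       folder_at(-10.0))
    assert kept is not None and kept.dG == -10.0  # dG == -10.0 passes (<=)
    assert fold_filter(dataclasses.replace(region), genome, ScanParams(),
                       folder_at(-9.9)) is None


def test_uniform_five_prime_ends_fail_dominance():
    species = [_sp(100 + k, 122 + k, count=10) for k in range(10)]
    region = CandidateRegion("c1", 100, 131, "+", strand_fraction=1.0)
    region.fold = FoldResult("A" * 61, "." * 61, -12.0)
    region.window = (85, 146)
    lib1 = Library("gfp_kd", species, total_mapped=100)
    lib2 = Library("dcr1_kd", [], total_mapped=100)
    out = classify_candidate(region, lib1, lib2, ScanParams())
    assert not out.dominant5p


def test_planted_hairpins_recovered_with_full_signature(default_sim):
    cfg, genome, loci, gfp, dcr1 = default_sim
    ann = truth_annotation(loci)
    cands = scan_genome(gfp, dcr1, genome, ann)
    truth = {(l.start, l.end) for l in loci if l.locus_class == "short_hairpin"}
    found = {(r.start, r.end): r for r in cands}
    for key in truth:
        assert key in found
        r = found[key]
        assert r.dominant5p and r.het3p and r.loop_crossing and r.acpre_like
        assert r.dG <= -10.0
        assert r.enrichment_fold > 1
    decoys = [l for l in loci if l.locus_class.startswith("decoy")]
    for d in decoys:
        assert not any(r.start < d.end and r.end > d.start for r in cands)


def test_canonical_locus_lacks_acpre_signature(default_sim):
    cfg, genome, loci, gfp, dcr1 = default_sim
    params = ScanParams(mask_annotated_mirna=False)
    cands = scan_genome(gfp, dcr1, genome, None, params)
    canon = {(l.start, l.end) for l in loci if l.locus_class == "canonical_mirna"}
    hits = [r for r in cands if (r.start, r.end) in canon]
    assert hits  # unmasked canonical loci do pass coverage/strand/dG
    for r in hits:
        assert not r.acpre_like  # no >=27-nt reads share the modal 5' end
        assert r.enrichment_fold < 1  # depleted, not enriched, in dcr-1 KD


def test_annotated_mirnas_masked_by_default(default_sim):
    cfg, genome, loci, gfp, dcr1 = default_sim
    ann = truth_annotation(loci)
    cands = scan_genome(gfp, dcr1, genome, ann)
    canon = {(l.start, l.end) for l in loci if l.locus_class == "canonical_mirna"}
    assert not any((r.start, r.end) in canon for r in cands)


def test_empty_libraries_give_empty_table(default_sim):
    _, genome, _, _, _ = default_sim
    empty = Library("gfp_kd", [], total_mapped=1)
    assert scan_genome(empty, Library("dcr1_kd", [], total_mapped=1),
                       genome, None) == []


def test_infinite_coverage_threshold_empties_output(default_sim):
    _, genome, loci, gfp, dcr1 = default_sim
    params = ScanParams(min_coverage=1e18)
    assert scan_genome(gfp, dcr1, genome, truth_annotation(loci), params) == []


def test_stricter_parameters_never_add_candidates(default_sim):
    _, genome, loci, gfp, dcr1 = default_sim
    ann = truth_annotation(loci)
    base = {(r.start, r.end) for r in scan_genome(gfp, dcr1, genome, ann)}
    for params in (ScanParams(min_coverage=200),
                   ScanParams(min_run_len=30),
                   ScanParams(min_strand_fraction=0.95),
                   ScanParams(max_dG=-20.0)):
        strict = {(r.start, r.end)
                  for r in scan_genome(gfp, dcr1, genome, ann, params)}
        assert strict <= base


def test_strand_symmetry_under_genome_reversal(default_sim):
    cfg, genome, loci, gfp, dcr1 = default_sim
    L = len(genome[cfg.chrom])
    mirror = {cfg.chrom: revcomp(genome[cfg.chrom])}

    def flip(lib):
        flipped = [dataclasses.replace(
            s, start=L - s.end, end=L - s.start,
            strand="-" if s.strand == "+" else "+")
            for s in lib.mapped_species()]
        return Library(lib.condition, flipped, lib.total_mapped)

    fwd = scan_genome(gfp, dcr1, genome, None, ScanParams())
    rev = scan_genome(flip(gfp), flip(dcr1), mirror, None, ScanParams())
    want = {(L - r.end, L - r.start, "-" if r.strand == "+" else "+")
            for r in fwd}
    got = {(r.start, r.end, r.strand) for r in rev}
    assert got == want
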