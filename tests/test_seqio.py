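"""IO layer: trimming, collapsing, RPM, spike scaling, BED/SAM round trips."""

import random

import pytest

from slicerscan.seqio import (TrimParams, library_sequence_table,
                              parse_alignments, rpm, spike_scale,
                              trim_and_collapse, write_bed, write_sam)
from slicerscan.simulate import emit_raw_reads

ADAPTER = TrimParams().adapter3_constant


def test_trim_recovers_constructed_insert():
    insert = "TGACCTAGGCATTCAGGACTGA"  # 22 nt
    read = "ACGT" + insert + "TTAA" + ADAPTER
    table, qc = trim_and_collapse([read, read, read])
    assert table == {insert: 3}
    assert qc["kept"] == 3 and qc["discarded_no_adapter"] == 0


def test_trim_tolerates_one_adapter_mismatch():
    insert = "TGACCTAGGCATTCAGGACTGA"
    mutated = ("C" if ADAPTER[0] != "C" else "G") + ADAPTER[1:]
    read = "ACGT" + insert + "TTAA" + mutated
    table, _ = trim_and_collapse([read])
    assert table == {insert: 1}


def test_trim_tallies_missing_adapter_and_length():
    no_adapter = "ACGT" + "TGACCTAGGCATTCAGGACTGA" + "TTAA"
    short = "ACGT" + "TGACC" + "TTAA" + ADAPTER  # 5-nt insert
    table, qc = trim_and_collapse([no_adapter, short])
    assert table == {}
    assert qc["discarded_no_adapter"] == 1
    assert qc["discarded_length"] == 1


def test_collapse_is_order_independent(small_sim):
    _, _, _, lib = small_sim
    reads = [seq for _, seq, _ in emit_raw_reads(lib, seed=5)]
    t1, _ = trim_and_collapse(reads, TrimParams(max_insert_len=60))
    random.Random(1).shuffle(reads)
    t2, _ = trim_and_collapse(reads, TrimParams(max_insert_len=60))
    assert t1 == t2


def test_emit_then_trim_is_identity_on_species_table(small_sim):
    _, _, _, lib = small_sim
    reads = (seq for _, seq, _ in emit_raw_reads(lib, seed=5))
    table, qc = trim_and_collapse(reads, TrimParams(max_insert_len=60))
    assert table == library_sequence_table(lib)
    assert qc["discarded_no_adapter"] == 0


def test_rpm_reproduces_printed_pair():
    # 1772 reads at a ~31.6M-read depth print as 56.1 RPM
    assert rpm(1772, 31_586_453) == pytest.approx(56.1, abs=0.05)


def test_rpm_edge_values():
    assert rpm(0, 12345) == 0.0
    assert rpm(777, 777) == 1e6
    with pytest.raises(ValueError):
        rpm(10, 0)


def test_rpm_fractions_sum_to_one_million(default_sim):
    _, _, _, gfp, _ = default_sim
    total = sum(rpm(s.count, gfp.total_mapped) for s in gfp.mapped_species())
    assert total == pytest.approx(1e6, rel=1e-6)


def test_spike_scale_identity_and_uniform_half():
    expected = {f"spike_{k}": 100 * (k + 1) for k in range(10)}
    assert spike_scale(expected, expected) == pytest.approx(1.0)
    halved = {k: v / 2 for k, v in expected.items()}
    assert spike_scale(halved, expected) == pytest.approx(2.0)


def test_spike_scale_median_robust_to_dropout():
    expected = {f"spike_{k}": 100 for k in range(10)}
    observed = {f"spike_{k}": 50 for k in range(10)}
    observed["spike_0"] = 0  # dropout: excluded, median over remaining 9
    assert spike_scale(observed, expected) == pytest.approx(2.0)
    with pytest.raises(ValueError, match="RPM-only"):
        spike_scale({k: 0 for k in expected}, expected)


def test_bed_round_trip(tmp_path, small_sim):
    _, genome, _, lib = small_sim
    path = tmp_path / "species.bed"
    mapped = [s for s in lib.mapped_species() if s.count > 0]
    write_bed(mapped, path)
    back = parse_alignments(path, "BED", genome)
    assert [(s.chrom, s.start, s.end, s.strand, s.count) for s in back] == \
           [(s.chrom, s.start, s.end, s.strand, s.count) for s in mapped]
    assert all(a.sequence == b.sequence for a, b in zip(back, mapped))


def test_sam_pos_is_one_based(tmp_path):
    sam = tmp_path / "one.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:100\n"
        "sp1\t0\tchrT\t5\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tXC:i:7\n")
    (sp,) = parse_alignments(sam, "SAM")
    assert sp.start == 4 and sp.end == 24  # POS k=5 -> 0-based start 4
    assert sp.count == 7 and sp.strand == "+"


def test_sam_round_trip_preserves_strand_totals(tmp_path, small_sim):
    cfg, genome, _, lib = small_sim
    path = tmp_path / "species.sam"
    mapped = [s for s in lib.mapped_species() if s.count > 0]
    write_sam(mapped, {cfg.chrom: len(genome[cfg.chrom])}, path)
    back = parse_alignments(path, "SAM", genome)
    # brute-force per-strand totals
    for strand in "+-":
        want = sum(s.count for s in mapped if s.strand == strand)
        got = sum(s.count for s in back if s.strand == strand)
        assert got == want
    assert all(a.sequence == b.sequence for a, b in zip(back, mapped))


def test_parse_alignments_rejects_malformed(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chrT\t5\t25\n")
    with pytest.raises(ValueError, match="bad.bed:1"):
        parse_alignments(bad, "BED")
    with pytest.raises(ValueError, match="unknown alignment format"):
        parse_alignments(bad, "CRAM")
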