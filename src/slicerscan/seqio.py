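"""Reading/writing of standard formats and small-RNA read preprocessing.

Adapter trimming follows the randomized-adapter library design: the 3'
adapter carries 4 randomized nucleotides at its ligation end and the 5'
adapter leaves 4 randomized nucleotides at the read start, so an insert is
recovered by locating the constant 3'-adapter region, cutting it off, and
stripping the fixed-width random bases from both ends of the remainder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from collections import Counter

import pysam

from .records import Library, ReadSpecies


@dataclass
class TrimParams:
    adapter3_constant: str = "TGGAATTCTCGGGTGCCAAGG"
    n_random_each_side: int = 4
    min_insert_len: int = 18
    max_insert_len: int = 50
    max_adapter_mismatches: int = 1
    min_adapter_overlap: int = 10

    def __post_init__(self) -> None:
        if self.min_insert_len < 1:
            raise ValueError("min_insert_len must be >= 1")
        if self.n_random_each_side < 0:
            raise ValueError("n_random_each_side must be >= 0")


def _find_adapter(read: str, params: TrimParams) -> int:
    """Leftmost start of the 3'-adapter constant region, or -1.

    Exact search first (fast path), then a Hamming scan allowing up to
    ``max_adapter_mismatches`` over at least ``min_adapter_overlap`` bases
    (the adapter may run off the end of the read).
    """
    adapter = params.adapter3_constant
    pos = read.find(adapter)
    if pos >= 0:
        return pos
    if params.max_adapter_mismatches <= 0:
        # still allow an exact partial match at the read end
        for p in range(len(read) - len(adapter) + 1, len(read) - params.min_adapter_overlap + 1):
            if p >= 0 and read[p:] == adapter[: len(read) - p]:
                return p
        return -1
    for p in range(0, len(read) - params.min_adapter_overlap + 1):
        span = min(len(adapter), len(read) - p)
        mism = 0
        for a, b in zip(read[p:p + span], adapter[:span]):
            if a != b:
                mism += 1
                if mism > params.max_adapter_mismatches:
                    break
        else:
            return p
    return -1


def iter_fastq(path):
    """Yield (name, sequence) from a FASTQ file (gzip ok, via pysam)."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence


def trim_and_collapse(reads, params: TrimParams | None = None):
    """Trim adapters, strip randomized bases, collapse identical inserts.

    ``reads`` is an iterable of sequences or (name, sequence) tuples (e.g.
    from :func:`iter_fastq`).  Returns ``(table, qc)`` where ``table`` maps
    insert sequence -> count and ``qc`` tallies discarded reads.
    """
    params = params or TrimParams()
    table: Counter = Counter()
    qc = {"input_reads": 0, "kept": 0,
          "discarded_no_adapter": 0, "discarded_length": 0}
    nr = params.n_random_each_side
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        qc["input_reads"] += 1
        pos = _find_adapter(seq.upper(), params)
        if pos < 0:
            qc["discarded_no_adapter"] += 1
            continue
        remainder = seq[:pos].upper()
        insert = remainder[nr: len(remainder) - nr] if nr else remainder
        if not (params.min_insert_len <= len(insert) <= params.max_insert_len):
            qc["discarded_length"] += 1
            continue
        table[insert] += 1
        qc["kept"] += 1
    return dict(table), qc


def rpm(count: float, total_mapped: int) -> float:
    """Reads-per-million-mapped normalization."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return count / total_mapped * 1e6


def spike_scale(observed: dict, expected: dict) -> float:
    """Cross-library scale factor from spike-in oligos.

    Median over spike species of expected/observed counts; robust to a
    single dropout among the usual 10 spikes.
    """
    ratios = []
    for key, exp in expected.items():
        obs = observed.get(key, 0)
        if obs > 0:
            ratios.append(exp / obs)
    if not ratios:
        raise ValueError(
            "no spike-in species observed; use RPM-only comparisons")
    ratios.sort()
    m = len(ratios)
    return (ratios[m // 2] if m % 2 else
            0.5 * (ratios[m // 2 - 1] + ratios[m // 2]))


# ---------------------------------------------------------------------------
# alignments: BED6 / SAM round trip
# ---------------------------------------------------------------------------

def write_bed(species, path) -> None:
    """Write species as BED6: count in the score field, id in the name."""
    with open(path, "w") as fh:
        for sp in species:
            fh.write(f"{sp.chrom}\t{sp.start}\t{sp.end}\t"
                     f"{sp.species_id or '.'}\t{sp.count}\t{sp.strand}\n")


def write_sam(species, chrom_lengths: dict, path) -> None:
    """One SAM record per collapsed species; count in the XC tag."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for sp in species:
            a = pysam.AlignedSegment(out.header)
            a.query_name = sp.species_id or "species"
            a.reference_name = sp.chrom
            a.reference_start = sp.start
            a.flag = 16 if sp.strand == "-" else 0
            seq = sp.sequence or "N" * (sp.end - sp.start)
            from .records import revcomp
            a.query_sequence = revcomp(seq) if sp.strand == "-" else seq
            a.cigarstring = f"{sp.end - sp.start}M"
            a.mapping_quality = 255
            a.set_tag("XC", sp.count)
            out.write(a)


def parse_alignments(path, format: str = "BED", genome: dict | None = None):
    """Parse collapsed-species alignments from BED6 or SAM.

    Coordinates come back 0-based half-open; SAM 1-based POS is shifted by
    pysam.  Species lacking a count default to 1.  If ``genome`` is given,
    sequences are reconstructed from it (molecule orientation).
    """
    from .records import revcomp
    species = []
    if format.upper() == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
                chrom, start, end, name, score, strand = parts[:6]
                start, end = int(start), int(end)
                count = int(float(score)) if score not in (".", "") else 1
                seq = ""
                if genome and chrom in genome:
                    seq = genome[chrom][start:end]
                    if strand == "-":
                        seq = revcomp(seq)
                species.append(ReadSpecies(
                    sequence=seq, chrom=chrom, start=start, end=end,
                    strand=strand, count=count, species_id=name))
    elif format.upper() == "SAM":
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                strand = "-" if rec.is_reverse else "+"
                count = rec.get_tag("XC") if rec.has_tag("XC") else 1
                seq = rec.query_sequence or ""
                if strand == "-" and seq:
                    seq = revcomp(seq)
                species.append(ReadSpecies(
                    sequence=seq, chrom=rec.reference_name,
                    start=rec.reference_start, end=rec.reference_end,
                    strand=strand, count=int(count),
                    species_id=rec.query_name))
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return species


# ---------------------------------------------------------------------------
# misc writers
# ---------------------------------------------------------------------------

def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_species_tsv(table: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tlength\n")
        for seq in sorted(table):
            fh.write(f"{seq}\t{table[seq]}\t{len(seq)}\n")


def write_qc_json(qc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def library_sequence_table(library: Library) -> dict:
    """Aggregate a library's species into a sequence -> count table."""
    table: Counter = Counter()
    for sp in library.species:
        if sp.count > 0:
            table[sp.sequence] += sp.count
    return dict(table)
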