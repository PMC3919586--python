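"""Strand-aware interval intersection, category assignment and composition.

Half-open interval arithmetic throughout; intersection is re-implemented
(bedtools-style, >=1 bp overlap) over per-chromosome start-sorted lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from bisect import bisect_left

CATEGORIES = ("miRNA", "hpRNA", "other_structured", "repeat", "gene", "intergenic")
DEFAULT_PRIORITY = CATEGORIES  # miRNA outranks everything


@dataclass(frozen=True)
class AnnotationInterval:
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.name}: [{self.start},{self.end})")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


class AnnotationSet:
    """Per-chromosome start-sorted annotation index."""

    def __init__(self, intervals):
        self._by_chrom: dict = {}
        self.warnings = {"unknown_chrom": 0}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda iv: (iv.start, iv.name))
        self._starts = {c: [iv.start for iv in ivs]
                        for c, ivs in self._by_chrom.items()}
        self._max_len = {c: max((iv.end - iv.start for iv in ivs), default=0)
                         for c, ivs in self._by_chrom.items()}

    def intersect(self, chrom: str, start: int, end: int,
                  strand: str | None = None, same_strand: bool = False):
        """All annotation intervals overlapping [start, end) by >= 1 bp,
        ordered by (start, name); strand-filtered when requested."""
        if chrom not in self._by_chrom:
            self.warnings["unknown_chrom"] += 1
            return []
        ivs = self._by_chrom[chrom]
        starts = self._starts[chrom]
        lo = bisect_left(starts, start - self._max_len[chrom])
        out = []
        for iv in ivs[lo:]:
            if iv.start >= end:
                break
            if iv.end <= start:
                continue
            if same_strand and strand is not None and iv.strand != strand:
                continue
            out.append(iv)
        return out


def intersect(query, annotation: AnnotationSet, same_strand: bool = False):
    """Overlaps of a (chrom, start, end, strand) query against the set."""
    chrom, start, end, strand = query
    return annotation.intersect(chrom, start, end, strand, same_strand)


def categorize(species, annotation: AnnotationSet,
               priority=DEFAULT_PRIORITY, same_strand: bool = True) -> str:
    """Category of the highest-priority overlapping annotation; intergenic
    when nothing overlaps (AGO1-IP reads are strand-specific, so the
    same-strand rule is on by default)."""
    hits = annotation.intersect(species.chrom, species.start, species.end,
                                species.strand, same_strand)
    if not hits:
        return "intergenic"
    rank = {cat: k for k, cat in enumerate(priority)}
    return min(hits, key=lambda iv: rank.get(iv.category, len(rank))).category


@dataclass
class CompositionSummary:
    condition: str
    counts: dict
    fractions: dict
    miRNA_fraction: float
    non_miRNA_fraction: float


def composition(library, annotation: AnnotationSet,
                priority=DEFAULT_PRIORITY) -> CompositionSummary:
    """Count-weighted genomic-category composition of a library.

    Spike-ins are excluded.  Raises on an empty library.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    total = 0
    for sp in library.mapped_species():
        if sp.count == 0:
            continue
        cat = categorize(sp, annotation, priority)
        counts[cat] += sp.count
        total += sp.count
    if total == 0:
        raise ValueError("no mapped species in library")
    fractions = {cat: c / total for cat, c in counts.items()}
    mi = fractions["miRNA"]
    return CompositionSummary(
        condition=library.condition, counts=counts, fractions=fractions,
        miRNA_fraction=mi, non_miRNA_fraction=1.0 - mi)


def fold_change(rpm_num: float, rpm_den: float) -> float:
    """Plain RPM ratio; see :func:`enrichment_from_counts` for the
    pseudocount path used when either raw count can be zero."""
    if rpm_num < 0 or rpm_den < 0:
        raise ValueError("RPM values must be >= 0")
    if rpm_den == 0:
        raise ValueError("denominator RPM is zero; use the pseudocount path")
    return rpm_num / rpm_den


def enrichment_from_counts(count_num: float, total_num: int,
                           count_den: float, total_den: int,
                           pseudocount: float = 0.5) -> float:
    """RPM fold change with +pseudocount on raw counts when either is zero."""
    if count_num == 0 or count_den == 0:
        count_num += pseudocount
        count_den += pseudocount
    num = count_num / total_num * 1e6
    den = count_den / total_den * 1e6
    return num / den


def truth_annotation(loci) -> AnnotationSet:
    """Annotation for a synthetic run: canonical loci are annotated miRNAs,
    hpRNA loci are annotated hpRNAs; everything else (including planted
    short hairpins — the 'novel' loci) is unannotated."""
    ivs = []
    for loc in loci:
        if loc.locus_class == "canonical_mirna":
            cat = "miRNA"
        elif loc.locus_class == "hpRNA":
            cat = "hpRNA"
        else:
            continue
        ivs.append(AnnotationInterval(loc.chrom, loc.start, loc.end,
                                      loc.strand, cat, loc.id))
    return AnnotationSet(ivs)


def read_annotation_bed(path) -> AnnotationSet:
    """BED6 + category in a 7th column."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: need 7 columns (BED6 + category)")
            chrom, start, end, name, _score, strand, cat = parts[:7]
            ivs.append(AnnotationInterval(chrom, int(start), int(end),
                                          strand, cat, name))
    return AnnotationSet(ivs)
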