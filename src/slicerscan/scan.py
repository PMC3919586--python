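"""Genome scan for candidate Dicer-independent short-hairpin miRNA loci.

The scan applies the published AGO1-IP criteria: maximal runs of >= 20 nt
where every base has combined-strand read coverage >= 40, with >= 75% of
the overlapping reads (count-weighted) on one strand, and a folded window
with dG <= -10 kcal/mol.  Surviving regions are classified by their read
signature: a dominant 5' end with 3' heterogeneity, mature-sized reads
crossing the terminal loop, and longer ac-pre-like reads extending into
the 3' arm; candidates are ranked by dcr-1-knockdown enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import enrichment_from_counts
from .fold import FoldResult, fold_mfe
from .records import revcomp


@dataclass
class ScanParams:
    min_coverage: float = 40.0
    min_run_len: int = 20
    min_strand_fraction: float = 0.75
    max_dG: float = -10.0
    flank: int = 15
    dominant5p_fraction: float = 0.5
    min_3p_ends: int = 2
    acpre_min_len: int = 27
    pseudocount: float = 0.5
    coverage_mode: str = "every_base"  # or "mean"
    mask_annotated_mirna: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_strand_fraction <= 1.0:
            raise ValueError("min_strand_fraction outside [0, 1]")
        if not 0.0 <= self.dominant5p_fraction <= 1.0:
            raise ValueError("dominant5p_fraction outside [0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.coverage_mode not in ("every_base", "mean"):
            raise ValueError("coverage_mode must be 'every_base' or 'mean'")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    strand: str
    peak_coverage: float = 0.0
    strand_fraction: float = 0.0
    dG: float = 0.0
    fold: FoldResult | None = None
    window: tuple | None = None
    dominant5p: bool = False
    het3p: bool = False
    loop_crossing: bool = False
    acpre_like: bool = False
    rpm_gfp: float = 0.0
    rpm_dcr1: float = 0.0
    enrichment_fold: float = 0.0

    @property
    def flags(self) -> dict:
        return {"dominant5p": self.dominant5p, "het3p": self.het3p,
                "loop_crossing": self.loop_crossing,
                "acpre_like": self.acpre_like}


def coverage_profile(species, chrom: str, chrom_len: int):
    """Per-base, per-strand coverage arrays from species counts."""
    plus = np.zeros(chrom_len, dtype=np.float64)
    minus = np.zeros(chrom_len, dtype=np.float64)
    for sp in species:
        if sp.chrom != chrom or sp.count == 0:
            continue
        target = plus if sp.strand == "+" else minus
        target[max(sp.start, 0):min(sp.end, chrom_len)] += sp.count
    return plus, minus


def find_candidate_regions(plus, minus, species, chrom: str,
                           params: ScanParams):
    """Maximal coverage runs passing the coverage/length/strand criteria."""
    combined = plus + minus
    if params.coverage_mode == "every_base":
        mask = combined >= params.min_coverage
    else:
        mask = combined > 0
    regions = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        if params.coverage_mode == "mean":
            if combined[run_start:run_end].mean() < params.min_coverage:
                continue
        if run_end - run_start < params.min_run_len:
            continue
        plus_w = minus_w = 0.0
        for sp in species:
            if sp.chrom != chrom or sp.count == 0:
                continue
            if sp.start < run_end and sp.end > run_start:
                if sp.strand == "+":
                    plus_w += sp.count
                else:
                    minus_w += sp.count
        total = plus_w + minus_w
        if total == 0:
            continue
        frac = max(plus_w, minus_w) / total
        if frac < params.min_strand_fraction:
            continue
        regions.append(CandidateRegion(
            chrom=chrom, start=int(run_start), end=int(run_end),
            strand="+" if plus_w >= minus_w else "-",
            peak_coverage=float(combined[run_start:run_end].max()),
            strand_fraction=float(frac)))
    return regions


def fold_filter(region: CandidateRegion, genome: dict, params: ScanParams,
                folder=None):
    """Fold the flank-extended window; keep iff dG <= max_dG (inclusive)."""
    folder = folder or fold_mfe
    chrom_seq = genome[region.chrom]
    w_start = max(0, region.start - params.flank)
    w_end = min(len(chrom_seq), region.end + params.flank)
    seq = chrom_seq[w_start:w_end]
    if region.strand == "-":
        seq = revcomp(seq)
    result = folder(seq)
    if result.dg > params.max_dG:
        return None
    region.dG = result.dg
    region.fold = result
    region.window = (w_start, w_end)
    return region


def _window_to_genome(region: CandidateRegion, interval):
    """Map a half-open interval in fold-window coordinates to genomic."""
    w_start, w_end = region.window
    a, b = interval
    if region.strand == "+":
        return w_start + a, w_start + b
    return w_end - b, w_end - a


def classify_candidate(region: CandidateRegion, lib_gfp, lib_dcr1,
                       params: ScanParams) -> CandidateRegion:
    """Attach read-signature flags and dcr-1 enrichment to a region.

    Signature flags use region-strand reads overlapping the region:
      dominant5p  - the modal 5' position carries >= dominant5p_fraction of reads
      het3p       - reads at the modal 5' end show >= min_3p_ends distinct 3' ends
      loop_crossing - a modal-5' read overlaps the called terminal loop
      acpre_like  - a modal-5' read of >= acpre_min_len ends inside the 3' arm
    """
    overlapping = []
    for lib in (lib_gfp, lib_dcr1):
        for sp in lib.mapped_species():
            if (sp.chrom == region.chrom and sp.strand == region.strand
                    and sp.start < region.end and sp.end > region.start):
                overlapping.append(sp)
    five_counts: dict = {}
    for sp in overlapping:
        five_counts[sp.five_prime] = five_counts.get(sp.five_prime, 0) + sp.count
    if five_counts:
        modal5 = min((p for p, c in five_counts.items()
                      if c == max(five_counts.values())))
        total = sum(five_counts.values())
        region.dominant5p = five_counts[modal5] / total >= params.dominant5p_fraction
        modal_reads = [sp for sp in overlapping if sp.five_prime == modal5]
        ends3 = {sp.three_prime for sp in modal_reads}
        region.het3p = len(ends3) >= params.min_3p_ends
        if region.fold is not None and region.fold.loop is not None:
            loop_g = _window_to_genome(region, region.fold.loop)
            arm3_g = _window_to_genome(region, region.fold.arm3)
            for sp in modal_reads:
                if sp.start < loop_g[1] and sp.end > loop_g[0]:
                    region.loop_crossing = True
                if (sp.length >= params.acpre_min_len
                        and arm3_g[0] <= sp.three_prime < arm3_g[1]):
                    region.acpre_like = True
    # per-condition quantification over the region (region strand)
    def _count(lib):
        return sum(sp.count for sp in lib.mapped_species()
                   if sp.chrom == region.chrom and sp.strand == region.strand
                   and sp.start < region.end and sp.end > region.start)

    c_gfp, c_dcr1 = _count(lib_gfp), _count(lib_dcr1)
    region.rpm_gfp = c_gfp / lib_gfp.total_mapped * 1e6
    region.rpm_dcr1 = c_dcr1 / lib_dcr1.total_mapped * 1e6
    region.enrichment_fold = enrichment_from_counts(
        c_dcr1, lib_dcr1.total_mapped, c_gfp, lib_gfp.total_mapped,
        params.pseudocount)
    return region


def scan_genome(lib_gfp, lib_dcr1, genome: dict, annotation=None,
                params: ScanParams | None = None, folder=None):
    """Full candidate scan over all chromosomes.

    Coverage is computed from the union of both condition libraries (the
    scan criteria are condition-agnostic; enrichment is quantified per
    condition afterwards).  Regions overlapping annotated canonical miRNAs
    are masked by default.  Output is ranked by enrichment fold, then peak
    coverage, then coordinates.
    """
    params = params or ScanParams()
    union = lib_gfp.mapped_species() + lib_dcr1.mapped_species()
    candidates = []
    for chrom, seq in sorted(genome.items()):
        chrom_species = [sp for sp in union if sp.chrom == chrom]
        plus, minus = coverage_profile(chrom_species, chrom, len(seq))
        regions = find_candidate_regions(plus, minus, chrom_species, chrom, params)
        for region in regions:
            if params.mask_annotated_mirna and annotation is not None:
                hits = annotation.intersect(chrom, region.start, region.end)
                if any(iv.category == "miRNA" for iv in hits):
                    continue
            kept = fold_filter(region, genome, params, folder)
            if kept is None:
                continue
            candidates.append(
                classify_candidate(kept, lib_gfp, lib_dcr1, params))
    candidates.sort(key=lambda r: (-r.enrichment_fold, -r.peak_coverage,
                                   r.chrom, r.start))
    return candidates


def candidates_table(candidates):
    """Candidates as a pandas DataFrame (extended TSV layout)."""
    import pandas as pd

    rows = []
    for r in candidates:
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "strand": r.strand, "peak_coverage": r.peak_coverage,
            "strand_fraction": round(r.strand_fraction, 4),
            "dG_kcal_mol": r.dG,
            "dominant5p": r.dominant5p, "het3p": r.het3p,
            "loop_crossing": r.loop_crossing, "acpre_like": r.acpre_like,
            "rpm_gfp": round(r.rpm_gfp, 3), "rpm_dcr1": round(r.rpm_dcr1, 3),
            "enrichment_fold": round(r.enrichment_fold, 3),
            "structure": r.fold.structure if r.fold else "",
        })
    return pd.DataFrame(rows)
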