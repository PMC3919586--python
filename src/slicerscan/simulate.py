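"""Synthetic genome and AGO1-IP library simulator.

Plants ground-truth loci in a toy genome and emits per-condition libraries
under the short-hairpin biogenesis model: a Drosha-cropped precursor
(L nt, with an o-nt 3' overhang) is loaded into an Argonaute; Slicer
cleavage of the 3' arm opposite guide positions 10/11 leaves a 5' fragment
of L - o - 10 nt (the Ago-cleaved precursor, "ac-pre"); in AGO1 this is
3'-resected to mature 23-26 nt species, while in AGO2 Hen1 methylation of
the 3' end arrests it at the ac-pre stage.  All three species classes
share a single genomic 5' end on the locus strand.

Two library conditions are modelled: a control knockdown (``gfp_kd``) and
a Dicer-1 knockdown (``dcr1_kd``) in which canonical mature miRNAs are
depleted, pre-miRNAs accumulate, short-hairpin loading rises ~8.3-fold and
hpRNA-siRNA loading ~2.8-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import Library, ReadSpecies, revcomp

CONDITIONS = ("gfp_kd", "dcr1_kd")

LOCUS_CLASSES = (
    "canonical_mirna",
    "short_hairpin",
    "hpRNA",
    "decoy_low_coverage",
    "decoy_mixed_strand",
    "decoy_unstructured",
)


def slicer_product_length(L: int, o: int = 2) -> int:
    """Length of the 5' fragment retained after Slicer cleavage.

    The guide strand is the hairpin's 5' arm; position i of the guide pairs
    with hairpin position L - o + 1 - i (1-based), and Slicer cuts between
    the bases paired to guide positions 10 and 11, keeping the 5' fragment
    of length L - o - 10.  For the 42-nt mir-451-class precursor with a
    2-nt overhang this gives the 30-nt ac-pre species.
    """
    if L - o - 10 <= 10:
        raise ValueError("hairpin too short to slice")
    return L - o - 10


@dataclass
class PlantedLocus:
    id: str
    locus_class: str
    chrom: str
    start: int
    end: int
    strand: str
    arm_len: int = 0
    loop_len: int = 0
    overhang: int = 0
    expression: float = 0.0

    @property
    def precursor_len(self) -> int:
        # stem arms + terminal loop + unpaired Drosha 3' overhang
        return 2 * self.arm_len + self.loop_len + self.overhang


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and libraries.

    Effect sizes anchor to the AGO1-IP sequencing comparison: short-hairpin
    loading x8.34 and hpRNA-siRNA x2.75 under dcr-1 knockdown; canonical
    mature x0.1 / pre-miRNA x5 are qualitative defaults for the strong
    dicing defect.  Per-class expression weights are expected read units on
    a common absolute scale across conditions.
    """

    seed: int = 0
    genome_len: int = 60_000
    chrom: str = "chrT"
    n_canonical: int = 3
    n_short_hairpin: int = 3
    n_hpRNA: int = 2
    n_decoy_low_coverage: int = 2
    n_decoy_mixed_strand: int = 2
    n_decoy_unstructured: int = 2
    n_background: int = 2000

    # hairpin geometry
    sh_arm_len: int = 18
    sh_loop_len: int = 4
    overhang: int = 2
    canonical_arm_len: int = 22
    canonical_loop_len: int = 12
    stem_mismatch_positions: tuple = ()

    # condition effect sizes
    dcr1_shorthairpin_fold: float = 8.34
    dcr1_hpRNA_fold: float = 2.75
    dcr1_mature_mirna_factor: float = 0.1
    dcr1_premirna_factor: float = 5.0

    # routing and resection
    ago1_routing_fraction: float = 0.4
    resection_len_range: tuple = (23, 26)
    sh_pre_fraction: float = 0.1

    # canonical locus species split (AGO1-IP; mature on the 3' arm)
    canonical_mature_fraction: float = 0.85
    canonical_star_fraction: float = 0.05
    canonical_pre_fraction: float = 0.10

    # expression weights (expected read units per locus, gfp scale)
    expr_canonical: float = 2000.0
    expr_short_hairpin: float = 100.0
    expr_hpRNA: float = 150.0
    expr_decoy_low_coverage: float = 2.0
    expr_decoy_mixed_strand: float = 200.0
    expr_decoy_unstructured: float = 200.0
    expr_background_total: float = 1200.0

    library_depth: int = 50_000
    spike_in_count: int = 10
    spike_base_count: int = 100

    def validate(self) -> None:
        for name in ("dcr1_shorthairpin_fold", "dcr1_hpRNA_fold",
                     "dcr1_mature_mirna_factor", "dcr1_premirna_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ago1_routing_fraction <= 1.0:
            raise ValueError("ago1_routing_fraction outside [0, 1]")
        lo, hi = self.resection_len_range
        L = 2 * self.sh_arm_len + self.sh_loop_len + self.overhang
        acpre = slicer_product_length(L, self.overhang)
        if not (10 < lo <= hi <= acpre):
            raise ValueError(
                f"resection range {self.resection_len_range} outside (10, {acpre}]")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _hairpin_seq(rng, arm_len, loop_len, overhang, mismatches=()) -> str:
    arm5 = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len, "ACT")  # loop kept AU/C-rich
    arm3 = list(revcomp(arm5))
    for pos in mismatches:
        # mismatch at stem position pos (0-based from the outer end of arm3)
        old = arm3[pos]
        arm3[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
    tail = _random_seq(rng, overhang, "ACT")
    return arm5 + loop + "".join(arm3) + tail


_LOCUS_SPANS = {
    "canonical_mirna": lambda c: 2 * c.canonical_arm_len + c.canonical_loop_len + c.overhang,
    "short_hairpin": lambda c: 2 * c.sh_arm_len + c.sh_loop_len + c.overhang,
    "hpRNA": lambda c: 120,
    "decoy_low_coverage": lambda c: 24,
    "decoy_mixed_strand": lambda c: 26,
    "decoy_unstructured": lambda c: 44,
}


def build_toy_genome(config: SimulationConfig):
    """Deterministically place planted loci in a random background genome.

    Returns ``(genome, loci)`` where genome is a dict chrom -> sequence.
    Raises if ``genome_len`` cannot accommodate all loci.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    order = []
    for cls in LOCUS_CLASSES:
        n = getattr(config, {
            "canonical_mirna": "n_canonical",
            "short_hairpin": "n_short_hairpin",
            "hpRNA": "n_hpRNA",
            "decoy_low_coverage": "n_decoy_low_coverage",
            "decoy_mixed_strand": "n_decoy_mixed_strand",
            "decoy_unstructured": "n_decoy_unstructured",
        }[cls])
        order.extend([cls] * n)
    # interleave classes so no class clusters at one end
    order = [order[i] for i in rng.permutation(len(order))]

    genome = list(_random_seq(rng, config.genome_len))
    loci: list[PlantedLocus] = []
    pos = 100
    counters: dict = {}
    for cls in order:
        span = _LOCUS_SPANS[cls](config)
        gap = int(rng.integers(80, 200))
        start = pos + gap
        end = start + span
        if end + 100 > config.genome_len:
            raise ValueError(
                f"genome_len {config.genome_len} too small to place "
                f"remaining {cls} locus")
        idx = counters.get(cls, 0)
        counters[cls] = idx + 1
        strand = "+" if rng.random() < 0.5 else "-"
        locus = PlantedLocus(
            id=f"{cls}_{idx}", locus_class=cls, chrom=config.chrom,
            start=start, end=end, strand=strand,
        )
        if cls == "canonical_mirna":
            locus.arm_len = config.canonical_arm_len
            locus.loop_len = config.canonical_loop_len
            locus.overhang = config.overhang
            seq = _hairpin_seq(rng, locus.arm_len, locus.loop_len,
                               locus.overhang, config.stem_mismatch_positions)
            locus.expression = config.expr_canonical
        elif cls == "short_hairpin":
            locus.arm_len = config.sh_arm_len
            locus.loop_len = config.sh_loop_len
            locus.overhang = config.overhang
            seq = _hairpin_seq(rng, locus.arm_len, locus.loop_len,
                               locus.overhang, config.stem_mismatch_positions)
            locus.expression = config.expr_short_hairpin
        elif cls == "hpRNA":
            arm = (span - 8) // 2
            seq = _hairpin_seq(rng, arm, span - 2 * arm, 0)
            locus.expression = config.expr_hpRNA
        elif cls == "decoy_unstructured":
            # low-complementarity by construction: A/C alphabet cannot pair
            seq = _random_seq(rng, span, "AC")
            locus.expression = config.expr_decoy_unstructured
        else:
            seq = _random_seq(rng, span)
            locus.expression = getattr(config, f"expr_{cls}")
        if strand == "-":
            seq = revcomp(seq)
        genome[start:end] = list(seq)
        loci.append(locus)
        pos = end
    return {config.chrom: "".join(genome)}, loci


# ---------------------------------------------------------------------------
# species expectations per locus
# ---------------------------------------------------------------------------

def _species_interval(locus: PlantedLocus, length: int):
    """Genomic interval of a species sharing the locus 5' end."""
    if locus.strand == "+":
        return locus.start, locus.start + length
    return locus.end - length, locus.end


def _mk_species(genome, locus, length, cls, weight, methylated=False, tag=""):
    start, end = _species_interval(locus, length)
    seq = genome[locus.chrom][start:end]
    if locus.strand == "-":
        seq = revcomp(seq)
    return ReadSpecies(
        sequence=seq, chrom=locus.chrom, start=start, end=end,
        strand=locus.strand, count=0, species_class=cls,
        methylated3p=methylated,
        species_id=f"{locus.id}:{cls}{tag}",
    ), weight


def _canonical_species(genome, locus, config, condition):
    """Mature (3' arm) + star (5' arm) + pre species of a canonical locus."""
    L = locus.precursor_len
    a, l = locus.arm_len, locus.loop_len
    mature_f = config.canonical_mature_fraction
    star_f = config.canonical_star_fraction
    pre_f = config.canonical_pre_fraction
    if condition == "dcr1_kd":
        mature_f *= config.dcr1_mature_mirna_factor
        star_f *= config.dcr1_mature_mirna_factor
        pre_f *= config.dcr1_premirna_factor
    out = []
    # pre: full hairpin, shares locus 5' end
    out.append(_mk_species(genome, locus, L, "pre", locus.expression * pre_f))
    # star: 5' arm; mature: 3' arm (so canonical loci lack 5'-shared long reads)
    if locus.strand == "+":
        star_iv = (locus.start, locus.start + a)
        mat_iv = (locus.start + a + l, locus.start + 2 * a + l)
    else:
        star_iv = (locus.end - a, locus.end)
        mat_iv = (locus.end - 2 * a - l, locus.end - a - l)
    for iv, cls, w in ((star_iv, "star", locus.expression * star_f),
                       (mat_iv, "mature", locus.expression * mature_f)):
        seq = genome[locus.chrom][iv[0]:iv[1]]
        if locus.strand == "-":
            seq = revcomp(seq)
        out.append((ReadSpecies(
            sequence=seq, chrom=locus.chrom, start=iv[0], end=iv[1],
            strand=locus.strand, count=0, species_class=cls,
            species_id=f"{locus.id}:{cls}"), w))
    return out


def _short_hairpin_species(genome, locus, config, condition):
    """Precursor, arrested ac-pre (AGO2, methylated) and resected 23-26 nt
    trimmed species (AGO1), all sharing the locus 5' end."""
    expr = locus.expression
    if condition == "dcr1_kd":
        expr *= config.dcr1_shorthairpin_fold
    L = locus.precursor_len
    acpre_len = slicer_product_length(L, locus.overhang)
    r = config.ago1_routing_fraction
    pre_f = config.sh_pre_fraction
    out = [_mk_species(genome, locus, L, "pre", expr * pre_f)]
    loaded = expr * (1.0 - pre_f)
    if r < 1.0:
        out.append(_mk_species(genome, locus, acpre_len, "ac_pre",
                               loaded * (1.0 - r), methylated=True))
    if r > 0.0:
        lo, hi = config.resection_len_range
        lengths = list(range(lo, hi + 1))
        for n in lengths:
            out.append(_mk_species(genome, locus, n, "trimmed",
                                   loaded * r / len(lengths), tag=f"_{n}"))
    return out


def _hpRNA_species(genome, locus, config, condition):
    """21-nt siRNAs tiled across the inverted repeat, both genomic strands
    (arm-ambiguous multi-mapping makes hpRNA siRNAs appear on both)."""
    expr = locus.expression
    if condition == "dcr1_kd":
        expr *= config.dcr1_hpRNA_fold
    out = []
    n_species = 6
    step = (locus.end - locus.start - 21) // (n_species - 1)
    for k in range(n_species):
        start = locus.start + k * step
        end = start + 21
        strand = "+" if k % 2 == 0 else "-"
        seq = genome[locus.chrom][start:end]
        if strand == "-":
            seq = revcomp(seq)
        out.append((ReadSpecies(
            sequence=seq, chrom=locus.chrom, start=start, end=end,
            strand=strand, count=0, species_class="siRNA",
            species_id=f"{locus.id}:siRNA_{k}"), expr / n_species))
    return out


def _decoy_species(genome, locus, config, condition):
    out = []
    if locus.locus_class == "decoy_low_coverage":
        out.append(_mk_species(genome, locus, 24, "background", locus.expression))
    elif locus.locus_class == "decoy_mixed_strand":
        for strand, tag in (("+", "_p"), ("-", "_m")):
            seq = genome[locus.chrom][locus.start:locus.end]
            if strand == "-":
                seq = revcomp(seq)
            out.append((ReadSpecies(
                sequence=seq, chrom=locus.chrom, start=locus.start,
                end=locus.end, strand=strand, count=0,
                species_class="background",
                species_id=f"{locus.id}:background{tag}"),
                locus.expression / 2))
    else:  # decoy_unstructured: stacked same-strand species, shared 5' end
        for n in (22, 25, 28):
            start = locus.start + 2
            end = start + n
            seq = genome[locus.chrom][start:end]
            if locus.strand == "-":
                start = locus.end - 2 - n
                end = locus.end - 2
                seq = revcomp(genome[locus.chrom][start:end])
            out.append((ReadSpecies(
                sequence=seq, chrom=locus.chrom, start=start, end=end,
                strand=locus.strand, count=0, species_class="background",
                species_id=f"{locus.id}:background_{n}"),
                locus.expression / 3))
    return out


def _background_species(genome, loci, config, rng):
    """Scattered low-count background species, kept clear of planted loci."""
    forbidden = []
    for loc in loci:
        forbidden.append((loc.start - 40, loc.end + 40))
    chrom = config.chrom
    glen = config.genome_len
    out = []
    per = config.expr_background_total / max(config.n_background, 1)
    k = 0
    while k < config.n_background:
        n = int(rng.integers(19, 29))
        start = int(rng.integers(0, glen - n))
        if any(start < e and start + n > s for s, e in forbidden):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[chrom][start:start + n]
        if strand == "-":
            seq = revcomp(seq)
        out.append((ReadSpecies(
            sequence=seq, chrom=chrom, start=start, end=start + n,
            strand=strand, count=0, species_class="background",
            species_id=f"background_{k}"), per))
        k += 1
    return out


def _spike_species(config, rng):
    out = []
    for k in range(config.spike_in_count):
        seq = _random_seq(rng, 22)
        count = config.spike_base_count * (k + 1)
        out.append(ReadSpecies(
            sequence=seq, chrom="spike", start=0, end=22, strand="+",
            count=count, species_class="spike", species_id=f"spike_{k}"))
    return out


def expected_species(genome, loci, condition: str, config: SimulationConfig):
    """(species, weight) expectations for one condition, common scale."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; use one of {CONDITIONS}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    out = []
    for locus in loci:
        if locus.locus_class == "canonical_mirna":
            out.extend(_canonical_species(genome, locus, config, condition))
        elif locus.locus_class == "short_hairpin":
            out.extend(_short_hairpin_species(genome, locus, config, condition))
        elif locus.locus_class == "hpRNA":
            out.extend(_hpRNA_species(genome, locus, config, condition))
        else:
            out.extend(_decoy_species(genome, locus, config, condition))
    out.extend(_background_species(genome, loci, config, rng))
    return [(sp, w) for sp, w in out if w > 0]


def simulate_library(genome, loci, condition: str, config: SimulationConfig,
                     expectation_mode: bool = False) -> Library:
    """Simulate one AGO1-IP library.

    Sampled mode draws ``library_depth`` reads multinomially from the
    per-species expectations; ``total_mapped`` is the realized non-spike sum
    (= depth).  Expectation mode instead emits rounded expected counts on a
    common absolute scale across conditions (control expectations sum to the
    configured depth) and records the configured depth as the RPM
    denominator for both conditions, so configured condition folds are
    recovered exactly.
    """
    pairs = expected_species(genome, loci, condition, config)
    species = [sp for sp, _ in pairs]
    weights = np.array([w for _, w in pairs], dtype=float)
    # common scale: control-condition weights sum to library_depth
    gfp_total = sum(w for _, w in expected_species(genome, loci, "gfp_kd", config)) \
        if condition != "gfp_kd" else weights.sum()
    scale = config.library_depth / gfp_total
    if expectation_mode:
        for sp, w in zip(species, weights):
            sp.count = int(round(w * scale))
        total = config.library_depth
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 303, CONDITIONS.index(condition)]))
        counts = rng.multinomial(config.library_depth, weights / weights.sum())
        for sp, c in zip(species, counts):
            sp.count = int(c)
        total = int(counts.sum())
    species = [sp for sp in species if sp.count > 0]
    spikes = _spike_species(config, np.random.default_rng(
        np.random.SeedSequence([config.seed, 404])))
    lib = Library(
        condition=condition,
        species=species + spikes,
        total_mapped=total,
        spike_observed={sp.species_id: sp.count for sp in spikes},
    )
    return lib


# ---------------------------------------------------------------------------
# raw read emission (FASTQ)
# ---------------------------------------------------------------------------

ADAPTER3_CONSTANT = "TGGAATTCTCGGGTGCCAAGG"


def emit_raw_reads(library: Library, adapter3: str = ADAPTER3_CONSTANT,
                   n_random: int = 4, seed: int = 0):
    """Yield FASTQ records reconstructing the library-cloning read layout:
    4 random nt + insert + 4 random nt + 3'-adapter constant region.

    The randomized nucleotides mimic the randomized-adapter design used to
    suppress ligation bias; they carry no information and are stripped again
    by :func:`slicerscan.seqio.trim_and_collapse`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    bases = np.array(list("ACGT"))
    idx = 0
    for sp in library.species:
        for rep in range(sp.count):
            rand = "".join(bases[rng.integers(0, 4, 2 * n_random)])
            read = rand[:n_random] + sp.sequence + rand[n_random:] + adapter3
            yield (f"read{idx}_{sp.species_id}_{rep}", read, "I" * len(read))
            idx += 1


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
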