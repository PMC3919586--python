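"""Core record types shared across the pipeline.

Coordinates are 0-based, half-open (BED convention) everywhere inside the
package; conversion to 1-based happens only at the SAM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(COMPLEMENT)[::-1]


SPECIES_CLASSES = (
    "pre",
    "ac_pre",
    "trimmed",
    "mature",
    "star",
    "siRNA",
    "spike",
    "background",
)


@dataclass
class ReadSpecies:
    """A collapsed, aligned small-RNA species.

    ``start``/``end`` are genomic, 0-based half-open.  ``sequence`` is the
    read sequence in molecule orientation (5'->3'); for minus-strand species
    it is the reverse complement of the genomic slice.  ``methylated3p``
    marks 2'-O-methylated 3' termini (Hen1 products in AGO2), which the
    simulator never resects.
    """

    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    count: int
    species_class: str = "background"
    methylated3p: bool = False
    species_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.sequence and self.end - self.start != len(self.sequence):
            raise ValueError(
                f"interval length {self.end - self.start} != sequence length "
                f"{len(self.sequence)} for species {self.species_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end (position of the last base)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Library:
    """One sequencing library (e.g. one AGO1-IP condition).

    ``total_mapped`` is the RPM denominator.  In sampled mode it equals the
    sum of non-spike species counts; spike-ins are exogenous and excluded.
    """

    condition: str
    species: list = field(default_factory=list)
    total_mapped: int = 0
    spike_observed: dict = field(default_factory=dict)

    def mapped_species(self) -> list:
        return [s for s in self.species if s.species_class != "spike"]

    def recompute_total(self) -> None:
        self.total_mapped = sum(s.count for s in self.mapped_species())
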