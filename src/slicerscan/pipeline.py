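"""End-to-end orchestration: simulate -> trim -> quantify -> scan -> report.

A single seeded, configured run producing deterministic (byte-identical)
output bundles.  Every output file carries a header comment with package
version, seed and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import composition, read_annotation_bed, truth_annotation
from .records import Library
from .scan import ScanParams, candidates_table, scan_genome
from .seqio import (TrimParams, library_sequence_table, parse_alignments,
                    trim_and_collapse, write_bed, write_fasta,
                    write_species_tsv)
from .simulate import (SimulationConfig, build_toy_genome, emit_raw_reads,
                       simulate_library, write_fastq)

log = logging.getLogger("slicerscan")


@dataclass
class RunConfig:
    mode: str = "synthetic"  # or "real"
    outdir: str = "slicerscan_out"
    seed: int = 0
    expectation_mode: bool = False
    write_fastq: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    trim: TrimParams = field(default_factory=TrimParams)
    scan: ScanParams = field(default_factory=ScanParams)
    # real-mode inputs
    genome_fasta: str | None = None
    gfp_alignments: str | None = None
    dcr1_alignments: str | None = None
    annotation_bed: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for name in ("genome_fasta", "gfp_alignments", "dcr1_alignments"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"real mode requires {name}")
                if not Path(path).exists():
                    raise ValueError(f"{name} does not exist: {path}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls()
        for key, value in raw.items():
            if key in ("sim", "trim", "scan"):
                sub = getattr(cfg, key)
                for k, v in value.items():
                    if not hasattr(sub, k):
                        raise ValueError(f"unknown {key} option {k!r}")
                    setattr(sub, k, tuple(v) if isinstance(v, list) else v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig) -> str:
    """Fingerprint of the analysis parameters (output location excluded)."""
    d = config.to_dict()
    d.pop("outdir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# slicerscan v{__version__} seed={config.seed} "
            f"config={config_hash(config)}\n")


def _write_with_header(path, header: str, body: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(body)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the report dict.

    Synthetic mode generates the genome, truth tables, FASTQ and alignments
    itself, trims the FASTQ back and verifies the species table round-trip
    as part of QC.  Real mode consumes pre-computed alignments.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    stage = "setup"
    report: dict = {
        "version": __version__, "seed": config.seed,
        "config_hash": config_hash(config), "mode": config.mode,
        "parameters": config.to_dict(),
    }
    try:
        if config.mode == "synthetic":
            stage = "simulate"
            config.sim.seed = config.seed
            genome, loci = build_toy_genome(config.sim)
            write_fasta(genome, outdir / "genome.fa")
            with open(outdir / "loci.tsv", "w") as fh:
                fh.write(header)
                fh.write("id\tclass\tchrom\tstart\tend\tstrand\tprecursor_len\n")
                for loc in loci:
                    fh.write(f"{loc.id}\t{loc.locus_class}\t{loc.chrom}\t"
                             f"{loc.start}\t{loc.end}\t{loc.strand}\t"
                             f"{loc.precursor_len}\n")
            libraries = {}
            qc_all = {}
            for cond in ("gfp_kd", "dcr1_kd"):
                lib = simulate_library(genome, loci, cond, config.sim,
                                       config.expectation_mode)
                libraries[cond] = lib
                write_bed(lib.species, outdir / f"{cond}.bed")
                if config.write_fastq:
                    stage = f"emit+trim {cond}"
                    fq = outdir / f"{cond}.fastq"
                    write_fastq(
                        emit_raw_reads(lib, config.trim.adapter3_constant,
                                       config.trim.n_random_each_side,
                                       seed=config.seed), fq)
                    table, qc = trim_and_collapse(
                        (seq for _, seq in _iter_fastq_seqs(fq)), config.trim)
                    write_species_tsv(table, outdir / f"{cond}.collapsed.tsv")
                    truth = library_sequence_table(lib)
                    in_range = {
                        s: c for s, c in truth.items()
                        if config.trim.min_insert_len <= len(s)
                        <= config.trim.max_insert_len}
                    qc["roundtrip_exact"] = table == in_range
                    qc_all[cond] = qc
            annotation = truth_annotation(loci)
        else:
            stage = "load inputs"
            from pyfaidx import Fasta
            fa = Fasta(config.genome_fasta)
            genome = {name: str(fa[name][:]) for name in fa.keys()}
            libraries = {}
            for cond, path in (("gfp_kd", config.gfp_alignments),
                               ("dcr1_kd", config.dcr1_alignments)):
                fmt = "SAM" if str(path).endswith(".sam") else "BED"
                species = parse_alignments(path, fmt, genome)
                lib = Library(condition=cond, species=species)
                lib.recompute_total()
                libraries[cond] = lib
            annotation = (read_annotation_bed(config.annotation_bed)
                          if config.annotation_bed else None)
            qc_all = {}

        stage = "composition"
        comps = {}
        for cond, lib in libraries.items():
            summary = composition(lib, annotation) if annotation else None
            if summary:
                comps[cond] = {
                    "counts": summary.counts,
                    "fractions": {k: round(v, 6)
                                  for k, v in summary.fractions.items()},
                    "non_miRNA_fraction": round(summary.non_miRNA_fraction, 6),
                }
        if comps:
            body = "condition\t" + "\t".join(
                f"{c}_fraction" for c in comps["gfp_kd"]["fractions"]) + "\n"
            for cond in comps:
                body += cond + "\t" + "\t".join(
                    str(v) for v in comps[cond]["fractions"].values()) + "\n"
            _write_with_header(outdir / "composition.tsv", header, body)

        stage = "scan"
        candidates = scan_genome(libraries["gfp_kd"], libraries["dcr1_kd"],
                                 genome, annotation, config.scan)
        table = candidates_table(candidates)
        with open(outdir / "candidates.tsv", "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)
        with open(outdir / "candidates.bed", "w") as fh:
            fh.write(header)
            for k, r in enumerate(candidates):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tcandidate_{k}\t"
                         f"{int(r.peak_coverage)}\t{r.strand}\n")

        stage = "report"
        report["qc"] = qc_all
        report["composition"] = comps
        if len(comps) == 2:
            ratio = (comps["dcr1_kd"]["non_miRNA_fraction"]
                     / comps["gfp_kd"]["non_miRNA_fraction"])
            report["non_mirna_fraction_ratio"] = round(ratio, 4)
        report["n_candidates"] = len(candidates)
        report["candidates"] = [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "strand": r.strand, "dG": r.dG, "flags": r.flags,
             "rpm_gfp": round(r.rpm_gfp, 3), "rpm_dcr1": round(r.rpm_dcr1, 3),
             "enrichment_fold": round(r.enrichment_fold, 4)}
            for r in candidates]
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _iter_fastq_seqs(path):
    with open(path) as fh:
        while True:
            name = fh.readline()
            if not name:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield name.strip().lstrip("@"), seq
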