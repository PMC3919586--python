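# slicerscan

Discovery of candidate **Dicer-independent (mir-451-like) short-hairpin
miRNA loci** from AGO1-immunoprecipitation small-RNA sequencing, together
with a ground-truth simulator of the Slicer-dependent biogenesis pathway.

## The scientific problem

Most animal miRNAs are made canonically: Drosha crops a ~55–70 nt
pre-miRNA hairpin, Dicer cuts near the terminal loop, and the resulting
duplex loads an Argonaute. The mir-451 class is different: its Drosha
product is only ~42 nt — too short for Dicer — so the hairpin loads an
Argonaute directly. A Slicer-competent Argonaute cleaves the 3′ arm
opposite guide positions 10/11, leaving a 30 nt *Ago-cleaved* precursor
(ac-pre-miRNA):

```
len(ac-pre) = L − o − 10        (L = precursor length, o = 3′ overhang)
            = 42 − 2 − 10 = 30 nt
```

In *Drosophila*, AGO1-loaded ac-pre hairpins are 3′-resected to mature
~23–26 nt miRNAs, whereas AGO2-loaded ones are 2′-O-methylated by Hen1 and
arrested at 30 nt. Depleting Dicer-1 frees AGO1 from canonical substrates,
boosting short-hairpin loading ~8.3-fold and roughly doubling the
non-miRNA fraction of the AGO1-IP library — the signal this package
exploits to hunt novel loci of the class.

A candidate locus must satisfy, per strand of the genome:

* coverage ≥ 40 reads at every base of a run ≥ 20 nt,
* ≥ 75% of overlapping reads on one strand (count-weighted),
* folding free energy ΔG ≤ −10 kcal/mol for the flank-extended window,

and is then classified by its read signature: a dominant 5′ end with 3′
heterogeneity, mature reads crossing the terminal loop, ac-pre-like long
reads extending into the 3′ arm, and enrichment in the *dcr-1* knockdown
relative to the *gfp* control (RPM fold change, with a 0.5 pseudocount on
zero counts).

## What's in the box

| module | role |
|---|---|
| `slicerscan.simulate` | toy genome with planted loci (canonical miRNA, short hairpin, hpRNA, three decoy classes), seeded AGO1-IP library sampling under `gfp_kd` / `dcr1_kd` conditions, FASTQ emission with the randomized-adapter layout |
| `slicerscan.seqio` | adapter trimming and read collapsing, RPM, spike-in scaling, FASTA/FASTQ/BED6/SAM IO |
| `slicerscan.annotate` | strand-aware interval intersection, category assignment, library composition, fold changes |
| `slicerscan.fold` | simplified nearest-neighbour MFE folding (stacks + loop penalties), exhaustive enumeration oracle, hairpin anatomy, optional RNAfold plug-in |
| `slicerscan.scan` | coverage-run detection, strand/fold filters, read-signature classification, enrichment ranking |
| `slicerscan.pipeline` / `slicerscan.cli` | one seeded, configured, deterministic run: simulate → trim → quantify → scan → report |

## Worked example

```bash
slicerscan run --mode synthetic --seed 42 --out demo_out
slicerscan report --report demo_out/report.json
```

prints

```
slicerscan v0.1.0 seed=42 config=6a05e7f5bcc7
non-miRNA fraction ratio (dcr-1/gfp): 1.9742
candidates: 3
  chrT:831-873(-) dG=-28.5 enrichment=8.531
  chrT:227-269(+) dG=-25.8 enrichment=8.2596
  chrT:393-435(-) dG=-28.2 enrichment=8.1929
```

Reading this: the simulated *dcr-1* knockdown AGO1-IP library contains
about twice the control's fraction of non-miRNA reads (1.97×), and the
scan recovered exactly the three planted 42-nt short-hairpin loci — each a
stable hairpin (ΔG ≤ −25 kcal/mol, far below the −10 threshold) enriched
~8.2–8.5-fold in the knockdown, scattering around the configured 8.34-fold
loading increase because counts are multinomially sampled. No canonical
miRNA, hpRNA or decoy locus appears. Each candidate also carries the four
signature flags (`demo_out/candidates.tsv` has the full table with
dot-bracket structures).

The same stages are importable directly:

```python
from slicerscan import SimulationConfig, build_toy_genome, simulate_library, scan_genome
from slicerscan.annotate import truth_annotation

cfg = SimulationConfig(seed=42)
genome, loci = build_toy_genome(cfg)
gfp  = simulate_library(genome, loci, "gfp_kd", cfg)
dcr1 = simulate_library(genome, loci, "dcr1_kd", cfg)
hits = scan_genome(gfp, dcr1, genome, truth_annotation(loci))
```

Real data enter through `slicerscan run --mode real --config ...` (see
`examples/real-template.json`) with a genome FASTA, per-condition BED/SAM
alignments of collapsed reads, and an optional annotation BED.

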