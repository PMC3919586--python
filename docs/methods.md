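# Methods

This note documents the models behind `slicerscan`, the defaults and why
they were chosen, and what the synthetic benchmark does and does not show
about real data.

## Biogenesis model

The short-hairpin (mir-451-like) pathway is modelled as three species
classes per locus, all sharing one genomic 5′ end on the locus strand:

1. **pre** — the Drosha product: a hairpin of length
   `L = 2·arm_len + loop_len + overhang`, where the `o = overhang` nt at
   the 3′ end are the unpaired RNase-III 3′ overhang (defaults: 18-bp
   arms, 4-nt loop, 2-nt overhang → L = 42).
2. **ac_pre** — the Ago-cleaved intermediate. The hairpin's 5′ arm acts as
   the guide; guide position *i* pairs with hairpin position `L − o + 1 − i`
   (1-based), Slicer cuts between the bases paired to guide positions 10
   and 11, and the retained 5′ fragment has length `L − o − 10` (30 nt at
   the defaults). `slicer_product_length` refuses hairpins where this
   fragment would not extend past the guide (`L − o − 10 ≤ 10`).
3. **trimmed** — 3′-resected mature species. Lengths are uniform over
   `resection_len_range = [23, 26]`; only the range is empirically
   grounded, so the distribution within it is a modelling choice and
   configurable.

Routing decides the fate of a loaded hairpin: a fraction
`ago1_routing_fraction` (default 0.4) goes to AGO1 and matures fully into
trimmed species; the remainder goes to AGO2, is 2′-O-methylated at the 3′
end by Hen1 (`methylated3p = True`) and arrests as ac_pre — methylated
species are never resected by the simulator. A consequence used by the
tests: the trimmed:ac_pre count ratio equals `r : (1 − r)` exactly, and
with `r = 0` no trimmed species exist at all. A further `sh_pre_fraction`
(0.1) of each locus' reads are unprocessed precursors, mirroring the
precursor band seen alongside the intermediates in Ago complexes.

Canonical miRNA loci emit mature (3′ arm, 85%), star (5′ arm, 5%) and pre
(10%) species. Placing the mature species on the 3′ arm makes canonical
loci a proper negative control for the ac-pre-like signature: no long
read shares the modal 5′ end. hpRNA loci emit 21-nt siRNAs tiled across
the inverted repeat on alternating genomic strands (multi-mapping between
the arms of an inverted repeat makes real hpRNA siRNAs strand-ambiguous),
which causes them to fail the 75% strand filter.

## Condition effect sizes

Under `dcr1_kd` relative to `gfp_kd`:

| effect | default | basis |
|---|---|---|
| short-hairpin loading | ×8.34 | measured RPM fold change of the mir-451 reporter between the AGO1-IP libraries |
| hpRNA-siRNA loading | ×2.75 | measured fold change of hpRNA-derived siRNAs |
| canonical mature / star | ×0.1 | qualitative: strong dicing defect (blot-level evidence only) |
| canonical pre-miRNA | ×5.0 | qualitative: precursor accumulation (blot-level evidence only) |

The last two are explicitly calibration defaults, not measured values.
Per-locus weights (canonical 2000, short hairpin 100, hpRNA 150, decoys
2/200/200, background 1200 total) were chosen once so that (a) every
planted short hairpin clears the 40× coverage threshold comfortably in
the control library, (b) the low-coverage decoy stays well below it even
in the two-condition union, and (c) the non-miRNA read fraction of the
knockdown library comes out ≈2× the control's, the composition shift the
scan design presupposes. Loci load independently; competition for a
shared Argonaute pool is not modelled.

## Sampling, expectation mode and RPM folds

Sampled mode draws `library_depth` (50 000) reads multinomially from the
per-species weights of that condition, so `total_mapped` equals the
realized non-spike sum and all RPM denominators are honest library sums.
Note that realized RPM fold changes then deviate from the configured
loading folds, because the knockdown changes total library composition
(≈8.1 realized vs 8.34 configured at the defaults) — the same
denominator effect that motivates spike-in normalization in real
experiments. Ten spike-in oligos at fixed known counts (100…1000) are
carried in every library, excluded from RPM denominators, and
`spike_scale` recovers a cross-library absolute scale as the median
expected/observed ratio (robust to a single dropout).

Expectation mode exists for deterministic tests: it emits rounded
expected counts on a common absolute scale (control expectations sum to
the configured depth) and records the configured depth as the RPM
denominator for both conditions. This makes configured folds exactly
recoverable from the output; the deviation from the "denominator = sum of
counts" rule is deliberate and confined to this mode.

## Read emission and trimming

Raw reads reconstruct the cloning layout: 4 random nt + insert + 4 random
nt + the 3′-adapter constant region `TGGAATTCTCGGGTGCCAAGG`. Trimming
locates the leftmost adapter occurrence (exact match fast path, then a
Hamming scan allowing 1 mismatch over ≥10 bases, including matches running
off the read end), removes it, strips the fixed-width randomized bases
from both ends and collapses identical inserts. The default insert window
is 18–50 nt; the 58-nt canonical precursors simulated here are
deliberately longer than that window, so exact round-trip comparisons use
`max_insert_len = 60`. The randomized 4-mers are stripped, not used as
UMIs; no sequencing-error, quality or PCR-duplicate model is included, so
the round-trip identity shows bookkeeping correctness, not robustness to
sequencing noise.

## Folding model

`fold_mfe` minimizes a deliberately small nearest-neighbour energy over
non-crossing structures (minimum hairpin loop 3; pairs AU/UA/GC/CG/GU/UG;
T≡U; N never pairs):

* **stacks** are the only favourable term: a per-step table
  (`data/stack_energies.tsv`) built from per-pair contributions
  GC −1.5, AU −0.6, GU −0.3 kcal/mol (so a GC/GC step is −3.0, GC/AU
  −2.1, AU/AU −1.2 — Turner-magnitude, not Turner-accurate);
* **loops** are charged size-dependent penalties
  (`data/loop_penalties.tsv`): hairpin 5.0/4.5/… capped at 7.0,
  bulge/internal 2.9 + 0.4 per nt capped at 6.0, multiloop a flat 3.0;
* an isolated (unstacked) pair contributes nothing, so it can never beat
  the open chain; the open chain is always admissible, hence ΔG ≤ 0.

Energies are integer tenths of kcal/mol throughout, so the dynamic
program (interior-loop recursion without a size cap, multiloop via a
two-branch auxiliary matrix, compiled with numba) agrees **exactly** with
the exhaustive enumeration oracle — verified for every sequence of length
≤ 10 and random sequences to 16 nt. Ties are broken toward fewer pairs
(an exact secondary DP objective packed into the cost integer) and then
by a fixed traceback preference order, making structures byte-stable.

The model reproduces hairpin-vs-unstructured discrimination at the
−10 kcal/mol threshold; it does not attempt numeric agreement with
RNAfold's Turner-model ΔG, and absolute candidate ΔG values are therefore
model-specific. The scanner accepts any folder callable with the same
result contract; `rnafold_folder` wraps an external RNAfold binary for
cross-checks, and threshold decisions are folder-agnostic.

`hairpin_anatomy` is strict (exactly one terminal loop or nothing);
`dominant_hairpin` is the tolerant variant used on scan windows, picking
the terminal loop under the deepest helix so that an incidental 2-bp stem
in flanking sequence does not abolish the loop call.

## Scan semantics

* "40 read coverage over 20 nt" is read strictly: every base of a ≥20-nt
  run must have combined-strand coverage ≥40 (`coverage_mode="mean"` is
  available but not default).
* The strand fraction is count-weighted over whole reads overlapping the
  run, not per-base.
* The fold window is the region ± 15 nt flank, reverse-complemented for
  minus-strand regions; ΔG ≤ −10.0 is inclusive.
* Scanning runs on the union of both condition libraries (a locus silent
  in the control must still be discoverable); quantification and
  enrichment are per-condition afterwards, with a 0.5 pseudocount on raw
  counts when either count is zero.
* Signature thresholds — modal-5′ fraction ≥ 0.5, ≥ 2 distinct 3′ ends,
  ac-pre-like length ≥ 27 nt — are quantifications of qualitative
  descriptions ("dominant 5′ end", "3′ heterogeneity") and are exposed in
  `ScanParams`.
* Regions overlapping annotated canonical miRNAs are masked by default
  (the scan hunts novel loci); disable with `mask_annotated_mirna=False`.
* Ranking is by enrichment fold, then peak coverage, then coordinates.

## Decoy design and what passing means

The three decoy classes each target exactly one filter: low-coverage
(stays under the 40× threshold even in the two-library union),
mixed-strand (50/50 split fails the 75% rule), and unstructured (an
A/C-only core cannot base-pair, so the window cannot approach
−10 kcal/mol). Planted hairpin stems are perfectly complementary by
construction; even an all-AU 18-bp stem scores ≤ −15 kcal/mol under the
model, so fold-filter recovery is guaranteed by design rather than by
luck. Background reads are spread thinly (2000 species, ~1200 read units
in 60 kb, kept 40 nt clear of planted loci) so random stacking stays far
below the coverage threshold.

Consequently the 100%-sensitivity / zero-decoy benchmark demonstrates
that the implementation applies the stated criteria correctly — it says
nothing about sensitivity or specificity on real libraries, where
coverage is ragged, hairpins are imperfect, multi-mapping is real and the
Turner energy landscape differs from this model.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; 1-based conversion only
  at the SAM boundary (via pysam).
* All randomness flows from numpy `SeedSequence([seed, stream])` spawns,
  one stream per stage, so outputs are byte-identical across runs of the
  same seed; report/TSV headers carry version, seed and a config hash
  (output paths excluded from the hash).
* Empty libraries: composition raises ("no mapped species"); the scan
  returns an empty table.
* Regions at chromosome edges have their fold windows clipped.
* An annotation query on an unknown chromosome returns empty and bumps a
  warning tally rather than raising.

## Known limitations

* Expression weights and the dcr-1 effects on canonical loci are
  calibration defaults, not measurements; only the 8.34× and 2.75×
  folds and the 23–26-nt resection range are anchored to data.
* No sequencing-error/quality model; no PCR duplicates; no AGO2-IP
  library; no multi-mapper fractional assignment.
* The energy model omits dangling ends, coaxial stacking, temperature and
  the partition function; pseudoknots are out of scope.
* Candidate enrichment values from the real AGO1-IP libraries are not
  reproducible without the deposited sequencing data; this package checks
  thresholding behaviour, not those specific numbers.
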