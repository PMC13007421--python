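# Methods

`gmoscreen` is a desk-scale, fully deterministic-per-seed model of an
introduced-gene GM screening workflow.  This note records the models, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open.

## The screening model

A sample is screened by (1) confirming species via a singleplex endogenous
assay (*Lec1* for soybean, *SSIIb* for maize), (2) running the crop's three
multiplex sets, (3) reading the products on simulated CE, (4) matching
positive peaks to member assays by expected size, and (5) decoding the
resulting +/− marker vector against the reference detection matrix.  All
calls are qualitative: the platform decides presence/absence and candidate
events, never GM content.

### Panel

Two amplicon sizes are printed for several assays in the source material;
the canonical size (the one all multiplex/CE interpretation uses) is kept
in `expected_size_bp`, the alternative in `table1_size_bp`, and each
disagreement (six assays: P-ubi10 201/210, T-tml 236/237, T-hsp17.3
111/101, T-H4 139/140, bar 189/242, CP4epsps 332/333) is surfaced as a
panel warning rather than silently resolved — which is correct is not
decidable from the printed record.  Within every multiplex set the sorted
canonical sizes are at least 26 bp apart (the tightest pair: csr1-2 157 vs
T-PinII 131 in Soy III), an order of magnitude above the CE sizing
tolerance, so peak-to-assay assignment is unambiguous at default settings.

Primer-dimer screening uses a 3'-anchored score: the length of the longest
perfect Watson–Crick duplex, over all antiparallel alignments of a primer
pair, that includes the 3'-terminal base of either primer.  Only
3'-anchored duplexes are extension-competent, which is why internal
complementarity is ignored.  Thermodynamic (ΔG) scoring is deliberately
out of scope; the built-in panels are clean at a threshold of 10 (in fact
at 8).  The score is symmetric in its two arguments, so unordered primer
pairs (including self-pairs) are each evaluated once.

### In-silico PCR

Binding sites are exact string matches by default (`max_mismatch = 0`,
`protected_3prime = 3`): the panel's specificity is an empirical property
of the real primers against real genomes, which synthetic templates cannot
re-derive, so exact matching is the faithful default and mismatch
tolerance is an exploration knob.  Products pair a forward site with an
opposite-strand reverse site in extensible orientation, require the two
primer footprints not to overlap, and are capped at 500 bp (the panel's
design bound; anything longer is excluded from analysis).  Product length
runs 5' end of the forward site to 5' end of the reverse site inclusive.
Coordinates are 0-based half-open on the + strand; circular products keep
`end > len(seq)`, which makes wrap-around arithmetic unambiguous.

End-point yield is `min(saturation, k · conc · (1 + e)^cycles · w)` with

| parameter | default | meaning |
|---|---|---|
| `cycles` | 28 multiplex / 30 singleplex | protocol cycle counts |
| `e` | 1.0 (DMO: 0.95) | per-cycle amplification efficiency |
| `k` (`copies_factor`) | 1e-5 (ng/µL)⁻¹-scaled | template-to-signal constant |
| `saturation` | 50 ng/µL | reagent-limited plateau |
| `w` | `min(1, pmol/40)` | saturating primer-amount weight |

This is not a kinetic simulation: cycles enter only as an exponent, and
the model's purpose is to make the *relative* behavior right — working
concentrations (30 ng/µL plasmid, 50 ng/µL genomic) saturate every assay;
a 0.005 % dilution of the plasmid stock (1.5 pg in a 1 µL aliquot) still
calls positive on all markers; 0.0005 % falls below the CE threshold.  The
primer weight saturates at 1 by design: the heavily dosed assays (DMO at
240 pmol, T-PinII at 400 pmol) are dosed *because* they compete poorly, so
their primer excess must compensate competition, not turn them into the
strongest signals.  With a linear weight instead, DMO would overtake every
other assay at low template, inverting its observed reduced sensitivity;
the reduced-efficiency default (0.95) plus the capped weight reproduces
the qualitative pattern (DMO drops out first as template is diluted).  The
mechanism behind DMO's weakness is not modeled — only the observation.

### Constructs

Standard plasmids are circular: `[backbone][insert][spacer]…[insert]`,
every insert `fwd + filler + revcomp(rev)` in the same 5'→3' orientation,
filler length = expected size − primer lengths.  Backbone (default
2000 bp), spacers (30 bp) and fillers are seeded random DNA at 50 % GC,
rejection-sampled until they contain no binding site for any panel primer
on either strand, and the assembled construct is self-verified by plain
substring counting (a code path independent of the PCR engine, which the
test suite uses as the cross-check in the other direction).  Because the
real insert and backbone sequences are not public, total plasmid lengths
(≈4.3 kb here) intentionally do not match the physical constructs
(3930/4010 bp); nothing downstream depends on total length.

Event genomes are linear, carry the endogenous insert plus one insert per
matrix marker at seeded random loci, and default to 3 kb of background —
enough to separate inserts by far more than the 500 bp product cap, so no
cross-insert products can form.  Junction structure of real transformation
events is not modeled; the screening method never queries junctions.
Off-target species are pure primer-free random genomes: they emulate the
*negative* property (no amplification from 29 quarantine species) only.

What passing tests therefore show: the pipeline's arithmetic, calling and
decoding logic are correct on templates that satisfy the panel's intended
binding structure.  What they cannot show: primer specificity or
sensitivity on real genomes, degraded/processed DNA, or inhibitor effects.

### Capillary electrophoresis

Migration time is linear in log(size) between the 20 bp and 1000 bp
alignment markers (defaults 60 s and 240 s, a ~4-minute window).  The
instrument's true sizing model is proprietary; any strictly monotone model
with an exact inverse satisfies the platform's contracts, and the tests
assert only those contracts (anchor exactness, inverse identity, monotone
ordering).  Peaks are Gaussian with a width of σ = 1.2 bp constant in size
units, so two equal fragments 4 bp apart (≈3.3 σ) always separate into two
maxima while 1 bp apart (<2 σ) they merge — matching the instrument
class's advertised 1–4 bp resolution band from the conservative end.
Baseline noise is seeded Gaussian (σ = 0.1 RFU) clipped at zero.

The caller smooths with a kernel of half the narrowest instrument peak
width before apex detection (suppressing shoulder ripple without merging
real peaks), requires height and prominence above `max(0.5 RFU, 6 ×
noise_sd)`, merges apexes closer than 1 bp, sizes by inverse calibration,
and estimates concentration as baseline-subtracted area (the instrument's
actual quantitation algorithm is undisclosed; area-proportionality is the
stand-in, with RFU units arbitrary).  Positivity is `conc ≥ 0.5 ng/µL`,
inclusive.  Peak-to-assay matching is greedy-injective on |estimated −
expected| within `tol_bp = 2` — half the instrument's 4 bp bound, wide
enough to absorb the ±1 bp printed-size ambiguities, far below the 26 bp
within-set spacing; ties break toward the smaller expected size and are
logged.

### Decoding

Single-event matching uses *exact* profile equality restricted to
determinate markers: a single-event sample must light every marker of its
event and nothing else.  Subset semantics are reserved for mixtures:
when no single event matches a non-empty positive set, the decoder returns
every inclusion-minimal set of event profiles whose union equals the
positive set, by exhaustive subset search (≤ 2^12 subsets).  Events with
identical profiles are reported as an ambiguity group, never silently
broken — the matrix itself cannot distinguish DAS68416-4/DAS81419,
Mon87705/Mon89788 or T25/TC1507 (hence 10 distinct profiles among 12
soybean events), and confirmatory event-specific testing is the designed
next tier.  Positive markers carried by no reference event (possible for
the four markers included for future expansion: DMO, gat4621, T-hsp17.3
and maize T-PinII) are reported as `unexplained_markers`; mixtures are
then searched for the remaining positives, since no cover containing an
uncarried marker exists by construction.  Indeterminate ("?") markers are
fully masked: the decode result is invariant to matrix values at those
markers (property-tested).

## Numerical / degenerate-input choices

* All randomness flows from explicit integer seeds; sub-seeds are derived
  by CRC-32 of labeled strings and kept below 2^31.
* Zero-concentration templates amplify nothing; empty amplicon lists
  produce marker-only traces and zero called peaks.
* Rejection sampling of neutral sequence is capped at 50 attempts (a
  20-mer site in random DNA has probability ≈ 4⁻²⁰ per position; the cap
  exists for safety, not for expected use).
* `dilution_series` is exact arithmetic: `mass_pg = conc × aliquot ×
  1000`; 0.005 % / 0.001 % / 0.0005 % of a 30 ng/µL, 1 µL aliquot give
  1.5 / 0.3 / 0.15 pg.

## Problem sizes

Default constructs are ~3–4.5 kb; traces span 25 000 samples; the full
test suite (unit + property + end-to-end over all 18 reference events)
runs in a few seconds on one core, and the acceptance script in well under
a minute.

## Known limitations

No thermodynamics (annealing temperature, ΔG dimer scoring, melting
curves), no polymerase errors or chimeras, no degenerate bases, no
junction/flanking structure for events, no gel-image rendering, no
quantitative GM content.  Off-target specificity and low-template
sensitivity claims about real samples are outside what synthetic templates
can establish.
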