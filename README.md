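# gmoscreen

An in-silico model of a screening platform for genetically modified (GM)
soybean and maize: multiplex PCR (mPCR) against a panel of introduced-gene
markers, capillary electrophoresis (CE) readout, and matrix-based decoding
of marker patterns into candidate GM events.

Border inspection of GM crops starts with qualitative screening: is the
sample the claimed species, does it carry foreign DNA, and which
transformation events could explain what it carries?  Event-specific assays
don't scale to hundreds of approved events, so screening instead targets the
*introduced elements* — promoters (e.g. *P-ubi10*, *P-act1*), terminators
(*T-35S*, *T-E9*, …) and trait genes (*pat*, *bar*, *CP4epsps*, …) shared
across many events.  `gmoscreen` implements that strategy end to end on
synthetic DNA, for assay developers and bioinformaticians who want to
reason about panel design, CE resolution, and the decodability of a
detection matrix before (or instead of) touching a wet lab.

## What it models

* **Panel** — 18 GM marker assays (11 soybean, 9 maize, two shared) plus an
  endogenous reference gene per crop (*Lec1* 198 bp, *SSIIb* 199 bp),
  organized in six multiplex sets of 3–4 primer pairs with per-primer
  amounts; validation includes a 3'-anchored primer-dimer screen.
* **Constructs** — circular standard plasmids carrying one amplifiable
  insert per marker (`fwd + neutral filler + revcomp(rev)`, sized to the
  canonical amplicon), GM event genomes that carry exactly the marker set
  of a reference event, non-GM backgrounds, and off-target species
  stand-ins.  All neutral sequence is seeded random DNA verified free of
  primer sites.
* **In-silico PCR** — exact primer-site search on both strands (circular
  templates scanned across the origin), product enumeration below 500 bp,
  and a deterministic end-point yield
  `min(saturation, k · conc · (1+e)^cycles · w)` per amplicon.
* **CE** — electropherogram simulation between 20 bp / 1000 bp alignment
  markers (log-linear migration model, Gaussian peaks of width 1.2 bp,
  seeded baseline noise), peak calling with size estimation, and an
  inclusive 0.5 ng/µL positivity threshold.
* **Decoder** — the reference detection matrix (12 soybean × 11 markers,
  6 maize × 9), exact single-event matching, ambiguity groups for events
  with identical profiles, and exhaustive minimal set-cover search for
  mixture explanations.

## Worked example

```python
from gmoscreen import builtin_panel, builtin_matrix
from gmoscreen.construct_factory import ConstructSpec, build_standard_plasmid
from gmoscreen.insilico_pcr import run_multiplex
from gmoscreen.ce import simulate_trace, call_peaks, match_peaks_to_assays

panel = builtin_panel("soybean")
plasmid = build_standard_plasmid(ConstructSpec(crop="soybean", seed=11), panel)
soy_i = panel.sets[0]                      # pat / P-TSF1 / T-E9
amps = run_multiplex(plasmid, soy_i, panel)
print([(a.assay, a.length_bp) for a in amps])
peaks = call_peaks(simulate_trace(amps, seed=42))
for p in peaks:
    print(f"{p.est_size_bp:6.1f} bp  {p.conc_ng_per_ul:5.1f} ng/uL  positive={p.positive}")
print(match_peaks_to_assays(peaks, soy_i, panel).positive_assays)
```

prints

```
[('pat', 93), ('P-TSF1', 148), ('T-E9', 223)]
  93.0 bp   49.9 ng/uL  positive=True
 148.0 bp   50.0 ng/uL  positive=True
 223.0 bp   50.0 ng/uL  positive=True
('pat', 'P-TSF1', 'T-E9')
```

i.e. the Soy I multiplex on the soybean standard plasmid produces its three
expected amplicons, each sized within a fraction of a bp and well above the
positivity threshold, and every member assay is called positive.

The same pipeline runs from the shell:

```
gmoscreen run --demo maize --seed 5 --out demo_out
```

screens the six maize reference events plus a non-GM sample and writes one
JSON report each; the T25 and TC1507 reports list a two-event ambiguity
group because the matrix cannot distinguish them (both carry only *pat*),
and the non-GM report decodes as `non-GM`.  Other subcommands: `fixtures`,
`panel-validate`, `pcr`, `ce`, `decode`, `matrix-report`
(see `gmoscreen --help`; file formats in `docs/FORMATS.md`).

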