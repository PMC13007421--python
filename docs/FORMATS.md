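# File formats

All files are UTF-8 text; CSVs are comma-separated with a header row.

## Templates: FASTA + sidecar CSV

FASTA wrapped at 60 columns.  Topology is declared by a header token:

```
>soybean_standard_plasmid topology=circular
ACGT...
```

The sidecar CSV supplies concentrations and may override topology:

| column | meaning |
|---|---|
| `name` | FASTA record id |
| `topology` | `linear` or `circular` |
| `conc_ng_per_ul` | template concentration (ng/µL) |

## Panel CSV / JSON

CSV columns: `name,category,fwd,rev,expected_size_bp,table1_size_bp,
accession,crops,set,pmol`.  One row per assay; `crops` is `|`-joined
(`soybean|maize`); `set`/`pmol` give multiplex membership and per-primer
amount (blank for the endogenous assay).  Primers are A/C/G/T only.
The JSON form mirrors the type structure (`crop`, `endogenous`, `assays`,
`sets`).  `load(save(panel))` is field-for-field identity.

## Detection matrix CSV

First column `event`; remaining columns are marker names, with a `*`
suffix flagging markers that have no reference event; cells are `+`/`-`.

## Amplicon CSV

`template,assay,start,end,length_bp,yield_ng_per_ul`.  Coordinates are
0-based half-open on the + strand; origin-spanning circular products have
`end > len(template)`.

## Trace / peak CSVs

Trace: `time_s,rfu`.  Peaks: `sample,set,apex_time,est_size_bp,
conc_ng_per_ul,positive` (positive is 0/1 at the inclusive 0.5 ng/µL
threshold).

## Marker-call CSV (decode input)

`marker,call` with call in `+`, `-`, `?` (indeterminate).

## Reports

Per-sample JSON: `sample`, `species_confirmed`, `gm_status`
(`GM`/`non-GM`/`invalid`), `single_event_candidates`, `ambiguity_group`,
`minimal_mixtures`, `unexplained_markers`, `notes`, plus a `details`
section with per-set amplicons, calls and unexpected peaks.  Runs also
write `summary.csv` (one row per sample), `peaks.csv`, and
`manifest.json` (full configuration + seed + package version).

## Run config JSON

Keys mirror `RunConfig`: `crop`, `panel`, `matrix` (paths or
`"builtin"`), `seed`, `cycles`, `efficiency` (assay → value),
`saturation`, `noise_sd`, `tol_bp`, `min_conc`, `outdir`.  Precedence:
command-line flags > config file > defaults.
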