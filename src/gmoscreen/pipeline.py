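"""End-to-end orchestration: fixtures, screening runs, reports.

Glue over the library modules: build the fixture bundle a screening study
needs, and run the full screen — multiplex PCR → CE trace → peak calling →
assay matching → matrix decoding — over a list of samples.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .panel import Panel, builtin_panel, load_panel
from .decoder import DetectionMatrix, builtin_matrix, load_matrix, decode
from .insilico_pcr import (
    AmplificationModel, Template, run_multiplex, run_singleplex,
)
from .construct_factory import (
    ConstructSpec, EventSpec, build_standard_plasmid, build_event_genome,
    build_background_species, dilution_series, PLASMID_CONC_NG_PER_UL,
)
from .ce import (
    DEFAULT_CALIBRATION, DEFAULT_NOISE_SD, POSITIVE_MIN_CONC,
    simulate_trace, call_peaks, match_peaks_to_assays, MarkerCall,
)
from . import io as gio

__all__ = ["RunConfig", "derive_seed", "screen_sample", "run_samples",
           "write_fixture_bundle", "DILUTION_FRACTIONS"]

#: sensitivity-series fractions (w/w): 0.005%, 0.001%, 0.0005%
DILUTION_FRACTIONS = (5.0e-5, 1.0e-5, 5.0e-6)


def derive_seed(base: int, *labels) -> int:
    """Stable sub-seed (< 2^31) from a base seed and string labels."""
    h = zlib.crc32(":".join([str(base), *map(str, labels)]).encode())
    return h & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Configuration for a screening run (CLI > file > defaults)."""

    crop: str = "soybean"
    panel: str = "builtin"   # path or "builtin"
    matrix: str = "builtin"  # path or "builtin"
    seed: int = 0
    cycles: int = 28
    efficiency: dict = field(default_factory=dict)  # assay -> efficiency
    saturation: float = 50.0
    noise_sd: float = DEFAULT_NOISE_SD
    tol_bp: float = 2.0
    min_conc: float = POSITIVE_MIN_CONC
    outdir: str = "gmoscreen_out"

    @classmethod
    def from_file(cls, path, **overrides):
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def load_panel(self) -> Panel:
        if self.panel == "builtin":
            return builtin_panel(self.crop)
        return load_panel(self.panel)

    def load_matrix(self) -> DetectionMatrix:
        if self.matrix == "builtin":
            return builtin_matrix(self.crop)
        return load_matrix(self.matrix, crop=self.crop)

    def model(self) -> AmplificationModel:
        overrides = {"DMO": 0.95}
        overrides.update(self.efficiency)
        return AmplificationModel(
            cycles=self.cycles, efficiency_overrides=overrides,
            saturation_ng_per_ul=self.saturation,
        )

    def manifest(self) -> dict:
        doc = asdict(self)
        doc["gmoscreen_version"] = __version__
        return doc


def screen_sample(template: Template, panel: Panel, matrix: DetectionMatrix,
                  config: RunConfig):
    """Screen one sample through all multiplex sets plus the endogenous assay.

    Returns ``(ScreeningResult, details)`` where ``details`` carries the
    per-set peaks and calls for reporting.
    """
    model = config.model()
    all_calls = []
    details = {"sets": {}, "warnings": [w.message for w in panel.warnings]}
    peak_rows = []
    for mset in panel.sets:
        amps = run_multiplex(template, mset, panel, model)
        trace = simulate_trace(
            amps, DEFAULT_CALIBRATION, noise_sd=config.noise_sd,
            seed=derive_seed(config.seed, template.name, mset.name),
        )
        peaks = call_peaks(trace, min_conc=config.min_conc)
        match = match_peaks_to_assays(peaks, mset, panel, tol_bp=config.tol_bp)
        all_calls.extend(match.calls)
        peak_rows.extend((template.name, mset.name, p) for p in peaks)
        details["sets"][mset.name] = {
            "amplicons": [
                {"assay": a.assay, "length_bp": a.length_bp,
                 "yield_ng_per_ul": round(a.yield_ng_per_ul, 4)}
                for a in amps
            ],
            "calls": {c.assay: c.call for c in match.calls},
            "unexpected_peaks": [round(p.est_size_bp, 1) for p in match.unexpected],
            "ties": list(match.ties),
        }
    # endogenous species check (singleplex)
    endo = panel.endogenous
    amps = run_singleplex(template, endo)
    trace = simulate_trace(
        amps, DEFAULT_CALIBRATION, noise_sd=config.noise_sd,
        seed=derive_seed(config.seed, template.name, endo.name),
    )
    peaks = call_peaks(trace, min_conc=config.min_conc)
    hit = any(
        p.positive and abs(p.est_size_bp - endo.expected_size_bp) <= config.tol_bp
        for p in peaks
    )
    endo_call = MarkerCall(assay=endo.name, call="+" if hit else "-")
    peak_rows.extend((template.name, endo.name, p) for p in peaks)
    details["endogenous"] = {endo.name: endo_call.call}
    details["peak_rows"] = peak_rows
    result = decode(all_calls, endo_call, matrix, sample=template.name)
    return result, details


def run_samples(templates, config: RunConfig, outdir) -> list:
    """Screen all samples, writing per-sample JSON reports + a summary CSV.

    Returns the list of (template, ScreeningResult, error-or-None).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = config.load_panel()
    matrix = config.load_matrix()
    results = []
    summary_rows = []
    peak_rows = []
    for t in templates:
        try:
            result, details = screen_sample(t, panel, matrix, config)
        except Exception as exc:  # record per-sample failure, keep going
            results.append((t, None, str(exc)))
            summary_rows.append([t.name, "error", "", "", str(exc)])
            continue
        doc = result.to_dict()
        doc["details"] = {k: v for k, v in details.items() if k != "peak_rows"}
        gio.write_report(doc, outdir / f"{t.name}.report.json")
        peak_rows.extend(details["peak_rows"])
        results.append((t, result, None))
        summary_rows.append([
            t.name, result.gm_status,
            "|".join(result.single_event_candidates),
            ";".join("+".join(sorted(m)) for m in result.minimal_mixtures),
            "",
        ])
    import csv as _csv
    with (outdir / "summary.csv").open("w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["sample", "gm_status", "candidates", "minimal_mixtures",
                    "error"])
        w.writerows(summary_rows)
    gio.write_peaks_csv(peak_rows, outdir / "peaks.csv")
    gio.write_report(config.manifest(), outdir / "manifest.json")
    return results


def event_genomes(matrix: DetectionMatrix, panel: Panel, seed: int) -> list:
    """Genomic stand-ins for every event of a detection matrix."""
    out = []
    for event in matrix.events:
        spec = EventSpec(event=event, crop=matrix.crop,
                         markers=matrix.profiles[event],
                         seed=derive_seed(seed, "event", event))
        out.append(build_event_genome(spec, panel))
    return out


def demo_samples(config: RunConfig):
    """The built-in demo: every reference event genome plus a non-GM sample."""
    panel = config.load_panel()
    matrix = config.load_matrix()
    samples = event_genomes(matrix, panel, config.seed)
    samples.append(build_event_genome(
        EventSpec(event=f"non-GM_{config.crop}", crop=config.crop,
                  markers=frozenset(),
                  seed=derive_seed(config.seed, "non-GM")),
        panel,
    ))
    return samples


def write_fixture_bundle(config: RunConfig, outdir) -> dict:
    """Write the full fixture bundle for one crop.

    Standard plasmid, one genome per reference event, a non-GM background,
    20 off-target species stand-ins, and the three-point sensitivity
    dilution series of the plasmid.  Deterministic per seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = config.load_panel()
    matrix = config.load_matrix()
    plasmid = build_standard_plasmid(
        ConstructSpec(crop=config.crop, seed=derive_seed(config.seed, "plasmid")),
        panel,
    )
    events = event_genomes(matrix, panel, config.seed)
    non_gm = build_event_genome(
        EventSpec(event=f"non-GM_{config.crop}", crop=config.crop,
                  markers=frozenset(), seed=derive_seed(config.seed, "non-GM")),
        panel,
    )
    offtargets = build_background_species(
        [builtin_panel("soybean"), builtin_panel("maize")],
        seed=derive_seed(config.seed, "offtarget"),
    )
    everything = [plasmid, *events, non_gm, *offtargets]
    gio.write_fasta(everything, outdir / "templates.fasta")
    gio.write_sidecar(everything, outdir / "templates.csv")
    series = dilution_series(plasmid, PLASMID_CONC_NG_PER_UL,
                             DILUTION_FRACTIONS, aliquot_ul=1.0)
    import csv as _csv
    with (outdir / "dilutions.csv").open("w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["fraction", "conc_ng_per_ul", "mass_pg"])
        for d in series:
            w.writerow([repr(d.fraction), repr(d.template.conc_ng_per_ul),
                        repr(d.mass_pg)])
    gio.write_report(config.manifest(), outdir / "manifest.json")
    return {"plasmid": plasmid, "events": events, "non_gm": non_gm,
            "offtargets": offtargets, "dilutions": series}
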