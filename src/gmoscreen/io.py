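"""File formats: FASTA templates with sidecars, amplicon/peak/report tables.

Templates travel as plain FASTA (wrapped at 60 columns) with topology
declared by a ``topology=circular`` token in the header; a sidecar CSV
(``name,topology,conc_ng_per_ul``) carries concentrations and can override
header topology.  See docs/FORMATS.md for the full format reference.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico_pcr import Template

__all__ = [
    "write_fasta",
    "read_templates",
    "write_sidecar",
    "write_amplicons_csv",
    "write_peaks_csv",
    "write_trace_csv",
    "write_report",
]

FASTA_WIDTH = 60


def write_fasta(templates, path) -> None:
    """Write templates to FASTA; circular topology is flagged in the header."""
    records = []
    for t in templates:
        desc = "topology=circular" if t.topology == "circular" else "topology=linear"
        records.append(SeqRecord(Seq(t.seq), id=t.name, description=desc))
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(records)


def write_sidecar(templates, path) -> None:
    """Write the template sidecar CSV (name, topology, concentration)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "topology", "conc_ng_per_ul"])
        for t in templates:
            w.writerow([t.name, t.topology, repr(t.conc_ng_per_ul)])


def read_templates(fasta_path, sidecar_path=None) -> list:
    """Read templates from FASTA plus optional sidecar CSV.

    The sidecar supplies concentrations (default 0) and may override the
    header topology token.
    """
    meta = {}
    if sidecar_path is not None:
        with Path(sidecar_path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                meta[row["name"]] = (
                    row.get("topology") or None,
                    float(row["conc_ng_per_ul"]) if row.get("conc_ng_per_ul") else 0.0,
                )
    templates = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        topology = "circular" if "topology=circular" in rec.description else "linear"
        conc = 0.0
        if rec.id in meta:
            side_top, conc = meta[rec.id]
            if side_top:
                topology = side_top
        templates.append(Template(name=rec.id, seq=str(rec.seq),
                                  topology=topology, conc_ng_per_ul=conc))
    return templates


def write_amplicons_csv(amplicons, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["template", "assay", "start", "end", "length_bp",
                    "yield_ng_per_ul"])
        for a in amplicons:
            w.writerow([a.template, a.assay, a.start, a.end, a.length_bp,
                        f"{a.yield_ng_per_ul:.6g}"])


def write_trace_csv(trace, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "rfu"])
        for t, r in zip(trace.time_s, trace.rfu):
            w.writerow([f"{t:.2f}", f"{r:.4f}"])


def write_peaks_csv(rows, path) -> None:
    """rows: iterables of (sample, set, Peak)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "set", "apex_time", "est_size_bp",
                    "conc_ng_per_ul", "positive"])
        for sample, set_name, p in rows:
            w.writerow([sample, set_name, f"{p.apex_time:.2f}",
                        f"{p.est_size_bp:.2f}", f"{p.conc_ng_per_ul:.4f}",
                        int(p.positive)])


def write_report(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
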