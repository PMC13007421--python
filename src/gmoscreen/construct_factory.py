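"""Synthetic construct generation: standard plasmids, event genomes, backgrounds.

The platform's positive controls are circular "standard plasmids" carrying
one amplifiable segment per marker assay, arranged unidirectionally with
neutral spacers, on a neutral backbone.  GM event samples are emulated as
linear genomic stand-ins carrying the endogenous reference gene plus the
marker inserts dictated by the detection matrix; non-GM backgrounds carry
only the endogenous gene; off-target species stand-ins carry nothing the
panel can amplify.

The true insert sequences of the published constructs are not reproduced:
each insert is synthesized as ``fwd + neutral filler + revcomp(rev)`` with
the filler sized so the amplicon comes out at the canonical expected size.
Total construct lengths therefore differ from the physical plasmids.  All
neutral sequence (fillers, spacers, backbones, genomic background) is
seeded random DNA at 50% GC, rejection-sampled until free of binding sites
for every panel primer, and every finished construct is self-verified by
substring counting so that the only primer-recognizable features are the
intended inserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import Panel, PanelError
from .insilico_pcr import Template, revcomp

__all__ = [
    "ConstructSpec",
    "EventSpec",
    "ConstructError",
    "build_standard_plasmid",
    "build_event_genome",
    "build_background_species",
    "dilution_series",
    "DilutionPoint",
    "PLASMID_CONC_NG_PER_UL",
    "GENOMIC_CONC_NG_PER_UL",
]

PLASMID_CONC_NG_PER_UL = 30.0  # working concentration of standard plasmids
GENOMIC_CONC_NG_PER_UL = 50.0  # working concentration of genomic DNA
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GC_PROBS = (0.25, 0.25, 0.25, 0.25)  # 50% GC
_RETRY_CAP = 50


class ConstructError(RuntimeError):
    """Construct generation failure (spec mismatch or sampling cap)."""


@dataclass(frozen=True)
class ConstructSpec:
    """Recipe for a standard plasmid."""

    crop: str
    insert_order: tuple = ()  # assay names; () = all panel GM markers, panel order
    spacer_len: int = 30
    backbone_len: int = 2000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "insert_order", tuple(self.insert_order))
        if self.spacer_len < 1:
            raise ConstructError("spacer_len must be ≥ 1")
        if self.backbone_len < 1:
            raise ConstructError("backbone_len must be ≥ 1")


@dataclass(frozen=True)
class EventSpec:
    """Recipe for a GM event genomic stand-in."""

    event: str
    crop: str
    markers: frozenset = frozenset()  # assay names carried by the event
    background_len: int = 3000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "markers", frozenset(self.markers))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n, p=_GC_PROBS).tobytes().decode()


def _contains_site(seq: str, primers, circular: bool = False) -> bool:
    probe = seq + seq[: max(len(p) for p in primers) - 1] if circular else seq
    return any(p in probe or revcomp(p) in probe for p in primers)


def _neutral(rng, n, primers) -> str:
    """Random DNA of length n containing no primer site on either strand."""
    for _ in range(_RETRY_CAP):
        seq = _random_dna(rng, n)
        if not _contains_site(seq, primers):
            return seq
    raise ConstructError(f"could not sample {n} nt of primer-free sequence")


def _insert(rng, assay, primers) -> str:
    """fwd + neutral filler + revcomp(rev), sized to the expected amplicon."""
    filler_len = assay.expected_size_bp - len(assay.fwd) - len(assay.rev)
    filler = _neutral(rng, filler_len, primers) if filler_len else ""
    return assay.fwd + filler + revcomp(assay.rev)


def _panel_primers(panel: Panel):
    return tuple(
        s for a in panel.assays.values() for s in (a.fwd, a.rev)
    )


def _count_occurrences(seq: str, primers, circular: bool) -> dict:
    """Occurrences of each primer (either strand) by plain substring counting.

    Deliberately independent of the binding-site scanner: used to
    self-verify generated constructs.
    """
    probe = seq + seq[: max(len(p) for p in primers) - 1] if circular else seq
    counts = {}
    for p in primers:
        n = 0
        for pat in (p, revcomp(p)):
            pos = probe.find(pat)
            while pos != -1 and pos < len(seq):
                n += 1
                pos = probe.find(pat, pos + 1)
        counts[p] = n
    return counts


def _verify(seq: str, panel: Panel, inserted, circular: bool):
    expected = {}
    for p in _panel_primers(panel):
        expected[p] = expected.get(p, 0)
    for name in inserted:
        a = panel.assays[name]
        expected[a.fwd] += 1
        expected[a.rev] += 1
    got = _count_occurrences(seq, tuple(expected), circular)
    return got == expected


def build_standard_plasmid(spec: ConstructSpec, panel: Panel) -> Template:
    """Synthesize the circular standard plasmid for a panel.

    Layout: ``[backbone][insert_1][spacer]...[spacer][insert_k]`` with every
    insert in the same 5'→3' orientation.  Deterministic per seed.
    """
    if spec.crop != panel.crop:
        raise ConstructError(f"spec crop {spec.crop} ≠ panel crop {panel.crop}")
    order = spec.insert_order or tuple(a.name for a in panel.gm_assays)
    unknown = [n for n in order if n not in panel.assays]
    if unknown:
        raise ConstructError(f"unknown assay(s) {unknown} for {panel.crop} panel")
    primers = _panel_primers(panel)
    for attempt in range(_RETRY_CAP):
        rng = np.random.default_rng((spec.seed, attempt))
        parts = [_neutral(rng, spec.backbone_len, primers)]
        for i, name in enumerate(order):
            if i:
                parts.append(_neutral(rng, spec.spacer_len, primers))
            parts.append(_insert(rng, panel.assays[name], primers))
        seq = "".join(parts)
        if _verify(seq, panel, order, circular=True):
            return Template(
                name=f"{spec.crop}_standard_plasmid", seq=seq,
                topology="circular", conc_ng_per_ul=PLASMID_CONC_NG_PER_UL,
            )
    raise ConstructError("plasmid assembly kept producing stray primer sites")


def build_event_genome(spec: EventSpec, panel: Panel) -> Template:
    """Synthesize a linear genomic stand-in for one GM event.

    Carries the crop's endogenous-gene insert plus one insert per marker in
    ``spec.markers``, embedded at seeded random loci in primer-free
    background.  With ``markers=∅`` this is a non-GM background genome.
    """
    if spec.crop != panel.crop:
        raise ConstructError(f"spec crop {spec.crop} ≠ panel crop {panel.crop}")
    unknown = sorted(n for n in spec.markers if n not in panel.assays)
    if unknown:
        raise ConstructError(f"{spec.event}: marker(s) {unknown} not in panel")
    primers = _panel_primers(panel)
    inserted = [panel.endogenous.name] + sorted(spec.markers)
    for attempt in range(_RETRY_CAP):
        rng = np.random.default_rng((spec.seed, attempt))
        # background split into len(inserted)+1 chunks of jittered length
        n_chunks = len(inserted) + 1
        weights = rng.dirichlet(np.full(n_chunks, 5.0))
        lens = np.maximum(20, (weights * spec.background_len).astype(int))
        parts = [_neutral(rng, int(lens[0]), primers)]
        for i, name in enumerate(inserted):
            parts.append(_insert(rng, panel.assays[name], primers))
            parts.append(_neutral(rng, int(lens[i + 1]), primers))
        seq = "".join(parts)
        if _verify(seq, panel, inserted, circular=False):
            return Template(name=spec.event, seq=seq, topology="linear",
                            conc_ng_per_ul=GENOMIC_CONC_NG_PER_UL)
    raise ConstructError("event genome assembly kept producing stray primer sites")


def build_background_species(
    panels, n: int = 20, length: int = 3000, seed: int = 0
) -> list:
    """Synthetic off-target species stand-ins.

    ``n`` seeded random linear genomes free of binding sites for every
    primer of every panel given — emulating the non-reactive quarantine
    species used to establish panel specificity.
    """
    primers = tuple(s for p in panels for s in _panel_primers(p))
    rng = np.random.default_rng((seed, 0xBACC))
    out = []
    for i in range(n):
        seq = _neutral(rng, length, primers)
        out.append(Template(name=f"species_{i + 1:02d}", seq=seq,
                            topology="linear",
                            conc_ng_per_ul=GENOMIC_CONC_NG_PER_UL))
    return out


@dataclass(frozen=True)
class DilutionPoint:
    fraction: float
    template: Template
    mass_pg: float


def dilution_series(
    template: Template,
    stock_conc_ng_per_ul: float,
    fractions,
    aliquot_ul: float = 1.0,
) -> list:
    """Dilute a template to ``stock × fraction`` and report aliquot mass.

    ``mass_pg = conc(ng/µL) × aliquot(µL) × 1000``; exact arithmetic.
    """
    if stock_conc_ng_per_ul < 0:
        raise ValueError("stock concentration must be ≥ 0")
    out = []
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValueError(f"fraction {f} outside [0, 1]")
        conc = stock_conc_ng_per_ul * f
        out.append(DilutionPoint(
            fraction=f,
            template=replace(template, conc_ng_per_ul=conc),
            mass_pg=conc * aliquot_ul * 1000.0,
        ))
    return out
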