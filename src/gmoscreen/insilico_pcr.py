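"""In-silico PCR: primer binding-site search and product prediction.

Predicts the amplicons a primer pair (or a whole multiplex set) produces on
a linear or circular DNA template, and assigns each product a deterministic
end-point yield from a saturation model of PCR amplification.

Conventions
-----------
* Coordinates are 0-based half-open on the + strand.  For circular
  templates a product that spans the origin keeps ``end > len(seq)``;
  ``start`` is always normalized into ``[0, len)``.
* A ``+`` strand site means the primer sequence matches the + strand (the
  primer extends rightward); a ``-`` strand site means the reverse
  complement of the primer matches the + strand (the primer anneals to the
  + strand and extends leftward).
* Product length runs from the 5'-most base of the forward primer's site to
  the 5'-most base of the reverse primer's site, both primers included —
  the convention under which the panel's printed amplicon sizes are stated.
* Exact matching (``max_mismatch=0``) is the default; the 3'-terminal
  ``protected_3prime`` bases of a primer must always match exactly, since a
  3' mismatch blocks extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import Assay, MultiplexSet, Panel, MAX_AMPLICON_BP

__all__ = [
    "Template",
    "BindingSite",
    "Amplicon",
    "AmplificationModel",
    "revcomp",
    "find_binding_sites",
    "predict_products",
    "run_multiplex",
    "run_singleplex",
]

_ALPHABET = frozenset("ACGT")
_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Watson–Crick reverse complement (strict A/C/G/T alphabet)."""
    seq = seq.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"non-ACGT character(s) {bad} in sequence")
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Template:
    """A DNA template: the substrate of in-silico PCR."""

    name: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"
    conc_ng_per_ul: float = 0.0

    def __post_init__(self):
        seq = self.seq.upper()
        if not set(seq) <= _ALPHABET:
            raise ValueError(f"template {self.name}: sequence must be A/C/G/T")
        object.__setattr__(self, "seq", seq)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"template {self.name}: topology {self.topology!r}")
        if self.conc_ng_per_ul < 0:
            raise ValueError(f"template {self.name}: negative concentration")

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site on a template (+ strand coordinates)."""

    primer: str
    strand: str  # "+" | "-"
    start: int
    end: int
    mismatches: int = 0

    def __len__(self):
        return self.end - self.start


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product."""

    assay: str
    template: str
    start: int
    end: int  # may exceed template length for origin-spanning circular products
    length_bp: int
    yield_ng_per_ul: float = 0.0


def _scan_exact(scan: str, pattern: str, limit: int):
    """Yield (start, 0) for every exact occurrence of pattern with start < limit."""
    pos = scan.find(pattern)
    while pos != -1 and pos < limit:
        yield pos, 0
        pos = scan.find(pattern, pos + 1)


def _scan_mismatch(scan: str, pattern: str, limit: int, max_mm: int, protected):
    """Sliding-window mismatch scan; protected positions must match exactly."""
    k = len(pattern)
    if len(scan) < k:
        return
    arr = np.frombuffer(scan.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    neq = win != pat
    mm = neq.sum(axis=1)
    ok = mm <= max_mm
    if protected:
        ok &= ~neq[:, list(protected)].any(axis=1)
    for pos in np.nonzero(ok)[0]:
        if pos < limit:
            yield int(pos), int(mm[pos])


def find_binding_sites(
    template: Template,
    primer: str,
    max_mismatch: int = 0,
    protected_3prime: int = 3,
) -> list:
    """Find all annealing sites of ``primer`` on both strands of ``template``.

    Sites with up to ``max_mismatch`` mismatches are reported, except that
    the ``protected_3prime`` bases at the primer's 3' end must match
    exactly.  Circular templates are scanned across the origin.  Sites are
    returned in ascending ``start`` order, + strand before − at ties.
    """
    primer = primer.upper()
    if not set(primer) <= _ALPHABET:
        raise ValueError("primer must be A/C/G/T")
    if protected_3prime > len(primer):
        raise ValueError("protected_3prime longer than primer")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be ≥ 0")
    k, L = len(primer), len(template)
    if L < k:
        return []
    circular = template.topology == "circular"
    scan = template.seq + (template.seq[: k - 1] if circular else "")
    limit = L if circular else L - k + 1
    rc = revcomp(primer)
    sites = []
    # + strand: primer matches + strand; 3' end = last k bases of the window
    prot_plus = tuple(range(k - protected_3prime, k))
    # − strand: rc(primer) matches + strand; primer 3' end = window start
    prot_minus = tuple(range(protected_3prime))
    for pattern, strand, prot in ((primer, "+", prot_plus), (rc, "-", prot_minus)):
        if max_mismatch == 0:
            hits = _scan_exact(scan, pattern, limit)
        else:
            hits = _scan_mismatch(scan, pattern, limit, max_mismatch, prot)
        for pos, mm in hits:
            sites.append(BindingSite(primer=primer, strand=strand,
                                     start=pos, end=pos + k, mismatches=mm))
    sites.sort(key=lambda s: (s.start, 0 if s.strand == "+" else 1))
    return sites


def _pair_products(left_sites, right_sites, L, circular, min_len, max_len):
    """Products with a left-anchored site extending toward a right site.

    ``left_sites`` carry the product's 5'-most + strand base; ``right_sites``
    carry its rightmost base (their ``end``).
    """
    for f in left_sites:
        for r in right_sites:
            if circular:
                length = ((r.end - f.start - 1) % L) + 1
            else:
                if r.start < f.end:
                    continue
                length = r.end - f.start
            if min_len <= length <= max_len:
                yield f.start, f.start + length, length


def predict_products(
    template: Template,
    assay: Assay,
    max_mismatch: int = 0,
    max_product_len: int = MAX_AMPLICON_BP,
) -> list:
    """Enumerate all products of one primer pair on a template.

    Both insert orientations are considered: forward primer on the + strand
    paired with a downstream reverse-primer site on the − strand, and the
    mirror configuration.  Products longer than ``max_product_len`` are
    excluded; duplicates (same start/end) are removed.
    """
    fwd_sites = find_binding_sites(template, assay.fwd, max_mismatch)
    rev_sites = find_binding_sites(template, assay.rev, max_mismatch)
    L = len(template)
    circular = template.topology == "circular"
    min_len = len(assay.fwd) + len(assay.rev)  # primers must not overlap
    fwd_p = [s for s in fwd_sites if s.strand == "+"]
    fwd_m = [s for s in fwd_sites if s.strand == "-"]
    rev_p = [s for s in rev_sites if s.strand == "+"]
    rev_m = [s for s in rev_sites if s.strand == "-"]
    seen = set()
    out = []
    for left, right in ((fwd_p, rev_m), (rev_p, fwd_m)):
        for start, end, length in _pair_products(
            left, right, L, circular, min_len, max_product_len
        ):
            key = (start % L if circular else start, length)
            if key not in seen:
                seen.add(key)
                out.append(Amplicon(assay=assay.name, template=template.name,
                                    start=start, end=end, length_bp=length))
    out.sort(key=lambda a: (a.start, a.length_bp))
    return out


@dataclass(frozen=True)
class AmplificationModel:
    """Deterministic end-point PCR yield model.

    Yield of a product is ``min(saturation, copies_factor · conc ·
    (1 + e)**cycles · w)`` where ``e`` is the per-cycle amplification
    efficiency of the assay (1.0 = perfect doubling) and ``w = min(1,
    pmol/ref_pmol)`` is a saturating primer-amount weight: extra primer
    compensates multiplex competition but cannot push the template-limited
    plateau higher.  28 cycles models the multiplex protocol; 30 the
    singleplex one.  *DMO* defaults to a slightly reduced efficiency, the
    platform's empirically weakest assay at low template input.
    """

    cycles: int = 28
    base_efficiency: float = 1.0
    efficiency_overrides: dict = field(default_factory=lambda: {"DMO": 0.95})
    saturation_ng_per_ul: float = 50.0
    copies_factor: float = 1e-5
    ref_pmol: float = 40.0

    def efficiency(self, assay_name: str) -> float:
        return self.efficiency_overrides.get(assay_name, self.base_efficiency)

    def endpoint_yield(self, conc_ng_per_ul: float, assay_name: str,
                       pmol: float) -> float:
        e = self.efficiency(assay_name)
        w = min(1.0, pmol / self.ref_pmol)
        raw = self.copies_factor * conc_ng_per_ul * (1.0 + e) ** self.cycles * w
        return min(self.saturation_ng_per_ul, raw)


#: default model for multiplex reactions (28 cycles)
DEFAULT_MODEL = AmplificationModel()
#: default model for singleplex reactions (30 cycles)
SINGLEPLEX_MODEL = AmplificationModel(cycles=30)


def run_multiplex(
    template: Template,
    mset: MultiplexSet,
    panel: Panel,
    model: AmplificationModel = DEFAULT_MODEL,
    max_mismatch: int = 0,
    max_product_len: int = MAX_AMPLICON_BP,
) -> list:
    """Run one multiplex primer set on a template.

    Returns the union of each member assay's products, each with an
    end-point yield.  A template at zero concentration yields nothing.
    """
    if template.conc_ng_per_ul == 0:
        return []
    out = []
    for assay_name, pmol in mset.members:
        if assay_name not in panel.assays:
            raise KeyError(f"set {mset.name}: assay {assay_name!r} not in panel")
        assay = panel.assays[assay_name]
        y = model.endpoint_yield(template.conc_ng_per_ul, assay_name, pmol)
        for amp in predict_products(template, assay, max_mismatch, max_product_len):
            out.append(replace(amp, yield_ng_per_ul=y))
    out.sort(key=lambda a: (a.length_bp, a.start))
    return out


def run_singleplex(
    template: Template,
    assay: Assay,
    pmol: float = 10.0,
    model: AmplificationModel = SINGLEPLEX_MODEL,
    max_mismatch: int = 0,
    max_product_len: int = MAX_AMPLICON_BP,
) -> list:
    """Run a single primer pair (e.g. the endogenous control) on a template."""
    if template.conc_ng_per_ul == 0:
        return []
    y = model.endpoint_yield(template.conc_ng_per_ul, assay.name, pmol)
    return [
        replace(a, yield_ng_per_ul=y)
        for a in predict_products(template, assay, max_mismatch, max_product_len)
    ]
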