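"""Assay panel for introduced-gene screening of GM soybean and maize.

The screening platform targets 18 introduced genetic elements — four
promoters, six terminators and eight trait genes — plus one endogenous
reference gene per crop (*Lec1* for soybean, *SSIIb* for maize).  The 18 GM
markers are split into a soybean panel (11 markers) and a maize panel
(9 markers; *pat* and *T-PinII* are shared between the crops), and each
panel is organized into three multiplex PCR sets of 3–4 primer pairs.

This module houses the built-in panel (primer sequences, expected amplicon
sizes, multiplex composition and per-primer amounts), panel validation
(primer-dimer screening, size collisions), and CSV/JSON round-tripping.

Two amplicon sizes are carried per assay: ``expected_size_bp`` is the
canonical size used throughout the downstream multiplex/CE interpretation,
and ``table1_size_bp`` is the alternative printed size kept as provenance
metadata.  Where they disagree a :class:`PanelWarning` is attached to the
built-in panel.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Assay",
    "MultiplexSet",
    "Panel",
    "PanelWarning",
    "Finding",
    "PanelError",
    "PanelParseError",
    "builtin_panel",
    "validate_panel",
    "dimer_score",
    "load_panel",
    "save_panel",
    "CROPS",
    "MAX_AMPLICON_BP",
]

CROPS = ("soybean", "maize")
MAX_AMPLICON_BP = 500  # assays are designed to amplify below this size
_ALPHABET = frozenset("ACGT")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_CATEGORIES = ("promoter", "terminator", "trait", "endogenous")


class PanelError(ValueError):
    """Panel construction or validation failure."""


class PanelParseError(PanelError):
    """Malformed panel file."""


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or not set(seq) <= _ALPHABET:
        raise PanelError(f"{what}: primer must be a non-empty A/C/G/T string, got {seq!r}")
    return seq


@dataclass(frozen=True)
class Assay:
    """One primer pair with its expected amplicon size and crop scope."""

    name: str
    category: str
    fwd: str
    rev: str
    expected_size_bp: int
    table1_size_bp: int
    accession: str = ""
    crops: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "fwd", _check_dna(self.fwd, f"{self.name}.fwd"))
        object.__setattr__(self, "rev", _check_dna(self.rev, f"{self.name}.rev"))
        object.__setattr__(self, "crops", frozenset(self.crops))
        if self.category not in _CATEGORIES:
            raise PanelError(f"{self.name}: unknown category {self.category!r}")
        if not self.crops <= set(CROPS):
            raise PanelError(f"{self.name}: unknown crop in {sorted(self.crops)}")
        if self.expected_size_bp < len(self.fwd) + len(self.rev):
            raise PanelError(
                f"{self.name}: expected size {self.expected_size_bp} shorter than primers"
            )
        if self.expected_size_bp >= MAX_AMPLICON_BP:
            raise PanelError(
                f"{self.name}: expected size {self.expected_size_bp} ≥ {MAX_AMPLICON_BP}"
            )


@dataclass(frozen=True)
class MultiplexSet:
    """A multiplex PCR primer mixture: (assay name, primer amount in pmol)."""

    name: str
    members: tuple  # tuple of (assay_name, pmol)

    def __post_init__(self):
        object.__setattr__(self, "members", tuple((a, float(p)) for a, p in self.members))
        if not 3 <= len(self.members) <= 4:
            raise PanelError(f"{self.name}: multiplex sets hold 3–4 primer pairs")
        if any(p <= 0 for _, p in self.members):
            raise PanelError(f"{self.name}: primer amounts must be positive")
        names = [a for a, _ in self.members]
        if len(set(names)) != len(names):
            raise PanelError(f"{self.name}: duplicate assay in set")

    @property
    def assay_names(self):
        return tuple(a for a, _ in self.members)


@dataclass(frozen=True)
class PanelWarning:
    """Non-fatal annotation, e.g. conflicting printed amplicon sizes."""

    assay: str
    message: str


@dataclass(frozen=True)
class Finding:
    """A validation finding (primer dimer risk, size collision, oversize)."""

    kind: str  # "dimer" | "duplicate_size" | "oversize"
    set_name: str
    detail: str
    score: int = 0


@dataclass(frozen=True)
class Panel:
    """A crop-specific screening panel: multiplex sets + endogenous control."""

    crop: str
    sets: tuple
    endogenous: Assay
    assays: dict = field(default_factory=dict)
    warnings: tuple = field(default=(), compare=False)

    def __post_init__(self):
        if self.crop not in CROPS:
            raise PanelError(f"unknown crop {self.crop!r}")
        object.__setattr__(self, "sets", tuple(self.sets))
        object.__setattr__(self, "warnings", tuple(self.warnings))
        for mset in self.sets:
            for name in mset.assay_names:
                assay = self.assays.get(name)
                if assay is None:
                    raise PanelError(f"set {mset.name}: unknown assay {name!r}")
                if self.crop not in assay.crops:
                    raise PanelError(
                        f"set {mset.name}: assay {name} not scoped to {self.crop}"
                    )
            # duplicate expected sizes within a set are reported by
            # validate_panel rather than rejected here

    @property
    def gm_assays(self):
        """GM marker assays (everything but the endogenous control), panel order."""
        return tuple(
            self.assays[a] for mset in self.sets for a in mset.assay_names
        )

    def set_of(self, assay_name: str):
        for mset in self.sets:
            if assay_name in mset.assay_names:
                return mset
        return None


# --------------------------------------------------------------------------
# Built-in panel: 20 primer pairs with both printed sizes and accessions.
# fields: name, category, fwd, rev, table1_size, canonical_size, accession, crops
_PRIMERS = [
    ("P-ubi10", "promoter", "AATAAACGGCGTCAAAGTGG", "ACGAGGACGACTAGGTCACG", 201, 210, "MG818373", ("soybean",)),
    ("P-act1", "promoter", "TCGGGTTTTAAGTTCGTTTGCT", "GGCTTGCTATGGATCGTGGATA", 282, 282, "AM88351", ("maize",)),
    ("P-rbcS", "promoter", "GAGTGATCGGAGGGTCTAGGA", "AATGAGCAAGCACCACTCCA", 242, 242, "KT954097.1", ("soybean",)),
    ("P-TSF1", "promoter", "ATTATGCCCCTGTTTAGCCGT", "TGGGAGACGAACATGTATAACCA", 148, 148, "LR782542", ("soybean",)),
    ("T-35S", "terminator", "AGGGTTTCGCTCATGTGTTGA", "GCCCTGGATTTTGGTTTTAGGA", 108, 108, "MW653813", ("soybean",)),
    ("T-PinII", "terminator", "TGGGCATCAAAGTTGTGTGT", "TGAAATGCATCTGGTTCATCA", 131, 131, "X04118.1", ("soybean", "maize")),
    ("T-E9", "terminator", "TCAGACCTAGAAAAGCTGCAAA", "CAGGTCGATTGATGCATGTT", 223, 223, "KM407007", ("soybean",)),
    ("T-tml", "terminator", "AACAGGATTTTTCGGCAATG", "CGTCGCCGACACCTAATAAA", 236, 237, "CP011249.1", ("soybean",)),
    ("T-hsp17.3", "terminator", "TTTGGTTGATGTGTGTGCGAG", "GCGATTAGCCGATTACACAAGT", 111, 101, "XM_044488049.1", ("maize",)),
    ("T-H4", "terminator", "CGCGTTTGTGTTTTCTGGGTT", "TTCAACCGAAACTGCTGAAGC", 139, 140, "JB255983.1", ("soybean",)),
    ("pat", "trait", "TGAACTTTAGGACAGAGCCACA", "CAACCTCAGCAACCAACCAAG", 93, 93, "GQ497217", ("soybean", "maize")),
    ("bar", "trait", "CTCTACACCCACCTGCTGAA", "GAAGTCCAGCTGCCAGAAAC", 189, 242, "KX510272.1", ("maize",)),
    ("CP4epsps", "trait", "CACCATCCTCAACGTGCTGA", "CATCGCAATCCACGCCATTG", 332, 333, "KX640115", ("maize",)),
    ("mEPSPS", "trait", "GGTTGTCGGATTGAAGCAGC", "AGCCAAGAAATAGCTTGCGC", 376, 376, "OR582972", ("maize",)),
    ("aad1", "trait", "CAGTTGATCCAGTGCCTCTTCT", "TTCTGTGCTTGGTAGAGGGAAC", 310, 310, "JA364030", ("maize",)),
    ("gat4621", "trait", "AAGCCTATCAACGCAGAGGA", "AATGAAGCCACGGAAATCAG", 155, 155, "JA387980", ("maize",)),
    ("csr1-2", "trait", "GTTGTTGGCGTTTGGGGTAA", "AGCCAGCTTAACATCACCACA", 157, 157, "WO 2010/080829", ("soybean",)),
    ("DMO", "trait", "GCCATCTCCAATGCCCCTAT", "CCGAGGTCCATCAGGTTGTC", 286, 286, "KP164814.1", ("soybean",)),
    ("Lec1", "endogenous", "ACTGACCAGCAAGGCAAACT", "ATGTGGATGGGGGTGGAGTA", 198, 198, "K00821", ("soybean",)),
    ("SSIIb", "endogenous", "TGAACCAGCTCTACGCCATG", "CGCCAGCTCTCCTTGTAGTT", 199, 199, "AF019297", ("maize",)),
]

# Multiplex composition with per-primer-pair amounts (pmol of each primer).
_SETS = {
    "soybean": [
        ("SoyI", [("pat", 32), ("P-TSF1", 32), ("T-E9", 60)]),
        ("SoyII", [("T-35S", 60), ("T-H4", 30), ("T-tml", 80), ("DMO", 240)]),
        ("SoyIII", [("T-PinII", 400), ("csr1-2", 32), ("P-ubi10", 40), ("P-rbcS", 40)]),
    ],
    "maize": [
        ("MaizeI", [("T-hsp17.3", 60), ("gat4621", 40), ("CP4epsps", 40)]),
        ("MaizeII", [("pat", 60), ("P-act1", 40), ("mEPSPS", 32)]),
        ("MaizeIII", [("T-PinII", 160), ("bar", 40), ("aad1", 40)]),
    ],
}

_ENDOGENOUS = {"soybean": "Lec1", "maize": "SSIIb"}


def _all_assays():
    out = {}
    for name, cat, fwd, rev, t1, canon, acc, crops in _PRIMERS:
        out[name] = Assay(
            name=name, category=cat, fwd=fwd, rev=rev,
            expected_size_bp=canon, table1_size_bp=t1,
            accession=acc, crops=frozenset(crops),
        )
    return out


def builtin_panel(crop: str) -> Panel:
    """Return the built-in screening panel for ``crop``.

    Deterministic.  A :class:`PanelWarning` is attached for every assay whose
    two printed sizes disagree (the canonical ``expected_size_bp`` is used
    downstream; ``table1_size_bp`` is metadata).
    """
    if crop not in CROPS:
        raise PanelError(f"unknown crop {crop!r}")
    assays = {
        n: a for n, a in _all_assays().items()
        if crop in a.crops and a.category != "endogenous"
    }
    endo = _all_assays()[_ENDOGENOUS[crop]]
    assays[endo.name] = endo
    sets = tuple(MultiplexSet(name, members) for name, members in _SETS[crop])
    warnings = tuple(
        PanelWarning(
            a.name,
            f"{a.name}: printed sizes disagree (table {a.table1_size_bp} bp "
            f"vs canonical {a.expected_size_bp} bp); using {a.expected_size_bp}",
        )
        for a in assays.values()
        if a.table1_size_bp != a.expected_size_bp
    )
    return Panel(crop=crop, sets=sets, endogenous=endo, assays=assays, warnings=warnings)


# --------------------------------------------------------------------------
# Primer-dimer screening


def dimer_score(p: str, q: str) -> int:
    """3'-anchored complementarity score between two primers.

    Slides ``p`` (5'→3') antiparallel against ``q`` and returns the length of
    the longest perfect Watson–Crick duplex that includes the 3'-terminal
    base of either primer.  Thermodynamics are deliberately out of scope —
    this is the screen used to flag extension-competent dimer risk.
    """
    p = _check_dna(p, "dimer p")
    q = _check_dna(q, "dimer q")
    lp, lq = len(p), len(q)
    best = 0
    # antiparallel register: p[i] pairs q[j] with i + j = s
    for s in range(lp + lq - 1):
        i0, i1 = max(0, s - lq + 1), min(lp - 1, s)
        run = 0
        anchored = False
        for i in range(i0, i1 + 1):
            j = s - i
            if _COMP[p[i]] == q[j]:
                run += 1
                anchored = anchored or i == lp - 1 or j == lq - 1
            else:
                if anchored:
                    best = max(best, run)
                run, anchored = 0, False
        if anchored:
            best = max(best, run)
    return best


def validate_panel(panel: Panel, max_dimer_score: int = 10) -> list:
    """Screen a panel for dimer risk and size problems.

    For every pair of primers co-occurring in a multiplex set (self-pairs
    included; the score is symmetric so each unordered pair is evaluated
    once) a finding is emitted when the 3'-anchored complementarity run
    exceeds ``max_dimer_score``.  Duplicate expected sizes within a set and
    sizes ≥ 500 bp are also reported.
    """
    findings = []
    for mset in panel.sets:
        primers = []
        sizes = {}
        for name in mset.assay_names:
            a = panel.assays[name]
            primers.append((f"{name}.F", a.fwd))
            primers.append((f"{name}.R", a.rev))
            sizes.setdefault(a.expected_size_bp, []).append(name)
            if a.expected_size_bp >= MAX_AMPLICON_BP:
                findings.append(Finding(
                    "oversize", mset.name,
                    f"{name}: {a.expected_size_bp} bp ≥ {MAX_AMPLICON_BP}",
                ))
        for size, names in sizes.items():
            if len(names) > 1:
                findings.append(Finding(
                    "duplicate_size", mset.name,
                    f"{'/'.join(names)} share expected size {size} bp",
                ))
        for (na, pa), (nb, pb) in itertools.combinations_with_replacement(primers, 2):
            score = dimer_score(pa, pb)
            if score > max_dimer_score:
                findings.append(Finding(
                    "dimer", mset.name,
                    f"{na} × {nb}: 3'-anchored complement run {score}",
                    score=score,
                ))
    return findings


# --------------------------------------------------------------------------
# Serialization

_CSV_COLUMNS = [
    "name", "category", "fwd", "rev", "expected_size_bp", "table1_size_bp",
    "accession", "crops", "set", "pmol",
]


def _panel_rows(panel: Panel):
    membership = {}
    for mset in panel.sets:
        for assay, pmol in mset.members:
            membership[assay] = (mset.name, pmol)
    order = [a.name for a in panel.gm_assays] + [panel.endogenous.name]
    for name in order:
        a = panel.assays[name]
        set_name, pmol = membership.get(name, ("", ""))
        yield {
            "name": a.name, "category": a.category, "fwd": a.fwd, "rev": a.rev,
            "expected_size_bp": a.expected_size_bp,
            "table1_size_bp": a.table1_size_bp, "accession": a.accession,
            "crops": "|".join(sorted(a.crops)), "set": set_name, "pmol": pmol,
        }


def save_panel(panel: Panel, path) -> None:
    """Write a panel to CSV or JSON (chosen by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "crop": panel.crop,
            "endogenous": panel.endogenous.name,
            "assays": list(_panel_rows(panel)),
            "sets": [
                {"name": m.name, "members": [[a, p] for a, p in m.members]}
                for m in panel.sets
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for row in _panel_rows(panel):
            writer.writerow(row)


def _assays_from_rows(rows, where):
    assays, set_members = {}, {}
    for lineno, row in enumerate(rows, start=2):
        missing = [c for c in _CSV_COLUMNS[:8] if row.get(c) in (None, "")]
        # accession may legitimately be empty
        missing = [c for c in missing if c != "accession"]
        if missing:
            raise PanelParseError(
                f"{where} line {lineno}: missing field(s) {', '.join(missing)}"
            )
        try:
            assay = Assay(
                name=row["name"], category=row["category"],
                fwd=row["fwd"], rev=row["rev"],
                expected_size_bp=int(row["expected_size_bp"]),
                table1_size_bp=int(row["table1_size_bp"]),
                accession=row.get("accession", "") or "",
                crops=frozenset(c for c in row["crops"].split("|") if c),
            )
        except PanelError:
            raise
        except (KeyError, ValueError) as exc:
            raise PanelParseError(f"{where} line {lineno}: {exc}") from exc
        assays[assay.name] = assay
        if row.get("set"):
            set_members.setdefault(row["set"], []).append(
                (assay.name, float(row["pmol"]))
            )
    return assays, set_members


def load_panel(path) -> Panel:
    """Load a panel from CSV or JSON; inverse of :func:`save_panel`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        assays, _ = _assays_from_rows(doc["assays"], path.name)
        sets = tuple(
            MultiplexSet(s["name"], [tuple(m) for m in s["members"]])
            for s in doc["sets"]
        )
        endo = assays[doc["endogenous"]]
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(reader.fieldnames) != set(_CSV_COLUMNS):
                missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
                raise PanelParseError(
                    f"{path.name}: header must be {','.join(_CSV_COLUMNS)}"
                    + (f" (missing {', '.join(sorted(missing))})" if missing else "")
                )
            assays, set_members = _assays_from_rows(reader, path.name)
        sets = tuple(MultiplexSet(n, m) for n, m in set_members.items())
        endos = [a for a in assays.values() if a.category == "endogenous"]
        if len(endos) != 1:
            raise PanelParseError(f"{path.name}: expected exactly one endogenous assay")
        endo = endos[0]
    crops = set.intersection(*(set(a.crops) for a in assays.values()))
    if len(crops) != 1:
        raise PanelError(
            f"{path.name}: cannot infer a unique panel crop from assay scopes"
        )
    (crop,) = crops
    warnings = tuple(
        PanelWarning(a.name, f"{a.name}: table {a.table1_size_bp} vs canonical "
                             f"{a.expected_size_bp}")
        for a in assays.values() if a.table1_size_bp != a.expected_size_bp
    )
    return Panel(crop=crop, sets=sets, endogenous=endo, assays=assays,
                 warnings=warnings)
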