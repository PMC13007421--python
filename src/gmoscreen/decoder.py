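"""Matrix-based decoding of marker calls into GM screening decisions.

The detection matrix is a boolean event × marker table: each reference GM
event lights a characteristic subset of the panel's introduced-gene
markers.  Decoding a sample's marker calls proceeds:

1. the endogenous-gene call confirms crop species (else the run is invalid);
2. no positive marker → non-GM;
3. events whose profile exactly equals the positive set are single-event
   candidates; identical profiles form an ambiguity group (the screening
   stage cannot split them — confirmatory event-specific tests can);
4. otherwise the positive set is explained as a mixture: all
   inclusion-minimal sets of event profiles whose union equals the positive
   set, found by exhaustive subset search (feasible at ≤ 2^12 events);
5. positive markers carried by no reference event (e.g. markers included in
   the plasmids for future expansion but without a reference event) are
   reported as unexplained.

Markers without a call ("?") are indeterminate and never constrain
matching: profiles are compared restricted to determinate markers only.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DetectionMatrix",
    "ScreeningResult",
    "MatrixReport",
    "builtin_matrix",
    "decode",
    "analyze_matrix",
    "load_matrix",
    "save_matrix",
]


@dataclass(frozen=True)
class DetectionMatrix:
    """Boolean event × marker detection table with testability flags."""

    crop: str
    events: tuple
    markers: tuple
    profiles: dict  # event -> frozenset of positive markers
    untested: frozenset = frozenset()  # markers with no reference event

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "untested", frozenset(self.untested))
        for e in self.events:
            prof = self.profiles.get(e)
            if prof is None:
                raise ValueError(f"event {e} has no profile")
            if not prof:
                raise ValueError(f"event {e} has no positive marker")
            if not prof <= set(self.markers):
                raise ValueError(f"event {e}: profile outside marker list")

    def profile(self, event: str) -> frozenset:
        return self.profiles[event]


# Transcribed reference matrices: rows are markers, columns events.
_SOY_EVENTS = (
    "A2704-12", "CV127", "DAS44406-6", "DAS68416-4", "DAS81419", "DP356043",
    "FG72", "Mon87705", "Mon87751", "Mon87769", "Mon89788", "SYHT0H2",
)
_SOY_MARKERS = (
    "T-E9", "P-TSF1", "pat", "DMO", "T-tml", "T-H4", "T-35S",
    "P-rbcS", "P-ubi10", "csr1-2", "T-PinII",
)
_SOY_PROFILES = {
    "A2704-12": {"pat", "T-35S"},
    "CV127": {"csr1-2"},
    "DAS44406-6": {"pat", "T-H4", "P-ubi10"},
    "DAS68416-4": {"pat", "P-ubi10"},
    "DAS81419": {"pat", "P-ubi10"},
    "DP356043": {"T-PinII"},
    "FG72": {"T-H4"},
    "Mon87705": {"T-E9", "P-TSF1"},
    "Mon87751": {"P-rbcS"},
    "Mon87769": {"T-E9", "T-tml"},
    "Mon89788": {"T-E9", "P-TSF1"},
    "SYHT0H2": {"pat"},
}
_SOY_UNTESTED = {"DMO"}

_MAIZE_EVENTS = ("Bt176", "DAS40278", "GA21", "NK603", "T25", "TC1507")
_MAIZE_MARKERS = (
    "CP4epsps", "gat4621", "T-hsp17.3", "mEPSPS", "P-act1", "pat",
    "aad1", "bar", "T-PinII",
)
_MAIZE_PROFILES = {
    "Bt176": {"bar"},
    "DAS40278": {"aad1"},
    "GA21": {"mEPSPS", "P-act1"},
    "NK603": {"CP4epsps", "P-act1"},
    "T25": {"pat"},
    "TC1507": {"pat"},
}
_MAIZE_UNTESTED = {"gat4621", "T-hsp17.3", "T-PinII"}


def builtin_matrix(crop: str) -> DetectionMatrix:
    """The built-in reference detection matrix (12 soybean / 6 maize events)."""
    if crop == "soybean":
        return DetectionMatrix(
            crop=crop, events=_SOY_EVENTS, markers=_SOY_MARKERS,
            profiles={e: frozenset(p) for e, p in _SOY_PROFILES.items()},
            untested=frozenset(_SOY_UNTESTED),
        )
    if crop == "maize":
        return DetectionMatrix(
            crop=crop, events=_MAIZE_EVENTS, markers=_MAIZE_MARKERS,
            profiles={e: frozenset(p) for e, p in _MAIZE_PROFILES.items()},
            untested=frozenset(_MAIZE_UNTESTED),
        )
    raise ValueError(f"unknown crop {crop!r}")


@dataclass(frozen=True)
class ScreeningResult:
    """Decoded screening decision for one sample."""

    sample: str
    species_confirmed: bool
    gm_status: str  # "GM" | "non-GM" | "invalid"
    single_event_candidates: tuple = ()
    ambiguity_group: tuple = ()
    minimal_mixtures: tuple = ()  # tuple of frozensets of event names
    unexplained_markers: frozenset = frozenset()
    notes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "species_confirmed": self.species_confirmed,
            "gm_status": self.gm_status,
            "single_event_candidates": list(self.single_event_candidates),
            "ambiguity_group": list(self.ambiguity_group),
            "minimal_mixtures": [sorted(m) for m in self.minimal_mixtures],
            "unexplained_markers": sorted(self.unexplained_markers),
            "notes": list(self.notes),
        }


def _minimal_covers(target: frozenset, usable: dict) -> tuple:
    """All inclusion-minimal sets of events whose profiles union to target.

    ``usable`` maps event → restricted profile (⊆ target, non-empty).
    Exhaustive over subsets, smallest cardinality first; a cover is kept
    only if no already-found cover is a proper subset of it.
    """
    names = sorted(usable)
    covers = []
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            union = frozenset().union(*(usable[e] for e in combo))
            if union != target:
                continue
            cset = frozenset(combo)
            if any(found < cset for found in covers):
                continue
            covers.append(cset)
    return tuple(sorted(covers, key=lambda c: (len(c), sorted(c))))


def decode(calls, endogenous_call, matrix: DetectionMatrix,
           sample: str = "sample") -> ScreeningResult:
    """Decode marker calls into a screening decision.

    ``calls`` are :class:`~gmoscreen.ce.MarkerCall`-like objects (fields
    ``assay`` and ``call`` in {'+', '-', '?'}); markers absent from
    ``calls`` are treated as indeterminate.  A call for a marker not in the
    matrix is an error.
    """
    call_map = {}
    for c in calls:
        if c.assay not in matrix.markers:
            raise KeyError(f"marker {c.assay!r} not in {matrix.crop} matrix")
        if c.call not in "+-?":
            raise ValueError(f"bad call {c.call!r} for {c.assay}")
        call_map[c.assay] = c.call
    species = getattr(endogenous_call, "call", endogenous_call) == "+"
    if not species:
        return ScreeningResult(
            sample=sample, species_confirmed=False, gm_status="invalid",
            notes=("endogenous reference gene not detected",),
        )
    determinate = frozenset(m for m in matrix.markers if call_map.get(m, "?") in "+-")
    positives = frozenset(m for m in matrix.markers if call_map.get(m) == "+")
    if not positives:
        return ScreeningResult(sample=sample, species_confirmed=True,
                               gm_status="non-GM")
    covered = frozenset().union(*matrix.profiles.values())
    unexplained = positives - covered
    notes = []
    if unexplained:
        notes.append(
            "positive marker(s) carried by no reference event: "
            + ", ".join(sorted(unexplained))
        )
    candidates = tuple(
        e for e in matrix.events
        if matrix.profiles[e] & determinate == positives
    )
    mixtures = ()
    if not candidates:
        target = positives - unexplained
        usable = {}
        for e in matrix.events:
            restricted = matrix.profiles[e] & determinate
            if restricted and restricted <= target:
                usable[e] = restricted
        if target:
            mixtures = _minimal_covers(target, usable)
        if not mixtures and target:
            notes.append("no combination of reference events explains the calls")
    return ScreeningResult(
        sample=sample, species_confirmed=True, gm_status="GM",
        single_event_candidates=candidates,
        ambiguity_group=candidates if len(candidates) > 1 else (),
        minimal_mixtures=mixtures,
        unexplained_markers=unexplained,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class MatrixReport:
    """Distinguishability analysis of a detection matrix."""

    n_events: int
    n_distinct_profiles: int
    identical_groups: tuple   # tuples of events sharing a profile
    subset_pairs: tuple       # (a, b) where profile(a) ⊂ profile(b)
    marker_discrimination: dict  # marker -> number of event pairs it splits


def analyze_matrix(matrix: DetectionMatrix) -> MatrixReport:
    """Report profile collisions, containments and per-marker discrimination."""
    by_profile = {}
    for e in matrix.events:
        by_profile.setdefault(matrix.profiles[e], []).append(e)
    identical = tuple(
        tuple(v) for v in by_profile.values() if len(v) > 1
    )
    subset_pairs = tuple(
        (a, b)
        for a, b in itertools.permutations(matrix.events, 2)
        if matrix.profiles[a] < matrix.profiles[b]
    )
    discrimination = {
        m: sum(
            1 for a, b in itertools.combinations(matrix.events, 2)
            if (m in matrix.profiles[a]) != (m in matrix.profiles[b])
        )
        for m in matrix.markers
    }
    return MatrixReport(
        n_events=len(matrix.events),
        n_distinct_profiles=len(by_profile),
        identical_groups=identical,
        subset_pairs=subset_pairs,
        marker_discrimination=discrimination,
    )


def save_matrix(matrix: DetectionMatrix, path) -> None:
    """Write a matrix as CSV: first column event, '+'/'-' cells, untested
    markers flagged with a '*' suffix in the header."""
    path = Path(path)
    header = ["event"] + [
        m + ("*" if m in matrix.untested else "") for m in matrix.markers
    ]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for e in matrix.events:
            w.writerow([e] + [
                "+" if m in matrix.profiles[e] else "-" for m in matrix.markers
            ])


def load_matrix(path, crop: str = "custom") -> DetectionMatrix:
    """Read a matrix CSV written by :func:`save_matrix`."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:1] != ["event"]:
        raise ValueError(f"{path.name}: first header column must be 'event'")
    raw_markers = rows[0][1:]
    markers = tuple(m.rstrip("*") for m in raw_markers)
    untested = frozenset(m.rstrip("*") for m in raw_markers if m.endswith("*"))
    events, profiles = [], {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(markers) + 1:
            raise ValueError(f"{path.name} line {lineno}: wrong column count")
        event = row[0]
        events.append(event)
        pos = set()
        for m, cell in zip(markers, row[1:]):
            if cell not in "+-":
                raise ValueError(
                    f"{path.name} line {lineno}: cell {cell!r} must be '+' or '-'"
                )
            if cell == "+":
                pos.add(m)
        profiles[event] = frozenset(pos)
    return DetectionMatrix(crop=crop, events=tuple(events), markers=markers,
                           profiles=profiles, untested=untested)
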