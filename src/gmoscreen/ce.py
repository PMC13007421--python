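"""Capillary-electrophoresis simulation, peak calling and assay matching.

Models a fragment-analyzer run: amplicons migrate between a lower (20 bp)
and an upper (1000 bp) alignment marker, the detector records an
electropherogram (RFU vs time), and a peak caller estimates each peak's
fragment size and concentration.  A peak is *positive* when its estimated
concentration is at or above ``min_conc`` (default 0.5 ng/µL, inclusive).

Migration model: time is linear in log(size) between the two alignment
markers — a strictly monotone stand-in with an exact inverse; the vendor's
sizing algorithm is proprietary and not reproduced.  Peak width is constant
in size units (``SIGMA_BP`` = 1.2 bp), so two equal peaks 4 bp apart
resolve into two maxima at any size while 1 bp apart they merge — the
resolution regime of the instrument class this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks as _find_peaks

from .panel import MultiplexSet, Panel

__all__ = [
    "CECalibration",
    "Electropherogram",
    "Peak",
    "MarkerCall",
    "MatchResult",
    "migration_time",
    "est_size",
    "simulate_trace",
    "call_peaks",
    "match_peaks_to_assays",
    "is_positive",
    "SIGMA_BP",
    "POSITIVE_MIN_CONC",
]

SIGMA_BP = 1.2            # Gaussian peak width (bp); 4 bp ≈ 3.3 σ separation
POSITIVE_MIN_CONC = 0.5   # ng/µL; inclusive positivity threshold
DEFAULT_NOISE_SD = 0.1    # RFU; baseline noise
_GRID_DT = 0.01           # s; trace sampling interval
_MARKER_AREA = 5.0        # arbitrary area of the alignment-marker peaks


@dataclass(frozen=True)
class CECalibration:
    """Alignment-marker calibration: log-linear size → time mapping."""

    lower_bp: float = 20.0
    upper_bp: float = 1000.0
    lower_time_s: float = 60.0
    upper_time_s: float = 240.0

    def __post_init__(self):
        if not (0 < self.lower_bp < self.upper_bp):
            raise ValueError("marker sizes must satisfy 0 < lower < upper")
        if not self.lower_time_s < self.upper_time_s:
            raise ValueError("lower marker must migrate earlier than upper")

    @property
    def _slope(self):
        return (self.upper_time_s - self.lower_time_s) / log(
            self.upper_bp / self.lower_bp
        )


DEFAULT_CALIBRATION = CECalibration()


def migration_time(size_bp: float, calib: CECalibration = DEFAULT_CALIBRATION) -> float:
    """Migration time of a fragment; strictly increasing in size."""
    if not calib.lower_bp <= size_bp <= calib.upper_bp:
        raise ValueError(
            f"size {size_bp} outside marker range "
            f"[{calib.lower_bp}, {calib.upper_bp}]"
        )
    return calib.lower_time_s + calib._slope * log(size_bp / calib.lower_bp)


def est_size(time_s: float, calib: CECalibration = DEFAULT_CALIBRATION) -> float:
    """Inverse calibration: fragment size from migration time."""
    return calib.lower_bp * np.exp((time_s - calib.lower_time_s) / calib._slope)


def _sigma_time(size_bp: float, calib: CECalibration) -> float:
    # constant SIGMA_BP in size units; dt/dsize = slope / size
    return SIGMA_BP * calib._slope / size_bp


@dataclass(frozen=True)
class Electropherogram:
    """Simulated CE trace with its alignment markers and calibration."""

    time_s: np.ndarray
    rfu: np.ndarray
    markers: tuple  # ((lower_bp, time), (upper_bp, time))
    calib: CECalibration = DEFAULT_CALIBRATION
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self):
        if len(self.time_s) != len(self.rfu):
            raise ValueError("time and signal grids differ in length")


def simulate_trace(
    amplicons,
    calib: CECalibration = DEFAULT_CALIBRATION,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> Electropherogram:
    """Simulate an electropherogram from an amplicon list.

    Each amplicon contributes a Gaussian peak centred at its migration
    time with area equal to its yield (ng/µL); the two alignment markers
    contribute fixed peaks at the trace ends.  Additive seeded Gaussian
    baseline noise; the detector clips at zero RFU.  Deterministic per seed.
    """
    t = np.arange(calib.lower_time_s - 5.0, calib.upper_time_s + 5.0, _GRID_DT)
    signal = np.zeros_like(t)
    peaks = [(calib.lower_bp, _MARKER_AREA), (calib.upper_bp, _MARKER_AREA)]
    for amp in amplicons:
        if not calib.lower_bp < amp.length_bp < calib.upper_bp:
            raise ValueError(
                f"amplicon {amp.assay} ({amp.length_bp} bp) outside marker range"
            )
        if amp.yield_ng_per_ul > 0:
            peaks.append((float(amp.length_bp), amp.yield_ng_per_ul))
    for size, area in peaks:
        mu = migration_time(size, calib)
        sig = _sigma_time(size, calib)
        signal += area / (sig * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - mu) / sig) ** 2
        )
    if noise_sd > 0:
        rng = np.random.default_rng((seed, 0xCE))
        signal = signal + rng.normal(0.0, noise_sd, size=t.shape)
    signal = np.clip(signal, 0.0, None)
    markers = (
        (calib.lower_bp, migration_time(calib.lower_bp, calib)),
        (calib.upper_bp, migration_time(calib.upper_bp, calib)),
    )
    return Electropherogram(time_s=t, rfu=signal, markers=markers,
                            calib=calib, noise_sd=noise_sd)


@dataclass(frozen=True)
class Peak:
    """A called CE peak."""

    apex_time: float
    est_size_bp: float
    conc_ng_per_ul: float
    rfu: float
    positive: bool = False


def is_positive(conc_ng_per_ul: float, min_conc: float = POSITIVE_MIN_CONC) -> bool:
    """Positivity rule: concentration at or above the threshold (inclusive)."""
    return conc_ng_per_ul >= min_conc


def call_peaks(
    trace: Electropherogram,
    min_conc: float = POSITIVE_MIN_CONC,
    resolution_bp: float = 1.0,
    min_rfu: float = 0.5,
    size_guard: tuple = (22.0, 980.0),
) -> list:
    """Detect, size and quantify peaks in a trace.

    Local maxima above a noise-derived floor are called; maxima whose
    estimated sizes differ by less than ``resolution_bp`` are merged
    (tallest kept); sizes inside ``size_guard`` only, excluding the
    alignment markers.  Concentration is estimated as baseline-subtracted
    peak area.  Peaks below ``min_conc`` are retained but flagged
    non-positive.  Returned sorted by estimated size.
    """
    floor = max(min_rfu, 6.0 * trace.noise_sd)
    dt_grid = float(trace.time_s[1] - trace.time_s[0])
    # denoise before apex detection: kernel well below the narrowest
    # instrument peak width (σ_time at the upper marker), so real peaks
    # are barely broadened while shoulder ripple is suppressed
    kernel_s = 0.5 * _sigma_time(trace.calib.upper_bp, trace.calib)
    smooth = gaussian_filter1d(trace.rfu, sigma=kernel_s / dt_grid)
    idx, _ = _find_peaks(smooth, height=floor, prominence=0.5 * floor)
    apexes = []
    for i in idx:
        size = float(est_size(trace.time_s[i], trace.calib))
        if size_guard[0] <= size <= size_guard[1]:
            apexes.append((i, size))
    # merge sub-resolution maxima, keeping the tallest
    merged = []
    for i, size in apexes:
        if merged and size - merged[-1][1] < resolution_bp:
            if smooth[i] > smooth[merged[-1][0]]:
                merged[-1] = (i, size)
        else:
            merged.append((i, size))
    baseline = float(np.median(trace.rfu))
    dt = dt_grid
    out = []
    for i, size in merged:
        sig = _sigma_time(size, trace.calib)
        half = max(1, int(round(4 * sig / dt)))
        lo, hi = max(0, i - half), min(len(trace.rfu), i + half + 1)
        area = float(np.trapezoid(trace.rfu[lo:hi] - baseline, dx=dt))
        conc = max(0.0, area)
        out.append(Peak(
            apex_time=float(trace.time_s[i]), est_size_bp=size,
            conc_ng_per_ul=conc, rfu=float(trace.rfu[i]),
            positive=is_positive(conc, min_conc),
        ))
    out.sort(key=lambda p: p.est_size_bp)
    return out


@dataclass(frozen=True)
class MarkerCall:
    """Presence/absence call for one assay ('+', '-' or '?')."""

    assay: str
    call: str
    est_size_bp: float = None
    conc_ng_per_ul: float = None


@dataclass(frozen=True)
class MatchResult:
    """Peak-to-assay assignment for one multiplex set."""

    set_name: str
    calls: tuple          # MarkerCall per member assay, set order
    unexpected: tuple     # positive Peaks matching no member within tolerance
    ties: tuple = ()      # logged tie-break events

    @property
    def positive_assays(self):
        return tuple(c.assay for c in self.calls if c.call == "+")


def match_peaks_to_assays(
    peaks,
    mset: MultiplexSet,
    panel: Panel,
    tol_bp: float = 2.0,
) -> MatchResult:
    """Assign positive peaks to the member assays of a multiplex set.

    Each positive peak goes to the assay minimizing |estimated − expected|
    when within ``tol_bp``; the assignment is injective (greedy on
    increasing difference, ties broken toward the smaller expected size and
    logged).  Unassigned positive peaks are reported as unexpected.
    """
    if tol_bp <= 0:
        raise ValueError("tol_bp must be > 0")
    positives = [p for p in peaks if p.positive]
    expected = {n: panel.assays[n].expected_size_bp for n in mset.assay_names}
    pairs = []
    for pi, peak in enumerate(positives):
        for name, size in expected.items():
            diff = abs(peak.est_size_bp - size)
            if diff <= tol_bp:
                pairs.append((diff, size, pi, name))
    pairs.sort()
    ties = []
    for a, b in zip(pairs, pairs[1:]):
        if a[0] == b[0] and a[2] == b[2]:
            ties.append(
                f"peak at {positives[a[2]].est_size_bp:.1f} bp equidistant from "
                f"{a[3]} and {b[3]}; assigned toward smaller expected size"
            )
    assigned_peaks, assigned_assays = set(), {}
    for diff, size, pi, name in pairs:
        if pi in assigned_peaks or name in assigned_assays:
            continue
        assigned_peaks.add(pi)
        assigned_assays[name] = positives[pi]
    calls = []
    for name in mset.assay_names:
        peak = assigned_assays.get(name)
        if peak is None:
            calls.append(MarkerCall(assay=name, call="-"))
        else:
            calls.append(MarkerCall(assay=name, call="+",
                                    est_size_bp=peak.est_size_bp,
                                    conc_ng_per_ul=peak.conc_ng_per_ul))
    unexpected = tuple(
        p for i, p in enumerate(positives) if i not in assigned_peaks
    )
    return MatchResult(set_name=mset.name, calls=tuple(calls),
                       unexpected=unexpected, ties=tuple(ties))
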