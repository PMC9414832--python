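"""Retention-index calibration, library matching, and heartcut library building.

Targets accumulated from automated sequential heartcut GC-GC/MS runs form a
cumulative library: each 1-min heartcut is deconvolved against everything
registered so far (components carried over from the previous cut are thereby
recognised rather than duplicated), and only genuinely new spectra are added.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .chromdata import (CalibrationRangeError, ChromRun, DataValidationError,
                        RICalibration, Spectrum, TargetCompound, TargetLibrary)
from .deconvolution import (MatchCriteria, NoiseModel, deconvolve_peak,
                            detect_peaks, _next_unknown_id)
from .similarity import cosine, weighted_cosine

logger = logging.getLogger(__name__)

DEFAULT_HEARTCUT_WIDTH = 1.0   # minutes


@dataclass
class HeartcutRun:
    """A second-column run of one first-column heartcut window [start, end)."""

    window: tuple[float, float]
    run: ChromRun

    def __post_init__(self):
        start, end = self.window
        if end <= start:
            raise DataValidationError(f"empty heartcut window {self.window}")


@dataclass
class LibraryMatch:
    """One ranked candidate from a library identity search."""

    candidate: TargetCompound
    score: float
    ri_delta: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise DataValidationError(f"score {self.score} outside [0, 1]")


def kovats_ri(rt: float, cal: RICalibration) -> float:
    """Temperature-programmed (van den Dool-Kratz) retention index.

    Linear interpolation between the bracketing n-alkanes:
    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)).  No extrapolation:
    retention times outside the calibrated span raise.
    """
    carbons = sorted(cal.alkanes)
    rts = [cal.alkanes[c] for c in carbons]
    if rt < rts[0] or rt > rts[-1]:
        raise CalibrationRangeError(
            f"rt {rt} min outside calibration span [{rts[0]}, {rts[-1]}]")
    j = int(np.searchsorted(rts, rt, side="right")) - 1
    j = min(j, len(carbons) - 2)
    n, rt_n, rt_n1 = carbons[j], rts[j], rts[j + 1]
    # carbon gaps other than 1 are supported (sparse calibrations)
    n_next = carbons[j + 1]
    return 100.0 * (n + (n_next - n) * (rt - rt_n) / (rt_n1 - rt_n))


def match_library(query: Spectrum, library: TargetLibrary,
                  ri: float | None = None, ri_window: float = 30.0,
                  ) -> list[LibraryMatch]:
    """Rank library entries against a query spectrum.

    Score is the NIST-style weighted cosine (m/z^1, intensity^0.5).
    When both the query and a candidate have retention indices, candidates
    beyond ``ri_window`` index units are excluded.  Ranking: descending
    score, then smaller RI difference, then lexical id.
    """
    if not query:
        raise DataValidationError("empty query spectrum")
    matches: list[LibraryMatch] = []
    for entry in library:
        ri_delta = None
        if ri is not None and entry.ri is not None:
            ri_delta = abs(ri - entry.ri)
            if ri_delta > ri_window:
                continue
        matches.append(LibraryMatch(candidate=entry,
                                    score=weighted_cosine(query, entry.ref_spectrum),
                                    ri_delta=ri_delta))
    matches.sort(key=lambda m: (-m.score,
                                m.ri_delta if m.ri_delta is not None else np.inf,
                                m.candidate.id))
    return matches


@dataclass(frozen=True)
class IdentificationThresholds:
    """Score and RI gates for tentative identification."""

    score_min: float = 0.80
    ri_window: float = 30.0


def classify_identification(match: LibraryMatch, has_reference_standard: bool,
                            thresholds: IdentificationThresholds = IdentificationThresholds(),
                            ) -> str:
    """'positive' | 'tentative' | 'unknown' per the confirmation ladder.

    Tentative requires the spectral score and (when known) the RI agreement;
    positive additionally requires a reference standard for the compound.
    Anything else is an unknown, to be assigned a numeric identifier.
    """
    tentative = match.score >= thresholds.score_min and (
        match.ri_delta is None or match.ri_delta <= thresholds.ri_window)
    if tentative and has_reference_standard:
        return "positive"
    if tentative:
        return "tentative"
    return "unknown"


DEDUP_COSINE = 0.95
DEDUP_RI_WINDOW = 10.0
DEDUP_RT_WINDOW = 0.1   # minutes, fallback when no RI calibration is given


def _duplicate_of(target: TargetCompound, library: TargetLibrary,
                  dedup_cosine: float, dedup_ri: float,
                  dedup_rt: float) -> TargetCompound | None:
    for entry in library:
        if target.ri is not None and entry.ri is not None:
            if abs(target.ri - entry.ri) > dedup_ri:
                continue
        elif abs(target.rt - entry.rt) > dedup_rt:
            continue
        if cosine(target.ref_spectrum, entry.ref_spectrum) >= dedup_cosine:
            return entry
    return None


def build_library(heartcuts: list[HeartcutRun],
                  ref_libraries: list[TargetLibrary] | None = None,
                  criteria: MatchCriteria = MatchCriteria(),
                  noise: NoiseModel | None = None,
                  cal: RICalibration | None = None,
                  starting_library: TargetLibrary | None = None,
                  score_min: float = 0.80,
                  dedup_cosine: float = DEDUP_COSINE,
                  dedup_ri: float = DEDUP_RI_WINDOW,
                  dedup_rt: float = DEDUP_RT_WINDOW,
                  invariant_tol: float = 0.05,
                  ) -> TargetLibrary:
    """Cumulative target-library building over an ordered heartcut campaign.

    The first heartcut is deconvolved fully and its components registered;
    every subsequent heartcut is deconvolved against the library accumulated
    so far, so components transferred from the previous cut are matched as
    known targets instead of re-registered.  A new component whose spectrum
    cosine is >= ``dedup_cosine`` against an existing entry within
    ``dedup_ri`` retention-index units (or ``dedup_rt`` minutes when no
    calibration is given) is merged into it, keeping the higher-abundance
    spectrum.  Unknown numeric ids are issued monotonically.
    """
    ordered = sorted(heartcuts, key=lambda h: h.window[0])
    for a, b in zip(ordered, ordered[1:]):
        if b.window[0] < a.window[1]:
            raise DataValidationError(
                f"overlapping heartcut windows {a.window} and {b.window}")

    ref = None
    if ref_libraries:
        merged: list[TargetCompound] = []
        seen = set()
        for lib in ref_libraries:
            for e in lib:
                if e.id not in seen:
                    merged.append(e)
                    seen.add(e.id)
        ref = TargetLibrary(entries=merged)

    library = starting_library or TargetLibrary(
        provenance={"built_from": f"{len(ordered)} heartcuts"})
    unknown_ids = itertools.count(_next_unknown_id(library))
    abundance_seen: dict[str, float] = {
        e.id: float(e.annotations.get("abundance", 0.0)) for e in library}

    for hc in ordered:
        run = hc.run
        hc_noise = noise or NoiseModel.estimate(run)
        try:
            regions = detect_peaks(run, hc_noise)
        except DataValidationError:
            regions = []
        for region in regions:
            comps, _ = deconvolve_peak(run, region, library, criteria, hc_noise,
                                       ref_library=ref, score_min=score_min,
                                       invariant_tol=invariant_tol,
                                       unknown_ids=unknown_ids)
            for comp in comps:
                target, result = comp.target, comp.result
                if target.id in library and not comp.is_unknown:
                    continue  # a known target re-observed (e.g. carryover)
                if cal is not None and target.ri is None:
                    try:
                        target.ri = kovats_ri(target.rt, cal)
                    except CalibrationRangeError:
                        pass
                target.source_heartcut = hc.window
                dup = _duplicate_of(target, library, dedup_cosine, dedup_ri, dedup_rt)
                if dup is not None:
                    if result.abundance > abundance_seen.get(dup.id, 0.0):
                        dup.ref_spectrum = target.ref_spectrum
                        dup.main_ion = target.main_ion
                        dup.qualifiers = target.qualifiers
                        abundance_seen[dup.id] = result.abundance
                    continue
                target.annotations["abundance"] = result.abundance
                abundance_seen[target.id] = result.abundance
                library.add(target)
    return library
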