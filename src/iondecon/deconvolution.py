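"""Ion-ratio target matching and the iterative subtraction deconvolution engine.

The identification criterion is a conjunction of four tests evaluated on a
candidate peak window:

1. every qualifier's reduced intensity ``Ii = Ai/(Ri*Amain)`` stays within a
   fractional deviation of 1 (default +/-20%) for at least ``min_consecutive_scans``
   consecutive scans, with the mean pairwise deviation ``dI <= K + d0/Amain``;
2. the scan-to-scan variance ``dE = dI * log10(Amain)`` stays below a ceiling
   (default 7) somewhere in that window;
3. the Q-value — 100 minus the mean percent deviation of observed from
   expected qualifier:main ratios across the window — is >= 95;
4. the Q-ratio — the worst fractional deviation of the window-mean
   qualifier:main ratio from its expected value — is within +/-20%.

Peaks whose targets pass are subtracted from the chromatogram, scan by scan,
scaled on the main ion; the loop of invariant-scan averaging, library lookup
and subtraction continues until the residual approximates background.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .chromdata import (ChromRun, DataValidationError, Scan, Spectrum,
                        TargetCompound, TargetLibrary, UndefinedReductionError)
from .similarity import cosine, pairwise_cosine_matrix, weighted_cosine

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Criteria, regions, results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchCriteria:
    """Thresholds of the four-part identification criterion.

    k
        user-defined acceptable relative difference for the mean pairwise
        reduced-intensity deviation (fraction, default 0.20).
    delta0
        additive error attributable to instrument noise, in counts; the
        criterion is ``dI <= k + delta0 / Amain``.  Use :meth:`with_noise`
        to set it to 3x the baseline MAD estimated from a run.
    delta_e_max
        ceiling on the scan-to-scan variance dE (default 7).
    min_consecutive_scans
        length of the consecutive qualifying stretch required (default 5).
    max_ion_deviation
        per-qualifier tolerance |Ii - 1| for a scan to qualify (default 0.20).
    q_value_min
        minimum Q-value in percent (default 95).
    q_ratio_tol
        tolerance on the Q-ratio fractional deviation (default 0.20).
    """

    k: float = 0.20
    delta0: float = 0.0
    delta_e_max: float = 7.0
    min_consecutive_scans: int = 5
    max_ion_deviation: float = 0.20
    q_value_min: float = 95.0
    q_ratio_tol: float = 0.20

    def __post_init__(self):
        if self.k <= 0 or self.delta_e_max <= 0 or self.min_consecutive_scans <= 0:
            raise DataValidationError("criteria fields must be positive")
        if self.delta0 < 0:
            raise DataValidationError("delta0 must be >= 0")
        for name in ("max_ion_deviation", "q_ratio_tol"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DataValidationError(f"{name}={v} outside (0, 1]")
        if not (0 < self.q_value_min <= 100):
            raise DataValidationError("q_value_min outside (0, 100]")

    def with_noise(self, noise: "NoiseModel") -> "MatchCriteria":
        return replace(self, delta0=3.0 * noise.baseline_mad)


@dataclass(frozen=True)
class PeakRegion:
    """Scan-index bounds of a chromatographic peak (inclusive)."""

    start_scan: int
    apex_scan: int
    end_scan: int

    def __post_init__(self):
        if not (self.start_scan <= self.apex_scan <= self.end_scan):
            raise DataValidationError("need start <= apex <= end")
        if self.n_scans < 3:
            raise DataValidationError("a peak region needs at least 3 scans")

    @property
    def n_scans(self) -> int:
        return self.end_scan - self.start_scan + 1

    @property
    def indices(self) -> range:
        return range(self.start_scan, self.end_scan + 1)


@dataclass
class NoiseModel:
    """Baseline statistics of the TIC trace used as the background yardstick."""

    baseline_level: float
    baseline_mad: float
    estimation_window: tuple[int, int] | None = None

    def __post_init__(self):
        if self.baseline_mad < 0:
            raise DataValidationError("baseline MAD must be >= 0")

    @property
    def threshold(self) -> float:
        """Background acceptance level: baseline + 3 x MAD."""
        return self.baseline_level + 3.0 * self.baseline_mad

    @classmethod
    def estimate(cls, run: ChromRun, window: tuple[int, int] | None = None) -> "NoiseModel":
        """Estimate baseline level and spread from the TIC trace.

        With an explicit scan ``window`` (a stretch known to be analyte-free)
        the level and MAD are taken directly from it.  Otherwise the noise
        spread comes from the median absolute first difference of the TIC —
        robust to peaks, which occupy few scan-to-scan steps — and the level
        from the median of the quieter 60% of scans.
        """
        tic = run.tic()
        if window is not None:
            lo, hi = window
            vals = tic[lo:hi]
            level = float(np.median(vals))
            mad = float(np.median(np.abs(vals - level)))
        else:
            if len(tic) < 3:
                raise DataValidationError("too few scans to estimate noise")
            # sd of (x_{i+1} - x_i) is sqrt(2) x noise sd; trimming the top
            # decile of |diff| removes peak flanks, and 0.7894 corrects the
            # rms of a normal truncated at its 90% absolute quantile
            d = np.abs(np.diff(tic))
            kept = d[d <= np.percentile(d, 90)]
            sigma = float(np.sqrt(np.mean(kept ** 2))) / (0.7894 * np.sqrt(2.0)) \
                if len(kept) else 0.0
            # peaks occupy a minority of scans, so the overall median tracks
            # the baseline level
            level = float(np.median(tic))
            mad = 0.6745 * sigma
        return cls(baseline_level=level, baseline_mad=mad, estimation_window=window)


@dataclass
class MatchResult:
    """Outcome of evaluating one target against one run."""

    target_id: str
    region: PeakRegion | None
    scan_indices: list[int] = field(default_factory=list)
    reduced: np.ndarray | None = None       # (n_scans, n_qualifiers) Ii(t)
    delta_i: np.ndarray | None = None       # per-scan dI
    delta_e: np.ndarray | None = None       # per-scan dE
    q_value: float = 0.0
    q_ratio_dev: float = float("inf")
    n_consecutive_pass: int = 0
    passed: bool = False
    abundance: float = 0.0                  # integrated main-ion response

    def histogram(self) -> np.ndarray | None:
        """Normalized qualifier:main ion signals per scan (flat = good match)."""
        return self.reduced


# ---------------------------------------------------------------------------
# The four-part criterion, piecewise
# ---------------------------------------------------------------------------

def reduced_intensities(scan: Scan, target: TargetCompound) -> np.ndarray:
    """Reduced ion intensity Ii = Ai / (Ri * Amain) per qualifier.

    A scan whose qualifier intensities sit exactly at the expected ratios
    gives Ii = 1 for every qualifier.
    """
    a_main = scan.spectrum.get(target.main_ion)
    if a_main <= 0:
        raise UndefinedReductionError(
            f"main ion {target.main_ion} absent at t={scan.time}")
    return np.array([scan.spectrum.get(mz) / (ri * a_main)
                     for mz, ri in target.qualifiers])


def delta_i(reduced: np.ndarray) -> float:
    """Mean pairwise absolute deviation of the reduced intensities.

    Sum of |Ii - Ij| over all pairs divided by the pair count N(N-1)/2
    (written as 1 + 2 + ... + (N-1)); zero iff all reduced intensities agree.
    """
    r = np.asarray(reduced, dtype=float)
    n = len(r)
    if n < 2:
        raise DataValidationError("delta_i needs at least 2 reduced intensities")
    total = sum(abs(r[i] - r[j]) for i in range(n - 1) for j in range(i + 1, n))
    return float(total / (n * (n - 1) / 2))


def ssv(delta_i_value: float, a_main: float) -> float:
    """Scan-to-scan variance dE = dI * log10(Amain)."""
    if a_main <= 0:
        raise DataValidationError("ssv needs a positive main-ion abundance")
    return float(delta_i_value * np.log10(a_main))


def _observed_ratios(scans: list[Scan], target: TargetCompound) -> np.ndarray:
    """(n_usable_scans, n_qualifiers) observed qualifier:main ratios."""
    rows = []
    for s in scans:
        a_main = s.spectrum.get(target.main_ion)
        if a_main <= 0:
            continue
        rows.append([s.spectrum.get(mz) / a_main for mz, _ in target.qualifiers])
    if not rows:
        raise UndefinedReductionError(
            f"no scan in region has main ion {target.main_ion}")
    return np.array(rows)


def q_value(target: TargetCompound, scans: list[Scan]) -> float:
    """Percent agreement of observed vs expected ion ratios across the peak.

    100 minus the mean (over scans with a nonzero main ion, and over
    qualifiers) of 100*|Ri - ri(t)|/Ri, clamped to [0, 100].
    """
    obs = _observed_ratios(scans, target)
    expected = np.array([ri for _, ri in target.qualifiers])
    dev = 100.0 * np.abs(expected - obs) / expected
    return float(max(0.0, 100.0 - dev.mean()))


def q_ratio_deviation(target: TargetCompound, scans: list[Scan]) -> float:
    """Worst fractional deviation of the peak-mean qualifier:main ratio from Ri."""
    obs = _observed_ratios(scans, target)
    expected = np.array([ri for _, ri in target.qualifiers])
    mean_ratio = obs.mean(axis=0)
    return float(np.max(np.abs(mean_ratio - expected) / expected))


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True; earliest on ties."""
    best_start, best_len, cur_start = 0, 0, None
    for i, v in enumerate(mask):
        if v and cur_start is None:
            cur_start = i
        if (not v or i == len(mask) - 1) and cur_start is not None:
            end = i if v else i - 1
            length = end - cur_start + 1
            if length > best_len:
                best_start, best_len = cur_start, length
            cur_start = None
    return best_start, best_len


def evaluate_target(run: ChromRun, target: TargetCompound,
                    criteria: MatchCriteria = MatchCriteria(),
                    rt_window: float = 0.2) -> MatchResult:
    """Evaluate the full four-part criterion for one target in one run.

    Scans within ``rt_window`` minutes of the target's retention time are
    searched for the longest consecutive stretch in which every qualifier's
    reduced intensity deviates from 1 by at most ``max_ion_deviation`` and
    ``dI <= k + delta0/Amain``.  The Q-value, Q-ratio and dE ceiling are then
    assessed on that stretch.  A target whose retention time misses the run
    yields a not-found result (``passed=False``), not an exception.
    """
    times = run.times()
    if len(times) == 0:
        return MatchResult(target_id=target.id, region=None)
    sel = np.where(np.abs(times - target.rt) <= rt_window)[0]
    if len(sel) == 0:
        return MatchResult(target_id=target.id, region=None)

    scans = [run.scans[i] for i in sel]
    n = len(scans)
    nq = len(target.qualifiers)
    reduced = np.full((n, nq), np.nan)
    d_i = np.full(n, np.nan)
    d_e = np.full(n, np.nan)
    a_main = np.array([s.spectrum.get(target.main_ion) for s in scans])
    for i, s in enumerate(scans):
        if a_main[i] <= 0:
            continue
        reduced[i] = reduced_intensities(s, target)
        d_i[i] = delta_i(reduced[i])
        d_e[i] = ssv(d_i[i], a_main[i])

    with np.errstate(invalid="ignore", divide="ignore"):
        ion_ok = np.all(np.abs(reduced - 1.0) <= criteria.max_ion_deviation, axis=1)
        di_ok = d_i <= criteria.k + criteria.delta0 / np.where(a_main > 0, a_main, np.inf)
    qualifies = ion_ok & di_ok & (a_main > 0)

    start, length = _longest_true_run(qualifies)
    result = MatchResult(target_id=target.id, region=None,
                         scan_indices=[int(i) for i in sel],
                         reduced=reduced, delta_i=d_i, delta_e=d_e)
    if length == 0:
        # report diagnostics over whatever scans have a main ion, if any
        usable = [s for s in scans if s.spectrum.get(target.main_ion) > 0]
        if usable:
            result.q_value = q_value(target, usable)
            result.q_ratio_dev = q_ratio_deviation(target, usable)
        return result

    window = list(range(start, start + length))
    window_scans = [scans[i] for i in window]
    result.n_consecutive_pass = length
    result.q_value = q_value(target, window_scans)
    result.q_ratio_dev = q_ratio_deviation(target, window_scans)
    apex_local = window[int(np.argmax(a_main[window]))]
    result.region = PeakRegion(int(sel[window[0]]), int(sel[apex_local]),
                               int(sel[window[-1]])) if length >= 3 else None
    result.abundance = float(a_main[window].sum())
    min_de = float(np.nanmin(d_e[window]))
    result.passed = (
        length >= criteria.min_consecutive_scans
        and min_de <= criteria.delta_e_max
        and result.q_value >= criteria.q_value_min
        and result.q_ratio_dev <= criteria.q_ratio_tol
    )
    return result


# ---------------------------------------------------------------------------
# Peak detection, invariant scans, subtraction
# ---------------------------------------------------------------------------

def _smooth_tic(tic: np.ndarray) -> np.ndarray:
    n = len(tic)
    window = min(9, n if n % 2 else n - 1)
    if window < 5:
        return tic.copy()
    # "nearest" padding avoids the variance blow-up of polynomial
    # extrapolation at the window edges
    return savgol_filter(tic, window_length=window, polyorder=3,
                         mode="nearest")


def detect_peaks(run: ChromRun, noise: NoiseModel) -> list[PeakRegion]:
    """TIC peak picking: Savitzky-Golay smoothing, apexes above baseline + 3 MAD.

    Region bounds extend from each apex to where the smoothed TIC returns to
    baseline (+1 MAD) or to the local minimum between adjacent apexes.
    Adjacent regions whose shared valley stays above half the lower apex
    height (baseline-corrected) are unresolved coeluters and are merged into
    one region, so the deconvolution loop sees the whole cluster.
    """
    if len(run) < 10:
        raise DataValidationError("peak detection needs at least 10 scans")
    tic = run.tic()
    smooth = _smooth_tic(tic)
    apexes, _ = find_peaks(smooth, height=noise.threshold)
    if len(apexes) == 0:
        return []
    floor = noise.baseline_level + noise.baseline_mad
    regions: list[PeakRegion] = []
    for j, apex in enumerate(apexes):
        left_limit = apexes[j - 1] if j > 0 else 0
        right_limit = apexes[j + 1] if j + 1 < len(apexes) else len(smooth) - 1
        lo = apex
        while lo > left_limit and smooth[lo - 1] > floor and smooth[lo - 1] <= smooth[lo]:
            lo -= 1
        hi = apex
        while hi < right_limit and smooth[hi + 1] > floor and smooth[hi + 1] <= smooth[hi]:
            hi += 1
        if hi - lo + 1 >= 3:
            regions.append(PeakRegion(int(lo), int(apex), int(hi)))

    merged: list[PeakRegion] = []
    for reg in regions:
        if merged and reg.start_scan - merged[-1].end_scan <= 1:
            prev = merged[-1]
            valley = smooth[prev.end_scan:reg.start_scan + 1].min() - noise.baseline_level
            lower_apex = min(smooth[prev.apex_scan], smooth[reg.apex_scan]) - noise.baseline_level
            # two equal Gaussians 5 sigma apart give a valley/apex ratio of
            # ~0.05, heavily overlapped clusters >= ~0.3 even when a weak
            # member sits at the valley; 0.2 separates the two regimes
            if lower_apex > 0 and valley >= 0.20 * lower_apex:
                apex = prev.apex_scan if smooth[prev.apex_scan] >= smooth[reg.apex_scan] \
                    else reg.apex_scan
                merged[-1] = PeakRegion(prev.start_scan, apex, reg.end_scan)
                continue
        merged.append(reg)
    return merged


def select_invariant_scans(run: ChromRun, region: PeakRegion,
                           n_min: int = 3, n_max: int = 5,
                           tol: float = 0.05) -> list[int] | None:
    """Find the 3-5 consecutive scans whose spectra are most mutually constant.

    Searches every contiguous window of n_min..n_max scans inside the region,
    keeps those in which every pairwise spectral distance (1 - cosine) is at
    most ``tol``, and returns the window with the smallest mean pairwise
    distance; larger windows win ties.  Returns None when no window
    satisfies the tolerance (e.g. a noise-only region).
    """
    idx = list(region.indices)
    spectra = {i: run.scans[i].spectrum for i in idx}
    best: tuple[float, int, int] | None = None  # (mean_dist, -n, start)
    best_window: list[int] | None = None
    for n in range(n_min, n_max + 1):
        for s in range(len(idx) - n + 1):
            window = idx[s:s + n]
            if any(not spectra[i] for i in window):
                continue
            dists = [1.0 - cosine(spectra[a], spectra[b])
                     for a, b in itertools.combinations(window, 2)]
            if max(dists) > tol:
                continue
            key = (float(np.mean(dists)), -n, window[0])
            if best is None or key < best:
                best, best_window = key, window
    return best_window


def scan_distance_matrix(run: ChromRun, region: PeakRegion) -> np.ndarray:
    """Diagnostic: pairwise spectral distance (1 - cosine) across region scans.

    This exposes the cross-scan comparison view of the scan-to-scan variance
    (scan 1 vs scans 2..n, scan 2 vs 3..n, ...) alongside the dE formula.
    """
    spectra = [run.scans[i].spectrum for i in region.indices]
    return 1.0 - pairwise_cosine_matrix(spectra)


def average_spectrum(run: ChromRun, scan_indices: list[int]) -> Spectrum:
    """Arithmetic mean spectrum over the given scans (absent ions count as 0)."""
    if not scan_indices:
        raise DataValidationError("average_spectrum needs at least one scan")
    acc: dict[int, float] = {}
    for i in scan_indices:
        for m, v in run.scans[i].spectrum.peaks.items():
            acc[m] = acc.get(m, 0.0) + v
    n = len(scan_indices)
    return Spectrum({m: v / n for m, v in acc.items()})


@dataclass
class SubtractionProfile:
    """Per-scan record of one component subtraction, with mass balance."""

    component_id: str
    anchor_ion: int
    scan_indices: list[int]
    scales: np.ndarray                  # per-scan anchor-derived scale factors
    subtracted_area: float              # total counts removed (pre-clipping)
    main_ion_area: float                # counts removed at the anchor ion
    original_sum: float                 # region total before subtraction
    residual_preclip_sum: float         # region total minus subtracted (exact)
    clipped: float                      # counts clipped from negative residuals

    @property
    def balance_error(self) -> float:
        """|original - (subtracted + residual-pre-clip)| — 0 up to float order."""
        return abs(self.original_sum - (self.subtracted_area + self.residual_preclip_sum))


def subtract_component(run: ChromRun, region: PeakRegion, component: Spectrum,
                       anchor_ion: int,
                       component_id: str = "") -> tuple[ChromRun, SubtractionProfile]:
    """Remove a component's scaled spectrum from every scan of a region.

    Each scan's scale factor is its intensity at the anchor ion divided by the
    component's anchor intensity, so the component is removed following its
    own elution profile.  Negative residuals are clipped to zero; the
    pre-clipping mass balance is recorded in the returned profile.
    """
    comp_anchor = component.get(anchor_ion)
    if comp_anchor <= 0:
        raise DataValidationError(
            f"component has no intensity at anchor ion {anchor_ion}")
    idx = list(region.indices)
    if idx[-1] >= len(run):
        raise DataValidationError("region extends past the end of the run")

    new_scans = list(run.scans)
    scales = np.zeros(len(idx))
    original_sum = sum(run.scans[i].tic for i in idx)
    subtracted = 0.0
    clipped = 0.0
    residual_preclip = 0.0
    for k, i in enumerate(idx):
        spec = run.scans[i].spectrum
        scale = spec.get(anchor_ion) / comp_anchor
        scales[k] = scale
        if scale <= 0:
            residual_preclip += spec.total()
            continue
        peaks = dict(spec.peaks)
        for m, v in component.peaks.items():
            take = scale * v
            have = peaks.get(m, 0.0)
            left = have - take
            subtracted += take
            residual_preclip += left
            if left <= 0:
                clipped += -min(left, 0.0)
                peaks.pop(m, None)
            else:
                peaks[m] = left
        residual_preclip += sum(v for m, v in peaks.items()
                                if m not in component.peaks)
        new_scans[i] = Scan(run.scans[i].time, Spectrum(peaks))
    profile = SubtractionProfile(
        component_id=component_id, anchor_ion=anchor_ion, scan_indices=idx,
        scales=scales, subtracted_area=subtracted,
        main_ion_area=float(scales.sum() * comp_anchor),
        original_sum=original_sum, residual_preclip_sum=residual_preclip,
        clipped=clipped)
    residual = ChromRun(scans=new_scans, scan_rate=run.scan_rate,
                        sample_id=run.sample_id, column_id=run.column_id,
                        mz_range=run.mz_range, metadata=dict(run.metadata))
    logger.debug("subtracted %s: scale %.3g..%.3g, removed %.4g counts, clipped %.3g",
                 component_id or "(component)", scales.min(initial=0),
                 scales.max(initial=0), subtracted, clipped)
    return residual, profile


def purify_component(run: ChromRun, region: PeakRegion, component: Spectrum,
                     anchor_ion: int, corr_min: float = 0.90) -> Spectrum:
    """Drop ions whose elution profile does not track the anchor ion's.

    An averaged invariant-scan spectrum from a coeluting region can carry
    ions of a neighbouring component.  A genuine fragment of the same
    compound rises and falls with the anchor (main) ion across the region;
    contaminating ions follow a different profile.  Ions whose Pearson
    correlation with the anchor profile falls below ``corr_min`` are removed
    (the anchor itself is always kept).
    """
    idx = list(region.indices)
    anchor_prof = np.array([run.scans[i].spectrum.get(anchor_ion) for i in idx])
    if anchor_prof.std() == 0:
        return component
    kept: dict[int, float] = {}
    for m, v in component.peaks.items():
        if m == anchor_ion:
            kept[m] = v
            continue
        prof = np.array([run.scans[i].spectrum.get(m) for i in idx])
        if prof.std() == 0:
            continue
        # only ions strong enough to judge are subject to removal: a weak
        # ion's profile is noise-dominated and its contamination negligible
        if prof.max() < 0.10 * anchor_prof.max():
            kept[m] = v
            continue
        r = float(np.corrcoef(anchor_prof, prof)[0, 1])
        if r >= corr_min:
            kept[m] = v
    if len(kept) < 3:
        return component  # too aggressive for this region; keep the average
    return Spectrum(kept)


def residual_is_background(run: ChromRun, region: PeakRegion,
                           noise: NoiseModel) -> bool:
    """True when the smoothed residual TIC stays at baseline + 3 MAD or below."""
    tic = run.tic()
    smooth = _smooth_tic(tic) if len(tic) >= 5 else tic
    window = smooth[region.start_scan:region.end_scan + 1]
    return bool(np.max(window, initial=0.0) <= noise.threshold)


# ---------------------------------------------------------------------------
# The deconvolution loop
# ---------------------------------------------------------------------------

@dataclass
class DeconvolvedComponent:
    """One component extracted from a peak region."""

    target: TargetCompound
    result: MatchResult
    is_unknown: bool = False


MAX_DECONVOLUTION_ITERATIONS = 20


def deconvolve_peak(run: ChromRun, region: PeakRegion, library: TargetLibrary,
                    criteria: MatchCriteria, noise: NoiseModel,
                    ref_library: TargetLibrary | None = None,
                    score_min: float = 0.80,
                    invariant_tol: float = 0.05,
                    profile_corr_min: float = 0.90,
                    unknown_ids=None,
                    max_iterations: int = MAX_DECONVOLUTION_ITERATIONS,
                    refine: bool = True,
                    ) -> tuple[list[DeconvolvedComponent], ChromRun]:
    """Iteratively extract every component of a coeluting peak region.

    Each pass first evaluates all library targets whose retention time falls
    inside the region and subtracts the passing ones, best Q-value first
    (ties: larger integrated main-ion area, then lexical id).  On the
    residual it then selects invariant scans, averages them, attempts an
    identity against ``ref_library`` (weighted cosine >= ``score_min``), or
    failing that emits an unknown with a fresh numeric id, and subtracts the
    averaged spectrum.  The loop stops when the residual approximates
    background, an iteration extracts nothing, or after ``max_iterations``.
    """
    if unknown_ids is None:
        unknown_ids = itertools.count(_next_unknown_id(library))
    times = run.times()
    t_lo, t_hi = times[region.start_scan], times[region.end_scan]
    half_span = max((t_hi - t_lo), 1e-6)

    residual = run
    components: list[DeconvolvedComponent] = []
    extracted: set[str] = set()

    for _ in range(max_iterations):
        if residual_is_background(residual, region, noise):
            break
        progressed = False

        # (a) known targets inside the region
        candidates = [t for t in library.in_window(t_lo, t_hi)
                      if t.id not in extracted]
        results = []
        for t in candidates:
            r = evaluate_target(residual, t, criteria, rt_window=half_span)
            if r.passed:
                results.append((t, r))
        results.sort(key=lambda tr: (-tr[1].q_value, -tr[1].abundance, tr[0].id))
        for t, r in results:
            # re-evaluate against the current residual: an earlier subtraction
            # may have removed this target's signal (shared ions)
            r2 = evaluate_target(residual, t, criteria, rt_window=half_span)
            if not r2.passed:
                continue
            residual, prof = subtract_component(
                residual, region, t.ref_spectrum, t.main_ion, component_id=t.id)
            r2.abundance = prof.main_ion_area
            components.append(DeconvolvedComponent(t, r2))
            extracted.add(t.id)
            progressed = True
        if progressed:
            continue

        # (b) invariant-scan extraction of an unassigned component
        window = select_invariant_scans(residual, region, tol=invariant_tol)
        if window is None:
            break
        avg = average_spectrum(residual, window)
        if not avg or len(avg) < 3:
            break
        # strip the noise floor: ions below 1% of the base peak are baseline
        # cells picked up by the average, not fragments of the component
        top = avg.max_intensity()
        avg = Spectrum({m: v for m, v in avg.peaks.items() if v >= 0.01 * top})
        if len(avg) < 3:
            break
        avg = purify_component(residual, region, avg, avg.base_peak(),
                               corr_min=profile_corr_min)
        apex_rt = float(times[window[int(np.argmax([residual.scans[i].tic for i in window]))]])
        ident: TargetCompound | None = None
        if ref_library is not None:
            scored = sorted(((weighted_cosine(avg, e.ref_spectrum), e)
                             for e in ref_library), key=lambda se: -se[0])
            if scored and scored[0][0] >= score_min:
                ref = scored[0][1]
                ident = TargetCompound.from_spectrum(
                    id=ref.id, name=ref.name, cas=ref.cas, rt=apex_rt,
                    ri=ref.ri, spectrum=avg,
                    annotations={"identified_from": "reference library",
                                 "match_score": scored[0][0]})
        if ident is None:
            ident = TargetCompound.from_spectrum(
                id=str(next(unknown_ids)), rt=apex_rt, spectrum=avg,
                annotations={"identified_from": "unknown"})
        if ident.id in extracted:
            break
        residual, prof = subtract_component(
            residual, region, ident.ref_spectrum, ident.main_ion,
            component_id=ident.id)
        result = MatchResult(target_id=ident.id, region=region,
                             scan_indices=window, passed=False,
                             abundance=prof.main_ion_area)
        components.append(DeconvolvedComponent(ident, result,
                                               is_unknown="unknown" in
                                               ident.annotations.get("identified_from", "")))
        extracted.add(ident.id)

    if refine and components:
        components, resid_matrix = refine_components(
            run, region, components, noise=noise, unknown_ids=unknown_ids)
        if resid_matrix is not None:
            # make the returned residual reflect the refined fit
            new_scans = list(residual.scans)
            for row, i in zip(resid_matrix, region.indices):
                new_scans[i] = Scan(run.scans[i].time,
                                    Spectrum.from_vector(row, run.mz_range))
            residual = ChromRun(scans=new_scans, scan_rate=run.scan_rate,
                                sample_id=run.sample_id, column_id=run.column_id,
                                mz_range=run.mz_range, metadata=dict(run.metadata))
    return components, residual


def _nnls_profiles(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-scan non-negative decomposition of X (scans x mz) onto rows of S."""
    from scipy.optimize import nnls

    A = S.T
    C = np.zeros((X.shape[0], S.shape[0]))
    for t, x in enumerate(X):
        C[t], _ = nnls(A, x)
    return C


def _cluster_profiles(X: np.ndarray,
                      min_rel_channel: float = 0.01,
                      apex_gap_scans: int = 3,
                      min_cluster_channels: int = 2,
                      min_cluster_energy: float = 0.01) -> list[np.ndarray]:
    """Model elution profiles of a (scans x mz) matrix from apex clusters.

    Every significant m/z channel reaches its maximum at the apex of the
    compound that dominates it.  Apex positions are clustered at the modes
    of their energy-weighted kernel density (bandwidth half of
    ``apex_gap_scans``), which keeps apex groups a few scans apart separate
    without gap-rule chaining; each cluster's model profile is the
    pointwise median of its members' max-normalised profiles, which
    suppresses the second hump a channel shared between two compounds would
    otherwise contribute.  Returns unit-sum profiles ordered by apex scan.
    """
    n_region = X.shape[0]
    chan_max = X.max(axis=0)
    if chan_max.max() <= 0 or n_region < 3:
        return []
    floor = min_rel_channel * chan_max.max()
    channels = np.where(chan_max >= floor)[0]
    smoothed = {}
    apexes = []
    for m in channels:
        prof = X[:, m]
        if len(prof) >= 5:
            prof = np.clip(_smooth_tic(prof), 0.0, None)
        if prof.max() <= 0:
            continue
        smoothed[m] = prof
        apexes.append((int(np.argmax(prof)), int(m), float(prof.sum())))
    if not apexes:
        return []
    positions = np.array([a for a, _, _ in apexes], dtype=float)
    weights = np.sqrt([e for _, _, e in apexes])
    grid = np.arange(n_region)
    # a narrow kernel keeps a weak component's mode from being swallowed by
    # the tail of a dominant neighbour a few scans away
    bandwidth = 1.0
    density = np.zeros(n_region)
    for pos, w in zip(positions, weights):
        density += w * np.exp(-0.5 * ((grid - pos) / bandwidth) ** 2)
    centers, _ = find_peaks(density)
    if n_region >= 2 and density[0] > density[1]:
        centers = np.concatenate([[0], centers])
    if n_region >= 2 and density[-1] > density[-2]:
        centers = np.concatenate([centers, [n_region - 1]])
    if len(centers) == 0:
        centers = np.array([int(np.argmax(density))])
    # apex jitter of a single compound can raise two modes a scan apart;
    # fuse centers closer than apex_gap_scans, keeping the denser one
    fused: list[int] = []
    for c in sorted(int(c) for c in centers):
        if fused and c - fused[-1] < apex_gap_scans:
            if density[c] > density[fused[-1]]:
                fused[-1] = c
        else:
            fused.append(c)
    centers = np.array(fused)
    groups_map: dict[int, list[tuple[int, int, float]]] = {int(c): [] for c in centers}
    for item in apexes:
        nearest = int(centers[np.argmin(np.abs(centers - item[0]))])
        groups_map[nearest].append(item)
    groups = [groups_map[c] for c in sorted(groups_map)]
    total_energy = sum(e for _, _, e in apexes)
    profiles = []
    for g in groups:
        if len(g) < min_cluster_channels:
            continue
        if sum(e for _, _, e in g) < min_cluster_energy * total_energy:
            continue
        member_profiles = [smoothed[m] / smoothed[m].max() for _, m, _ in g]
        model = np.median(np.array(member_profiles), axis=0)
        if model.sum() <= 0:
            continue
        profiles.append(model / model.sum())
    return profiles


def estimate_component_profiles(run: ChromRun, region: PeakRegion,
                                max_passes: int = 3,
                                residual_tol: float = 0.01,
                                **cluster_kwargs) -> list[np.ndarray]:
    """Model elution profiles of a coeluting peak region.

    Profiles are first taken from the apex clusters of the region matrix
    (:func:`_cluster_profiles`).  A compound hidden under a dominant
    neighbour can escape the initial clustering, so the matrix is then fit
    channel-by-channel against the profiles found so far (non-negative
    least squares, plus a flat background) and, while the unexplained
    residual exceeds ``residual_tol`` of the total signal energy, the
    residual is clustered again and any genuinely new profiles are added.
    """
    idx = list(region.indices)
    X = np.array([run.scans[i].spectrum.to_vector(run.mz_range) for i in idx])
    profiles = _cluster_profiles(X, **cluster_kwargs)
    if not profiles:
        return profiles
    total_energy = float((X ** 2).sum())
    if total_energy <= 0:
        return profiles
    from scipy.optimize import nnls

    n_scans = X.shape[0]
    background = np.full(n_scans, 1.0 / n_scans)
    for _ in range(max_passes):
        Pb = np.vstack([np.array(profiles), background]).T
        S = np.zeros((Pb.shape[1], X.shape[1]))
        active = np.where(X.max(axis=0) > 0)[0]
        for m in active:
            S[:, m], _ = nnls(Pb, X[:, m])
        R = np.clip(X - Pb @ S, 0.0, None)
        if float((R ** 2).sum()) <= residual_tol * total_energy:
            break
        extra = _cluster_profiles(R, **cluster_kwargs)
        fresh = [p for p in extra
                 if all(float(np.corrcoef(p, q)[0, 1]) < 0.98 for q in profiles)]
        if not fresh:
            break
        profiles.extend(fresh)
    # keep profiles ordered by apex position
    profiles.sort(key=lambda p: int(np.argmax(p)))
    return profiles


def refine_components(run: ChromRun, region: PeakRegion,
                      components: list[DeconvolvedComponent],
                      noise: NoiseModel | None = None,
                      unknown_ids=None,
                      min_rel_intensity: float = 0.005,
                      identity_cosine: float = 0.70,
                      n_als: int = 2,
                      ) -> tuple[list[DeconvolvedComponent], np.ndarray | None]:
    """Re-derive clean spectra and abundances from model elution profiles.

    Sequential subtraction discovers the components but can misallocate
    shared ions and leave residues.  This step rebuilds the region from
    scratch: model profiles come from apex-clustered channels
    (:func:`estimate_component_profiles`); each m/z channel of the original
    region matrix is decomposed over those profiles (plus a flat background)
    by non-negative least squares, which apportions shared ions between
    coeluters; a few alternating passes (profiles from spectra, spectra from
    profiles) sharpen the median-based initial profiles.  Components whose
    reconstructed chromatographic peak stays within the noise band are
    baseline artifacts and are dropped, with the signal refit over the
    survivors.  Identities found by the subtraction loop are carried over to
    the profile whose spectrum matches best (cosine >=
    ``identity_cosine``); profiles matching nothing become fresh unknowns.
    """
    if unknown_ids is None:
        unknown_ids = itertools.count(10 ** 6)
    profiles = estimate_component_profiles(run, region)
    if not profiles:
        return components, None

    from scipy.optimize import nnls

    idx = list(region.indices)
    times = run.times()
    X = np.array([run.scans[i].spectrum.to_vector(run.mz_range) for i in idx])
    n_scans = X.shape[0]
    background = np.full(n_scans, 1.0 / n_scans)
    active = np.where(X.max(axis=0) > 0)[0]

    def fit_spectra(P):
        """Per-channel decomposition X[:, m] ~ [P; bg]^T s_m."""
        Pb = np.vstack([P, background]).T
        S = np.zeros((P.shape[0] + 1, X.shape[1]))
        for m in active:
            S[:, m], _ = nnls(Pb, X[:, m])
        return S

    P = np.array(profiles)                        # (K, n_scans), unit-sum rows
    S = fit_spectra(P)
    for _ in range(n_als):
        # profile step: per-scan decomposition onto the fitted spectra
        rows = S.copy()
        norms = np.linalg.norm(rows, axis=1)
        rows[norms > 0] = rows[norms > 0] / norms[norms > 0][:, None]
        C = _nnls_profiles(X, rows)               # (n_scans, K+1)
        newP = []
        for k in range(P.shape[0]):
            col = C[:, k]
            newP.append(col / col.sum() if col.sum() > 0 else P[k])
        P = np.array(newP)
        S = fit_spectra(P)

    # drop baseline artifacts: reconstructed TIC peak below the noise band
    if noise is not None:
        heights = np.array([float(S[k].sum() * P[k].max())
                            for k in range(P.shape[0])])
        keep = heights >= 3.0 * noise.baseline_mad
        if keep.any() and not keep.all():
            P = P[keep]
            S = fit_spectra(P)

    C_fit = P.T                                   # (n_scans, K); S rows in counts
    refined: list[DeconvolvedComponent] = []
    used_ids: set[str] = set()
    for k in range(P.shape[0]):
        vec = S[k]
        if vec.max() <= 0:
            continue
        vec = np.where(vec >= min_rel_intensity * vec.max(), vec, 0.0)
        spec = Spectrum.from_vector(vec, run.mz_range)
        if len(spec) < 3:
            continue
        apex_scan = idx[int(np.argmax(P[k]))]
        rt = float(times[apex_scan])
        # carry over the loop's identity when a component matches this profile
        donor = None
        best_cos = identity_cosine
        for comp in components:
            if comp.target.id in used_ids:
                continue
            c = cosine(spec, comp.target.ref_spectrum)
            if c >= best_cos:
                donor, best_cos = comp, c
        # counts assigned to this profile at its main-ion channel
        main_frac = spec.get(spec.base_peak()) / spec.total()
        abundance = float(S[k].sum() * main_frac)
        if donor is not None:
            target = TargetCompound.from_spectrum(
                id=donor.target.id, name=donor.target.name,
                cas=donor.target.cas, rt=rt, ri=donor.target.ri,
                spectrum=spec, annotations=dict(donor.target.annotations))
            target.source_heartcut = donor.target.source_heartcut
            result = donor.result
            result.abundance = abundance
            refined.append(DeconvolvedComponent(target, result,
                                                is_unknown=donor.is_unknown))
            used_ids.add(target.id)
        else:
            target = TargetCompound.from_spectrum(
                id=str(next(unknown_ids)), rt=rt, spectrum=spec,
                annotations={"identified_from": "unknown"})
            result = MatchResult(target_id=target.id, region=region,
                                 passed=False, abundance=abundance)
            refined.append(DeconvolvedComponent(target, result, is_unknown=True))
    if not refined:
        return components, None
    # residual of the fit: region signal minus the components' contribution
    # (the flat background column stays in the residual)
    residual_matrix = np.clip(X - C_fit[:, :P.shape[0]] @ S[:P.shape[0]], 0.0, None)
    return refined, residual_matrix


def _next_unknown_id(library: TargetLibrary) -> int:
    numeric = [int(e.id) for e in library if e.id.isdigit()]
    return max(numeric, default=0) + 1


def deconvolve_run(run: ChromRun, library: TargetLibrary | None = None,
                   criteria: MatchCriteria | None = None,
                   noise: NoiseModel | None = None,
                   **kwargs) -> list[DeconvolvedComponent]:
    """Detect every peak region of a run and deconvolve each in turn."""
    noise = noise or NoiseModel.estimate(run)
    criteria = (criteria or MatchCriteria()).with_noise(noise)
    library = library if library is not None else TargetLibrary()
    unknown_ids = kwargs.pop("unknown_ids", None) or itertools.count(
        _next_unknown_id(library))
    components: list[DeconvolvedComponent] = []
    for region in detect_peaks(run, noise):
        comps, _ = deconvolve_peak(run, region, library, criteria, noise,
                                   unknown_ids=unknown_ids, **kwargs)
        components.extend(comps)
    return components
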