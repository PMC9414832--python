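"""Seeded synthetic chromatogram generator and the packaged abundance fixture.

The simulator emulates the acquisition this package is built for: a scanning
quadrupole at 12 scans/s over m/z 50-350, Gaussian chromatographic peaks with
known unit-mass spectra, an additive baseline with Gaussian noise clipped at
zero, an optional deuterated-naphthalene internal standard (main ion m/z 136),
and contiguous 1-min heartcut windows with adjacent-cut carryover.  Every
generator is a pure function of its seed and configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .chromdata import (AbundanceTable, ChromRun, DataValidationError,
                        DEFAULT_MZ_RANGE, Scan, Spectrum, TargetCompound)
from .librarian import HeartcutRun


@dataclass(frozen=True)
class PlantedCompound:
    """Ground truth for one simulated analyte."""

    truth_id: str
    spectrum: Spectrum            # unit-mass, typically 5-25 ions
    rt: float                     # apex, minutes
    sigma: float                  # Gaussian peak width, minutes
    total_abundance: float        # integrated TIC counts

    def __post_init__(self):
        if self.sigma <= 0:
            raise DataValidationError("sigma must be > 0")
        if self.total_abundance <= 0:
            raise DataValidationError("total_abundance must be > 0")
        if len(self.spectrum) < 2:
            raise DataValidationError("planted spectrum needs >= 2 ions")

    @property
    def main_ion(self) -> int:
        return self.spectrum.base_peak()

    def main_ion_area(self) -> float:
        """True integrated main-ion response (counts x scans)."""
        return self.total_abundance * (self.spectrum.get(self.main_ion)
                                       / self.spectrum.total())


@dataclass(frozen=True)
class SimConfig:
    """Instrument and noise settings for a simulated acquisition."""

    duration: float               # minutes
    seed: int
    scan_rate: float = 12.0       # scans/s
    mz_range: tuple[int, int] = DEFAULT_MZ_RANGE
    baseline: float = 0.0         # constant counts per (scan, m/z) cell
    noise_sd: float = 0.0         # Gaussian sd per cell, clipped at 0
    include_internal_standard: bool = False
    internal_standard_rt: float | None = None
    internal_standard_abundance: float = 1e5
    peak_shape: str = "gaussian"  # or "emg" (exponentially modified)
    emg_tau: float = 0.01         # exponential tail constant, minutes

    def __post_init__(self):
        if self.duration <= 0 or self.scan_rate <= 0:
            raise DataValidationError("duration and scan_rate must be positive")
        if self.baseline < 0 or self.noise_sd < 0:
            raise DataValidationError("baseline and noise_sd must be >= 0")
        if self.peak_shape not in ("gaussian", "emg"):
            raise DataValidationError(f"unknown peak shape {self.peak_shape!r}")

    @property
    def n_scans(self) -> int:
        return int(round(self.duration * 60.0 * self.scan_rate))

    def scan_times(self) -> np.ndarray:
        dt = 1.0 / (60.0 * self.scan_rate)
        return dt * (np.arange(self.n_scans) + 0.5)


#: d8-naphthalene-like internal standard: molecular ion 136 dominates,
#: with the d8 fragment/isotope pattern around it
INTERNAL_STANDARD_SPECTRUM = Spectrum({136: 999.0, 137: 110.0, 108: 160.0,
                                       68: 95.0, 84: 60.0})
INTERNAL_STANDARD_ID = "d8-naphthalene (IS)"


def internal_standard_compound(rt: float, total_abundance: float = 1e5,
                               sigma: float = 0.01) -> PlantedCompound:
    return PlantedCompound(truth_id=INTERNAL_STANDARD_ID,
                           spectrum=INTERNAL_STANDARD_SPECTRUM,
                           rt=rt, sigma=sigma, total_abundance=total_abundance)


def internal_standard_target(rt: float) -> TargetCompound:
    return TargetCompound.from_spectrum(id=INTERNAL_STANDARD_ID, rt=rt,
                                        spectrum=INTERNAL_STANDARD_SPECTRUM,
                                        n_qualifiers=3)


def random_spectrum(seed: int, n_ions: int,
                    mz_range: tuple[int, int] = DEFAULT_MZ_RANGE) -> Spectrum:
    """Seeded random unit-mass spectrum with a long-tailed intensity draw.

    ``n_ions`` distinct m/z values drawn uniformly over the range; intensities
    are lognormal (a handful of dominant fragments over many minor ones), and
    the base peak is normalised to 999.
    """
    if n_ions < 2:
        raise DataValidationError("a spectrum needs at least 2 ions")
    lo, hi = mz_range
    if n_ions > hi - lo + 1:
        raise DataValidationError("more ions than m/z channels")
    rng = np.random.default_rng(seed)
    mzs = rng.choice(np.arange(lo, hi + 1), size=n_ions, replace=False)
    intensities = rng.lognormal(mean=0.0, sigma=1.2, size=n_ions)
    return Spectrum({int(m): float(v) for m, v in zip(mzs, intensities)}).normalized()


@dataclass
class SimTruth:
    """Per-compound ground truth of a simulated run."""

    compounds: list[PlantedCompound]
    profiles: dict[str, np.ndarray]       # truth_id -> per-scan TIC contribution
    noiseless_matrix: np.ndarray          # (n_scans, n_mz) without noise
    times: np.ndarray

    def contribution(self, truth_id: str) -> np.ndarray:
        return self.profiles[truth_id]


def _peak_weights(times: np.ndarray, rt: float, sigma: float,
                  shape: str, tau: float) -> np.ndarray:
    if shape == "gaussian":
        w = np.exp(-0.5 * ((times - rt) / sigma) ** 2)
    else:  # exponentially modified Gaussian, tail constant tau
        from scipy.stats import exponnorm
        w = exponnorm.pdf(times, K=tau / sigma, loc=rt, scale=sigma)
    s = w.sum()
    return w / s if s > 0 else w


def simulate_run(compounds: list[PlantedCompound],
                 cfg: SimConfig) -> tuple[ChromRun, SimTruth]:
    """Render planted compounds into a chromatographic run with known truth.

    Each compound contributes ``total_abundance`` counts distributed over
    scans by its (discretised, normalised) peak shape and over m/z by its
    unit-sum spectrum.  Baseline and seeded Gaussian noise are added per
    cell and clipped at zero.  The same seed gives a bit-identical run.
    """
    times = cfg.scan_times()
    lo, hi = cfg.mz_range
    n_mz = hi - lo + 1
    planted = list(compounds)
    if cfg.include_internal_standard:
        is_rt = (cfg.internal_standard_rt if cfg.internal_standard_rt is not None
                 else cfg.duration / 2.0)
        planted.append(internal_standard_compound(
            is_rt, cfg.internal_standard_abundance))

    noiseless = np.zeros((cfg.n_scans, n_mz))
    profiles: dict[str, np.ndarray] = {}
    for comp in planted:
        if not (0 <= comp.rt <= cfg.duration):
            raise DataValidationError(
                f"compound {comp.truth_id!r} rt {comp.rt} outside run duration")
        for m in comp.spectrum.peaks:
            if not (lo <= m <= hi):
                raise DataValidationError(
                    f"compound {comp.truth_id!r} ion {m} outside m/z range")
        w = _peak_weights(times, comp.rt, comp.sigma, cfg.peak_shape, cfg.emg_tau)
        tic_profile = comp.total_abundance * w
        spec_frac = comp.spectrum.to_vector(cfg.mz_range)
        spec_frac = spec_frac / spec_frac.sum()
        noiseless += np.outer(tic_profile, spec_frac)
        profiles[comp.truth_id] = tic_profile

    matrix = noiseless + cfg.baseline
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        matrix = matrix + rng.normal(0.0, cfg.noise_sd, size=matrix.shape)
    matrix = np.clip(matrix, 0.0, None)

    run = ChromRun.from_matrix(times, matrix, scan_rate=cfg.scan_rate,
                               mz_range=cfg.mz_range,
                               metadata={"seed": cfg.seed})
    truth = SimTruth(compounds=planted, profiles=profiles,
                     noiseless_matrix=noiseless, times=times)
    return run, truth


@dataclass
class CampaignTruth:
    """Ground truth of a heartcut campaign: cut assignments and carryover."""

    assignments: dict[str, list[int]]     # truth_id -> cut indices (0-based)
    abundances: dict[tuple[str, int], float]
    run_truths: list[SimTruth]


def simulate_heartcut_campaign(compounds: list[PlantedCompound],
                               n_cuts: int, cfg: SimConfig,
                               carryover_fraction: float = 0.3,
                               carryover_probability: float = 0.1,
                               force_carryover: set[str] | None = None,
                               ) -> tuple[list[HeartcutRun], CampaignTruth]:
    """Emulate sequential 1-min heartcuts with adjacent-cut transference.

    Each compound's first-column retention assigns it to cut
    ``floor(rt)``; a seeded fraction of compounds (default probability 0.1)
    also appears in the next cut at ``carryover_fraction`` of its abundance,
    emulating transference between injections.  Windows are contiguous
    half-open [k, k+1) minute intervals.  Within each cut the compound's
    second-column retention is its fractional first-column time mapped onto
    the cut's run duration.
    """
    if n_cuts < 1:
        raise DataValidationError("need at least one heartcut")
    rng = np.random.default_rng(cfg.seed)
    force_carryover = force_carryover or set()

    assignments: dict[str, list[int]] = {}
    abundances: dict[tuple[str, int], float] = {}
    per_cut: dict[int, list[PlantedCompound]] = {k: [] for k in range(n_cuts)}
    for comp in compounds:
        cut = int(math.floor(comp.rt))
        if not (0 <= cut < n_cuts):
            raise DataValidationError(
                f"compound {comp.truth_id!r} rt {comp.rt} outside the "
                f"{n_cuts}-cut campaign")
        frac = comp.rt - cut
        rt2 = 0.1 * cfg.duration + 0.8 * cfg.duration * frac
        local = PlantedCompound(comp.truth_id, comp.spectrum, rt2,
                                comp.sigma, comp.total_abundance)
        per_cut[cut].append(local)
        assignments[comp.truth_id] = [cut]
        abundances[(comp.truth_id, cut)] = comp.total_abundance
        carried = (comp.truth_id in force_carryover
                   or rng.random() < carryover_probability)
        if carried and carryover_fraction > 0 and cut + 1 < n_cuts:
            ghost = PlantedCompound(comp.truth_id, comp.spectrum, rt2,
                                    comp.sigma,
                                    comp.total_abundance * carryover_fraction)
            per_cut[cut + 1].append(ghost)
            assignments[comp.truth_id].append(cut + 1)
            abundances[(comp.truth_id, cut + 1)] = ghost.total_abundance

    heartcuts: list[HeartcutRun] = []
    run_truths: list[SimTruth] = []
    for k in range(n_cuts):
        sub_cfg = SimConfig(duration=cfg.duration, seed=int(cfg.seed + 1 + k),
                            scan_rate=cfg.scan_rate, mz_range=cfg.mz_range,
                            baseline=cfg.baseline, noise_sd=cfg.noise_sd,
                            peak_shape=cfg.peak_shape, emg_tau=cfg.emg_tau)
        run, truth = simulate_run(per_cut[k], sub_cfg)
        run.sample_id = f"heartcut_{k:02d}"
        heartcuts.append(HeartcutRun(window=(float(k), float(k + 1)), run=run))
        run_truths.append(truth)
    return heartcuts, CampaignTruth(assignments=assignments,
                                    abundances=abundances,
                                    run_truths=run_truths)


FIXTURE_FILENAME = "tables_1_2_3.csv"
FIXTURE_SAMPLES = ("Green AAA", "Green AA", "Roast AAA", "Roast AA")


def tables_fixture() -> AbundanceTable:
    """The packaged green/roasted coffee abundance fixture.

    227 compounds x 4 samples of relative abundances (analyte:internal
    standard response, arbitrary units) with retention times and literature
    odor notes as annotations: 24 compounds unique to the high-quality green
    coffee plus 1 unique to the low-quality green, 74 and 56 unique to the
    two roasted coffees, and 72 compounds present in all four samples.
    """
    ref = resources.files("iondecon").joinpath("data").joinpath(FIXTURE_FILENAME)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col=0)
    values = df[list(FIXTURE_SAMPLES)]
    ann = df[[c for c in df.columns if c not in FIXTURE_SAMPLES]]
    return AbundanceTable(values, annotations=ann)


FIXTURE_ROLES = {"green_high": "Green AAA", "green_low": "Green AA",
                 "roast_high": "Roast AAA", "roast_low": "Roast AA"}


# ---------------------------------------------------------------------------
# Canonical simulation scenarios for validating the deconvolution engine
# ---------------------------------------------------------------------------

def random_coelution_trial(seed: int,
                           n_range: tuple[int, int] = (2, 4),
                           sep_sigma_range: tuple[float, float] = (0.5, 2.0),
                           snr_range: tuple[float, float] = (30.0, 300.0),
                           sigma: float = 0.01,
                           noise_sd: float = 3.0,
                           duration: float = 0.5,
                           ) -> tuple[list[PlantedCompound], SimConfig]:
    """A seeded cluster of 2-4 coeluting compounds under realistic conditions.

    Adjacent apexes are separated by 0.5-2 peak widths (sigma), signal-to-
    noise ratios (apex TIC height over the TIC noise sd) span 30-300, and
    spectra are random unit-mass patterns of 5-25 ions.  Returns the planted
    compounds and the matching simulation config; pass both to
    :func:`simulate_run`.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    seps = rng.uniform(*sep_sigma_range, size=n - 1) * sigma
    rts = 0.44 * duration + np.concatenate([[0.0], np.cumsum(seps)])
    snrs = rng.uniform(*snr_range, size=n)
    n_mz = DEFAULT_MZ_RANGE[1] - DEFAULT_MZ_RANGE[0] + 1
    tic_noise_sd = noise_sd * math.sqrt(n_mz)
    dt = 1.0 / (60.0 * 12.0)
    compounds = []
    for k in range(n):
        spec = random_spectrum(int(seed * 100 + k), int(rng.integers(5, 26)))
        height = snrs[k] * tic_noise_sd
        total = height * math.sqrt(2.0 * math.pi) * sigma / dt
        compounds.append(PlantedCompound(f"T{k}", spec, float(rts[k]),
                                         sigma, float(total)))
    cfg = SimConfig(duration=duration, seed=int(seed), noise_sd=noise_sd)
    return compounds, cfg


def seven_component_cluster(seed: int, span: float = 0.15,
                            sigma: float = 0.01, noise_sd: float = 3.0,
                            snr_range: tuple[float, float] = (50.0, 300.0),
                            ) -> tuple[list[PlantedCompound], SimConfig]:
    """Seven compounds whose apexes all fall within a ``span``-minute window.

    Emulates the hardest coelution scenario the engine must untangle: seven
    distinct spectra overlapping within 0.15 min at 12 scans/s.
    """
    rng = np.random.default_rng(seed)
    rts = 0.30 + np.linspace(0.0, span, 7)
    n_mz = DEFAULT_MZ_RANGE[1] - DEFAULT_MZ_RANGE[0] + 1
    tic_noise_sd = noise_sd * math.sqrt(n_mz)
    dt = 1.0 / (60.0 * 12.0)
    compounds = []
    for k in range(7):
        spec = random_spectrum(int(seed * 1000 + k), int(rng.integers(8, 26)))
        snr = rng.uniform(*snr_range)
        total = snr * tic_noise_sd * math.sqrt(2.0 * math.pi) * sigma / dt
        compounds.append(PlantedCompound(f"C{k}", spec, float(rts[k]),
                                         sigma, float(total)))
    cfg = SimConfig(duration=0.75, seed=int(seed), noise_sd=noise_sd)
    return compounds, cfg


def score_recovery(components, compounds: list[PlantedCompound],
                   cosine_min: float = 0.95,
                   abundance_rel_tol: float = 0.10) -> dict:
    """Match extracted components to planted truth, greedily by cosine.

    Returns per-compound best cosine and main-ion-area relative error, plus
    the overall pass verdict (every compound recovered within both bounds).
    """
    from .similarity import cosine as _cos

    per = {}
    ok = True
    for c in compounds:
        best = max(components,
                   key=lambda x: _cos(x.target.ref_spectrum, c.spectrum),
                   default=None)
        if best is None:
            per[c.truth_id] = {"cosine": 0.0, "abundance_rel_err": math.inf}
            ok = False
            continue
        cs = _cos(best.target.ref_spectrum, c.spectrum)
        err = abs(best.result.abundance - c.main_ion_area()) / c.main_ion_area()
        per[c.truth_id] = {"cosine": cs, "abundance_rel_err": err}
        if cs < cosine_min or err > abundance_rel_tol:
            ok = False
    return {"per_compound": per, "recovered": ok}
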