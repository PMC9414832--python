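"""Data model and I/O for chromatograms, spectra, target libraries, and abundance tables.

All spectra are unit-mass (nominal integer m/z) because the data premise is a
scanning quadrupole acquiring m/z 50-350 at 12 scans/s: profile or centroided
input is binned to the nearest integer.  Times are minutes throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default nominal scan range of the instrument (inclusive)
DEFAULT_MZ_RANGE = (50, 350)

#: base-peak intensity used by the MSP normalisation convention
MSP_BASE = 999.0


class IonDeconError(Exception):
    """Base class for all package errors."""


class DataValidationError(IonDeconError):
    """An object or file violates a structural invariant."""


class UndefinedReductionError(IonDeconError):
    """Main-ion intensity is zero: reduced ion intensities are undefined."""


class CalibrationRangeError(IonDeconError):
    """Retention time falls outside the n-alkane calibration span."""


class InternalStandardNotFoundError(IonDeconError):
    """The internal standard failed the identification criterion in a run."""


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

class Spectrum:
    """A unit-mass mass spectrum: mapping of integer m/z to intensity counts.

    Intensities are non-negative floats in arbitrary counts.  The object is
    treated as immutable by all package code; mutating ``peaks`` directly is
    not supported.
    """

    __slots__ = ("peaks",)

    def __init__(self, peaks: Mapping[int, float]):
        clean: dict[int, float] = {}
        for mz, inten in peaks.items():
            m = int(mz)
            if m != mz:
                raise DataValidationError(f"non-integer m/z {mz!r}")
            v = float(inten)
            if v < 0:
                raise DataValidationError(f"negative intensity {v} at m/z {m}")
            if m <= 0:
                raise DataValidationError(f"non-positive m/z {m}")
            if v > 0:
                clean[m] = v
        self.peaks = dict(sorted(clean.items()))

    def __repr__(self) -> str:
        return f"Spectrum({len(self.peaks)} ions, base={self.base_peak() if self.peaks else None})"

    def __len__(self) -> int:
        return len(self.peaks)

    def __bool__(self) -> bool:
        return bool(self.peaks)

    def __eq__(self, other) -> bool:
        return isinstance(other, Spectrum) and self.peaks == other.peaks

    def __hash__(self):
        return hash(tuple(self.peaks.items()))

    def get(self, mz: int, default: float = 0.0) -> float:
        return self.peaks.get(int(mz), default)

    def base_peak(self) -> int:
        """m/z of the most intense ion."""
        if not self.peaks:
            raise DataValidationError("empty spectrum has no base peak")
        # ties broken toward lower m/z for determinism
        return min(self.peaks, key=lambda m: (-self.peaks[m], m))

    def max_intensity(self) -> float:
        return self.peaks[self.base_peak()] if self.peaks else 0.0

    def total(self) -> float:
        return float(sum(self.peaks.values()))

    def normalized(self, scale: float = MSP_BASE) -> "Spectrum":
        """Pure view with the base peak scaled to ``scale`` (MSP convention).

        Idempotent: normalising a normalised spectrum returns an equal one.
        """
        if not self.peaks:
            return Spectrum({})
        top = self.max_intensity()
        return Spectrum({m: v * scale / top for m, v in self.peaks.items()})

    def scaled(self, factor: float) -> "Spectrum":
        if factor < 0:
            raise DataValidationError("scale factor must be non-negative")
        return Spectrum({m: v * factor for m, v in self.peaks.items()})

    def to_vector(self, mz_range: tuple[int, int] = DEFAULT_MZ_RANGE) -> np.ndarray:
        """Dense intensity vector over the inclusive integer range."""
        lo, hi = mz_range
        vec = np.zeros(hi - lo + 1)
        for m, v in self.peaks.items():
            if lo <= m <= hi:
                vec[m - lo] = v
        return vec

    @classmethod
    def from_vector(cls, vec: np.ndarray,
                    mz_range: tuple[int, int] = DEFAULT_MZ_RANGE) -> "Spectrum":
        lo = mz_range[0]
        return cls({lo + i: float(v) for i, v in enumerate(vec) if v > 0})

    @classmethod
    def from_arrays(cls, mz: Sequence[float], intensities: Sequence[float]) -> "Spectrum":
        """Bin centroided (possibly non-integer) peaks to the nearest integer m/z."""
        acc: dict[int, float] = {}
        for m, v in zip(mz, intensities):
            key = int(round(float(m)))
            acc[key] = acc.get(key, 0.0) + float(v)
        return cls(acc)


# ---------------------------------------------------------------------------
# Scans and runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scan:
    """One acquisition: a spectrum with its retention time in minutes."""

    time: float
    spectrum: Spectrum

    def __post_init__(self):
        if self.time < 0:
            raise DataValidationError(f"negative scan time {self.time}")

    @property
    def tic(self) -> float:
        return self.spectrum.total()


@dataclass
class ChromRun:
    """A time-ordered GC/MS acquisition.

    ``tic()`` is always recomputed from the scans; it is never cached so it
    cannot go stale after subtraction edits a copy of the run.
    """

    scans: list[Scan]
    scan_rate: float = 12.0          # scans per second
    sample_id: str = ""
    column_id: str = ""
    mz_range: tuple[int, int] = DEFAULT_MZ_RANGE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [s.time for s in self.scans]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DataValidationError("scan times must be strictly increasing")
        lo, hi = self.mz_range
        for s in self.scans:
            for m in s.spectrum.peaks:
                if not (lo <= m <= hi):
                    raise DataValidationError(
                        f"m/z {m} outside scan range {self.mz_range} at t={s.time}")

    def __len__(self) -> int:
        return len(self.scans)

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])

    def tic(self) -> np.ndarray:
        """Total ion current per scan, recomputed on every call."""
        return np.array([s.tic for s in self.scans])

    def to_matrix(self) -> np.ndarray:
        """(n_scans, n_mz) dense intensity matrix over ``mz_range``."""
        lo, hi = self.mz_range
        mat = np.zeros((len(self.scans), hi - lo + 1))
        for i, s in enumerate(self.scans):
            for m, v in s.spectrum.peaks.items():
                mat[i, m - lo] = v
        return mat

    @classmethod
    def from_matrix(cls, times: np.ndarray, matrix: np.ndarray, **kwargs) -> "ChromRun":
        mz_range = kwargs.get("mz_range", DEFAULT_MZ_RANGE)
        scans = [Scan(float(t), Spectrum.from_vector(row, mz_range))
                 for t, row in zip(times, matrix)]
        return cls(scans=scans, **kwargs)

    def index_at(self, time: float) -> int:
        """Index of the scan closest in time."""
        if not self.scans:
            raise DataValidationError("empty run")
        return int(np.argmin(np.abs(self.times() - time)))

    def approx_equal(self, other: "ChromRun", rtol: float = 1e-6) -> bool:
        if len(self) != len(other) or self.mz_range != other.mz_range:
            return False
        if not np.allclose(self.times(), other.times(), rtol=rtol, atol=1e-9):
            return False
        return bool(np.allclose(self.to_matrix(), other.to_matrix(),
                                rtol=rtol, atol=1e-9))


# ---------------------------------------------------------------------------
# Targets and libraries
# ---------------------------------------------------------------------------

MIN_QUALIFIERS = 2
MAX_QUALIFIERS = 5


@dataclass
class TargetCompound:
    """A library target: reference spectrum plus main ion and qualifier ions.

    The main ion is the 100% (base) ion of the reference spectrum.  Each
    qualifier carries its expected relative abundance Ri in (0, 1], which is
    the reference intensity at that m/z divided by the intensity at the main
    ion.  A target needs 2-5 qualifiers, i.e. 3-6 ions in total including the
    main ion.
    """

    id: str
    rt: float
    ref_spectrum: Spectrum
    main_ion: int
    qualifiers: list[tuple[int, float]]
    name: str | None = None
    cas: str | None = None
    ri: float | None = None
    source_heartcut: tuple[float, float] | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (MIN_QUALIFIERS <= len(self.qualifiers) <= MAX_QUALIFIERS):
            raise DataValidationError(
                f"target {self.id!r}: {len(self.qualifiers)} qualifiers, "
                f"need {MIN_QUALIFIERS}-{MAX_QUALIFIERS}")
        if self.main_ion != self.ref_spectrum.base_peak():
            raise DataValidationError(
                f"target {self.id!r}: main ion {self.main_ion} is not the base "
                f"peak {self.ref_spectrum.base_peak()} of the reference spectrum")
        a_main = self.ref_spectrum.get(self.main_ion)
        for mz, ri in self.qualifiers:
            if not (0 < ri <= 1):
                raise DataValidationError(
                    f"target {self.id!r}: qualifier {mz} Ri={ri} outside (0, 1]")
            expected = self.ref_spectrum.get(mz) / a_main
            if abs(expected - ri) > 1e-6 * max(1.0, ri):
                raise DataValidationError(
                    f"target {self.id!r}: qualifier {mz} Ri={ri} inconsistent "
                    f"with reference spectrum ratio {expected:.6g}")

    @property
    def display_name(self) -> str:
        return self.name or self.id

    @classmethod
    def from_spectrum(cls, id: str, rt: float, spectrum: Spectrum,
                      n_qualifiers: int = 3, **kwargs) -> "TargetCompound":
        """Build a target taking the top-N ions after the base peak as qualifiers."""
        if len(spectrum) < MIN_QUALIFIERS + 1:
            raise DataValidationError(
                f"target {id!r}: spectrum has {len(spectrum)} ions, need >= 3")
        main = spectrum.base_peak()
        a_main = spectrum.get(main)
        others = sorted((m for m in spectrum.peaks if m != main),
                        key=lambda m: (-spectrum.get(m), m))
        n = min(max(n_qualifiers, MIN_QUALIFIERS), MAX_QUALIFIERS, len(others))
        quals = [(m, spectrum.get(m) / a_main) for m in others[:n]]
        return cls(id=id, rt=rt, ref_spectrum=spectrum, main_ion=main,
                   qualifiers=quals, **kwargs)


@dataclass
class TargetLibrary:
    """An ordered collection of target compounds with unique ids."""

    entries: list[TargetCompound] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate target ids: {dup}")
        self.entries.sort(key=lambda e: e.rt)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, target_id: str) -> bool:
        return any(e.id == target_id for e in self.entries)

    def get(self, target_id: str) -> TargetCompound:
        for e in self.entries:
            if e.id == target_id:
                return e
        raise KeyError(target_id)

    def add(self, target: TargetCompound) -> None:
        if target.id in self:
            raise DataValidationError(f"duplicate target id {target.id!r}")
        self.entries.append(target)
        self.entries.sort(key=lambda e: e.rt)

    def in_window(self, t0: float, t1: float) -> list[TargetCompound]:
        return [e for e in self.entries if t0 <= e.rt <= t1]

    # -- JSON serialisation (schema versioned) ------------------------------

    def to_json(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "provenance": self.provenance,
            "entries": [
                {
                    "id": e.id, "name": e.name, "cas": e.cas,
                    "rt": e.rt, "ri": e.ri,
                    "main_ion": e.main_ion,
                    "qualifiers": [[m, r] for m, r in e.qualifiers],
                    "spectrum": {str(m): v for m, v in e.ref_spectrum.peaks.items()},
                    "source_heartcut": list(e.source_heartcut) if e.source_heartcut else None,
                    "annotations": e.annotations,
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_json(cls, doc: dict) -> "TargetLibrary":
        if doc.get("schema_version") != cls.SCHEMA_VERSION:
            raise DataValidationError(
                f"unsupported library schema version {doc.get('schema_version')!r}")
        entries = []
        for rec in doc["entries"]:
            entries.append(TargetCompound(
                id=rec["id"], name=rec.get("name"), cas=rec.get("cas"),
                rt=rec["rt"], ri=rec.get("ri"),
                ref_spectrum=Spectrum({int(m): v for m, v in rec["spectrum"].items()}),
                main_ion=rec["main_ion"],
                qualifiers=[(int(m), float(r)) for m, r in rec["qualifiers"]],
                source_heartcut=tuple(rec["source_heartcut"]) if rec.get("source_heartcut") else None,
                annotations=rec.get("annotations", {}),
            ))
        return cls(entries=entries, provenance=doc.get("provenance", {}))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path) -> "TargetLibrary":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass
class RICalibration:
    """n-alkane retention calibration: carbon number (7-30) -> rt minutes."""

    alkanes: dict[int, float]

    def __post_init__(self):
        carbons = sorted(self.alkanes)
        if len(carbons) < 2:
            raise DataValidationError("calibration needs at least two alkanes")
        rts = [self.alkanes[c] for c in carbons]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise DataValidationError(
                "alkane retention times must increase strictly with carbon number")
        self.alkanes = {c: float(self.alkanes[c]) for c in carbons}

    @property
    def span(self) -> tuple[float, float]:
        rts = list(self.alkanes.values())
        return rts[0], rts[-1]

    @classmethod
    def read_csv(cls, path) -> "RICalibration":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        try:
            carbon, rt = cols["carbon"], cols["rt_min"]
        except KeyError as exc:
            raise DataValidationError(
                f"{path}: alkane table needs 'carbon' and 'rt_min' columns") from exc
        return cls({int(r[carbon]): float(r[rt]) for _, r in df.iterrows()})


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

class AbundanceTable:
    """Compound x sample relative-abundance matrix.

    Values are analyte:internal-standard response ratios in arbitrary units;
    0 means not detected.  Backed by a pandas DataFrame with the compound id
    index and sample-id columns.
    """

    def __init__(self, values: pd.DataFrame, annotations: pd.DataFrame | None = None):
        if values.index.has_duplicates:
            dup = sorted(values.index[values.index.duplicated()].unique())
            raise DataValidationError(f"duplicate compound ids: {dup}")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise DataValidationError("abundance table contains missing values")
        if (arr < 0).any():
            raise DataValidationError("abundance values must be >= 0")
        self.values = values.astype(float)
        self.annotations = annotations
        absent = self.values.index[(arr == 0).all(axis=1)]
        if len(absent):
            logger.warning("compounds absent in every sample: %s", list(absent))

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __getitem__(self, key):
        return self.values[key]

    def all_absent(self) -> list[str]:
        return list(self.values.index[(self.values.to_numpy() == 0).all(axis=1)])


#: columns of the packaged fixture that are annotations, not sample abundances
ANNOTATION_COLUMNS = ("rt_min", "odor", "source_table")


def read_abundance_table(path, annotation_columns: Sequence[str] = ANNOTATION_COLUMNS,
                         ) -> AbundanceTable:
    """Read a compound x sample CSV (first column = compound id)."""
    df = pd.read_csv(path, index_col=0)
    ann_cols = [c for c in df.columns if c in annotation_columns]
    ann = df[ann_cols] if ann_cols else None
    vals = df.drop(columns=ann_cols)
    try:
        return AbundanceTable(vals, annotations=ann)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.values.copy()
    if table.annotations is not None:
        df = df.join(table.annotations)
    df.index.name = "compound"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Run I/O
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".csv":
        return "csv"
    raise DataValidationError(f"cannot infer run format from {path!r}")


def read_run(path, format: str | None = None, **run_kwargs) -> ChromRun:
    """Read a chromatographic run from mzML or a CSV scan matrix.

    The CSV dialect is: first column ``time_min``, remaining column headers
    integer m/z values, one row per scan.
    """
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        from . import _mzml
        return _mzml.read_mzml(path, **run_kwargs)
    if fmt == "csv":
        return _read_run_csv(path, **run_kwargs)
    raise DataValidationError(f"unknown run format {fmt!r}")


def write_run(run: ChromRun, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        from . import _mzml
        _mzml.write_mzml(run, path)
    elif fmt == "csv":
        _write_run_csv(run, path)
    else:
        raise DataValidationError(f"unknown run format {fmt!r}")


def _read_run_csv(path, **run_kwargs) -> ChromRun:
    df = pd.read_csv(path)
    if df.columns.empty or df.columns[0] != "time_min":
        raise DataValidationError(f"{path}: first CSV column must be 'time_min'")
    mz_range = run_kwargs.get("mz_range", DEFAULT_MZ_RANGE)
    mzs = []
    for c in df.columns[1:]:
        try:
            m = int(c)
        except ValueError as exc:
            raise DataValidationError(f"{path}: non-integer m/z header {c!r}") from exc
        if not (mz_range[0] <= m <= mz_range[1]):
            raise DataValidationError(
                f"{path}: m/z column {m} outside scan range {mz_range}")
        mzs.append(m)
    times = df["time_min"].to_numpy(dtype=float)
    if len(times) and (np.diff(times) <= 0).any():
        raise DataValidationError(f"{path}: scan times not strictly increasing")
    inten = df[df.columns[1:]].to_numpy(dtype=float)
    if (inten < 0).any():
        raise DataValidationError(f"{path}: negative intensities")
    scans = [Scan(float(t), Spectrum({m: v for m, v in zip(mzs, row) if v > 0}))
             for t, row in zip(times, inten)]
    kwargs = dict(run_kwargs)
    kwargs.setdefault("mz_range", mz_range)
    return ChromRun(scans=scans, **kwargs)


def _write_run_csv(run: ChromRun, path) -> None:
    mzs = sorted({m for s in run.scans for m in s.spectrum.peaks})
    lo, hi = run.mz_range
    bad = [m for m in mzs if not (lo <= m <= hi)]
    if bad:
        raise DataValidationError(f"m/z {bad} outside scan range {run.mz_range}")
    rows = []
    for s in run.scans:
        rows.append([s.time] + [s.spectrum.get(m) for m in mzs])
    df = pd.DataFrame(rows, columns=["time_min"] + [str(m) for m in mzs])
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# MSP library I/O (via matchms)
# ---------------------------------------------------------------------------

def read_msp(path, n_qualifiers: int = 3,
             mz_range: tuple[int, int] | None = None) -> TargetLibrary:
    """Read an MSP spectral library into a target library.

    Records missing explicit qualifier ions (the usual case: MSP carries only
    the peak list) get the top ``n_qualifiers`` ions after the base peak as
    qualifiers.  Malformed records are skipped with a warning; the skip count
    is recorded in the library provenance.
    """
    import matchms.importing
    logging.getLogger("matchms").setLevel(logging.ERROR)

    entries: list[TargetCompound] = []
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        specs = list(matchms.importing.load_from_msp(str(path),
                                                     metadata_harmonization=True))
    # records the parser dropped silently (e.g. missing Num Peaks)
    n_records = sum(1 for line in Path(path).read_text().splitlines()
                    if line.split(":")[0].strip().lower()
                    in ("name", "compound_name"))
    skipped += max(0, n_records - len(specs))
    for i, ms in enumerate(specs):
        if ms is None:
            skipped += 1
            continue
        meta = ms.metadata
        name = meta.get("compound_name") or meta.get("name")
        try:
            spec = Spectrum.from_arrays(ms.peaks.mz, ms.peaks.intensities)
            if mz_range is not None:
                spec = Spectrum({m: v for m, v in spec.peaks.items()
                                 if mz_range[0] <= m <= mz_range[1]})
            rt = float(meta.get("retention_time", 0.0) or 0.0)
            ri = meta.get("retention_index")
            target = TargetCompound.from_spectrum(
                id=str(name if name else f"msp_{i}"),
                name=str(name) if name else None,
                cas=str(meta["cas"]) if meta.get("cas") else None,
                rt=rt, ri=float(ri) if ri is not None else None,
                spectrum=spec, n_qualifiers=n_qualifiers)
            entries.append(target)
        except (DataValidationError, ValueError, KeyError) as exc:
            logger.warning("skipping MSP record %d (%r): %s", i, name, exc)
            skipped += 1
    try:
        lib = TargetLibrary(entries=entries,
                            provenance={"source": str(path), "skipped_records": skipped})
    except DataValidationError:
        # duplicate names in the source file: disambiguate with an index suffix
        seen: dict[str, int] = {}
        for e in entries:
            n = seen.get(e.id, 0)
            seen[e.id] = n + 1
            if n:
                e.id = f"{e.id}#{n + 1}"
        lib = TargetLibrary(entries=entries,
                            provenance={"source": str(path), "skipped_records": skipped})
    if skipped:
        logger.warning("%s: skipped %d malformed MSP record(s)", path, skipped)
    return lib


def write_msp(library: TargetLibrary, path) -> None:
    """Write a target library as MSP, base peak normalised to 999."""
    import matchms
    import matchms.exporting
    logging.getLogger("matchms").setLevel(logging.ERROR)

    out = []
    for e in library.entries:
        spec = e.ref_spectrum.normalized()
        mzs = np.array(sorted(spec.peaks), dtype=float)
        intens = np.array([spec.peaks[int(m)] for m in mzs])
        meta = {"compound_name": e.display_name, "retention_time": e.rt}
        if e.cas:
            meta["cas"] = e.cas
        if e.ri is not None:
            meta["retention_index"] = e.ri
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(matchms.Spectrum(mz=mzs, intensities=intens, metadata=meta,
                                        metadata_harmonization=True))
    p = Path(path)
    if p.exists():
        p.unlink()  # matchms appends to existing files
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matchms.exporting.save_as_msp(out, str(path))


def plot_tic(run: ChromRun, ax=None):
    """Debug helper: plot the TIC trace. Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(run.times(), run.tic(), lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("TIC (counts)")
    ax.set_title(run.sample_id or "chromatogram")
    return ax
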