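"""Multi-sample comparison: detection, Venn partitioning, fold changes, reports.

This layer turns compound x sample abundance tables (analyte:internal-standard
response ratios) into the quality-comparison outputs: which compounds are
unique to which sample, which are common, and how strongly shared compounds
differ in concentration between sample pairs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromdata import (AbundanceTable, ChromRun, DataValidationError,
                        InternalStandardNotFoundError, TargetCompound,
                        TargetLibrary)
from .deconvolution import (MatchCriteria, NoiseModel, deconvolve_peak,
                            detect_peaks, evaluate_target)

logger = logging.getLogger(__name__)

#: nominal response scale so table values land in instrument-like magnitudes
DEFAULT_RESPONSE_SCALE = 1e6


def quantify(run: ChromRun, library: TargetLibrary, criteria: MatchCriteria,
             internal_standard: TargetCompound,
             noise: NoiseModel | None = None,
             response_scale: float = DEFAULT_RESPONSE_SCALE,
             rt_window: float = 0.2) -> pd.Series:
    """Relative abundance of every library target in one run.

    Abundance = (deconvolved main-ion area of the target / internal-standard
    main-ion area) x ``response_scale``.  Targets failing the identification
    criterion report 0.  Raises when the internal standard itself fails.
    """
    noise = noise or NoiseModel.estimate(run)
    is_result = evaluate_target(run, internal_standard,
                                criteria.with_noise(noise), rt_window)
    if not is_result.passed or is_result.abundance <= 0:
        raise InternalStandardNotFoundError(
            f"internal standard {internal_standard.id!r} not detected in "
            f"run {run.sample_id!r}")

    crit = criteria.with_noise(noise)
    areas = {e.id: 0.0 for e in library}
    regions = detect_peaks(run, noise)
    for region in regions:
        comps, _ = deconvolve_peak(run, region, library, crit, noise)
        for comp in comps:
            if not comp.is_unknown and comp.target.id in areas:
                areas[comp.target.id] += comp.result.abundance

    is_area = is_result.abundance
    if internal_standard.id in areas:
        # prefer the deconvolved IS area when the IS is in the library
        deconv = areas[internal_standard.id]
        if deconv > 0:
            is_area = deconv
    values = {tid: a / is_area * response_scale for tid, a in areas.items()
              if tid != internal_standard.id}
    return pd.Series(values, name=run.sample_id or "sample")


def detect(table: AbundanceTable, threshold: float = 0.0) -> pd.DataFrame:
    """Boolean presence matrix: present iff abundance > threshold."""
    return table.values > threshold


@dataclass
class VennPartition:
    """Disjoint assignment of compounds to the exact subset of samples present."""

    regions: dict[frozenset, set] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)

    def region(self, *samples: str) -> set:
        """Compounds present in exactly these samples and no others."""
        return self.regions.get(frozenset(samples), set())

    def commonality(self, a: str, b: str) -> int:
        """Compounds present in both a and b (summed over containing regions)."""
        return sum(len(c) for subset, c in self.regions.items()
                   if a in subset and b in subset)

    def total(self) -> int:
        return sum(len(c) for c in self.regions.values())

    def counts(self) -> dict[str, int]:
        return {"+".join(sorted(subset)): len(c)
                for subset, c in sorted(self.regions.items(),
                                        key=lambda kv: sorted(kv[0]))}


def venn_partition(presence: pd.DataFrame) -> VennPartition:
    """Partition compounds by their exact sample-presence pattern.

    Compounds absent everywhere are excluded; regions are disjoint and their
    union is every compound detected in at least one sample.
    """
    if presence.shape[1] < 2:
        raise DataValidationError("venn partition needs at least 2 samples")
    regions: dict[frozenset, set] = {}
    for compound, row in presence.iterrows():
        subset = frozenset(presence.columns[row.to_numpy(dtype=bool)])
        if subset:
            regions.setdefault(subset, set()).add(compound)
    return VennPartition(regions=regions, samples=list(presence.columns))


@dataclass
class FoldChangeRow:
    """One compound's concentration ratio between two samples."""

    compound: str
    numerator: str
    denominator: str
    ratio: float                 # math.inf when denominator is 0
    rounded_fold: int | None     # nearest integer, half away from zero

    @property
    def infinite(self) -> bool:
        return math.isinf(self.ratio)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fold_change(table: AbundanceTable, compound: str,
                numerator: str, denominator: str) -> FoldChangeRow | None:
    """Concentration ratio of one compound between two samples.

    A zero denominator with a positive numerator flags the compound as
    unique (infinite ratio) rather than a fold.  Both zero: the row is
    omitted (None) with a warning.
    """
    if compound not in table.values.index:
        raise KeyError(compound)
    num = float(table.values.at[compound, numerator])
    den = float(table.values.at[compound, denominator])
    if num == 0 and den == 0:
        logger.warning("fold change undefined for %r: absent in both %s and %s",
                       compound, numerator, denominator)
        return None
    if den == 0:
        return FoldChangeRow(compound, numerator, denominator, math.inf, None)
    ratio = num / den
    return FoldChangeRow(compound, numerator, denominator, ratio,
                         _round_half_away(ratio))


def count_fold_threshold(table: AbundanceTable, numerator: str, denominator: str,
                         k: float = 2.0, restrict_to=None) -> int:
    """Number of compounds whose unrounded ratio is >= k (finite ratios only)."""
    compounds = table.compounds if restrict_to is None else [
        c for c in table.compounds if c in set(restrict_to)]
    n = 0
    for c in compounds:
        den = float(table.values.at[c, denominator])
        if den > 0 and float(table.values.at[c, numerator]) / den >= k:
            n += 1
    return n


REQUIRED_ROLES = ("green_high", "green_low", "roast_high", "roast_low")


@dataclass
class ComparisonReport:
    """Structured four-sample comparison: uniques, folds, survivors."""

    roles: dict[str, str]
    venn: VennPartition
    unique_tables: dict[str, pd.DataFrame]
    green_folds: pd.DataFrame          # green_high vs green_low, both present
    roast_folds: pd.DataFrame          # roast_high vs roast_low, both present
    survivors: pd.DataFrame            # all-four compounds with green->roast folds

    def green_fold_list(self, k: float) -> pd.DataFrame:
        """Green-pair compounds at or above a fold threshold in either direction."""
        g = self.green_folds
        return g[(g["ratio"] >= k) | (g["ratio"] <= 1.0 / k)]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "venn.json").write_text(json.dumps(self.venn.counts(), indent=1))
        for sample, df in self.unique_tables.items():
            df.to_csv(out / f"unique_{sample.replace(' ', '_')}.csv")
        self.green_folds.to_csv(out / "folds_green.csv", index=False)
        self.roast_folds.to_csv(out / "folds_roast.csv", index=False)
        self.survivors.to_csv(out / "survivors.csv", index=False)


def _pair_folds(table: AbundanceTable, num: str, den: str) -> pd.DataFrame:
    rows = []
    for c in table.compounds:
        vn = float(table.values.at[c, num])
        vd = float(table.values.at[c, den])
        if vn > 0 and vd > 0:
            fc = fold_change(table, c, num, den)
            rows.append({"compound": c, "numerator": num, "denominator": den,
                         "ratio": fc.ratio, "rounded_fold": fc.rounded_fold})
    return pd.DataFrame(rows, columns=["compound", "numerator", "denominator",
                                       "ratio", "rounded_fold"])


def comparison_report(table: AbundanceTable, roles: dict[str, str],
                      threshold: float = 0.0) -> ComparisonReport:
    """Full four-sample quality comparison.

    ``roles`` maps the role names green_high/green_low/roast_high/roast_low
    to sample column ids.  Produces the Venn partition, per-region unique
    tables, green-pair and roast-pair fold lists, and the survivor table
    (compounds present in all four samples) with green-to-roast folds.
    """
    missing = [r for r in REQUIRED_ROLES if r not in roles]
    if missing:
        raise DataValidationError(f"missing sample roles: {missing}")
    unknown = [s for s in roles.values() if s not in table.samples]
    if unknown:
        raise DataValidationError(f"role samples not in table: {unknown}")

    presence = detect(table, threshold)
    venn = venn_partition(presence)

    unique_tables = {}
    for sample in (roles[r] for r in REQUIRED_ROLES):
        compounds = sorted(venn.region(sample))
        unique_tables[sample] = table.values.loc[compounds]

    green_folds = _pair_folds(table, roles["green_high"], roles["green_low"])
    roast_folds = _pair_folds(table, roles["roast_high"], roles["roast_low"])

    all_four = sorted(venn.region(*[roles[r] for r in REQUIRED_ROLES]))
    surv_rows = []
    for c in all_four:
        gh = float(table.values.at[c, roles["green_high"]])
        rh = float(table.values.at[c, roles["roast_high"]])
        gl = float(table.values.at[c, roles["green_low"]])
        rl = float(table.values.at[c, roles["roast_low"]])
        surv_rows.append({
            "compound": c,
            "green_high": gh, "green_low": gl,
            "roast_high": rh, "roast_low": rl,
            "roast_over_green_high": rh / gh,
            "roast_over_green_low": rl / gl,
        })
    survivors = pd.DataFrame(surv_rows, columns=[
        "compound", "green_high", "green_low", "roast_high", "roast_low",
        "roast_over_green_high", "roast_over_green_low"])

    return ComparisonReport(roles=dict(roles), venn=venn,
                            unique_tables=unique_tables,
                            green_folds=green_folds, roast_folds=roast_folds,
                            survivors=survivors)
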