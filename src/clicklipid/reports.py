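"""Derived analytics over quantification tables.

Covers the summary numbers a propargylcholine tracing study reports: labeling
specificity (share of total detectable label per labeled class), the fatty-acid
distribution over all chain positions, the fraction of the labeled pool that
no longer carries the tracer's original FA, per-cell normalization, recovery
from a post-click spike-in, and calibration (linearity, LOD, LOQ) from a
dilution series.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ident_quant import QuantTable
from .lipids import FattyAcyl

__all__ = [
    "LabelSpecificityResult",
    "FaDistribution",
    "FaFreeSummary",
    "CalibrationResult",
    "label_specificity",
    "fa_distribution",
    "fa_free_summary",
    "per_cell",
    "recovery",
    "calibration",
]


@dataclass(frozen=True)
class LabelSpecificityResult:
    """pmol and percent of total detectable label, per labeled class."""

    pmol: dict[str, float]
    percent: dict[str, float]

    @property
    def total_pmol(self) -> float:
        return sum(self.pmol.values())


def label_specificity(labeled_pmol: Mapping[str, float]) -> LabelSpecificityResult:
    """Share of the total detectable label carried by each labeled class.

    percent(class) = 100 * pmol(class) / sum over labeled classes.
    """
    total = sum(labeled_pmol.values())
    if total <= 0:
        raise ValueError("no detectable label: all class amounts are zero")
    if any(v < 0 for v in labeled_pmol.values()):
        raise ValueError("negative class amount")
    pmol = dict(labeled_pmol)
    return LabelSpecificityResult(pmol, {k: 100.0 * v / total for k, v in pmol.items()})


# ---------------------------------------------------------------------------
# FA distribution over subspecies

_ETHER_PREFIX = re.compile(r"^O-")


def _chains_frame(table: QuantTable | pd.DataFrame) -> pd.DataFrame:
    """Normalize a subspecies table to columns fa1, fa2, pmol, is_ether.

    Accepts either a pipeline :class:`QuantTable` (chains encoded in the
    ``subspecies`` strings, ``O-`` marking an ether sn-1 chain) or a plain
    DataFrame already carrying ``fa1``/``fa2``/``pmol`` columns.
    """
    if isinstance(table, QuantTable):
        df = table.subspecies_rows()
        rows = []
        for _, r in df.iterrows():
            name = r["subspecies"]
            is_ether = bool(_ETHER_PREFIX.match(name))
            fa1, fa2 = _ETHER_PREFIX.sub("", name).split("_")
            rows.append({"species": r["species"], "fa1": fa1, "fa2": fa2,
                         "pmol": float(r["pmol"]), "is_ether": is_ether})
        return pd.DataFrame(rows)
    df = table.copy()
    if "is_ether" not in df.columns:
        df["is_ether"] = False
    need = {"fa1", "fa2", "pmol"}
    if not need.issubset(df.columns):
        raise ValueError(f"subspecies table needs columns {sorted(need)}")
    return df


@dataclass(frozen=True)
class FaDistribution:
    """Per-FA totals over all chain positions, with SFA/MUFA/PUFA rollups."""

    per_fa: pd.DataFrame  # index FA name; columns pmol, percent, positions
    rollups: pd.DataFrame  # index SFA/MUFA/PUFA; columns pmol, percent, positions

    @property
    def total_pmol(self) -> float:
        return float(self.per_fa["pmol"].sum())


def fa_distribution(table: QuantTable | pd.DataFrame,
                    include_ether_acyl: bool = True) -> FaDistribution:
    """Distribute subspecies amounts over their individual FA chains.

    Each diacyl subspecies contributes its pmol to each of its two FA bins
    (a homoacyl pair contributes twice to one bin) and one position count per
    occurrence.  Ether subspecies contribute only the sn-2 acyl (the sn-1
    alkyl is not an FA); ``include_ether_acyl=False`` drops them entirely.
    """
    df = _chains_frame(table)
    bins: dict[str, dict[str, float]] = {}

    def add(fa_name: str, pmol: float) -> None:
        b = bins.setdefault(fa_name, {"pmol": 0.0, "positions": 0})
        b["pmol"] += pmol
        b["positions"] += 1

    for _, r in df.iterrows():
        if r["is_ether"]:
            if include_ether_acyl:
                add(r["fa2"], r["pmol"])
            continue
        add(r["fa1"], r["pmol"])
        add(r["fa2"], r["pmol"])
    if not bins:
        raise ValueError("no FA chains to distribute")
    per_fa = pd.DataFrame.from_dict(bins, orient="index")
    total = per_fa["pmol"].sum()
    per_fa["percent"] = 100.0 * per_fa["pmol"] / total
    per_fa["positions"] = per_fa["positions"].astype(int)
    per_fa = per_fa.sort_values("pmol", ascending=False)
    per_fa.index.name = "fa"

    def _d(fa_name: str) -> int:
        return FattyAcyl.from_name(fa_name).d

    cat = per_fa.index.map(lambda n: "SFA" if _d(n) == 0 else "MUFA" if _d(n) == 1 else "PUFA")
    roll = per_fa.groupby(cat)[["pmol", "positions"]].sum()
    roll["percent"] = 100.0 * roll["pmol"] / total
    roll = roll.reindex(["SFA", "MUFA", "PUFA"]).fillna(0.0)
    roll["positions"] = roll["positions"].astype(int)
    return FaDistribution(per_fa[["pmol", "percent", "positions"]], roll)


@dataclass(frozen=True)
class FaFreeSummary:
    """Subspecies not containing a target FA in either chain."""

    count: int
    pmol: float
    percent_of_subspecies_total: float | None
    percent_of_species_total: float | None = None


def fa_free_summary(table: QuantTable | pd.DataFrame, target: FattyAcyl | str,
                    species_total_pmol: float | None = None) -> FaFreeSummary:
    """Count and sum the subspecies in which neither chain is the target FA.

    The percentage is given against the subspecies-table total and, when a
    species-level (NL-based) total is supplied, against that as well — the two
    denominators can differ because the quantification routes differ.
    """
    target_name = target.name if isinstance(target, FattyAcyl) else target
    df = _chains_frame(table)
    if df.empty:
        return FaFreeSummary(0, 0.0, None)
    free = df[(df["fa1"] != target_name) & (df["fa2"] != target_name)]
    total = df["pmol"].sum()
    pmol = float(free["pmol"].sum())
    return FaFreeSummary(
        count=int(len(free)),
        pmol=pmol,
        percent_of_subspecies_total=100.0 * pmol / total if total > 0 else None,
        percent_of_species_total=(100.0 * pmol / species_total_pmol
                                  if species_total_pmol else None),
    )


def per_cell(pmol: float, n_cells: int) -> float:
    """Convert a per-sample amount to fmol per cell: 1000 * pmol / n_cells."""
    if n_cells <= 0:
        raise ValueError("cell count must be positive")
    return 1000.0 * pmol / n_cells


def recovery(a: float, b: float) -> float:
    """Recovery percentage from an unspiked (a) and post-click-spiked (b) signal.

    recovery = 100 * a / (b - a); the spike must increase the signal.
    """
    if a < 0:
        raise ValueError("signals must be non-negative")
    if b <= a:
        raise ValueError("spiked signal must exceed the unspiked signal")
    return 100.0 * a / (b - a)


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    linear_range_orders: float
    lod_pmol: float
    loq_pmol: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("R^2 out of [0, 1]")
        if self.lod_pmol > self.loq_pmol:
            raise ValueError("LOD must not exceed LOQ")


def calibration(series: Iterable[tuple[float, float]]) -> CalibrationResult:
    """Linearity and detection/quantification limits from a dilution series.

    ``series`` holds (spiked pmol, measured response) pairs; repeated levels
    are replicates.  An ordinary least-squares line is fit over the nonzero
    levels; LOD = 3.3 sigma / slope and LOQ = 10 sigma / slope, with sigma the
    replicate SD at the blank (level 0) if present, else at the lowest level.
    The linear range is log10(highest / lowest nonzero level).
    """
    pts = [(float(x), float(y)) for x, y in series]
    levels: dict[float, list[float]] = {}
    for x, y in pts:
        levels.setdefault(x, []).append(y)
    nonzero = sorted(l for l in levels if l > 0)
    if len(nonzero) < 3:
        raise ValueError("need at least 3 distinct nonzero levels")
    xs = np.array([x for x, _ in pts if x > 0])
    ys = np.array([y for x, y in pts if x > 0])
    fit = stats.linregress(xs, ys)
    if fit.slope <= 0:
        raise ValueError("non-positive calibration slope; LOD/LOQ undefined")
    sigma_level = 0.0 if 0.0 in levels else nonzero[0]
    reps = levels[sigma_level]
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates at the blank/lowest level for LOD/LOQ")
    sigma = float(np.std(reps, ddof=1))
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        linear_range_orders=math.log10(nonzero[-1] / nonzero[0]),
        lod_pmol=3.3 * sigma / fit.slope,
        loq_pmol=10.0 * sigma / fit.slope,
    )
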