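"""Rule-based identification and internal-standard quantification.

A labeled species is accepted when a peak at the expected clicked-precursor
mass co-occurs with the reporter's characteristic neutral-loss fragment in the
precursor's own 1-m/z DIA window; the NL fragment is the defining evidence and
is mandatory.  Species amounts come from single-point calibration against a
spiked internal standard using the NL-fragment intensities; subspecies amounts
use the summed FA-carboxylate fragment intensities with a per-chain response
factor derived from the internal standard's own FA peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lipids import (
    DEFAULT_ACYL_C_RANGE,
    DEFAULT_ACYL_D_RANGE,
    InternalStandard,
    ReporterDefinition,
    Subspecies,
    SumSpecies,
    clicked_precursor,
    enumerate_subspecies,
    fa_fragment_mz,
    nl_fragment_mz,
)
from .spectra import (
    DEFAULT_MS1_PPM,
    DEFAULT_MS2_PPM,
    Peak,
    Run,
    Spectrum,
    averaged_ms1,
    find_peak,
    ms2_window_for,
)

__all__ = [
    "SpeciesHit",
    "SubspeciesHit",
    "QuantTable",
    "identify_species",
    "quantify_species",
    "identify_subspecies",
    "quantify_subspecies",
    "subspecies_percentages",
]

QUANT_COLUMNS = ["sample", "lipid_class", "species", "subspecies",
                 "pmol", "quant_basis", "internal_standard", "flags"]

# 13C natural abundance, for the optional type-I isotope correction.
_P13C = 0.0107


def type1_isotope_factor(n_carbons: int) -> float:
    """Fraction of an ion population found in the monoisotopic peak (13C only)."""
    return (1.0 - _P13C) ** n_carbons


@dataclass
class SpeciesHit:
    """A sum species identified by its clicked precursor and diagnostic NL fragment."""

    species: SumSpecies
    reporter: ReporterDefinition
    expected_precursor_mz: float
    nl_peak: Peak
    ms2_window: Spectrum
    ms1_peak: Peak | None = None
    precursor_peak: Peak | None = None  # residual precursor in the MS2 window
    flags: tuple[str, ...] = ()

    @property
    def nl_intensity(self) -> float:
        return self.nl_peak.intensity


@dataclass
class SubspeciesHit:
    """A chain-resolved hit within an identified species' MS2 window."""

    subspecies: Subspecies
    fa_peaks: tuple[Peak | None, ...]  # aligned with subspecies.observable_fas
    flags: tuple[str, ...] = ()

    @property
    def summed_fa_intensity(self) -> float:
        return sum(p.intensity for p in self.fa_peaks if p is not None)


@dataclass
class QuantTable:
    """Identified species/subspecies with picomole amounts versus internal standard."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in QUANT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"quant table missing columns {missing}")
        if (self.df["pmol"] < 0).any():
            raise ValueError("negative pmol")

    def species_rows(self) -> pd.DataFrame:
        return self.df[self.df["subspecies"] == "-"]

    def subspecies_rows(self) -> pd.DataFrame:
        return self.df[self.df["subspecies"] != "-"]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "QuantTable":
        df = pd.read_csv(path, sep="\t", dtype={"subspecies": str})
        return cls(df)

    @staticmethod
    def from_rows(rows: list[dict], metadata: dict | None = None) -> "QuantTable":
        df = pd.DataFrame(rows, columns=QUANT_COLUMNS)
        return QuantTable(df, metadata or {})


def _sorted_rows(rows: list[dict]) -> list[dict]:
    return sorted(rows, key=lambda r: (r["lipid_class"], r["species"], r["subspecies"]))


def identify_species(
    run: Run,
    candidates: list[SumSpecies],
    reporter: ReporterDefinition,
    ms1_tol_ppm: float = DEFAULT_MS1_PPM,
    ms2_tol_ppm: float = DEFAULT_MS2_PPM,
    require_ms1: bool = True,
) -> list[SpeciesHit]:
    """Identify clicked propargyl species in a DIA run.

    For each candidate the expected clicked-precursor m/z selects its DIA
    window; a hit requires the diagnostic fragment at (precursor - NL) within
    tolerance, and, when ``require_ms1`` is set, a precursor peak in the
    averaged MS1 as well.  Candidates whose precursor falls outside the
    acquired range are skipped.
    """
    if run.polarity is not reporter.polarity:
        raise ValueError(
            f"run polarity {run.polarity.value} does not match reporter "
            f"{reporter.name} ({reporter.polarity.value})")
    ms1 = averaged_ms1(run, ms1_tol_ppm) if (require_ms1 and run.ms1_scans()) else None
    if require_ms1 and ms1 is None:
        raise ValueError("require_ms1 is set but the run has no MS1 scans")
    hits: list[SpeciesHit] = []
    expected_cache: list[tuple[SumSpecies, float]] = []
    for sp in candidates:
        if not sp.lipid_class.is_propargyl:
            continue
        expected_cache.append((sp, clicked_precursor(sp, reporter).mz))
    for sp, expected in sorted(expected_cache, key=lambda t: t[0].sort_key):
        try:
            window = ms2_window_for(run, expected, ms2_tol_ppm)
        except ValueError:
            continue  # outside acquired DIA range
        nl_expected = nl_fragment_mz(expected, reporter)
        nl_peak = find_peak(window, nl_expected, ms2_tol_ppm)
        if nl_peak is None:
            continue  # the NL fragment is mandatory evidence
        ms1_peak = None
        if ms1 is not None:
            ms1_peak = find_peak(ms1, expected, ms1_tol_ppm)
            if ms1_peak is None:
                continue
        flags = []
        near = [other for other, mz in expected_cache
                if other != sp and abs(mz - expected) <= expected * ms1_tol_ppm * 1e-6]
        if near:
            flags.append("ambiguous_precursor:" + ",".join(o.name for o in near))
        hits.append(SpeciesHit(
            species=sp, reporter=reporter, expected_precursor_mz=expected,
            nl_peak=nl_peak, ms2_window=window, ms1_peak=ms1_peak,
            precursor_peak=find_peak(window, expected, ms2_tol_ppm),
            flags=tuple(flags)))
    return hits


def quantify_species(
    hits: list[SpeciesHit],
    internal_standard: InternalStandard,
    sample: str = "sample",
    isotope_correction: bool = False,
) -> QuantTable:
    """Single-point quantification from NL-fragment intensities.

    pmol(species) = I_NL(species) / I_NL(IS) * pmol(IS).  The optional type-I
    isotope correction rescales each intensity by the monoisotopic fraction of
    its precursor's carbon envelope before taking the ratio.
    """
    is_hit = next((h for h in hits if h.species == internal_standard.species), None)
    if is_hit is None or is_hit.nl_intensity <= 0:
        raise ValueError(
            f"internal standard not detected: {internal_standard.species.name}")

    def corrected(h: SpeciesHit) -> float:
        if not isotope_correction:
            return h.nl_intensity
        n_c = (h.species.composition + h.reporter.composition)["C"]
        return h.nl_intensity / type1_isotope_factor(n_c)

    ref = corrected(is_hit)
    rows = []
    for h in hits:
        rows.append({
            "sample": sample,
            "lipid_class": h.species.lipid_class.value,
            "species": h.species.name,
            "subspecies": "-",
            "pmol": corrected(h) / ref * internal_standard.amount_pmol,
            "quant_basis": "NL",
            "internal_standard": internal_standard.species.name,
            "flags": ";".join(h.flags) or "-",
        })
    return QuantTable.from_rows(_sorted_rows(rows), {"sample": sample})


def identify_subspecies(
    run: Run,
    species_hits: list[SpeciesHit],
    ms2_tol_ppm: float = DEFAULT_MS2_PPM,
    acyl_c_range: tuple[int, int] = DEFAULT_ACYL_C_RANGE,
    acyl_d_range: tuple[int, int] = DEFAULT_ACYL_D_RANGE,
    require_both_fa: bool = False,
) -> list[SubspeciesHit]:
    """Resolve identified species into chain pairs via FA-carboxylate fragments.

    Each enumerated subspecies is looked up in the parent species' own MS2
    window.  Heteroacyl diacyl pairs need both carboxylate peaks when
    ``require_both_fa`` is set; otherwise one peak suffices and the missing
    partner contributes zero intensity (flagged ``single_fragment``).
    Homoacyl pairs and ether/sphingo species have exactly one observable peak.
    """
    out: list[SubspeciesHit] = []
    for hit in species_hits:
        if hit.species.lipid_class.is_lyso:
            continue
        window = hit.ms2_window
        for sub in enumerate_subspecies(hit.species, acyl_c_range, acyl_d_range):
            peaks = tuple(find_peak(window, fa_fragment_mz(fa), ms2_tol_ppm)
                          for fa in sub.observable_fas)
            n_found = sum(p is not None for p in peaks)
            if n_found == 0:
                continue
            flags = []
            if len(peaks) == 2 and n_found == 1:
                if require_both_fa:
                    continue
                flags.append("single_fragment")
            out.append(SubspeciesHit(sub, peaks, tuple(flags)))
    return out


def quantify_subspecies(
    subspecies_hits: list[SubspeciesHit],
    internal_standard: InternalStandard,
    sample: str = "sample",
) -> QuantTable:
    """Quantify chain-resolved subspecies against the IS's own FA fragments.

    The per-chain response factor is RF = (I_IS,fa1 + I_IS,fa2) / (2 pmol_IS).
    A heteroacyl pair is (I1 + I2) / (2 RF); a homoacyl pair's single shared
    peak carries both chains, I / (2 RF); ether and sphingo species expose one
    chain only, I / RF.
    """
    is_sub = internal_standard.subspecies
    is_hit = next((h for h in subspecies_hits if h.subspecies == is_sub), None)
    if is_hit is None or is_hit.summed_fa_intensity <= 0:
        raise ValueError(
            f"internal standard FA fragments not detected: {is_sub}")
    n_is_chains = 2 if is_sub.parent.lipid_class.n_fa_fragments == 2 else 1
    rf = is_hit.summed_fa_intensity / (n_is_chains * internal_standard.amount_pmol)
    rows = []
    for h in subspecies_hits:
        sub = h.subspecies
        cls = sub.parent.lipid_class
        if cls.n_fa_fragments == 1:
            pmol = h.summed_fa_intensity / rf
        else:
            pmol = h.summed_fa_intensity / (2.0 * rf)
        rows.append({
            "sample": sample,
            "lipid_class": cls.value,
            "species": sub.parent.name,
            "subspecies": sub.name,
            "pmol": pmol,
            "quant_basis": "FA",
            "internal_standard": is_sub.parent.name,
            "flags": ";".join(h.flags) or "-",
        })
    return QuantTable.from_rows(_sorted_rows(rows), {"sample": sample})


def subspecies_percentages(quant: QuantTable) -> pd.DataFrame:
    """Per species, each subspecies' share of the species' total subspecies pmol.

    Species whose subspecies amounts sum to zero are omitted (the share is
    undefined).  Shares sum to 100 within every reported species.
    """
    sub = quant.subspecies_rows().copy()
    if sub.empty:
        raise ValueError("no subspecies rows to summarize")
    totals = sub.groupby("species")["pmol"].transform("sum")
    sub = sub[totals > 0].copy()
    sub["pct_of_subspecies"] = 100.0 * sub["pmol"] / sub.groupby("species")["pmol"].transform("sum")
    return sub
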