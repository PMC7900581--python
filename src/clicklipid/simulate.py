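"""Synthetic direct-infusion DIA runs with the statistical structure the method assumes.

The simulator emulates the acquisition scheme of a high-resolution
direct-infusion experiment — MS1 survey scans over fixed 100-m/z windows and
data-independent MS2 scans in 1-m/z isolation windows — and the fragmentation
chemistry of click-labeled propargyl lipids: each clicked precursor leaves a
residual precursor peak, the reporter-diagnostic neutral-loss fragment, and
(in negative mode, when chains are specified) one FA-carboxylate fragment per
observable chain.  Polyunsaturated chains lose CO2 during fragmentation with a
per-chain probability 1 - (1 - q)^(d-1) for d >= 2; the decarboxylated mass is
emitted as a distinct peak, so FA-based quantification of PUFA chains is
biased low while the NL route is untouched — the suppression the method's
recovery experiments observe.

Intensities are pmol x response factor, scaled by the fragment branching
fractions, multiplied by log-normal noise; m/z values receive Normal ppm
jitter; a homogeneous Poisson noise floor with exponential intensities fills
each scan.  A seed fixes the whole run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem import Polarity
from .ident_quant import QUANT_COLUMNS, QuantTable
from .lipids import (
    InternalStandard,
    ReporterDefinition,
    Subspecies,
    SumSpecies,
    clicked_precursor,
    fa_fragment_mz,
    nl_fragment_mz,
    N3PAL,
)
from .spectra import Run, Spectrum, dia_window_for

__all__ = [
    "MixtureSpec",
    "InstrumentModel",
    "simulate_run",
    "ground_truth",
    "CO2_MASS",
]

CO2_MASS = 43.98982924  # C + 2 O


@dataclass(frozen=True)
class MixtureSpec:
    """What is in the sprayed sample: analytes, internal standards, reporter."""

    components: tuple[tuple[SumSpecies | Subspecies, float], ...]
    internal_standards: tuple[InternalStandard, ...] = ()
    reporter: ReporterDefinition = N3PAL

    def __post_init__(self) -> None:
        for item, pmol in self.components:
            if pmol < 0:
                raise ValueError(f"negative amount for {item}")

    def all_entries(self) -> list[tuple[SumSpecies | Subspecies, float]]:
        """Analytes plus internal standards (as subspecies where the acyl pair is known)."""
        out = list(self.components)
        for istd in self.internal_standards:
            try:
                out.append((istd.subspecies, istd.amount_pmol))
            except ValueError:
                out.append((istd.species, istd.amount_pmol))
        return out


@dataclass(frozen=True)
class InstrumentModel:
    """Acquisition and response model of the simulated instrument.

    Fragment branching: ``p_nl`` of a precursor's signal appears in the NL
    fragment, ``p_fa`` per observable chain in its carboxylate fragment, and
    ``residual_fraction`` survives as un-fragmented precursor.  ``decarbox_q``
    is the per-double-bond CO2-loss parameter for PUFA chains.
    """

    polarity: Polarity = Polarity.NEGATIVE
    ms1_range: tuple[float, float] = (950.0, 1300.0)
    ms2_range: tuple[float, float] = (950.0, 1300.0)
    ms1_window_width: float = 100.0
    dia_window_width: float = 1.0
    scans_per_window: int = 1
    response_factor: float = 1000.0  # intensity units per pmol
    p_nl: float = 0.5
    p_fa: float = 0.25
    residual_fraction: float = 0.2
    decarbox_q: float = 0.0
    mass_error_ppm_sd: float = 0.0
    lognormal_sd: float = 0.0
    noise_peaks_per_scan: float = 0.0
    noise_intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_nl, self.p_fa, self.residual_fraction, self.decarbox_q):
            if not (0.0 <= p <= 1.0):
                raise ValueError("branching probabilities must be in [0, 1]")

    @classmethod
    def negative_mode(cls, **kw) -> "InstrumentModel":
        """Negative-mode defaults: MS1 in 100-m/z windows and DIA in 1-m/z windows, 950-1300."""
        return cls(**kw)

    @classmethod
    def positive_mode(cls, **kw) -> "InstrumentModel":
        """Positive-mode defaults: MS1 250-1200, DIA MS2 200-1200."""
        defaults = dict(polarity=Polarity.POSITIVE, ms1_range=(250.0, 1200.0),
                        ms2_range=(200.0, 1200.0))
        defaults.update(kw)
        return cls(**defaults)


def _decarbox_prob(d: int, q: float) -> float:
    if d < 2:
        return 0.0
    return 1.0 - (1.0 - q) ** (d - 1)


def _accumulate(peaks: dict[float, float], mz: float, intensity: float) -> None:
    if intensity <= 0.0:
        return  # a zero branching fraction yields no peak
    key = round(mz, 6)
    peaks[key] = peaks.get(key, 0.0) + intensity


def simulate_run(mixture: MixtureSpec, instrument: InstrumentModel, seed: int) -> Run:
    """Simulate a full direct-infusion DIA acquisition of a mixture.

    MS1 scans tile ``ms1_range`` in ``ms1_window_width`` windows and contain
    the clicked-precursor peaks; MS2 DIA scans tile ``ms2_range`` in 1-m/z
    windows and contain, for every co-isolated precursor, the residual
    precursor, the NL fragment and the chain carboxylate fragments (with the
    decarboxylated satellite for PUFA chains).  Species whose clicked
    precursor falls outside the acquired range are omitted with a warning and
    listed in ``run.metadata['omitted']``.
    """
    if instrument.polarity is not mixture.reporter.polarity:
        raise ValueError("instrument polarity does not match the reporter")
    rng = np.random.default_rng(seed)
    rf = instrument.response_factor

    # expected peak content per DIA window and per MS1 window
    ms1_peaks: dict[float, float] = {}
    dia_content: dict[float, dict[float, float]] = {}
    omitted: list[str] = []
    for entry, pmol in mixture.all_entries():
        species = entry.parent if isinstance(entry, Subspecies) else entry
        prec = clicked_precursor(species, mixture.reporter).mz
        lo, hi = instrument.ms2_range
        if not (lo <= prec < hi) or pmol == 0:
            if pmol > 0:
                omitted.append(species.name)
            continue
        base = pmol * rf
        m1lo, m1hi = instrument.ms1_range
        if m1lo <= prec < m1hi:
            _accumulate(ms1_peaks, prec, base)
        center, width = dia_window_for(prec, instrument.dia_window_width)
        window = dia_content.setdefault(center, {})
        _accumulate(window, prec, base * instrument.residual_fraction)
        _accumulate(window, nl_fragment_mz(prec, mixture.reporter), base * instrument.p_nl)
        if isinstance(entry, Subspecies) and mixture.reporter.polarity is Polarity.NEGATIVE:
            chains = list(entry.observable_fas)
            if entry.is_homoacyl and entry.parent.lipid_class.n_fa_fragments == 2:
                chains = [entry.fa1, entry.fa2]  # both chains share one m/z
            for fa in chains:
                p_dec = _decarbox_prob(fa.d, instrument.decarbox_q)
                fa_mz = fa_fragment_mz(fa)
                _accumulate(window, fa_mz, base * instrument.p_fa * (1.0 - p_dec))
                if p_dec > 0:
                    _accumulate(window, fa_mz - CO2_MASS, base * instrument.p_fa * p_dec)
    if omitted:
        warnings.warn(f"species outside acquired range omitted: {omitted}")

    def _noise_floor(scan_lo: float, scan_hi: float) -> tuple[np.ndarray, np.ndarray]:
        n = rng.poisson(instrument.noise_peaks_per_scan)
        if n == 0:
            return np.empty(0), np.empty(0)
        return (rng.uniform(scan_lo, scan_hi, n),
                rng.exponential(instrument.noise_intensity_scale, n))

    def _jitter(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if instrument.mass_error_ppm_sd > 0:
            mz = mz * (1.0 + rng.normal(0.0, instrument.mass_error_ppm_sd * 1e-6, len(mz)))
        if instrument.lognormal_sd > 0:
            inten = inten * rng.lognormal(0.0, instrument.lognormal_sd, len(inten))
        return mz, inten

    spectra: list[Spectrum] = []
    # MS1 survey scans over fixed windows
    m1lo, m1hi = instrument.ms1_range
    edges = np.arange(m1lo, m1hi, instrument.ms1_window_width)
    for lo in edges:
        hi = min(lo + instrument.ms1_window_width, m1hi)
        in_window = {m: i for m, i in ms1_peaks.items() if lo <= m < hi}
        for _ in range(instrument.scans_per_window):
            mz = np.array(sorted(in_window))
            inten = np.array([in_window[m] for m in sorted(in_window)])
            mz, inten = _jitter(mz, inten)
            nz_mz, nz_int = _noise_floor(lo, hi)
            spectra.append(Spectrum(1, instrument.polarity, (float(lo), float(hi)),
                                    np.concatenate([mz, nz_mz]),
                                    np.concatenate([inten, nz_int])))
    # DIA MS2 scans tile the precursor axis
    w = instrument.dia_window_width
    lo2, hi2 = instrument.ms2_range
    centers = np.arange(np.floor(lo2 / w) * w + w / 2, hi2, w)
    frag_lo = 100.0  # fragment scan range floor: FA fragments sit well above it
    for center in centers:
        content = dia_content.get(float(center), {})
        for _ in range(instrument.scans_per_window):
            mz = np.array(sorted(content))
            inten = np.array([content[m] for m in sorted(content)])
            mz, inten = _jitter(mz, inten)
            nz_mz, nz_int = _noise_floor(frag_lo, center + w)
            spectra.append(Spectrum(2, instrument.polarity, (frag_lo, float(center) + w),
                                    np.concatenate([mz, nz_mz]),
                                    np.concatenate([inten, nz_int]),
                                    precursor_window=(float(center), w)))
    return Run(spectra, instrument.polarity,
               {"id": f"sim-seed{seed}", "omitted": omitted,
                "reporter": mixture.reporter.name})


def ground_truth(mixture: MixtureSpec, sample: str = "truth") -> QuantTable:
    """The mixture itself as a QuantTable, for comparison against pipeline output.

    Species rows aggregate every component of a sum species (basis NL);
    subspecies components additionally appear as their own rows (basis FA).
    """
    species_totals: dict[SumSpecies, float] = {}
    rows: list[dict] = []
    for entry, pmol in mixture.all_entries():
        species = entry.parent if isinstance(entry, Subspecies) else entry
        species_totals[species] = species_totals.get(species, 0.0) + pmol
        if isinstance(entry, Subspecies):
            rows.append({
                "sample": sample, "lipid_class": species.lipid_class.value,
                "species": species.name, "subspecies": entry.name, "pmol": pmol,
                "quant_basis": "FA", "internal_standard": "-", "flags": "-"})
    for species, pmol in species_totals.items():
        rows.append({
            "sample": sample, "lipid_class": species.lipid_class.value,
            "species": species.name, "subspecies": "-", "pmol": pmol,
            "quant_basis": "NL", "internal_standard": "-", "flags": "-"})
    rows.sort(key=lambda r: (r["lipid_class"], r["species"], r["subspecies"]))
    import pandas as pd
    return QuantTable(pd.DataFrame(rows, columns=QUANT_COLUMNS), {"sample": sample})
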