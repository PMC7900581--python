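"""Direct-infusion DIA runs: mzML I/O, acquisition-window model, peak lookup.

A run is an ordered list of centroided spectra of one polarity: MS1 survey
scans recorded over fixed m/z windows, followed by data-independent MS2 scans
whose precursor isolation windows are 1 m/z wide and tile the precursor axis
on integer boundaries (window k covers [k, k+1), center k + 0.5).  Direct
infusion acquires repeated scans per window; averaging across scans is the
default before any peak lookup.

Both directions of mzML I/O are implemented here on the standard cvParam
vocabulary: the writer emits minimal centroid mzML with uncompressed 64-bit
float arrays, and the reader handles 32/64-bit float arrays with or without
zlib compression, plain or indexed files.
"""

from __future__ import annotations

import base64
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .chem import Polarity

__all__ = [
    "Peak",
    "Spectrum",
    "Run",
    "read_run",
    "write_run",
    "average_scans",
    "ms2_window_for",
    "find_peak",
    "dia_window_for",
    "read_peaklist",
    "write_peaklist",
    "DEFAULT_MS1_PPM",
    "DEFAULT_MS2_PPM",
]

# Default tolerances reflecting R = 280,000 acquisition.
DEFAULT_MS1_PPM = 5.0
DEFAULT_MS2_PPM = 10.0


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One centroided scan: MS level, polarity, scan range, optional precursor window."""

    ms_level: int
    polarity: Polarity
    scan_range: tuple[float, float]  # [lo, hi)
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    precursor_window: tuple[float, float] | None = None  # (center, width)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.mz <= 0):
            raise ValueError("non-positive m/z")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.ms_level not in (1, 2):
            raise ValueError("ms level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_window is None:
            raise ValueError("MS2 spectrum needs a precursor isolation window")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def isolation_interval(self) -> tuple[float, float]:
        """Half-open [lo, hi) isolation interval of an MS2 scan."""
        if self.precursor_window is None:
            raise ValueError("not an MS2 spectrum")
        center, width = self.precursor_window
        return (center - width / 2.0, center + width / 2.0)


@dataclass
class Run:
    """An ordered direct-infusion acquisition of one polarity."""

    spectra: list[Spectrum]
    polarity: Polarity
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [i for i, s in enumerate(self.spectra) if s.polarity is not self.polarity]
        if bad:
            raise ValueError(f"mixed polarity in run: scan indices {bad}")

    def ms1_scans(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_scans(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


def dia_window_for(precursor_mz: float, width: float = 1.0) -> tuple[float, float]:
    """The DIA isolation window (center, width) owning a precursor m/z.

    Windows are half-open [k*width, (k+1)*width) with centers at (k+0.5)*width,
    so every precursor belongs to exactly one window.
    """
    k = np.floor(precursor_mz / width)
    return ((k + 0.5) * width, width)


# ---------------------------------------------------------------------------
# mzML writing (minimal, uncompressed 64-bit floats)

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent: ET.Element, accession: str, name: str, value: str = "",
        unit: tuple[str, str, str] | None = None) -> None:
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit:
        attrib.update(unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2])
    ET.SubElement(parent, "cvParam", attrib)


_MZ_UNIT = ("MS", "MS:1000040", "m/z")


def _binary_array(parent: ET.Element, data: np.ndarray, kind: str) -> None:
    payload = base64.b64encode(np.asarray(data, dtype="<f8").tobytes()).decode("ascii")
    arr = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(payload))})
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(arr, "MS:1000514", "m/z array", unit=_MZ_UNIT)
    else:
        _cv(arr, "MS:1000515", "intensity array",
            unit=("MS", "MS:1000131", "number of detector counts"))
    ET.SubElement(arr, "binary").text = payload


def write_run(run: Run, path: str | Path) -> None:
    """Write a run as centroid mzML with precursor isolation windows recorded."""
    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    cvlist = ET.SubElement(root, "cvList", {"count": "1"})
    ET.SubElement(cvlist, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    run_el = ET.SubElement(root, "run", {"id": str(run.metadata.get("id", "run"))})
    slist = ET.SubElement(run_el, "spectrumList", {"count": str(len(run.spectra))})
    for i, s in enumerate(run.spectra):
        sp = ET.SubElement(slist, "spectrum", {
            "index": str(i), "id": f"scan={i + 1}", "defaultArrayLength": str(len(s.mz))})
        _cv(sp, "MS:1000511", "ms level", str(s.ms_level))
        _cv(sp, "MS:1000579" if s.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        if s.polarity is Polarity.POSITIVE:
            _cv(sp, "MS:1000130", "positive scan")
        else:
            _cv(sp, "MS:1000129", "negative scan")
        scan_list = ET.SubElement(sp, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        swl = ET.SubElement(scan, "scanWindowList", {"count": "1"})
        sw = ET.SubElement(swl, "scanWindow")
        _cv(sw, "MS:1000501", "scan window lower limit", f"{s.scan_range[0]:.6f}", unit=_MZ_UNIT)
        _cv(sw, "MS:1000500", "scan window upper limit", f"{s.scan_range[1]:.6f}", unit=_MZ_UNIT)
        if s.ms_level == 2:
            center, width = s.precursor_window
            plist = ET.SubElement(sp, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", f"{center:.6f}", unit=_MZ_UNIT)
            _cv(iso, "MS:1000828", "isolation window lower offset", f"{width / 2:.6f}", unit=_MZ_UNIT)
            _cv(iso, "MS:1000829", "isolation window upper offset", f"{width / 2:.6f}", unit=_MZ_UNIT)
        arrs = ET.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrs, s.mz, "mz")
        _binary_array(arrs, s.intensity, "intensity")
    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# mzML reading

def _centroid_profile(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum picking with 3-point parabolic apex interpolation."""
    if len(mz) < 3:
        return mz, intensity
    keep_mz, keep_int = [], []
    for i in range(1, len(mz) - 1):
        y0, y1, y2 = intensity[i - 1], intensity[i], intensity[i + 1]
        if y1 > 0 and y1 >= y0 and y1 >= y2 and (y1 > y0 or y1 > y2):
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                step = (mz[i + 1] - mz[i - 1]) / 2.0
                keep_mz.append(mz[i] + delta * step)
            else:
                keep_mz.append(mz[i])
            keep_int.append(y1)
    return np.asarray(keep_mz), np.asarray(keep_int)


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(el: ET.Element) -> dict[str, str]:
    """Accession -> value for the direct cvParam children of an element."""
    return {c.get("accession"): c.get("value", "")
            for c in el if _strip(c.tag) == "cvParam"}


def _find(el: ET.Element, *path: str) -> ET.Element | None:
    cur = el
    for name in path:
        nxt = next((c for c in cur if _strip(c.tag) == name), None)
        if nxt is None:
            return None
        cur = nxt
    return cur


def _decode_array(arr_el: ET.Element) -> tuple[str | None, np.ndarray]:
    cv = _cv_params(arr_el)
    kind = "mz" if "MS:1000514" in cv else "intensity" if "MS:1000515" in cv else None
    binary = _find(arr_el, "binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "MS:1000574" in cv:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in cv else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(sp: ET.Element) -> tuple[Spectrum, Polarity]:
    cv = _cv_params(sp)
    ms_level = int(cv.get("MS:1000511", 1))
    if "MS:1000129" in cv:
        pol = Polarity.NEGATIVE
    elif "MS:1000130" in cv:
        pol = Polarity.POSITIVE
    else:
        raise ValueError(f"scan {sp.get('id')!r}: polarity not recorded")
    mz = inten = np.empty(0)
    arr_list = _find(sp, "binaryDataArrayList")
    if arr_list is not None:
        for arr_el in arr_list:
            kind, data = _decode_array(arr_el)
            if kind == "mz":
                mz = data
            elif kind == "intensity":
                inten = data
    if "MS:1000128" in cv:  # profile spectrum
        warnings.warn("profile spectrum encountered; centroiding by local maxima")
        mz, inten = _centroid_profile(mz, inten)
    lo = hi = None
    sw = _find(sp, "scanList", "scan", "scanWindowList", "scanWindow")
    if sw is not None:
        sw_cv = _cv_params(sw)
        if "MS:1000501" in sw_cv and "MS:1000500" in sw_cv:
            lo, hi = float(sw_cv["MS:1000501"]), float(sw_cv["MS:1000500"])
    if lo is None:
        lo = float(mz.min()) if len(mz) else 0.0
        hi = float(mz.max()) + 1.0 if len(mz) else 1.0
    window = None
    if ms_level >= 2:
        iso = _find(sp, "precursorList", "precursor", "isolationWindow")
        if iso is None:
            raise ValueError(f"MS2 scan {sp.get('id')!r} lacks an isolation window")
        iso_cv = _cv_params(iso)
        center = float(iso_cv["MS:1000827"])
        width = (float(iso_cv.get("MS:1000828", 0.5)) + float(iso_cv.get("MS:1000829", 0.5)))
        window = (center, width)
    return Spectrum(min(ms_level, 2), pol, (lo, hi), mz, inten, window), pol


def read_run(path: str | Path) -> Run:
    """Read a centroided direct-infusion mzML file (plain or indexed).

    Profile spectra are centroided by local-maximum picking with a warning.
    Mixed polarity in one file is an error listing the offending scan indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"corrupt mzML file {path}: {exc}") from exc
    if _strip(root.tag) == "indexedmzML":
        root = next((c for c in root if _strip(c.tag) == "mzML"), root)
    slist = _find(root, "run", "spectrumList")
    spectra: list[Spectrum] = []
    polarities: list[Polarity] = []
    if slist is not None:
        for sp in slist:
            if _strip(sp.tag) != "spectrum":
                continue
            spectrum, pol = _parse_spectrum(sp)
            spectra.append(spectrum)
            polarities.append(pol)
    if not spectra:
        raise ValueError(f"no spectra in {path}")
    majority = max(set(polarities), key=polarities.count)
    bad = [i for i, p in enumerate(polarities) if p is not majority]
    if bad:
        raise ValueError(f"mixed polarity in run: scan indices {bad}")
    return Run(spectra, majority, {"source": str(path)})


# ---------------------------------------------------------------------------
# scan averaging, window selection, peak lookup

def average_scans(scans: Sequence[Spectrum], ppm_tol: float = 3.0) -> Spectrum:
    """Average repeated scans of one window into a single spectrum.

    Peaks are pooled across scans and clustered greedily along m/z, breaking a
    cluster wherever consecutive peaks are further apart than ``ppm_tol``.
    Cluster intensity is the mean over the number of scans (a peak absent from
    a scan counts as zero), cluster m/z the intensity-weighted mean.
    """
    if not scans:
        raise ValueError("no matching scans to average")
    first = scans[0]
    for s in scans[1:]:
        if s.ms_level != first.ms_level or s.precursor_window != first.precursor_window:
            raise ValueError("cannot average scans from different windows")
    n = len(scans)
    all_mz = np.concatenate([s.mz for s in scans]) if n else np.empty(0)
    all_int = np.concatenate([s.intensity for s in scans])
    if len(all_mz) == 0:
        return Spectrum(first.ms_level, first.polarity, first.scan_range,
                        precursor_window=first.precursor_window)
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]
    gaps = np.diff(all_mz) / all_mz[1:] * 1e6
    breaks = np.flatnonzero(gaps > ppm_tol) + 1
    out_mz, out_int = [], []
    for chunk_mz, chunk_int in zip(np.split(all_mz, breaks), np.split(all_int, breaks)):
        total = chunk_int.sum()
        center = float(np.average(chunk_mz, weights=chunk_int)) if total > 0 else float(chunk_mz.mean())
        out_mz.append(center)
        out_int.append(total / n)
    lo = min(s.scan_range[0] for s in scans)
    hi = max(s.scan_range[1] for s in scans)
    return Spectrum(first.ms_level, first.polarity, (lo, hi),
                    np.asarray(out_mz), np.asarray(out_int), first.precursor_window)


def averaged_ms1(run: Run, ppm_tol: float = DEFAULT_MS1_PPM) -> Spectrum:
    """One averaged MS1 spectrum covering the whole acquired precursor range."""
    scans = run.ms1_scans()
    if not scans:
        raise ValueError("run has no MS1 scans")
    # average within each survey window, then concatenate across windows
    by_window: dict[tuple[float, float], list[Spectrum]] = {}
    for s in scans:
        by_window.setdefault(s.scan_range, []).append(s)
    pieces = [average_scans(v, ppm_tol) for v in by_window.values()]
    mz = np.concatenate([p.mz for p in pieces])
    inten = np.concatenate([p.intensity for p in pieces])
    lo = min(s.scan_range[0] for s in scans)
    hi = max(s.scan_range[1] for s in scans)
    return Spectrum(1, run.polarity, (lo, hi), mz, inten)


def ms2_window_for(run: Run, precursor_mz: float, ppm_tol: float = DEFAULT_MS2_PPM) -> Spectrum:
    """The averaged DIA MS2 spectrum whose isolation interval owns a precursor.

    Isolation intervals are half-open [lo, hi): a boundary value belongs to
    the window whose interval starts there.
    """
    matches = [s for s in run.ms2_scans()
               if s.isolation_interval()[0] <= precursor_mz < s.isolation_interval()[1]]
    if not matches:
        raise ValueError(
            f"precursor {precursor_mz:.4f} outside the acquired DIA range")
    return average_scans(matches, ppm_tol)


def find_peak(spectrum: Spectrum, target_mz: float, tol_ppm: float) -> Peak | None:
    """Most intense peak within +-tol_ppm of target; ties go to the closest m/z."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    tol = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz, target_mz - tol, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + tol, side="right")
    if lo == hi:
        return None
    cand_mz = spectrum.mz[lo:hi]
    cand_int = spectrum.intensity[lo:hi]
    best = np.lexsort((np.abs(cand_mz - target_mz), -cand_int))[0]
    return Peak(float(cand_mz[best]), float(cand_int[best]))


# ---------------------------------------------------------------------------
# plain peak-list interchange (two-column TSV)

def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    lines = [f"{m:.6f}\t{i:.6f}" for m, i in zip(spectrum.mz, spectrum.intensity)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_peaklist(path: str | Path, ms_level: int = 1,
                  polarity: Polarity = Polarity.NEGATIVE,
                  precursor_window: tuple[float, float] | None = None) -> Spectrum:
    rows = [ln.split("\t") for ln in Path(path).read_text().splitlines() if ln.strip()]
    mz = np.array([float(r[0]) for r in rows])
    inten = np.array([float(r[1]) for r in rows])
    lo = float(mz.min()) if len(mz) else 0.0
    hi = float(mz.max()) + 1.0 if len(mz) else 1.0
    return Spectrum(ms_level, polarity, (lo, hi), mz, inten, precursor_window)
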