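"""In-memory MS/MS spectrum model and standard-format I/O.

A :class:`Spectrum` is a precursor descriptor plus a peak list. Peak lists are
always stored sorted strictly ascending in m/z: duplicate m/z values are merged
by summing their intensities, and zero-intensity peaks are dropped on
construction, so every downstream window lookup is deterministic.

Reading uses pyteomics (MGF always; mzML optionally, MS2 scans only). Writing
uses a small deterministic MGF writer so that synthetic fixtures are
byte-reproducible for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

from .errors import MGFParseError

__all__ = [
    "Peak",
    "Spectrum",
    "RelativeSpectrum",
    "normalize",
    "read_mgf",
    "read_mzml",
    "write_mgf",
    "write_assignments",
]


@dataclass(frozen=True)
class Peak:
    """One fragment ion: m/z in Thomson, intensity in arbitrary abundance units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


def _clean_peaks(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
    """Drop zero intensities, merge exact duplicate m/z by summing, sort ascending."""
    merged: dict[float, float] = {}
    for p in peaks:
        if p.intensity == 0:
            continue
        merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
    return tuple(Peak(mz, inten) for mz, inten in sorted(merged.items()))


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum: scan identifier, precursor descriptor and peak list.

    Parameters
    ----------
    scan_id
        Unique identifier of the scan within a dataset.
    precursor_mz
        Precursor ion m/z (Th).
    peaks
        Fragment peaks; normalised on construction (sorted, deduplicated,
        zero intensities removed). Must leave at least one peak.
    charge
        Precursor charge, or ``None`` when unknown.
    retention_time
        Retention time in seconds, optional.
    """

    scan_id: str
    precursor_mz: float
    peaks: tuple[Peak, ...]
    charge: int | None = None
    retention_time: float | None = None

    def __post_init__(self) -> None:
        cleaned = _clean_peaks(self.peaks)
        if not cleaned:
            raise ValueError(f"spectrum {self.scan_id!r} has no peak with positive intensity")
        object.__setattr__(self, "peaks", cleaned)

    @classmethod
    def from_arrays(
        cls,
        scan_id: str,
        precursor_mz: float,
        mz: Sequence[float],
        intensity: Sequence[float],
        charge: int | None = None,
        retention_time: float | None = None,
    ) -> "Spectrum":
        if len(mz) != len(intensity):
            raise ValueError("mz and intensity arrays differ in length")
        peaks = tuple(Peak(float(m), float(i)) for m, i in zip(mz, intensity) if i > 0)
        return cls(scan_id, float(precursor_mz), peaks, charge, retention_time)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def tic(self) -> float:
        """Total ion current: sum of peak intensities."""
        return float(sum(p.intensity for p in self.peaks))

    @property
    def base_peak_intensity(self) -> float:
        return float(max(p.intensity for p in self.peaks))


@dataclass(frozen=True)
class RelativeSpectrum(Spectrum):
    """A spectrum whose intensities are percent of the base peak, in (0, 100]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        top = self.base_peak_intensity
        if abs(top - 100.0) > 1e-9:
            raise ValueError(f"relative spectrum base peak must be 100, got {top}")


def normalize(spectrum: Spectrum) -> RelativeSpectrum:
    """Rescale intensities to percent of the base peak.

    Idempotent on an already-normalized spectrum. Raises ``ValueError`` when
    no peak has positive intensity (impossible for a valid :class:`Spectrum`).
    """
    top = spectrum.base_peak_intensity
    peaks = tuple(Peak(p.mz, p.intensity / top * 100.0) for p in spectrum.peaks)
    return RelativeSpectrum(
        spectrum.scan_id,
        spectrum.precursor_mz,
        peaks,
        spectrum.charge,
        spectrum.retention_time,
    )


# ---------------------------------------------------------------------------
# MGF reading (pyteomics) and deterministic writing
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    The scan identifier is taken from ``SCANS`` if present, else ``TITLE``,
    else the 1-based block index. The precursor m/z is the first ``PEPMASS``
    field (an optional intensity second field is tolerated, as are unknown
    headers). Zero-intensity peaks are dropped.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        it = iter(reader)
        index = 0
        while True:
            index += 1
            try:
                entry = next(it)
            except StopIteration:
                break
            except Exception as exc:  # malformed peak line, bad header, ...
                raise MGFParseError(f"{path.name}: cannot parse spectrum block {index}: {exc}") from exc
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MGFParseError(f"{path.name}: spectrum block {index} has no PEPMASS")
            precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)

            scans = params.get("scans")
            title = params.get("title")
            if scans is not None and str(scans).strip():
                scan_id = str(scans).strip()
            elif title is not None and str(title).strip():
                scan_id = str(title).strip()
            else:
                scan_id = str(index)

            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else None
            rt = params.get("rtinseconds")
            rt = float(rt) if rt is not None else None

            mz = entry.get("m/z array")
            inten = entry.get("intensity array")
            if mz is None or inten is None or len(mz) == 0 or not np.any(np.asarray(inten) > 0):
                raise MGFParseError(
                    f"{path.name}: spectrum block {index} ({scan_id}) has no peaks with positive intensity"
                )
            spectra.append(
                Spectrum.from_arrays(scan_id, precursor_mz, mz, inten, charge=charge, retention_time=rt)
            )
    if not spectra:
        warnings.warn(f"{path.name}: no spectra found", stacklevel=2)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed 6-decimal formatting (byte-deterministic)."""
    path = Path(path)
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.scan_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        if s.charge is not None:
            sign = "+" if s.charge >= 0 else "-"
            lines.append(f"CHARGE={abs(s.charge)}{sign}")
        lines.append(f"SCANS={s.scan_id}")
        if s.retention_time is not None:
            lines.append(f"RTINSECONDS={s.retention_time:.3f}")
        for p in s.peaks:
            lines.append(f"{p.mz:.6f} {p.intensity:.6f}")
        lines.append("END IONS")
        lines.append("")
    path.write_text("\n".join(lines))


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read MS2 scans (those with a selected precursor) from an mzML file.

    All other content — MS1 scans, chromatograms, instrument metadata — is
    ignored; the classification pipeline consumes MS2-level spectra only.
    """
    from pyteomics import mzml as _pymzml

    path = Path(path)
    spectra: list[Spectrum] = []
    with _pymzml.MzML(str(path)) as reader:
        for index, entry in enumerate(reader, start=1):
            if entry.get("ms level") != 2:
                continue
            try:
                precursor = entry["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                precursor_mz = float(ion["selected ion m/z"])
                charge = ion.get("charge state")
                charge = int(charge) if charge is not None else None
            except (KeyError, IndexError):
                continue
            scan_id = str(entry.get("id", index))
            mz = entry.get("m/z array")
            inten = entry.get("intensity array")
            if mz is None or len(mz) == 0 or not np.any(np.asarray(inten) > 0):
                continue
            rt = None
            scan_list = entry.get("scanList", {}).get("scan", [])
            if scan_list and "scan start time" in scan_list[0]:
                rt = float(scan_list[0]["scan start time"]) * 60.0  # minutes → seconds
            spectra.append(
                Spectrum.from_arrays(scan_id, precursor_mz, mz, inten, charge=charge, retention_time=rt)
            )
    return spectra


# ---------------------------------------------------------------------------
# Assignment table output
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = [
    "scan_id",
    "precursor_mz",
    "tree_name",
    "node_path",
    "terminal_bin",
    "ambiguous",
    "matched_bins",
]


def write_assignments(assignments: Iterable, path: str | Path) -> pd.DataFrame:
    """Write bin assignments as a TSV; ambiguous scans get one row per matched bin.

    Returns the DataFrame that was written (handy for logging and tests).
    """
    rows = []
    for a in assignments:
        matched = ";".join(a.matched_bins)
        if a.ambiguous:
            for leaf, leaf_path in zip(a.matched_bins, a.matched_paths):
                rows.append(
                    {
                        "scan_id": a.scan_id,
                        "precursor_mz": a.precursor_mz,
                        "tree_name": a.tree_name,
                        "node_path": ">".join(leaf_path),
                        "terminal_bin": leaf,
                        "ambiguous": True,
                        "matched_bins": matched,
                    }
                )
        else:
            rows.append(
                {
                    "scan_id": a.scan_id,
                    "precursor_mz": a.precursor_mz,
                    "tree_name": a.tree_name,
                    "node_path": ">".join(a.node_path),
                    "terminal_bin": a.terminal_bin or "",
                    "ambiguous": False,
                    "matched_bins": matched,
                }
            )
    frame = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return frame
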