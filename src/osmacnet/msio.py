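"""MGF spectrum I/O, sample metadata, and global background-intensity correction.

MS/MS scans are exchanged as Mascot generic format (MGF) files, one
``BEGIN IONS``/``END IONS`` block per scan, parsed and written through
:mod:`pyteomics.mgf`.  Retention times are normalised to minutes on read.
Sample metadata (which extract came from which strain, activator, medium and
clone) travels as a separate CSV keyed by ``extract_id``; the MGF ``TITLE``
carries ``extract_id::scan_index``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

logger = logging.getLogger(__name__)

#: Default global background-correction threshold (arbitrary intensity counts).
DEFAULT_BACKGROUND_INTENSITY = 1000.0

METADATA_COLUMNS = ["strain_id", "activator", "media_id", "clone_id", "origin", "extract_id"]

ACTIVATORS = ("WT", "AdpA", "Crp", "SarA", "FAS", "RedD", "other")


class MGFParseError(ValueError):
    """Raised when an MGF block cannot be interpreted as a spectrum."""


class Peak(NamedTuple):
    """A single centroided fragment peak."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class ExtractMeta:
    """Provenance of one fermentation extract.

    ``activator`` is ``"WT"`` for the unedited parent strain and the name of
    the overexpressed regulator/flux gene otherwise.
    """

    extract_id: str
    strain_id: str
    activator: str
    media_id: str
    clone_id: str
    origin: str = "terrestrial"

    @property
    def is_wildtype(self) -> bool:
        return self.activator == "WT"


@dataclass
class Spectrum:
    """One MS/MS scan: precursor, retention time and a sorted peak list.

    Peaks are stored as parallel numpy arrays sorted by ascending m/z;
    duplicated m/z values are kept as distinct entries.
    """

    spectrum_id: str
    precursor_mz: float
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    extract_id: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if np.any(self.mz <= 0):
            raise ValueError("peak m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        if not np.all(np.diff(self.mz) >= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Total ion current: the sum of fragment peak intensities."""
        return float(self.intensity.sum())

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    def with_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Spectrum":
        return replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    RT is taken from ``RTINSECONDS`` (divided by 60) or ``RTINMINUTES``;
    a missing ``CHARGE`` defaults to 1.  A block without ``PEPMASS`` raises
    :class:`MGFParseError` naming the block index.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MGFParseError(f"{path.name}: block {i} lacks a PEPMASS line")
            precursor_mz = float(pepmass[0])
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            elif "rtinminutes" in params:
                rt = float(params["rtinminutes"])
            else:
                rt = 0.0
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 1
            title = str(params.get("title", f"scan_{i}"))
            extract_id = title.split("::", 1)[0] if "::" in title else None
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor_mz,
                    rt=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    charge=charge,
                    extract_id=extract_id,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (RT emitted as RTINSECONDS; TITLE = spectrum_id)."""
    records = []
    for s in spectra:
        records.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt * 60.0,
                    "charge": s.charge,
                },
            }
        )
    _pymgf.write(records, str(path), file_mode="w")


def background_filter(
    spectra: Sequence[Spectrum], min_intensity: float = DEFAULT_BACKGROUND_INTENSITY
) -> list[Spectrum]:
    """Remove fragment peaks below ``min_intensity`` (global background correction).

    Peaks with intensity >= ``min_intensity`` are kept (a peak exactly at the
    threshold survives).  Spectra whose peak list empties are dropped and the
    count is logged.
    """
    if min_intensity < 0:
        raise ValueError(f"min_intensity must be >= 0, got {min_intensity}")
    kept: list[Spectrum] = []
    n_dropped = 0
    for s in spectra:
        mask = s.intensity >= min_intensity
        if not mask.any():
            n_dropped += 1
            continue
        kept.append(s if mask.all() else s.with_peaks(s.mz[mask], s.intensity[mask]))
    if n_dropped:
        logger.info(
            "background_filter: dropped %d spectra emptied at intensity threshold %g",
            n_dropped,
            min_intensity,
        )
    return kept


def read_metadata(path: str | Path) -> dict[str, ExtractMeta]:
    """Read the extract-metadata CSV into a mapping extract_id -> ExtractMeta."""
    df = pd.read_csv(path, dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {sorted(missing)}")
    meta: dict[str, ExtractMeta] = {}
    for row in df.itertuples(index=False):
        m = ExtractMeta(
            extract_id=row.extract_id,
            strain_id=row.strain_id,
            activator=row.activator,
            media_id=row.media_id,
            clone_id=row.clone_id,
            origin=row.origin,
        )
        if m.extract_id in meta:
            raise ValueError(f"duplicate extract_id {m.extract_id!r} in metadata")
        meta[m.extract_id] = m
    return meta


def write_metadata(meta: Iterable[ExtractMeta], path: str | Path) -> None:
    rows = [
        {
            "strain_id": m.strain_id,
            "activator": m.activator,
            "media_id": m.media_id,
            "clone_id": m.clone_id,
            "origin": m.origin,
            "extract_id": m.extract_id,
        }
        for m in meta
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)
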