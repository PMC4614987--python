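"""Packaged raw measurement tables and tabular I/O for chamber series.

The package ships, as plain CSV, the published per-specimen metadata
(taxon, maturity, sex, maximum conch diameter, chamber count) and the
per-chamber volume/width series for two Jurassic *Normannites mitis*
ammonites (volumes in mm^3) and modern *Nautilus pompilius* conchs
(volumes in ml).  Only the specimen columns that appear in the published
raw-data tables are embedded; the *Nautilus* volume table covers
specimens 7, 8, 10, 11, 12, 15, 16, 17, 20 and 23, and widths are
published for specimens 7, 8 and 53 only.

Values are stored verbatim in the unit of the source table.  Dashes in
the printed tables become missing markers (NaN); nothing is imputed.
File checksums are pinned so the embedded tables cannot drift.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SpecimenRecord",
    "ChamberSeries",
    "FixtureIntegrityError",
    "SeriesParseError",
    "UnknownSpecimenError",
    "MM3_PER_ML",
    "ARTIFACT_CHAMBERS",
    "load_specimens",
    "load_series",
    "list_series_ids",
    "read_series",
    "read_series_table",
    "write_series",
    "validate_against_specimen",
]

#: conversion constant, applied only on explicit request
MM3_PER_ML = 1000.0

#: chambers flagged in the source as probable segmentation artefacts
#: (anomalously large early-chamber volumes in Nautilus specimen 17)
ARTIFACT_CHAMBERS: Mapping[str, tuple[int, ...]] = {"17": (5, 6)}

_SERIES_COLUMNS = ["specimen_id", "chamber", "volume", "volume_unit", "width_mm"]

# sha256 of the packaged CSVs, pinned against accidental edits
_EXPECTED_SHA256 = {
    "specimens.csv": "9d2ed36b46713586bf3c327906c13c54e011186f79e061ff9b2abb7ad336278c",
    "chamber_series.csv": "25b1e4b58197fbc15b72b622fc0273fb23c92cf786cc3de389e54fa3ab8e90dd",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its pinned checksum."""


class SeriesParseError(ValueError):
    """A chamber-series file is malformed; the message names the line."""


class UnknownSpecimenError(KeyError):
    """Requested specimen is not present in the fixture set."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One row of the specimen metadata table."""

    specimen_id: str
    taxon: str
    maturity: str  # "mature" | "immature"
    sex: str  # "male" | "female" | "indeterminate"
    max_diameter_mm: float
    n_chambers: int
    #: True for "60?"-style counts printed with a question mark
    n_chambers_uncertain: bool = False

    def __post_init__(self) -> None:
        if self.max_diameter_mm <= 0:
            raise ValueError(f"max_diameter_mm must be > 0, got {self.max_diameter_mm}")
        if self.n_chambers < 1:
            raise ValueError(f"n_chambers must be >= 1, got {self.n_chambers}")
        if self.maturity not in ("mature", "immature"):
            raise ValueError(f"unknown maturity {self.maturity!r}")
        if self.sex not in ("male", "female", "indeterminate"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class ChamberSeries:
    """Ordered per-chamber measurements for one specimen.

    Chambers are numbered 1-based from the first chamber (protoconch);
    a series may begin at an index greater than 1 when early chambers
    were not measurable.  Missing measurements are NaN.
    """

    specimen_id: str
    volume_unit: str  # "mm3" | "ml"
    chambers: np.ndarray
    volumes: np.ndarray
    widths_mm: np.ndarray

    def __post_init__(self) -> None:
        self.chambers = np.asarray(self.chambers, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.widths_mm = np.asarray(self.widths_mm, dtype=float)
        if self.volume_unit not in ("mm3", "ml"):
            raise ValueError(f"volume_unit must be 'mm3' or 'ml', got {self.volume_unit!r}")
        if not (len(self.chambers) == len(self.volumes) == len(self.widths_mm)):
            raise ValueError("chambers, volumes and widths_mm must have equal length")
        if len(self.chambers) and np.any(np.diff(self.chambers) <= 0):
            raise ValueError(f"{self.specimen_id}: chamber indices must be strictly increasing")
        if len(self.chambers) and self.chambers[0] < 1:
            raise ValueError("chamber numbering is 1-based")
        present = ~np.isnan(self.volumes)
        if np.any(self.volumes[present] <= 0):
            raise ValueError(f"{self.specimen_id}: all present volumes must be > 0")
        wpresent = ~np.isnan(self.widths_mm)
        if np.any(self.widths_mm[wpresent] <= 0):
            raise ValueError(f"{self.specimen_id}: all present widths must be > 0")

    def __len__(self) -> int:
        return len(self.chambers)

    @property
    def volume_mask(self) -> np.ndarray:
        return ~np.isnan(self.volumes)

    def volume_at(self, chamber: int) -> float:
        idx = np.nonzero(self.chambers == chamber)[0]
        if not len(idx):
            raise KeyError(f"chamber {chamber} not in series {self.specimen_id}")
        return float(self.volumes[idx[0]])

    def volumes_mm3(self) -> np.ndarray:
        """Volumes converted to mm^3 (explicit unit conversion)."""
        if self.volume_unit == "mm3":
            return self.volumes.copy()
        return self.volumes * MM3_PER_ML

    def total_volume(self) -> float:
        """Sum of present chamber volumes, in the series unit."""
        return float(np.nansum(self.volumes))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "specimen_id": self.specimen_id,
                "chamber": self.chambers,
                "volume": self.volumes,
                "volume_unit": self.volume_unit,
                "width_mm": self.widths_mm,
            }
        )


def _data_path(name: str) -> Path:
    return Path(str(files("phragmovol").joinpath("data", name)))


def _checked_bytes(name: str) -> bytes:
    raw = _data_path(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _EXPECTED_SHA256[name]
    if digest != expected:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} does not match pinned {expected}; "
            "the packaged table has been modified"
        )
    return raw


def load_specimens() -> list[SpecimenRecord]:
    """All specimen metadata rows (2 ammonites + 30 Nautilus), verbatim."""
    raw = _checked_bytes("specimens.csv").decode("utf-8").splitlines()
    out = []
    for row in csv.DictReader(raw):
        out.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                taxon=row["taxon"],
                maturity=row["maturity"],
                sex=row["sex"],
                max_diameter_mm=float(row["max_diameter_mm"]),
                n_chambers=int(row["n_chambers"]),
                n_chambers_uncertain=row["n_chambers_uncertain"] == "yes",
            )
        )
    return out


def _parse_series_rows(lines: Iterable[str], source: str) -> dict[str, ChamberSeries]:
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise SeriesParseError(f"{source}: empty file") from None
    if header != _SERIES_COLUMNS:
        raise SeriesParseError(
            f"{source}, line 1: expected header {','.join(_SERIES_COLUMNS)!r}, "
            f"got {','.join(header)!r}"
        )
    acc: dict[str, dict[str, list]] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c for c in row):
            continue
        if len(row) != len(_SERIES_COLUMNS):
            raise SeriesParseError(
                f"{source}, line {lineno}: expected {len(_SERIES_COLUMNS)} fields, got {len(row)}"
            )
        sid, ch_s, vol_s, unit, wid_s = row
        try:
            ch = int(ch_s)
            vol = float(vol_s) if vol_s != "" else math.nan
            wid = float(wid_s) if wid_s != "" else math.nan
        except ValueError as exc:
            raise SeriesParseError(f"{source}, line {lineno}: {exc}") from None
        rec = acc.setdefault(sid, {"unit": unit, "ch": [], "vol": [], "wid": []})
        if unit != rec["unit"]:
            raise SeriesParseError(
                f"{source}, line {lineno}: specimen {sid} mixes volume units "
                f"{rec['unit']!r} and {unit!r}"
            )
        rec["ch"].append(ch)
        rec["vol"].append(vol)
        rec["wid"].append(wid)
    out = {}
    for sid, rec in acc.items():
        try:
            out[sid] = ChamberSeries(
                specimen_id=sid,
                volume_unit=rec["unit"],
                chambers=np.array(rec["ch"]),
                volumes=np.array(rec["vol"]),
                widths_mm=np.array(rec["wid"]),
            )
        except ValueError as exc:
            raise SeriesParseError(f"{source}: specimen {sid}: {exc}") from None
    return out


_SERIES_CACHE: dict[str, ChamberSeries] | None = None


def _fixture_series() -> dict[str, ChamberSeries]:
    global _SERIES_CACHE
    if _SERIES_CACHE is None:
        lines = _checked_bytes("chamber_series.csv").decode("utf-8").splitlines()
        _SERIES_CACHE = _parse_series_rows(lines, "chamber_series.csv")
    return _SERIES_CACHE


def list_series_ids() -> list[str]:
    """Specimen ids that have a packaged chamber series."""
    return sorted(_fixture_series(), key=lambda s: (s.startswith("Nm"), s.zfill(4)))


def load_series(specimen_id: str, exclude_artifacts: bool = False) -> ChamberSeries:
    """The packaged chamber series for one specimen, values verbatim.

    With ``exclude_artifacts=True`` the chambers flagged as probable
    segmentation artefacts (see :data:`ARTIFACT_CHAMBERS`) are masked to
    missing.  Default is off: the source tables keep those values and do
    not state that they were excluded from any statistic.
    """
    table = _fixture_series()
    if specimen_id not in table:
        raise UnknownSpecimenError(
            f"no packaged series for specimen {specimen_id!r}; "
            f"available: {', '.join(list_series_ids())}"
        )
    series = table[specimen_id]
    series = replace(
        series,
        chambers=series.chambers.copy(),
        volumes=series.volumes.copy(),
        widths_mm=series.widths_mm.copy(),
    )
    if exclude_artifacts and specimen_id in ARTIFACT_CHAMBERS:
        mask = np.isin(series.chambers, ARTIFACT_CHAMBERS[specimen_id])
        series.volumes[mask] = np.nan
    return series


def read_series_table(path: str | Path) -> dict[str, ChamberSeries]:
    """Read a chamber-series CSV that may hold several specimens."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_series_rows(fh, str(path))


def read_series(path: str | Path) -> ChamberSeries:
    """Read a chamber-series CSV holding exactly one specimen."""
    table = read_series_table(path)
    if len(table) != 1:
        raise SeriesParseError(
            f"{path}: expected a single specimen, found {sorted(table)}"
        )
    return next(iter(table.values()))


def _cell(x: float) -> str:
    if math.isnan(x):
        return ""
    return repr(float(x))  # shortest exact representation; round-trips


def write_series(series: ChamberSeries | Iterable[ChamberSeries], path: str | Path) -> None:
    """Write one or more series in the CSV schema used throughout.

    ``write_series`` then :func:`read_series` is the identity, including
    missing markers and the unit field.
    """
    if isinstance(series, ChamberSeries):
        series = [series]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_SERIES_COLUMNS)
        for s in series:
            for ch, vol, wid in zip(s.chambers, s.volumes, s.widths_mm):
                w.writerow([s.specimen_id, int(ch), _cell(vol), s.volume_unit, _cell(wid)])


def validate_against_specimen(series: ChamberSeries, record: SpecimenRecord) -> list[str]:
    """Cross-check a series against its metadata row.

    Returns human-readable discrepancy flags (empty list = consistent);
    nothing is silently fixed.
    """
    flags = []
    if series.specimen_id != record.specimen_id:
        flags.append(
            f"series id {series.specimen_id!r} != record id {record.specimen_id!r}"
        )
    if len(series.chambers) and int(series.chambers[-1]) > record.n_chambers:
        flags.append(
            f"last measured chamber {int(series.chambers[-1])} exceeds recorded "
            f"chamber count {record.n_chambers}"
            + (" (count uncertain)" if record.n_chambers_uncertain else "")
        )
    return flags
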