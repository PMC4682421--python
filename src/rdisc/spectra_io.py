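"""Data model and on-disk formats for full and discrete Raman spectra.

Two plain-text formats are supported:

* **Full spectrum** — two whitespace- or tab-separated columns
  (Raman shift in cm^-1, intensity in arbitrary units), ``#`` comment
  lines, ``.`` decimal separator.  This matches common spectrometer
  CSV/TXT exports.

* **rDisc v1** — the discrete-spectrum record.  Each data row is one
  representative peak (shift position, intensity, curvature); the header
  records the number of channels of the originating full spectrum so
  compression ratios are computable from the discrete file alone::

      # rDisc v1
      # n_shifts: 2048
      # <key>: <value>          (optional metadata)
      shift_cm1	intensity	curvature
      1002.5	0.731	0.0042
      ...
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, FormatError

__all__ = [
    "RamanSpectrum",
    "Peak",
    "DiscreteSpectrum",
    "read_spectrum",
    "write_spectrum",
    "read_rdisc",
    "write_rdisc",
]

RDISC_MAGIC = "# rDisc v1"
RDISC_HEADER = "shift_cm1\tintensity\tcurvature"


@dataclass
class RamanSpectrum:
    """A full continuous Raman spectrum on a strictly increasing shift grid.

    Parameters
    ----------
    shifts
        Raman shift axis in cm^-1, strictly increasing, length >= 3.
    intensities
        One intensity value (arbitrary units) per shift.
    meta
        Free-form string metadata (cell id, species label, processing stage).
    """

    shifts: np.ndarray
    intensities: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise DataError("shifts and intensities must be 1-D arrays")
        if len(self.shifts) != len(self.intensities):
            raise DataError(
                f"length mismatch: {len(self.shifts)} shifts vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.shifts) < 3:
            raise DataError(f"spectrum needs >= 3 channels, got {len(self.shifts)}")
        if not (np.all(np.isfinite(self.shifts)) and np.all(np.isfinite(self.intensities))):
            raise DataError("non-finite value in spectrum")
        d = np.diff(self.shifts)
        if np.any(d == 0):
            raise DataError("duplicate shift values")
        if np.any(d < 0):
            raise DataError("shifts not strictly increasing")

    def __len__(self) -> int:
        return len(self.shifts)

    def replace(self, intensities: np.ndarray, **meta: str) -> "RamanSpectrum":
        """Return a copy on the same grid with new intensities and merged meta."""
        return RamanSpectrum(self.shifts.copy(), np.asarray(intensities, float), {**self.meta, **meta})


@dataclass(frozen=True)
class Peak:
    """A representative peak: position (cm^-1), intensity and curvature at its apex."""

    position: float
    intensity: float
    curvature: float

    def __post_init__(self) -> None:
        for name in ("position", "intensity", "curvature"):
            if not np.isfinite(getattr(self, name)):
                raise DataError(f"peak {name} is not finite")
        if self.curvature < 0:
            raise DataError("peak curvature must be >= 0")


@dataclass
class DiscreteSpectrum:
    """An ordered list of representative peaks — the rDisc record.

    ``n_source_shifts`` is the channel count of the full spectrum the peaks
    were selected from; it makes the condensation ratio computable from the
    discrete record alone.
    """

    peaks: list[Peak]
    n_source_shifts: int
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = list(self.peaks)
        if self.n_source_shifts < 0:
            raise DataError("n_source_shifts must be non-negative")
        if len(self.peaks) > self.n_source_shifts:
            raise DataError("more peaks than source channels")
        pos = [p.position for p in self.peaks]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise DataError("peak positions not strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


def _parse_meta_line(line: str) -> tuple[str, str] | None:
    body = line[1:].strip()
    if ":" in body:
        key, _, value = body.partition(":")
        return key.strip(), value.strip()
    return None


def read_spectrum(path: str | os.PathLike, dialect: str | None = None) -> RamanSpectrum:
    """Read a two-column (shift, intensity) text file.

    Rows are sorted by shift if not already ascending.  ``dialect`` is an
    optional explicit field delimiter; by default any run of whitespace
    separates the two columns.  ``#`` lines are treated as comments;
    ``# key: value`` comments populate ``meta``.

    Raises
    ------
    FormatError
        On an unparseable row (the message names the line number).
    DataError
        On duplicate shift values or fewer than 3 data rows.
    """
    shifts: list[float] = []
    intens: list[float] = []
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                kv = _parse_meta_line(line)
                if kv:
                    meta[kv[0]] = kv[1]
                continue
            fields = line.split(dialect) if dialect else line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            try:
                shifts.append(float(fields[0]))
                intens.append(float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if len(shifts) < 3:
        raise DataError(f"{path}: fewer than 3 data rows ({len(shifts)})")
    s = np.array(shifts)
    y = np.array(intens)
    if len(np.unique(s)) != len(s):
        raise DataError(f"{path}: duplicate shift values")
    order = np.argsort(s)
    meta.setdefault("source", str(path))
    return RamanSpectrum(s[order], y[order], meta)


def write_spectrum(s: RamanSpectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as tab-separated two-column text with ``#`` meta lines.

    Values are written with :func:`repr`-level precision so that
    ``read_spectrum(write_spectrum(s))`` reproduces the arrays exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in s.meta.items():
            fh.write(f"# {key}: {value}\n")
        for x, y in zip(s.shifts, s.intensities):
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def write_rdisc(d: DiscreteSpectrum, path: str | os.PathLike) -> None:
    """Write a discrete spectrum in rDisc v1 format (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(RDISC_MAGIC + "\n")
        fh.write(f"# n_shifts: {d.n_source_shifts}\n")
        for key, value in d.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(RDISC_HEADER + "\n")
        for p in d.peaks:
            fh.write(f"{float(p.position)!r}\t{float(p.intensity)!r}\t{float(p.curvature)!r}\n")


def read_rdisc(path: str | os.PathLike) -> DiscreteSpectrum:
    """Read an rDisc v1 file.

    Raises
    ------
    FormatError
        Missing magic line, missing ``n_shifts`` header, or a malformed row.
    DataError
        Non-increasing peak positions.
    """
    n_shifts: int | None = None
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != RDISC_MAGIC:
        raise FormatError(f"{path}: not an rDisc v1 file (missing '{RDISC_MAGIC}')")
    seen_header = False
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            kv = _parse_meta_line(line)
            if kv is None:
                continue
            key, value = kv
            if key == "n_shifts":
                try:
                    n_shifts = int(value)
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: bad n_shifts {value!r}") from exc
            else:
                meta[key] = value
            continue
        if line == RDISC_HEADER or line.split() == RDISC_HEADER.split():
            seen_header = True
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
        try:
            peaks.append(Peak(float(fields[0]), float(fields[1]), float(fields[2])))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if n_shifts is None:
        raise FormatError(f"{path}: missing '# n_shifts:' header")
    if not seen_header:
        raise FormatError(f"{path}: missing column header line")
    return DiscreteSpectrum(peaks, n_shifts, meta)
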