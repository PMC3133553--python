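"""Domain types and I/O for GCxGC-MS peak lists.

A peak list is the tabular reduction of one GCxGC-TOF-MS run: one record per
detected compound peak, carrying the two retention times (seconds on the
primary column, seconds within the modulation window on the secondary column),
a fragment-ion mass spectrum on integer m/z bins, and optionally a compound
label (ground-truth identity) and a peak area.

The CSV dialect used throughout is ``name,rt1,rt2,area,spectrum`` where
``spectrum`` is a space-separated list of ``mz:intensity`` tokens; empty
fields denote missing optional values.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "Peak",
    "PeakList",
    "order_peaklist",
    "dedupe_largest_area",
    "read_peaklist",
    "write_peaklist",
]


class PeakListError(ValueError):
    """Raised for invalid peak-list content or malformed peak-list files."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MassSpectrum:
    """Fragment-ion mass spectrum on integer (nominal-mass) m/z bins.

    ``mz`` must be strictly increasing non-negative integers and
    ``intensity`` non-negative with at least one positive entry.
    """

    mz: tuple[int, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity) or len(self.mz) == 0:
            raise PeakListError("spectrum needs equal-length, non-empty mz and intensity")
        if any(m < 0 for m in self.mz):
            raise PeakListError("negative m/z bin")
        if any(a >= b for a, b in zip(self.mz, self.mz[1:])):
            raise PeakListError("m/z bins must be strictly increasing")
        if any(v < 0 for v in self.intensity):
            raise PeakListError("negative intensity")
        if not any(v > 0 for v in self.intensity):
            raise PeakListError("spectrum has no positive intensity")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "MassSpectrum":
        """Build a spectrum from (m/z, intensity) pairs.

        Fractional m/z values are rounded half-up to the nominal-mass bin;
        intensities landing in the same bin are summed.
        """
        binned: dict[int, float] = {}
        for mz, inten in pairs:
            if inten < 0:
                raise PeakListError(f"negative intensity {inten} at m/z {mz}")
            b = _round_half_up(float(mz))
            binned[b] = binned.get(b, 0.0) + float(inten)
        mzs = tuple(sorted(binned))
        return cls(mz=mzs, intensity=tuple(binned[m] for m in mzs))

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.mz, self.intensity))


@dataclass(frozen=True)
class Peak:
    """One detected compound peak: retention coordinates plus spectrum."""

    rt1: float
    rt2: float
    spectrum: MassSpectrum
    label: Optional[str] = None
    area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rt1 < 0 or self.rt2 < 0:
            raise PeakListError("retention times must be non-negative")
        if self.area is not None and self.area < 0:
            raise PeakListError("peak area must be non-negative")

    @property
    def rt_sum(self) -> float:
        return self.rt1 + self.rt2


@dataclass
class PeakList:
    """An ordered sequence of peaks from one run (reference X or target Y)."""

    peaks: list[Peak] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def labels(self) -> list[Optional[str]]:
        return [p.label for p in self.peaks]


def order_peaklist(pl: PeakList) -> PeakList:
    """Sort peaks in ascending order of rt1 + rt2 (the combined elution axis).

    Ties break on smaller rt1, then smaller rt2, then original position, so
    the ordering is total and the downstream alignment deterministic.
    Idempotent; raises on an empty list.
    """
    if len(pl) == 0:
        raise PeakListError("empty peak list")
    keyed = sorted(
        enumerate(pl.peaks), key=lambda t: (t[1].rt_sum, t[1].rt1, t[1].rt2, t[0])
    )
    return PeakList(peaks=[p for _, p in keyed], name=pl.name)


def dedupe_largest_area(pl: PeakList) -> PeakList:
    """Resolve multiple peaks carrying the same compound label.

    For each label only the peak with the largest area is kept; unlabeled
    peaks pass through untouched. Relative order of surviving peaks is
    preserved. A duplicated label whose peaks lack areas is an error, since
    there is then no basis for choosing.
    """
    by_label: dict[str, list[int]] = {}
    for idx, p in enumerate(pl.peaks):
        if p.label is not None:
            by_label.setdefault(p.label, []).append(idx)
    drop: set[int] = set()
    for label, idxs in by_label.items():
        if len(idxs) == 1:
            continue
        if any(pl.peaks[i].area is None for i in idxs):
            raise PeakListError(f"duplicate label {label!r} with missing peak area")
        best = max(idxs, key=lambda i: (pl.peaks[i].area, -i))
        drop.update(i for i in idxs if i != best)
    return PeakList(
        peaks=[p for i, p in enumerate(pl.peaks) if i not in drop], name=pl.name
    )


# ---------------------------------------------------------------------------
# I/O

_CSV_HEADER = ["name", "rt1", "rt2", "area", "spectrum"]


def _parse_spectrum_token_string(text: str, lineno: int) -> MassSpectrum:
    pairs = []
    for tok in text.split():
        try:
            mz_s, int_s = tok.split(":")
            mz, inten = float(mz_s), float(int_s)
        except ValueError:
            raise PeakListError(f"line {lineno}: malformed spectrum token {tok!r}")
        if inten < 0:
            raise PeakListError(f"line {lineno}: negative intensity in token {tok!r}")
        pairs.append((mz, inten))
    if not pairs:
        raise PeakListError(f"line {lineno}: empty spectrum")
    try:
        return MassSpectrum.from_pairs(pairs)
    except PeakListError as e:
        raise PeakListError(f"line {lineno}: {e}")


def _read_csv(path: Path, rt1_unit: str) -> PeakList:
    scale = 60.0 if rt1_unit == "min" else 1.0
    peaks: list[Peak] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CSV_HEADER:
            raise PeakListError(
                f"{path}: expected header {','.join(_CSV_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise PeakListError(f"line {lineno}: expected 5 fields, got {len(row)}")
            name, rt1_s, rt2_s, area_s, spec_s = (c.strip() for c in row)
            try:
                rt1 = float(rt1_s) * scale
                rt2 = float(rt2_s)
            except ValueError:
                raise PeakListError(f"line {lineno}: missing or non-numeric rt columns")
            area = float(area_s) if area_s else None
            spectrum = _parse_spectrum_token_string(spec_s, lineno)
            peaks.append(
                Peak(rt1=rt1, rt2=rt2, spectrum=spectrum, label=name or None, area=area)
            )
    return PeakList(peaks=peaks, name=path.stem)


def _read_msp(path: Path, rt_csv: Optional[Path], rt1_unit: str) -> PeakList:
    """Read spectra from a NIST MSP file, retention times from a sidecar CSV.

    The sidecar has header ``name,rt1,rt2,area`` keyed on the MSP ``Name:``
    field. Spectra without a sidecar entry are rejected (a peak needs its
    retention coordinates to be alignable).
    """
    from matchms.importing import load_from_msp

    if rt_csv is None:
        rt_csv = path.with_suffix(".rt.csv")
    scale = 60.0 if rt1_unit == "min" else 1.0
    rts: dict[str, tuple[float, float, Optional[float]]] = {}
    with open(rt_csv, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            area = float(row["area"]) if row.get("area", "").strip() else None
            rts[row["name"].strip()] = (
                float(row["rt1"]) * scale,
                float(row["rt2"]),
                area,
            )
    peaks: list[Peak] = []
    for sp in load_from_msp(str(path), metadata_harmonization=False):
        name = sp.get("compound_name") or sp.get("name")
        if name is None or name not in rts:
            raise PeakListError(f"{path}: no retention-time entry for MSP block {name!r}")
        rt1, rt2, area = rts[name]
        spectrum = MassSpectrum.from_pairs(zip(sp.peaks.mz, sp.peaks.intensities))
        peaks.append(Peak(rt1=rt1, rt2=rt2, spectrum=spectrum, label=name, area=area))
    return PeakList(peaks=peaks, name=path.stem)


def read_peaklist(
    path: str | Path,
    format: Literal["csv", "msp"] = "csv",
    rt_csv: str | Path | None = None,
    rt1_unit: Literal["s", "min"] = "s",
) -> PeakList:
    """Read a peak list from CSV (native dialect) or NIST MSP + sidecar CSV.

    The returned list is *not* ordered or deduplicated; those are explicit
    pipeline steps (:func:`order_peaklist`, :func:`dedupe_largest_area`).
    """
    path = Path(path)
    if not path.exists():
        raise PeakListError(f"no such file: {path}")
    if format == "csv":
        return _read_csv(path, rt1_unit)
    if format == "msp":
        return _read_msp(path, Path(rt_csv) if rt_csv else None, rt1_unit)
    raise PeakListError(f"unknown peak-list format {format!r}")


def _fmt(x: float) -> str:
    return np.format_float_positional(x, precision=9, trim="-")


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write the native CSV dialect; round-trips all fields via read_peaklist."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for p in pl.peaks:
            spec = " ".join(
                f"{m}:{_fmt(v)}" for m, v in zip(p.spectrum.mz, p.spectrum.intensity)
            )
            writer.writerow(
                [
                    p.label or "",
                    _fmt(p.rt1),
                    _fmt(p.rt2),
                    _fmt(p.area) if p.area is not None else "",
                    spec,
                ]
            )
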