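"""Light-source spectral power distributions and catalog coverage reports.

Measured lamp curves are not bundled; named presets synthesize stand-ins
(Planck blackbodies for sun-like/incandescent sources, Gaussian line sets
for LED/CFL-like sources) and user-measured two-column CSVs are read
directly.  Coverage asks, per catalog record, whether the source emits at
least a threshold fraction of its own maximum within a half-band window
around the record's activating wavelength.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.constants import c, h, k

from .catalog import CatalogRecord
from .errors import ValidationError

DEFAULT_COVERAGE_THRESHOLD = 0.05
DEFAULT_HALF_BAND_NM = 10.0
DEFAULT_WATER_WINDOW = (380.0, 750.0)  # conventional visible band, not a paper value


@dataclass(frozen=True)
class LightSpectrum:
    """Relative spectral power distribution on an ascending wavelength grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, float)
        i = np.asarray(self.intensities, float)
        if w.size < 2:
            raise ValidationError("a light spectrum needs at least 2 grid points")
        if w.shape != i.shape:
            raise ValidationError("wavelength and intensity lengths differ")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelength grid must be strictly ascending")
        if np.any(i < 0):
            raise ValidationError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", i)

    @property
    def max_intensity(self) -> float:
        return float(self.intensities.max())


@dataclass(frozen=True)
class RecordCoverage:
    record: CatalogRecord
    covered: bool
    relative_intensity_at_band: float
    status: str  # "covered" | "uncovered" | "out_of_range" | "unevaluable"


@dataclass(frozen=True)
class CoverageReport:
    source_label: str
    threshold: float
    half_band_nm: float
    entries: list[RecordCoverage]
    superfamily_summary: dict[str, float] = field(default_factory=dict)

    def covered_records(self) -> list[RecordCoverage]:
        return [e for e in self.entries if e.covered]

    def uncovered_records(self) -> list[RecordCoverage]:
        return [e for e in self.entries if not e.covered and e.status != "unevaluable"]


@dataclass(frozen=True)
class WaterWindowPartition:
    inside: list[CatalogRecord]
    outside: list[CatalogRecord]
    unevaluable: list[CatalogRecord]


def blackbody_spectrum(
    temperature_K: float,
    grid_nm: Sequence[float] | np.ndarray,
    label: str = "",
    per: str = "wavelength",
) -> LightSpectrum:
    """Planck spectral radiance on a wavelength grid, normalized to max 1.

    ``per="wavelength"`` (default) is B_lambda, whose maximum follows the
    Wien displacement law 2.898e6/T nm.  ``per="frequency"`` evaluates
    B_nu at the same wavelengths; its far-infrared tail falls off much
    more slowly relative to its own peak, which matters when thresholding
    coverage of long-wavelength bands.
    """
    if temperature_K <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature_K}")
    if per not in ("wavelength", "frequency"):
        raise ValidationError(f"per must be 'wavelength' or 'frequency', got {per!r}")
    lam = np.asarray(grid_nm, float) * 1e-9  # to metres
    with np.errstate(over="ignore"):
        if per == "wavelength":
            # B_lambda = 2hc^2 / lam^5 / (exp(hc / lam k T) - 1)
            radiance = (2 * h * c**2 / lam**5) / np.expm1(
                h * c / (lam * k * temperature_K)
            )
        else:
            nu = c / lam
            # B_nu = 2h nu^3 / c^2 / (exp(h nu / k T) - 1)
            radiance = (2 * h * nu**3 / c**2) / np.expm1(
                h * nu / (k * temperature_K)
            )
    radiance = radiance / radiance.max()
    return LightSpectrum(
        wavelengths_nm=np.asarray(grid_nm, float),
        intensities=radiance,
        label=label or f"blackbody {temperature_K:g} K",
    )


def line_spectrum(
    peaks: Sequence[tuple[float, float, float]],
    grid_nm: Sequence[float] | np.ndarray,
    label: str = "",
) -> LightSpectrum:
    """Sum of Gaussian bumps (center nm, sigma nm, height), normalized to max 1.

    An empty peak list yields an all-zero spectrum (allowed, but any
    coverage computed from it is vacuous).
    """
    grid = np.asarray(grid_nm, float)
    total = np.zeros_like(grid)
    for center, width, height in peaks:
        if width <= 0 or height <= 0:
            raise ValidationError(
                f"peak widths and heights must be positive, got ({center}, {width}, {height})"
            )
        total += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    peak_value = total.max()
    if peak_value > 0:
        total = total / peak_value
    return LightSpectrum(wavelengths_nm=grid, intensities=total, label=label or "line spectrum")


# Synthetic stand-ins for common sources; NOT measured data.
_DEFAULT_GRID = np.arange(100.0, 10000.0 + 1, 2.0)
_LED_PEAKS = [(450.0, 10.0, 1.0), (560.0, 50.0, 0.7)]  # blue die + phosphor hump
_CFL_PEAKS = [
    (405.0, 5.0, 0.35),
    (436.0, 5.0, 0.8),
    (546.0, 5.0, 1.0),
    (578.0, 5.0, 0.5),
    (611.0, 5.0, 0.9),
]


def preset_spectrum(name: str, grid_nm: np.ndarray | None = None) -> LightSpectrum:
    """Named synthetic source: sunlike, incandescent, led_fixture, cfl_fixture."""
    grid = _DEFAULT_GRID if grid_nm is None else np.asarray(grid_nm, float)
    if name == "sunlike":
        return blackbody_spectrum(5778.0, grid, label="sunlike (5778 K blackbody)")
    if name == "incandescent":
        return blackbody_spectrum(2700.0, grid, label="incandescent (2700 K blackbody)")
    if name == "led_fixture":
        return line_spectrum(_LED_PEAKS, grid, label="led_fixture (synthetic)")
    if name == "cfl_fixture":
        return line_spectrum(_CFL_PEAKS, grid, label="cfl_fixture (synthetic)")
    from .errors import NotFoundError

    raise NotFoundError(
        f"unknown preset {name!r}; valid: sunlike, incandescent, led_fixture, cfl_fixture"
    )


def read_spectrum_csv(path: str | Path, label: str = "") -> LightSpectrum:
    """Read a two-column ``wavelength_nm,intensity`` CSV."""
    wavelengths: list[float] = []
    intensities: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"empty spectrum file {path}")
        if [col.strip().lower() for col in header[:2]] != ["wavelength_nm", "intensity"]:
            raise ValidationError(
                f"{path}: expected header 'wavelength_nm,intensity', got {header!r}"
            )
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            wavelengths.append(float(row[0]))
            intensities.append(float(row[1]))
    return LightSpectrum(
        wavelengths_nm=np.array(wavelengths),
        intensities=np.array(intensities),
        label=label or Path(path).stem,
    )


def coverage_report(
    source: LightSpectrum,
    catalog: list[CatalogRecord],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    half_band_nm: float = DEFAULT_HALF_BAND_NM,
) -> CoverageReport:
    """Which catalog records does the source illuminate?

    A record is covered iff the source's maximum intensity inside
    ``[lambda - half_band, lambda + half_band]`` reaches ``threshold`` of
    the source's own maximum.  Records whose band lies wholly outside the
    grid are "out_of_range"; the non-numeric "K" rows are "unevaluable".
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if half_band_nm <= 0:
        raise ValidationError(f"half_band_nm must be positive, got {half_band_nm}")
    source_max = source.max_intensity
    if source_max == 0.0:
        warnings.warn(
            f"source {source.label!r} has zero maximum intensity; nothing is covered",
            stacklevel=2,
        )
    entries: list[RecordCoverage] = []
    grid = source.wavelengths_nm
    for record in catalog:
        if not record.evaluable:
            entries.append(RecordCoverage(record, False, 0.0, "unevaluable"))
            continue
        lo = record.wavelength_nm - half_band_nm
        hi = record.wavelength_nm + half_band_nm
        mask = (grid >= lo) & (grid <= hi)
        if not mask.any():
            entries.append(RecordCoverage(record, False, 0.0, "out_of_range"))
            continue
        band_max = float(source.intensities[mask].max())
        relative = band_max / source_max if source_max > 0 else 0.0
        covered = source_max > 0 and band_max >= threshold * source_max
        entries.append(
            RecordCoverage(record, covered, relative, "covered" if covered else "uncovered")
        )

    summary: dict[str, float] = {}
    families = {
        e.record.super_family
        for e in entries
        if e.record.super_family and e.status != "unevaluable"
    }
    for family in sorted(families):
        members = [
            e
            for e in entries
            if e.record.super_family == family and e.status != "unevaluable"
        ]
        summary[family] = sum(e.covered for e in members) / len(members)

    return CoverageReport(
        source_label=source.label,
        threshold=threshold,
        half_band_nm=half_band_nm,
        entries=entries,
        superfamily_summary=summary,
    )


def water_window_filter(
    catalog: list[CatalogRecord],
    window: tuple[float, float] = DEFAULT_WATER_WINDOW,
) -> WaterWindowPartition:
    """Partition records by whether the activating wavelength sits in ``window``."""
    lo, hi = window
    if not lo < hi:
        raise ValidationError(f"window must satisfy min < max, got {window}")
    inside, outside, unevaluable = [], [], []
    for record in catalog:
        if not record.evaluable:
            unevaluable.append(record)
        elif lo <= record.wavelength_nm <= hi:
            inside.append(record)
        else:
            outside.append(record)
    return WaterWindowPartition(inside=inside, outside=outside, unevaluable=unevaluable)


def write_coverage_csv(report: CoverageReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "rrm_frequency",
                "wavelength_nm",
                "functional_group",
                "super_family",
                "covered",
                "relative_intensity_at_band",
                "status",
            ]
        )
        for e in report.entries:
            writer.writerow(
                [
                    f"{e.record.rrm_frequency:.10g}",
                    e.record.wavelength_text,
                    e.record.functional_group,
                    e.record.super_family or "",
                    str(e.covered).lower(),
                    f"{e.relative_intensity_at_band:.6g}",
                    e.status,
                ]
            )
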