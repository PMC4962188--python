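"""The bundled catalog of characteristic RRM frequencies per biological function.

Each record carries a dimensionless characteristic frequency, the printed
activating wavelength in nm, a functional-group label, and (for roughly
half the records) a super-family label grouping functions that share a
frequency band.  Two low-frequency rows print their wavelength with a "K"
suffix ("100 K", "20 K"); those strings are preserved verbatim, their
numeric wavelength is None, and every numeric code path excludes them.

The catalog CSV is checksummed: a corrupted installation fails loudly
rather than silently reclassifying frequencies.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import DomainError, IntegrityError, NotFoundError, ValidationError
from .photomap import in_rrm_band

_CATALOG_FILE = "catalog.csv"
_CATALOG_SHA256 = "c5abcc1318c4469cb927ad219a36ccc540cd7d2d1976cd627a8e5051eb4fc814"

SUPER_FAMILIES = (
    "Tumor regulation",
    "Viral-bacterial infection",
    "Growth",
    "Enzymes",
    "Structural proteins",
    "Blue",
)

#: Super-family band edges as stated in running text vs. as implied by the
#: table's own colour blocks disagree for Tumor regulation: the text gives a
#: lower edge of 0.031 while the table block starts at 0.027 (Protein
#: A-VHIII).  The catalog follows the table; this constant documents the
#: discrepancy instead of resolving it.
TUMOR_BAND_TEXT_LOWER_EDGE = 0.031

#: Rows whose printed nm value differs from round(K / frequency) with K=201
#: (limited precision of the printed frequencies); keyed by
#: (frequency, printed nm).  Excluded from strict round-trip checks.
ROUNDING_DISCREPANCIES = {
    (0.0446, 4508): 4507,
    (0.289, 695): 696,
    (0.297, 678): 677,
}

DEFAULT_CLASSIFY_TOLERANCE = 0.004


@dataclass(frozen=True)
class CatalogRecord:
    rrm_frequency: float
    wavelength_nm: int | None
    wavelength_text: str
    functional_group: str
    super_family: str | None = None

    def __post_init__(self) -> None:
        if not in_rrm_band(self.rrm_frequency):
            raise ValidationError(
                f"catalog frequency {self.rrm_frequency} outside (0, 0.5]"
            )

    @property
    def evaluable(self) -> bool:
        """True when the record has a usable numeric wavelength."""
        return self.wavelength_nm is not None


@dataclass(frozen=True)
class FrequencyBinCount:
    bin_start: float
    count: int


def _catalog_bytes() -> bytes:
    return (resources.files("rrmkit.data") / _CATALOG_FILE).read_bytes()


def load_catalog() -> list[CatalogRecord]:
    """Load all bundled catalog records, sorted by frequency ascending.

    Raises :class:`IntegrityError` if the bundled CSV fails its checksum.
    """
    raw = _catalog_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CATALOG_SHA256:
        raise IntegrityError(
            f"bundled catalog failed checksum: {digest} != {_CATALOG_SHA256}"
        )
    records: list[CatalogRecord] = []
    reader = csv.DictReader(raw.decode("utf-8").splitlines())
    for row in reader:
        text = row["wavelength_nm"].strip()
        try:
            nm: int | None = int(text)
        except ValueError:
            nm = None  # the verbatim "100 K" / "20 K" rows
        records.append(
            CatalogRecord(
                rrm_frequency=float(row["rrm_frequency"]),
                wavelength_nm=nm,
                wavelength_text=text,
                functional_group=row["functional_group"],
                super_family=row["super_family"].strip() or None,
            )
        )
    records.sort(key=lambda r: r.rrm_frequency)
    return records


def classify(
    f: float,
    tolerance: float = DEFAULT_CLASSIFY_TOLERANCE,
    records: list[CatalogRecord] | None = None,
) -> list[CatalogRecord]:
    """All catalog records within ``tolerance`` of ``f``, nearest first."""
    if not in_rrm_band(f):
        raise DomainError(f"frequency {f} outside the RRM band (0, 0.5]")
    if tolerance < 0:
        raise ValidationError(f"tolerance must be >= 0, got {tolerance}")
    if records is None:
        records = load_catalog()
    hits = [r for r in records if abs(r.rrm_frequency - f) <= tolerance]
    hits.sort(key=lambda r: (abs(r.rrm_frequency - f), r.rrm_frequency))
    return hits


def superfamily_band(
    name: str, records: list[CatalogRecord] | None = None
) -> tuple[float, float]:
    """(min, max) characteristic frequency over one super family's records.

    Note: for "Tumor regulation" the lower edge returned (0.027, from the
    table block) differs from the 0.031 quoted in running text; see
    :data:`TUMOR_BAND_TEXT_LOWER_EDGE`.
    """
    # tolerate the en-dash spelling of the viral-bacterial family
    canonical = name.replace("–", "-").replace("—", "-")
    if canonical not in SUPER_FAMILIES:
        raise NotFoundError(
            f"unknown super family {name!r}; valid names: "
            + ", ".join(SUPER_FAMILIES)
        )
    if records is None:
        records = load_catalog()
    freqs = [r.rrm_frequency for r in records if r.super_family == canonical]
    if not freqs:
        raise NotFoundError(f"super family {name!r} has no catalog records")
    return (min(freqs), max(freqs))


def histogram(
    records: list[CatalogRecord], bin_width: float = 0.01
) -> list[FrequencyBinCount]:
    """Row counts per half-open frequency bin ``[k*w, (k+1)*w)`` over [0, 0.5].

    Zero-count bins are included.  When two rows share a frequency each row
    counts separately.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin width must be positive, got {bin_width}")
    n_bins = int(0.5 / bin_width)
    if n_bins * bin_width < 0.5 - 1e-12:
        n_bins += 1
    counts = [0] * n_bins
    for record in records:
        k = int(record.rrm_frequency / bin_width)
        if k >= n_bins:  # frequency exactly at the band edge
            k = n_bins - 1
        counts[k] += 1
    return [
        FrequencyBinCount(bin_start=round(k * bin_width, 12), count=c)
        for k, c in enumerate(counts)
    ]


def write_histogram_csv(bins: list[FrequencyBinCount], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_start", "count"])
        for b in bins:
            writer.writerow([f"{b.bin_start:.10g}", b.count])
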