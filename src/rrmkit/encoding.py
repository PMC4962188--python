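"""Numerical encoding of biological sequences.

Sequences are rendered as series of per-residue electron-ion interaction
potential (EIIP) values — the "energy of delocalized electrons" parameter —
so that periodicities in the potential profile can be analysed spectrally.

The bundled potential tables are data, not code: they live in
``rrmkit/data/*.csv`` and any user table with the same two-column layout
can be substituted via :func:`load_scale`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import NotFoundError, ValidationError

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

#: Accepted values for the unknown-residue policy of :func:`encode`.
POLICIES = ("strict", "skip", "zero")

_BUNDLED = {
    "eiip_protein": (
        "eiip_protein.csv",
        "protein",
        "EIIP amino-acid potentials (Veljkovic & Slavic 1972; "
        "Cosic 1994, IEEE Trans Biomed Eng 41:1101-1114)",
    ),
    "eiip_dna": (
        "eiip_dna.csv",
        "dna",
        "EIIP nucleotide potentials (Veljkovic & Slavic 1972; "
        "Cosic 1997, The Resonant Recognition Model of Macromolecular "
        "Bioactivity, Birkhauser)",
    ),
}


@dataclass(frozen=True)
class ResidueScale:
    """Mapping from residue letter to a non-negative potential value."""

    name: str
    alphabet: str  # "protein" or "dna"
    values: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "dna"):
            raise ValidationError(
                f"alphabet must be 'protein' or 'dna', got {self.alphabet!r}"
            )
        canonical = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        missing = [r for r in canonical if r not in self.values]
        if missing:
            raise ValidationError(
                f"scale {self.name!r} is missing canonical residue(s): "
                + ", ".join(missing)
            )
        for residue, value in self.values.items():
            if not np.isfinite(value):
                raise ValidationError(
                    f"scale {self.name!r}: non-finite value for residue {residue!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"scale {self.name!r}: negative value {value} for residue "
                    f"{residue!r}"
                )

    def __contains__(self, residue: str) -> bool:
        return residue in self.values

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class NumericalSeries:
    """A sequence rendered as an ordered array of potential values."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("series must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("series contains non-finite values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def length(self) -> int:
        return len(self)


def load_scale(identifier: str | Path) -> ResidueScale:
    """Load a residue-potential scale by bundled name or CSV path.

    Parameters
    ----------
    identifier:
        Either a bundled scale name (``"eiip_protein"``, ``"eiip_dna"``)
        or a path to a readable CSV with header ``residue,value``.

    Raises
    ------
    NotFoundError
        Unknown bundled name and no such file.
    ValidationError
        CSV malformed or missing a canonical residue.
    """
    key = str(identifier)
    if key in _BUNDLED:
        filename, alphabet, citation = _BUNDLED[key]
        text = (resources.files("rrmkit.data") / filename).read_text()
        values = _parse_scale_csv(text.splitlines(), key)
        return ResidueScale(name=key, alphabet=alphabet, values=values, source=citation)

    path = Path(identifier)
    if not path.is_file():
        raise NotFoundError(
            f"unknown scale {key!r}: not a bundled name "
            f"({', '.join(sorted(_BUNDLED))}) and not a readable file"
        )
    values = _parse_scale_csv(path.read_text().splitlines(), path.name)
    # infer alphabet: 4 nucleotide letters only -> dna, else protein
    alphabet = "dna" if set(values) <= set(DNA_ALPHABET) else "protein"
    return ResidueScale(
        name=path.stem, alphabet=alphabet, values=values, source=f"user file {path}"
    )


def _parse_scale_csv(lines: Iterator[str] | list[str], label: str) -> dict[str, float]:
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise ValidationError(f"scale {label!r}: empty file") from None
    if [h.strip().lower() for h in header[:2]] != ["residue", "value"]:
        raise ValidationError(
            f"scale {label!r}: expected header 'residue,value', got {header!r}"
        )
    values: dict[str, float] = {}
    for row in reader:
        if not row or not "".join(row).strip():
            continue
        residue = row[0].strip().upper()
        if len(residue) != 1:
            raise ValidationError(
                f"scale {label!r}: residue field must be one letter, got {row[0]!r}"
            )
        try:
            values[residue] = float(row[1])
        except (IndexError, ValueError):
            raise ValidationError(
                f"scale {label!r}: bad value for residue {residue!r}: {row[1:]!r}"
            ) from None
    return values


def encode(
    sequence: str,
    scale: ResidueScale,
    policy: str = "strict",
    source_id: str = "",
) -> NumericalSeries:
    """Encode a residue string as a numerical potential series.

    Letters are upper-cased first; in DNA mode ``U`` is read as ``T`` so
    RNA sequences encode transparently.  ``policy`` controls residues not
    present in the scale: ``"strict"`` raises naming the position and
    letter, ``"skip"`` drops them, ``"zero"`` substitutes 0.0.
    """
    if not sequence:
        raise ValidationError("cannot encode an empty sequence")
    if policy not in POLICIES:
        raise ValidationError(f"policy must be one of {POLICIES}, got {policy!r}")

    seq = sequence.upper()
    if scale.alphabet == "dna":
        seq = seq.replace("U", "T")

    out: list[float] = []
    for i, letter in enumerate(seq):
        if letter in scale:
            out.append(scale[letter])
        elif policy == "strict":
            raise ValidationError(
                f"unknown residue {letter!r} at position {i} "
                f"(scale {scale.name!r}, policy=strict)"
            )
        elif policy == "zero":
            out.append(0.0)
        # policy == "skip": drop silently
    if not out:
        raise ValidationError(
            "encoding produced an empty series (all residues skipped)"
        )
    return NumericalSeries(values=np.array(out), source_id=source_id)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file into ``(id, sequence)`` pairs.

    IDs are the header token before the first whitespace; wrapped sequence
    lines are joined.
    """
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records
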