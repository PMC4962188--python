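"""Synthetic fixtures with known embedded characteristic frequencies.

Every spectral operation in the toolkit is testable offline: a group of
series each embeds the same cosine at a chosen frequency plus independent
Gaussian noise, and :func:`quantize_to_sequence` maps a series back onto
residue letters so the full FASTA -> encode -> consensus path can be
exercised end to end with ground truth in hand.  All randomness flows
through an explicit seed; no global RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import NumericalSeries, ResidueScale
from .errors import DomainError, ValidationError

DEFAULT_SEED = 42
DEFAULT_NOISE_SD = 0.5
DEFAULT_AMPLITUDE = 1.0
DEFAULT_LENGTH = 128
DEFAULT_MEMBERS = 5


@dataclass(frozen=True)
class GroupFixture:
    """A seeded group of series sharing one embedded frequency."""

    series: tuple[NumericalSeries, ...]
    true_frequency: float
    amplitude: float
    noise_sd: float
    seed: int
    lengths: tuple[int, ...]
    phases: tuple[float, ...]
    offset: float = 0.0


def _check_frequency(f0: float) -> None:
    if not 0.0 < f0 < 0.5:
        raise DomainError(f"embedded frequency must lie in (0, 0.5), got {f0}")


def synth_group(
    f0: float,
    n: int = DEFAULT_MEMBERS,
    lengths: Sequence[int] | int = DEFAULT_LENGTH,
    amplitude: float = DEFAULT_AMPLITUDE,
    noise_sd: float = DEFAULT_NOISE_SD,
    phases: Sequence[float] | str = "random",
    seed: int = DEFAULT_SEED,
    offset: float = 0.0,
) -> GroupFixture:
    """Generate ``n`` series, each ``a*cos(2 pi f0 j + phi_i) + offset + noise``.

    ``phases`` is either an explicit per-member list or ``"random"``
    (uniform on (-pi, pi], drawn from the seeded generator).  ``offset``
    shifts the series baseline, useful before quantization onto a
    non-negative potential scale.
    """
    _check_frequency(f0)
    if n < 2:
        raise ValidationError(f"a group needs n >= 2 members, got {n}")
    if isinstance(lengths, int):
        lengths = [lengths] * n
    if len(lengths) != n:
        raise ValidationError(f"got {len(lengths)} lengths for {n} members")
    if any(length < 8 for length in lengths):
        raise ValidationError("member lengths must be >= 8")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")

    rng = np.random.default_rng(seed)
    if phases == "random":
        phase_list = tuple(float(p) for p in rng.uniform(-np.pi, np.pi, size=n))
    else:
        if len(phases) != n:
            raise ValidationError(f"got {len(phases)} phases for {n} members")
        phase_list = tuple(float(p) for p in phases)

    members = []
    for i, (length, phi) in enumerate(zip(lengths, phase_list)):
        j = np.arange(length)
        values = amplitude * np.cos(2 * np.pi * f0 * j + phi) + offset
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=length)
        members.append(
            NumericalSeries(values=values, source_id=f"synth_f{f0:g}_s{seed}_m{i}")
        )
    return GroupFixture(
        series=tuple(members),
        true_frequency=f0,
        amplitude=amplitude,
        noise_sd=noise_sd,
        seed=seed,
        lengths=tuple(int(x) for x in lengths),
        phases=phase_list,
        offset=offset,
    )


def synth_opposite_pair(
    f0: float,
    length: int = DEFAULT_LENGTH,
    amplitude: float = DEFAULT_AMPLITUDE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = DEFAULT_SEED,
    offset: float = 0.0,
) -> tuple[NumericalSeries, NumericalSeries]:
    """Two series whose embedded cosines are exactly antiphase at ``f0``."""
    fixture = synth_group(
        f0,
        n=2,
        lengths=[length, length],
        amplitude=amplitude,
        noise_sd=noise_sd,
        phases=[0.0, np.pi],
        seed=seed,
        offset=offset,
    )
    return fixture.series[0], fixture.series[1]


def quantize_to_sequence(series: NumericalSeries, scale: ResidueScale) -> str:
    """Map each value to the residue with the nearest scale value.

    Ties (several residues sharing one potential, e.g. I/L or C/S in the
    protein EIIP table) resolve to the alphabetically first residue, so the
    mapping is deterministic and ``encode`` round-trips it exactly when the
    input already sits on scale values.
    """
    residues = sorted(scale.values)  # alphabetical: first wins on ties
    levels = np.array([scale.values[r] for r in residues])
    indices = np.abs(series.values[:, None] - levels[None, :]).argmin(axis=1)
    return "".join(residues[i] for i in indices)


def write_fixture(
    fixture: GroupFixture,
    scale: ResidueScale,
    out_dir: str | Path,
    basename: str = "fixture",
) -> tuple[Path, Path]:
    """Write a quantized fixture as FASTA plus a JSON ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = out / f"{basename}.fasta"
    with open(fasta_path, "w") as fh:
        for member in fixture.series:
            seq = quantize_to_sequence(member, scale)
            fh.write(f">{member.source_id}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start : start + 60] + "\n")
    manifest_path = out / f"{basename}.json"
    manifest = {
        "true_frequency": fixture.true_frequency,
        "amplitude": fixture.amplitude,
        "noise_sd": fixture.noise_sd,
        "seed": fixture.seed,
        "offset": fixture.offset,
        "lengths": list(fixture.lengths),
        "phases": list(fixture.phases),
        "scale": scale.name,
        "member_ids": [m.source_id for m in fixture.series],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return fasta_path, manifest_path
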