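"""Amplitude/phase spectra, multiplicative cross-spectra and peak calls.

The frequency axis is dimensionless (cycles per residue) on the grid
``k / n_points`` for ``k = 0 .. n_points // 2``, i.e. up to the Nyquist
limit 0.5 for unit residue spacing.  Group consensus is the pointwise
product of member amplitude spectra; peak significance is the ratio of a
bin's consensus amplitude to the mean consensus amplitude (zero-frequency
bin excluded).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import NumericalSeries
from .errors import DomainError, ValidationError

DEFAULT_N_POINTS = 512
DEFAULT_MIN_SNR = 20.0
#: Default tolerance for the "opposite phase" predicate, radians.
OPPOSITE_PHASE_TOL = np.pi / 4
_PHASE_AMPLITUDE_FLOOR = 1e-12  # relative to spectrum max


@dataclass(frozen=True)
class Spectrum:
    """Single-series amplitude and phase spectrum on the RRM grid."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    n_points: int
    source_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        a = np.asarray(self.amplitudes, float)
        p = np.asarray(self.phases, float)
        if not (f.shape == a.shape == p.shape):
            raise ValidationError("frequency/amplitude/phase lengths differ")
        if f.size and f[-1] > 0.5 + 1e-12:
            raise ValidationError("frequencies exceed the Nyquist limit 0.5")
        if np.any(a < 0):
            raise ValidationError("amplitudes must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "phases", p)


@dataclass(frozen=True)
class ConsensusSpectrum:
    """Multiplicative cross-spectrum over a group of member spectra."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    member_count: int
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.member_count < 2:
            raise ValidationError("a consensus needs at least 2 members")
        f = np.asarray(self.frequencies, float)
        a = np.asarray(self.amplitudes, float)
        if f.shape != a.shape:
            raise ValidationError("frequency/amplitude lengths differ")
        if np.any(a < 0):
            raise ValidationError("consensus amplitudes must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "amplitudes", a)


@dataclass(frozen=True)
class PeakCall:
    frequency: float
    amplitude: float
    snr: float


def amplitude_spectrum(series: NumericalSeries, n_points: int = DEFAULT_N_POINTS) -> Spectrum:
    """One-sided DFT amplitude/phase spectrum of a mean-removed series.

    The series mean is subtracted, the result zero-padded to ``n_points``
    samples, and the transform evaluated on the grid ``k / n_points`` for
    ``k = 0 .. n_points // 2``.  The zero-frequency amplitude is exactly 0
    because the padded series sums to 0.
    """
    n = len(series)
    if n < 4:
        raise ValidationError(f"series too short for spectral analysis: {n} < 4")
    if n_points < n:
        raise ValidationError(f"n_points={n_points} < series length {n}")
    x = series.values - series.values.mean()
    transform = np.fft.rfft(x, n=n_points)
    freqs = np.arange(n_points // 2 + 1) / n_points
    amplitudes = np.abs(transform)
    amplitudes[0] = 0.0  # mean removal makes the DC bin zero up to fp error
    return Spectrum(
        frequencies=freqs,
        amplitudes=amplitudes,
        phases=np.angle(transform),
        n_points=n_points,
        source_id=series.source_id,
    )


def cross_spectrum(
    spectra: Sequence[Spectrum], normalize_members: bool = False
) -> ConsensusSpectrum:
    """Pointwise product of member amplitude spectra.

    ``normalize_members`` divides each member by its own maximum before
    multiplying — a sensitivity check only; the default (off) follows the
    plain multiplicative convention.
    """
    if len(spectra) < 2:
        raise ValidationError("cross_spectrum needs at least 2 spectra")
    n_points = spectra[0].n_points
    for s in spectra[1:]:
        if s.n_points != n_points:
            raise ValidationError(
                f"mismatched frequency grids: n_points {s.n_points} != {n_points}"
            )
    product = np.ones_like(spectra[0].amplitudes)
    for s in spectra:
        member = s.amplitudes
        if normalize_members:
            peak = member.max()
            if peak > 0:
                member = member / peak
        product = product * member
    return ConsensusSpectrum(
        frequencies=spectra[0].frequencies.copy(),
        amplitudes=product,
        member_count=len(spectra),
        member_ids=tuple(s.source_id for s in spectra),
    )


def _grid_index(frequencies: np.ndarray, frequency: float) -> int:
    idx = int(np.argmin(np.abs(frequencies - frequency)))
    if abs(frequencies[idx] - frequency) > 1e-9:
        raise DomainError(
            f"frequency {frequency} is not on the spectral grid "
            f"(nearest bin {frequencies[idx]:.6g})"
        )
    return idx


def signal_to_noise(consensus: ConsensusSpectrum, frequency: float) -> float:
    """Consensus amplitude at ``frequency`` over the grid-mean amplitude.

    The mean runs over every bin except zero frequency (the peak bin is
    included).  Undefined — and an error — when the consensus is all zero.
    """
    idx = _grid_index(consensus.frequencies, frequency)
    nonzero_freq = consensus.amplitudes[1:]
    mean = nonzero_freq.mean() if nonzero_freq.size else 0.0
    if mean == 0.0:
        raise DomainError("signal-to-noise undefined for an all-zero consensus")
    return float(consensus.amplitudes[idx] / mean)


def find_consensus_peak(
    consensus: ConsensusSpectrum, min_snr: float = DEFAULT_MIN_SNR
) -> PeakCall | None:
    """Call the highest consensus bin if its S/N clears ``min_snr``.

    The zero-frequency bin is never callable.  Ties break toward the
    lower frequency.  Returns ``None`` (not an error) when no bin clears
    the threshold or the consensus is entirely zero.
    """
    amplitudes = consensus.amplitudes[1:]
    if amplitudes.size == 0 or amplitudes.max() == 0.0:
        return None
    idx = 1 + int(np.argmax(amplitudes))  # argmax returns first (= lowest) maximum
    frequency = float(consensus.frequencies[idx])
    snr = signal_to_noise(consensus, frequency)
    if snr < min_snr:
        return None
    return PeakCall(
        frequency=frequency,
        amplitude=float(consensus.amplitudes[idx]),
        snr=snr,
    )


def phase_difference(
    a: NumericalSeries,
    b: NumericalSeries,
    frequency: float,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Absolute principal-value phase difference of two series at a grid frequency.

    Returns a value in ``[0, pi]``.  Raises if either spectrum has
    (numerically) zero amplitude at that frequency, where phase is
    undefined.
    """
    sa = amplitude_spectrum(a, n_points)
    sb = amplitude_spectrum(b, n_points)
    idx = _grid_index(sa.frequencies, frequency)
    for s, label in ((sa, "first"), (sb, "second")):
        peak = s.amplitudes.max()
        if peak == 0.0 or s.amplitudes[idx] < _PHASE_AMPLITUDE_FLOOR * peak:
            raise DomainError(
                f"phase undefined: {label} series has ~zero amplitude at "
                f"frequency {frequency}"
            )
    delta = sa.phases[idx] - sb.phases[idx]
    # wrap into (-pi, pi], then take magnitude
    wrapped = np.angle(np.exp(1j * delta))
    return float(abs(wrapped))


def is_opposite_phase(
    a: NumericalSeries,
    b: NumericalSeries,
    frequency: float,
    n_points: int = DEFAULT_N_POINTS,
    tol: float = OPPOSITE_PHASE_TOL,
) -> bool:
    """True when the two series are within ``tol`` of antiphase at ``frequency``."""
    return abs(phase_difference(a, b, frequency, n_points) - np.pi) <= tol


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency", "amplitude", "phase"])
        for f, amp, ph in zip(
            spectrum.frequencies, spectrum.amplitudes, spectrum.phases
        ):
            writer.writerow([f"{f:.10g}", f"{amp:.10g}", f"{ph:.10g}"])


def write_consensus_csv(consensus: ConsensusSpectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency", "amplitude"])
        for f, amp in zip(consensus.frequencies, consensus.amplitudes):
            writer.writerow([f"{f:.10g}", f"{amp:.10g}"])
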