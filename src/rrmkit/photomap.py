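"""Conversions between RRM frequencies, wavelengths and physical frequencies.

Two routes to a physical scale coexist and are deliberately not reconciled:
the empirical wavelength relation ``lambda_nm = K / f`` with K = 201 nm,
and the charge-transport estimate ``nu_Hz = f * v / d`` from the charge
velocity ``v`` and the inter-residue spacing ``d``.  Both sets of constants
live in one :class:`PhysicalConstants` record so no literal is buried in
logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError

#: Nyquist limit of the dimensionless frequency axis.
RRM_BAND = (0.0, 0.5)


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the frequency/wavelength mapping.

    K : wavelength-scale coefficient, nm
    charge_velocity : charge transport speed along the backbone, m/s
    residue_spacing : inter-residue distance, m
    light_speed : m/s
    """

    K: float = 201.0
    charge_velocity: float = 7.87e5
    residue_spacing: float = 3.8e-10
    light_speed: float = 2.998e8

    def __post_init__(self) -> None:
        for name in ("K", "charge_velocity", "residue_spacing", "light_speed"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"constant {name} must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


def rrm_to_wavelength(
    f: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Wavelength in nm activating the interaction at RRM frequency ``f``."""
    if f <= 0:
        raise DomainError(f"RRM frequency must be positive, got {f}")
    return constants.K / f


def rrm_to_wavelength_nm(
    f: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> int:
    """:func:`rrm_to_wavelength` rounded half-up to integer nm (catalog form)."""
    return round_half_up(rrm_to_wavelength(f, constants))


def wavelength_to_rrm(
    lambda_nm: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Inverse mapping; values above 0.5 are out of the RRM band but returned."""
    if lambda_nm <= 0:
        raise DomainError(f"wavelength must be positive, got {lambda_nm}")
    return constants.K / lambda_nm


def in_rrm_band(f: float) -> bool:
    return RRM_BAND[0] < f <= RRM_BAND[1]


def rrm_to_physical_frequency(
    f: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Physical oscillation frequency in Hz from the charge-transport estimate."""
    if f <= 0:
        raise DomainError(f"RRM frequency must be positive, got {f}")
    return f * constants.charge_velocity / constants.residue_spacing


def fit_K(pairs: Sequence[tuple[float, float]]) -> float:
    """Least-squares estimate of K in ``lambda = K / f`` through the origin.

    ``pairs`` are (rrm_frequency, wavelength_nm) observations.  Regressing
    wavelength on reciprocal frequency with no intercept gives
    ``K = sum(lambda_i / f_i) / sum(1 / f_i^2)``.
    """
    if len(pairs) < 2:
        raise ValidationError("fit_K needs at least 2 (frequency, wavelength) pairs")
    f = np.array([p[0] for p in pairs], float)
    lam = np.array([p[1] for p in pairs], float)
    if np.any(f <= 0) or np.any(lam <= 0):
        raise ValidationError("all frequencies and wavelengths must be positive")
    x = 1.0 / f
    denominator = float(np.dot(x, x))
    if denominator == 0.0:
        raise ValidationError("degenerate input: zero design norm")
    return float(np.dot(x, lam) / denominator)
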