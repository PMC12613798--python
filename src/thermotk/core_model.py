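"""Closed-form relations for temperature-dependent toxicokinetics.

Uptake and elimination of organic chemicals by aquatic ectotherms are
dominated by transport processes (diffusion, advection, ventilation), so
their first-order rate constants follow the Arrhenius law

    k(T) = A * exp(-E_A / (R * T)),

which linearizes to ``ln k = ln A + slope_K / T`` with a slope of
``-E_A / R`` in Kelvin.  Rate constants additionally scale with organism
mass roughly as ``m**(-1/4)`` (quarter-power allometry), so dividing a
rate constant by ``m**(-1/4)`` — equivalently multiplying by ``m**(1/4)``
— normalizes it to a 1 kg organism.  In a one-compartment model the
steady-state bioconcentration factor is the ratio ``k_u / k_e``; when the
two processes share an Arrhenius slope the temperature dependence cancels
and the BCF is temperature-independent.

This module holds the domain types and these scalar relations; all
functions accept NumPy arrays as well as scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "GAS_CONSTANT",
    "KELVIN_OFFSET",
    "Process",
    "ArrheniusParams",
    "RateRecord",
    "TKParameters",
    "arrhenius_rate",
    "mass_correct",
    "mass_uncorrect",
    "bcf",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Ideal gas constant in J K^-1 mol^-1 at the working precision of the
#: analysis (activation energies are reported as -slope_K * GAS_CONSTANT).
GAS_CONSTANT = 8.31

#: Additive offset between degrees Celsius and Kelvin.
KELVIN_OFFSET = 273.15

ArrayLike = Union[float, np.ndarray]


class Process(str, Enum):
    """Which toxicokinetic process a rate constant describes."""

    UPTAKE = "uptake"
    ELIMINATION = "elimination"


def celsius_to_kelvin(t_celsius: ArrayLike) -> ArrayLike:
    return np.asarray(t_celsius, dtype=float) + KELVIN_OFFSET


def kelvin_to_celsius(t_kelvin: ArrayLike) -> ArrayLike:
    return np.asarray(t_kelvin, dtype=float) - KELVIN_OFFSET


@dataclass(frozen=True)
class ArrheniusParams:
    """Parameters of the linearized Arrhenius relation for one process.

    Attributes
    ----------
    process
        Whether the parameters describe uptake or elimination.
    ln_A
        Natural log of the frequency factor.  ``A`` carries the units of
        the rate constant itself (L kg^-1 d^-1 for uptake, d^-1 for
        elimination), so ``ln_A`` is dimensionless by convention.
    slope_K
        Slope of ``ln k`` against ``1/T`` in Kelvin; equals ``-E_A / R``.
        Negative for thermally activated processes.
    """

    process: Process
    ln_A: float
    slope_K: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "process", Process(self.process))
        if not (math.isfinite(self.ln_A) and math.isfinite(self.slope_K)):
            raise InvalidInputError(
                f"ArrheniusParams requires finite ln_A and slope_K, got "
                f"ln_A={self.ln_A!r}, slope_K={self.slope_K!r}"
            )

    @property
    def activation_energy(self) -> float:
        """Activation energy E_A = -slope_K * R, in J mol^-1."""
        return -self.slope_K * GAS_CONSTANT


@dataclass(frozen=True)
class TKParameters:
    """One-compartment toxicokinetic parameters for one organism/chemical/T.

    ``k_u`` in L kg^-1 d^-1, ``k_e`` in d^-1; the bioconcentration factor
    is derived as ``k_u / k_e`` (L kg^-1) and never stored independently.
    """

    k_u: float
    k_e: float

    def __post_init__(self) -> None:
        if not (self.k_u > 0 and self.k_e > 0):
            raise InvalidInputError(
                f"TKParameters requires k_u > 0 and k_e > 0, got "
                f"k_u={self.k_u!r}, k_e={self.k_e!r}"
            )

    @property
    def bcf(self) -> float:
        """Steady-state bioconcentration factor k_u / k_e, L kg^-1."""
        return self.k_u / self.k_e


@dataclass
class RateRecord:
    """One compiled rate-constant observation.

    ``k`` is in L kg^-1 d^-1 for uptake and d^-1 for elimination;
    ``temperature_K`` is the (constant) experimental temperature;
    ``log_dow`` is the log10 octanol-water distribution ratio of the
    chemical; ``mass_kg`` the organism wet mass where known.
    """

    species: str
    taxon: str
    chemical: str
    chemical_group: str
    temperature_K: float
    rate_type: Process
    k: float
    log_dow: Optional[float] = None
    mass_kg: Optional[float] = None
    life_stage: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.rate_type = Process(self.rate_type)
        if not self.k > 0:
            raise InvalidInputError(f"rate constant must be positive, got {self.k!r}")
        if not self.temperature_K > 200:
            raise InvalidInputError(
                f"temperature_K must exceed 200 K, got {self.temperature_K!r} "
                "(was a Celsius value passed unconverted?)"
            )
        if self.mass_kg is not None and not self.mass_kg > 0:
            raise InvalidInputError(f"mass_kg must be positive, got {self.mass_kg!r}")

    @property
    def temperature_C(self) -> float:
        return self.temperature_K - KELVIN_OFFSET


def arrhenius_rate(params: ArrheniusParams, temperature_K: ArrayLike) -> ArrayLike:
    """Evaluate the Arrhenius relation: ``exp(ln_A + slope_K / T)``.

    Strictly increasing in ``T`` whenever ``slope_K < 0`` (positive
    activation energy).  ``temperature_K`` may be a scalar or array and
    must be strictly positive.
    """
    t = np.asarray(temperature_K, dtype=float)
    if np.any(~(t > 0)):
        raise InvalidInputError(f"temperature must be positive, got {temperature_K!r}")
    out = np.exp(params.ln_A + params.slope_K / t)
    return float(out) if np.isscalar(temperature_K) else out


def mass_correct(k: ArrayLike, mass_kg: ArrayLike) -> ArrayLike:
    """Normalize a rate constant to a 1 kg organism: ``k* = k * m**(1/4)``.

    Under quarter-power allometry rate constants scale as ``m**(-1/4)``,
    so dividing by ``m**(-1/4)`` removes the expected size dependence.
    Units gain a factor kg^(1/4).
    """
    k_arr = np.asarray(k, dtype=float)
    m_arr = np.asarray(mass_kg, dtype=float)
    if np.any(~(k_arr > 0)):
        raise InvalidInputError(f"rate constant must be positive, got {k!r}")
    if np.any(~(m_arr > 0)):
        raise InvalidInputError(f"mass must be positive, got {mass_kg!r}")
    out = k_arr * m_arr ** 0.25
    scalar = np.isscalar(k) and np.isscalar(mass_kg)
    return float(out) if scalar else out


def mass_uncorrect(k_star: ArrayLike, mass_kg: ArrayLike) -> ArrayLike:
    """Invert :func:`mass_correct`: ``k = k* * m**(-1/4)``."""
    ks_arr = np.asarray(k_star, dtype=float)
    m_arr = np.asarray(mass_kg, dtype=float)
    if np.any(~(ks_arr > 0)):
        raise InvalidInputError(f"rate constant must be positive, got {k_star!r}")
    if np.any(~(m_arr > 0)):
        raise InvalidInputError(f"mass must be positive, got {mass_kg!r}")
    out = ks_arr * m_arr ** -0.25
    scalar = np.isscalar(k_star) and np.isscalar(mass_kg)
    return float(out) if scalar else out


def bcf(k_u: ArrayLike, k_e: ArrayLike) -> ArrayLike:
    """Steady-state one-compartment bioconcentration factor ``k_u / k_e``.

    When uptake and elimination share the same Arrhenius slope the
    ``slope_K / T`` terms cancel in the ratio, so the BCF reduces to
    ``exp(ln_A_u - ln_A_e)`` — constant in temperature.
    """
    ku_arr = np.asarray(k_u, dtype=float)
    ke_arr = np.asarray(k_e, dtype=float)
    if np.any(~(ku_arr > 0)) or np.any(~(ke_arr > 0)):
        raise InvalidInputError(
            f"bcf requires positive rate constants, got k_u={k_u!r}, k_e={k_e!r}"
        )
    out = ku_arr / ke_arr
    scalar = np.isscalar(k_u) and np.isscalar(k_e)
    return float(out) if scalar else out
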