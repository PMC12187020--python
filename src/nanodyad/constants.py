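"""Physical constants, unit system, ion species and buffer definitions.

The internal unit system is nm / ms / mM / mV.  This combination is
self-consistent for the whole model:

* the thermal voltage ``kB*T/e`` comes out directly in mV when ``kB`` is
  expressed in mJ/K and ``e`` in C;
* with the vacuum permittivity expressed in fF/m, the Poisson operator
  ``eps_r*eps0*lap(phi)`` evaluated with phi in mV and lengths in nm yields a
  charge density directly in C/m^3, which equals ``F * sum_k z_k c_k`` with
  ``F`` in C/mol and concentrations in mM (1 mM = 1 mol/m^3);
* channel conductances in zS (1e-21 S) times potentials in mV give currents
  in yA (1e-24 A), and the flux-density identity
  ymol/(nm^2 s) = mM nm/ms holds by construction.

Conversions to/from SI therefore only occur at input parsing and output
reporting, never inside the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "IonSpecies",
    "BufferSpec",
    "UnitSystem",
    "CONSTANTS",
    "default_species",
    "default_buffers",
    "thermal_voltage",
    "nernst_potential",
    "buffer_equilibrium",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants in the internal unit system.

    Attributes
    ----------
    F : float
        Faraday's constant (C/mol).
    eps0 : float
        Vacuum permittivity (fF/m).
    e : float
        Elementary charge (C).
    kB : float
        Boltzmann constant (mJ/K).
    T : float
        Absolute temperature (K).
    """

    F: float = 96485.3365
    eps0: float = 8854.0
    e: float = 1.60217662e-19
    kB: float = 1.380649e-20
    T: float = 310.0

    def __post_init__(self) -> None:
        for name in ("F", "eps0", "e", "kB", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"physical constant {name!r} must be positive")


#: Module-level default constants (temperature 310 K).
CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species with valence, diffusivities and initial concentrations.

    Diffusion coefficients are in nm^2/ms (``De`` extracellular, ``Di``
    intracellular; zero inside the membrane), concentrations in mM.
    """

    name: str
    z: int
    De: float
    Di: float
    c0e: float
    c0i: float

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("ion valence must be nonzero")
        if self.De < 0 or self.Di < 0:
            raise ValueError("diffusion coefficients must be nonnegative")


@dataclass(frozen=True)
class BufferSpec:
    """A stationary (non-diffusing) ion-binding buffer.

    Attributes
    ----------
    name : str
    target : str
        Name of the ion the buffer binds (Ca in the defaults).
    Btot : float
        Total buffer concentration (mM).
    kon : float
        Binding on-rate (1/(ms*mM)).
    koff : float
        Unbinding off-rate (1/ms).
    """

    name: str
    target: str
    Btot: float
    kon: float
    koff: float

    def __post_init__(self) -> None:
        if min(self.Btot, self.kon, self.koff) <= 0:
            raise ValueError("Btot, kon and koff must be positive")

    @property
    def Kd(self) -> float:
        """Dissociation constant koff/kon (mM)."""
        return self.koff / self.kon


def default_species() -> list[IonSpecies]:
    """The four-species set used in the dyad simulations.

    Extracellular diffusivities are free-solution values; intracellular
    values are reduced by the same cytosolic crowding factor for all species
    (anchored by the intracellular Ca2+ diffusivity).  Initial concentrations
    are standard cardiomyocyte resting values; the extracellular column is
    electroneutral by itself (100 + 5 + 2*1.4 - 107.8 = 0).
    """
    return [
        IonSpecies("Na", +1, 1.33e6, 0.37e6, 100.0, 12.0),
        IonSpecies("K", +1, 1.96e6, 0.55e6, 5.0, 125.0),
        IonSpecies("Ca", +2, 0.71e6, 0.20e6, 1.4, 1.0e-4),
        IonSpecies("Cl", -1, 2.03e6, 0.57e6, 107.8, 15.0),
    ]


def default_buffers() -> list[BufferSpec]:
    """The two stationary intracellular Ca2+ buffers (high and low affinity)."""
    return [
        BufferSpec("high_affinity", "Ca", Btot=0.20, kon=100.0, koff=0.03),
        BufferSpec("low_affinity", "Ca", Btot=0.56, kon=100.0, koff=1.3),
    ]


# ---------------------------------------------------------------------------
# Unit system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSystem:
    """Conversion factors between internal units and SI for reporting.

    Factors are multiplicative: ``value_SI = value_internal * to_si[unit]``.
    Charge density needs no factor — the internal Poisson bookkeeping already
    carries it in C/m^3 (see module docstring).
    """

    to_si: dict = field(default_factory=lambda: {
        "length": 1e-9,            # nm -> m
        "time": 1e-3,              # ms -> s
        "concentration": 1.0,      # mM = mol/m^3
        "potential": 1e-3,         # mV -> V
        "conductance": 1e-21,      # zS -> S
        "current": 1e-24,          # yA -> A
        "capacitance_density": 1e-24 / 1e-18,   # yF/nm^2 -> F/m^2
        "amount": 1e-24,           # ymol -> mol
        "charge_density": 1.0,     # already C/m^3
        # mM nm/ms = 1 mol/m^3 * 1e-9 m / 1e-3 s; equals ymol/(nm^2 s)
        "flux_density": 1e-6,
    })

    def si(self, value: float, unit: str) -> float:
        return value * self.to_si[unit]

    def internal(self, value: float, unit: str) -> float:
        return value / self.to_si[unit]


# ---------------------------------------------------------------------------
# Closed-form electrochemical helpers
# ---------------------------------------------------------------------------

def thermal_voltage(constants: PhysicalConstants = CONSTANTS) -> float:
    """Thermal voltage kB*T/e in mV."""
    return constants.kB * constants.T / constants.e


def nernst_potential(
    z: int,
    ce: float,
    ci: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Nernst equilibrium potential (mV) for valence ``z``.

    ``v0 = (kB*T/(z*e)) * ln(ce/ci)`` with ``ce``/``ci`` the extracellular and
    intracellular concentrations (mM) at the two channel mouths.
    """
    if z == 0:
        raise ValueError("valence must be nonzero")
    if ce <= 0 or ci <= 0:
        raise ValueError("concentrations must be positive")
    return thermal_voltage(constants) / z * math.log(ce / ci)


def buffer_equilibrium(c: float, spec: BufferSpec) -> float:
    """Bound concentration (mM) at which the binding flux vanishes.

    Solves ``kon*c*(Btot - b) - koff*b = 0`` for b, i.e.
    ``b = Btot * kon*c / (kon*c + koff)``.
    """
    if c < 0:
        raise ValueError("free concentration must be nonnegative")
    return spec.Btot * spec.kon * c / (spec.kon * c + spec.koff)
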