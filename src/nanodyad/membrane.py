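"""Channel and exchanger flux models delivered as internal flux boundaries.

Channels and the Na+/Ca2+ exchanger (NCX) occupy wc x wc patches of the
membrane.  Their fluxes are not resolved by the electrodiffusion equations;
instead each unit contributes an internal boundary condition on the mouth
faces between the membrane and the adjacent intracellular (dOmega_ci) and
extracellular (dOmega_ce) cell layers.  A flux density J (mM nm/ms) is
positive for ion flow from the intracellular to the extracellular space.

Channel fluxes follow the single-channel ohmic model
``i = g (v - v0)`` with the Nernst equilibrium potential ``v0`` evaluated
from the mouth-averaged concentrations; the logarithm is linearized around
the interim (post-buffering) concentrations so the flux enters the coupled
implicit step as an affine function of the current-step unknowns.  The NCX
current density follows an established allosterically-regulated formulation
and is applied explicitly (previous-step potential, interim concentrations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, PhysicalConstants, thermal_voltage
from .mesh import UnitPlacement

__all__ = [
    "GatingSchedule",
    "ChannelSpec",
    "NCXSpec",
    "MouthState",
    "AffineFlux",
    "PotentialTrace",
    "mouth_state",
    "channel_flux_affine",
    "ncx_current_density",
    "ncx_flux_densities",
    "ALWAYS_OPEN",
    "ALWAYS_CLOSED",
]


@dataclass(frozen=True)
class GatingSchedule:
    """Deterministic gating: the unit is open iff t lies in an interval.

    ``intervals`` is an ordered list of (open_time, close_time) in ms;
    ``math.inf`` marks an open-ended interval.
    """

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_close = -math.inf
        for o, c in self.intervals:
            if not o < c:
                raise ValueError("gating interval must have open < close")
            if o < prev_close:
                raise ValueError("gating intervals must be disjoint and increasing")
            prev_close = c

    def is_open(self, t: float) -> bool:
        return any(o <= t < c for o, c in self.intervals)

    @staticmethod
    def open_from(t: float) -> "GatingSchedule":
        return GatingSchedule(((t, math.inf),))


ALWAYS_OPEN = GatingSchedule(((0.0, math.inf),))
ALWAYS_CLOSED = GatingSchedule(())


@dataclass(frozen=True)
class ChannelSpec:
    """A single ion channel: species, conductance (zS), placement, gating."""

    ion: str
    g: float
    placement: UnitPlacement
    schedule: GatingSchedule = ALWAYS_CLOSED

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("channel conductance must be positive")

    @property
    def unit_id(self) -> str:
        return self.placement.unit_id


@dataclass(frozen=True)
class NCXSpec:
    """Sodium-calcium exchanger (3 Na+ in : 1 Ca2+ out per forward cycle).

    ``Ibar`` is the whole-cell scaling current density in A/F; the single
    exchanger current is ``i = (Cm / delta) * I`` (yA) with ``Cm`` the
    specific membrane capacitance (yF/nm^2) and ``delta`` the NCX surface
    density (1/nm^2).
    """

    placement: UnitPlacement
    schedule: GatingSchedule = ALWAYS_CLOSED
    Ibar: float = 4.9
    delta: float = 4e-4
    Cm: float = 1e4
    nu: float = 0.3
    ksat: float = 0.3
    Kact: float = 0.00015
    KCai: float = 0.0036
    KCae: float = 1.3
    KNai: float = 12.3
    KNae: float = 87.5

    def __post_init__(self) -> None:
        for name in ("Ibar", "delta", "Cm", "nu", "ksat", "Kact",
                     "KCai", "KCae", "KNai", "KNae"):
            if getattr(self, name) <= 0:
                raise ValueError(f"NCX parameter {name!r} must be positive")

    @property
    def unit_id(self) -> str:
        return self.placement.unit_id


@dataclass
class MouthState:
    """Area-averaged potentials (mV) and concentrations (mM) at the mouths."""

    phii: float
    phie: float
    ci: dict[str, float]
    ce: dict[str, float]

    @property
    def v(self) -> float:
        return self.phii - self.phie


def mouth_state(
    phi: np.ndarray,
    conc: dict[str, np.ndarray],
    faces: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> MouthState:
    """Area-weighted mouth averages from flat per-cell arrays."""
    cells_i, cells_e, areas = faces
    if len(cells_i) == 0 or len(cells_e) == 0:
        raise ValueError("empty mouth face set")
    w = areas / areas.sum()
    return MouthState(
        phii=float(phi[cells_i] @ w),
        phie=float(phi[cells_e] @ w),
        ci={k: float(c[cells_i] @ w) for k, c in conc.items()},
        ce={k: float(c[cells_e] @ w) for k, c in conc.items()},
    )


@dataclass
class AffineFlux:
    """A flux density affine in current-step unknowns.

    ``J = const + sum(phi_coeffs * phi[phi_cells]) + sum(conc_coeffs *
    c_k[conc_cells])`` in mM nm/ms.  ``species`` names the transported ion.
    """

    species: str
    const: float
    phi_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    phi_coeffs: np.ndarray = field(default_factory=lambda: np.array([]))
    conc_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    conc_coeffs: np.ndarray = field(default_factory=lambda: np.array([]))

    def evaluate(self, phi: np.ndarray, c_k: np.ndarray) -> float:
        val = self.const
        if len(self.phi_cells):
            val += float(phi[self.phi_cells] @ self.phi_coeffs)
        if len(self.conc_cells):
            val += float(c_k[self.conc_cells] @ self.conc_coeffs)
        return val


def channel_flux_affine(
    spec: ChannelSpec,
    mouth_interim: MouthState,
    faces: tuple[np.ndarray, np.ndarray, np.ndarray],
    z: int,
    wc: float,
    constants: PhysicalConstants = CONSTANTS,
    phi_fixed: tuple[float, float] | None = None,
) -> AffineFlux:
    """Linearized single-channel flux density (mM nm/ms).

    The Nernst logarithm is expanded to first order around the interim mouth
    concentrations ``c~``:

        ln(ce/ci) ~ ln(c~e/c~i) + ce/c~e - ci/c~i

    so that ``J = g/(z F wc^2) * (phi_i - phi_e - (kB T/(z e)) * [...])`` is
    affine in the current-step unknowns and vanishes exactly at
    ``v = v0(c~)`` with ``c = c~``.  With ``phi_fixed = (phii, phie)`` the
    potential is not an unknown (reaction-diffusion mode) and its
    contribution is folded into the constant term.
    """
    cells_i, cells_e, areas = faces
    ct_i = mouth_interim.ci[spec.ion]
    ct_e = mouth_interim.ce[spec.ion]
    if ct_i <= 0 or ct_e <= 0:
        raise ValueError(
            f"nonpositive interim mouth concentration for {spec.ion} channel"
        )
    alpha = spec.g / (z * constants.F * wc * wc)
    vtz = thermal_voltage(constants) / z
    w = areas / areas.sum()

    const = -alpha * vtz * math.log(ct_e / ct_i)
    conc_cells = np.concatenate([cells_i, cells_e])
    conc_coeffs = np.concatenate([alpha * vtz / ct_i * w, -alpha * vtz / ct_e * w])
    if phi_fixed is not None:
        phii, phie = phi_fixed
        return AffineFlux(
            species=spec.ion,
            const=const + alpha * (phii - phie),
            conc_cells=conc_cells,
            conc_coeffs=conc_coeffs,
        )
    phi_cells = np.concatenate([cells_i, cells_e])
    phi_coeffs = np.concatenate([alpha * w, -alpha * w])
    return AffineFlux(
        species=spec.ion,
        const=const,
        phi_cells=phi_cells,
        phi_coeffs=phi_coeffs,
        conc_cells=conc_cells,
        conc_coeffs=conc_coeffs,
    )


def channel_flux_value(
    spec: ChannelSpec,
    v: float,
    ce: float,
    ci: float,
    z: int,
    wc: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Nonlinear single-channel flux density J = g (v - v0)/(z F wc^2)."""
    if ce <= 0 or ci <= 0:
        raise ValueError("concentrations must be positive")
    v0 = thermal_voltage(constants) / z * math.log(ce / ci)
    return spec.g * (v - v0) / (z * constants.F * wc * wc)


def ncx_current_density(
    mouth: MouthState,
    constants: PhysicalConstants = CONSTANTS,
    spec: NCXSpec | None = None,
) -> float:
    """NCX current density I_NCX in A/F.

    Positive I_NCX corresponds to net positive current out of the cell
    (reverse mode: Na+ out, Ca2+ in); the zero crossing sits at the exchanger
    reversal potential ``v = 3 v_Na - 2 v_Ca``.
    """
    spec = spec if spec is not None else NCXSpec(UnitPlacement("ncx", 0.0))
    nai, nae = mouth.ci["Na"], mouth.ce["Na"]
    cai, cae = mouth.ci["Ca"], mouth.ce["Ca"]
    if min(nai, nae, cai, cae) <= 0:
        raise ValueError("nonpositive mouth concentration in NCX evaluation")
    v = mouth.v
    vt = thermal_voltage(constants)
    ef = math.exp(spec.nu * v / vt)
    eb = math.exp((spec.nu - 1.0) * v / vt)
    num = ef * nai**3 * cae - eb * nae**3 * cai
    s = (
        spec.KCai * nae**3 * (1.0 + (nai / spec.KNai) ** 3)
        + spec.KNae**3 * cai * (1.0 + cai / spec.KCai)
        + spec.KCae * nai**3
        + nai**3 * cae
        + nae**3 * cai
    )
    denom = s * (1.0 + (spec.Kact / cai) ** 2) * (1.0 + spec.ksat * eb)
    return spec.Ibar * num / denom


def ncx_flux_densities(
    INCX: float,
    spec: NCXSpec,
    wc: float,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[float, float]:
    """Convert I_NCX (A/F) to (J_Na, J_Ca) flux densities (mM nm/ms).

    The single-exchanger current is ``i = (Cm/delta) I_NCX`` (yA); the 3:1
    stoichiometry gives ``J_Na = 3 i/(F wc^2)`` and ``J_Ca = -i/(F wc^2)``,
    so ``J_Na / J_Ca = -3`` whenever the current is nonzero.
    """
    i_single = spec.Cm / spec.delta * INCX
    jna = 3.0 * i_single / (constants.F * wc * wc)
    jca = -i_single / (constants.F * wc * wc)
    return jna, jca


@dataclass
class PotentialTrace:
    """Per-unit mouth potential time series recorded from a PNP run.

    Used to drive transmembrane fluxes in models that do not compute an
    electrical potential.  Piecewise-linear interpolation in time; querying
    outside the recorded range raises.
    """

    times: np.ndarray
    phii: dict[str, np.ndarray]
    phie: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")

    def __call__(self, unit_id: str, t: float) -> tuple[float, float]:
        if len(self.times) == 0:
            raise ValueError("empty potential trace")
        t0, t1 = self.times[0], self.times[-1]
        if t < t0 - 1e-12 or t > t1 + 1e-12:
            raise ValueError(
                f"time {t} ms outside potential trace range [{t0}, {t1}] ms"
            )
        t = min(max(t, t0), t1)
        pi = float(np.interp(t, self.times, self.phii[unit_id]))
        pe = float(np.interp(t, self.times, self.phie[unit_id]))
        return pi, pe

    @staticmethod
    def zeros(unit_ids: list[str], t_end: float) -> "PotentialTrace":
        times = np.array([0.0, t_end])
        return PotentialTrace(
            times=times,
            phii={u: np.zeros(2) for u in unit_ids},
            phie={u: np.zeros(2) for u in unit_ids},
        )
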