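"""Reduced comparison models: pure diffusion, reaction-diffusion with an
imported potential, and one-/two-compartment ODE representations of the dyad.

The diffusion and reaction-diffusion models reuse the finite-volume
machinery of the full electrodiffusion solver with the potential equation
and drift term switched off; the reaction-diffusion model drives its
membrane fluxes with mouth potentials recorded from a matched full run
(``PotentialTrace``).

The compartment ODE models are reconstructions: mass-action buffering plus
linear diffusive exchange between well-mixed compartments, with volumes from
the dyad geometry and the exchange coefficient set by calibrating the RyR
activation time against a spatially resolved reference at one point
(DCa = 2e5 nm^2/ms, Li = 7 nm by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import (
    CONSTANTS,
    BufferSpec,
    PhysicalConstants,
    buffer_equilibrium,
    thermal_voltage,
)
from .membrane import PotentialTrace
from .mesh import TensorMesh
from .solver import FieldState, SolverConfig, Stepper

__all__ = [
    "diffusion_step",
    "reaction_diffusion_step",
    "CompartmentModel",
    "one_compartment_model",
    "two_compartment_model",
    "calibrate_ode_model",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Root-finding for the exchange coefficient failed."""


# ---------------------------------------------------------------------------
# PDE reductions (thin wrappers over the shared stepper)
# ---------------------------------------------------------------------------

def diffusion_step(
    state: FieldState, mesh: TensorMesh, config: SolverConfig
) -> FieldState:
    """One backward-Euler step of pure diffusion (no potential, no buffering,
    no membrane fluxes; species fully decoupled)."""
    stepper = Stepper(
        mesh, list(state.species), [], [], config, model="diffusion"
    )
    return stepper.step(state)


def reaction_diffusion_step(
    state: FieldState,
    mesh: TensorMesh,
    units: list,
    potential: PotentialTrace,
    config: SolverConfig,
) -> FieldState:
    """One split step of buffered diffusion plus membrane fluxes computed
    with imported mouth potentials and local mouth concentrations."""
    stepper = Stepper(
        mesh, list(state.species), list(state.buffers), units, config,
        model="reaction_diffusion", potential_trace=potential,
    )
    return stepper.step(state)


# ---------------------------------------------------------------------------
# Compartment ODE models
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    name: str
    volume: float                       # nm^3
    c: float                            # free Ca2+ (mM)
    b: np.ndarray                       # bound Ca2+ per buffer (mM)


@dataclass
class CompartmentModel:
    """Well-mixed Ca2+ compartments with linear diffusive exchange.

    ``exchanges`` lists ``(i, j, k)``: a flux amount ``k * (c_j - c_i)``
    (mM nm^3/ms) into compartment i from j.  The membrane Ca2+ channel feeds
    the first compartment; its flux uses the single-channel model with the
    transmembrane potential from ``potential_source`` (a callable t -> v in
    mV) and a fixed extracellular concentration.  Buffering follows the same
    mass-action kinetics as the spatial models.
    """

    compartments: list[Compartment]
    exchanges: list[tuple[int, int, float]]
    buffers: list[BufferSpec]
    g_ca: float = 8e9                   # channel conductance, zS
    wc: float = 4.0
    ce: float = 1.4                     # extracellular Ca2+ (mM), fixed
    z: int = 2
    potential_source: object = None     # callable t -> v (mV); None = closed
    t_open: float = 0.0
    constants: PhysicalConstants = CONSTANTS
    t: float = 0.0
    influx_total: float = 0.0           # integrated channel influx (mM nm^3)

    def copy(self) -> "CompartmentModel":
        m = CompartmentModel(
            compartments=[
                Compartment(c.name, c.volume, c.c, c.b.copy())
                for c in self.compartments
            ],
            exchanges=list(self.exchanges),
            buffers=list(self.buffers),
            g_ca=self.g_ca,
            wc=self.wc,
            ce=self.ce,
            z=self.z,
            potential_source=self.potential_source,
            t_open=self.t_open,
            constants=self.constants,
            t=self.t,
        )
        m.influx_total = self.influx_total
        return m

    # -- one operator-split backward-Euler step ------------------------------
    def step(self, dt: float, buffer_substeps: int = 1) -> None:
        n = len(self.compartments)
        # explicit buffering sub-step (same scheme as the PDE solver)
        h = dt / buffer_substeps
        for _ in range(buffer_substeps):
            for j, bf in enumerate(self.buffers):
                for comp in self.compartments:
                    JB = bf.kon * comp.c * (bf.Btot - comp.b[j]) - bf.koff * comp.b[j]
                    comp.c -= h * JB
                    comp.b[j] += h * JB
        c_tilde = np.array([comp.c for comp in self.compartments])
        V = np.array([comp.volume for comp in self.compartments])

        # implicit linear step: exchange + affine channel flux
        A = np.eye(n)
        rhs = c_tilde.copy()
        for i, j, k in self.exchanges:
            A[i, i] += dt * k / V[i]
            A[i, j] -= dt * k / V[i]
            A[j, j] += dt * k / V[j]
            A[j, i] -= dt * k / V[j]
        channel_open = (
            self.potential_source is not None and self.t >= self.t_open
        )
        if channel_open:
            v = float(self.potential_source(self.t + dt))
            cd = max(c_tilde[0], 1e-30)
            alpha = self.g_ca / (self.z * self.constants.F * self.wc**2)
            vtz = thermal_voltage(self.constants) / self.z
            # J = alpha*(v - vtz*(ln(ce/c~d) + 1 - cd/c~d)), affine in cd
            const = alpha * (v - vtz * (math.log(self.ce / cd) + 1.0))
            slope = alpha * vtz / cd
            # influx into compartment 0 is -J*wc^2
            area = self.wc**2
            A[0, 0] += dt * area * slope / V[0]
            rhs[0] += -dt * area * const / V[0]
        c_new = np.linalg.solve(A, rhs)
        if channel_open:
            J = const + slope * c_new[0]
            self.influx_total += -J * self.wc**2 * dt
        for comp, c in zip(self.compartments, c_new):
            comp.c = float(c)
        self.t += dt

    def total_ca(self) -> float:
        """Total Ca amount, free + bound (mM nm^3)."""
        return sum(c.volume * (c.c + float(c.b.sum())) for c in self.compartments)

    def run_activation_time(
        self,
        dt: float,
        t_max: float,
        threshold: float = 5e-4,
        monitor: int | None = None,
        buffer_substeps: int = 1,
    ) -> float:
        """Time from channel opening until the monitored compartment's free
        [Ca2+] exceeds the threshold; inf if never reached within t_max.

        By default the RyR-facing compartment is monitored: the dyad in the
        one-compartment model, the SR-side half in the two-compartment model
        (the cytosol is always the last compartment).
        """
        if monitor is None:
            monitor = len(self.compartments) - 2
        prev_t, prev_c = self.t, self.compartments[monitor].c
        while self.t < t_max - 1e-12:
            self.step(dt, buffer_substeps)
            c = self.compartments[monitor].c
            if c >= threshold and self.t > self.t_open:
                if c == prev_c:
                    t_cross = self.t
                else:
                    t_cross = prev_t + (threshold - prev_c) / (c - prev_c) * (
                        self.t - prev_t
                    )
                return max(0.0, t_cross - self.t_open)
            prev_t, prev_c = self.t, c
        return math.inf


def _equilibrated(name: str, volume: float, c0: float, buffers: list[BufferSpec]):
    b = np.array([buffer_equilibrium(c0, bf) for bf in buffers])
    return Compartment(name, volume, c0, b)


def one_compartment_model(
    Li: float,
    buffers: list[BufferSpec],
    k_dl: float,
    potential_source=None,
    t_open: float = 0.0,
    dyad_area: float = 900.0,
    cytosol_area: float = 1e6,
    c0: float = 1e-4,
    g_ca: float = 8e9,
    wc: float = 4.0,
    ce: float = 1.4,
) -> CompartmentModel:
    """Dyad compartment (Li x dyad_area) exchanging with a large cytosol.

    ``k_dl`` (nm^3/ms) is the dyad-cytosol exchange coefficient; it does not
    depend on the diffusion coefficient, so the activation time is
    insensitive to DCa in this variant.
    """
    Vd = Li * dyad_area
    Vl = Li * cytosol_area - Vd
    return CompartmentModel(
        compartments=[
            _equilibrated("dyad", Vd, c0, buffers),
            _equilibrated("cytosol", Vl, c0, buffers),
        ],
        exchanges=[(0, 1, k_dl)],
        buffers=buffers,
        g_ca=g_ca,
        wc=wc,
        ce=ce,
        potential_source=potential_source,
        t_open=t_open,
    )


def two_compartment_model(
    Li: float,
    DCa: float,
    buffers: list[BufferSpec],
    theta: float,
    potential_source=None,
    t_open: float = 0.0,
    dyad_area: float = 900.0,
    cytosol_area: float = 1e6,
    c0: float = 1e-4,
    g_ca: float = 8e9,
    wc: float = 4.0,
    ce: float = 1.4,
) -> CompartmentModel:
    """Two dyad half-compartments (channel side / RyR side) plus cytosol.

    The channel-to-RyR exchange coefficient is ``theta * DCa * A_d / (Li/2)``
    — a Fickian estimate for two slabs of thickness Li/2 scaled by the single
    calibrated factor ``theta`` — so the activation time is monotone
    (decreasing) in DCa and increasing in Li.  Each half also leaks laterally
    into the cytosol across the patch perimeter with an unscaled Fickian
    coefficient; only the transfer coefficient is calibrated, which keeps the
    activation time monotone in ``theta`` (a prerequisite for the scalar
    root-find).
    """
    Vh = Li / 2.0 * dyad_area
    Vl = Li * cytosol_area - 2.0 * Vh
    side = math.sqrt(dyad_area)
    k_cr = theta * DCa * dyad_area / (Li / 2.0)
    k_lat = DCa * (4.0 * side * Li / 2.0) / (side / 2.0)
    return CompartmentModel(
        compartments=[
            _equilibrated("channel_side", Vh, c0, buffers),
            _equilibrated("ryr_side", Vh, c0, buffers),
            _equilibrated("cytosol", Vl, c0, buffers),
        ],
        exchanges=[(0, 1, k_cr), (0, 2, k_lat), (1, 2, k_lat)],
        buffers=buffers,
        g_ca=g_ca,
        wc=wc,
        ce=ce,
        potential_source=potential_source,
        t_open=t_open,
    )


def calibrate_ode_model(
    reference_time: float,
    model_builder,
    dt: float,
    t_max: float,
    threshold: float = 5e-4,
    bracket: tuple[float, float] = (1e-8, 1e8),
    rtol: float = 1e-3,
    buffer_substeps: int = 1,
) -> float:
    """Scalar root-find on the exchange coefficient.

    ``model_builder(coefficient)`` must return a fresh CompartmentModel; the
    returned coefficient makes the model's activation time equal the
    reference within ``rtol``.  A larger exchange coefficient drains the
    dyad into the cytosol faster, delaying (and eventually preventing)
    activation, so the activation time increases with the coefficient and a
    sign change over the bracket is required.
    """

    def f(log_k: float) -> float:
        m = model_builder(10.0 ** log_k)
        t = m.run_activation_time(
            dt, t_max, threshold, buffer_substeps=buffer_substeps
        )
        if math.isinf(t):
            t = t_max * 10.0
        return t - reference_time

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            "no sign change over the exchange-coefficient bracket; "
            f"f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
        )
    log_k = brentq(f, lo, hi, rtol=1e-6)
    k = 10.0 ** log_k
    m = model_builder(k)
    t = m.run_activation_time(dt, t_max, threshold, buffer_substeps=buffer_substeps)
    if abs(t - reference_time) > rtol * reference_time + dt:
        raise CalibrationError(
            f"calibrated activation time {t:.4g} ms misses the reference "
            f"{reference_time:.4g} ms"
        )
    return k


# ---------------------------------------------------------------------------
# Scenario plumbing for ODE models
# ---------------------------------------------------------------------------

def run_ode_scenario(scenario, initial_state=None):
    """Run an ode1/ode2 scenario declared via ``scenario.ode_params``.

    Returns a RunResult-like object whose trajectory holds the dyad (ode1) or
    RyR-side (ode2) free [Ca2+].
    """
    from .observables import Trajectory
    from .solver import RunResult

    p = dict(scenario.ode_params)
    buffers = scenario.buffers_list()
    v_src = p.get("potential_source") or (lambda t: p.get("v", -80.0))
    common = dict(
        potential_source=v_src,
        t_open=p.get("t_open", 0.0),
        dyad_area=p.get("dyad_area", 900.0),
        c0=p.get("c0", 1e-4),
        g_ca=p.get("g_ca", 8e9),
        wc=scenario.geometry.wc,
        ce=p.get("ce", 1.4),
    )
    if scenario.model == "ode1":
        model = one_compartment_model(
            scenario.geometry.Li, buffers, p["k_dl"], **common
        )
        monitor = 0
    else:
        model = two_compartment_model(
            scenario.geometry.Li, p["DCa"], buffers, p["theta"], **common
        )
        monitor = 1
    dt = scenario.solver.dt
    substeps = scenario.solver.buffer_substeps
    traj = Trajectory(metadata={"scenario": scenario.name})
    traj.append(model.t, {"ca_monitor": model.compartments[monitor].c})
    n = int(round(scenario.duration / dt))
    for _ in range(n):
        model.step(dt, substeps)
        traj.append(model.t, {"ca_monitor": model.compartments[monitor].c})
    return RunResult(
        state=model, mesh=None, trajectory=traj,
        trace=PotentialTrace.zeros([], scenario.duration), scenario=scenario,
    )
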