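"""Derived quantities: transmembrane potential, charge profiles, equation-term
magnitudes, RyR activation time, and the Trajectory container."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .membrane import mouth_state
from .mesh import OMEGA_I, OMEGA_M, TensorMesh, UnitPlacement, observation_point
from .solver import FieldState, Stepper, charge_density, total_amounts

__all__ = [
    "Trajectory",
    "TermBreakdown",
    "transmembrane_potential",
    "term_breakdown",
    "ryr_activation_time",
    "ryr_patch_cells",
    "line_profile",
    "make_observables",
    "NOT_ACTIVATED",
]

#: Sentinel returned when the activation threshold is never reached.
NOT_ACTIVATED = math.inf


@dataclass
class Trajectory:
    """Sampled times (ms) and per-observable series of equal length."""

    times: list = field(default_factory=list)
    series: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def append(self, t: float, values: dict) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("trajectory times must be strictly increasing")
        if self.series and set(values) != set(self.series):
            raise ValueError("observable set changed mid-run")
        self.times.append(t)
        for name, v in values.items():
            self.series.setdefault(name, []).append(v)

    def __len__(self) -> int:
        return len(self.times)

    def array(self, name: str) -> np.ndarray:
        return np.asarray(self.series[name], dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.times, **self.series})


@dataclass
class TermBreakdown:
    """Magnitudes of the three concentration-equation terms at one point.

    ``Bd`` diffusion, ``Be`` electrical drift, ``Bb`` buffering (all mM/ms).
    Away from membrane-unit mouths the discrete balance
    ``Bd + Be - Bb = dc/dt`` holds exactly.
    """

    Bd: float
    Be: float
    Bb: float


def transmembrane_potential(state: FieldState, mesh: TensorMesh, unit_id: str) -> float:
    """v = phi_i - phi_e from area-averaged mouth potentials (mV)."""
    m = mouth_state(state.phi, state.conc_dict(), mesh.unit_faces[unit_id])
    return m.v


def term_breakdown(stepper: Stepper, species: str, cell: int) -> TermBreakdown:
    """Equation-term magnitudes at one cell for the most recent step."""
    if stepper.sub[cell] == OMEGA_M:
        raise ValueError("term breakdown is undefined inside the membrane")
    k = [s.name for s in stepper.species].index(species)
    Bd, Be, Bb = stepper.term_fields()
    return TermBreakdown(
        Bd=float(Bd[k][cell]), Be=float(Be[k][cell]), Bb=float(Bb[k][cell])
    )


def ryr_patch_cells(
    mesh: TensorMesh,
    placement: UnitPlacement | str,
    width: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cells and area weights of the RyR patch on the SR boundary.

    The patch is the ``width x width`` (nm) area on the rightmost
    intracellular cell layer (the SR membrane), centered directly across the
    dyad from the given unit; weights are the overlap areas of each cell's
    y-z rectangle with the patch.
    """
    if isinstance(placement, str):
        placement = mesh.placements[placement]
    g = mesh.geometry
    y0, z0 = placement.y, (placement.z if g.dims == 3 else 0.5)
    half = width / 2.0

    def _overlaps(edges: np.ndarray, lo: float, hi: float):
        w = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
        idx = np.where(w > 1e-12)[0]
        return idx, w[idx]

    iy, wy = _overlaps(mesh.edges[1], y0 - half, y0 + half)
    if g.dims == 3:
        iz, wz = _overlaps(mesh.edges[2], z0 - half, z0 + half)
    else:
        iz, wz = np.array([0]), np.array([1.0])
    ix = mesh.shape[0] - 1
    if mesh.x_subdomain[ix] != OMEGA_I:
        raise ValueError("the rightmost cell layer is not intracellular")
    IY, IZ = np.meshgrid(iy, iz, indexing="ij")
    cells = mesh.ravel(np.full(IY.size, ix), IY.ravel(), IZ.ravel())
    weights = (wy[:, None] * wz[None, :]).ravel()
    return cells, weights / weights.sum()


def ryr_activation_time(
    times: np.ndarray,
    ca_patch: np.ndarray,
    t_open: float,
    threshold: float = 5e-4,
) -> float:
    """Delay (ms) from channel opening until the patch-averaged [Ca2+]
    first exceeds the threshold (default 0.5 uM), linearly interpolated
    between output samples.  Returns ``NOT_ACTIVATED`` (inf) if the
    threshold is never reached."""
    times = np.asarray(times, dtype=float)
    ca = np.asarray(ca_patch, dtype=float)
    above = ca >= threshold
    if not above.any():
        return NOT_ACTIVATED
    i = int(np.argmax(above))
    if i == 0:
        t_cross = times[0]
    else:
        t0, t1 = times[i - 1], times[i]
        c0, c1 = ca[i - 1], ca[i]
        t_cross = t0 + (threshold - c0) / (c1 - c0) * (t1 - t0)
    return max(0.0, float(t_cross) - t_open)


def line_profile(
    state: FieldState,
    mesh: TensorMesh,
    anchor: tuple[float, float] | UnitPlacement | str = None,
    constants: PhysicalConstants = CONSTANTS,
) -> dict:
    """Solution profiles along a mesh line in x at the given (y, z) anchor.

    Returns x cell centers, subdomain labels, phi, per-species c, and rho.
    Concentrations are reported as NaN inside the membrane (no unknowns
    there).
    """
    if anchor is None:
        anchor = (mesh.geometry.Ly / 2.0, mesh.geometry.Lz / 2.0)
    if isinstance(anchor, str):
        anchor = mesh.placements[anchor]
    if isinstance(anchor, UnitPlacement):
        anchor = (anchor.y, anchor.z if mesh.geometry.dims == 3 else 0.5)
    iy = int(np.argmin(np.abs(mesh.centers[1] - anchor[0])))
    iz = (
        int(np.argmin(np.abs(mesh.centers[2] - anchor[1])))
        if mesh.geometry.dims == 3
        else 0
    )
    nx = mesh.shape[0]
    cells = mesh.ravel(np.arange(nx), np.full(nx, iy), np.full(nx, iz))
    rho = charge_density(state, constants)
    mem = mesh.x_subdomain == OMEGA_M
    out = {
        "x": mesh.centers[0].copy(),
        "subdomain": mesh.x_subdomain.copy(),
        "phi": state.phi[cells].copy(),
        "rho": rho[cells].copy(),
    }
    for i, s in enumerate(state.species):
        prof = state.c[i][cells].copy()
        prof[mem] = np.nan
        out[s.name] = prof
    return out


# ---------------------------------------------------------------------------
# Observable registry for the run loop
# ---------------------------------------------------------------------------

def make_observables(scenario, mesh: TensorMesh, stepper: Stepper):
    """Build (name, fn(state, stepper) -> float) pairs from declarations.

    Supported kinds:

    * ``v``            — transmembrane potential of a unit (mV)
    * ``point``        — species concentration at an observation point
                          (unit + x_fraction), mM
    * ``ryr_patch``    — patch-averaged [Ca2+] on the SR boundary across
                          from a unit (mM); optional ``width`` (nm)
    * ``mass``         — total free+bound amount of a species (mM nm^3)
    * ``rho_point``    — charge density at a unit observation point or the
                          domain center (C/m^3)
    * ``conc_center``  — species concentration at the domain-center cell
    * ``terms``        — Bd/Be/Bb of a species at an observation point
                          (three series; NaN before the first step)
    """
    out = []
    names = [s.name for s in stepper.species]
    center_cell = int(mesh.ravel(*[n // 2 for n in mesh.shape]))
    for decl in getattr(scenario, "observables", []):
        kind = decl["kind"]
        if kind == "v":
            uid = decl["unit"]

            def fn(s, st, uid=uid):
                return transmembrane_potential(s, mesh, uid)

            out.append((decl.get("name", f"v_{uid}"), fn))
        elif kind == "point":
            uid = decl["unit"]
            k = names.index(decl["species"])
            cell = observation_point(mesh, uid, decl.get("x_fraction", 0.5))

            def fn(s, st, k=k, cell=cell):
                return float(s.c[k][cell])

            out.append((decl.get("name", f"{decl['species']}_point_{uid}"), fn))
        elif kind == "ryr_patch":
            uid = decl["unit"]
            k = names.index(decl.get("species", "Ca"))
            cells, w = ryr_patch_cells(mesh, uid, decl.get("width", 30.0))

            def fn(s, st, k=k, cells=cells, w=w):
                return float(s.c[k][cells] @ w)

            out.append((decl.get("name", f"ca_ryr_{uid}"), fn))
        elif kind == "mass":
            sp = decl["species"]

            def fn(s, st, sp=sp):
                return total_amounts(s, mesh)[sp]

            out.append((decl.get("name", f"mass_{sp}"), fn))
        elif kind == "rho_point":
            cell = center_cell
            if "unit" in decl:
                cell = observation_point(mesh, decl["unit"], decl.get("x_fraction", 0.5))

            def fn(s, st, cell=cell):
                return float(charge_density(s)[cell])

            out.append((decl.get("name", "rho_center"), fn))
        elif kind == "conc_center":
            k = names.index(decl["species"])

            def fn(s, st, k=k):
                return float(s.c[k][center_cell])

            out.append((decl.get("name", f"{decl['species']}_center"), fn))
        elif kind == "terms":
            k = names.index(decl["species"])
            cell = (
                observation_point(mesh, decl["unit"], decl.get("x_fraction", 0.5))
                if "unit" in decl
                else center_cell
            )
            stem = decl.get("name", f"{decl['species']}")
            for term_i, term in enumerate(("Bd", "Be", "Bb")):

                def fn(s, st, k=k, cell=cell, term_i=term_i):
                    try:
                        fields = st.term_fields()
                    except Exception:
                        return math.nan
                    return float(fields[term_i][k][cell])

                out.append((f"{term}_{stem}", fn))
        else:
            raise ValueError(f"unknown observable kind {kind!r}")
    return out
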