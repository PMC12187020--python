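"""Buffered Poisson-Nernst-Planck solver on the tensor mesh.

Each time step is split into two sub-steps:

1. an explicit (forward-Euler) update of the buffer binding kinetics,
   producing interim concentrations ``c~`` and updated bound concentrations;
2. a fully coupled implicit (backward-Euler) solve of the Poisson equation
   and the Nernst-Planck equations, with the drift mobility frozen at ``c~``
   so that the system is linear in the current-step unknowns (potential at
   every cell, concentrations at every non-membrane cell).

Open channels enter the coupled system implicitly through an affine flux
(linearized Nernst term); the NCX flux is evaluated explicitly from the
previous step's potential and the interim concentrations.  The spatial
discretization is conservative two-point-flux finite volumes: face diffusion
coefficients are harmonic means (exactly zero into the membrane) and the
face drift mobility uses the arithmetic mean of the adjacent interim
concentrations.  Interior face fluxes cancel pairwise, so species mass is
conserved to linear-solver tolerance whenever boundaries and units are
closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import (
    CONSTANTS,
    BufferSpec,
    IonSpecies,
    PhysicalConstants,
    buffer_equilibrium,
    thermal_voltage,
)
from .membrane import (
    ChannelSpec,
    NCXSpec,
    PotentialTrace,
    channel_flux_affine,
    mouth_state,
    ncx_current_density,
    ncx_flux_densities,
)
from .mesh import OMEGA_E, OMEGA_I, OMEGA_M, TensorMesh

__all__ = [
    "SolverConfig",
    "FieldState",
    "ConfigurationError",
    "SolverError",
    "init_state",
    "charge_density",
    "buffering_step",
    "Stepper",
    "LinearSystem",
    "assemble_coupled_system",
    "solve_step",
    "total_amounts",
    "run",
    "RunResult",
]

_SIDES = ("x-", "x+", "y-", "y+", "z-", "z+")


class ConfigurationError(ValueError):
    """Inconsistent solver or scenario configuration."""


class SolverError(RuntimeError):
    """Linear solve failed or produced an unusable state."""


@dataclass(frozen=True)
class SolverConfig:
    """Time step, tolerances, permittivities and boundary conditions.

    ``phi_dirichlet`` maps domain sides ('x-', 'x+', ...) to fixed potentials
    (mV); all other sides are homogeneous Neumann.  ``conc_dirichlet`` maps
    sides to per-species fixed concentrations (mM); elsewhere the *total*
    (diffusive + drift) normal flux vanishes.  A side with a concentration
    Dirichlet condition must also fix the potential.
    """

    dt: float = 1e-3
    tol: float = 1e-8
    eps_bulk: float = 80.0
    eps_membrane: float = 2.0
    output_every: int = 1
    buffer_substeps: int = 1
    include_drift: bool = True
    phi_dirichlet: dict = field(default_factory=lambda: {"x-": 0.0})
    conc_dirichlet: dict = field(default_factory=dict)
    neg_conc_tol: float = 1e-8
    linear_strategy: str = "auto"     # "auto" | "direct" | "frozen_lu"
    direct_below: int = 4000          # unknown count below which "auto" = direct

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not 0.0 < self.tol < 1.0:
            raise ConfigurationError("solver tolerance must lie in (0, 1)")
        if self.buffer_substeps < 1:
            raise ConfigurationError("buffer_substeps must be >= 1")
        for side in list(self.phi_dirichlet) + list(self.conc_dirichlet):
            if side not in _SIDES:
                raise ConfigurationError(f"unknown boundary side {side!r}")
        for side in self.conc_dirichlet:
            if side not in self.phi_dirichlet:
                raise ConfigurationError(
                    "concentration Dirichlet sides must also fix the potential"
                )
        if self.linear_strategy not in ("auto", "direct", "frozen_lu"):
            raise ConfigurationError(
                f"unknown linear_strategy {self.linear_strategy!r}"
            )


@dataclass
class FieldState:
    """Potential, concentrations, bound buffers and background charge.

    ``phi`` (mV) lives at every cell; ``c`` (mM, shape (K, N)) is zero in the
    membrane where no concentration unknowns exist; ``b`` (mM, shape
    (n_buffers, N)) is nonzero only in the intracellular domain; ``rho0``
    (C/m^3) is the fixed background charge.
    """

    species: tuple[IonSpecies, ...]
    buffers: tuple[BufferSpec, ...]
    phi: np.ndarray
    c: np.ndarray
    b: np.ndarray
    rho0: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(
            species=self.species,
            buffers=self.buffers,
            phi=self.phi.copy(),
            c=self.c.copy(),
            b=self.b.copy(),
            rho0=self.rho0.copy(),
            t=self.t,
        )

    def species_index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(name)

    def conc_dict(self, c: np.ndarray | None = None) -> dict[str, np.ndarray]:
        c = self.c if c is None else c
        return {s.name: c[i] for i, s in enumerate(self.species)}


def init_state(
    species: list[IonSpecies],
    buffers: list[BufferSpec],
    mesh: TensorMesh,
    constants: PhysicalConstants = CONSTANTS,
    electroneutral: bool = True,
) -> FieldState:
    """Initial condition: per-subdomain concentrations, buffers at binding
    equilibrium, zero potential, and (by default) a background charge chosen
    so the initial charge density vanishes everywhere."""
    sub = mesh.subdomain.ravel()
    N = mesh.n_cells
    c = np.zeros((len(species), N))
    for i, s in enumerate(species):
        c[i][sub == OMEGA_E] = s.c0e
        c[i][sub == OMEGA_I] = s.c0i
    b = np.zeros((len(buffers), N))
    intra = sub == OMEGA_I
    names = [s.name for s in species]
    for j, bf in enumerate(buffers):
        k = names.index(bf.target)
        b[j][intra] = buffer_equilibrium(float(species[k].c0i), bf)
    state = FieldState(
        species=tuple(species),
        buffers=tuple(buffers),
        phi=np.zeros(N),
        c=c,
        b=b,
        rho0=np.zeros(N),
        t=0.0,
    )
    if electroneutral:
        state.rho0 = -_mobile_charge(state, constants)
    return state


def _mobile_charge(state: FieldState, constants: PhysicalConstants) -> np.ndarray:
    """F * sum_k z_k (c_k + sum_j b_kj) in C/m^3."""
    rho = np.zeros_like(state.phi)
    names = [s.name for s in state.species]
    for i, s in enumerate(state.species):
        rho += s.z * state.c[i]
    for j, bf in enumerate(state.buffers):
        rho += state.species[names.index(bf.target)].z * state.b[j]
    return constants.F * rho


def charge_density(
    state: FieldState, constants: PhysicalConstants = CONSTANTS
) -> np.ndarray:
    """Charge density rho = rho0 + F sum_k z_k (c_k + sum_j b_kj) (C/m^3)."""
    return state.rho0 + _mobile_charge(state, constants)


def buffering_step(
    state: FieldState,
    dt: float,
    intra_mask: np.ndarray,
    substeps: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Explicit forward-Euler buffer kinetics sub-step.

    Returns ``(c_tilde, b_new, Bb)`` where ``Bb = (c - c_tilde)/dt`` is the
    per-cell buffering rate (mM/ms).  Free + bound amount is conserved
    exactly per cell.  Raises if a bound concentration leaves [0, Btot].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = state.c.copy()
    b = state.b.copy()
    names = [s.name for s in state.species]
    h = dt / substeps
    for _ in range(substeps):
        for j, bf in enumerate(state.buffers):
            k = names.index(bf.target)
            JB = np.where(
                intra_mask,
                bf.kon * c[k] * (bf.Btot - b[j]) - bf.koff * b[j],
                0.0,
            )
            c[k] -= h * JB
            b[j] += h * JB
    for j, bf in enumerate(state.buffers):
        if b[j].min() < -1e-9 or b[j].max() > bf.Btot + 1e-9:
            raise SolverError(
                f"buffer {bf.name!r} left [0, Btot] in the explicit buffering "
                "step; reduce dt or increase buffer_substeps"
            )
    Bb = (state.c - c) / dt
    return c, b, Bb


def total_amounts(state: FieldState, mesh: TensorMesh) -> dict[str, float]:
    """Total amount per species (free + buffer-bound), in mM nm^3."""
    V = mesh.cell_volumes.ravel()
    out = {s.name: float(state.c[i] @ V) for i, s in enumerate(state.species)}
    for j, bf in enumerate(state.buffers):
        out[bf.target] += float(state.b[j] @ V)
    return out


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    return np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)


# ---------------------------------------------------------------------------
# Stepper: precomputed connectivity + per-step assembly and solve
# ---------------------------------------------------------------------------

class Stepper:
    """One (mesh, species, units, config) problem with precomputed assembly.

    ``model`` selects the equations solved in the implicit step:

    * ``"pnp"`` — Poisson + Nernst-Planck, fully coupled;
    * ``"reaction_diffusion"`` — diffusion + buffering + membrane fluxes with
      the potential imported from ``potential_trace``;
    * ``"diffusion"`` — pure diffusion, species decoupled, no membrane flux.
    """

    def __init__(
        self,
        mesh: TensorMesh,
        species: list[IonSpecies],
        buffers: list[BufferSpec],
        units: list,
        config: SolverConfig,
        constants: PhysicalConstants = CONSTANTS,
        model: str = "pnp",
        potential_trace: PotentialTrace | None = None,
    ) -> None:
        if model not in ("pnp", "diffusion", "reaction_diffusion"):
            raise ConfigurationError(f"unknown model {model!r}")
        if model == "reaction_diffusion" and units and potential_trace is None:
            raise ConfigurationError(
                "reaction_diffusion with membrane units requires a potential trace"
            )
        self.mesh = mesh
        self.species = list(species)
        self.buffers = list(buffers)
        self.units = list(units)
        self.config = config
        self.constants = constants
        self.model = model
        self.trace = potential_trace
        self.vt = thermal_voltage(constants)
        self.has_potential = model == "pnp"

        shape = mesh.shape
        N = mesh.n_cells
        self.N = N
        sub = mesh.subdomain.ravel()
        self.sub = sub
        self.V = mesh.cell_volumes.ravel()
        self.intra = sub == OMEGA_I
        self.conc_mask = sub != OMEGA_M
        self.conc_cells = np.where(self.conc_mask)[0]
        self.cmap = -np.ones(N, dtype=np.int64)
        self.cmap[self.conc_mask] = np.arange(int(self.conc_mask.sum()))
        self.Nc = int(self.conc_mask.sum())
        self.K = len(self.species)
        self.col0 = N if self.has_potential else 0
        self.n_unknowns = self.col0 + self.K * self.Nc

        if self.has_potential and not config.phi_dirichlet:
            raise ConfigurationError(
                "the Poisson equation needs at least one Dirichlet side "
                "to anchor the potential"
            )

        self.eps_cell = np.where(
            sub == OMEGA_M, config.eps_membrane, config.eps_bulk
        ).astype(float)
        self.D = {}
        for s in self.species:
            d = np.zeros(N)
            d[sub == OMEGA_E] = s.De
            d[sub == OMEGA_I] = s.Di
            self.D[s.name] = d

        # interior faces, all axes
        ids = np.arange(N).reshape(shape)
        axes_w = mesh.widths
        fL, fR, G = [], [], []
        for ax in range(3):
            if shape[ax] < 2:
                continue
            slc_l = [slice(None)] * 3
            slc_r = [slice(None)] * 3
            slc_l[ax] = slice(0, -1)
            slc_r[ax] = slice(1, None)
            L = ids[tuple(slc_l)]
            R = ids[tuple(slc_r)]
            w = axes_w[ax]
            d = 0.5 * (w[:-1] + w[1:])
            others = [axes_w[a] for a in range(3) if a != ax]
            area = np.multiply.outer(others[0], others[1])
            bshape = [1, 1, 1]
            bshape[ax] = shape[ax] - 1
            ashape = list(shape)
            ashape[ax] = 1
            g = (area.reshape(ashape) / d.reshape(bshape)) * np.ones(L.shape)
            fL.append(L.ravel())
            fR.append(R.ravel())
            G.append(g.ravel())
        self.fL = np.concatenate(fL)
        self.fR = np.concatenate(fR)
        self.G = np.concatenate(G)
        eps_f = _harmonic(self.eps_cell[self.fL], self.eps_cell[self.fR])
        self.Tphi = constants.eps0 * eps_f * self.G

        self.sp_faces = {}
        for s in self.species:
            d = self.D[s.name]
            Td = _harmonic(d[self.fL], d[self.fR]) * self.G
            keep = Td > 0
            self.sp_faces[s.name] = (self.fL[keep], self.fR[keep], Td[keep])

        self._build_static()
        self._static_lu = None   # cached factorization (static matrix only)
        self._static_A = None
        self._frozen_lu = None   # reference factorization for GMRES
        self._xprev = None
        self._open_signature = None
        self.last_residual = None
        self.last_iterations = 0

    # -- boundary geometry ---------------------------------------------------
    def _boundary(self, side: str) -> tuple[np.ndarray, np.ndarray, float]:
        """(cell ids, face areas, half cell width) on one domain side."""
        shape = self.mesh.shape
        widths = self.mesh.widths
        ids = np.arange(self.N).reshape(shape)
        ax = "xyz".index(side[0])
        if shape[ax] < 2:
            raise ConfigurationError(
                f"boundary {side!r} does not exist on this mesh"
            )
        idx = 0 if side[1] == "-" else shape[ax] - 1
        slc = [slice(None)] * 3
        slc[ax] = idx
        cells = ids[tuple(slc)].ravel()
        others = [w for a, w in enumerate(widths) if a != ax]
        areas = (np.multiply.outer(others[0], others[1]) * 1.0).ravel()
        half = widths[ax][idx] / 2.0
        return cells, areas, half

    # -- static matrix/rhs pieces ---------------------------------------------
    def _build_static(self) -> None:
        cfg = self.config
        F = self.constants.F
        N, Nc = self.N, self.Nc

        rows, cols, vals = [], [], []
        rhs_static = np.zeros(self.n_unknowns)

        if self.has_potential:
            L, R, T = self.fL, self.fR, self.Tphi
            rows += [L, L, R, R]
            cols += [L, R, R, L]
            vals += [-T, T, -T, T]
            for side, phib in cfg.phi_dirichlet.items():
                cells, areas, half = self._boundary(side)
                Tb = self.constants.eps0 * self.eps_cell[cells] * areas / half
                rows.append(cells)
                cols.append(cells)
                vals.append(-Tb)
                np.subtract.at(rhs_static, cells, Tb * phib)
            for k, s in enumerate(self.species):
                rows.append(self.conc_cells)
                cols.append(self.col0 + k * Nc + self.cmap[self.conc_cells])
                vals.append(self.V[self.conc_cells] * F * s.z)

        self.conc_dirichlet_terms = {}
        for k, s in enumerate(self.species):
            base = self.col0 + k * Nc
            r_all = base + self.cmap[self.conc_cells]
            rows.append(r_all)
            cols.append(r_all)
            vals.append(self.V[self.conc_cells] / cfg.dt)
            L, R, Td = self.sp_faces[s.name]
            rL, rR = base + self.cmap[L], base + self.cmap[R]
            rows += [rL, rL, rR, rR]
            cols += [rL, rR, rR, rL]
            vals += [Td, -Td, Td, -Td]
            terms = []
            for side, values in cfg.conc_dirichlet.items():
                if s.name not in values:
                    continue
                cells, areas, half = self._boundary(side)
                keep = self.conc_mask[cells]
                cells, areas = cells[keep], areas[keep]
                Tb = self.D[s.name][cells] * areas / half
                rows.append(base + self.cmap[cells])
                cols.append(base + self.cmap[cells])
                vals.append(Tb)
                cb = float(values[s.name])
                np.add.at(rhs_static, base + self.cmap[cells], Tb * cb)
                terms.append((cells, Tb, cb, cfg.phi_dirichlet[side]))
            self.conc_dirichlet_terms[s.name] = terms

        self.static_rows = np.concatenate(rows)
        self.static_cols = np.concatenate(cols)
        self.static_vals = np.concatenate(vals).astype(float)
        self.rhs_static = rhs_static

        # drift sparsity (values depend on the interim concentrations)
        self.drift_idx = {}
        if self.has_potential and cfg.include_drift:
            for k, s in enumerate(self.species):
                base = self.col0 + k * Nc
                L, R, Td = self.sp_faces[s.name]
                rL, rR = base + self.cmap[L], base + self.cmap[R]
                drows = np.concatenate([rL, rL, rR, rR])
                dcols = np.concatenate([L, R, R, L])
                self.drift_idx[s.name] = (drows, dcols, L, R, Td)

    # -- membrane units --------------------------------------------------------
    def _open_units(self, t: float) -> list:
        return [u for u in self.units if u.schedule.is_open(t)]

    def membrane_contributions(
        self, state: FieldState, c_tilde: np.ndarray
    ) -> tuple[list, dict[int, np.ndarray]]:
        """Affine channel fluxes and explicit NCX sources for this step.

        Returns ``(affine, explicit)``: ``affine`` holds
        ``(species_index, AffineFlux, faces)`` tuples; ``explicit`` maps a
        species index to a signed per-cell source (mM nm^3/ms).
        """
        if self.model == "diffusion":
            return [], {}
        affine: list = []
        explicit: dict[int, np.ndarray] = {}
        wc = self.mesh.geometry.wc
        names = [s.name for s in self.species]
        conc_interim = {s.name: c_tilde[i] for i, s in enumerate(self.species)}
        t_new = state.t + self.config.dt
        for unit in self._open_units(state.t):
            faces = self.mesh.unit_faces[unit.unit_id]
            cells_i, cells_e, areas = faces
            if isinstance(unit, ChannelSpec):
                k = names.index(unit.ion)
                interim = mouth_state(state.phi, conc_interim, faces)
                phi_fixed = None if self.has_potential else self.trace(
                    unit.unit_id, t_new
                )
                flux = channel_flux_affine(
                    unit, interim, faces, self.species[k].z, wc,
                    self.constants, phi_fixed=phi_fixed,
                )
                affine.append((k, flux, faces))
            elif isinstance(unit, NCXSpec):
                mouth = mouth_state(state.phi, conc_interim, faces)
                if not self.has_potential:
                    mouth.phii, mouth.phie = self.trace(unit.unit_id, state.t)
                I = ncx_current_density(mouth, self.constants, unit)
                jna, jca = ncx_flux_densities(I, unit, wc, self.constants)
                for name, J in (("Na", jna), ("Ca", jca)):
                    k = names.index(name)
                    src = explicit.setdefault(k, np.zeros(self.N))
                    np.subtract.at(src, cells_i, areas * J)
                    np.add.at(src, cells_e, areas * J)
            else:  # pragma: no cover
                raise ConfigurationError(f"unknown unit type {type(unit)!r}")
        return affine, explicit

    # -- matrix / rhs -----------------------------------------------------------
    def matrix(self, c_tilde: np.ndarray, affine: list) -> sp.csc_matrix:
        rows = [self.static_rows]
        cols = [self.static_cols]
        vals = [self.static_vals]
        for k, s in enumerate(self.species):
            if s.name not in self.drift_idx:
                continue
            base = self.col0 + k * self.Nc
            drows, dcols, L, R, Td = self.drift_idx[s.name]
            W = Td * (s.z / self.vt) * 0.5 * (c_tilde[k][L] + c_tilde[k][R])
            rows.append(drows)
            cols.append(dcols)
            vals.append(np.concatenate([W, -W, W, -W]))
            for cells_b, Tb, cb, phib in self.conc_dirichlet_terms[s.name]:
                Wb = Tb * (s.z / self.vt) * 0.5 * (c_tilde[k][cells_b] + cb)
                rows.append(base + self.cmap[cells_b])
                cols.append(cells_b)
                vals.append(Wb)
        for k, flux, faces in affine:
            base = self.col0 + k * self.Nc
            cells_i, cells_e, areas = faces
            cc = base + self.cmap[flux.conc_cells]
            coef = flux.conc_coeffs
            if self.has_potential and len(flux.phi_cells):
                cc = np.concatenate([flux.phi_cells, cc])
                coef = np.concatenate([flux.phi_coeffs, coef])
            for mouth_cells, sign in ((cells_i, +1.0), (cells_e, -1.0)):
                r = base + self.cmap[mouth_cells]
                rows.append(np.repeat(r, len(cc)))
                cols.append(np.tile(cc, len(r)))
                vals.append(sign * np.outer(areas, coef).ravel())
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_unknowns, self.n_unknowns),
        ).tocsc()

    def rhs(
        self,
        state: FieldState,
        c_tilde: np.ndarray,
        b_new: np.ndarray,
        affine: list,
        explicit: dict[int, np.ndarray],
    ) -> np.ndarray:
        cfg = self.config
        F = self.constants.F
        out = self.rhs_static.copy()
        names = [s.name for s in self.species]
        if self.has_potential:
            bsum = np.zeros(self.N)
            for j, bf in enumerate(self.buffers):
                bsum += self.species[names.index(bf.target)].z * b_new[j]
            out[: self.N] += -self.V * (state.rho0 + F * bsum)
        for k, s in enumerate(self.species):
            base = self.col0 + k * self.Nc
            r_all = base + self.cmap[self.conc_cells]
            out[r_all] += self.V[self.conc_cells] / cfg.dt * c_tilde[k][self.conc_cells]
            if s.name in self.drift_idx:
                for cells_b, Tb, cb, phib in self.conc_dirichlet_terms[s.name]:
                    Wb = Tb * (s.z / self.vt) * 0.5 * (c_tilde[k][cells_b] + cb)
                    np.add.at(out, base + self.cmap[cells_b], Wb * phib)
            if k in explicit:
                out[r_all] += explicit[k][self.conc_cells]
        for k, flux, faces in affine:
            base = self.col0 + k * self.Nc
            cells_i, cells_e, areas = faces
            np.add.at(out, base + self.cmap[cells_i], -areas * flux.const)
            np.add.at(out, base + self.cmap[cells_e], areas * flux.const)
        return out

    def assemble(
        self, state: FieldState, c_tilde: np.ndarray, b_new: np.ndarray
    ) -> tuple[sp.csc_matrix, np.ndarray]:
        affine, explicit = self.membrane_contributions(state, c_tilde)
        A = self.matrix(c_tilde, affine)
        return A, self.rhs(state, c_tilde, b_new, affine, explicit)

    # -- solve -------------------------------------------------------------------
    _PERMC = "COLAMD"   # cheapest fill-reducing ordering at scenario scale

    def _check(self, A, x, rhs) -> float:
        if not np.all(np.isfinite(x)):
            raise SolverError("linear solve produced non-finite values")
        scale = max(float(np.linalg.norm(rhs)), 1e-300)
        residual = float(np.linalg.norm(A @ x - rhs)) / scale
        if residual > self.config.tol:
            raise SolverError(
                f"linear solve residual {residual:.3e} exceeds tolerance "
                f"{self.config.tol:.1e}"
            )
        self.last_residual = residual
        return residual

    def _solve(self, A: sp.csc_matrix, lu, rhs: np.ndarray) -> np.ndarray:
        x = lu.solve(rhs)
        self._check(A, x, rhs)
        return x

    def _factor(self, A: sp.csc_matrix):
        try:
            return spla.splu(A, permc_spec=self._PERMC)
        except RuntimeError as err:
            raise SolverError(f"sparse factorization failed: {err}") from err

    def solve_coupled(self, A: sp.csc_matrix, rhs: np.ndarray, open_sig) -> np.ndarray:
        """Solve one implicit step's system.

        Small systems use a direct factorization.  Larger systems reuse a
        frozen LU factorization (of an earlier step's matrix) as a GMRES
        preconditioner — the matrix changes slowly through the drift
        coefficients — and refactor when gating changes or convergence
        degrades.
        """
        strategy = self.config.linear_strategy
        if strategy == "auto":
            strategy = (
                "direct" if self.n_unknowns <= self.config.direct_below
                else "frozen_lu"
            )
        if strategy == "direct":
            x = self._factor(A).solve(rhs)
            self.last_iterations = 0
            self._check(A, x, rhs)
            return x

        if self._frozen_lu is None or open_sig != self._open_signature:
            self._frozen_lu = self._factor(A)
            self._open_signature = open_sig
            x = self._frozen_lu.solve(rhs)
            self.last_iterations = 0
            self._check(A, x, rhs)
            return x

        M = spla.LinearOperator(A.shape, self._frozen_lu.solve)
        count = [0]

        def _cb(_):
            count[0] += 1

        x0 = self._xprev if self._xprev is not None else None
        rtol = min(self.config.tol * 1e-4, 1e-12)
        x, info = spla.gmres(
            A, rhs, x0=x0, M=M, rtol=rtol, atol=0.0,
            restart=40, maxiter=2, callback=_cb, callback_type="pr_norm",
        )
        self.last_iterations = count[0]
        scale = max(float(np.linalg.norm(rhs)), 1e-300)
        ok = info == 0 and np.all(np.isfinite(x)) and (
            float(np.linalg.norm(A @ x - rhs)) / scale <= self.config.tol
        )
        if not ok or count[0] > 30:
            self._frozen_lu = self._factor(A)
            if not ok:
                x = self._frozen_lu.solve(rhs)
        self._check(A, x, rhs)
        self._xprev = x
        return x

    def step(self, state: FieldState) -> FieldState:
        """Advance the state by one dt (buffering + coupled implicit solve)."""
        cfg = self.config
        if self.buffers and self.model in ("pnp", "reaction_diffusion"):
            c_tilde, b_new, Bb = buffering_step(
                state, cfg.dt, self.intra, cfg.buffer_substeps
            )
        else:
            c_tilde = state.c.copy()
            b_new = state.b.copy()
            Bb = np.zeros_like(state.c)

        affine, explicit = self.membrane_contributions(state, c_tilde)
        rhs = self.rhs(state, c_tilde, b_new, affine, explicit)
        if not self.has_potential and not affine:
            # matrix is time-independent: factorize once and reuse
            if self._static_lu is None:
                self._static_A = self.matrix(c_tilde, [])
                self._static_lu = self._factor(self._static_A)
            x = self._solve(self._static_A, self._static_lu, rhs)
        else:
            A = self.matrix(c_tilde, affine)
            open_sig = tuple(
                u.unit_id for u in self._open_units(state.t)
            )
            x = self.solve_coupled(A, rhs, open_sig)

        new = state.copy()
        if self.has_potential:
            new.phi = x[: self.N].copy()
        for k in range(self.K):
            ck = np.zeros(self.N)
            ck[self.conc_mask] = x[
                self.col0 + k * self.Nc: self.col0 + (k + 1) * self.Nc
            ]
            new.c[k] = ck
        new.b = b_new
        new.t = state.t + cfg.dt
        cmin = float(new.c[:, self.conc_mask].min())
        if cmin < -cfg.neg_conc_tol:
            raise SolverError(
                f"negative concentration {cmin:.3e} mM after implicit step; "
                "reduce dt or refine the mesh"
            )
        self._last = (state.c, c_tilde, new.c, new.phi, Bb)
        return new

    # -- diagnostics ----------------------------------------------------------
    def term_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Bd, Be, Bb) per species per cell (mM/ms) for the last step.

        Uses the same discrete stencils as the solve, so
        ``Bd + Be - Bb = (c^n - c^{n-1})/dt`` holds exactly away from
        membrane-unit mouths.
        """
        if not hasattr(self, "_last"):
            raise SolverError("no step has been taken yet")
        c_prev, c_tilde, c_new, phi_new, Bb = self._last
        Bd = np.zeros((self.K, self.N))
        Be = np.zeros((self.K, self.N))
        for k, s in enumerate(self.species):
            L, R, Td = self.sp_faces[s.name]
            dflux = Td * (c_new[k][R] - c_new[k][L])
            np.add.at(Bd[k], L, dflux)
            np.subtract.at(Bd[k], R, dflux)
            for cells_b, Tb, cb, phib in self.conc_dirichlet_terms[s.name]:
                np.add.at(Bd[k], cells_b, Tb * (cb - c_new[k][cells_b]))
            if s.name in self.drift_idx:
                W = Td * (s.z / self.vt) * 0.5 * (c_tilde[k][L] + c_tilde[k][R])
                eflux = W * (phi_new[R] - phi_new[L])
                np.add.at(Be[k], L, eflux)
                np.subtract.at(Be[k], R, eflux)
                for cells_b, Tb, cb, phib in self.conc_dirichlet_terms[s.name]:
                    Wb = Tb * (s.z / self.vt) * 0.5 * (c_tilde[k][cells_b] + cb)
                    np.add.at(Be[k], cells_b, Wb * (phib - phi_new[cells_b]))
            Bd[k] /= self.V
            Be[k] /= self.V
        return Bd, Be, Bb


# ---------------------------------------------------------------------------
# Spec-level operation wrappers
# ---------------------------------------------------------------------------

@dataclass
class LinearSystem:
    """Assembled coupled system for one implicit step."""

    A: sp.csc_matrix
    rhs: np.ndarray
    stepper: Stepper
    state: FieldState
    c_tilde: np.ndarray
    b_new: np.ndarray


def assemble_coupled_system(
    state: FieldState,
    c_tilde: np.ndarray,
    mesh: TensorMesh,
    units: list,
    config: SolverConfig,
    constants: PhysicalConstants = CONSTANTS,
    b_new: np.ndarray | None = None,
    model: str = "pnp",
    potential_trace: PotentialTrace | None = None,
) -> LinearSystem:
    stepper = Stepper(
        mesh, list(state.species), list(state.buffers), units, config,
        constants, model=model, potential_trace=potential_trace,
    )
    b = state.b if b_new is None else b_new
    A, rhs = stepper.assemble(state, c_tilde, b)
    return LinearSystem(A, rhs, stepper, state, c_tilde, b)


def solve_step(system: LinearSystem, config: SolverConfig) -> FieldState:
    st = system.stepper
    try:
        lu = spla.splu(system.A)
    except RuntimeError as err:
        raise SolverError(f"factorization failed: {err}") from err
    x = st._solve(system.A, lu, system.rhs)
    new = system.state.copy()
    if st.has_potential:
        new.phi = x[: st.N].copy()
    for k in range(st.K):
        ck = np.zeros(st.N)
        ck[st.conc_mask] = x[st.col0 + k * st.Nc: st.col0 + (k + 1) * st.Nc]
        new.c[k] = ck
    new.b = system.b_new.copy()
    new.t = system.state.t + config.dt
    return new


# ---------------------------------------------------------------------------
# Trajectory-producing run loop
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Final state plus recorded observables and per-unit potential trace."""

    state: FieldState
    mesh: TensorMesh
    trajectory: object           # observables.Trajectory
    trace: PotentialTrace
    scenario: object = None


def run(scenario, initial_state: FieldState | None = None, stop=None) -> RunResult:
    """Run a scenario from its initial (or a supplied restart) state.

    The scenario provides the mesh, species, buffers, units, solver
    configuration, duration and observable declarations (see
    ``nanodyad.scenarios.Scenario``).  When ``initial_state`` is given its
    clock is reset to zero, so gating schedules are relative to this run.
    ``stop``, if given, is called as ``stop(trajectory)`` after each recorded
    sample; returning True ends the run early (e.g. once an activation
    threshold has been crossed).
    """
    from .observables import Trajectory, make_observables  # local: no cycle

    if getattr(scenario, "model", "pnp") in ("ode1", "ode2"):
        from .reduced import run_ode_scenario

        return run_ode_scenario(scenario, initial_state)

    mesh = scenario.build_mesh()
    species = scenario.species_list()
    buffers = scenario.buffers_list()
    units = scenario.build_units()
    config = scenario.solver

    if initial_state is not None:
        state = initial_state.copy()
        state.t = 0.0
    else:
        state = scenario.initial_state(mesh)

    stepper = Stepper(
        mesh, species, buffers, units, config,
        model=scenario.model,
        potential_trace=getattr(scenario, "potential_trace", None),
    )
    observables = make_observables(scenario, mesh, stepper)
    trajectory = Trajectory(metadata={"scenario": scenario.name})

    unit_ids = [u.unit_id for u in units]
    trace_t: list[float] = []
    trace_i = {u: [] for u in unit_ids}
    trace_e = {u: [] for u in unit_ids}

    def _record_trace(s: FieldState) -> None:
        trace_t.append(s.t)
        for u in units:
            m = mouth_state(s.phi, s.conc_dict(), mesh.unit_faces[u.unit_id])
            trace_i[u.unit_id].append(m.phii)
            trace_e[u.unit_id].append(m.phie)

    def _record(s: FieldState) -> None:
        trajectory.append(s.t, {name: fn(s, stepper) for name, fn in observables})

    _record_trace(state)
    _record(state)
    n_steps = int(round(scenario.duration / config.dt))
    for istep in range(n_steps):
        state = stepper.step(state)
        _record_trace(state)
        if (istep + 1) % config.output_every == 0 or istep == n_steps - 1:
            _record(state)
            if stop is not None and stop(trajectory):
                break

    trace = PotentialTrace(
        times=np.array(trace_t),
        phii={u: np.array(v) for u, v in trace_i.items()},
        phie={u: np.array(v) for u, v in trace_e.items()},
    )
    return RunResult(
        state=state, mesh=mesh, trajectory=trajectory, trace=trace,
        scenario=scenario,
    )
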