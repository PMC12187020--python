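"""Scenario declarations and the preset registry.

A Scenario is a declarative description of one simulation: geometry, mesh
refinement, ion species, buffers, membrane units with gating schedules,
solver settings, duration, and the observables to record.  Presets reproduce
the canonical simulation setups; each carries two resolutions, ``"reference"``
(original time step and mesh grading) and ``"smoke"`` (coarsened transverse
mesh and larger time step for desk-scale runs and tests).
"""

from __future__ import annotations

import copy
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .constants import IonSpecies, default_buffers, default_species
from .membrane import ChannelSpec, GatingSchedule, NCXSpec
from .mesh import DomainGeometry, TensorMesh, UnitPlacement, build_mesh
from .solver import ConfigurationError, FieldState, SolverConfig, init_state

__all__ = [
    "Scenario",
    "preset",
    "preset_names",
    "sweep_point",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
]

_MODELS = ("pnp", "diffusion", "reaction_diffusion", "ode1", "ode2")

_UNIT_KEYS = {
    "id", "type", "ion", "g", "y", "z", "region", "schedule",
    "Ibar", "delta", "Cm", "nu", "ksat", "Kact", "KCai", "KCae", "KNai", "KNae",
}
_INITIAL_KEYS = {"electroneutral", "perturbation"}
_PERTURB_KEYS = {"species", "amplitude", "sigma"}


@dataclass
class Scenario:
    """One fully specified simulation."""

    name: str
    model: str = "pnp"
    geometry: DomainGeometry = field(default_factory=DomainGeometry)
    fine_dx: float = 0.5
    fine_dyz: float = 2.0
    max_spacing: float = 64.0
    uniform_mesh: bool = False
    custom_species: list | None = None      # list of IonSpecies or None
    d_intra_scale: float = 1.0              # scales every intracellular D
    buffers_enabled: bool = True
    units: list = field(default_factory=list)      # list of unit dicts
    solver: SolverConfig = field(default_factory=SolverConfig)
    duration: float = 1.0                   # ms
    observables: list = field(default_factory=list)
    initial: dict = field(default_factory=lambda: {"electroneutral": True})
    ode_params: dict = field(default_factory=dict)
    potential_trace: object = None          # runtime-only, not serialized
    restart: str | None = None
    seed: int | None = None                 # reserved for stochastic gating
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}")
        for u in self.units:
            unknown = set(u) - _UNIT_KEYS
            if unknown:
                raise ConfigurationError(f"unknown unit keys: {sorted(unknown)}")
        unknown = set(self.initial) - _INITIAL_KEYS
        if unknown:
            raise ConfigurationError(f"unknown initial-condition keys: {sorted(unknown)}")
        pert = self.initial.get("perturbation")
        if pert is not None:
            unknown = set(pert) - _PERTURB_KEYS
            if unknown:
                raise ConfigurationError(f"unknown perturbation keys: {sorted(unknown)}")

    # -- derived builders ---------------------------------------------------
    def species_list(self) -> list[IonSpecies]:
        base = self.custom_species if self.custom_species is not None else default_species()
        if self.d_intra_scale != 1.0:
            base = [replace(s, Di=s.Di * self.d_intra_scale) for s in base]
        return list(base)

    def buffers_list(self):
        return default_buffers() if self.buffers_enabled else []

    def placements(self) -> list[UnitPlacement]:
        return [
            UnitPlacement(u["id"], float(u["y"]), float(u.get("z", 0.5)),
                          u.get("region", "dyad"))
            for u in self.units
        ]

    def build_mesh(self) -> TensorMesh:
        return build_mesh(
            self.geometry,
            self.placements(),
            fine_dx=self.fine_dx,
            fine_dyz=self.fine_dyz,
            max_spacing=self.max_spacing,
            uniform=self.uniform_mesh,
        )

    def build_units(self) -> list:
        out = []
        pls = {p.unit_id: p for p in self.placements()}
        for u in self.units:
            sched = GatingSchedule(tuple(
                (float(o), float(c)) for o, c in u.get("schedule", [])
            ))
            if u["type"] == "channel":
                out.append(ChannelSpec(
                    ion=u["ion"], g=float(u["g"]),
                    placement=pls[u["id"]], schedule=sched,
                ))
            elif u["type"] == "ncx":
                kwargs = {
                    k: float(u[k]) for k in
                    ("Ibar", "delta", "Cm", "nu", "ksat", "Kact",
                     "KCai", "KCae", "KNai", "KNae") if k in u
                }
                out.append(NCXSpec(placement=pls[u["id"]], schedule=sched, **kwargs))
            else:
                raise ConfigurationError(f"unknown unit type {u['type']!r}")
        return out

    def initial_state(self, mesh: TensorMesh) -> FieldState:
        state = init_state(
            self.species_list(), self.buffers_list(), mesh,
            electroneutral=self.initial.get("electroneutral", True),
        )
        pert = self.initial.get("perturbation")
        if pert:
            k = state.species_index(pert["species"])
            g = self.geometry
            cx = (g.Lx / 2.0, g.Ly / 2.0, g.Lz / 2.0 if g.dims == 3 else 0.5)
            X, Y, Z = np.meshgrid(*mesh.centers, indexing="ij")
            r2 = (X - cx[0]) ** 2 + (Y - cx[1]) ** 2
            if g.dims == 3:
                r2 = r2 + (Z - cx[2]) ** 2
            bump = pert["amplitude"] * np.exp(-r2 / (2.0 * pert["sigma"] ** 2))
            mask = (mesh.subdomain != 1).astype(float)  # no bump in the membrane
            state.c[k] += bump.ravel() * mask.ravel()
        return state

    # -- convenience --------------------------------------------------------
    def with_(self, **changes) -> "Scenario":
        """Functional update; dicts passed for geometry/solver are merged."""
        out = copy.deepcopy(self)
        for key, value in changes.items():
            if key == "geometry" and isinstance(value, dict):
                value = replace(out.geometry, **value)
            if key == "solver" and isinstance(value, dict):
                value = replace(out.solver, **value)
            setattr(out, key, value)
        out.__post_init__()
        return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "name", "model", "geometry", "fine_dx", "fine_dyz", "max_spacing",
    "uniform_mesh", "custom_species", "d_intra_scale", "buffers_enabled",
    "units", "solver", "duration", "observables", "initial", "ode_params",
    "restart", "seed", "metadata",
}


def scenario_to_dict(s: Scenario) -> dict:
    d = {
        "name": s.name,
        "model": s.model,
        "geometry": asdict(s.geometry),
        "fine_dx": s.fine_dx,
        "fine_dyz": s.fine_dyz,
        "max_spacing": s.max_spacing,
        "uniform_mesh": s.uniform_mesh,
        "custom_species": (
            [asdict(sp) for sp in s.custom_species]
            if s.custom_species is not None else None
        ),
        "d_intra_scale": s.d_intra_scale,
        "buffers_enabled": s.buffers_enabled,
        "units": copy.deepcopy(s.units),
        "solver": asdict(s.solver),
        "duration": s.duration,
        "observables": copy.deepcopy(s.observables),
        "initial": copy.deepcopy(s.initial),
        "ode_params": copy.deepcopy(s.ode_params),
        "restart": s.restart,
        "seed": s.seed,
        "metadata": copy.deepcopy(s.metadata),
    }
    return d


def scenario_from_dict(d: dict) -> Scenario:
    unknown = set(d) - _SCENARIO_KEYS
    if unknown:
        raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    d = copy.deepcopy(d)
    if "geometry" in d:
        d["geometry"] = DomainGeometry(**d["geometry"])
    if "solver" in d:
        d["solver"] = SolverConfig(**d["solver"])
    if d.get("custom_species") is not None:
        d["custom_species"] = [IonSpecies(**sp) for sp in d["custom_species"]]
    return Scenario(**d)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(s: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Preset registry
# ---------------------------------------------------------------------------

def _kcl_species(D: float, cK: tuple[float, float], cCl: tuple[float, float]):
    return [
        IonSpecies("K", +1, D, D, cK[0], cK[1]),
        IonSpecies("Cl", -1, D, D, cCl[0], cCl[1]),
    ]


_INF = math.inf


def units_3d(Ly: float = 1000.0, Lz: float = 1000.0) -> list:
    """Default transverse placements (nm): the Ca2+ channel and NCX sit in
    the dyad 20 nm apart at mid-height; the K+/Na+ pair sits on the main
    membrane at 0.7*Ly with adjacent patches."""
    zc = Lz / 2.0
    return [
        {"id": "K", "type": "channel", "ion": "K", "g": 5e9,
         "y": 0.7 * Ly - 2.0, "z": zc, "region": "main", "schedule": [[0.0, _INF]]},
        {"id": "Na", "type": "channel", "ion": "Na", "g": 20e9,
         "y": 0.7 * Ly + 2.0, "z": zc, "region": "main", "schedule": []},
        {"id": "ca", "type": "channel", "ion": "Ca", "g": 8e9,
         "y": Ly / 2.0 - 10.0, "z": zc, "region": "dyad", "schedule": []},
        {"id": "ncx", "type": "ncx",
         "y": Ly / 2.0 + 10.0, "z": zc, "region": "dyad", "schedule": []},
    ]

_DYAD_OBSERVABLES = [
    {"kind": "v", "unit": "K"},
    {"kind": "v", "unit": "ca"},
    {"kind": "point", "species": "Ca", "unit": "ca", "x_fraction": 0.5},
    {"kind": "point", "species": "Ca", "unit": "ncx", "x_fraction": 0.5},
    {"kind": "ryr_patch", "unit": "ca"},
    {"kind": "mass", "species": "Ca"},
]


def _units(open_times: dict, base=None, Ly: float = 1000.0, Lz: float = 1000.0) -> list:
    """Copy the 3D unit set with per-unit opening times (None = closed)."""
    units = copy.deepcopy(base if base is not None else units_3d(Ly, Lz))
    for u in units:
        if u["id"] in open_times:
            t = open_times[u["id"]]
            u["schedule"] = [] if t is None else [[t, _INF]]
    return units


def _smoke(s: Scenario, dt: float, Lyz: float | None = None) -> Scenario:
    """Coarsened transverse mesh and a larger time step for desk-scale runs.

    ``Lyz`` optionally shrinks the transverse domain (dyad scenarios; the
    upstroke keeps the full membrane area, which sets the depolarization
    speed).  Unit placements scale with the domain.
    """
    out = s.with_(
        fine_dyz=4.0, max_spacing=512.0,
        solver={"dt": dt, "buffer_substeps": 10},
    )
    if Lyz is not None:
        schedules = {u["id"]: u["schedule"] for u in out.units}
        units = units_3d(Lyz, Lyz)
        for u in units:
            u["schedule"] = copy.deepcopy(schedules[u["id"]])
        out = out.with_(geometry={"Ly": Lyz, "Lz": Lyz}, units=units)
    return out


def _preset_perturbation2d(resolution: str) -> Scenario:
    dx = 0.25 if resolution == "reference" else 1.0
    dt = 1e-7 if resolution == "reference" else 2e-7
    s = Scenario(
        name="perturbation2d",
        geometry=DomainGeometry(Le=0.0, Lm=0.0, Li=50.0, Ly=50.0, Lz=1.0, dims=2),
        fine_dx=dx, fine_dyz=dx, uniform_mesh=True,
        custom_species=_kcl_species(2.03e6, (100.0, 100.0), (100.0, 100.0)),
        buffers_enabled=False,
        solver=SolverConfig(
            dt=dt,
            phi_dirichlet={sd: 0.0 for sd in ("x-", "x+", "y-", "y+")},
            conc_dirichlet={sd: {"K": 100.0, "Cl": 100.0}
                            for sd in ("x-", "x+", "y-", "y+")},
        ),
        duration=1e-5,  # 10 ns
        initial={"electroneutral": False,
                 "perturbation": {"species": "K", "amplitude": 10.0, "sigma": 5.0}},
        observables=[
            {"kind": "conc_center", "species": "K"},
            {"kind": "conc_center", "species": "Cl"},
            {"kind": "rho_point", "name": "rho_center"},
            {"kind": "terms", "species": "K", "name": "K_center"},
        ],
    )
    return s


def _preset_debye2d(resolution: str) -> Scenario:
    if resolution == "reference":
        dx, dyz, uniform, dt = 0.1, 0.1, True, 1e-7
    else:
        dx, dyz, uniform, dt = 0.25, 50.0, False, 1e-7
    return Scenario(
        name="debye2d",
        geometry=DomainGeometry(Le=22.5, Lm=5.0, Li=22.5, Ly=50.0, Lz=1.0, dims=2),
        fine_dx=dx, fine_dyz=dyz, uniform_mesh=uniform, max_spacing=2.0,
        custom_species=_kcl_species(2.03e6, (100.1, 99.9), (100.0, 100.0)),
        buffers_enabled=False,
        solver=SolverConfig(dt=dt),
        duration=1e-5,
        initial={"electroneutral": False},
        observables=[],
    )


def _preset_rest3d(resolution: str) -> Scenario:
    s = Scenario(
        name="rest3d",
        units=_units({"K": 0.0, "Na": None, "ca": None, "ncx": None}),
        solver=SolverConfig(dt=1e-2),
        duration=5.0,
        observables=_DYAD_OBSERVABLES,
    )
    return s if resolution == "reference" else _smoke(s, 5e-2)


def _preset_upstroke3d(resolution: str) -> Scenario:
    s = Scenario(
        name="upstroke3d",
        units=_units({"K": 0.0, "Na": 0.05, "ca": None, "ncx": None}),
        solver=SolverConfig(dt=1e-3),
        duration=0.7,
        observables=_DYAD_OBSERVABLES,
    )
    return s if resolution == "reference" else _smoke(s, 2.5e-3)


def _preset_ca_open(resolution: str) -> Scenario:
    s = Scenario(
        name="ca_open",
        units=_units({"K": 0.0, "Na": 0.05, "ca": 0.1, "ncx": None}),
        solver=SolverConfig(dt=1e-3),
        duration=1.0,
        observables=_DYAD_OBSERVABLES,
    )
    return s if resolution == "reference" else _smoke(s, 5e-3)


def _preset_ca_ncx(resolution: str) -> Scenario:
    s = _preset_ca_open(resolution)
    return s.with_(name="ca_ncx", units=_units(
        {"K": 0.0, "Na": 0.05, "ca": 0.1, "ncx": 0.0}, base=s.units))


def _preset_ncx_only(resolution: str) -> Scenario:
    s = _preset_ca_open(resolution)
    return s.with_(name="ncx_only", units=_units(
        {"K": 0.0, "Na": 0.05, "ca": None, "ncx": 0.0}, base=s.units))


def _preset_ncx_enhanced(resolution: str) -> Scenario:
    s = _preset_ncx_only(resolution)
    units = copy.deepcopy(s.units)
    ncx = next(u for u in units if u["id"] == "ncx")
    for u in units:
        if u["id"] == "Na":           # move the Na+ channel next to the NCX
            u["y"], u["z"], u["region"] = ncx["y"] + 4.0, ncx["z"], "dyad"
    return s.with_(
        name="ncx_enhanced",
        geometry={"Li": 5.0},
        d_intra_scale=0.5,
        units=units,
    )


def _preset_ryr_sweep(resolution: str) -> Scenario:
    """Base point of the dyad-width / diffusivity sweep.

    The sweep protocol opens only the Ca2+ channel after a short settling
    period from the electroneutral initial state (identical for the full and
    reaction-diffusion models), and measures the RyR activation time on the
    SR-side patch.  ``sweep_point`` derives the other grid points.
    """
    if resolution == "reference":
        dt, dyz, cap, Lyz = 1e-6, 2.0, 64.0, 1000.0
    else:
        dt, dyz, cap, Lyz = 2e-5, 4.0, 512.0, 100.0
    units = [
        {"id": "ca", "type": "channel", "ion": "Ca", "g": 8e9,
         "y": Lyz / 2.0 - 10.0, "z": Lyz / 2.0, "region": "dyad",
         "schedule": [[0.005, _INF]]},
        {"id": "ncx", "type": "ncx",
         "y": Lyz / 2.0 + 10.0, "z": Lyz / 2.0, "region": "dyad",
         "schedule": []},
    ]
    return Scenario(
        name="ryr_sweep",
        geometry=DomainGeometry(Ly=Lyz, Lz=Lyz),
        fine_dyz=dyz, max_spacing=cap,
        units=units,
        solver=SolverConfig(dt=dt, buffer_substeps=10),
        duration=0.08,
        observables=[
            {"kind": "ryr_patch", "unit": "ca"},
            {"kind": "v", "unit": "ca"},
        ],
        metadata={
            "sweep": {
                "Li": [1.0, 3.0, 5.0, 7.0, 9.0, 12.0, 15.0, 19.0],
                "DCa": [1.5e5, 2.0e5, 2.5e5, 3.0e5],
            },
            "t_open": 0.005,
        },
    )


def sweep_point(base: Scenario, Li: float, DCa: float) -> Scenario:
    """One point of the dyad sweep: dyad width Li (nm), intracellular Ca2+
    diffusivity DCa (nm^2/ms); the other intracellular diffusivities scale by
    the same factor, and the near-membrane x-resolution is refined to 0.25 nm
    for dyads narrower than 5 nm."""
    scale = DCa / 2.0e5
    out = base.with_(
        name=f"{base.name}_Li{Li:g}_D{DCa:g}",
        geometry={"Li": float(Li)},
        d_intra_scale=scale,
        fine_dx=0.25 if Li < 5.0 else base.fine_dx,
    )
    out.metadata = dict(base.metadata, Li=Li, DCa=DCa)
    return out


_PRESETS = {
    "perturbation2d": _preset_perturbation2d,
    "debye2d": _preset_debye2d,
    "rest3d": _preset_rest3d,
    "upstroke3d": _preset_upstroke3d,
    "ca_open": _preset_ca_open,
    "ca_ncx": _preset_ca_ncx,
    "ncx_only": _preset_ncx_only,
    "ncx_enhanced": _preset_ncx_enhanced,
    "ryr_sweep": _preset_ryr_sweep,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str, resolution: str = "smoke") -> Scenario:
    """Build a preset scenario at ``"reference"`` or ``"smoke"`` resolution."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    if resolution not in ("reference", "smoke"):
        raise ConfigurationError("resolution must be 'reference' or 'smoke'")
    return _PRESETS[name](resolution)
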