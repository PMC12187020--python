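"""Output writing: trajectory CSV, VTK rectilinear snapshots, checkpoints
and run manifests.

Trajectory CSVs carry unit-annotated headers and ``#``-prefixed metadata
lines.  Snapshots use the XML VTK rectilinear-grid dialect (.vtr, ASCII)
readable by ParaView and VisIt; concentrations are masked (NaN) inside the
membrane, where no concentration unknowns exist.  Checkpoints are NumPy
``.npz`` containers holding the mesh, full state and a config hash, enabling
bit-for-bit restarts.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import BufferSpec, IonSpecies
from .mesh import OMEGA_M, DomainGeometry, TensorMesh, UnitPlacement, locate_unit_faces
from .observables import Trajectory
from .solver import FieldState, charge_density

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_vtr",
    "read_vtr",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
    "write_outputs",
    "config_hash",
]


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in sorted(trajectory.metadata.items()):
            fh.write(f"# {key}: {value}\n")
        trajectory.to_frame().to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip)
    traj = Trajectory(metadata=meta)
    traj.times = df["t_ms"].tolist()
    traj.series = {c: df[c].tolist() for c in df.columns if c != "t_ms"}
    return traj


# ---------------------------------------------------------------------------
# VTK rectilinear grid (.vtr), ASCII
# ---------------------------------------------------------------------------

def _ascii(a: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(a).ravel())


def write_vtr(mesh: TensorMesh, arrays: dict, path) -> None:
    """Write per-cell arrays on the tensor mesh as an XML .vtr file.

    ``arrays`` maps names to flat (n_cells,) or shaped arrays.  VTK expects
    x-fastest ordering for cell data, so arrays are transposed accordingly.
    """
    nx, ny, nz = mesh.shape
    ex, ey, ez = mesh.edges
    root = ET.Element("VTKFile", type="RectilinearGrid", version="1.0",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "RectilinearGrid",
                         WholeExtent=f"0 {nx} 0 {ny} 0 {nz}")
    piece = ET.SubElement(grid, "Piece", Extent=f"0 {nx} 0 {ny} 0 {nz}")
    coords = ET.SubElement(piece, "Coordinates")
    for name, e in (("x", ex), ("y", ey), ("z", ez)):
        da = ET.SubElement(coords, "DataArray", type="Float64",
                           Name=f"{name}_nm", format="ascii")
        da.text = _ascii(e)
    cd = ET.SubElement(piece, "CellData")
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float).reshape(mesh.shape)
        da = ET.SubElement(cd, "DataArray", type="Float64", Name=name,
                           format="ascii")
        da.text = _ascii(arr.transpose(2, 1, 0))  # VTK: x fastest
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtr(path) -> tuple[tuple[np.ndarray, ...], dict]:
    """Read back edges and cell arrays written by :func:`write_vtr`."""
    root = ET.parse(path).getroot()
    piece = root.find("RectilinearGrid/Piece")
    edges = tuple(
        np.fromstring(da.text, sep=" ")
        for da in piece.find("Coordinates")
    )
    shape = tuple(len(e) - 1 for e in edges)
    arrays = {}
    for da in piece.find("CellData"):
        flat = np.fromstring(da.text, sep=" ")
        arrays[da.get("Name")] = (
            flat.reshape(shape[::-1]).transpose(2, 1, 0).reshape(-1)
        )
    return edges, arrays


def snapshot_arrays(state: FieldState, mesh: TensorMesh) -> dict:
    """phi, per-species c (NaN in the membrane), bound buffers and rho."""
    mem = (mesh.subdomain.ravel() == OMEGA_M)
    out = {"phi_mV": state.phi, "rho_C_per_m3": charge_density(state),
           "subdomain": mesh.subdomain.ravel().astype(float)}
    for i, s in enumerate(state.species):
        arr = state.c[i].copy()
        arr[mem] = np.nan
        out[f"c_{s.name}_mM"] = arr
    for j, bf in enumerate(state.buffers):
        out[f"b_{bf.name}_mM"] = state.b[j]
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def config_hash(scenario_dict: dict) -> str:
    blob = json.dumps(scenario_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(path, state: FieldState, mesh: TensorMesh,
                    scenario_dict: dict | None = None) -> None:
    g = mesh.geometry
    pls = list(mesh.placements.values())
    np.savez(
        path,
        phi=state.phi, c=state.c, b=state.b, rho0=state.rho0,
        t=np.array([state.t]),
        species=np.array(
            [(s.name, s.z, s.De, s.Di, s.c0e, s.c0i) for s in state.species],
            dtype=object,
        ),
        buffers=np.array(
            [(b.name, b.target, b.Btot, b.kon, b.koff) for b in state.buffers],
            dtype=object,
        ),
        x_edges=mesh.edges[0], y_edges=mesh.edges[1], z_edges=mesh.edges[2],
        x_subdomain=mesh.x_subdomain,
        geometry=np.array([g.Le, g.Lm, g.Li, g.Ly, g.Lz, g.wc, g.dims]),
        placements=np.array(
            [(p.unit_id, p.y, p.z, p.region) for p in pls], dtype=object
        ),
        fine=np.array([mesh.fine_dx, mesh.fine_dyz]),
        config_hash=np.array([config_hash(scenario_dict or {})]),
    )


def load_checkpoint(path) -> tuple[FieldState, TensorMesh, str]:
    with np.load(path, allow_pickle=True) as z:
        gvals = z["geometry"]
        geometry = DomainGeometry(
            Le=float(gvals[0]), Lm=float(gvals[1]), Li=float(gvals[2]),
            Ly=float(gvals[3]), Lz=float(gvals[4]), wc=float(gvals[5]),
            dims=int(gvals[6]),
        )
        placements = [
            UnitPlacement(str(p[0]), float(p[1]), float(p[2]), str(p[3]))
            for p in z["placements"]
        ]
        mesh = TensorMesh(
            geometry=geometry,
            edges=(z["x_edges"], z["y_edges"], z["z_edges"]),
            x_subdomain=z["x_subdomain"],
            placements={p.unit_id: p for p in placements},
            fine_dx=float(z["fine"][0]),
            fine_dyz=float(z["fine"][1]),
        )
        for p in placements:
            mesh.unit_faces[p.unit_id] = locate_unit_faces(mesh, p, geometry.wc)
        species = tuple(
            IonSpecies(str(s[0]), int(s[1]), float(s[2]), float(s[3]),
                       float(s[4]), float(s[5]))
            for s in z["species"]
        )
        buffers = tuple(
            BufferSpec(str(b[0]), str(b[1]), float(b[2]), float(b[3]),
                       float(b[4]))
            for b in z["buffers"]
        )
        state = FieldState(
            species=species, buffers=buffers,
            phi=z["phi"].copy(), c=z["c"].copy(), b=z["b"].copy(),
            rho0=z["rho0"].copy(), t=float(z["t"][0]),
        )
        chash = str(z["config_hash"][0])
    return state, mesh, chash


# ---------------------------------------------------------------------------
# Run output directory
# ---------------------------------------------------------------------------

def write_manifest(path, scenario_dict: dict, extra: dict | None = None) -> None:
    import nanodyad

    manifest = {
        "package": "nanodyad",
        "version": getattr(nanodyad, "__version__", "unknown"),
        "numpy": np.__version__,
        "config_hash": config_hash(scenario_dict),
        "scenario": scenario_dict,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def write_outputs(result, outdir, scenario_dict: dict | None = None) -> dict:
    """Write trajectory CSV, final snapshot, checkpoint and manifest.

    Returns the mapping of artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sd = scenario_dict or {}
    files = {}
    traj_path = outdir / "trajectory.csv"
    result.trajectory.metadata.setdefault("config_hash", config_hash(sd))
    write_trajectory_csv(result.trajectory, traj_path)
    files["trajectory"] = str(traj_path)
    if result.mesh is not None:
        vtr_path = outdir / "final_state.vtr"
        write_vtr(result.mesh, snapshot_arrays(result.state, result.mesh), vtr_path)
        files["snapshot"] = str(vtr_path)
        ck_path = outdir / "checkpoint.npz"
        save_checkpoint(ck_path, result.state, result.mesh, sd)
        files["checkpoint"] = str(ck_path)
    mf_path = outdir / "manifest.json"
    write_manifest(mf_path, sd, {"files": files})
    files["manifest"] = str(mf_path)
    return files
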