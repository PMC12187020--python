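"""Computational domain and adaptive tensor-product mesh.

The domain is a rectangular cuboid split along x into an extracellular part
(T-tubule lumen, ``0 <= x < Le``), the cell membrane (``Le <= x < Le+Lm``)
and an intracellular part (dyad, ``Le+Lm <= x <= Le+Lm+Li``) whose right
boundary represents the closed SR membrane.

The mesh is cell-centered finite-volume on a tensor-product grid.  Along x
the spacing equals ``fine_dx`` in the cells adjacent to both membrane faces
and to the SR boundary and doubles interval-by-interval away from them,
capped at ``max_spacing``.  Along y and z the spacing equals ``fine_dyz``
over each channel/exchanger patch and doubles away from it.  Remainders are
filled with a uniform block sized so that neighbouring intervals never
differ by more than a factor of two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OMEGA_E",
    "OMEGA_M",
    "OMEGA_I",
    "DomainGeometry",
    "UnitPlacement",
    "TensorMesh",
    "MeshError",
    "graded_intervals",
    "build_mesh",
    "locate_unit_faces",
    "observation_point",
]

OMEGA_E, OMEGA_M, OMEGA_I = 0, 1, 2

_TOL = 1e-9


class MeshError(ValueError):
    """Invalid geometry, placement or refinement configuration."""


@dataclass(frozen=True)
class DomainGeometry:
    """Rectangular-cuboid domain dimensions (nm)."""

    Le: float = 100.0
    Lm: float = 5.0
    Li: float = 7.0
    Ly: float = 1000.0
    Lz: float = 1000.0
    wc: float = 4.0
    dims: int = 3

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise MeshError("dims must be 2 or 3")
        if self.Li <= 0 or self.Ly <= 0 or self.wc <= 0:
            raise MeshError("domain lengths must be positive")
        if self.Le < 0 or self.Lm < 0:
            raise MeshError("Le and Lm must be nonnegative")
        if self.dims == 3 and self.Lz <= 0:
            raise MeshError("Lz must be positive in 3D")

    @property
    def Lx(self) -> float:
        return self.Le + self.Lm + self.Li


@dataclass(frozen=True)
class UnitPlacement:
    """Center of a wc x wc membrane patch hosting a channel or exchanger."""

    unit_id: str
    y: float
    z: float = 0.5
    region: str = "dyad"


# ---------------------------------------------------------------------------
# Graded interval generation
# ---------------------------------------------------------------------------

def _ladder(h0: float, budget: float, h_max: float) -> list[float]:
    """Doubling sequence h0, 2*h0, ... capped at h_max, total <= budget."""
    out: list[float] = []
    h, total = h0, 0.0
    while total + h <= budget + _TOL:
        out.append(h)
        total += h
        h = min(2.0 * h, h_max)
    return out


def graded_intervals(
    length: float,
    h_left: float | None,
    h_right: float | None,
    h_max: float,
) -> np.ndarray:
    """Intervals summing to ``length`` with fine spacing at refined ends.

    ``h_left``/``h_right`` give the exact first interval at that end (None
    means unrefined).  Spacing doubles away from refined ends up to
    ``h_max``; any remainder is filled with a uniform block whose size stays
    within a factor two of its neighbours (ladder steps are dropped if the
    remainder would otherwise be too small).
    """
    if length <= 0:
        raise MeshError("segment length must be positive")
    for h in (h_left, h_right):
        if h is not None and (h <= 0 or h > length + _TOL):
            raise MeshError("fine spacing must be positive and fit the segment")

    if h_left is None and h_right is None:
        k = max(1, math.ceil(length / h_max - _TOL))
        return np.full(k, length / k)

    if h_left is not None and h_right is not None:
        left = _ladder(h_left, length / 2.0, h_max)
        right = _ladder(h_right, length / 2.0, h_max)
    elif h_left is not None:
        left, right = _ladder(h_left, length, h_max), []
    else:
        left, right = [], _ladder(h_right, length, h_max)

    def _fill() -> list[float]:
        gap = length - sum(left) - sum(right)
        if gap < -_TOL:
            raise MeshError("refinement ladders exceed segment length")
        if gap <= _TOL:
            return []
        last_l = left[-1] if left else 0.0
        last_r = right[-1] if right else 0.0
        cap = h_max
        if left:
            cap = min(cap, 2.0 * last_l)
        if right:
            cap = min(cap, 2.0 * last_r)
        k = max(1, math.ceil(gap / cap - _TOL))
        s = gap / k
        if s + _TOL < max(last_l, last_r) / 2.0:
            return []  # signal: filler too small, drop a ladder step
        return [s] * k

    while True:
        mid = _fill()
        gap = length - sum(left) - sum(right)
        if gap <= _TOL or mid:
            break
        # drop the largest trailing ladder interval and retry; if that would
        # remove a refined end's own fine interval, fall back to a uniform
        # grid no coarser than the fine spacing (degenerate short segments)
        can_pop_left = len(left) > 1
        can_pop_right = len(right) > 1
        if can_pop_left and (not can_pop_right or left[-1] >= right[-1]):
            left.pop()
        elif can_pop_right:
            right.pop()
        else:
            h_min = min(h for h in (h_left, h_right) if h is not None)
            k = max(1, math.ceil(length / h_min - _TOL))
            return np.full(k, length / k)

    intervals = np.array(left + mid + right[::-1], dtype=float)
    # absorb floating-point residue into the largest interval
    intervals[np.argmax(intervals)] += length - intervals.sum()
    return intervals


def _axis_edges_with_windows(
    length: float,
    windows: list[tuple[float, float]],
    h_fine: float,
    h_max: float,
) -> np.ndarray:
    """Edges along one transverse axis, fine over windows, graded between."""
    if not windows:
        return np.concatenate(([0.0], np.cumsum(graded_intervals(length, None, None, h_max))))
    windows = sorted(windows)
    merged: list[list[float]] = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1] + _TOL:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    pieces: list[np.ndarray] = []
    cursor = 0.0
    for i, (a, b) in enumerate(merged):
        if a < -_TOL or b > length + _TOL:
            raise MeshError("refinement window outside the domain cross-section")
        if a - cursor > _TOL:
            pieces.append(graded_intervals(
                a - cursor,
                h_fine if cursor > _TOL else None,
                h_fine,
                h_max,
            ))
        k = max(1, round((b - a) / h_fine))
        pieces.append(np.full(k, (b - a) / k))
        cursor = b
    if length - cursor > _TOL:
        pieces.append(graded_intervals(length - cursor, h_fine, None, h_max))
    intervals = np.concatenate(pieces)
    edges = np.concatenate(([0.0], np.cumsum(intervals)))
    edges[-1] = length
    return edges


# ---------------------------------------------------------------------------
# TensorMesh
# ---------------------------------------------------------------------------

@dataclass
class TensorMesh:
    """Nonuniform rectilinear grid with subdomain labels and unit face sets.

    Cells are indexed ``(ix, iy, iz)`` and flattened in C order.  The
    subdomain label depends on x only.  ``unit_faces`` maps each registered
    membrane unit to its intracellular/extracellular mouth cells (the first
    non-membrane cell layer adjacent to each membrane face over the unit's
    wc x wc patch) and the per-face areas.
    """

    geometry: DomainGeometry
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    x_subdomain: np.ndarray          # label per x index
    placements: dict[str, UnitPlacement] = field(default_factory=dict)
    unit_faces: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    fine_dx: float = 0.5
    fine_dyz: float = 2.0

    def __post_init__(self) -> None:
        self.widths = tuple(np.diff(e) for e in self.edges)
        self.centers = tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)
        self.shape = tuple(len(w) for w in self.widths)

    # -- basic bookkeeping -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def ravel(self, ix, iy, iz):
        return np.ravel_multi_index((ix, iy, iz), self.shape)

    @property
    def subdomain(self) -> np.ndarray:
        """Per-cell subdomain label, shape ``self.shape``."""
        return np.broadcast_to(
            self.x_subdomain[:, None, None], self.shape
        ).copy()

    @property
    def cell_volumes(self) -> np.ndarray:
        wx, wy, wz = self.widths
        return wx[:, None, None] * wy[None, :, None] * wz[None, None, :]

    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())


def _transverse_center(geometry: DomainGeometry, p: UnitPlacement) -> tuple[float, float]:
    z = p.z if geometry.dims == 3 else 0.5
    return p.y, z


def build_mesh(
    geometry: DomainGeometry,
    placements: list[UnitPlacement] | None = None,
    fine_dx: float = 0.5,
    fine_dyz: float = 2.0,
    max_spacing: float = 64.0,
    uniform: bool = False,
) -> TensorMesh:
    """Construct the adaptive tensor mesh.

    With ``uniform=True`` every axis uses constant spacing ``fine_dx``
    (x) / ``fine_dyz`` (y, z), as in the simple 2D box examples.
    """
    placements = list(placements or [])
    g = geometry
    half = g.wc / 2.0

    # validate placements
    for p in placements:
        y, z = _transverse_center(g, p)
        if y - half < -_TOL or y + half > g.Ly + _TOL:
            raise MeshError(f"unit {p.unit_id!r} patch outside the membrane cross-section (y)")
        if g.dims == 3 and (z - half < -_TOL or z + half > g.Lz + _TOL):
            raise MeshError(f"unit {p.unit_id!r} patch outside the membrane cross-section (z)")
    for i, a in enumerate(placements):
        for b in placements[i + 1:]:
            ya, za = _transverse_center(g, a)
            yb, zb = _transverse_center(g, b)
            if abs(ya - yb) < g.wc - _TOL and (g.dims == 2 or abs(za - zb) < g.wc - _TOL):
                raise MeshError(f"unit patches {a.unit_id!r} and {b.unit_id!r} overlap")
    if placements and g.Lm <= 0:
        raise MeshError("membrane units require a membrane (Lm > 0)")

    # x axis
    if uniform:
        def _uniform(L, h):
            k = max(1, round(L / h))
            return np.linspace(0.0, L, k + 1)
        x_edges = _uniform(g.Lx, fine_dx)
        # keep subdomain boundaries on mesh lines
        for xb in (g.Le, g.Le + g.Lm):
            if 0 < xb < g.Lx and not np.any(np.isclose(x_edges, xb, atol=_TOL)):
                raise MeshError("uniform spacing must divide the subdomain boundaries")
        y_edges = _uniform(g.Ly, fine_dyz)
        z_edges = _uniform(g.Lz, fine_dyz) if g.dims == 3 else np.array([0.0, 1.0])
    else:
        xs: list[np.ndarray] = [np.array([0.0])]

        def _append(intervals: np.ndarray) -> None:
            xs.append(xs[-1][-1] + np.cumsum(intervals))

        if g.Le > 0:
            _append(graded_intervals(g.Le, None, fine_dx if g.Lm > 0 else None, max_spacing))
        if g.Lm > 0:
            _append(graded_intervals(g.Lm, fine_dx, fine_dx, max_spacing))
        _append(graded_intervals(g.Li, fine_dx if g.Lm > 0 else None, fine_dx, max_spacing))
        x_edges = np.concatenate(xs)

        windows = []
        windows_z = []
        for p in placements:
            y, z = _transverse_center(g, p)
            windows.append((y - half, y + half))
            windows_z.append((z - half, z + half))
        y_edges = _axis_edges_with_windows(g.Ly, windows, fine_dyz, max_spacing)
        if g.dims == 3:
            z_edges = _axis_edges_with_windows(g.Lz, windows_z, fine_dyz, max_spacing)
        else:
            z_edges = np.array([0.0, 1.0])

    # subdomain labels per x cell
    xc = 0.5 * (x_edges[1:] + x_edges[:-1])
    x_subdomain = np.full(len(xc), OMEGA_I, dtype=np.int8)
    x_subdomain[xc < g.Le] = OMEGA_E
    x_subdomain[(xc >= g.Le) & (xc < g.Le + g.Lm)] = OMEGA_M

    mesh = TensorMesh(
        geometry=g,
        edges=(x_edges, y_edges, z_edges),
        x_subdomain=x_subdomain,
        placements={p.unit_id: p for p in placements},
        fine_dx=fine_dx,
        fine_dyz=fine_dyz,
    )
    for p in placements:
        mesh.unit_faces[p.unit_id] = locate_unit_faces(mesh, p, g.wc)
    return mesh


def _axis_cells_in_window(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of cells fully inside [lo, hi] (within tolerance)."""
    return np.where((edges[:-1] >= lo - 1e-6) & (edges[1:] <= hi + 1e-6))[0]


def locate_unit_faces(
    mesh: TensorMesh,
    placement: UnitPlacement,
    wc: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mouth cells and face areas of one membrane unit.

    Returns ``(cells_i, cells_e, areas)``: flat indices of the first
    intracellular and extracellular cell layers adjacent to the membrane over
    the unit's patch, plus the y-z face area of each (total = wc^2).
    """
    g = mesh.geometry
    wc = g.wc if wc is None else wc
    half = wc / 2.0
    mem = np.where(mesh.x_subdomain == OMEGA_M)[0]
    if len(mem) == 0:
        raise MeshError("mesh has no membrane cells")
    ix_e, ix_i = mem[0] - 1, mem[-1] + 1
    if ix_e < 0 or ix_i >= mesh.shape[0]:
        raise MeshError("membrane touches the domain boundary")

    y, z = _transverse_center(g, placement)
    iy = _axis_cells_in_window(mesh.edges[1], y - half, y + half)
    if g.dims == 3:
        iz = _axis_cells_in_window(mesh.edges[2], z - half, z + half)
    else:
        iz = np.array([0])
    if len(iy) == 0 or len(iz) == 0:
        raise MeshError(f"mesh cannot resolve the patch of unit {placement.unit_id!r}")
    wy = mesh.widths[1][iy]
    wz = mesh.widths[2][iz]
    area_target = wc * wc if g.dims == 3 else wc * 1.0
    areas = (wy[:, None] * wz[None, :]).ravel()
    if abs(areas.sum() - area_target) > 1e-6 * area_target:
        raise MeshError(
            f"mouth faces of unit {placement.unit_id!r} cover "
            f"{areas.sum():g} nm^2, expected {area_target:g}"
        )
    IY, IZ = np.meshgrid(iy, iz, indexing="ij")
    cells_i = mesh.ravel(np.full(IY.size, ix_i), IY.ravel(), IZ.ravel())
    cells_e = mesh.ravel(np.full(IY.size, ix_e), IY.ravel(), IZ.ravel())
    return cells_i, cells_e, areas


def observation_point(
    mesh: TensorMesh,
    placement: UnitPlacement | str,
    x_fraction: float,
) -> int:
    """Flat index of the intracellular cell nearest ``x = Le+Lm+f*Li`` at the
    unit's (y, z) center."""
    if not 0.0 <= x_fraction <= 1.0:
        raise ValueError("x_fraction must lie in [0, 1]")
    if isinstance(placement, str):
        placement = mesh.placements[placement]
    g = mesh.geometry
    x = g.Le + g.Lm + x_fraction * g.Li
    y, z = _transverse_center(g, placement)
    xi = mesh.centers[0]
    candidates = np.where(mesh.x_subdomain == OMEGA_I)[0]
    ix = candidates[np.argmin(np.abs(xi[candidates] - x))]
    iy = int(np.argmin(np.abs(mesh.centers[1] - y)))
    iz = int(np.argmin(np.abs(mesh.centers[2] - z))) if g.dims == 3 else 0
    return int(mesh.ravel(ix, iy, iz))
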