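"""Finite-volume electrostatics on the IDE cross-section.

Solves the variable-coefficient Laplace equation div(eps grad V) = 0 on a 2D
cross-section through the interdigitated fingers, with Dirichlet conditions on
the driven fingers (bias voltage), the grounded fingers and the grounded
substrate plane, and zero-normal-field (Neumann) conditions on the open side
and top boundaries.  The terminal capacitance follows from the field energy,

    C = 2 W / V_drive^2,

computed per unit length of the cross-section and scaled by the finger length.
The mesh is a tensor-product grid whose lines are snapped to every material
boundary (finger edges, metal top, the 10 nm passivation film, cell/water
layer tops), uniform at the requested resolution near the electrodes and
geometrically graded towards the far boundaries.

The domain details the fabricated chip does not publish (oxide depth to the
substrate, lateral/top margins) are configuration values with documented
defaults; absolute agreement with a full 3D model is therefore approximate,
while the discretisation itself is validated against closed-form plate and
layered-slab solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .circuit_model import EPS0, ElectrodeGeometry, InvalidParameterError, MaterialStack

__all__ = [
    "ConvergenceError",
    "FieldGrid",
    "FieldSolution",
    "SolverSettings",
    "build_grid",
    "solve_potential",
    "evaporation_sweep",
    "parallel_plate_grid",
    "layered_slab_grid",
]

FREE, DRIVEN, GROUNDED = 0, 1, 2


class ConvergenceError(RuntimeError):
    """Linear solve failed to meet the residual tolerance."""

    def __init__(self, residual: float, tol: float):
        super().__init__(f"relative residual {residual:.3e} exceeds tolerance {tol:.3e}")
        self.residual = residual
        self.tol = tol


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs of the electrostatic solve."""

    resolution: float = 0.5  # µm, target spacing near the electrodes
    tolerance: float = 1e-8  # relative residual of the linear system
    margin_factor: float = 3.0  # side/top margin as multiple of electrode span
    max_spacing: float = 16.0  # µm, coarsest graded spacing far from electrodes
    growth: float = 1.3  # geometric grading ratio
    oxide_depth: float = 2.0  # µm, SiO2 between substrate plane and finger bottom
    v_drive: float = 2.7  # V  (3.3 V supply minus one 0.6 V threshold)


@dataclass
class FieldGrid:
    """Tensor-product grid: node coordinates, cell permittivities, node roles."""

    x: np.ndarray  # (nx,) node coordinates, µm
    y: np.ndarray  # (ny,)
    eps: np.ndarray  # (ny-1, nx-1) relative permittivity per cell
    roles: np.ndarray  # (ny, nx) int: FREE / DRIVEN / GROUNDED
    v_drive: float = 2.7  # V
    depth: float = 1.0  # µm, out-of-plane extent used to scale capacitance

    def __post_init__(self) -> None:
        if np.any(self.eps < 1.0):
            raise InvalidParameterError("eps must be >= 1 in every cell")
        if not (self.roles == DRIVEN).any() or not (self.roles == GROUNDED).any():
            raise InvalidParameterError("driven and grounded node sets must be non-empty")
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.y) <= 0):
            raise InvalidParameterError("grid coordinates must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return self.x.size * self.y.size

    def material_areas(self) -> dict[float, float]:
        """Total cell area (µm²) per distinct permittivity value."""
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        cell_area = np.outer(dy, dx)
        out: dict[float, float] = {}
        for val in np.unique(self.eps):
            out[float(val)] = float(cell_area[self.eps == val].sum())
        return out


@dataclass(frozen=True)
class FieldSolution:
    """Potential field and the energy-derived capacitance."""

    potential: np.ndarray  # (ny, nx), volts
    energy_per_length: float  # fF·V²/µm (per µm of out-of-plane depth)
    capacitance: float  # fF, scaled by grid depth
    residual: float  # relative residual of the linear solve
    n_nodes: int


def _uniform(a: float, b: float, h: float) -> np.ndarray:
    """Grid lines from a to b at spacing <= h, endpoints exact."""
    n = max(1, int(np.ceil((b - a) / h - 1e-9)))
    return np.linspace(a, b, n + 1)


def _graded(length: float, h0: float, hmax: float, growth: float) -> np.ndarray:
    """Offsets 0..length with spacing starting at h0 and growing geometrically."""
    if length <= 0:
        return np.array([0.0])
    offs = [0.0]
    h = h0
    while offs[-1] < length:
        offs.append(offs[-1] + h)
        h = min(h * growth, hmax)
    arr = np.asarray(offs)
    return arr * (length / arr[-1])  # rescale so the far end lands exactly


def _layer_lines(length: float, h0: float, hmax: float, growth: float) -> np.ndarray:
    """Lines across a thick layer: graded symmetrically from both faces."""
    if length <= 2 * h0:
        return _uniform(0.0, length, h0)
    half = _graded(length / 2.0, h0, hmax, growth)
    return np.unique(np.concatenate([half, length - half]))


def build_grid(
    geom: ElectrodeGeometry,
    stack: MaterialStack,
    water_thickness: float = 0.0,
    cell_layer_thickness: float = 0.0,
    settings: SolverSettings | None = None,
) -> FieldGrid:
    """Assemble the cross-section grid for the IDE under a dielectric stack.

    Bottom-up: grounded substrate plane at y = 0, SiO2 embedding the metal
    fingers, the native passivation film, an optional cell layer, an optional
    water layer, and air up to the open top boundary.  Alternate fingers are
    driven / grounded (the two outer-comb fingers grounded for a five-finger
    array).
    """
    st = settings or SolverSettings()
    res = st.resolution
    if res > geom.finger_width / 4.0 + 1e-12:
        raise InvalidParameterError(
            f"resolution {res} µm too coarse: need at least 4 nodes across a "
            f"{geom.finger_width} µm finger"
        )
    if water_thickness < 0 or cell_layer_thickness < 0:
        raise InvalidParameterError("layer thicknesses must be >= 0")

    span = geom.span
    margin = st.margin_factor * span

    # x lines: finger/gap edges exact, uniform inside, graded into the margins
    x_parts = []
    edge = -span / 2.0
    edges = [edge]
    for k in range(geom.n_fingers):
        edges.append(edges[-1] + geom.finger_width)
        if k < geom.n_fingers - 1:
            edges.append(edges[-1] + geom.gap)
    for a, b in zip(edges[:-1], edges[1:]):
        x_parts.append(_uniform(a, b, res))
    core_x = np.unique(np.concatenate(x_parts))
    left = edges[0] - _graded(margin, res, st.max_spacing, st.growth)[::-1]
    right = edges[-1] + _graded(margin, res, st.max_spacing, st.growth)
    x = np.unique(np.concatenate([left, core_x, right]))

    # y lines: material boundaries exact
    y_metal0 = st.oxide_depth
    y_metal1 = y_metal0 + geom.thickness
    y_film = y_metal1 + stack.d_PL
    y_cell = y_film + cell_layer_thickness
    y_water = y_cell + water_thickness
    y_top = y_water + max(margin, 2.0 * res)

    y_parts = [
        _uniform(0.0, y_metal0, res),
        _uniform(y_metal0, y_metal1, res),
        np.array([y_metal1, y_film]),  # one cell across the 10 nm film
    ]
    if cell_layer_thickness > 0:
        y_parts.append(y_film + _layer_lines(cell_layer_thickness, res, st.max_spacing, st.growth))
    if water_thickness > 0:
        y_parts.append(y_cell + _layer_lines(water_thickness, res, st.max_spacing, st.growth))
    y_parts.append(y_water + _graded(y_top - y_water, res, st.max_spacing, st.growth))
    y = np.unique(np.concatenate(y_parts))

    # cell permittivities from cell-centre heights
    xc = 0.5 * (x[:-1] + x[1:])
    yc = 0.5 * (y[:-1] + y[1:])
    eps = np.full((yc.size, xc.size), stack.eps_air)
    eps[yc < y_water] = stack.eps_water if water_thickness > 0 else stack.eps_air
    eps[yc < y_cell] = stack.eps_cell if cell_layer_thickness > 0 else eps[yc < y_cell]
    eps[yc < y_film] = stack.eps_PL
    eps[yc < y_metal1] = stack.eps_SiO2  # metal-layer band: SiO2 between fingers
    eps[yc < y_metal0] = stack.eps_SiO2
    # inside the metal fingers the potential is fixed; eps there is irrelevant
    # to the energy but set to 1 for bookkeeping
    finger_x0 = [edges[2 * k] for k in range(geom.n_fingers)]
    in_metal_row = (yc >= y_metal0 - 1e-12) & (yc <= y_metal1 + 1e-12)
    for x0 in finger_x0:
        cols = (xc > x0) & (xc < x0 + geom.finger_width)
        eps[np.ix_(in_metal_row, cols)] = 1.0

    # node roles
    roles = np.zeros((y.size, x.size), dtype=np.int8)
    roles[0, :] = GROUNDED  # substrate plane
    tol = 1e-9
    in_metal_y = (y >= y_metal0 - tol) & (y <= y_metal1 + tol)
    for k, x0 in enumerate(finger_x0):
        in_x = (x >= x0 - tol) & (x <= x0 + geom.finger_width + tol)
        # alternate combs; the outer comb (more fingers) is the grounded one,
        # and a degenerate single finger is driven against the substrate
        role = DRIVEN if (k % 2 == 1 or geom.n_fingers == 1) else GROUNDED
        roles[np.ix_(in_metal_y, in_x)] = role

    return FieldGrid(x=x, y=y, eps=eps, roles=roles,
                     v_drive=st.v_drive, depth=geom.finger_length)


def _edge_conductances(grid: FieldGrid) -> tuple[np.ndarray, np.ndarray]:
    """Finite-volume edge conductances (dimensionless, eps-weighted)."""
    dx = np.diff(grid.x)
    dy = np.diff(grid.y)
    eps = grid.eps
    ny, nx = grid.y.size, grid.x.size
    # horizontal edges: node (j,i)-(j,i+1); adjacent cells (j-1,i) and (j,i)
    gh = np.zeros((ny, nx - 1))
    gh[1:, :] += eps * dy[:, None] / 2.0
    gh[:-1, :] += eps * dy[:, None] / 2.0
    gh /= dx[None, :]
    # vertical edges: node (j,i)-(j+1,i); adjacent cells (j,i-1) and (j,i)
    gv = np.zeros((ny - 1, nx))
    gv[:, 1:] += eps * dx[None, :] / 2.0
    gv[:, :-1] += eps * dx[None, :] / 2.0
    gv /= dy[:, None]
    return gh, gv


def solve_potential(grid: FieldGrid, tolerance: float = 1e-8) -> FieldSolution:
    """Solve div(eps grad V) = 0 and return the energy capacitance.

    The discrete system is symmetric positive definite; it is solved with a
    sparse direct factorisation and the relative residual is verified against
    ``tolerance`` (raising :class:`ConvergenceError` otherwise), so the result
    is deterministic for a fixed grid.
    """
    ny, nx = grid.y.size, grid.x.size
    n = ny * nx
    gh, gv = _edge_conductances(grid)

    idx = np.arange(n).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def add_edges(a: np.ndarray, b: np.ndarray, g: np.ndarray) -> None:
        rows.extend([a.ravel(), b.ravel(), a.ravel(), b.ravel()])
        cols.extend([b.ravel(), a.ravel(), a.ravel(), b.ravel()])
        vals.extend([-g.ravel(), -g.ravel(), g.ravel(), g.ravel()])

    add_edges(idx[:, :-1], idx[:, 1:], gh)
    add_edges(idx[:-1, :], idx[1:, :], gv)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )

    fixed = grid.roles.ravel() != FREE
    v_fixed = np.where(grid.roles.ravel() == DRIVEN, grid.v_drive, 0.0)
    free = ~fixed
    A_ff = A[free][:, free]
    b = -A[free][:, fixed] @ v_fixed[fixed]

    v = np.empty(n)
    v[fixed] = v_fixed[fixed]
    if free.any():
        sol = spla.spsolve(A_ff.tocsc(), b)
        v[free] = sol
        bnorm = np.linalg.norm(b)
        residual = float(np.linalg.norm(A_ff @ sol - b) / (bnorm if bnorm > 0 else 1.0))
        if not np.isfinite(residual) or residual > tolerance:
            raise ConvergenceError(residual, tolerance)
    else:
        residual = 0.0

    V = v.reshape(ny, nx)
    dx = np.diff(grid.x)
    dy = np.diff(grid.y)
    ex = (np.diff(V, axis=1)[:-1, :] + np.diff(V, axis=1)[1:, :]) / (2.0 * dx[None, :])
    ey = (np.diff(V, axis=0)[:, :-1] + np.diff(V, axis=0)[:, 1:]) / (2.0 * dy[:, None])
    cell_area = np.outer(dy, dx)
    w = 0.5 * EPS0 * float(np.sum(grid.eps * (ex**2 + ey**2) * cell_area))
    cap = 2.0 * w / grid.v_drive**2 * grid.depth
    return FieldSolution(
        potential=V, energy_per_length=w, capacitance=cap,
        residual=residual, n_nodes=n,
    )


def evaporation_sweep(
    geom: ElectrodeGeometry,
    stack: MaterialStack,
    thicknesses: list[float],
    cell_layer_thickness: float = 0.0,
    settings: SolverSettings | None = None,
) -> list[tuple[float, float]]:
    """Capacitance along a receding water layer (thickness µm -> C fF).

    ``thicknesses`` must be sorted descending (the evaporation direction);
    a trailing 0 entry gives the returned dry/cell baseline.
    """
    ts = list(thicknesses)
    if any(b > a for a, b in zip(ts[:-1], ts[1:])):
        raise InvalidParameterError("thicknesses must be sorted descending")
    curve: list[tuple[float, float]] = []
    for t in ts:
        grid = build_grid(geom, stack, water_thickness=t,
                          cell_layer_thickness=cell_layer_thickness, settings=settings)
        sol = solve_potential(grid, tolerance=(settings or SolverSettings()).tolerance)
        curve.append((float(t), sol.capacitance))
    return curve


def parallel_plate_grid(
    width: float, height: float, eps_r: float, resolution: float, v_drive: float = 1.0
) -> FieldGrid:
    """Degenerate grid: uniform dielectric between full-width plates.

    Closed form C = eps0 * eps_r * width * depth / height (depth = 1 µm).
    """
    x = _uniform(0.0, width, resolution)
    y = _uniform(0.0, height, resolution)
    eps = np.full((y.size - 1, x.size - 1), float(eps_r))
    roles = np.zeros((y.size, x.size), dtype=np.int8)
    roles[0, :] = GROUNDED
    roles[-1, :] = DRIVEN
    return FieldGrid(x=x, y=y, eps=eps, roles=roles, v_drive=v_drive, depth=1.0)


def layered_slab_grid(
    width: float,
    layers: list[tuple[float, float]],
    resolution: float,
    v_drive: float = 1.0,
) -> FieldGrid:
    """Degenerate grid: horizontal dielectric layers (thickness, eps) stacked
    between full-width plates; oracle is the series plate formula."""
    y_parts = [np.array([0.0])]
    bounds = [0.0]
    for t, _ in layers:
        y_parts.append(bounds[-1] + _uniform(0.0, t, resolution)[1:])
        bounds.append(bounds[-1] + t)
    y = np.concatenate(y_parts)
    x = _uniform(0.0, width, resolution)
    yc = 0.5 * (y[:-1] + y[1:])
    eps = np.empty((yc.size, x.size - 1))
    lo = 0.0
    for t, e in layers:
        eps[(yc >= lo) & (yc < lo + t), :] = e
        lo += t
    roles = np.zeros((y.size, x.size), dtype=np.int8)
    roles[0, :] = GROUNDED
    roles[-1, :] = DRIVEN
    return FieldGrid(x=x, y=y, eps=eps, roles=roles, v_drive=v_drive, depth=1.0)
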