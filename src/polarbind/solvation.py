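"""Polar and nonpolar solvation energies.

The polar term comes from a finite-difference linear Poisson-Boltzmann
solver at zero ionic strength: ``div(eps grad phi) = -4 pi k rho`` on a
regular grid (phi in kcal/(mol e), rho spread onto grid nodes by trilinear
weights, k the Coulomb constant).  The dielectric boundary is the
solvent-excluded region: atom spheres inflated by the probe radius and
then eroded by the probe (two distance-transform passes), giving a
DelPhi-style molecular surface on the voxel grid.  Dirichlet boundary
values are atom-centered monopoles screened by the solvent dielectric.
The linear system (symmetric positive definite) is solved by
Jacobi-preconditioned conjugate gradients.

The reaction-field (polar solvation) energy is the two-solve difference
``1/2 sum_i q_i [phi_solvated(r_i) - phi_reference(r_i)]`` with the
reference solve on the identical grid at uniform interior dielectric, so
the grid self-energy cancels by construction.

The nonpolar term is the empirical SASA formula ``gamma * SASA + beta``
with Shrake-Rupley sphere-point surface areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, cg

from .constants import COULOMB_KCAL
from .model_io import Topology

__all__ = ["PBParams", "NonpolarParams", "GridSolution", "GridError",
           "ConvergenceError", "dielectric_map", "solve_pb",
           "polar_solvation_energy", "induced_surface_charges", "sasa",
           "nonpolar_energy", "born_energy"]


class GridError(ValueError):
    """Molecule does not fit the grid, or bad grid parameters."""


class ConvergenceError(RuntimeError):
    """Iterative PB solve failed to reach the residual tolerance."""


@dataclass(frozen=True)
class PBParams:
    """Finite-difference PB settings.

    Defaults follow standard implicit-solvent practice: interior/exterior
    dielectrics 1/80, probe radius 1.4 A, 4 grid points per Angstrom,
    zero ionic strength (linear PB).
    """

    eps_in: float = 1.0
    eps_out: float = 80.0
    probe_radius: float = 1.4
    grid_density: float = 4.0      # grids / A
    grid_padding: float = 10.0     # A added on every side
    ionic_strength: float = 0.0    # M; only 0 supported (linear, salt-free)
    max_iterations: int = 20000
    tolerance: float = 1e-8        # relative residual

    def __post_init__(self):
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("need eps_out > eps_in >= 1")
        if self.grid_density <= 0:
            raise ValueError("grid_density must be > 0")
        if self.ionic_strength != 0.0:
            raise ValueError("only zero ionic strength is supported")


@dataclass(frozen=True)
class NonpolarParams:
    """SASA nonpolar model: E = gamma * SASA + beta."""

    gamma: float = 0.00542         # kcal/(mol A^2)
    beta: float = 0.92             # kcal/mol
    sphere_points: int = 960

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class GridSolution:
    """A converged PB solution on its grid."""

    origin: np.ndarray             # A
    spacing: float                 # A
    shape: tuple
    phi: np.ndarray                # kcal/(mol e), full grid incl. boundary
    interior: np.ndarray           # bool node mask (solvent-excluded region)
    rho: np.ndarray                # free charge per node, e
    eps_edges: tuple               # per-axis edge dielectric arrays
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def make_grid(coords, radii, params: PBParams, origin=None, shape=None):
    """Grid origin/spacing/shape covering the molecule plus padding.

    Passing ``origin``/``shape`` pins the geometry (used to solve receptor
    and ligand on the complex's grid).
    """
    h = 1.0 / params.grid_density
    coords = np.atleast_2d(np.asarray(coords, float))
    radii = np.asarray(radii, float)
    if coords.size == 0:
        if origin is None or shape is None:
            raise GridError("empty system needs explicit origin and shape")
        return np.asarray(origin, float), h, tuple(shape)
    if origin is not None and shape is not None:
        origin = np.asarray(origin, float)
        shape = tuple(shape)
    else:
        lo = (coords - radii[:, None]).min(0) - params.grid_padding
        hi = (coords + radii[:, None]).max(0) + params.grid_padding
        origin = lo
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / h)) + 1 for k in range(3))
    hi_corner = origin + (np.array(shape) - 1) * h
    if (np.any(coords - radii[:, None] < origin + h)
            or np.any(coords + radii[:, None] > hi_corner - h)):
        raise GridError("molecule (plus radii) does not fit inside the grid")
    return origin, h, shape


def _node_coords(origin, h, shape, axis):
    return origin[axis] + h * np.arange(shape[axis])


def _interior_mask(coords, radii, origin, h, shape, probe):
    """Solvent-excluded node mask: inflate by probe, erode by probe."""
    if len(coords) == 0:
        return np.zeros(shape, bool)
    X = _node_coords(origin, h, shape, 0)[:, None, None]
    Y = _node_coords(origin, h, shape, 1)[None, :, None]
    Z = _node_coords(origin, h, shape, 2)[None, None, :]
    inflated = np.zeros(shape, bool)
    vdw = np.zeros(shape, bool)
    for c, r in zip(coords, radii):
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        inflated |= d2 <= (r + probe) ** 2
        vdw |= d2 <= r * r
    if probe <= 0:
        return inflated
    # erode: a node stays interior if no solvent-center point (outside the
    # inflated region) lies within the probe radius
    dist_to_outside = ndimage.distance_transform_edt(inflated, sampling=h)
    return vdw | (inflated & (dist_to_outside >= probe))


def dielectric_map(coords, topology_or_radii, params: PBParams,
                   origin=None, shape=None):
    """Per-edge dielectric assignment for the 7-point PB stencil.

    Returns ``(origin, h, shape, interior_mask, (ex, ey, ez))``.  Edge
    dielectrics are the harmonic mean of the endpoint node values (flux
    continuity across the dielectric jump; converges to the Born value
    with grid refinement, unlike the arithmetic mean).
    """
    radii = (topology_or_radii.pb_radii
             if isinstance(topology_or_radii, Topology)
             else np.asarray(topology_or_radii, float))
    origin, h, shape = make_grid(coords, radii, params, origin, shape)
    interior = _interior_mask(np.atleast_2d(coords), radii, origin, h, shape,
                              params.probe_radius)
    eps = np.where(interior, params.eps_in, params.eps_out)

    def edge(axis):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        a = eps[tuple(sl_lo)]
        b = eps[tuple(sl_hi)]
        return 2.0 * a * b / (a + b)

    return origin, h, shape, interior, (edge(0), edge(1), edge(2))


def _spread_charges(coords, charges, origin, h, shape):
    """Trilinear (cloud-in-cell) assignment of point charges to nodes."""
    rho = np.zeros(shape)
    if len(coords) == 0:
        return rho
    frac = (np.atleast_2d(coords) - origin) / h
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    for (ix, iy, iz), (tx, ty, tz), q in zip(i0, t, np.atleast_1d(charges)):
        for dx, wx in ((0, 1 - tx), (1, tx)):
            for dy, wy in ((0, 1 - ty), (1, ty)):
                for dz, wz in ((0, 1 - tz), (1, tz)):
                    rho[ix + dx, iy + dy, iz + dz] += q * wx * wy * wz
    return rho


def _interpolate(phi, coords, origin, h):
    """Trilinear interpolation of a node field at arbitrary points."""
    frac = (np.atleast_2d(coords) - origin) / h
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    out = np.zeros(len(frac))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                out += w * phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def _boundary_potential(coords, charges, origin, h, shape, eps):
    """Screened monopole potential on the six grid faces."""
    phi = np.zeros(shape)
    coords = np.atleast_2d(coords)
    charges = np.atleast_1d(charges)
    X = _node_coords(origin, h, shape, 0)
    Y = _node_coords(origin, h, shape, 1)
    Z = _node_coords(origin, h, shape, 2)

    def fill(face_slices, gx, gy, gz):
        gx, gy, gz = np.broadcast_arrays(gx, gy, gz)
        val = np.zeros(gx.shape)
        for c, q in zip(coords, charges):
            r = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
            val += COULOMB_KCAL * q / (eps * np.maximum(r, 1e-6))
        phi[face_slices] = val

    fill((0, slice(None), slice(None)), X[0], Y[:, None], Z[None, :])
    fill((-1, slice(None), slice(None)), X[-1], Y[:, None], Z[None, :])
    fill((slice(None), 0, slice(None)), X[:, None], Y[0], Z[None, :])
    fill((slice(None), -1, slice(None)), X[:, None], Y[-1], Z[None, :])
    fill((slice(None), slice(None), 0), X[:, None], Y[None, :], Z[0])
    fill((slice(None), slice(None), -1), X[:, None], Y[None, :], Z[-1])
    return phi


def _apply_operator(phi, ex, ey, ez):
    """A phi = -sum_edges eps_e (phi_nbr - phi_i), on interior nodes."""
    out = np.zeros_like(phi)
    core = (slice(1, -1),) * 3
    flux = ex * np.diff(phi, axis=0)
    out[1:, :, :] -= flux
    out[:-1, :, :] += flux
    flux = ey * np.diff(phi, axis=1)
    out[:, 1:, :] -= flux
    out[:, :-1, :] += flux
    flux = ez * np.diff(phi, axis=2)
    out[:, :, 1:] -= flux
    out[:, :, :-1] += flux
    return -out[core]


def solve_pb(coords, topology_or_radii, charges, params: PBParams,
             origin=None, shape=None, uniform_eps=None,
             x0=None) -> GridSolution:
    """Solve the discrete linear PB equation on a regular grid.

    ``uniform_eps`` replaces the dielectric map with a constant (the
    reference state of the two-solve reaction-field scheme and the
    analytic-Coulomb validation case).  ``origin``/``shape`` pin the grid
    geometry; ``x0`` warm-starts the iteration.
    """
    charges = np.atleast_1d(np.asarray(charges, float))
    coords = np.atleast_2d(np.asarray(coords, float))
    origin, h, shape, interior, (ex, ey, ez) = dielectric_map(
        coords, topology_or_radii, params, origin, shape)
    if uniform_eps is not None:
        ex = np.full_like(ex, uniform_eps)
        ey = np.full_like(ey, uniform_eps)
        ez = np.full_like(ez, uniform_eps)
        screen = uniform_eps
    else:
        screen = params.eps_out

    rho = _spread_charges(coords, charges, origin, h, shape)
    phi = _boundary_potential(coords, charges, origin, h, shape, screen)

    # right-hand side: source + boundary terms moved over
    core = (slice(1, -1),) * 3
    b = (4.0 * np.pi * COULOMB_KCAL / h) * rho[core]
    bc_only = phi.copy()
    bc_only[core] = 0.0
    b -= _apply_operator(bc_only, ex, ey, ez)

    n_core = (shape[0] - 2) * (shape[1] - 2) * (shape[2] - 2)

    def matvec(x):
        full = np.zeros(shape)
        full[core] = x.reshape(shape[0] - 2, shape[1] - 2, shape[2] - 2)
        return _apply_operator(full, ex, ey, ez).ravel()

    # Jacobi preconditioner: diagonal = sum of the six incident edge eps
    diag = (ex[:-1, 1:-1, 1:-1] + ex[1:, 1:-1, 1:-1]
            + ey[1:-1, :-1, 1:-1] + ey[1:-1, 1:, 1:-1]
            + ez[1:-1, 1:-1, :-1] + ez[1:-1, 1:-1, 1:]).ravel()
    A = LinearOperator((n_core, n_core), matvec=matvec)
    M = LinearOperator((n_core, n_core), matvec=lambda x: x / diag)

    x_init = None
    if x0 is not None:
        x_init = np.asarray(x0)[core].ravel()
    x, info = cg(A, b.ravel(), x0=x_init, rtol=params.tolerance, atol=0.0,
                 maxiter=params.max_iterations, M=M)
    resid = float(np.linalg.norm(matvec(x) - b.ravel())
                  / max(np.linalg.norm(b), 1e-300))
    if info != 0:
        raise ConvergenceError(
            f"PB solve did not converge in {params.max_iterations} "
            f"iterations (relative residual {resid:.2e})")
    phi[core] = x.reshape(shape[0] - 2, shape[1] - 2, shape[2] - 2)
    return GridSolution(origin=np.asarray(origin, float), spacing=h,
                        shape=tuple(shape), phi=phi, interior=interior,
                        rho=rho, eps_edges=(ex, ey, ez),
                        residual=resid, converged=True)


def potential_at(solution: GridSolution, points):
    """Trilinear interpolation of the solved potential at points (A)."""
    return _interpolate(solution.phi, points, solution.origin,
                        solution.spacing)


def polar_solvation_energy(coords, topology_or_radii, charges,
                           params: PBParams, origin=None, shape=None):
    """Reaction-field energy: solvated minus uniform-interior reference.

    ``dG_pol = 1/2 sum_i q_i [phi_solv(r_i) - phi_ref(r_i)]`` with both
    solves on the identical grid so the grid self-energy cancels.
    Returns ``(energy kcal/mol, solvated GridSolution)``.
    """
    charges = np.atleast_1d(np.asarray(charges, float))
    coords = np.atleast_2d(np.asarray(coords, float))
    solv = solve_pb(coords, topology_or_radii, charges, params, origin, shape)
    ref = solve_pb(coords, topology_or_radii, charges, params,
                   origin=solv.origin, shape=solv.shape,
                   uniform_eps=params.eps_in, x0=solv.phi)
    dphi = potential_at(solv, coords) - potential_at(ref, coords)
    return 0.5 * float((charges * dphi).sum()), solv


def induced_surface_charges(solution: GridSolution):
    """Discrete induced (polarization) charges at the dielectric boundary.

    The total node charge follows from Gauss's law applied to the solved
    potential with vacuum permittivity; subtracting the free charge leaves
    the induced surface charge.  Returns ``(positions (M,3), charges (M,)
    e)`` for nodes with non-negligible induced charge.
    """
    if not solution.converged:
        raise ConvergenceError("induced charges need a converged solution")
    phi = solution.phi
    h = solution.spacing
    lap = np.zeros_like(phi)
    core = (slice(1, -1),) * 3
    lap[core] = (phi[2:, 1:-1, 1:-1] + phi[:-2, 1:-1, 1:-1]
                 + phi[1:-1, 2:, 1:-1] + phi[1:-1, :-2, 1:-1]
                 + phi[1:-1, 1:-1, 2:] + phi[1:-1, 1:-1, :-2]
                 - 6.0 * phi[core])
    q_total = -lap * h / (4.0 * np.pi * COULOMB_KCAL)
    q_induced = q_total - solution.rho
    q_induced[0, :, :] = q_induced[-1, :, :] = 0.0
    q_induced[:, 0, :] = q_induced[:, -1, :] = 0.0
    q_induced[:, :, 0] = q_induced[:, :, -1] = 0.0
    cut = 1e-8 * max(np.abs(q_induced).max(), 1e-30)
    sel = np.abs(q_induced) > cut
    idx = np.argwhere(sel)
    positions = solution.origin + h * idx
    return positions, q_induced[sel]


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_points(n):
    """Deterministic golden-spiral unit sphere points."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(coords, radii, params: NonpolarParams = NonpolarParams(),
         probe: float = 1.4):
    """Shrake-Rupley solvent-accessible surface area.

    Returns ``(total, per_atom)`` in A^2; per-atom contributions sum to
    the total exactly.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    radii = np.atleast_1d(np.asarray(radii, float))
    n = len(coords)
    pts = _sphere_points(params.sphere_points)
    expanded = radii + probe
    per_atom = np.zeros(n)
    for i in range(n):
        surf = coords[i] + expanded[i] * pts
        buried = np.zeros(len(pts), bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) > expanded[i] + expanded[j]:
                continue
            d2 = ((surf - coords[j]) ** 2).sum(1)
            buried |= d2 < expanded[j] ** 2
        frac = 1.0 - buried.mean()
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return float(per_atom.sum()), per_atom


def nonpolar_energy(sasa_total: float,
                    params: NonpolarParams = NonpolarParams()) -> float:
    """Empirical nonpolar solvation energy gamma * SASA + beta (kcal/mol)."""
    if sasa_total < 0:
        raise ValueError("SASA must be >= 0")
    return params.gamma * sasa_total + params.beta


def born_energy(q: float, radius: float, eps_in: float = 1.0,
                eps_out: float = 80.0) -> float:
    """Analytic Born reaction-field energy (kcal/mol) — validation oracle."""
    return -0.5 * COULOMB_KCAL * (1.0 / eps_in - 1.0 / eps_out) * q * q / radius
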