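"""Normal-mode entropies for the -T dS term of the binding free energy.

Pipeline: local minimization of the toy force field, mass-weighted
numerical Hessian (central differences of the analytic gradient), rigid
translation/rotation projection, harmonic frequencies, and ideal-gas /
rigid-rotor / quantum-harmonic-oscillator entropies at temperature T.

Conventions: quantum (not classical) oscillator vibrational entropy,
1 atm standard state for the translational term, symmetry numbers fixed
at 1 — the standard normal-mode end-state protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import (AMU_KG, AVOGADRO, C_CM, EIGVAL_TO_OMEGA2, H_J, KB_J,
                        KCAL_PER_J_MOL, P_STANDARD, R_KCAL)
from .mm_energy import toy_total_energy
from .model_io import Selection, Topology

__all__ = ["EntropyParams", "ModeSpectrum", "EntropyResult", "SaddleError",
           "minimize", "normal_modes", "entropy", "binding_entropy_term"]


class SaddleError(RuntimeError):
    """More imaginary modes than rigid-body degrees of freedom."""


@dataclass(frozen=True)
class EntropyParams:
    """Temperature, minimization/Hessian controls, snapshot count."""

    temperature: float = 300.0        # K
    min_tolerance: float = 1e-4       # kcal/mol/A, RMS gradient target
    hessian_step: float = 1e-4        # A, central-difference displacement
    snapshot_count: int = 20          # snapshots averaged for T dS

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class ModeSpectrum:
    """Vibrational frequencies (cm^-1, ascending) with eigenvectors."""

    frequencies: np.ndarray
    eigenvectors: np.ndarray
    n_rigid: int = 6


@dataclass
class EntropyResult:
    """Entropy components (kcal/mol/K) and T*S (kcal/mol)."""

    s_trans: float
    s_rot: float
    s_vib: float
    temperature: float

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib

    @property
    def ts_total(self) -> float:
        return self.temperature * self.s_total


def minimize(coords, topology: Topology, charges=None,
             params: EntropyParams = EntropyParams(),
             include: Selection | None = None, max_iter: int = 20000):
    """Local minimization of the toy force field (L-BFGS, analytic gradient).

    Returns minimized coordinates; raises on failure to reach the RMS
    gradient tolerance.
    """
    coords = np.asarray(coords, float)
    shape = coords.shape

    def fun(x):
        e, g = toy_total_energy(x.reshape(shape), topology, charges, include)
        return e, g.ravel()

    res = _scipy_minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": max_iter, "ftol": 1e-14,
                                   "gtol": 1e-10})
    _, g = fun(res.x)
    rms_g = float(np.sqrt((g ** 2).mean()))
    if rms_g > params.min_tolerance:
        raise RuntimeError(
            f"minimization did not converge: RMS gradient {rms_g:.2e} "
            f"kcal/mol/A > {params.min_tolerance:.2e}")
    return res.x.reshape(shape)


def _rigid_body_vectors(coords, masses):
    """Orthonormal mass-weighted translation + rotation vectors."""
    n = len(coords)
    sqm = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(0) / masses.sum()
    x = coords - com
    vecs = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = sqm
        vecs.append(v.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        v = np.cross(np.broadcast_to(axis, (n, 3)), x) * sqm[:, None]
        vecs.append(v.ravel())
    V = np.array(vecs).T        # (3n, 6)
    Q, R = np.linalg.qr(V)
    keep = np.abs(np.diag(R)) > 1e-10
    return Q[:, keep]


def normal_modes(coords, topology: Topology, charges=None,
                 params: EntropyParams = EntropyParams(),
                 include: Selection | None = None) -> ModeSpectrum:
    """Harmonic frequencies from a mass-weighted numerical Hessian.

    The Hessian is built by central differences of the analytic gradient,
    symmetrized, mass-weighted, and projected against rigid translations
    and rotations; eigenvalues convert to wavenumbers.  Raises
    :class:`SaddleError` when more than ``n_rigid`` modes are imaginary.
    """
    coords = np.asarray(coords, float)
    n3 = coords.size
    h = params.hessian_step

    _, g0 = toy_total_energy(coords, topology, charges, include)
    rms_g = float(np.sqrt((g0 ** 2).mean()))
    if rms_g > 10.0 * params.min_tolerance:
        warnings.warn(f"normal_modes at RMS gradient {rms_g:.2e} kcal/mol/A; "
                      "frequencies may be unreliable", stacklevel=2)

    H = np.empty((n3, n3))
    flat = coords.ravel()
    for k in range(n3):
        xp = flat.copy()
        xp[k] += h
        _, gp = toy_total_energy(xp.reshape(coords.shape), topology, charges,
                                 include)
        xm = flat.copy()
        xm[k] -= h
        _, gm = toy_total_energy(xm.reshape(coords.shape), topology, charges,
                                 include)
        H[:, k] = (gp - gm).ravel() / (2.0 * h)
    H = 0.5 * (H + H.T)

    masses = topology.masses
    sqm_inv = 1.0 / np.sqrt(np.repeat(masses, 3))
    Hm = H * sqm_inv[:, None] * sqm_inv[None, :]

    Q = _rigid_body_vectors(coords, masses)
    P = np.eye(n3) - Q @ Q.T
    Hp = P @ Hm @ P
    evals, evecs = np.linalg.eigh(Hp)

    n_rigid = Q.shape[1]
    order = np.argsort(np.abs(evals))
    internal = np.sort(order[n_rigid:])
    lam = evals[internal]
    n_imag = int((lam < -1e-8).sum())
    if n_imag > 0:
        if n_imag > 6:
            raise SaddleError(f"{n_imag} imaginary modes: not a minimum")
        warnings.warn(f"{n_imag} weakly imaginary modes dropped",
                      stacklevel=2)
        keep = lam > 1e-10
        lam = lam[keep]
        internal = internal[keep]
    omega2 = np.maximum(lam, 0.0) * EIGVAL_TO_OMEGA2
    freqs = np.sqrt(omega2) / (2.0 * np.pi * C_CM)
    order = np.argsort(freqs)
    return ModeSpectrum(frequencies=freqs[order],
                        eigenvectors=evecs[:, internal][:, order],
                        n_rigid=n_rigid)


def _s_trans(total_mass_amu, T):
    """Sackur-Tetrode translational entropy, 1 atm standard state."""
    m = total_mass_amu * AMU_KG
    lam = (2.0 * np.pi * m * KB_J * T / H_J ** 2) ** 1.5
    v = KB_J * T / P_STANDARD
    s_j = KB_J * AVOGADRO * (np.log(lam * v) + 2.5)
    return s_j * KCAL_PER_J_MOL


def _s_rot(coords, masses, T, sigma=1.0):
    """Classical rigid-rotor entropy; 0 for a single atom."""
    if len(coords) == 1:
        return 0.0
    com = (masses[:, None] * coords).sum(0) / masses.sum()
    x = (coords - com) * 1e-10                      # m
    m = masses * AMU_KG
    I = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        I += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.sort(np.linalg.eigvalsh(I))
    if moments[0] / max(moments[2], 1e-300) < 1e-8:   # linear molecule
        Ib = moments[2]
        q_rot = 8.0 * np.pi ** 2 * Ib * KB_J * T / (sigma * H_J ** 2)
        s_j = KB_J * AVOGADRO * (np.log(q_rot) + 1.0)
    else:
        pref = (8.0 * np.pi ** 2 * KB_J * T / H_J ** 2) ** 1.5
        q_rot = (np.sqrt(np.pi) / sigma) * pref * np.sqrt(np.prod(moments))
        s_j = KB_J * AVOGADRO * (np.log(q_rot) + 1.5)
    return s_j * KCAL_PER_J_MOL


def _s_vib(frequencies_cm, T):
    """Quantum harmonic oscillator entropy over positive frequencies."""
    nu = np.asarray(frequencies_cm, float)
    if nu.size == 0:
        return 0.0
    if np.any(nu <= 0):
        raise ValueError("vibrational entropy needs positive frequencies")
    theta = H_J * C_CM * nu / KB_J                 # K
    x = theta / T
    s_j = KB_J * AVOGADRO * (x / np.expm1(x) - np.log(-np.expm1(-x)))
    return float(s_j.sum()) * KCAL_PER_J_MOL


def entropy(coords, spectrum: ModeSpectrum | None, topology: Topology,
            params: EntropyParams = EntropyParams(),
            sigma: float = 1.0) -> EntropyResult:
    """Translational + rotational + vibrational entropy of one species.

    ``spectrum=None`` treats the species as having no internal modes
    (monatomic): S_vib = S_rot(single atom) = 0.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    masses = topology.masses
    T = params.temperature
    s_t = _s_trans(float(masses.sum()), T)
    s_r = _s_rot(coords, masses, T, sigma)
    s_v = 0.0 if spectrum is None else _s_vib(spectrum.frequencies, T)
    return EntropyResult(s_t, s_r, s_v, T)


def binding_entropy_term(complex_result: EntropyResult,
                         receptor_result: EntropyResult,
                         ligand_result: EntropyResult) -> float:
    """The T dS column entry: -T dS_bind = T (S_R + S_L - S_complex).

    Positive when binding loses entropy, so that
    ``dG_bind = dG_sub + (this term)``.
    """
    T = complex_result.temperature
    ds = (complex_result.s_total - receptor_result.s_total
          - ligand_result.s_total)
    return -T * ds
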