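"""Local geometry optimization, finite-difference Hessians, normal modes.

The minimizer is FIRE-style damped dynamics with an energy-monotonicity
guard: a proposed step that raises the energy is rejected and retried with
a smaller time step, so the energy trace over accepted steps never
increases. Convergence is judged on Fmax, the largest per-atom force norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .calculators import PotentialModel
from .core import Geometry

__all__ = [
    "OptimizationResult",
    "VibrationalAnalysis",
    "fmax",
    "local_minimize",
    "fire_minimize_array",
    "finite_difference_hessian",
    "vibrational_analysis",
]


def fmax(forces: np.ndarray) -> float:
    """Largest per-atom force magnitude (eV/Å)."""
    return float(np.max(np.linalg.norm(forces.reshape(-1, 3), axis=1)))


@dataclass
class OptimizationResult:
    geometry: Geometry
    converged: bool
    iterations: int
    fmax: float
    energy_trace: list[float]


@dataclass
class VibrationalAnalysis:
    """Mass-weighted normal-mode analysis.

    ``eigenvalues`` (ascending, eV/(Å²·amu)) and ``modes`` span the full 3N
    space; the first ``n_rigid`` entries correspond to the projected-out
    rigid-body subspace and are exactly zero by construction.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray  # columns, orthonormal in mass-weighted coordinates
    n_rigid: int

    @property
    def vibrational_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the non-rigid subspace, ascending."""
        order = np.argsort(self.eigenvalues)
        # rigid modes were mapped to exactly 0 by projection; drop the
        # n_rigid eigenvalues closest to zero among the |λ|-smallest
        lam = self.eigenvalues
        rigid_idx = set(np.argsort(np.abs(lam))[: self.n_rigid].tolist())
        keep = [i for i in order if i not in rigid_idx]
        return lam[keep]

    def count_negative(self, eps: float = 1e-4) -> int:
        return int(np.sum(self.vibrational_eigenvalues < -eps))


# ---------------------------------------------------------------------------
# FIRE minimization


_FIRE_DEFAULTS = dict(
    dt=0.05, dt_max=0.5, n_min=5, f_inc=1.1, f_dec=0.5, alpha0=0.1, f_alpha=0.99
)


def fire_minimize_array(
    x0: np.ndarray,
    grad_fn: Callable[[np.ndarray], tuple[float, np.ndarray]],
    fmax_tol: float,
    max_steps: int = 500,
    max_disp: float = 1.0,
    force_transform: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    fmax_fn: Callable[[np.ndarray], float] | None = None,
) -> tuple[np.ndarray, bool, int, list[float]]:
    """FIRE descent on a flat coordinate array.

    ``grad_fn(x)`` returns (energy, forces) with forces = −∇E flattened.
    ``force_transform(x, f)`` may project the forces (used for constrained
    relaxation); convergence is judged on the transformed forces. Steps whose
    displacement exceeds ``max_disp`` per atom, or that raise the energy, are
    rejected by backtracking the time step.
    """
    if fmax_tol <= 0:
        raise ValueError("fmax_tol must be positive")
    p = dict(_FIRE_DEFAULTS)
    x = np.array(x0, dtype=np.float64)
    v = np.zeros_like(x)
    dt, alpha = p["dt"], p["alpha0"]
    n_pos = 0
    energy, forces = grad_fn(x)
    if force_transform is not None:
        forces = force_transform(x, forces)
    trace = [energy]
    _fm = fmax_fn or (lambda f: fmax(f))
    it = 0
    converged = _fm(forces) <= fmax_tol
    while not converged and it < max_steps:
        it += 1
        # FIRE velocity mixing
        power = float(np.dot(forces, v))
        fnorm = float(np.linalg.norm(forces))
        vnorm = float(np.linalg.norm(v))
        if power > 0:
            v = (1 - alpha) * v + alpha * (forces / fnorm if fnorm > 0 else 0.0) * vnorm
            if n_pos > p["n_min"]:
                dt = min(dt * p["f_inc"], p["dt_max"])
                alpha *= p["f_alpha"]
            n_pos += 1
        else:
            v[:] = 0.0
            dt *= p["f_dec"]
            alpha = p["alpha0"]
            n_pos = 0
        v = v + dt * forces
        step = dt * v
        # cap the per-atom displacement
        disp = np.max(np.linalg.norm(step.reshape(-1, 3), axis=1))
        if disp > max_disp:
            step *= max_disp / disp
        x_new = x + step
        e_new, f_new = grad_fn(x_new)
        if e_new > energy + 1e-12:
            # reject: restart damped dynamics with a smaller time step
            v[:] = 0.0
            dt *= p["f_dec"]
            alpha = p["alpha0"]
            n_pos = 0
            if dt < 1e-12:
                break
            continue
        if force_transform is not None:
            f_new = force_transform(x_new, f_new)
        x, energy, forces = x_new, e_new, f_new
        trace.append(energy)
        converged = _fm(forces) <= fmax_tol
    return x, converged, it, trace


def local_minimize(
    geometry: Geometry,
    model: PotentialModel,
    fmax_tol: float = 0.01,
    max_steps: int = 1000,
    force_transform: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> OptimizationResult:
    """Relax a geometry on the model's surface until Fmax ≤ fmax_tol."""
    shape = geometry.positions.shape

    def grad(x: np.ndarray):
        e, f = model.evaluate(geometry.with_positions(x.reshape(shape)))
        return e, f.ravel()

    x, converged, it, trace = fire_minimize_array(
        geometry.positions.ravel(),
        grad,
        fmax_tol=fmax_tol,
        max_steps=max_steps,
        force_transform=(
            None
            if force_transform is None
            else lambda x, f: force_transform(x.reshape(shape), f.reshape(shape)).ravel()
        ),
    )
    final = model.label(geometry.with_positions(x.reshape(shape)))
    return OptimizationResult(
        geometry=final,
        converged=converged,
        iterations=it,
        fmax=fmax(final.forces),
        energy_trace=trace,
    )


# ---------------------------------------------------------------------------
# Hessians and normal modes


def finite_difference_hessian(
    geometry: Geometry, model: PotentialModel, step: float = 0.01
) -> np.ndarray:
    """Symmetrized central-difference Hessian (3N×3N, eV/Å²) from forces."""
    if not 1e-4 <= step <= 5e-2:
        raise ValueError(f"step {step} outside [1e-4, 5e-2] Å")
    n3 = geometry.n_atoms * 3
    pos = geometry.positions.ravel()
    H = np.empty((n3, n3))
    for k in range(n3):
        xp = pos.copy()
        xp[k] += step
        xm = pos.copy()
        xm[k] -= step
        try:
            _, fp = model.evaluate(geometry.with_positions(xp.reshape(-1, 3)))
            _, fm = model.evaluate(geometry.with_positions(xm.reshape(-1, 3)))
        except Exception as exc:
            raise RuntimeError(
                f"calculator failed at displacement of coordinate {k}"
            ) from exc
        # H[k, :] = -d F / d x_k (central difference)
        H[k, :] = -(fp.ravel() - fm.ravel()) / (2.0 * step)
    return 0.5 * (H + H.T)


def _rigid_mode_basis(geometry: Geometry, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = geometry.n_atoms
    sqrtm = np.sqrt(masses)
    com = np.sum(geometry.positions * masses[:, None], axis=0) / masses.sum()
    rel = geometry.positions - com
    vecs = []
    for ax in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, ax] = sqrtm
        vecs.append(v.ravel())
    for ax in range(3):  # rotations about the principal axes through the COM
        e = np.zeros(3)
        e[ax] = 1.0
        v = np.cross(np.tile(e, (n, 1)), rel) * sqrtm[:, None]
        vecs.append(v.ravel())
    # orthonormalize, dropping null rotations (linear molecules, single atoms)
    basis: list[np.ndarray] = []
    for v in vecs:
        for b in basis:
            v = v - np.dot(b, v) * b
        nrm = np.linalg.norm(v)
        if nrm > 1e-8:
            basis.append(v / nrm)
    return np.array(basis).T if basis else np.zeros((3 * n, 0))


def vibrational_analysis(
    geometry: Geometry,
    hessian: np.ndarray,
    masses: np.ndarray | None = None,
    projection: str = "auto",
) -> VibrationalAnalysis:
    """Mass-weight the Hessian, project out rigid modes, diagonalize.

    projection="auto" removes 3 translations and 3 (2 for linear molecules)
    rotations; "none" skips projection for reduced-dimensional surfaces.
    """
    n = geometry.n_atoms
    if masses is None:
        masses = geometry.masses
    masses = np.asarray(masses, float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError("hessian shape mismatch")
    if not np.allclose(hessian, hessian.T, atol=1e-8):
        raise ValueError("hessian must be symmetric")
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    Hm = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    if projection == "none":
        n_rigid = 0
        P = np.eye(3 * n)
    elif projection == "auto":
        B = _rigid_mode_basis(geometry, masses)
        n_rigid = B.shape[1]
        P = np.eye(3 * n) - B @ B.T
    else:
        raise ValueError(f"unknown projection {projection!r}")
    Hp = P @ Hm @ P
    Hp = 0.5 * (Hp + Hp.T)
    eigenvalues, modes = np.linalg.eigh(Hp)
    return VibrationalAnalysis(eigenvalues=eigenvalues, modes=modes, n_rigid=n_rigid)
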