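"""Normal-mode sampling: thermally perturbed near-equilibrium structures.

The classical harmonic Boltzmann distribution at temperature T assigns each
vibrational mode an independent zero-mean Gaussian coefficient with
variance k_B·T / k_mode (equipartition: mean potential energy k_B·T/2 per
mode). Mode displacements are un-mass-weighted and summed onto the
equilibrium geometry. This is the baseline dataset the pathway-sampling
method is contrasted against: it covers equilibrium wells densely but
never reaches dissociative or transition-state regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calculators import PotentialModel
from .core import Geometry
from .optimizers import (
    finite_difference_hessian,
    fmax,
    vibrational_analysis,
)

__all__ = ["BOLTZMANN_EV_PER_K", "NMSConfig", "normal_mode_sample"]

BOLTZMANN_EV_PER_K = 8.617333e-5  # k_B in eV/K


@dataclass(frozen=True)
class NMSConfig:
    temperature: float = 1500.0  # K
    n_samples: int = 1000  # structures per equilibrium geometry
    seed: int = 0
    min_fmax: float = 0.02  # eV/Å precondition on the equilibrium input
    eig_floor: float = 1e-6  # modes with k below this are treated as rigid noise

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


def normal_mode_sample(
    equilibrium: Geometry,
    model: PotentialModel,
    masses: np.ndarray | None = None,
    config: NMSConfig = NMSConfig(),
) -> list[Geometry]:
    """Draw thermally displaced structures around a minimized geometry.

    Raises if the input is not a minimum (residual force above the
    precondition tolerance, or any negative vibrational eigenvalue).
    Deterministic for a given seed.
    """
    e0, f0 = model.evaluate(equilibrium)
    if fmax(f0) > config.min_fmax:
        raise ValueError(
            f"geometry not minimized (Fmax {fmax(f0):.4f} > {config.min_fmax})"
        )
    if masses is None:
        masses = equilibrium.masses
    masses = np.asarray(masses, float)
    H = finite_difference_hessian(equilibrium, model)
    vib = vibrational_analysis(
        equilibrium, H, masses=masses, projection=model.rigid_projection
    )
    lam = vib.vibrational_eigenvalues
    if np.any(lam < -config.eig_floor):
        raise ValueError("negative vibrational eigenvalue: not a minimum")
    # columns of vib.modes matching the vibrational eigenvalues
    order = np.argsort(np.abs(vib.eigenvalues))
    rigid_idx = set(order[: vib.n_rigid].tolist())
    keep = [i for i in np.argsort(vib.eigenvalues) if i not in rigid_idx]
    modes = vib.modes[:, keep]
    k_modes = vib.eigenvalues[keep]
    usable = k_modes > config.eig_floor
    modes = modes[:, usable]
    k_modes = k_modes[usable]

    kT = BOLTZMANN_EV_PER_K * config.temperature
    sigma = np.sqrt(kT / k_modes)  # per-mode coefficient std dev
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)

    rng = np.random.default_rng(config.seed)
    out: list[Geometry] = []
    for _ in range(config.n_samples):
        coeffs = rng.normal(0.0, sigma)
        disp_mw = modes @ coeffs  # mass-weighted Cartesian displacement
        disp = (disp_mw * inv_sqrt_m).reshape(-1, 3)
        out.append(equilibrium.with_positions(equilibrium.positions + disp))
    return out
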