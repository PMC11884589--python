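"""Potential-energy models behind a uniform, deterministic contract.

Built-in analytic toys (pairwise Morse clusters, the Müller–Brown benchmark
surface, a harmonic bowl) make every pipeline stage testable without an
external electronic-structure engine; a subprocess adapter defines the
boundary to real tight-binding/DFT codes.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ATOMIC_NUMBERS, Geometry, write_xyz

__all__ = [
    "PotentialModel",
    "CalculatorError",
    "UnsupportedElementError",
    "CalculatorFailure",
    "MorseClusterParams",
    "MorseCluster",
    "DEFAULT_MORSE_TABLE",
    "default_morse_cluster",
    "MuellerBrown",
    "MUELLER_BROWN_MINIMA",
    "MUELLER_BROWN_SADDLES",
    "HarmonicBowl",
    "ExternalEngine",
]


class CalculatorError(RuntimeError):
    """Base class for potential-evaluation errors."""


class UnsupportedElementError(CalculatorError):
    """The model cannot describe one of the requested elements."""


class CalculatorFailure(CalculatorError):
    """The engine returned a non-finite or unparseable result; callers must
    treat the pathway as non-convergent."""


class PotentialModel(ABC):
    """Deterministic energy/force model.

    ``evaluate`` must return bitwise-identical results for identical
    geometries, and forces must be the negative gradient of the energy.
    """

    name: str = "potential"
    #: element symbols the model supports; None means unrestricted
    supported_elements: frozenset[str] | None = None
    #: "auto" projects 3 translations (+rotations) in vibrational analysis;
    #: "none" is for reduced-dimensional surfaces like Müller–Brown
    rigid_projection: str = "auto"

    def check_support(self, geometry: Geometry) -> None:
        if self.supported_elements is None:
            return
        bad = set(geometry.symbols) - set(self.supported_elements)
        if bad:
            raise UnsupportedElementError(
                f"{self.name} does not support elements {sorted(bad)}"
            )

    def evaluate(self, geometry: Geometry) -> tuple[float, np.ndarray]:
        """Return (energy in eV, forces in eV/Å of shape (N, 3))."""
        self.check_support(geometry)
        energy, forces = self._evaluate(geometry.positions, geometry.symbols)
        forces = np.asarray(forces, dtype=np.float64).reshape(geometry.positions.shape)
        if not (np.isfinite(energy) and np.all(np.isfinite(forces))):
            raise CalculatorFailure(f"{self.name} returned non-finite energy/forces")
        return float(energy), forces

    def label(self, geometry: Geometry) -> Geometry:
        """Evaluate and attach energy/forces/level tag to the geometry."""
        e, f = self.evaluate(geometry)
        return geometry.with_labels(e, f, level_tag=self.name)

    @abstractmethod
    def _evaluate(self, positions: np.ndarray, symbols: tuple[str, ...]):
        ...


# ---------------------------------------------------------------------------
# pairwise Morse cluster


@dataclass(frozen=True)
class MorseClusterParams:
    """Per-pair Morse parameters: E(r) = D (1 - exp(-a (r - r0)))^2 - D.

    Keys are unordered element-symbol pairs. D in eV, a in 1/Å, r0 in Å,
    all strictly positive.
    """

    table: dict[frozenset, tuple[float, float, float]]

    def __post_init__(self) -> None:
        norm = {}
        for key, (D, a, r0) in self.table.items():
            pair = frozenset(key) if not isinstance(key, frozenset) else key
            if not (len(pair) in (1, 2) and all(s in ATOMIC_NUMBERS for s in pair)):
                raise ValueError(f"bad element pair {key!r}")
            if not (D > 0 and a > 0 and r0 > 0):
                raise ValueError(f"Morse parameters for {key!r} must be positive")
            norm[pair] = (float(D), float(a), float(r0))
        object.__setattr__(self, "table", norm)

    def lookup(self, s1: str, s2: str) -> tuple[float, float, float]:
        try:
            return self.table[frozenset((s1, s2))]
        except KeyError:
            raise UnsupportedElementError(
                f"no Morse parameters for pair ({s1}, {s2})"
            ) from None

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(s for pair in self.table for s in pair)


# Default toy-chemistry table (D eV, a 1/Å, r0 Å). Wells are deep and narrow
# for bondable pairs and heavy-atom pairs carry a soft long-range repulsion,
# so that bond-exchange reactions cross genuine first-order saddles with
# barriers of order 0.5–2 eV instead of forming stable shared-atom complexes
# (pure pairwise attraction would otherwise stabilise them). H–H is
# non-bonding at short range to keep hydrogens apart within molecules.
DEFAULT_MORSE_TABLE: dict[tuple[str, ...], tuple[float, float, float]] = {
    ("H", "H"): (0.20, 1.8, 1.60),
    ("O", "H"): (5.00, 3.5, 0.96),
    ("N", "H"): (4.30, 3.4, 1.01),
    ("C", "H"): (4.50, 3.2, 1.09),
    ("S", "H"): (3.80, 3.0, 1.34),
    ("Cl", "H"): (4.60, 3.3, 1.27),
    ("C", "C"): (3.60, 3.0, 1.54),
    ("C", "N"): (3.30, 3.1, 1.47),
    ("C", "O"): (3.70, 3.2, 1.43),
    ("C", "S"): (2.90, 2.8, 1.82),
    ("C", "Cl"): (3.40, 3.0, 1.77),
    ("N", "N"): (0.10, 1.8, 3.30),
    ("N", "O"): (0.10, 1.8, 3.40),
    ("O", "O"): (0.10, 1.8, 3.40),
    ("O", "S"): (0.10, 1.8, 3.60),
    ("O", "Cl"): (0.10, 1.8, 3.60),
    ("N", "S"): (0.10, 1.8, 3.60),
    ("N", "Cl"): (0.10, 1.8, 3.60),
    ("S", "S"): (0.10, 1.8, 3.80),
    ("S", "Cl"): (0.10, 1.8, 3.80),
    ("Cl", "Cl"): (0.10, 1.8, 3.80),
}


class MorseCluster(PotentialModel):
    """Sum of pairwise Morse terms over all atom pairs."""

    def __init__(self, params: MorseClusterParams | dict | None = None, name: str = "morse"):
        if params is None:
            params = MorseClusterParams(dict(DEFAULT_MORSE_TABLE))
        elif isinstance(params, dict):
            params = MorseClusterParams(params)
        self.params = params
        self.name = name
        self.supported_elements = params.elements

    def _evaluate(self, positions: np.ndarray, symbols: tuple[str, ...]):
        n = len(symbols)
        energy = 0.0
        forces = np.zeros_like(positions)
        for i in range(n):
            for j in range(i + 1, n):
                D, a, r0 = self.params.lookup(symbols[i], symbols[j])
                rij = positions[i] - positions[j]
                r = float(np.linalg.norm(rij))
                ex = np.exp(-a * (r - r0))
                energy += D * (1.0 - ex) ** 2 - D
                # dE/dr = 2 D a (1 - ex) ex
                dEdr = 2.0 * D * a * (1.0 - ex) * ex
                if r > 0:
                    g = dEdr * rij / r
                    forces[i] -= g
                    forces[j] += g
        return energy, forces


def default_morse_cluster() -> MorseCluster:
    return MorseCluster()


# ---------------------------------------------------------------------------
# Müller–Brown benchmark surface


_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])

# Stationary points (refined by Newton iteration on the analytic gradient;
# energies in the surface's own units, treated as eV).
MUELLER_BROWN_MINIMA: tuple[tuple[float, float], ...] = (
    (-0.5582236346, 1.4417258418),
    (-0.0500108228, 0.4666941049),
    (0.6234994049, 0.0280377586),
)
MUELLER_BROWN_SADDLES: tuple[tuple[float, float], ...] = (
    (-0.8220015587, 0.6243128028),
    (0.2124865821, 0.2929883251),
)


def mueller_brown_energy(x: float, y: float) -> float:
    """Energy of the four-Gaussian Müller–Brown surface at (x, y)."""
    dx = x - _MB_x0
    dy = y - _MB_y0
    return float(np.sum(_MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)))


def mueller_brown_gradient(x: float, y: float) -> tuple[float, float]:
    dx = x - _MB_x0
    dy = y - _MB_y0
    terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    gx = float(np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy)))
    gy = float(np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy)))
    return gx, gy


class MuellerBrown(PotentialModel):
    """The Müller–Brown surface exposed through the Geometry interface.

    A single pseudo-atom carries (x, y) in its first two coordinates; the z
    coordinate is inert (zero force, zero curvature), so chain-of-states,
    Hessian and TS-signature code paths run unchanged on this 2-D benchmark.
    """

    name = "mueller-brown"
    rigid_projection = "none"

    @staticmethod
    def geometry(x: float, y: float) -> Geometry:
        return Geometry((1,), np.array([[x, y, 0.0]]))

    def _evaluate(self, positions: np.ndarray, symbols: tuple[str, ...]):
        if positions.shape[0] != 1:
            raise CalculatorError("Müller–Brown expects a single pseudo-atom")
        x, y = float(positions[0, 0]), float(positions[0, 1])
        gx, gy = mueller_brown_gradient(x, y)
        forces = np.array([[-gx, -gy, 0.0]])
        return mueller_brown_energy(x, y), forces


class HarmonicBowl(PotentialModel):
    """Isotropic quadratic well E = ½ k Σ |r_i - c|²; a minimal test surface."""

    name = "harmonic-bowl"

    def __init__(self, k: float = 2.0, center: np.ndarray | None = None):
        self.k = float(k)
        self.center = np.zeros(3) if center is None else np.asarray(center, float)

    def _evaluate(self, positions: np.ndarray, symbols: tuple[str, ...]):
        d = positions - self.center
        return 0.5 * self.k * float(np.sum(d**2)), -self.k * d


# ---------------------------------------------------------------------------
# external-engine adapter


class ExternalEngine(PotentialModel):
    """Subprocess adapter to an external energy/force engine.

    The engine is invoked as ``<command> <geometry.xyz>`` and must print a
    simple key-value layout::

        energy <eV>
        force <fx> <fy> <fz>     # one line per atom, eV/Å

    Parse failures, missing binaries and non-finite results are reported as
    distinct errors. Disabled unless a command is configured.
    """

    rigid_projection = "auto"

    def __init__(self, command: list[str] | str, name: str = "external",
                 supported_elements=None):
        self.command = [command] if isinstance(command, str) else list(command)
        self.name = name
        self.supported_elements = (
            frozenset(supported_elements) if supported_elements else None
        )

    def _evaluate(self, positions: np.ndarray, symbols: tuple[str, ...]):
        if shutil.which(self.command[0]) is None and not Path(self.command[0]).exists():
            raise CalculatorError(f"engine binary {self.command[0]!r} not found")
        with tempfile.TemporaryDirectory() as tmp:
            xyz = Path(tmp) / "geom.xyz"
            geom = Geometry.from_symbols(symbols, positions)
            write_xyz(xyz, geom)
            try:
                proc = subprocess.run(
                    [*self.command, str(xyz)],
                    capture_output=True,
                    text=True,
                    check=True,
                )
            except subprocess.CalledProcessError as exc:
                raise CalculatorFailure(
                    f"engine exited with status {exc.returncode}"
                ) from exc
        return self._parse(proc.stdout, len(symbols))

    @staticmethod
    def _parse(text: str, n_atoms: int):
        energy = None
        forces = []
        for line in text.splitlines():
            parts = line.split()
            if not parts:
                continue
            try:
                if parts[0] == "energy":
                    if len(parts) != 2:
                        raise ValueError
                    energy = float(parts[1])
                elif parts[0] == "force":
                    if len(parts) != 4:
                        raise ValueError
                    forces.append([float(x) for x in parts[1:]])
            except ValueError:
                raise CalculatorError(f"malformed engine output line: {line!r}") from None
        if energy is None or len(forces) != n_atoms:
            raise CalculatorError(
                f"engine output missing energy or forces ({len(forces)}/{n_atoms} atoms)"
            )
        return energy, np.array(forces)
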