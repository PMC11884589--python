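"""Molecular data model: geometries, bonded graphs, connectivity perception.

Energies are in eV, lengths in Å, forces in eV/Å throughout the package.
Atom indices are 0-based internally; the driving-coordinate text dialect
uses 1-based indices (see :mod:`rpskit.driving`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "COVALENT_RADII",
    "DEFAULT_MAX_VALENCE",
    "FULL_VALENCE",
    "SUPPORTED_ELEMENTS",
    "ATOMIC_NUMBERS",
    "ELEMENT_SYMBOLS",
    "ATOMIC_MASSES",
    "Geometry",
    "MolecularGraph",
    "BondChange",
    "BondChangeKind",
    "DegenerateGeometryError",
    "perceive_bonds",
    "hill_formula",
    "canonical_graph_key",
    "graph_diff",
    "is_closed_shell_realizable",
    "read_xyz",
    "write_xyz",
]

# Single-bond covalent radii (Å), Cordero et al. 2008 consensus values.
# A fixed table shipped with the package keeps bond perception deterministic.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "Cl": 1.02,
}

# Maximum coordination numbers used for valence-legality checks. Graphs are
# treated as neutral closed-shell; under-coordination is allowed (reaction
# intermediates are legitimately under-coordinated), only the maxima bind.
DEFAULT_MAX_VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 4,  # configurable up to 6 via the max_valence argument
    "Cl": 1,
}

ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "Cl": 17}
ELEMENT_SYMBOLS: dict[int, str] = {z: s for s, z in ATOMIC_NUMBERS.items()}
SUPPORTED_ELEMENTS: frozenset[int] = frozenset(ATOMIC_NUMBERS.values())

# Full (closed-shell) valences: the total bond order of every atom in a
# saturated neutral organic molecule. Used by the closed-shell feasibility
# check that the GDB-style enumeration mode applies to candidate products.
FULL_VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "Cl": 1,
}

# Standard atomic weights (amu), used for mass-weighted Hessians and NMS.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
}


class DegenerateGeometryError(ValueError):
    """Raised when atoms overlap so closely that perception is meaningless."""


def _as_symbol(z: int | str) -> str:
    if isinstance(z, str):
        if z not in ATOMIC_NUMBERS:
            raise ValueError(f"unsupported element symbol {z!r}")
        return z
    try:
        return ELEMENT_SYMBOLS[int(z)]
    except KeyError:
        raise ValueError(f"unsupported atomic number {z}") from None


@dataclass(frozen=True)
class Geometry:
    """A molecular structure with optional energy/force labels.

    Parameters
    ----------
    atomic_numbers
        Proton numbers, one per atom.
    positions
        Cartesian coordinates, shape (N, 3), Å.
    energy
        Optional total energy, eV.
    forces
        Optional forces, shape (N, 3), eV/Å.
    level_tag
        Short string naming the theory level that produced the labels.
    """

    atomic_numbers: tuple[int, ...]
    positions: np.ndarray
    energy: float | None = None
    forces: np.ndarray | None = None
    level_tag: str | None = None
    allowed_elements: frozenset[int] = field(default=SUPPORTED_ELEMENTS, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "atomic_numbers", tuple(int(z) for z in self.atomic_numbers))
        pos = np.array(self.positions, dtype=np.float64, copy=True, order="C")
        if pos.ndim != 2 or pos.shape != (len(self.atomic_numbers), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.atomic_numbers)} atoms"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite coordinates")
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        bad = set(self.atomic_numbers) - self.allowed_elements
        if bad:
            raise ValueError(f"unsupported atomic numbers {sorted(bad)}")
        if self.forces is not None:
            f = np.array(self.forces, dtype=np.float64, copy=True, order="C")
            if f.shape != pos.shape:
                raise ValueError(f"forces shape {f.shape} != positions shape {pos.shape}")
            f.setflags(write=False)
            object.__setattr__(self, "forces", f)
        if self.energy is not None:
            object.__setattr__(self, "energy", float(self.energy))

    @classmethod
    def from_symbols(
        cls,
        symbols: Sequence[str],
        positions: np.ndarray,
        **kwargs,
    ) -> "Geometry":
        return cls(tuple(ATOMIC_NUMBERS[s] for s in symbols), positions, **kwargs)

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(ELEMENT_SYMBOLS[z] for z in self.atomic_numbers)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.symbols])

    def with_positions(self, positions: np.ndarray) -> "Geometry":
        """Copy with new coordinates and stale labels dropped."""
        return replace(self, positions=positions, energy=None, forces=None)

    def with_labels(
        self, energy: float, forces: np.ndarray, level_tag: str | None = None
    ) -> "Geometry":
        return replace(
            self,
            energy=energy,
            forces=forces,
            level_tag=level_tag if level_tag is not None else self.level_tag,
        )

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))


def _normalize_bond(pair: Iterable[int]) -> tuple[int, int]:
    i, j = sorted(int(x) for x in pair)
    if i == j:
        raise ValueError(f"self-bond ({i},{j})")
    return (i, j)


@dataclass(frozen=True)
class MolecularGraph:
    """Element-labeled connectivity graph with valence bookkeeping.

    Bonds are unordered index pairs; bond orders are not tracked — driving
    coordinates specify connectivity changes only.
    """

    elements: tuple[str, ...]
    bonds: frozenset[tuple[int, int]]
    formal_charge: int = 0
    max_valence: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MAX_VALENCE))
    #: strict graphs reject over-valent atoms at construction; perceived
    #: graphs along reaction paths may transiently exceed the maxima and are
    #: built non-strict, to be judged by the feasibility filter instead
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(_as_symbol(e) for e in self.elements))
        n = len(self.elements)
        norm = frozenset(_normalize_bond(b) for b in self.bonds)
        for i, j in norm:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
        object.__setattr__(self, "bonds", norm)
        for idx, d in enumerate(self.degrees()):
            cap = self.max_valence.get(self.elements[idx])
            if cap is None:
                raise ValueError(f"no valence cap configured for {self.elements[idx]}")
            if self.strict and d > cap:
                raise ValueError(
                    f"atom {idx} ({self.elements[idx]}) has degree {d} > max valence {cap}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def degrees(self) -> list[int]:
        deg = [0] * len(self.elements)
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b in self.bonds:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def has_bond(self, i: int, j: int) -> bool:
        return _normalize_bond((i, j)) in self.bonds

    def with_bonds(
        self,
        add: Iterable[tuple[int, int]] = (),
        remove: Iterable[tuple[int, int]] = (),
    ) -> "MolecularGraph":
        bonds = set(self.bonds)
        bonds -= {_normalize_bond(b) for b in remove}
        bonds |= {_normalize_bond(b) for b in add}
        return MolecularGraph(self.elements, frozenset(bonds), self.formal_charge, dict(self.max_valence), strict=self.strict)

    def is_valence_legal(self) -> bool:
        return all(
            d <= self.max_valence[self.elements[i]] for i, d in enumerate(self.degrees())
        )

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms: new index perm[i] holds old atom i."""
        elements = [None] * self.n_atoms
        for old, new in enumerate(perm):
            elements[new] = self.elements[old]
        bonds = frozenset(_normalize_bond((perm[i], perm[j])) for i, j in self.bonds)
        return MolecularGraph(tuple(elements), bonds, self.formal_charge, dict(self.max_valence), strict=self.strict)


def is_closed_shell_realizable(
    graph: MolecularGraph, full_valence: dict[str, int] | None = None
) -> bool:
    """Whether bond orders can saturate every atom exactly (no radicals).

    The connectivity graph is realizable as a closed-shell molecule iff
    extra bond orders x_e ∈ {0, 1, 2} can be placed on existing bonds so
    that each atom's degree plus its incident extras equals its full
    valence (double/triple bonds absorb the deficiencies).
    """
    fv = full_valence or FULL_VALENCE
    deg = graph.degrees()
    try:
        deficiency = [fv[e] - d for e, d in zip(graph.elements, deg)]
    except KeyError as exc:
        raise ValueError(f"no full valence configured for {exc.args[0]}") from None
    if any(d < 0 for d in deficiency):
        return False
    active = sorted(
        (i, j) for i, j in graph.bonds if deficiency[i] > 0 and deficiency[j] > 0
    )

    def assign(k: int, deficiency: list[int]) -> bool:
        if all(d == 0 for d in deficiency):
            return True
        if k == len(active):
            return False
        i, j = active[k]
        for x in range(min(deficiency[i], deficiency[j], 2), -1, -1):
            deficiency[i] -= x
            deficiency[j] -= x
            if assign(k + 1, deficiency):
                return True
            deficiency[i] += x
            deficiency[j] += x
        return False

    return assign(0, list(deficiency))


class BondChangeKind(str, Enum):
    ADD = "ADD"
    BREAK = "BREAK"


@dataclass(frozen=True, order=True)
class BondChange:
    """A single connectivity alteration: form or break one bond."""

    kind: BondChangeKind
    pair: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", BondChangeKind(self.kind))
        object.__setattr__(self, "pair", _normalize_bond(self.pair))


# ---------------------------------------------------------------------------
# connectivity perception


def perceive_bonds(geometry: Geometry, scale: float = 1.2) -> MolecularGraph:
    """Perceive bonds from interatomic distances.

    A bond is present iff d(i, j) < scale * (r_cov_i + r_cov_j) using the
    package's fixed covalent-radius table.

    Raises
    ------
    DegenerateGeometryError
        If any two atoms are closer than 0.1 Å.
    ValueError
        If scale is outside (1.0, 1.5].
    """
    if not 1.0 < scale <= 1.5:
        raise ValueError(f"scale must be in (1.0, 1.5], got {scale}")
    symbols = geometry.symbols
    radii = np.array([COVALENT_RADII[s] for s in symbols])
    pos = geometry.positions
    n = geometry.n_atoms
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    if n > 1 and np.any(dist[iu] < 0.1):
        i = int(np.argmin(dist[iu]))
        a, b = iu[0][i], iu[1][i]
        raise DegenerateGeometryError(
            f"atoms {a} and {b} overlap (d = {dist[a, b]:.3f} Å)"
        )
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonds = frozenset(
        (int(i), int(j)) for i, j in zip(*iu) if dist[i, j] < cutoff[i, j]
    )
    return MolecularGraph(symbols, bonds, strict=False)


def hill_formula(geometry_or_symbols: Geometry | Sequence[str]) -> str:
    """Hill-notation chemical formula: C first, H second, rest alphabetical."""
    if isinstance(geometry_or_symbols, Geometry):
        symbols: Sequence[str] = geometry_or_symbols.symbols
    else:
        symbols = [_as_symbol(s) for s in geometry_or_symbols]
    if not symbols:
        raise ValueError("empty atom list")
    counts: dict[str, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(sorted(k for k in counts if k not in ("C", "H")))
    else:
        ordered.extend(sorted(counts))
    return "".join(f"{s}{counts[s] if counts[s] > 1 else ''}" for s in ordered)


# ---------------------------------------------------------------------------
# canonical graph keys (isomorphism-invariant dedup backbone)


def _refine_colors(
    n: int, adj: list[set[int]], colors: list[int]
) -> list[int]:
    """Iterative neighborhood refinement until the partition is stable."""
    while True:
        sigs = [
            (colors[i], tuple(sorted(colors[j] for j in adj[i]))) for i in range(n)
        ]
        order = sorted(set(sigs))
        relabel = {s: k for k, s in enumerate(order)}
        new = [relabel[s] for s in sigs]
        if new == colors:
            return new
        colors = new


def _certificate(n: int, adj: list[set[int]], colors: list[int], elements) -> tuple:
    """Canonical certificate by individualization-refinement.

    Chooses the lexicographically minimal adjacency encoding over all
    discrete orderings reachable by individualizing atoms in the first
    non-singleton color class. Exponential worst case but molecular graphs
    here are small (≤13 atoms).
    """
    colors = _refine_colors(n, adj, colors)
    classes: dict[int, list[int]] = {}
    for i, c in enumerate(colors):
        classes.setdefault(c, []).append(i)
    target = None
    for c in sorted(classes):
        if len(classes[c]) > 1:
            target = c
            break
    if target is None:
        # discrete: order atoms by color, encode element string + edge list
        perm = sorted(range(n), key=lambda i: colors[i])
        rank = {atom: k for k, atom in enumerate(perm)}
        edges = tuple(
            sorted(tuple(sorted((rank[i], rank[j]))) for i in range(n) for j in adj[i] if i < j)
        )
        return (tuple(elements[i] for i in perm), edges)
    best = None
    for atom in classes[target]:
        split = list(colors)
        split = [c + 1 if c > target or (c == target and i != atom) else c
                 for i, c in enumerate(split)]
        cert = _certificate(n, adj, split, elements)
        if best is None or cert < best:
            best = cert
    return best


def canonical_graph_key(graph: MolecularGraph) -> str:
    """Deterministic key equal for exactly the isomorphic element-labeled graphs."""
    n = graph.n_atoms
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in graph.bonds:
        adj[i].add(j)
        adj[j].add(i)
    elem_order = sorted(set(graph.elements))
    colors = [elem_order.index(e) for e in graph.elements]
    cert = _certificate(n, adj, colors, graph.elements)
    payload = repr((graph.formal_charge, cert)).encode()
    return hashlib.sha256(payload).hexdigest()[:32]


def graphs_isomorphic_brute(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Exhaustive permutation isomorphism test (oracle; small graphs only)."""
    if sorted(a.elements) != sorted(b.elements) or len(a.bonds) != len(b.bonds):
        return False
    n = a.n_atoms
    for perm in permutations(range(n)):
        if any(a.elements[i] != b.elements[perm[i]] for i in range(n)):
            continue
        if frozenset(_normalize_bond((perm[i], perm[j])) for i, j in a.bonds) == b.bonds:
            return True
    return False


def graph_diff(
    reactant: MolecularGraph, product: MolecularGraph
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Bond changes from reactant to product on a conserved atom list.

    Returns (added, removed); the bond-change count is ``len(added) +
    len(removed)``.
    """
    if reactant.elements != product.elements:
        raise ValueError("graph_diff requires identical atom lists")
    added = set(product.bonds) - set(reactant.bonds)
    removed = set(reactant.bonds) - set(product.bonds)
    return added, removed


# ---------------------------------------------------------------------------
# XYZ I/O


def write_xyz(path, geometries: Geometry | Sequence[Geometry], mode: str = "w") -> None:
    """Write one or more frames in XYZ format; energy goes on the comment line."""
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    with open(path, mode) as fh:
        for g in geometries:
            fh.write(f"{g.n_atoms}\n")
            comment = ""
            if g.energy is not None:
                comment = f"energy={g.energy:.12f} eV"
                if g.level_tag:
                    comment += f" level={g.level_tag}"
            fh.write(comment + "\n")
            for s, (x, y, z) in zip(g.symbols, g.positions):
                fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path) -> list[Geometry]:
    """Read all frames of a (multi-frame) XYZ file.

    Recognizes ``energy=<float>`` and ``level=<tag>`` tokens on the comment
    line as written by :func:`write_xyz`.
    """
    frames: list[Geometry] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        energy = None
        level = None
        for tok in comment.split():
            if tok.startswith("energy="):
                energy = float(tok[len("energy="):])
            elif tok.startswith("level="):
                level = tok[len("level="):]
        symbols = []
        coords = []
        for ln in lines[k + 2 : k + 2 + n]:
            parts = ln.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append(
            Geometry.from_symbols(symbols, np.array(coords), energy=energy, level_tag=level)
        )
        k += 2 + n
    return frames
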