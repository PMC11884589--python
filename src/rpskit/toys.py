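"""Ready-made toy systems for exercising the pipeline end to end.

These small fixtures pair geometries with the default Morse-cluster
chemistry: a hydroxyl + oxygen hydrogen-transfer system whose bond exchange
crosses a genuine first-order saddle, a toy water molecule, and simple
dimers. They are first-class inputs — the pipeline's study conditions —
not test-only scaffolding.
"""

from __future__ import annotations

import numpy as np

from .calculators import MorseCluster, MorseClusterParams, DEFAULT_MORSE_TABLE
from .core import Geometry, MolecularGraph
from .optimizers import local_minimize

__all__ = [
    "morse_dimer",
    "toy_water",
    "hydrogen_transfer_reactant",
    "gdb_style_reactant_c4h4clno",
    "refined_morse_cluster",
]


def morse_dimer(d: float = 0.96, elements: tuple[str, str] = ("O", "H")) -> Geometry:
    """Two atoms on the x axis at separation d (Å)."""
    return Geometry.from_symbols(elements, np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))


def toy_water(model: MorseCluster | None = None, fmax_tol: float = 1e-4) -> Geometry:
    """Bent H2O minimized on the default Morse chemistry."""
    model = model or MorseCluster()
    start = Geometry.from_symbols(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [0.96, 0.1, 0.0], [-0.25, 0.93, 0.05]]),
    )
    return local_minimize(start, model, fmax_tol=fmax_tol, max_steps=5000).geometry


def hydrogen_transfer_reactant(
    model: MorseCluster | None = None, fmax_tol: float = 1e-4
) -> Geometry:
    """O–H with a nitrogen acceptor nearby: the toy bond-exchange reactant.

    Driving ADD(1,2) + BREAK(0,1) transfers the hydrogen from oxygen to
    nitrogen over a barrier of order 1 eV on the default Morse table; the
    product graph differs from the reactant's, so the transformation is not
    an identity and survives enumeration and the repetition filter.
    """
    model = model or MorseCluster()
    start = Geometry.from_symbols(
        ("O", "H", "N"),
        np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [3.2, 0.6, 0.0]]),
    )
    return local_minimize(start, model, fmax_tol=fmax_tol, max_steps=5000).geometry


def gdb_style_reactant_c4h4clno() -> MolecularGraph:
    """A saturated GDB-style C4H4ClNO reactant graph for enumeration demos.

    The connectivity is a chloro-dihydropyrrolone: a five-membered
    N1–C2(=O)–C3H2–C4(H)(Cl)–C5(H)=N1 ring (SMILES ``O=C1CC(Cl)C=N1``).
    Every atom is closed-shell saturated once the C2=O and C5=N double
    bonds are assigned, so the closed-shell enumeration mode applies.

    Atom order: O(carbonyl), C2, C3, C4, C5, N1, Cl, then the four
    hydrogens (two on C3, one on C4, one on C5).
    """
    elements = ("O", "C", "C", "C", "C", "N", "Cl", "H", "H", "H", "H")
    bonds = frozenset(
        {
            (0, 1),  # O=C2 (double bond absorbed in saturation)
            (1, 2),  # C2–C3
            (2, 3),  # C3–C4
            (3, 4),  # C4–C5
            (4, 5),  # C5=N1
            (1, 5),  # C2–N1 closes the ring
            (3, 6),  # C4–Cl
            (2, 7),  # C3–H
            (2, 8),  # C3–H
            (3, 9),  # C4–H
            (4, 10),  # C5–H
        }
    )
    return MolecularGraph(elements, bonds)


def refined_morse_cluster(name: str = "morse-refined") -> MorseCluster:
    """A second theory level for the toy two-level refinement protocol.

    Same functional form, slightly deeper and stiffer wells (D ×1.06,
    a ×1.03) — a stand-in level hierarchy for exercising selective
    relabeling, labelled as its own synthetic theory level.
    """
    table = {
        pair: (1.06 * D, 1.03 * a, r0)
        for pair, (D, a, r0) in DEFAULT_MORSE_TABLE.items()
    }
    return MorseCluster(MorseClusterParams(table), name=name)
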