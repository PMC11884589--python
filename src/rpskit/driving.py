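"""Unbiased enumeration of candidate bond alterations (driving coordinates).

A driving-coordinate set is a small collection of ADD/BREAK bond primitives
that steers the growing-string product search toward one candidate
transformation. Enumeration is exhaustive over sets with up to ``max_break``
bonds broken and up to ``max_form`` bonds formed, subject to legality
filters: the altered graph must respect maximum valences, an ADD pair must
not already be bonded, a pair may appear at most once, and the altered
graph must not be isomorphic to the reactant (identity transformations are
excluded). Sets acting on symmetry-equivalent atoms are kept distinct:
driving coordinates act on labeled atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .core import (
    BondChange,
    BondChangeKind,
    MolecularGraph,
    canonical_graph_key,
    is_closed_shell_realizable,
)

__all__ = [
    "DrivingCoordinateSet",
    "enumerate_driving_coordinates",
    "format_driving_coordinates",
    "parse_driving_coordinates",
]


@dataclass(frozen=True)
class DrivingCoordinateSet:
    """One candidate transformation: an ordered list of bond alterations."""

    changes: tuple[BondChange, ...]
    provenance: str = ""  # canonical key of the reactant graph

    def __post_init__(self) -> None:
        changes = tuple(sorted(self.changes))
        if len({c.pair for c in changes}) != len(changes):
            raise ValueError("an atom pair may appear at most once")
        object.__setattr__(self, "changes", changes)

    @property
    def breaks(self) -> tuple[tuple[int, int], ...]:
        return tuple(c.pair for c in self.changes if c.kind is BondChangeKind.BREAK)

    @property
    def adds(self) -> tuple[tuple[int, int], ...]:
        return tuple(c.pair for c in self.changes if c.kind is BondChangeKind.ADD)

    def apply(self, graph: MolecularGraph) -> MolecularGraph:
        """Altered connectivity graph (valence legality checked by the graph)."""
        return graph.with_bonds(add=self.adds, remove=self.breaks)

    def __len__(self) -> int:
        return len(self.changes)


def _altered_graph_ok(
    graph: MolecularGraph,
    breaks: Sequence[tuple[int, int]],
    adds: Sequence[tuple[int, int]],
) -> bool:
    bonds = set(graph.bonds)
    bonds -= set(breaks)
    bonds |= set(adds)
    deg = [0] * graph.n_atoms
    for i, j in bonds:
        deg[i] += 1
        deg[j] += 1
    return all(
        d <= graph.max_valence[graph.elements[i]] for i, d in enumerate(deg)
    )


def enumerate_driving_coordinates(
    graph: MolecularGraph,
    max_break: int = 2,
    max_form: int = 2,
    heavy_only: bool = False,
    closed_shell_products: bool = False,
) -> list[DrivingCoordinateSet]:
    """All legal driving-coordinate sets for a reactant graph.

    Sets contain 0..max_break BREAKs of existing bonds and 0..max_form ADDs
    of currently non-bonded pairs, at least one change in total. The altered
    graph must be valence-legal and non-isomorphic to the reactant. Output
    order is deterministic (lexicographic over the sorted change lists).

    With ``heavy_only`` hydrogens are excluded from alterations (hydrogen
    transfer is chemically essential, so the default includes them).

    ``closed_shell_products`` additionally requires every altered graph to
    admit a full bond-order saturation (no radical products) — the
    enumeration mode for saturated GDB-style organic reactants, where
    homolytic fragments are not meaningful products. Off by default so that
    open-shell toy species and radical intermediates can be driven.
    """
    if max_break < 0 or max_form < 0 or (max_break == 0 and max_form == 0):
        raise ValueError("max_break/max_form must be ≥ 0 and not both 0")
    n = graph.n_atoms

    def allowed(i: int, j: int) -> bool:
        if heavy_only and ("H" in (graph.elements[i], graph.elements[j])):
            return False
        return True

    bond_list = sorted(b for b in graph.bonds if allowed(*b))
    nonbond_list = sorted(
        (i, j)
        for i, j in combinations(range(n), 2)
        if (i, j) not in graph.bonds and allowed(i, j)
    )
    reactant_key = canonical_graph_key(graph)
    out: list[DrivingCoordinateSet] = []
    for nb in range(max_break + 1):
        for breaks in combinations(bond_list, nb):
            for nf in range(max_form + 1):
                if nb + nf == 0:
                    continue
                for adds in combinations(nonbond_list, nf):
                    if not _altered_graph_ok(graph, breaks, adds):
                        continue
                    altered = graph.with_bonds(add=adds, remove=breaks)
                    if closed_shell_products and not is_closed_shell_realizable(altered):
                        continue
                    if canonical_graph_key(altered) == reactant_key:
                        continue
                    out.append(
                        DrivingCoordinateSet(
                            changes=tuple(
                                [BondChange(BondChangeKind.BREAK, b) for b in breaks]
                                + [BondChange(BondChangeKind.ADD, a) for a in adds]
                            ),
                            provenance=reactant_key,
                        )
                    )
    out.sort(key=lambda s: [(c.kind.value, c.pair) for c in s.changes])
    return out


# ---------------------------------------------------------------------------
# text dialect: "BREAK i j" / "ADD i j", 1-based atom indices


def format_driving_coordinates(dcs: DrivingCoordinateSet) -> str:
    return "\n".join(
        f"{c.kind.value} {c.pair[0] + 1} {c.pair[1] + 1}" for c in dcs.changes
    )


def parse_driving_coordinates(text: str, provenance: str = "") -> DrivingCoordinateSet:
    changes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, i, j = line.split()
        changes.append(BondChange(BondChangeKind(kind), (int(i) - 1, int(j) - 1)))
    return DrivingCoordinateSet(tuple(changes), provenance=provenance)
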