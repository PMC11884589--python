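"""Simplified single-ended growing-string product search.

From a minimized reactant and one driving-coordinate set, a string of nodes
is grown: each step displaces the targeted pair distances (ADD pairs pulled
toward 1.1× the covalent-radius sum, BREAK pairs pushed apart) by a fixed
increment, then relaxes every other degree of freedom with the targeted
distances constrained (forces projected off the constraint directions).
Growth stops when the perceived connectivity matches the altered graph; the
final node is then freely minimized to the product. The maximum-energy
interior node is a transition-state *proposal* — refinement is the job of
the climbing-image NEB stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .calculators import CalculatorError, PotentialModel
from .core import COVALENT_RADII, Geometry, MolecularGraph, perceive_bonds
from .driving import DrivingCoordinateSet
from .optimizers import fmax, local_minimize

__all__ = [
    "PathStatus",
    "StringPath",
    "ReactionTriad",
    "GSMParams",
    "TriadExtractionError",
    "run_se_gsm",
    "extract_triad",
]


class PathStatus(str, Enum):
    GROWN = "grown"
    CONVERGED = "converged"
    FAILED_DISSOCIATED = "failed-dissociated"
    FAILED_CALCULATOR = "failed-calculator"
    FAILED_NO_BARRIER = "failed-no-barrier"


@dataclass
class StringPath:
    nodes: list[Geometry]
    energies: list[float]
    status: PathStatus
    driving: DrivingCoordinateSet

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.energies):
            raise ValueError("energies must match node count")


@dataclass(frozen=True)
class ReactionTriad:
    """Reactant / transition-state / product with energies (eV)."""

    reactant: Geometry
    ts: Geometry
    product: Geometry
    driving: DrivingCoordinateSet

    def __post_init__(self) -> None:
        for g in (self.reactant, self.ts, self.product):
            if g.energy is None:
                raise ValueError("triad geometries must carry energies")
        if self.ts.energy < max(self.reactant.energy, self.product.energy) - 1e-6:
            raise ValueError("transition state below an endpoint energy")

    @property
    def barrier(self) -> float:
        """Activation energy E(ts) − E(reactant), eV."""
        return float(self.ts.energy - self.reactant.energy)


@dataclass(frozen=True)
class GSMParams:
    growth_increment: float = 0.3  # Å moved per targeted distance per node
    max_nodes: int = 30
    relax_fmax: float = 0.05  # eV/Å for constrained node relaxation
    relax_steps: int = 300
    reactant_fmax: float = 0.02  # precondition on the input reactant
    product_fmax: float = 0.01  # free minimization of the final node
    add_target_scale: float = 1.1  # × covalent-radius sum for ADD pairs
    dissociation_cutoff: float = 20.0  # Å
    perception_scale: float = 1.2
    #: abort growth once a node rises this far above the reactant — the
    #: driven connectivity is unreachable at chemically relevant energies
    max_energy_rise: float = 10.0  # eV


class TriadExtractionError(RuntimeError):
    def __init__(self, status: PathStatus, message: str):
        super().__init__(message)
        self.status = status


def _pair_distance_transform(pairs: list[tuple[int, int]]):
    """Force transform projecting off the constrained pair-distance directions."""

    def transform(positions: np.ndarray, forces: np.ndarray) -> np.ndarray:
        f = forces.copy()
        for i, j in pairs:
            u = positions[i] - positions[j]
            r = np.linalg.norm(u)
            if r < 1e-12:
                continue
            u = u / r
            # constraint gradient direction in full coordinate space: (+u, -u)/√2
            comp = (np.dot(f[i], u) - np.dot(f[j], u)) / 2.0
            f[i] -= comp * u
            f[j] += comp * u
        return f

    return transform


def _set_pair_distance(positions: np.ndarray, i: int, j: int, d_new: float) -> None:
    u = positions[i] - positions[j]
    r = np.linalg.norm(u)
    if r < 1e-12:
        raise ValueError(f"coincident atoms {i},{j}")
    shift = 0.5 * (d_new - r) * (u / r)
    positions[i] += shift
    positions[j] -= shift


def run_se_gsm(
    reactant: Geometry,
    driving: DrivingCoordinateSet,
    model: PotentialModel,
    params: GSMParams = GSMParams(),
) -> StringPath:
    """Grow a string from the reactant along one driving-coordinate set.

    Node 0 is the (already minimized) reactant and is never modified.
    """
    if len(driving) == 0:
        raise ValueError("empty driving-coordinate set")
    e0, f0 = model.evaluate(reactant)
    if fmax(f0) > params.reactant_fmax:
        raise ValueError(
            f"reactant not minimized (Fmax {fmax(f0):.3f} > {params.reactant_fmax})"
        )
    reactant = reactant.with_labels(e0, f0, level_tag=model.name)
    symbols = reactant.symbols
    target_graph = driving.apply(perceive_bonds(reactant, params.perception_scale))

    add_targets = {
        p: params.add_target_scale
        * (COVALENT_RADII[symbols[p[0]]] + COVALENT_RADII[symbols[p[1]]])
        for p in driving.adds
    }
    # a broken pair counts as separated once beyond the perception cutoff
    break_targets = {
        p: 1.5 * params.perception_scale
        * (COVALENT_RADII[symbols[p[0]]] + COVALENT_RADII[symbols[p[1]]])
        for p in driving.breaks
    }
    break_set = set(driving.breaks)
    # an ADD constraint is released once its pair reaches the target — the
    # new bond holds by itself and the string tail relaxes into the product
    # basin, leaving the saddle interior to the path. BREAK pairs stay
    # constrained for the whole growth: a freed pair would simply slide back
    # down its pair well and re-form the bond.
    achieved: set[tuple[int, int]] = set()
    held_breaks: list[tuple[int, int]] = list(driving.breaks)

    nodes = [reactant]
    energies = [e0]

    current = reactant
    for _ in range(params.max_nodes - 1):
        pos = current.positions.copy()
        for p, tgt in add_targets.items():
            if p in achieved:
                continue
            d = np.linalg.norm(pos[p[0]] - pos[p[1]])
            d_new = max(tgt, d - params.growth_increment)
            if d > tgt + 1e-9:
                _set_pair_distance(pos, *p, d_new)
            if d_new <= tgt + 1e-9:
                achieved.add(p)
        for p, tgt in break_targets.items():
            if p in achieved:
                continue
            d = np.linalg.norm(pos[p[0]] - pos[p[1]])
            d_new = min(tgt, d + params.growth_increment)
            if d < tgt - 1e-9:
                _set_pair_distance(pos, *p, d_new)
            if d_new >= tgt - 1e-9:
                achieved.add(p)
        active = [p for p in driving.adds if p not in achieved] + held_breaks
        done = all(p in achieved for p in list(driving.adds) + held_breaks)
        try:
            result = local_minimize(
                current.with_positions(pos),
                model,
                fmax_tol=params.relax_fmax,
                max_steps=params.relax_steps,
                force_transform=_pair_distance_transform(active) if active else None,
            )
        except CalculatorError:
            return StringPath(nodes, energies, PathStatus.FAILED_CALCULATOR, driving)
        node = result.geometry
        # dissociation guard on pairs not deliberately broken
        dmat = np.linalg.norm(
            node.positions[:, None, :] - node.positions[None, :, :], axis=-1
        )
        n = node.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in break_set:
                    continue
                if dmat[i, j] > params.dissociation_cutoff:
                    return StringPath(
                        nodes, energies, PathStatus.FAILED_DISSOCIATED, driving
                    )
        previous_energy = energies[-1]
        nodes.append(node)
        energies.append(node.energy)
        current = node
        if node.energy - e0 > params.max_energy_rise:
            return StringPath(nodes, energies, PathStatus.FAILED_NO_BARRIER, driving)
        if done:
            if perceive_bonds(node, params.perception_scale).bonds == target_graph.bonds:
                break
            if abs(node.energy - previous_energy) < 1e-8:
                break  # settled without matching the driven connectivity
    # a budget-exhausted string is still a product proposal: the free
    # minimization in extract_triad and the pathway filters judge it
    return StringPath(nodes, energies, PathStatus.GROWN, driving)


def extract_triad(path: StringPath, model: PotentialModel,
                  params: GSMParams = GSMParams()) -> ReactionTriad:
    """Locate the TS proposal and minimize the final node to the product.

    The TS is the maximum-energy interior node, refined by one parabolic
    interpolation over the three nodes bracketing the maximum; full TS
    refinement is left to climbing-image NEB.
    """
    if path.status not in (PathStatus.GROWN, PathStatus.CONVERGED):
        raise TriadExtractionError(path.status, f"path status {path.status.value}")
    e = np.asarray(path.energies)
    k = int(np.argmax(e))
    if k == 0 or k == len(e) - 1:
        raise TriadExtractionError(
            PathStatus.FAILED_NO_BARRIER, "energy maximum at an endpoint"
        )
    # parabolic vertex through (k-1, k, k+1) in node-index coordinate
    denom = e[k - 1] - 2.0 * e[k] + e[k + 1]
    ts_geom = path.nodes[k]
    ts_energy = float(e[k])
    if denom < -1e-12:
        t = 0.5 * (e[k - 1] - e[k + 1]) / denom  # offset from node k in [-1, 1]
        t = float(np.clip(t, -1.0, 1.0))
        if t >= 0:
            lo, hi, w = k, k + 1, t
        else:
            lo, hi, w = k - 1, k, 1.0 + t
        pos = (1.0 - w) * path.nodes[lo].positions + w * path.nodes[hi].positions
        try:
            cand = model.label(path.nodes[k].with_positions(pos))
            if cand.energy >= ts_energy:
                ts_geom, ts_energy = cand, float(cand.energy)
        except CalculatorError:
            pass  # keep the node itself
    if ts_geom.energy is None:
        ts_geom = model.label(ts_geom)
    try:
        product = local_minimize(
            path.nodes[-1], model, fmax_tol=params.product_fmax
        ).geometry
    except CalculatorError as exc:
        raise TriadExtractionError(PathStatus.FAILED_CALCULATOR, str(exc)) from exc
    reactant = path.nodes[0]
    if reactant.energy is None:
        reactant = model.label(reactant)
    return ReactionTriad(reactant=reactant, ts=ts_geom, product=product, driving=path.driving)
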