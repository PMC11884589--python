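"""Pathway and structure quality gates between pipeline stages.

Three families of rejection: trivial pathways (strictly uphill profiles,
negligible energy variation, repeated or identity products), infeasible
structures (atom clashes, over-coordination), and transition states whose
mass-weighted Hessian does not have exactly one negative eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .calculators import CalculatorError, PotentialModel
from .core import Geometry, MolecularGraph, canonical_graph_key, perceive_bonds
from .optimizers import finite_difference_hessian, vibrational_analysis

__all__ = ["FilterReason", "FilterVerdict", "filter_pathway", "is_feasible_structure", "validate_ts"]


class FilterReason(str, Enum):
    OK = "ok"
    UPHILL = "uphill"
    FLAT = "flat"
    REPETITIVE = "repetitive"
    INFEASIBLE = "infeasible"
    NON_CONVERGENT = "non-convergent"
    BAD_TS_SIGNATURE = "bad-ts-signature"


@dataclass(frozen=True)
class FilterVerdict:
    accepted: bool
    reason: FilterReason
    detail: str = ""

    def __post_init__(self) -> None:
        if self.accepted != (self.reason is FilterReason.OK):
            raise ValueError("accepted must mirror reason == ok")

    @classmethod
    def ok(cls, detail: str = "") -> "FilterVerdict":
        return cls(True, FilterReason.OK, detail)

    @classmethod
    def reject(cls, reason: FilterReason, detail: str = "") -> "FilterVerdict":
        return cls(False, reason, detail)


#: per-step slack when deciding whether a profile is monotonically uphill
UPHILL_SLACK = 1e-3  # eV


def filter_pathway(
    energies: Sequence[float],
    reactant_graph: MolecularGraph,
    product_graph: MolecularGraph,
    seen_product_keys: Iterable[str] = (),
    flat_threshold: float = 0.1,
) -> FilterVerdict:
    """Reject trivial pathways.

    uphill: energies non-decreasing (within a small per-step slack) with a
    total rise above ``flat_threshold`` — pure dissociations.
    flat: total energy variation below ``flat_threshold`` (default 0.1 eV).
    repetitive: the product graph is the reactant graph or was already seen.
    """
    e = np.asarray(list(energies), float)
    if e.size < 2:
        raise ValueError("need at least two path energies")
    rise = float(e[-1] - e[0])
    if np.all(np.diff(e) >= -UPHILL_SLACK) and rise > flat_threshold:
        return FilterVerdict.reject(FilterReason.UPHILL, f"monotone rise {rise:.3f} eV")
    variation = float(e.max() - e.min())
    if variation < flat_threshold:
        return FilterVerdict.reject(
            FilterReason.FLAT, f"variation {variation:.3f} eV < {flat_threshold}"
        )
    pkey = canonical_graph_key(product_graph)
    if pkey == canonical_graph_key(reactant_graph) or pkey in set(seen_product_keys):
        return FilterVerdict.reject(FilterReason.REPETITIVE, f"product key {pkey}")
    return FilterVerdict.ok()


def is_feasible_structure(
    geometry: Geometry,
    graph: MolecularGraph | None = None,
    min_distance: float = 0.7,
    perception_scale: float = 1.2,
) -> FilterVerdict:
    """Reject structures with atom clashes or over-coordinated atoms."""
    pos = geometry.positions
    n = geometry.n_atoms
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        iu = np.triu_indices(n, k=1)
        dmin = float(dist[iu].min())
        if dmin < min_distance:
            return FilterVerdict.reject(
                FilterReason.INFEASIBLE, f"minimum distance {dmin:.3f} Å"
            )
    if graph is None:
        try:
            graph = perceive_bonds(geometry, scale=perception_scale)
        except ValueError as exc:
            return FilterVerdict.reject(FilterReason.INFEASIBLE, str(exc))
    for i, d in enumerate(graph.degrees()):
        cap = graph.max_valence[graph.elements[i]]
        if d > cap:
            return FilterVerdict.reject(
                FilterReason.INFEASIBLE,
                f"atom {i} ({graph.elements[i]}) degree {d} > {cap}",
            )
    return FilterVerdict.ok()


def validate_ts(
    ts: Geometry,
    model: PotentialModel,
    masses: np.ndarray | None = None,
    eps: float = 1e-4,
    hessian_step: float = 0.01,
) -> FilterVerdict:
    """Accept iff the mass-weighted, rigid-projected Hessian has exactly one
    negative eigenvalue (a first-order saddle)."""
    try:
        H = finite_difference_hessian(ts, model, step=hessian_step)
        vib = vibrational_analysis(
            ts, H, masses=masses, projection=model.rigid_projection
        )
    except (CalculatorError, RuntimeError) as exc:
        return FilterVerdict.reject(FilterReason.NON_CONVERGENT, str(exc))
    n_neg = vib.count_negative(eps=eps)
    if n_neg == 1:
        return FilterVerdict.ok(detail="1 negative eigenvalue")
    return FilterVerdict.reject(
        FilterReason.BAD_TS_SIGNATURE, f"{n_neg} negative eigenvalues"
    )
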