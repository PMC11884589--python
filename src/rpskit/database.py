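"""Selective relabeling and the hierarchical dataset format.

Structures harvested at the fast sampling level are re-labeled (energy and
forces only — geometries untouched) by a second, higher-level potential,
subsampled per reaction, and stored in an HDF5 layout grouped by chemical
formula with reaction-specific subgroups::

    /<formula>/<reaction_id>/atomic_numbers   [N]       int64
    /<formula>/<reaction_id>/positions        [S, N, 3] float64, Å
    /<formula>/<reaction_id>/energies         [S]       float64, eV
    /<formula>/<reaction_id>/forces           [S, N, 3] float64, eV/Å

Units and the labeling level are recorded as group attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .calculators import CalculatorError, PotentialModel
from .core import Geometry, hill_formula, write_xyz

__all__ = [
    "ReactionRecord",
    "DatabaseFormatError",
    "relabel_structures",
    "subsample_per_reaction",
    "deduplicate_structures",
    "write_database",
    "read_database",
    "export_reaction_xyz",
]

logger = logging.getLogger(__name__)


class DatabaseFormatError(ValueError):
    """Malformed dataset file; the message names the offending group."""


@dataclass
class ReactionRecord:
    """All labeled structures belonging to one discovered reaction."""

    formula: str
    reaction_id: str
    structures: list[Geometry]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("a reaction record needs at least one structure")
        z0 = self.structures[0].atomic_numbers
        for s in self.structures:
            if s.atomic_numbers != z0:
                raise ValueError("structures within a record must share the atom list")
            if s.energy is None or s.forces is None:
                raise ValueError("all structures must carry energy and forces")

    @property
    def n_structures(self) -> int:
        return len(self.structures)


def relabel_structures(
    structures: list[Geometry], high_model: PotentialModel
) -> list[Geometry]:
    """Replace energy/force labels with evaluations of the refinement model.

    Geometries are untouched; structures whose evaluation fails are dropped
    with a logged reason (mirroring the discarding of non-converged points).
    """
    out: list[Geometry] = []
    for idx, s in enumerate(structures):
        try:
            out.append(high_model.label(s))
        except CalculatorError as exc:
            logger.warning("dropping structure %d: %s", idx, exc)
    return out


def subsample_per_reaction(
    structures: list[Geometry], n: int = 1000, seed: int = 0
) -> list[Geometry]:
    """Uniform sample without replacement of min(n, available) structures.

    Order follows the original sequence; deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if len(structures) <= n:
        return list(structures)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(structures), size=n, replace=False))
    return [structures[i] for i in idx]


def deduplicate_structures(structures: list[Geometry]) -> list[Geometry]:
    """Drop structures whose positions are bitwise-identical to an earlier one."""
    seen: set[bytes] = set()
    out: list[Geometry] = []
    for s in structures:
        key = s.positions.tobytes()
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def write_database(records: list[ReactionRecord], path) -> None:
    """Write records into the hierarchical formula/reaction layout."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["units_energy"] = "eV"
        fh.attrs["units_positions"] = "Angstrom"
        fh.attrs["units_forces"] = "eV/Angstrom"
        for rec in records:
            if hill_formula(rec.structures[0]) != rec.formula:
                raise DatabaseFormatError(
                    f"record {rec.reaction_id}: formula {rec.formula} does not "
                    f"match its structures"
                )
            grp = fh.require_group(rec.formula).create_group(rec.reaction_id)
            z = np.asarray(rec.structures[0].atomic_numbers, dtype=np.int64)
            grp.create_dataset("atomic_numbers", data=z, track_times=False)
            grp.create_dataset(
                "positions",
                data=np.stack([s.positions for s in rec.structures]).astype(np.float64),
                track_times=False,
            )
            grp.create_dataset(
                "energies",
                data=np.array([s.energy for s in rec.structures], dtype=np.float64),
                track_times=False,
            )
            grp.create_dataset(
                "forces",
                data=np.stack([s.forces for s in rec.structures]).astype(np.float64),
                track_times=False,
            )
            tags = {s.level_tag for s in rec.structures if s.level_tag}
            if tags:
                grp.attrs["level"] = sorted(tags)[0]
            for key, val in rec.provenance.items():
                grp.attrs[f"provenance_{key}"] = str(val)


def read_database(path) -> list[ReactionRecord]:
    """Read a dataset back; inverse of :func:`write_database`."""
    records: list[ReactionRecord] = []
    with h5py.File(path, "r") as fh:
        for formula in sorted(fh.keys()):
            for rid in sorted(fh[formula].keys()):
                grp = fh[formula][rid]
                for name in ("atomic_numbers", "positions", "energies", "forces"):
                    if name not in grp:
                        raise DatabaseFormatError(
                            f"group /{formula}/{rid} is missing dataset {name!r}"
                        )
                z = tuple(int(x) for x in grp["atomic_numbers"][()])
                pos = grp["positions"][()]
                en = grp["energies"][()]
                fo = grp["forces"][()]
                if pos.ndim != 3 or fo.shape != pos.shape or en.shape[0] != pos.shape[0]:
                    raise DatabaseFormatError(
                        f"group /{formula}/{rid} has inconsistent tensor shapes"
                    )
                level = grp.attrs.get("level")
                structures = [
                    Geometry(
                        z,
                        pos[s],
                        energy=float(en[s]),
                        forces=fo[s],
                        level_tag=level,
                    )
                    for s in range(pos.shape[0])
                ]
                prov = {
                    k[len("provenance_"):]: grp.attrs[k]
                    for k in grp.attrs
                    if k.startswith("provenance_")
                }
                records.append(
                    ReactionRecord(
                        formula=formula,
                        reaction_id=rid,
                        structures=structures,
                        provenance=prov,
                    )
                )
    return records


def export_reaction_xyz(record: ReactionRecord, path) -> None:
    """Multi-frame XYZ dump of one reaction record for inspection."""
    write_xyz(path, record.structures)
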