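"""Reactant preparation: SMILES/XYZ ingestion and re-optimization.

SMILES handling (parsing, hydrogen completion, 3D embedding with a force
field) is delegated to RDKit; the resulting structure is then re-optimized
with the active sampling potential so every downstream stage starts from a
minimum of the surface it will explore. RDKit is an optional dependency —
XYZ-sourced reactants and graph construction work without it.
"""

from __future__ import annotations

import numpy as np

from .calculators import PotentialModel
from .core import ATOMIC_NUMBERS, Geometry, MolecularGraph, read_xyz
from .optimizers import OptimizationResult, local_minimize

__all__ = ["graph_from_smiles", "embed_smiles", "prepare_reactant"]


def _require_rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import AllChem
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "SMILES ingestion requires the optional rdkit dependency"
        ) from exc
    return Chem, AllChem


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Connectivity graph (explicit hydrogens, bond orders collapsed)."""
    Chem, _ = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bad = set(elements) - set(ATOMIC_NUMBERS)
    if bad:
        raise ValueError(f"unsupported elements {sorted(bad)} in {smiles!r}")
    bonds = frozenset(
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()
    )
    return MolecularGraph(elements, bonds, formal_charge=Chem.GetFormalCharge(mol))


def embed_smiles(smiles: str, seed: int = 1) -> Geometry:
    """Initial 3D structure from a SMILES string (ETKDG + MMFF94)."""
    Chem, AllChem = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    pos = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return Geometry.from_symbols(tuple(a.GetSymbol() for a in mol.GetAtoms()), pos)


def prepare_reactant(
    source: str | Geometry,
    model: PotentialModel,
    fmax_tol: float = 0.01,
    max_steps: int = 2000,
    seed: int = 1,
) -> OptimizationResult:
    """Turn a SMILES string, XYZ path or Geometry into a minimized reactant."""
    if isinstance(source, Geometry):
        geom = source
    elif isinstance(source, str) and source.lower().endswith(".xyz"):
        geom = read_xyz(source)[0]
    elif isinstance(source, str):
        geom = embed_smiles(source, seed=seed)
    else:
        raise TypeError(f"unsupported reactant source {source!r}")
    return local_minimize(geom, model, fmax_tol=fmax_tol, max_steps=max_steps)
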