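"""Shared fixtures: tiny structures built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
import biotite.structure as struc

from predope.structure import StructureModel


def make_atom_array(records: list[tuple]) -> struc.AtomArray:
    """Build an AtomArray from (atom_name, res_name, chain, res_id, xyz, element)."""
    arr = struc.AtomArray(len(records))
    for i, (name, res_name, chain, res_id, xyz, element) in enumerate(records):
        arr.atom_name[i] = name
        arr.res_name[i] = res_name
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.coord[i] = xyz
        arr.element[i] = element
        arr.hetero[i] = False
    return arr


def pdb_text(records: list[tuple]) -> str:
    """Render the same records as minimal PDB ATOM lines."""
    lines = []
    for i, (name, res_name, chain, res_id, xyz, element) in enumerate(records, 1):
        n = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d} {n}{res_name:>4s} {chain}{res_id:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


GLYCINE_WITH_H = [
    ("N", "GLY", "A", 1, (0.0, 0.0, 0.0), "N"),
    ("H", "GLY", "A", 1, (-0.6, 0.8, 0.0), "H"),      # amide H on N
    ("CA", "GLY", "A", 1, (1.45, 0.0, 0.0), "C"),
    ("HA2", "GLY", "A", 1, (1.8, -1.0, 0.0), "H"),    # aliphatic, not exchangeable
    ("C", "GLY", "A", 1, (2.0, 1.4, 0.0), "C"),
    ("O", "GLY", "A", 1, (1.3, 2.4, 0.0), "O"),
]

# two glycines, no hydrogens; peptide geometry good enough for H construction
DIPEPTIDE_NO_H = [
    ("N", "GLY", "A", 1, (0.0, 0.0, 0.0), "N"),
    ("CA", "GLY", "A", 1, (1.45, 0.0, 0.0), "C"),
    ("C", "GLY", "A", 1, (2.0, 1.4, 0.0), "C"),
    ("O", "GLY", "A", 1, (1.3, 2.4, 0.0), "O"),
    ("N", "GLY", "A", 2, (3.3, 1.5, 0.0), "N"),
    ("CA", "GLY", "A", 2, (4.1, 2.7, 0.0), "C"),
    ("C", "GLY", "A", 2, (5.6, 2.5, 0.0), "C"),
    ("O", "GLY", "A", 2, (6.1, 1.4, 0.0), "O"),
]

# one tryptophan side chain with the CZ3 (5-position) carbon present
TRP_RESIDUE = [
    ("N", "TRP", "A", 10, (0.0, 0.0, 0.0), "N"),
    ("CA", "TRP", "A", 10, (1.46, 0.0, 0.0), "C"),
    ("C", "TRP", "A", 10, (2.0, 1.42, 0.0), "C"),
    ("O", "TRP", "A", 10, (1.3, 2.4, 0.2), "O"),
    ("CB", "TRP", "A", 10, (2.0, -0.8, -1.2), "C"),
    ("CG", "TRP", "A", 10, (3.5, -0.9, -1.2), "C"),
    ("CD1", "TRP", "A", 10, (4.3, -1.95, -0.85), "C"),
    ("CD2", "TRP", "A", 10, (4.4, 0.1, -1.66), "C"),
    ("NE1", "TRP", "A", 10, (5.6, -1.6, -1.05), "N"),
    ("CE2", "TRP", "A", 10, (5.7, -0.36, -1.55), "C"),
    ("CE3", "TRP", "A", 10, (4.2, 1.4, -2.2), "C"),
    ("CZ2", "TRP", "A", 10, (6.8, 0.45, -1.9), "C"),
    ("CZ3", "TRP", "A", 10, (5.3, 2.2, -2.55), "C"),
    ("CH2", "TRP", "A", 10, (6.6, 1.72, -2.4), "C"),
]


@pytest.fixture
def glycine_model() -> StructureModel:
    return StructureModel(make_atom_array(GLYCINE_WITH_H), source="synthetic")


@pytest.fixture
def dipeptide_model() -> StructureModel:
    return StructureModel(make_atom_array(DIPEPTIDE_NO_H), source="synthetic")


@pytest.fixture
def trp_model() -> StructureModel:
    return StructureModel(make_atom_array(TRP_RESIDUE), source="synthetic")
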