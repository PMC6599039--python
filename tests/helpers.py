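"""Helpers for building tiny fixture models and PDB text."""

from __future__ import annotations

import numpy as np

from xlchamber.structure_io import AtomRecord, Residue, ResidueRef, StructureModel


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz,
    element: str,
    hetero: bool = False,
    occ: float = 1.0,
    altloc: str = " ",
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    return (
        f"{record}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{20.0:6.2f}          "
        f"{element:>2s}"
    )


def build_model(atoms, identifier="test") -> StructureModel:
    """Model from (chain, resnum, resname, atom_name, element, xyz, is_het) tuples."""
    model = StructureModel(identifier)
    by_res: dict[tuple, Residue] = {}
    for chain, resnum, resname, name, element, xyz, het in atoms:
        key = (chain, resnum)
        if key not in by_res:
            res = Residue(ref=ResidueRef(chain, resnum, "", resname), is_hetero=het)
            by_res[key] = res
            model.add_residue(res)
        by_res[key].atoms[name] = AtomRecord(
            name, element, tuple(np.asarray(xyz, float)), is_hetero=het
        )
    return model
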