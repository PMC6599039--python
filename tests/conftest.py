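"""Shared fixtures: hand-written PDB text and synthetic assemblies."""

from __future__ import annotations

import pytest

from xlchamber.synthetic_data import SyntheticComplexSpec, make_ring_complex

from tests.helpers import pdb_atom_line


@pytest.fixture(scope="session")
def tiny_pdb(tmp_path_factory) -> str:
    """2 polymer chains x 5 residues plus one hetero group (10+1 residues)."""
    lines = []
    serial = 0
    for chain in "AB":
        for i in range(1, 6):
            serial += 1
            x = i * 3.8 + (10.0 if chain == "B" else 0.0)
            lines.append(
                pdb_atom_line(serial, "CA", "LYS" if i % 2 else "ALA", chain, i, (x, 1.0, 2.0), "C")
            )
    serial += 1
    lines.append(pdb_atom_line(serial, "PA", "ADP", "C", 101, (5.0, 8.0, 2.0), "P", hetero=True))
    serial += 1
    lines.append(pdb_atom_line(serial, "O1A", "ADP", "C", 101, (6.2, 8.5, 2.0), "O", hetero=True))
    lines.append("END")
    path = tmp_path_factory.mktemp("fixtures") / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def ring_complex():
    """Default synthetic two-ring assembly with planted substrate (seed 11)."""
    return make_ring_complex(SyntheticComplexSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec() -> SyntheticComplexSpec:
    return SyntheticComplexSpec(seed=11)
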