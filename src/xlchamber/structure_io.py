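"""Atomic-model I/O and residue/atom lookup.

Reads PDB and mmCIF coordinate files (via gemmi) into a lightweight
:class:`StructureModel` that keeps author chain identifiers, author residue
numbering and insertion codes, and distinguishes polymer residues from hetero
groups (ligands such as ADP are retained).

The module also implements the *surrogate anchor* rule used when a
cross-linked residue lies in a disordered, unmodelled terminal tail: the
restraint is re-anchored on the nearest residue that is actually resolved in
the model, typically the last ordered residue of that terminus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "StructureModel",
    "StructureFormatError",
    "EmptyModelError",
    "NoAnchorError",
    "MissingAtomError",
    "load_structure",
    "write_pdb",
    "surrogate_anchor",
]


class StructureFormatError(ValueError):
    """The coordinate file could not be parsed in the indicated format."""


class EmptyModelError(ValueError):
    """The coordinate file contains no ATOM/HETATM records."""


class NoAnchorError(LookupError):
    """A chain has no resolved residue to anchor a restraint on."""


class MissingAtomError(LookupError):
    """A required anchor atom (normally C-alpha) is absent from a residue."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates in Angstrom."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name!r} has an empty element symbol")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Reference to a residue by chain, author number and insertion code."""

    chain_id: str
    resnum: int
    icode: str = ""
    resname: str = ""

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    def __str__(self) -> str:  # e.g. "A/LYS215"
        return f"{self.chain_id}/{self.resname}{self.resnum}{self.icode}"


@dataclass
class Residue:
    ref: ResidueRef
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    is_hetero: bool = False

    def atom(self, name: str) -> AtomRecord | None:
        return self.atoms.get(name)

    @property
    def ca(self) -> AtomRecord | None:
        return self.atoms.get("CA")

    def reference_atom(self) -> AtomRecord | None:
        """C-alpha for polymer residues; any atom for hetero groups."""
        ca = self.atoms.get("CA")
        if ca is not None:
            return ca
        if self.is_hetero and self.atoms:
            return next(iter(self.atoms.values()))
        return None

    def is_resolved(self) -> bool:
        return self.reference_atom() is not None


class StructureModel:
    """Chains of residues with deterministic lookup by :class:`ResidueRef`.

    Chains preserve file order; residues preserve file order within a chain.
    ``(chain_id, resnum, icode)`` is unique within the model.
    """

    def __init__(self, identifier: str = ""):
        self.identifier = identifier
        self._chains: dict[str, list[Residue]] = {}
        self._index: dict[tuple[str, int, str], Residue] = {}

    # -- construction ----------------------------------------------------

    def add_residue(self, residue: Residue) -> None:
        key = residue.ref.key()
        if key in self._index:
            raise ValueError(f"duplicate residue {residue.ref}")
        self._chains.setdefault(residue.ref.chain_id, []).append(residue)
        self._index[key] = residue

    # -- lookup ----------------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def residues(self, chain_id: str) -> list[Residue]:
        try:
            return self._chains[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not in model {self.identifier!r}") from None

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self._chains

    def iter_residues(self) -> Iterator[Residue]:
        for residues in self._chains.values():
            yield from residues

    def get_residue(self, chain_id: str, resnum: int, icode: str = "") -> Residue | None:
        return self._index.get((chain_id, resnum, icode))

    def resolved_resnums(self, chain_id: str) -> set[int]:
        """Residue numbers with at least a C-alpha (any atom for hetero)."""
        return {r.ref.resnum for r in self.residues(chain_id) if r.is_resolved()}

    def polymer_chain_ids(self) -> list[str]:
        return [c for c, rs in self._chains.items() if any(not r.is_hetero for r in rs)]

    def hetero_groups(self) -> list[Residue]:
        return [r for r in self.iter_residues() if r.is_hetero]

    def n_polymer_residues(self) -> int:
        return sum(1 for r in self.iter_residues() if not r.is_hetero)

    def ca_coord(self, ref: ResidueRef) -> np.ndarray:
        """C-alpha coordinates of a residue (reference atom for hetero groups)."""
        res = self.get_residue(ref.chain_id, ref.resnum, ref.icode)
        if res is None:
            raise MissingAtomError(f"residue {ref} not present in model")
        atom = res.reference_atom()
        if atom is None:
            raise MissingAtomError(f"residue {ref} has no C-alpha/reference atom")
        return atom.xyz

    # -- coordinate access for whole selections --------------------------

    def atom_table(self, chain_ids: Iterable[str] | None = None) -> tuple[np.ndarray, list[tuple[ResidueRef, str, str]]]:
        """All atom coordinates plus (residue, atom name, element) labels."""
        coords: list[np.ndarray] = []
        labels: list[tuple[ResidueRef, str, str]] = []
        chains = list(chain_ids) if chain_ids is not None else self.chain_ids
        for cid in chains:
            for res in self.residues(cid):
                for atom in res.atoms.values():
                    coords.append(atom.xyz)
                    labels.append((res.ref, atom.name, atom.element))
        arr = np.asarray(coords, dtype=float).reshape(-1, 3)
        return arr, labels


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def load_structure(path: str | Path, format_hint: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Coordinate file. May be plain text PDB or mmCIF.
    format_hint
        One of ``pdb``, ``mmcif``, ``auto``.

    All chains, polymer residues and hetero groups are kept; nothing is
    silently dropped. Alternate conformations collapse to the
    highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format_hint)
    if fmt is None:
        raise ValueError(f"format_hint must be pdb/mmcif/auto, got {format_hint!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path.name} as {format_hint}: {exc}") from exc

    model = StructureModel(identifier=st.name or path.stem)
    if len(st) == 0:
        raise EmptyModelError(f"{path.name}: no coordinate model present")
    gmodel = st[0]
    n_atoms = 0
    for chain in gmodel:
        for res in chain:
            is_het = res.het_flag == "H"
            icode = res.seqid.icode.strip()
            ref = ResidueRef(chain.name, res.seqid.num, icode, res.name)
            residue = Residue(ref=ref, is_hetero=is_het)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                atom = _best_altloc(group)
                element = atom.element.name or _guess_element(name)
                pos = atom.pos
                residue.atoms[name] = AtomRecord(
                    name=name,
                    element=element,
                    coords=(pos.x, pos.y, pos.z),
                    occupancy=atom.occ,
                    is_hetero=is_het,
                )
                n_atoms += 1
            model.add_residue(residue)
    if n_atoms == 0:
        raise EmptyModelError(f"{path.name}: zero atoms (header-only file?)")
    return model


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'\" *")
    return (stripped[:1] or "X").upper()


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model back out as a PDB file (chain ids, author numbering
    and coordinates preserved to the format's printed precision)."""
    st = gemmi.Structure()
    st.name = model.identifier or "XLCH"
    gmodel = gemmi.Model("1")
    for cid in model.chain_ids:
        chain = gemmi.Chain(cid)
        for res in model.residues(cid):
            gres = gemmi.Residue()
            gres.name = res.ref.resname
            gres.seqid = gemmi.SeqId(res.ref.resnum, res.ref.icode or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# surrogate anchors
# ---------------------------------------------------------------------------

def surrogate_anchor(
    model: StructureModel, chain_id: str, resnum: int
) -> tuple[ResidueRef, bool]:
    """Resolve a residue number onto an anchor residue of the model.

    If the residue is resolved (has a C-alpha), it is its own anchor and the
    surrogate flag is False. Otherwise the nearest resolved residue in
    sequence is returned with the flag True — for a disordered terminal tail
    this is the last ordered residue of that terminus. Equidistant ties break
    toward the lower residue number.

    Raises
    ------
    NoAnchorError
        If the chain has no resolved residues at all.
    """
    residues = model.residues(chain_id)  # KeyError if chain absent
    resolved = sorted(model.resolved_resnums(chain_id))
    if not resolved:
        raise NoAnchorError(f"chain {chain_id!r} has no resolved residues")
    if resnum in resolved:
        res = model.get_residue(chain_id, resnum)
        if res is not None and res.is_resolved():
            return res.ref, False
        # insertion-code duplicates: fall through to nearest-resolved scan
    nearest = min(resolved, key=lambda n: (abs(n - resnum), n))
    res = model.get_residue(chain_id, nearest)
    assert res is not None
    return res.ref, True
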