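"""Solvent-accessible surface area, ligand burial and contact fingerprints.

SASA is computed with the Shrake–Rupley rolling-probe method on a
deterministic Fibonacci-spiral point set — no random numbers, so results
are bit-stable across runs. The point set is oriented in a molecular frame
derived from the coordinates themselves (principal axes with
skewness-fixed signs), which makes the areas equivariant under rigid
motions of the whole model, not just translations.

Burial of a bound ligand is 1 - SASA(ligand in complex) / SASA(ligand
alone): the fraction of the ligand surface occluded by its pocket.
Contacts are classified from heavy-atom distances only (deposited models
carry no hydrogens): donor/acceptor N/O pairs as hydrogen bonds, phosphate
oxygens against Lys/Arg/His side-chain nitrogens as salt bridges, and
carbon–carbon proximity as hydrophobic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, ResidueRef, StructureModel

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "ContactRecord",
    "sasa",
    "buried_fraction",
    "ligand_contacts",
    "select_ligand",
    "fibonacci_sphere",
]

#: van der Waals radii in Angstrom (Bondi 1964, plus common ions);
#: unknown elements fall back to 1.8 A with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75, "CA": 2.31,
    "FE": 1.80, "MN": 1.80, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.8
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(
            f"no van der Waals radius for element {element!r}; using {_DEFAULT_RADIUS} A",
            stacklevel=3,
        )
        return _DEFAULT_RADIUS
    return r


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal-axes frame with deterministic signs.

    Equivariant under proper rigid motions, so SASA computed with spiral
    points expressed in this frame is invariant under them.
    """
    if len(coords) < 3:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows are axes
    for k in range(2):
        proj = centered @ axes[k]
        skew = float(np.sum(proj**3))
        if abs(skew) > 1e-9:
            if skew < 0:
                axes[k] = -axes[k]
        else:  # symmetric direction: fix sign by the largest component
            j = int(np.argmax(np.abs(axes[k])))
            if axes[k][j] < 0:
                axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def _sasa_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_points: int,
    frame: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom accessible areas (A^2) by Shrake–Rupley point counting."""
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    if frame is None:
        frame = _molecular_frame(coords)
    unit = fibonacci_sphere(n_points) @ frame  # spiral expressed in molecule frame
    extended = radii + probe
    tree = cKDTree(coords)
    areas = np.zeros(n)
    r_max = float(extended.max())
    for i in range(n):
        pts = coords[i] + extended[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], extended[i] + r_max) if j != i]
        if neighbors:
            nb_xyz = coords[neighbors]
            nb_r2 = (extended[neighbors]) ** 2
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            accessible = ~np.any(d2 < nb_r2[None, :], axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        areas[i] = 4.0 * np.pi * extended[i] ** 2 * accessible.mean()
    return areas


@dataclass
class SasaResult:
    """Per-atom accessible areas with per-residue totals."""

    probe: float
    n_points: int
    atom_areas: dict[tuple[ResidueRef, str], float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.atom_areas.values()))

    def residue_total(self, ref: ResidueRef) -> float:
        return float(sum(a for (r, _), a in self.atom_areas.items() if r == ref))

    def selection_total(self, refs: Iterable[ResidueRef]) -> float:
        wanted = set(refs)
        return float(sum(a for (r, _), a in self.atom_areas.items() if r in wanted))


def _collect_atoms(
    model: StructureModel, refs: set[ResidueRef] | None = None
) -> tuple[np.ndarray, np.ndarray, list[tuple[ResidueRef, str]]]:
    coords, radii, keys = [], [], []
    for res in model.iter_residues():
        if refs is not None and res.ref not in refs:
            continue
        for atom in res.atoms.values():
            coords.append(atom.xyz)
            radii.append(_vdw_radius(atom.element))
            keys.append((res.ref, atom.name))
    return (
        np.asarray(coords, float).reshape(-1, 3),
        np.asarray(radii, float),
        keys,
    )


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    selection: Iterable[ResidueRef] | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of the model (or of a residue selection taken in
    isolation). Deterministic for fixed ``n_points``."""
    refs = set(selection) if selection is not None else None
    coords, radii, keys = _collect_atoms(model, refs)
    areas = _sasa_areas(coords, radii, probe, n_points)
    result = SasaResult(probe=probe, n_points=n_points)
    for key, area in zip(keys, areas):
        result.atom_areas[key] = float(area)
    return result


def select_ligand(
    model: StructureModel, resname: str, chain_id: str | None = None
) -> list[ResidueRef]:
    """Hetero groups matching a residue name (optionally one chain)."""
    return [
        r.ref
        for r in model.iter_residues()
        if r.is_hetero
        and r.ref.resname == resname
        and (chain_id is None or r.ref.chain_id == chain_id)
    ]


def buried_fraction(
    complex_model: StructureModel,
    ligand: Sequence[ResidueRef],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[float, float, float]:
    """Fraction of the ligand surface buried by its environment.

    Returns ``(fraction, isolated_area, complexed_area)`` where fraction =
    1 - complexed/isolated, clipped to [0, 1]. Both areas use the same
    molecular frame (the whole complex's) so they differ only through
    occlusion, not quadrature orientation.
    """
    ligand = list(ligand)
    if not ligand:
        raise ValueError("empty ligand selection")
    all_coords, all_radii, all_keys = _collect_atoms(complex_model)
    if len(all_coords) == 0:
        raise ValueError("empty model")
    frame = _molecular_frame(all_coords)
    lig_set = set(ligand)
    lig_mask = np.array([ref in lig_set for ref, _ in all_keys])
    if not lig_mask.any():
        raise ValueError(f"ligand residues {ligand} have no atoms in the model")

    complexed = _sasa_areas(all_coords, all_radii, probe, n_points, frame=frame)
    iso = _sasa_areas(
        all_coords[lig_mask], all_radii[lig_mask], probe, n_points, frame=frame
    )
    isolated_area = float(iso.sum())
    complexed_area = float(complexed[lig_mask].sum())
    if isolated_area <= 0:
        raise ZeroDivisionError("isolated ligand area is zero; burial undefined")
    fraction = min(1.0, max(0.0, 1.0 - complexed_area / isolated_area))
    return fraction, isolated_area, complexed_area


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactRecord:
    ligand_ref: ResidueRef
    ligand_atom: str
    residue_ref: ResidueRef
    residue_atom: str
    distance: float
    type: str  # hbond | salt_bridge | hydrophobic | other


_BASIC_SIDECHAIN_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}


def _phosphate_oxygens(residue: Residue) -> set[str]:
    """Oxygen atoms within bonding distance (1.8 A) of any ligand P atom."""
    p_atoms = [a for a in residue.atoms.values() if a.element.upper() == "P"]
    out: set[str] = set()
    for o in residue.atoms.values():
        if o.element.upper() != "O":
            continue
        for p in p_atoms:
            if np.linalg.norm(o.xyz - p.xyz) <= 1.8:
                out.add(o.name)
                break
    return out


def ligand_contacts(
    model: StructureModel,
    ligand: Sequence[ResidueRef],
    hbond_max: float = 3.5,
    hydrophobic_max: float = 4.0,
    salt_max: float = 4.0,
) -> list[ContactRecord]:
    """Distance-based ligand–protein contact fingerprint.

    Heavy atoms only; each atom pair appears once with its most specific
    type (salt bridge > hydrogen bond > hydrophobic > other).
    """
    lig_set = set(ligand)
    lig_residues = [
        model.get_residue(r.chain_id, r.resnum, r.icode) for r in lig_set
    ]
    lig_residues = [r for r in lig_residues if r is not None]
    if not lig_residues:
        return []

    env: list[tuple[Residue, str]] = []  # (residue, atom name)
    for res in model.iter_residues():
        if res.ref in lig_set:
            continue
        for name in res.atoms:
            env.append((res, name))
    if not env:
        return []
    env_xyz = np.array([r.atoms[n].xyz for r, n in env])
    tree = cKDTree(env_xyz)
    max_cut = max(hbond_max, hydrophobic_max, salt_max)

    records: list[ContactRecord] = []
    for lres in lig_residues:
        phos_o = _phosphate_oxygens(lres)
        for aname, atom in lres.atoms.items():
            el = atom.element.upper()
            for j in tree.query_ball_point(atom.xyz, max_cut):
                res, rname = env[j]
                ratom = res.atoms[rname]
                rel = ratom.element.upper()
                d = float(np.linalg.norm(atom.xyz - ratom.xyz))
                ctype: str | None = None
                if (
                    aname in phos_o
                    and d <= salt_max
                    and rname in _BASIC_SIDECHAIN_N.get(res.ref.resname, set())
                ):
                    ctype = "salt_bridge"
                elif el in ("N", "O") and rel in ("N", "O") and d <= hbond_max:
                    ctype = "hbond"
                elif el == "C" and rel == "C" and d <= hydrophobic_max:
                    ctype = "hydrophobic"
                elif d <= hbond_max:
                    ctype = "other"
                if ctype is not None:
                    records.append(
                        ContactRecord(lres.ref, aname, res.ref, rname, d, ctype)
                    )
    records.sort(key=lambda c: (c.distance, c.ligand_atom, str(c.residue_ref)))
    return records
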