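"""Synthetic chaperonin-like assemblies with known ground truth.

The generator emulates the geometry that matters to the analyses, not the
physics: a two-ring assembly of eight pseudo-subunits per ring, each a
compact C-alpha-only body with a disordered N-terminal tail extending
toward the central cavity; a seven-bladed propeller-like substrate planted
between the rings at a known rigid-body pose; stochastic distance-dependent
cross-link detection with a hard linker limit and a controllable false-link
rate; and density-map pairs differing only by pseudo-ligands planted in a
subset of annotated pockets.

Tail residues exist in the ground truth but are withheld from the emitted
model, exactly like disordered termini missing from a deposited structure,
so surrogate-anchor logic is exercised end to end. Lysines are placed at
irregular positions (as in real sequences) so the cross-link pattern
identifies the substrate orientation uniquely.

Every stochastic operation takes an explicit seed; one generator instance
per call, no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crosslinks import ChainMap
from .density_tools import DensityMap, PocketAnnotation, simulate_map
from .pose_search import Pose, apply_pose
from .structure_io import AtomRecord, Residue, ResidueRef, StructureModel

__all__ = [
    "SyntheticComplexSpec",
    "GroundTruth",
    "SpecError",
    "make_ring_complex",
    "simulate_crosslinks",
    "simulate_occupancy_pair",
    "default_pockets",
]


class SpecError(ValueError):
    """Geometrically impossible synthetic-complex specification."""


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Parameters of the toy assembly (distances in Angstrom)."""

    subunits_per_ring: int = 8
    rings: int = 2
    ring_radius: float = 40.0
    inter_ring_gap: float = 28.0
    tail_length: int = 12
    propeller_blades: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.subunits_per_ring, self.rings, self.propeller_blades) < 1:
            raise SpecError("counts must be positive")
        if min(self.ring_radius, self.inter_ring_gap) <= 0:
            raise SpecError("geometric parameters must be positive")
        if self.tail_length < 0:
            raise SpecError("tail_length must be >= 0")
        # adjacent subunit bodies (cube extent ~14 A) must not overlap
        if self.subunits_per_ring > 1:
            sep = 2.0 * self.ring_radius * math.sin(math.pi / self.subunits_per_ring)
            if sep < 14.0:
                raise SpecError(
                    f"subunit centre separation {sep:.1f} A overlaps 14 A bodies"
                )


@dataclass
class GroundTruth:
    """Everything the generator knows that a real experiment would not."""

    spec: SyntheticComplexSpec
    pose: Pose  # planted substrate pose (rotation about its centroid)
    substrate_chain: str
    substrate_reference: dict[int, np.ndarray]  # resnum -> unplaced coords
    protein_of_chain: dict[str, str]
    subunit_centers: dict[str, np.ndarray]
    anchors: dict[str, np.ndarray]  # chain -> last-ordered-residue coords
    full_coords: dict[tuple[str, int], np.ndarray]  # incl. unresolved tails
    lysines: list[tuple[str, int]]  # (chain, resnum), true positions known
    tail_resnums: dict[str, set[int]] = field(default_factory=dict)

    def chain_map(self) -> ChainMap:
        by_protein: dict[str, list[str]] = {}
        for chain, protein in self.protein_of_chain.items():
            by_protein.setdefault(protein, []).append(chain)
        return ChainMap({p: (tuple(cs), 0) for p, cs in by_protein.items()})

    def lysine_coord(self, chain: str, resnum: int) -> np.ndarray:
        return self.full_coords[(chain, resnum)]

    def true_pairs(self) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
        """All unordered lysine pairs with their true distances."""
        out = []
        for i in range(len(self.lysines)):
            for j in range(i + 1, len(self.lysines)):
                a, b = self.lysines[i], self.lysines[j]
                d = float(np.linalg.norm(self.full_coords[a] - self.full_coords[b]))
                out.append((a, b, d))
        return out

    def inter_ring_midplane_z(self) -> float:
        return 0.0


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

_BODY_N = 27  # 3 x 3 x 3 pseudo-fold
_BODY_SPACING = 4.0
_BODY_LYS = {4, 10, 17, 23}  # 0-based indices within the body
_TAIL_LYS_OFFSETS = {1, 5, 9}  # 0-based from the tail tip
_CA_STEP = 3.8


def _body_coords(center: np.ndarray) -> np.ndarray:
    pts = []
    for i in range(_BODY_N):
        ix, iy, iz = i % 3, (i // 3) % 3, i // 9
        pts.append(center + _BODY_SPACING * (np.array([ix, iy, iz]) - 1.0))
    return np.asarray(pts)


def _propeller_coords(n_blades: int) -> tuple[dict[int, np.ndarray], list[int]]:
    """Unplaced propeller C-alpha coords (resnum -> xyz) and lysine resnums.

    Each blade runs outward then back (10 residues); lysines sit at
    irregular positions on a subset of blades to break circular symmetry.
    """
    coords: dict[int, np.ndarray] = {}
    lys: list[int] = []
    resnum = 0
    r_in, r_out = 4.0, 18.0
    for b in range(n_blades):
        phi = 2.0 * math.pi * b / n_blades
        for leg, dphi in ((0, -math.radians(5)), (1, math.radians(5))):
            for k in range(5):
                resnum += 1
                frac = k / 4.0 if leg == 0 else 1.0 - k / 4.0
                r = r_in + (r_out - r_in) * frac
                a = phi + dphi
                z = 1.5 * math.sin(2.0 * math.pi * (resnum % 10) / 10.0)
                coords[resnum] = np.array([r * math.cos(a), r * math.sin(a), z])
        # one lysine per blade at an irregular position, a second on
        # alternate blades — about the lysine density of a real propeller
        lys.append((b * 10) + 1 + ((3 * b + 1) % 10))
        if b % 2 == 0:
            second = (b * 10) + 1 + ((5 * b + 6) % 10)
            if second not in lys:
                lys.append(second)
    return coords, sorted(set(lys))


def make_ring_complex(spec: SyntheticComplexSpec) -> tuple[StructureModel, GroundTruth]:
    """Build the toy assembly and its ground truth.

    The emitted model contains only the *resolved* residues (bodies and the
    placed substrate); tail coordinates live in the ground truth alone. The
    substrate is planted at a uniformly random rotation (drawn from
    ``spec.seed``) about its centroid on the inter-ring midplane.
    """
    rng = np.random.default_rng(spec.seed)
    model = StructureModel(identifier=f"synthetic-ring-complex-seed{spec.seed}")
    truth = GroundTruth(
        spec=spec,
        pose=Pose.identity(),
        substrate_chain="S",
        substrate_reference={},
        protein_of_chain={},
        subunit_centers={},
        anchors={},
        full_coords={},
        lysines=[],
    )

    n, tail = spec.subunits_per_ring, spec.tail_length
    z_body = spec.inter_ring_gap / 2.0 + 6.0
    chain_index = 0
    for ring in range(spec.rings):
        z_sign = 1.0 if ring == 0 else -1.0
        offset = 0.0 if ring == 0 else math.pi / n  # rings are staggered
        for k in range(n):
            chain_id = chr(ord("A") + chain_index)
            chain_index += 1
            protein = f"SUB{k + 1}"
            theta = 2.0 * math.pi * k / n + offset
            center = np.array(
                [
                    spec.ring_radius * math.cos(theta),
                    spec.ring_radius * math.sin(theta),
                    z_sign * z_body,
                ]
            )
            truth.protein_of_chain[chain_id] = protein
            truth.subunit_centers[chain_id] = center
            body = _body_coords(center)
            # tail attaches at the first body residue and descends toward the
            # inter-ring midplane while moving inward at its own azimuth,
            # like a disordered terminus reaching into the cavity
            attach = body[0]
            r0 = float(np.hypot(attach[0], attach[1]))
            phi = math.atan2(attach[1], attach[0])
            r_tip = max(12.0, 0.35 * r0)
            z_tip = z_sign * 2.0
            tail_coords = []
            for i in range(1, tail + 1):
                frac = i / max(tail, 1)
                r = r0 + (r_tip - r0) * frac
                z = attach[2] + (z_tip - attach[2]) * frac
                tail_coords.append(np.array([r * math.cos(phi), r * math.sin(phi), z]))
            tail_coords.reverse()  # residue 1 is the tail tip, deepest in the cavity

            truth.tail_resnums[chain_id] = set(range(1, tail + 1))
            for resnum in range(1, tail + 1):
                xyz = tail_coords[resnum - 1]
                truth.full_coords[(chain_id, resnum)] = xyz
                if (resnum - 1) in _TAIL_LYS_OFFSETS:
                    truth.lysines.append((chain_id, resnum))
            for i in range(_BODY_N):
                resnum = tail + 1 + i
                xyz = body[i]
                truth.full_coords[(chain_id, resnum)] = xyz
                resname = "LYS" if i in _BODY_LYS else "ALA"
                if resname == "LYS":
                    truth.lysines.append((chain_id, resnum))
                res = Residue(
                    ref=ResidueRef(chain_id, resnum, "", resname),
                    is_hetero=False,
                )
                res.atoms["CA"] = AtomRecord("CA", "C", tuple(xyz))
                model.add_residue(res)
            truth.anchors[chain_id] = body[0].copy()

    # substrate propeller, planted at a random rotation about its centroid
    ref_coords, sub_lys = _propeller_coords(spec.propeller_blades)
    truth.substrate_reference = {r: c.copy() for r, c in ref_coords.items()}
    centroid = np.mean(list(ref_coords.values()), axis=0)
    quat = _random_unit_quaternion(rng)
    pose = Pose(tuple(quat), (0.0, 0.0, 0.0), tuple(centroid))
    truth.pose = pose
    placed = apply_pose(np.asarray(list(ref_coords.values())), pose)
    schain = truth.substrate_chain
    truth.protein_of_chain[schain] = "PROP"
    for (resnum, _), xyz in zip(sorted(ref_coords.items()), placed):
        resname = "LYS" if resnum in sub_lys else "ALA"
        truth.full_coords[(schain, resnum)] = xyz
        if resname == "LYS":
            truth.lysines.append((schain, resnum))
        res = Residue(ref=ResidueRef(schain, resnum, "", resname), is_hetero=False)
        res.atoms["CA"] = AtomRecord("CA", "C", tuple(xyz))
        model.add_residue(res)
    return model, truth


def _random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


# ---------------------------------------------------------------------------
# cross-link simulation
# ---------------------------------------------------------------------------

def simulate_crosslinks(
    model: StructureModel,
    truth: GroundTruth,
    p_detect: float = 0.4,
    lambda_decay: float = 15.0,
    max_dist: float = 32.0,
    false_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stochastic cross-link observation with a hard linker limit.

    A lysine pair at true distance d <= ``max_dist`` is detected with
    probability ``p_detect * exp(-d / lambda_decay)`` (so a zero-distance
    pair is detected with ``p_detect``; pass ``lambda_decay=math.inf`` for
    distance-independent detection). ``floor(false_rate * n_true)``
    additional uniformly random lysine pairs are appended and flagged.

    Returns ``(links, truth_table)``: a pLink-style table with
    Protein_1/Position_1/Protein_2/Position_2/Score columns, and the truth
    table with chain assignments, true distances and the false-link flag.
    """
    if not (0.0 <= p_detect <= 1.0 and 0.0 <= false_rate):
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = truth.true_pairs()
    emitted: list[tuple] = []
    emitted_idx: set[int] = set()
    for idx, (a, b, d) in enumerate(pairs):
        if d > max_dist:
            continue
        p = p_detect * math.exp(-d / lambda_decay) if math.isfinite(lambda_decay) else p_detect
        if rng.random() < p:
            emitted.append((a, b, d, False))
            emitted_idx.add(idx)
    n_false = int(math.floor(false_rate * len(emitted)))
    candidates = [i for i in range(len(pairs)) if i not in emitted_idx]
    if n_false > 0 and candidates:
        chosen = rng.choice(len(candidates), size=min(n_false, len(candidates)), replace=False)
        for ci in sorted(int(c) for c in chosen):
            a, b, d = pairs[candidates[ci]]
            emitted.append((a, b, d, True))

    link_rows, truth_rows = [], []
    for (ca_id, ra), (cb_id, rb), d, is_false in emitted:
        link_rows.append(
            {
                "Protein_1": truth.protein_of_chain[ca_id],
                "Position_1": ra,
                "Protein_2": truth.protein_of_chain[cb_id],
                "Position_2": rb,
                "Score": round(float(rng.random()) * 1e-3, 9),
            }
        )
        truth_rows.append(
            {
                "chain_a": ca_id, "resnum_a": ra,
                "chain_b": cb_id, "resnum_b": rb,
                "distance": round(d, 3), "is_false": is_false,
            }
        )
    links = pd.DataFrame(
        link_rows, columns=["Protein_1", "Position_1", "Protein_2", "Position_2", "Score"]
    )
    truth_table = pd.DataFrame(
        truth_rows,
        columns=["chain_a", "resnum_a", "chain_b", "resnum_b", "distance", "is_false"],
    )
    return links, truth_table


# ---------------------------------------------------------------------------
# occupancy-pair simulation
# ---------------------------------------------------------------------------

def docking_problem(
    truth: GroundTruth, truth_table: pd.DataFrame
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], list[tuple[str, str]]]:
    """Turn simulated links into an orientation-search problem.

    Substrate-involving links become restraints between the *unplaced*
    substrate reference coordinates and the true coordinates of their fixed
    partners (chain assignments from the generator's truth table). Labels
    are ``chain:resnum`` strings.
    """
    schain = truth.substrate_chain
    sub_coords = {f"{schain}:{r}": c for r, c in truth.substrate_reference.items()}
    fixed: dict[str, np.ndarray] = {}
    restraints: list[tuple[str, str]] = []
    for row in truth_table.itertuples(index=False):
        ends = ((row.chain_a, row.resnum_a), (row.chain_b, row.resnum_b))
        sides = [e[0] == schain for e in ends]
        if sides[0] == sides[1]:
            continue  # need exactly one substrate end
        s = ends[0] if sides[0] else ends[1]
        f = ends[1] if sides[0] else ends[0]
        flabel = f"{f[0]}:{f[1]}"
        fixed[flabel] = truth.full_coords[f]
        restraints.append((f"{schain}:{s[1]}", flabel))
    return sub_coords, fixed, restraints


def _ligand_atoms(center: np.ndarray) -> list[np.ndarray]:
    """A 25-atom pseudo-nucleotide cluster filling a ~3.5 A pocket core
    (about the heavy-atom count and footprint of an adenine nucleotide)."""
    golden = math.pi * (1.0 + math.sqrt(5.0))
    pts = [center.copy()]
    for shell_r, n in ((1.8, 10), (3.2, 14)):
        for i in range(n):
            z = 1.0 - 2.0 * (i + 0.5) / n
            r = math.sqrt(max(0.0, 1.0 - z * z))
            th = golden * (i + 0.5) + shell_r
            pts.append(
                center + shell_r * np.array([r * math.cos(th), r * math.sin(th), z])
            )
    return pts


def default_pockets(truth: GroundTruth, radius: float = 6.0) -> list[PocketAnnotation]:
    """One pocket per subunit, centred on the subunit body."""
    return [
        PocketAnnotation(label=chain, center=tuple(center), radius=radius)
        for chain, center in truth.subunit_centers.items()
    ]


def _with_ligands(
    model: StructureModel, pockets: Sequence[PocketAnnotation], subset: set[str]
) -> StructureModel:
    out = StructureModel(identifier=model.identifier + "+ligands")
    for res in model.iter_residues():
        out.add_residue(res)
    lig_num = 9000
    for p in pockets:
        if p.label not in subset:
            continue
        lig_num += 1
        res = Residue(ref=ResidueRef("L", lig_num, "", "LIG"), is_hetero=True)
        for i, xyz in enumerate(_ligand_atoms(np.asarray(p.center, float))):
            res.atoms[f"P{i}"] = AtomRecord(f"P{i}", "P", tuple(xyz), is_hetero=True)
        out.add_residue(res)
    return out


def simulate_occupancy_pair(
    model: StructureModel,
    pockets: Sequence[PocketAnnotation],
    occupied_subset: Sequence[str],
    resolution: float = 8.0,
    voxel: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[DensityMap, DensityMap, dict]:
    """Simulate a (reference, query) map pair for occupancy calling.

    The reference carries a pseudo-ligand in every pocket; the query only in
    ``occupied_subset``. Both maps receive i.i.d. Gaussian voxel noise of
    ``noise_sigma`` (absolute density units). The truth dict records the
    occupied labels and the isolated ligand peak height, the natural unit
    for choosing a noise level.
    """
    labels = {p.label for p in pockets}
    extra = set(occupied_subset) - labels
    if extra:
        raise ValueError(f"occupied_subset not within pockets: {sorted(extra)}")
    rng = np.random.default_rng(seed)
    ref_model = _with_ligands(model, pockets, labels)
    query_model = _with_ligands(model, pockets, set(occupied_subset))
    ref = simulate_map(ref_model, resolution, voxel)
    query = simulate_map(query_model, resolution, voxel)

    # isolated ligand peak: one ligand cluster on its own grid
    lone = StructureModel(identifier="lone-ligand")
    res = Residue(ref=ResidueRef("L", 1, "", "LIG"), is_hetero=True)
    for i, xyz in enumerate(_ligand_atoms(np.zeros(3))):
        res.atoms[f"P{i}"] = AtomRecord(f"P{i}", "P", tuple(xyz), is_hetero=True)
    lone.add_residue(res)
    ligand_peak = float(simulate_map(lone, resolution, voxel).grid.max())

    if noise_sigma > 0:
        ref.grid = ref.grid + rng.normal(0.0, noise_sigma, ref.shape).astype(np.float32)
        query.grid = query.grid + rng.normal(0.0, noise_sigma, query.shape).astype(np.float32)
    ref.label, query.label = "reference", "query"
    occupied = set(occupied_subset)
    truth = {
        "occupied": sorted(occupied),
        "empty": sorted(labels - occupied),
        "ligand_peak": ligand_peak,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return ref, query, truth
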