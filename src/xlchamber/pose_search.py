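"""Cross-link-restrained rigid-body orientation search.

A roughly circular substrate (a seven-bladed beta-propeller) can fit a
featureless density envelope in many orientations. The cross-links to fixed
anchor points on the surrounding assembly discriminate between them: the
preferred placement is the one that minimises restraint violations. This
module formalises that selection as an exhaustive, deterministic search
over a near-uniform grid of 3-D rotations (super-Fibonacci sampling of
SO(3)), optionally combined with a small translation box around a target
centroid.

Scoring uses a squared-hinge penalty beyond the linker cutoff by default
(all-satisfied poses are equivalent at zero), with a raw distance-sum mode
for strict distance minimisation and an optional trimming fraction that
ignores the worst restraints to tolerate false links.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "Pose",
    "PoseScore",
    "SearchError",
    "apply_pose",
    "score_pose",
    "orientation_search",
    "super_fibonacci_quaternions",
    "rotation_grid_size",
    "quat_to_matrix",
    "angular_distance_deg",
]


class SearchError(ValueError):
    """The orientation search cannot run (e.g. no restraints)."""


def _normalize_quat(q: Sequence[float]) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = float(np.linalg.norm(q))
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("quaternion has zero or non-finite norm")
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm deviates from 1 by {abs(n - 1.0):.3g} (> 1e-6)")
    if abs(n - 1.0) > 1e-12:  # real deviation, not float rounding
        warnings.warn("normalizing quaternion with sub-1e-6 norm deviation", stacklevel=3)
    return q / n


def quat_to_matrix(q: Sequence[float]) -> np.ndarray:
    """Rotation matrix from a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(q, dtype=float)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def angular_distance_deg(q1: Sequence[float], q2: Sequence[float]) -> float:
    """Rotation angle (degrees) taking one orientation to the other."""
    d = abs(float(np.dot(np.asarray(q1, float), np.asarray(q2, float))))
    d = min(d, 1.0)
    return math.degrees(2.0 * math.acos(d))


@dataclass(frozen=True)
class Pose:
    """Rigid-body placement: rotate about ``pivot`` then translate."""

    rotation: tuple[float, float, float, float]  # unit quaternion (w, x, y, z)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        q = _normalize_quat(self.rotation)
        object.__setattr__(self, "rotation", tuple(float(v) for v in q))

    @property
    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.rotation)

    def inverse(self) -> "Pose":
        w, x, y, z = self.rotation
        q_inv = (w, -x, -y, -z)
        R_inv = quat_to_matrix(q_inv)
        p = np.asarray(self.pivot)
        t = np.asarray(self.translation)
        # inverse maps y back: x = R^-1 (y - t - p) + p  => pivot p, translation R^-1(-t)
        t_inv = R_inv @ (-t)
        return Pose(q_inv, tuple(t_inv), tuple(p))

    @staticmethod
    def identity(pivot: Sequence[float] = (0.0, 0.0, 0.0)) -> "Pose":
        return Pose((1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0), tuple(float(v) for v in pivot))


def apply_pose(coords: np.ndarray, pose: Pose) -> np.ndarray:
    """Apply a rigid transform: rotation about the pivot, then translation.

    Pairwise distances are preserved exactly (up to float rounding).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    p = np.asarray(pose.pivot)
    t = np.asarray(pose.translation)
    return (coords - p) @ pose.matrix.T + p + t


@dataclass
class PoseScore:
    """Restraint score of one pose."""

    n_satisfied: int
    penalty: float  # A^2: sum of squared excesses over the cutoff
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total_distance(self) -> float:
        return float(np.sum(self.distances))


def _resolve_restraints(
    substrate_coords: Mapping[str, Sequence[float]],
    fixed_coords: Mapping[str, Sequence[float]],
    restraints: Sequence[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray]:
    sub, fix = [], []
    for sub_label, fixed_label in restraints:
        if sub_label not in substrate_coords:
            raise KeyError(f"restraint substrate label {sub_label!r} not resolvable")
        if fixed_label not in fixed_coords:
            raise KeyError(f"restraint fixed label {fixed_label!r} not resolvable")
        sub.append(substrate_coords[sub_label])
        fix.append(fixed_coords[fixed_label])
    return np.asarray(sub, float), np.asarray(fix, float)


def _penalties(dists: np.ndarray, cutoff: float, mode: str) -> np.ndarray:
    if mode == "hinge":
        return np.square(np.maximum(0.0, dists - cutoff))
    if mode == "sum":
        return dists
    raise ValueError(f"score mode must be 'hinge' or 'sum', got {mode!r}")


def _trimmed_sum(per_restraint: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Sum per-restraint penalties along the last axis, ignoring the worst
    ceil(f*n) restraints of each pose."""
    n = per_restraint.shape[-1]
    n_drop = math.ceil(trim_fraction * n) if trim_fraction > 0 else 0
    if n_drop == 0:
        return per_restraint.sum(axis=-1)
    if n_drop >= n:
        return np.zeros(per_restraint.shape[:-1])
    kept = np.sort(per_restraint, axis=-1)[..., : n - n_drop]
    return kept.sum(axis=-1)


def score_pose(
    substrate_coords: Mapping[str, Sequence[float]],
    pose: Pose,
    fixed_coords: Mapping[str, Sequence[float]],
    restraints: Sequence[tuple[str, str]],
    cutoff: float = 32.0,
    score_mode: Literal["hinge", "sum"] = "hinge",
    trim_fraction: float = 0.0,
) -> PoseScore:
    """Score one pose: distances of each restraint after transforming the
    substrate side, hinge penalty beyond the cutoff (or raw sum)."""
    sub, fix = _resolve_restraints(substrate_coords, fixed_coords, restraints)
    moved = apply_pose(sub, pose)
    dists = np.linalg.norm(moved - fix, axis=1)
    pen = float(_trimmed_sum(_penalties(dists, cutoff, score_mode), trim_fraction))
    return PoseScore(
        n_satisfied=int(np.sum(dists <= cutoff)),
        penalty=pen,
        distances=dists,
    )


# ---------------------------------------------------------------------------
# rotation grid
# ---------------------------------------------------------------------------

_PHI = math.sqrt(2.0)
_PSI = 1.533751168755204288118041  # positive root of psi^4 = psi + 4


def super_fibonacci_quaternions(n: int) -> np.ndarray:
    """n near-uniform unit quaternions (w, x, y, z) on the rotation group.

    Deterministic low-discrepancy spiral construction; antipodal quaternions
    represent the same rotation, which is fine for grid search.
    """
    i = np.arange(n, dtype=float)
    s = i + 0.5
    t = s / n
    d = 2.0 * np.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / _PHI
    beta = d / _PSI
    q = np.stack(
        [r * np.sin(alpha), r * np.cos(alpha), big_r * np.sin(beta), big_r * np.cos(beta)],
        axis=1,
    )
    return q


def rotation_grid_size(rot_step_deg: float, oversample: float = 1.0) -> int:
    """Number of grid rotations so nearest-neighbour spacing <= rot_step_deg.

    The rotation group has volume pi^2 in quaternion geodesic measure; a
    covering by balls of geodesic radius step/4 (rotation angle step/2)
    needs ~ pi^2 / ((4/3) pi r^3) centres, padded by ``oversample`` for the
    spiral's covering inefficiency.
    """
    r = math.radians(rot_step_deg) / 4.0
    n = oversample * math.pi**2 / ((4.0 / 3.0) * math.pi * r**3)
    return max(24, int(math.ceil(n)))


def _quats_to_matrices(q: np.ndarray) -> np.ndarray:
    """Vectorised quaternion-to-matrix for a (n, 4) array."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty((len(q), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - w * z)
    m[:, 0, 2] = 2 * (x * z + w * y)
    m[:, 1, 0] = 2 * (x * y + w * z)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - w * x)
    m[:, 2, 0] = 2 * (x * z - w * y)
    m[:, 2, 1] = 2 * (y * z + w * x)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def _translation_grid(half_width: float, step: float = 2.0) -> np.ndarray:
    if half_width <= 0:
        return np.zeros((1, 3))
    k = int(math.floor(half_width / step))
    axis = np.arange(-k, k + 1) * step
    return np.array(list(itertools.product(axis, axis, axis)), dtype=float)


def _compose_quats(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2 (apply q2 first, then q1)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _rotvec_to_quat(v: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / angle
    return np.concatenate([[math.cos(angle / 2.0)], math.sin(angle / 2.0) * axis])


def _refine_pose(
    pose: Pose,
    sub: np.ndarray,
    fix: np.ndarray,
    pivot: np.ndarray,
    cutoff: float,
    score_mode: str,
    trim_fraction: float,
) -> Pose:
    """Continuous local polish of a grid candidate.

    Minimises the same trimmed penalty over a small rotation-vector
    perturbation composed with the candidate (translation held fixed), so
    the result is no longer limited by the grid spacing. Derivative-free
    Powell search keeps the piecewise-smooth trimmed objective happy.
    """
    from scipy.optimize import minimize

    q0 = np.asarray(pose.rotation)
    t = np.asarray(pose.translation)

    def objective(v: np.ndarray) -> float:
        q = _compose_quats(_rotvec_to_quat(v), q0)
        moved = (sub - pivot) @ quat_to_matrix(q).T + pivot + t
        d = np.linalg.norm(moved - fix, axis=1)
        return float(_trimmed_sum(_penalties(d, cutoff, score_mode), trim_fraction))

    res = minimize(objective, np.zeros(3), method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 200})
    q = _compose_quats(_rotvec_to_quat(res.x), q0)
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return Pose(tuple(q), pose.translation, pose.pivot)


def _refine_pose_robust(
    pose: Pose,
    sub: np.ndarray,
    fix: np.ndarray,
    pivot: np.ndarray,
    cutoff: float,
    score_mode: str,
    trim_fraction: float,
    rot_step_deg: float,
) -> Pose:
    """Local polish for the trimmed (robust) mode.

    The trimmed penalty is flat over a wide basin, so gradient-style
    descent wanders; instead a deterministic shrinking-ball hill-climb
    maximises the consensus key (n_satisfied, then trimmed penalty) over
    small rotation offsets around the candidate.
    """
    from .surface_contacts import fibonacci_sphere  # deterministic directions

    dirs = fibonacci_sphere(40)
    q_best = np.asarray(pose.rotation)
    t = np.asarray(pose.translation)

    def key(q: np.ndarray) -> tuple:
        moved = (sub - pivot) @ quat_to_matrix(q).T + pivot + t
        d = np.linalg.norm(moved - fix, axis=1)
        pen = float(_trimmed_sum(_penalties(d, cutoff, score_mode), trim_fraction))
        return (-int(np.sum(d <= cutoff)), pen, float(d.sum()))

    best_key = key(q_best)
    radius = math.radians(rot_step_deg) / 2.0
    for _ in range(4):
        improved = False
        for mag in (radius, radius / 2.0):
            for u in dirs:
                q = _compose_quats(_rotvec_to_quat(mag * u), q_best)
                k = key(q)
                if k < best_key:
                    best_key, q_best, improved = k, q, True
        if not improved:
            radius /= 2.0
    q_best = q_best / np.linalg.norm(q_best)
    if q_best[0] < 0:
        q_best = -q_best
    return Pose(tuple(q_best), pose.translation, pose.pivot)


def orientation_search(
    substrate_coords: Mapping[str, Sequence[float]],
    fixed_coords: Mapping[str, Sequence[float]],
    restraints: Sequence[tuple[str, str]],
    centroid: Sequence[float] | None = None,
    rot_step_deg: float = 10.0,
    trans_box: float = 0.0,
    cutoff: float = 32.0,
    score_mode: Literal["hinge", "sum"] = "hinge",
    trim_fraction: float = 0.0,
    top_k: int | None = 50,
    refine_top: int = 5,
) -> list[tuple[Pose, PoseScore]]:
    """Exhaustive rigid-body search over a near-uniform rotation grid.

    The substrate centroid is moved to ``centroid`` (default: left where it
    is) and every grid rotation about that point is scored; when
    ``trans_box`` > 0 the centroid additionally scans a cubic grid of step
    2 A within +/- trans_box. The best ``refine_top`` grid candidates are
    then polished by continuous local minimisation of the same objective,
    so the final orientation is not limited to the grid. Results are ranked
    by (penalty ascending, n_satisfied descending, total restraint
    distance, quaternion order) — a deterministic total order — and the
    best ``top_k`` returned.
    """
    if not restraints:
        raise SearchError("orientation search needs at least one restraint")
    if not (0.0 < rot_step_deg <= 90.0):
        raise ValueError("rot_step_deg must be in (0, 90]")
    sub, fix = _resolve_restraints(substrate_coords, fixed_coords, restraints)
    all_sub = np.asarray(list(substrate_coords.values()), float)
    pivot = all_sub.mean(axis=0)
    target = pivot if centroid is None else np.asarray(centroid, float)
    base_shift = target - pivot

    # identity is prepended so an already-satisfying input placement is
    # always part of the scored set
    quats = np.vstack(
        [
            np.array([[1.0, 0.0, 0.0, 0.0]]),
            super_fibonacci_quaternions(rotation_grid_size(rot_step_deg)),
        ]
    )
    mats = _quats_to_matrices(quats)  # whole grid at once
    centered = sub - pivot
    rotated = np.einsum("nij,mj->nmi", mats, centered) + pivot

    offsets = _translation_grid(trans_box)
    nq = len(quats)
    pen_all = np.empty(nq * len(offsets))
    nsat_all = np.empty(nq * len(offsets), dtype=int)
    total_all = np.empty(nq * len(offsets))
    for oi, offset in enumerate(offsets):
        shift = base_shift + offset
        dists = np.linalg.norm(rotated + shift - fix[None, :, :], axis=2)
        sl = slice(oi * nq, (oi + 1) * nq)
        pen_all[sl] = _trimmed_sum(_penalties(dists, cutoff, score_mode), trim_fraction)
        nsat_all[sl] = np.sum(dists <= cutoff, axis=1)
        total_all[sl] = dists.sum(axis=1)

    # deterministic total order. Without trimming: penalty asc, n_satisfied
    # desc, total distance asc, then grid index (a fixed quaternion order).
    # With trimming the trimmed penalty develops spurious zeros (any pose
    # sacrificing a different restraint subset), so the robust mode ranks
    # by consensus first: n_satisfied desc, then trimmed penalty.
    robust = trim_fraction > 0
    if robust:
        order = np.lexsort((total_all, pen_all, -nsat_all))
    else:
        order = np.lexsort((total_all, -nsat_all, pen_all))

    def materialize(flat_idx: int) -> tuple[Pose, PoseScore]:
        oi, qi = divmod(int(flat_idx), nq)
        shift = base_shift + offsets[oi]
        pose = Pose(tuple(quats[qi]), tuple(shift), tuple(pivot))
        d = np.linalg.norm(apply_pose(sub, pose) - fix, axis=1)
        pen = float(_trimmed_sum(_penalties(d, cutoff, score_mode), trim_fraction))
        return pose, PoseScore(int(np.sum(d <= cutoff)), pen, d)

    n_keep = len(order) if top_k is None else min(len(order), max(top_k, refine_top))
    results = [materialize(i) for i in order[:n_keep]]

    if robust:
        sort_key = lambda ps: (
            -ps[1].n_satisfied,
            ps[1].penalty,
            ps[1].total_distance,
            ps[0].rotation,
            ps[0].translation,
        )
    else:
        sort_key = lambda ps: (
            ps[1].penalty,
            -ps[1].n_satisfied,
            ps[1].total_distance,
            ps[0].rotation,
            ps[0].translation,
        )
    if refine_top > 0:
        polished: list[tuple[Pose, PoseScore]] = []
        for pose, _ in results[:refine_top]:
            if robust:
                new_pose = _refine_pose_robust(
                    pose, sub, fix, pivot, cutoff, score_mode, trim_fraction,
                    rot_step_deg,
                )
            else:
                new_pose = _refine_pose(
                    pose, sub, fix, pivot, cutoff, score_mode, trim_fraction
                )
            moved = apply_pose(sub, new_pose)
            d = np.linalg.norm(moved - fix, axis=1)
            pen = float(_trimmed_sum(_penalties(d, cutoff, score_mode), trim_fraction))
            polished.append((new_pose, PoseScore(int(np.sum(d <= cutoff)), pen, d)))
        results = polished + results[refine_top:]
        results.sort(key=sort_key)
    return results if top_k is None else results[:top_k]
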