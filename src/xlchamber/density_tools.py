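"""Density maps: I/O, simulation, difference maps and pocket occupancy.

A nucleotide-binding pocket that is empty in a query reconstruction but
occupied in a fully-loaded reference shows up as positive mass in the
(reference - query) difference map. Each annotated pocket sphere is scored
by the mean difference density inside it, expressed as a z-score against
the whole-map difference distribution, and classified as occupied, partial
or empty by fixed thresholds. High difference means the nucleotide is
absent from the query.

Maps are MRC2014/CCP4 files handled through gemmi; grids are cubic-voxel
numpy arrays indexed so that position = origin + voxel * index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage

from .structure_io import StructureModel

__all__ = [
    "DensityMap",
    "PocketAnnotation",
    "OccupancyCall",
    "MapGeometryError",
    "AnnotationError",
    "read_map",
    "write_map",
    "simulate_map",
    "subtract_maps",
    "pocket_occupancy",
    "read_pockets_tsv",
    "write_pockets_tsv",
]


class MapGeometryError(ValueError):
    """Incompatible or unsupported map geometry (e.g. anisotropic voxels)."""


class AnnotationError(ValueError):
    """A pocket annotation does not fit the map grid."""


@dataclass
class DensityMap:
    """3-D density grid with isotropic voxel size and an origin in Angstrom."""

    grid: np.ndarray
    voxel: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a 3-D array with all dims >= 1")
        if not self.voxel > 0:
            raise ValueError("voxel size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def same_geometry(self, other: "DensityMap", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel - other.voxel) <= tol * self.voxel
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def index_of(self, position: Sequence[float]) -> np.ndarray:
        """Fractional grid index of a position in Angstrom."""
        return (np.asarray(position, float) - self.origin) / self.voxel

    def contains_sphere(self, center: Sequence[float], radius: float) -> bool:
        lo = self.index_of(np.asarray(center) - radius)
        hi = self.index_of(np.asarray(center) + radius)
        return bool(np.all(lo >= -0.5) and np.all(hi <= np.asarray(self.shape) - 0.5))


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC2014/CCP4 map. Voxels must be isotropic (resample first
    otherwise); axis order is normalised to X, Y, Z."""
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read {path.name} as MRC/CCP4: {exc}") from exc
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = ccp4.grid
    spacing = np.array(
        [
            grid.unit_cell.a / grid.nu,
            grid.unit_cell.b / grid.nv,
            grid.unit_cell.c / grid.nw,
        ]
    )
    if not np.allclose(spacing, spacing[0], rtol=1e-3):
        raise MapGeometryError(
            f"{path.name}: anisotropic voxels {spacing} not supported; resample first"
        )
    voxel = float(spacing.mean())
    # MRC2014 origin: words 50-52; fall back to start indices if unset
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        start = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = start * voxel
    values = np.array(grid, copy=True)
    return DensityMap(grid=values, voxel=voxel, origin=origin, label=path.stem)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write an MRC2014/CCP4 map; round-trip is lossless for float32 grids."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel, ny * dmap.voxel, nz * dmap.voxel, 90.0, 90.0, 90.0
    )
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# simulated density
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def simulate_map(
    model: StructureModel,
    resolution: float,
    voxel: float,
    pad: float = 8.0,
    chain_ids: Sequence[str] | None = None,
) -> DensityMap:
    """Render a model as a sum of spherical atom Gaussians.

    Gaussian FWHM equals ``resolution``; amplitude is proportional to the
    atomic number. The box covers the model plus ``pad`` on every side.
    """
    if resolution < 2.0 * voxel:
        raise ValueError("need resolution >= 2 * voxel (Nyquist)")
    coords, labels = model.atom_table(chain_ids)
    if coords.size == 0:
        raise ValueError("cannot simulate a map from an empty model")
    weights = np.array(
        [max(1, gemmi.Element(el).atomic_number) for _, _, el in labels], dtype=float
    )
    sigma = resolution * _FWHM_TO_SIGMA
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    origin = np.floor(lo / voxel) * voxel
    shape = np.ceil((hi - origin) / voxel).astype(int) + 1
    grid = np.zeros(tuple(shape), dtype=np.float64)

    cut = 5.0 * sigma
    ncut = int(np.ceil(cut / voxel))
    for xyz, w in zip(coords, weights):
        center_idx = (xyz - origin) / voxel
        lo_i = np.maximum(np.floor(center_idx).astype(int) - ncut, 0)
        hi_i = np.minimum(np.floor(center_idx).astype(int) + ncut + 1, shape)
        ax = [np.arange(lo_i[d], hi_i[d]) for d in range(3)]
        dx = [(ax[d] * voxel + origin[d]) - xyz[d] for d in range(3)]
        r2 = (
            dx[0][:, None, None] ** 2
            + dx[1][None, :, None] ** 2
            + dx[2][None, None, :] ** 2
        )
        grid[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]] += w * np.exp(
            -r2 / (2.0 * sigma**2)
        )
    return DensityMap(grid=grid, voxel=voxel, origin=origin, label=model.identifier)


# ---------------------------------------------------------------------------
# difference maps
# ---------------------------------------------------------------------------

def _resample_onto(target: DensityMap, source: DensityMap) -> np.ndarray:
    """Trilinear resampling of ``source`` values onto ``target``'s grid."""
    idx = np.indices(target.shape, dtype=float)
    pos = idx * target.voxel + target.origin.reshape(3, 1, 1, 1)
    src_idx = (pos - source.origin.reshape(3, 1, 1, 1)) / source.voxel
    return ndimage.map_coordinates(
        source.grid.astype(float), src_idx, order=1, mode="constant", cval=0.0
    )


def subtract_maps(
    a: DensityMap,
    b: DensityMap,
    scale_mode: Literal["none", "lsq"] = "none",
    resample: bool = False,
    mask: np.ndarray | None = None,
) -> DensityMap:
    """Voxelwise difference a - s*b.

    ``s`` is 1 for ``none`` or the least-squares scalar <a,b>/<b,b> for
    ``lsq`` (compensates arbitrary intensity scaling between maps). With
    ``lsq``, an optional boolean ``mask`` restricts the fit to
    high-confidence voxels (e.g. a well-resolved region); fitting over a
    signal mask avoids the attenuation that background noise causes in the
    whole-map fit. Grids must share geometry unless ``resample=True``, in
    which case b is trilinearly interpolated onto a's grid first.
    """
    if a.same_geometry(b):
        bvals = b.grid.astype(float)
    elif resample:
        bvals = _resample_onto(a, b)
    else:
        raise MapGeometryError(
            "maps differ in geometry; pass resample=True to interpolate b onto a"
        )
    avals = a.grid.astype(float)
    if scale_mode == "lsq":
        if mask is not None:
            if mask.shape != avals.shape:
                raise MapGeometryError("mask shape does not match the map grid")
            af, bf = avals[mask], bvals[mask]
        else:
            af, bf = avals.ravel(), bvals.ravel()
        denom = float(np.dot(bf, bf))
        s = float(np.dot(af, bf)) / denom if denom > 0 else 1.0
    elif scale_mode == "none":
        s = 1.0
    else:
        raise ValueError(f"scale_mode must be 'none' or 'lsq', got {scale_mode!r}")
    return DensityMap(
        grid=avals - s * bvals,
        voxel=a.voxel,
        origin=a.origin.copy(),
        label=f"{a.label}-minus-{b.label}",
    )


# ---------------------------------------------------------------------------
# pocket occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketAnnotation:
    """A labelled sphere around one nucleotide-binding site."""

    label: str
    center: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("pocket radius must be positive")


@dataclass
class OccupancyCall:
    """Per-pocket z-scores and occupancy classes from a difference map."""

    t_occupied: float
    t_empty: float
    zscores: dict[str, float]
    classes: dict[str, str]

    def occupied(self) -> list[str]:
        return [l for l, c in self.classes.items() if c == "occupied"]

    def empty(self) -> list[str]:
        return [l for l, c in self.classes.items() if c == "empty"]

    def partial(self) -> list[str]:
        return [l for l, c in self.classes.items() if c == "partial"]


def pocket_occupancy(
    diff: DensityMap,
    pockets: Sequence[PocketAnnotation],
    t_occupied: float = 0.5,
    t_empty: float = 1.5,
) -> OccupancyCall:
    """Call nucleotide occupancy per pocket from a reference-minus-query
    difference map.

    The mean difference density within each pocket sphere is z-scored
    against the whole-map voxel distribution. ``z < t_occupied`` means no
    missing density — the pocket holds its nucleotide; ``z > t_empty``
    means a strong positive difference — the pocket is empty in the query;
    in between is a partial call. A uniformly zero difference map (identical
    inputs) yields z = 0 everywhere: all pockets occupied.
    """
    labels = [p.label for p in pockets]
    if len(set(labels)) != len(labels):
        raise AnnotationError("pocket labels must be unique")
    vals = diff.grid.astype(float)
    mu = float(vals.mean())
    sd = float(vals.std())
    idx = np.indices(diff.shape, dtype=float)
    zscores: dict[str, float] = {}
    classes: dict[str, str] = {}
    for p in pockets:
        ci = diff.index_of(p.center)
        if np.any(ci < -0.5) or np.any(ci > np.asarray(diff.shape) - 0.5):
            raise AnnotationError(f"pocket {p.label!r} lies outside the map grid")
        r_vox = p.radius / diff.voxel
        mask = (
            (idx[0] - ci[0]) ** 2 + (idx[1] - ci[1]) ** 2 + (idx[2] - ci[2]) ** 2
        ) <= r_vox**2
        if not mask.any():
            raise AnnotationError(f"pocket {p.label!r} covers no voxel at this sampling")
        mean_p = float(vals[mask].mean())
        z = (mean_p - mu) / sd if sd > 1e-12 else 0.0
        zscores[p.label] = z
        if z < t_occupied:
            classes[p.label] = "occupied"
        elif z > t_empty:
            classes[p.label] = "empty"
        else:
            classes[p.label] = "partial"
    return OccupancyCall(t_occupied=t_occupied, t_empty=t_empty, zscores=zscores, classes=classes)


# ---------------------------------------------------------------------------
# pocket TSV
# ---------------------------------------------------------------------------

def write_pockets_tsv(pockets: Sequence[PocketAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"label": p.label, "x": p.center[0], "y": p.center[1], "z": p.center[2], "radius": p.radius}
            for p in pockets
        ],
        columns=["label", "x", "y", "z", "radius"],
    ).to_csv(path, sep="\t", index=False)


def read_pockets_tsv(path: str | Path) -> list[PocketAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PocketAnnotation(str(r.label), (float(r.x), float(r.y), float(r.z)), float(r.radius))
        for r in df.itertuples(index=False)
    ]
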