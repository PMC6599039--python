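"""Map I/O, simulated density, difference maps and occupancy calls."""

import math

import numpy as np
import pytest

from xlchamber.density_tools import (
    AnnotationError,
    DensityMap,
    MapGeometryError,
    PocketAnnotation,
    pocket_occupancy,
    read_map,
    read_pockets_tsv,
    simulate_map,
    subtract_maps,
    write_map,
    write_pockets_tsv,
)
from tests.helpers import build_model


@pytest.fixture
def random_map():
    rng = np.random.default_rng(0)
    return DensityMap(
        grid=rng.normal(size=(16, 16, 16)).astype(np.float32),
        voxel=1.25,
        origin=np.array([2.0, -3.5, 10.0]),
    )


class TestMapIO:
    def test_round_trip_lossless(self, random_map, tmp_path):
        p = tmp_path / "m.mrc"
        write_map(random_map, p)
        back = read_map(p)
        assert np.array_equal(back.grid, random_map.grid)
        assert back.voxel == pytest.approx(random_map.voxel)
        assert np.allclose(back.origin, random_map.origin)

    def test_header_geometry_vs_binary_decode(self, random_map, tmp_path):
        # oracle: decode the MRC2014 header words straight from the bytes
        import struct

        p = tmp_path / "m.mrc"
        write_map(random_map, p)
        raw = open(p, "rb").read(1024)
        nx, ny, nz = struct.unpack("<3i", raw[0:12])
        assert (nx, ny, nz) == random_map.shape
        cella = struct.unpack("<3f", raw[40:52])
        assert cella[0] == pytest.approx(16 * 1.25, rel=1e-6)
        origin = struct.unpack("<3f", raw[196:208])
        assert origin == pytest.approx(tuple(random_map.origin), rel=1e-6)

    def test_corrupt_magic_is_format_error(self, tmp_path):
        p = tmp_path / "bad.mrc"
        p.write_bytes(b"\x00" * 2048)
        with pytest.raises(ValueError):
            read_map(p)


def point_model(entries):
    return build_model(
        [("A", i + 1, "UNK", "X", el, xyz, True) for i, (el, xyz) in enumerate(entries)]
    )


class TestSimulateMap:
    def test_single_atom_peak_at_origin_voxel(self):
        m = point_model([("C", (0.0, 0.0, 0.0))])
        dmap = simulate_map(m, resolution=5.0, voxel=1.0, pad=8.0)
        idx = np.unravel_index(np.argmax(dmap.grid), dmap.shape)
        pos = np.asarray(idx) * dmap.voxel + dmap.origin
        assert np.linalg.norm(pos) <= dmap.voxel / 2 + 1e-9

    def test_total_mass_matches_analytic_gaussian_integral(self):
        m = point_model([("C", (0, 0, 0)), ("O", (4, 2, -1)), ("P", (-3, 1, 2))])
        dmap = simulate_map(m, resolution=5.0, voxel=1.0, pad=12.0)
        sigma = 5.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        expect = (6 + 8 + 15) * (2.0 * math.pi * sigma**2) ** 1.5
        got = float(dmap.grid.sum()) * dmap.voxel**3
        assert got == pytest.approx(expect, rel=0.01)

    def test_mirrored_atoms_give_symmetric_map(self):
        m = point_model([("C", (-3.0, 0.0, 0.0)), ("C", (3.0, 0.0, 0.0))])
        dmap = simulate_map(m, resolution=4.0, voxel=1.0, pad=8.0)
        assert np.abs(dmap.grid - dmap.grid[::-1, :, :]).max() < 1e-6

    def test_nyquist_violation_rejected(self):
        m = point_model([("C", (0, 0, 0))])
        with pytest.raises(ValueError):
            simulate_map(m, resolution=1.0, voxel=1.0)


class TestSubtractMaps:
    def test_self_subtraction_is_zero(self, random_map):
        diff = subtract_maps(random_map, random_map)
        assert np.abs(diff.grid).max() == 0.0

    def test_lsq_closed_form_scalar(self, random_map):
        half = DensityMap(grid=0.5 * random_map.grid, voxel=random_map.voxel,
                          origin=random_map.origin)
        diff = subtract_maps(random_map, half, scale_mode="lsq")
        # closed form: s = <a,b>/<b,b> = 2, so a - 2*(a/2) = 0
        assert np.abs(diff.grid).max() < 1e-5

    def test_antisymmetric_without_scaling(self, random_map):
        rng = np.random.default_rng(1)
        other = DensityMap(grid=rng.normal(size=random_map.shape).astype(np.float32),
                           voxel=random_map.voxel, origin=random_map.origin)
        ab = subtract_maps(random_map, other).grid
        ba = subtract_maps(other, random_map).grid
        assert np.allclose(ab + ba, 0.0, atol=1e-6)

    def test_geometry_mismatch_requires_resample(self, random_map):
        shifted = DensityMap(grid=random_map.grid, voxel=random_map.voxel,
                             origin=random_map.origin + 1.0)
        with pytest.raises(MapGeometryError):
            subtract_maps(random_map, shifted)
        diff = subtract_maps(random_map, shifted, resample=True)
        assert diff.shape == random_map.shape

    def test_ligand_difference_concentrated_near_ligand(self):
        protein = point_model([("C", (x, 0.0, 0.0)) for x in range(0, 20, 4)])
        with_lig = point_model(
            [("C", (x, 0.0, 0.0)) for x in range(0, 20, 4)] + [("P", (10.0, 8.0, 0.0))]
        )
        a = simulate_map(with_lig, resolution=5.0, voxel=1.0, pad=10.0)
        b = simulate_map(protein, resolution=5.0, voxel=1.0, pad=10.0)
        diff = subtract_maps(a, b, resample=True)
        idx = np.indices(diff.shape).reshape(3, -1).T * diff.voxel + diff.origin
        d_to_lig = np.linalg.norm(idx - np.array([10.0, 8.0, 0.0]), axis=1)
        vals = diff.grid.ravel()
        # a 5 A resolution Gaussian keeps ~86% of its mass within 5 A
        assert vals[d_to_lig <= 5.0].sum() > 0.8 * vals.sum()
        assert vals[d_to_lig <= 8.0].sum() > 0.97 * vals.sum()


class TestPocketOccupancy:
    def test_zero_difference_calls_everything_occupied(self):
        diff = DensityMap(grid=np.zeros((20, 20, 20)), voxel=2.0)
        pockets = [PocketAnnotation("P1", (10.0, 10.0, 10.0)), PocketAnnotation("P2", (30.0, 30.0, 30.0))]
        call = pocket_occupancy(diff, pockets)
        assert call.empty() == []
        assert set(call.occupied()) == {"P1", "P2"}

    def test_planted_subset_recovered(self, ring_complex):
        from xlchamber.synthetic_data import default_pockets, simulate_occupancy_pair

        model, truth = ring_complex
        pockets = default_pockets(truth)[:8]
        occupied = [p.label for p in pockets[:3]]
        ref, qry, _ = simulate_occupancy_pair(model, pockets, occupied, seed=0)
        diff = subtract_maps(ref, qry)
        call = pocket_occupancy(diff, pockets)
        assert set(call.occupied()) == set(occupied)
        assert set(call.empty()) == {p.label for p in pockets} - set(occupied)

    def test_pocket_outside_grid_is_annotation_error(self):
        diff = DensityMap(grid=np.zeros((10, 10, 10)), voxel=1.0)
        with pytest.raises(AnnotationError):
            pocket_occupancy(diff, [PocketAnnotation("X", (50.0, 0.0, 0.0))])

    def test_duplicate_labels_rejected(self):
        diff = DensityMap(grid=np.zeros((10, 10, 10)), voxel=1.0)
        pockets = [PocketAnnotation("X", (5.0, 5.0, 5.0)), PocketAnnotation("X", (4.0, 4.0, 4.0))]
        with pytest.raises(AnnotationError):
            pocket_occupancy(diff, pockets)

    def test_calls_invariant_under_common_rescaling_with_lsq(self, ring_complex):
        from xlchamber.synthetic_data import default_pockets, simulate_occupancy_pair

        model, truth = ring_complex
        pockets = default_pockets(truth)[:8]
        occupied = [p.label for p in pockets[:4]]
        ref, qry, _ = simulate_occupancy_pair(model, pockets, occupied, seed=2)
        call1 = pocket_occupancy(subtract_maps(ref, qry, scale_mode="lsq"), pockets)
        ref2 = DensityMap(grid=ref.grid * 7.5, voxel=ref.voxel, origin=ref.origin)
        qry2 = DensityMap(grid=qry.grid * 7.5, voxel=qry.voxel, origin=qry.origin)
        call2 = pocket_occupancy(subtract_maps(ref2, qry2, scale_mode="lsq"), pockets)
        assert call1.classes == call2.classes


def test_pockets_tsv_round_trip(tmp_path):
    pockets = [PocketAnnotation("A", (1.0, 2.0, 3.0), 6.0), PocketAnnotation("B", (-4.0, 0.0, 9.5), 5.0)]
    p = tmp_path / "pockets.tsv"
    write_pockets_tsv(pockets, p)
    assert read_pockets_tsv(p) == pockets
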