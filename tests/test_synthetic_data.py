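"""Generator geometry, cross-link observation model, map-pair simulation."""

import math

import numpy as np
import pandas as pd
import pytest

from xlchamber.pose_search import apply_pose
from xlchamber.synthetic_data import (
    SpecError,
    SyntheticComplexSpec,
    default_pockets,
    make_ring_complex,
    simulate_crosslinks,
    simulate_occupancy_pair,
)


class TestMakeRingComplex:
    def test_eightfold_ring_angles(self, ring_complex):
        model, truth = ring_complex
        # ring 1 = chains A..H; consecutive centroids subtend 45 degrees
        centers = [truth.subunit_centers[c] for c in "ABCDEFGH"]
        angles = [math.atan2(c[1], c[0]) for c in centers]
        for a1, a2 in zip(angles, angles[1:]):
            step = (a2 - a1) % (2.0 * math.pi)
            assert math.degrees(step) == pytest.approx(45.0, abs=1e-6)

    def test_substrate_centroid_on_midplane(self, ring_complex):
        model, truth = ring_complex
        coords = [truth.full_coords[(truth.substrate_chain, r)]
                  for r in truth.substrate_reference]
        centroid = np.mean(coords, axis=0)
        assert abs(centroid[2] - truth.inter_ring_midplane_z()) < 1e-6

    def test_planted_pose_consistent_with_emitted_coordinates(self, ring_complex):
        model, truth = ring_complex
        resnums = sorted(truth.substrate_reference)
        ref = np.array([truth.substrate_reference[r] for r in resnums])
        placed = apply_pose(ref, truth.pose)
        emitted = np.array(
            [truth.full_coords[(truth.substrate_chain, r)] for r in resnums]
        )
        assert np.allclose(placed, emitted, atol=1e-9)

    def test_zero_tail_length_everything_resolved(self):
        model, truth = make_ring_complex(SyntheticComplexSpec(tail_length=0, seed=1))
        for chain in "ABCDEFGH":
            assert truth.tail_resnums[chain] == set()
            assert model.resolved_resnums(chain) == {r.ref.resnum for r in model.residues(chain)}

    def test_tails_absent_from_model_but_in_truth(self, ring_complex):
        model, truth = ring_complex
        tail = truth.spec.tail_length
        assert model.get_residue("A", 1) is None
        assert ("A", 1) in truth.full_coords
        assert min(model.resolved_resnums("A")) == tail + 1

    def test_overlapping_subunits_rejected(self):
        with pytest.raises(SpecError):
            SyntheticComplexSpec(ring_radius=8.0)

    def test_same_seed_reproducible(self):
        m1, t1 = make_ring_complex(SyntheticComplexSpec(seed=4))
        m2, t2 = make_ring_complex(SyntheticComplexSpec(seed=4))
        assert t1.pose.rotation == t2.pose.rotation
        for key, xyz in t1.full_coords.items():
            assert np.array_equal(xyz, t2.full_coords[key])


class TestSimulateCrosslinks:
    def test_zero_detection_probability_empty(self, ring_complex):
        model, truth = ring_complex
        links, table = simulate_crosslinks(model, truth, p_detect=0.0, seed=0)
        assert len(links) == 0 and len(table) == 0

    def test_exhaustive_regime_equals_bruteforce_pairs(self, ring_complex):
        model, truth = ring_complex
        links, table = simulate_crosslinks(
            model, truth, p_detect=1.0, lambda_decay=math.inf, false_rate=0.0, seed=0
        )
        # oracle: every lysine pair within the hard limit, enumerated directly
        expect = {
            frozenset({a, b})
            for a, b, d in truth.true_pairs()
            if d <= 32.0
        }
        got = {
            frozenset({(r.chain_a, r.resnum_a), (r.chain_b, r.resnum_b)})
            for r in table.itertuples(index=False)
        }
        assert got == expect

    def test_false_link_count_and_flags(self, ring_complex):
        model, truth = ring_complex
        links, table = simulate_crosslinks(model, truth, false_rate=0.1, seed=2)
        n_true = int((~table.is_false).sum())
        assert int(table.is_false.sum()) == math.floor(0.1 * n_true)

    def test_deterministic_per_seed(self, ring_complex):
        model, truth = ring_complex
        a, ta = simulate_crosslinks(model, truth, seed=9)
        b, tb = simulate_crosslinks(model, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_detection_decays_with_distance(self, ring_complex):
        # aggregate over seeds: detection frequency of near pairs exceeds far pairs
        model, truth = ring_complex
        pairs = truth.true_pairs()
        near = {frozenset({a, b}) for a, b, d in pairs if d <= 10.0}
        far = {frozenset({a, b}) for a, b, d in pairs if 25.0 <= d <= 32.0}
        counts = {"near": 0, "far": 0}
        for seed in range(10):
            _, table = simulate_crosslinks(model, truth, seed=seed)
            got = {
                frozenset({(r.chain_a, r.resnum_a), (r.chain_b, r.resnum_b)})
                for r in table.itertuples(index=False)
            }
            counts["near"] += len(got & near)
            counts["far"] += len(got & far)
        rate_near = counts["near"] / (10 * len(near))
        rate_far = counts["far"] / (10 * len(far))
        assert rate_near > 2.0 * rate_far

    def test_lambda_recoverable_by_maximum_likelihood(self, ring_complex):
        # refit the decay length from >=500 simulated links; within 20%
        from scipy.optimize import minimize_scalar

        model, truth = ring_complex
        pairs = [(a, b, d) for a, b, d in truth.true_pairs() if d <= 32.0]
        detected = []
        for seed in range(12):
            _, table = simulate_crosslinks(
                model, truth, p_detect=0.8, lambda_decay=15.0, false_rate=0.0, seed=seed
            )
            got = {
                frozenset({(r.chain_a, r.resnum_a), (r.chain_b, r.resnum_b)})
                for r in table.itertuples(index=False)
            }
            detected.append(got)
        n_links = sum(len(g) for g in detected)
        assert n_links >= 500

        def nll(lam):
            total = 0.0
            for got in detected:
                for a, b, d in pairs:
                    p = min(1.0 - 1e-12, 0.8 * math.exp(-d / lam))
                    if frozenset({a, b}) in got:
                        total -= math.log(p)
                    else:
                        total -= math.log(1.0 - p)
            return total

        fit = minimize_scalar(nll, bounds=(5.0, 60.0), method="bounded")
        assert abs(fit.x - 15.0) / 15.0 < 0.2


class TestSimulateOccupancyPair:
    def test_all_occupied_gives_zero_difference(self, ring_complex):
        model, truth = ring_complex
        pockets = default_pockets(truth)[:4]
        ref, qry, _ = simulate_occupancy_pair(model, pockets, [p.label for p in pockets], seed=0)
        assert np.abs(ref.grid - qry.grid).max() < 1e-6

    def test_same_seed_identical_maps(self, ring_complex):
        model, truth = ring_complex
        pockets = default_pockets(truth)[:4]
        r1, q1, _ = simulate_occupancy_pair(model, pockets, ["A"], noise_sigma=3.0, seed=5)
        r2, q2, _ = simulate_occupancy_pair(model, pockets, ["A"], noise_sigma=3.0, seed=5)
        assert np.array_equal(r1.grid, r2.grid) and np.array_equal(q1.grid, q2.grid)

    def test_unknown_pocket_label_rejected(self, ring_complex):
        model, truth = ring_complex
        pockets = default_pockets(truth)[:4]
        with pytest.raises(ValueError):
            simulate_occupancy_pair(model, pockets, ["NOPE"], seed=0)

    def test_truth_table_partitions_pockets(self, ring_complex):
        model, truth = ring_complex
        pockets = default_pockets(truth)[:6]
        occupied = [p.label for p in pockets[:2]]
        _, _, tr = simulate_occupancy_pair(model, pockets, occupied, seed=1)
        assert set(tr["occupied"]) | set(tr["empty"]) == {p.label for p in pockets}
        assert set(tr["occupied"]) & set(tr["empty"]) == set()
        assert tr["ligand_peak"] > 0
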