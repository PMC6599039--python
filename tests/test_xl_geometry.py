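"""Distances, restraint satisfaction and the foldedness statistic."""

import itertools
import math

import numpy as np
import pytest

from xlchamber.crosslinks import ChainMap, CrossLink, map_all
from xlchamber.structure_io import ResidueRef
from xlchamber.xl_geometry import (
    background_pairs,
    ca_distance,
    compatibility_pvalue,
    evaluate_restraints,
)
from tests.helpers import build_model


def grid_model(n=8, spacing=7.0, resname="LYS"):
    atoms = []
    for i in range(n):
        xyz = (spacing * (i % 3), spacing * ((i // 3) % 3), spacing * (i // 9))
        atoms.append(("A", i + 1, resname, "CA", "C", xyz, False))
    return build_model(atoms)


class TestCaDistance:
    def test_identity_and_pythagorean(self):
        model = build_model(
            [
                ("A", 1, "LYS", "CA", "C", (0, 0, 0), False),
                ("A", 2, "LYS", "CA", "C", (3, 4, 0), False),
            ]
        )
        a, b = ResidueRef("A", 1, "", "LYS"), ResidueRef("A", 2, "", "LYS")
        assert ca_distance(model, a, a) == 0.0
        assert ca_distance(model, a, b) == pytest.approx(5.0)
        assert ca_distance(model, b, a) == pytest.approx(5.0)

    def test_random_pairs_match_norm_oracle(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(-30, 30, size=(20, 3))
        atoms = [("A", i + 1, "ALA", "CA", "C", tuple(p), False) for i, p in enumerate(pts)]
        model = build_model(atoms)
        for i, j in rng.integers(0, 20, size=(20, 2)):
            got = ca_distance(
                model, ResidueRef("A", int(i) + 1, "", "ALA"), ResidueRef("A", int(j) + 1, "", "ALA")
            )
            assert got == pytest.approx(float(np.linalg.norm(pts[i] - pts[j])), abs=1e-9)


class TestEvaluateRestraints:
    def test_counts_partition(self, ring_complex):
        model, truth = ring_complex
        from xlchamber.synthetic_data import simulate_crosslinks
        from xlchamber.crosslinks import parse_plink

        links_df, _ = simulate_crosslinks(model, truth, seed=11)
        links = [
            CrossLink(r.Protein_1, int(r.Position_1), r.Protein_2, int(r.Position_2))
            for r in links_df.itertuples(index=False)
        ]
        restraints, unmapped = map_all(links, truth.chain_map(), model)
        report = evaluate_restraints(model, restraints)
        assert report.n_satisfied + report.n_violated == len(report.rows)
        assert report.n_total == len(report.rows) + report.n_unmapped + 0 * len(unmapped)

    def test_empty_restraint_list_all_zero(self, ring_complex):
        model, _ = ring_complex
        report = evaluate_restraints(model, [])
        assert (report.n_total, report.n_satisfied, report.n_violated) == (0, 0, 0)

    def test_raising_cutoff_never_decreases_satisfaction(self, ring_complex):
        model, truth = ring_complex
        from xlchamber.synthetic_data import simulate_crosslinks

        links_df, _ = simulate_crosslinks(model, truth, seed=5)
        links = [
            CrossLink(r.Protein_1, int(r.Position_1), r.Protein_2, int(r.Position_2))
            for r in links_df.itertuples(index=False)
        ]
        restraints, _ = map_all(links, truth.chain_map(), model)
        n_prev = -1
        for cutoff in (10.0, 20.0, 32.0, 50.0):
            n = evaluate_restraints(model, restraints, cutoff=cutoff).n_satisfied
            assert n >= n_prev
            n_prev = n

    def test_distances_invariant_under_rigid_motion(self, ring_complex):
        from scipy.spatial.transform import Rotation

        model, truth = ring_complex
        from xlchamber.synthetic_data import simulate_crosslinks
        from xlchamber.structure_io import StructureModel, Residue, AtomRecord
        import dataclasses

        links_df, _ = simulate_crosslinks(model, truth, seed=3)
        links = [
            CrossLink(r.Protein_1, int(r.Position_1), r.Protein_2, int(r.Position_2))
            for r in links_df.itertuples(index=False)
        ][:40]
        restraints, _ = map_all(links, truth.chain_map(), model)
        report1 = evaluate_restraints(model, restraints)

        R = Rotation.from_rotvec([0.4, -0.9, 1.3]).as_matrix()
        t = np.array([11.0, -7.0, 3.0])
        moved = StructureModel("moved")
        for res in model.iter_residues():
            new = Residue(ref=res.ref, is_hetero=res.is_hetero)
            for name, atom in res.atoms.items():
                new.atoms[name] = dataclasses.replace(atom, coords=tuple(R @ atom.xyz + t))
            moved.add_residue(new)
        report2 = evaluate_restraints(moved, restraints)
        d1 = np.array([r.distance for r in report1.rows])
        d2 = np.array([r.distance for r in report2.rows])
        assert np.allclose(d1, d2, atol=1e-6)


class TestBackgroundPairs:
    def test_exhaustive_pair_oracle_four_lysines(self):
        pts = [(0, 0, 0), (10, 0, 0), (0, 20, 0), (40, 0, 0)]
        atoms = [("A", i + 1, "LYS", "CA", "C", p, False) for i, p in enumerate(pts)]
        model = build_model(atoms)
        bg = background_pairs(model, "A", cutoff=32.0)
        assert bg.n_pairs == 6
        expect = {
            frozenset({1, 2}): 10.0,
            frozenset({1, 3}): 20.0,
            frozenset({1, 4}): 40.0,
            frozenset({2, 3}): math.hypot(10, 20),
            frozenset({2, 4}): 30.0,
            frozenset({3, 4}): math.hypot(40, 20),
        }
        got = {frozenset({a.resnum, b.resnum}): d for a, b, d in bg.pairs}
        for key, val in expect.items():
            assert got[key] == pytest.approx(val)
        assert bg.n_exceeding == 2  # 40.0 and hypot(40,20)

    def test_single_lysine_no_pairs(self):
        model = build_model([("A", 1, "LYS", "CA", "C", (0, 0, 0), False)])
        assert background_pairs(model, "A").n_pairs == 0

    def test_non_lysines_excluded(self):
        model = grid_model(6, resname="ALA")
        assert background_pairs(model, "A").n_pairs == 0

    def test_exceeding_monotone_in_cutoff(self, ring_complex):
        model, _ = ring_complex
        prev = None
        for cutoff in (5.0, 15.0, 32.0, 60.0):
            n = background_pairs(model, "S", cutoff=cutoff).n_exceeding
            if prev is not None:
                assert n <= prev
            prev = n


class TestCompatibilityPvalue:
    def test_no_violating_pairs_gives_one(self):
        assert compatibility_pvalue(10, 0, 5, 0) == pytest.approx(1.0)
        assert compatibility_pvalue(10, 0, 5, 3) == pytest.approx(1.0)

    def test_small_case_exact_enumeration(self):
        # 4 pairs, 2 violating, draw 2, want P(no violators) = C(2,2)/C(4,2) = 1/6
        assert compatibility_pvalue(4, 2, 2, 0) == pytest.approx(1.0 / 6.0)

    @pytest.mark.parametrize("n_pairs,n_exc,n_obs", [(8, 3, 4), (12, 5, 6), (10, 10, 4), (9, 0, 9)])
    def test_oracle_equivalence_exhaustive(self, n_pairs, n_exc, n_obs):
        # brute force: enumerate every draw of n_obs pairs from the population
        population = [1] * n_exc + [0] * (n_pairs - n_exc)
        draws = list(itertools.combinations(range(n_pairs), n_obs))
        for k in range(n_obs + 1):
            count = sum(1 for d in draws if sum(population[i] for i in d) <= k)
            expect = count / len(draws)
            assert compatibility_pvalue(n_pairs, n_exc, n_obs, k) == pytest.approx(expect, abs=1e-12)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            compatibility_pvalue(10, 11, 5, 0)
        with pytest.raises(ValueError):
            compatibility_pvalue(10, 2, 5, 6)
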