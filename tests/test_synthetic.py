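"""Planted-sequence generator and the exhaustive oracle."""

import random

import pytest

from coaxfold import build_orderings, find_helix_candidates
from coaxfold.candidates import HelixCandidate, Region
from coaxfold.errors import InputError
from coaxfold.geometry import StackKind, enumerate_coax_pairs
from coaxfold.synthetic import (
    HelixPlan,
    PlantNode,
    PlantSpec,
    brute_force_optimum,
    generate_planted_sequence,
    random_plant_spec,
)


class TestGenerator:
    def test_single_hairpin(self):
        spec = PlantSpec([PlantNode(HelixPlan(6), gaps=[4])], [0, 0], seed=1)
        seq, truth = generate_planted_sequence(spec)
        assert len(seq) == 16
        assert len(truth.pairs) == 6
        assert truth.coax == ()

    def test_planted_pairs_are_reverse_complementary(self):
        spec = PlantSpec([PlantNode(HelixPlan(8, 0.5), gaps=[5])], [1, 2], seed=3)
        seq, truth = generate_planted_sequence(spec)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}
        for a, b in truth.pairs:
            assert seq[b - 1] == comp[seq[a - 1]]

    def test_cloverleaf_truth_has_nested_and_parallel_stack(self, cloverleaf):
        seq, truth = cloverleaf
        kinds = sorted(s.kind.value for s in truth.coax)
        assert kinds == ["nested", "parallel"]
        assert all(s.k <= 1 for s in truth.coax)
        assert truth.decoys == ()

    def test_deterministic_per_seed(self):
        spec = lambda: PlantSpec(
            [PlantNode(HelixPlan(6, 0.8), gaps=[4])], [1, 1], seed=7
        )
        assert generate_planted_sequence(spec()) == generate_planted_sequence(spec())

    def test_short_hairpin_loop_rejected(self):
        spec = PlantSpec([PlantNode(HelixPlan(4), gaps=[2])], [0, 0], seed=0)
        with pytest.raises(InputError):
            generate_planted_sequence(spec)

    def test_bulged_helix_plant(self):
        spec = PlantSpec(
            [PlantNode(HelixPlan(6, 0.8, bulge=True), gaps=[4])], [0, 0], seed=2
        )
        seq, truth = generate_planted_sequence(spec)
        h = truth.helices[0]
        assert len(h.region5) == 7 and len(h.pairs) == 6


class TestBruteForce:
    def _instance(self, seq):
        cands = find_helix_candidates(seq)
        index = build_orderings(cands)
        return index, enumerate_coax_pairs(index, seq)

    def test_single_helix_scores_its_weight(self):
        spec = PlantSpec([PlantNode(HelixPlan(7, 0.0), gaps=[4])], [0, 0], seed=4)
        seq, _ = generate_planted_sequence(spec)
        index, coax = self._instance(seq)
        res = brute_force_optimum(index, coax)
        assert res.score_centi == max(-c.energy_centi for c in index.candidates)

    def test_crossing_helices_never_coselected(self):
        # two strong artificial candidates that cross each other
        a = HelixCandidate(
            id=0, region5=Region(1, 4), region3=Region(10, 13),
            pairs=((1, 13), (2, 12), (3, 11), (4, 10)),
            energy_centi=-500, n_gc=4, tier=None,
        )
        b = HelixCandidate(
            id=1, region5=Region(6, 9), region3=Region(15, 18),
            pairs=((6, 18), (7, 17), (8, 16), (9, 15)),
            energy_centi=-600, n_gc=4, tier=None,
        )
        from coaxfold.energy import StabilityTier

        a.tier = b.tier = StabilityTier.STABLE
        index = build_orderings([a, b])
        res = brute_force_optimum(index, [])
        assert res.score_centi == 600
        assert all(len(h) <= 1 for h, _ in res.optima)

    def test_refuses_oversized_instances(self):
        cands = find_helix_candidates("GGCGCGAAAACGCGCCAAAGGCGCGAAAACGCGCC")
        index = build_orderings(cands)
        assert index.n_regions > 12
        with pytest.raises(InputError):
            brute_force_optimum(index, [])

    def test_empty_instance_scores_zero(self):
        index = build_orderings([])
        res = brute_force_optimum(index, [])
        assert res.score_centi == 0 and res.optima == [(frozenset(), frozenset())]


class TestRandomSpecs:
    def test_specs_are_buildable_and_reproducible(self):
        rng1, rng2 = random.Random(11), random.Random(11)
        for _ in range(10):
            s1, s2 = random_plant_spec(rng1), random_plant_spec(rng2)
            out1 = generate_planted_sequence(s1, max_attempts=1, repair_rounds=0)
            out2 = generate_planted_sequence(s2, max_attempts=1, repair_rounds=0)
            assert out1[0] == out2[0]
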