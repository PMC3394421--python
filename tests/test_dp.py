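"""Helix weights, combined 2-way strength, DP fill/traceback, prediction."""

import random

import pytest

from coaxfold import build_orderings, find_helix_candidates, predict
from coaxfold.candidates import HelixCandidate, Region
from coaxfold.dp import (
    DPConfig,
    combined_strength,
    fill_tables,
    helix_weight,
    traceback,
)
from coaxfold.energy import EnergyConfig, StabilityTier
from coaxfold.geometry import StackKind, enumerate_coax_pairs
from coaxfold.synthetic import (
    audit_prediction,
    brute_force_optimum,
    generate_planted_sequence,
    random_plant_spec,
)


def _cand(cid, l_start, l_end, h_start, h_end, dg_centi, n_bp, n_gc, tier):
    return HelixCandidate(
        id=cid,
        region5=Region(l_start, l_end),
        region3=Region(h_start, h_end),
        pairs=tuple((l_start + i, h_end - i) for i in range(n_bp)),
        energy_centi=dg_centi,
        n_gc=n_gc,
        tier=tier,
    )


class TestHelixWeight:
    def setup_method(self):
        self.cand = _cand(0, 1, 4, 10, 13, -400, 4, 2, StabilityTier.STABLE)
        self.index = build_orderings([self.cand])
        self.i = self.index.spo_index[0]
        self.j = self.index.epo_index[1]

    def test_weight_is_negated_energy(self):
        assert helix_weight(self.index, self.i, self.j, "ANY") == 4.0

    def test_filter_excludes_weaker_tiers(self):
        assert helix_weight(self.index, self.i, self.j, "ULTRA") == float("-inf")

    def test_unpaired_region_combination_is_minus_inf(self):
        assert helix_weight(self.index, self.i, self.i, "ANY") == float("-inf")


class TestCombinedStrength:
    def _pair(self, dg_out, dg_in, gc=1):
        outer = _cand(0, 1, 3, 20, 22, dg_out, 3, gc, StabilityTier.SEMI_STABLE)
        inner = _cand(1, 5, 7, 15, 17, dg_in, 3, 0, StabilityTier.SEMI_STABLE)
        return outer, inner

    def test_combined_reaches_stable(self):
        outer, inner = self._pair(-260, -150)
        assert combined_strength(outer, inner, 0.0) == StabilityTier.STABLE

    def test_coax_reward_lifts_to_ultra(self):
        outer, inner = self._pair(-260, -150)
        assert combined_strength(outer, inner, 0.9) == StabilityTier.ULTRA_STABLE

    def test_weak_pair_stays_none(self):
        outer, inner = self._pair(-100, -100)
        assert combined_strength(outer, inner, 0.0) == StabilityTier.NONE

    def test_non_nested_arrangement_rejected(self):
        outer = _cand(0, 1, 3, 10, 12, -260, 3, 1, StabilityTier.SEMI_STABLE)
        other = _cand(1, 14, 16, 20, 22, -150, 3, 0, StabilityTier.SEMI_STABLE)
        from coaxfold.errors import InputError

        with pytest.raises(InputError):
            combined_strength(outer, other)


class TestFillAndTraceback:
    def test_single_helix_optimum_is_its_weight(self, hairpin_instance):
        seq, index, coax = hairpin_instance
        tables = fill_tables(index, coax)
        pred = traceback(tables, index, coax)
        best = max(-c.energy_centi for c in index.candidates)
        assert pred.score_centi == best
        assert len(pred.helices) == 1 and not pred.coax_stacks

    def test_no_candidates_scores_zero(self):
        pred = predict("AAAAAAAAAAAA")
        assert pred.score_centi == 0 and pred.pairs == frozenset()

    def test_traceback_deterministic(self, hairpin_instance):
        seq, index, coax = hairpin_instance
        a = traceback(fill_tables(index, coax), index, coax)
        b = traceback(fill_tables(index, coax), index, coax)
        assert a == b

    def test_score_decomposes_into_weights_plus_rewards(self, cloverleaf):
        seq, truth = cloverleaf
        cands = find_helix_candidates(seq)
        index = build_orderings(cands)
        coax = enumerate_coax_pairs(index, seq)
        pred = traceback(fill_tables(index, coax), index, coax)
        total = sum(-index.by_id[c].energy_centi for c in pred.helices) + sum(
            p.reward_centi for p in pred.coax_stacks
        )
        assert pred.score_centi == total

    def test_score_monotone_in_coax_availability(self, cloverleaf):
        # coaxial stacks both reward and structurally enable junctions
        # (a k=0 boundary is admissible only with its stack), so removing
        # them can only lower the optimum
        seq, truth = cloverleaf
        cands = find_helix_candidates(seq)
        index = build_orderings(cands)
        coax = enumerate_coax_pairs(index, seq)
        with_coax = traceback(fill_tables(index, coax), index, coax)
        without = traceback(fill_tables(index, []), index, [])
        assert without.score_centi <= with_coax.score_centi
        assert with_coax.coax_stacks and not without.coax_stacks

    def test_planted_two_way_coax_recovered(self):
        # two AU helices in a 2-way junction joined at k=1 on both sides
        from coaxfold.synthetic import HelixPlan, PlantNode, PlantSpec

        spec = PlantSpec(
            roots=[
                PlantNode(
                    HelixPlan(7, 0.0),
                    [PlantNode(HelixPlan(7, 0.0), gaps=[4])],
                    gaps=[1, 1],
                )
            ],
            outer_gaps=[0, 0],
            seed=5,
        )
        seq, truth = generate_planted_sequence(spec)
        assert [s.kind for s in truth.coax] == [StackKind.NESTED]
        pred = predict(seq)
        assert truth.pairs <= pred.pairs
        kinds = [p.kind for p in pred.coax_stacks]
        assert kinds == [StackKind.NESTED]


class TestOracleAgreement:
    def test_small_instances_match_brute_force(self):
        rng = random.Random(2024)
        done = 0
        while done < 25:
            spec = random_plant_spec(rng)
            seq, truth = generate_planted_sequence(
                spec, max_attempts=1, repair_rounds=0
            )
            cands = find_helix_candidates(seq)
            if not (1 <= len(cands) <= 6):
                continue
            index = build_orderings(cands)
            coax = enumerate_coax_pairs(index, seq)
            pred = traceback(fill_tables(index, coax), index, coax)
            brute = brute_force_optimum(index, coax)
            assert pred.score_centi == brute.score_centi
            assert audit_prediction(pred, index, coax) == []
            done += 1
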