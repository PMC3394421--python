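"""Stacking table, helix free energy, tier classification, coax reward."""

import pytest
from hypothesis import given, settings, strategies as st

from coaxfold.candidates import HelixCandidate, Region
from coaxfold.energy import (
    PAIR_TYPES,
    WATSON_CRICK,
    EnergyConfig,
    StabilityTier,
    classify_tier,
    coax_reward_centi,
    helix_free_energy,
    helix_free_energy_centi,
    stack_energy,
    stack_energy_centi,
)
from coaxfold.errors import InputError, NonCanonicalPairError


def _cand(pairs, n_gc=0):
    pairs = tuple(pairs)
    return HelixCandidate(
        id=0,
        region5=Region(pairs[0][0], pairs[-1][0]),
        region3=Region(pairs[-1][1], pairs[0][1]),
        pairs=pairs,
        n_gc=n_gc,
    )


class TestStackTable:
    def test_full_coverage(self):
        for a in PAIR_TYPES:
            for b in PAIR_TYPES:
                assert isinstance(stack_energy_centi(a, b), int)

    def test_strand_flip_symmetry(self):
        # dG(5'WX/3'ZY) == dG(5'YZ/3'XW) for every entry
        for a in PAIR_TYPES:
            for b in PAIR_TYPES:
                assert stack_energy_centi(a, b) == stack_energy_centi(
                    b[::-1], a[::-1]
                )

    @pytest.mark.parametrize(
        "pa, pb, expected",
        [(("G", "C"), ("C", "G"), -3.4), (("A", "U"), ("A", "U"), -0.9)],
    )
    def test_extreme_watson_crick_stacks(self, pa, pb, expected):
        assert round(stack_energy(pa, pb), 1) == expected

    def test_watson_crick_range_matches_coax_bounds(self):
        vals = [
            round(stack_energy(a, b), 1)
            for a in WATSON_CRICK
            for b in WATSON_CRICK
        ]
        assert min(vals) == -3.4
        assert max(vals) == -0.9

    def test_non_canonical_pair_rejected(self):
        with pytest.raises(NonCanonicalPairError):
            stack_energy(("G", "A"), ("C", "G"))


class TestHelixFreeEnergy:
    def test_two_bp_helix_is_single_stack(self):
        seq = "GCAAAAGC"  # pairs (1,8)=G-C and (2,7)=C-G
        cand = _cand([(1, 8), (2, 7)])
        cfg = EnergyConfig(include_terminal_penalty=False)
        assert helix_free_energy(cand, seq, cfg) == stack_energy(("G", "C"), ("C", "G"))

    def test_six_bp_helix_is_sum_of_five_stacks(self):
        seq = "GGCGCGAAAACGCGCC"
        pairs = [(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)]
        cand = _cand(pairs)
        cfg = EnergyConfig(include_terminal_penalty=False)
        expected = sum(
            stack_energy((seq[a1 - 1], seq[b1 - 1]), (seq[a2 - 1], seq[b2 - 1]))
            for (a1, b1), (a2, b2) in zip(pairs, pairs[1:])
        )
        assert helix_free_energy(cand, seq, cfg) == pytest.approx(expected)

    def test_bulge_adds_penalty_and_keeps_flanking_stack(self):
        # stack run (1,14)(2,13)(3,12), bulged A at 4, then (5,11)
        seq = "GGCAGAAAAACGCC"
        pairs = [(1, 14), (2, 13), (3, 12), (5, 11)]
        cand = _cand(pairs)
        cfg = EnergyConfig(include_terminal_penalty=False)
        plain = sum(
            stack_energy((seq[a1 - 1], seq[b1 - 1]), (seq[a2 - 1], seq[b2 - 1]))
            for (a1, b1), (a2, b2) in zip(pairs, pairs[1:])
        )
        assert helix_free_energy(cand, seq, cfg) == pytest.approx(
            plain + cfg.bulge1_penalty
        )

    def test_strand_flip_invariance(self):
        # a helix read on the reverse complement has the same free energy
        seq = "GGCGAAAACGCC"
        pairs = [(1, 12), (2, 11), (3, 10), (4, 9)]
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(seq))
        n = len(seq)
        flipped = [(n + 1 - b, n + 1 - a) for a, b in pairs]
        assert helix_free_energy_centi(
            _cand(pairs), seq, EnergyConfig()
        ) == helix_free_energy_centi(_cand(flipped), rc, EnergyConfig())

    def test_empty_candidate_rejected(self):
        empty = HelixCandidate(
            id=0, region5=Region(1, 2), region3=Region(7, 8), pairs=()
        )
        with pytest.raises(InputError):
            helix_free_energy(empty, "GCAAAAGC")

    def test_non_canonical_candidate_rejected(self):
        with pytest.raises(NonCanonicalPairError):
            helix_free_energy(_cand([(1, 8), (2, 7)]), "GAAAAAGC")


class TestClassifyStability:
    @pytest.mark.parametrize(
        "dg, bp, gc, tier",
        [
            (-4.0, 4, 2, StabilityTier.STABLE),
            (-5.0, 6, 3, StabilityTier.ULTRA_STABLE),
            (-3.0, 3, 0, StabilityTier.NONE),
            (-2.0, 5, 2, StabilityTier.NONE),
            (-2.6, 3, 1, StabilityTier.SEMI_STABLE),
            (-5.0, 5, 2, StabilityTier.STABLE),  # too few bp for ultra
        ],
    )
    def test_threshold_cases(self, dg, bp, gc, tier):
        assert classify_tier(round(dg * 100), bp, gc, EnergyConfig()) == tier

    @given(
        dg=st.integers(min_value=-900, max_value=0),
        delta=st.integers(min_value=0, max_value=500),
        bp=st.integers(min_value=1, max_value=10),
        gc=st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_free_energy(self, dg, delta, bp, gc):
        cfg = EnergyConfig()
        assert classify_tier(dg - delta, bp, gc, cfg) >= classify_tier(dg, bp, gc, cfg)

    def test_threshold_order_enforced(self):
        with pytest.raises(InputError):
            EnergyConfig(semi_stable_max=-5.0, stable_max=-3.7, ultra_stable_max=-4.6)


class TestCoaxReward:
    def test_reward_is_negated_stack_energy(self):
        assert coax_reward_centi(("G", "C"), ("C", "G")) == 340
        assert coax_reward_centi(("A", "U"), ("A", "U")) == 90

    def test_destabilizing_wobble_stack_clipped_to_zero(self):
        # GU on GU stacks are destabilizing in the table
        assert stack_energy(("G", "U"), ("U", "G")) > 0
        assert coax_reward_centi(("G", "U"), ("U", "G")) == 0

    def test_reward_bounded_by_table_minimum(self):
        for a in PAIR_TYPES:
            for b in PAIR_TYPES:
                r = coax_reward_centi(a, b)
                assert 0 <= r <= 340
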