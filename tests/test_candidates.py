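"""Candidate search, SPO/EPO orderings, distance and order queries."""

import pytest
from hypothesis import given, settings, strategies as st

from coaxfold.candidates import (
    CandidateIndex,
    FinderConfig,
    HelixCandidate,
    Region,
    build_orderings,
    distance,
    find_helix_candidates,
    order_query,
)
from coaxfold.energy import StabilityTier
from coaxfold.errors import InputError


def _cand(cid, l_start, l_end, h_start, h_end):
    return HelixCandidate(
        id=cid,
        region5=Region(l_start, l_end),
        region3=Region(h_start, h_end),
        pairs=((l_start, h_end), (l_end, h_start)),
    )


class TestFinder:
    def test_perfect_gc_hairpin_found_as_ultra(self):
        cands = find_helix_candidates("GGCGCGAAAACGCGCC")
        full = [
            c
            for c in cands
            if c.region5 == Region(1, 6) and c.region3 == Region(11, 16)
            and c.n_pairs == 6
        ]
        assert len(full) == 1
        assert full[0].tier == StabilityTier.ULTRA_STABLE

    def test_unpairable_sequence_yields_nothing(self):
        assert find_helix_candidates("AAAAAAAA") == []

    def test_min_hairpin_loop_respected(self):
        for cand in find_helix_candidates("GCGCAAAGCGC"):
            i5, i3 = cand.inner_pair
            assert i3 - i5 - 1 >= 3

    def test_invalid_alphabet_names_position(self):
        with pytest.raises(InputError, match="position 4"):
            find_helix_candidates("GGCXGCC")

    def test_short_sequence_empty(self):
        assert find_helix_candidates("GC") == []

    def test_deterministic(self):
        seq = "GGCGCGAAAACGCGCCAAAGGGCAAACCCAAA"
        a = find_helix_candidates(seq)
        b = find_helix_candidates(seq)
        assert [(c.id, c.pairs, c.energy_centi, c.tier) for c in a] == [
            (c.id, c.pairs, c.energy_centi, c.tier) for c in b
        ]

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_planted_inverted_repeat_always_found(self, seed):
        import random

        rng = random.Random(seed)
        stem = "".join(rng.choice("GC") for _ in range(6))
        comp = {"G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(stem))
        seq = stem + "AAAA" + rc
        planted = tuple((i + 1, len(seq) - i) for i in range(6))
        found = {c.pairs for c in find_helix_candidates(seq)}
        assert any(set(planted) <= set(p) for p in found)


class TestOrderings:
    def setup_method(self):
        # L regions (1..5), (1..7), (3..6); far-away H regions keep them apart
        self.cands = [
            _cand(0, 1, 5, 50, 54),
            _cand(1, 1, 7, 60, 64),
            _cand(2, 3, 6, 70, 74),
        ]
        self.index = build_orderings(self.cands)

    def test_spo_rule(self):
        spans = [
            (r.start, r.end)
            for r in (self.index.region_at_spo(i) for i in range(3))
        ]
        assert spans == [(1, 5), (1, 7), (3, 6)]

    def test_epo_rule(self):
        spans = [
            (r.start, r.end)
            for r in (self.index.region_at_epo(j) for j in range(3))
        ]
        assert spans == [(1, 5), (3, 6), (1, 7)]

    def test_every_region_once_in_each_order(self):
        assert sorted(self.index.spo) == sorted(self.index.epo) == list(range(6))

    def test_identical_spans_ordered_consistently(self):
        cands = [_cand(0, 1, 5, 50, 54), _cand(1, 1, 5, 60, 64)]
        index = build_orderings(cands)
        spo_order = [index.entry_at_spo(i).cand_id for i in range(2)]
        epo_order = [index.entry_at_epo(j).cand_id for j in range(2)]
        assert spo_order == epo_order == [0, 1]

    def test_pair_map_links_the_two_regions_of_each_candidate(self):
        for c in self.cands:
            i = self.index.spo_index[2 * c.id]
            j = self.index.epo_index[2 * c.id + 1]
            assert self.index.candidate_at(i, j).id == c.id


class TestDistance:
    def test_adjacent_regions_have_distance_one(self):
        assert distance(Region(5, 10), Region(11, 14)) == 1

    def test_one_unpaired_nucleotide_gives_two(self):
        assert distance(Region(5, 10), Region(12, 14)) == 2

    def test_overlap_rejected(self):
        with pytest.raises(InputError):
            distance(Region(5, 10), Region(9, 14))


class TestOrderQueries:
    def setup_method(self):
        # anchor region ends at 10; successors start at 11, 12, 13, 20
        self.cands = [
            _cand(0, 5, 10, 80, 84),
            _cand(1, 11, 14, 60, 64),
            _cand(2, 12, 15, 66, 70),
            _cand(3, 13, 16, 72, 76),
            _cand(4, 20, 24, 40, 44),
        ]
        self.index = build_orderings(self.cands)
        self.anchor = 0  # region id of candidate 0's L region

    def test_succ_geq_returns_first_at_distance(self):
        rid = order_query(self.index, self.anchor, "succ_geq", 2)
        assert self.index.entries[rid].region.start == 12

    def test_succ_leq2_returns_all_close_successors(self):
        rids = order_query(self.index, self.anchor, "succ_leq2")
        starts = sorted(self.index.entries[r].region.start for r in rids)
        assert starts == [11, 12]

    def test_none_sentinel_when_no_region_qualifies(self):
        last = 8  # H region of candidate 4 (entry id 2*4)
        last = 2 * 0 + 1  # candidate 0's H region, ends at 84 (the last)
        assert order_query(self.index, last, "succ_geq", 1) is None

    def test_unknown_anchor_rejected(self):
        with pytest.raises(InputError):
            order_query(self.index, 99, "succ_geq", 1)

    @given(st.integers(min_value=1, max_value=6))
    @settings(max_examples=20, deadline=None)
    def test_succ_geq_is_first_qualifying(self, bound):
        for i in range(self.index.n_regions):
            k = self.index.s_geq(i, bound)
            anchor = self.index.region_at_spo(i)
            if k is None:
                for j in range(self.index.n_regions):
                    r = self.index.region_at_spo(j)
                    assert r.start <= anchor.end + bound - 1 or r.overlaps(anchor)
            else:
                r = self.index.region_at_spo(k)
                assert distance(anchor, r) >= bound
                for j in range(k):
                    rj = self.index.region_at_spo(j)
                    if not rj.overlaps(anchor) and rj.start > anchor.end:
                        assert distance(anchor, rj) < bound
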