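"""Helix candidate search and the SPO/EPO order structures.

A helix candidate is two antiparallel base-pairing backbone regions (the
5'-side region L and the 3'-side region H), each allowed to contain at most
one unpaired (bulged) nucleotide.  The search enumerates maximal inward
extensions of complementary runs, preferring a contiguous stack step and
branching into bulge steps only where stacking is impossible, then adds
end-trimmed sub-helices when trimming reaches a different stability tier.

Every candidate contributes its two regions to the order structures: SPO
(Starting Position Order: by start, then end) and EPO (Ending Position
Order: by end, then start).  The dynamic program walks cells keyed by one
SPO index and one EPO index and needs the successor/predecessor queries
implemented here (first successor at distance >= x; all successors at
distance <= 2; mirrored for predecessors).

Positions are 1-based inclusive throughout.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .energy import (
    EnergyConfig,
    StabilityTier,
    classify_tier,
    helix_free_energy_centi,
    _is_canonical,
)
from .errors import InputError


@dataclass(frozen=True, order=True)
class Region:
    """A contiguous backbone segment, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(f"invalid region {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return not (self.end < other.start or other.end < self.start)


def distance(a: Region, b: Region) -> int:
    """Nucleotide distance d(a, b) = b.start - a.end.

    Adjacent regions have distance 1; k unpaired nucleotides between them
    give distance k + 1.  Requires a to end before b starts.
    """
    if a.end >= b.start:
        raise InputError(f"regions {a} and {b} overlap or are out of order")
    return b.start - a.end


@dataclass
class HelixCandidate:
    """A candidate helix: paired regions, base pairs, energy, tier."""

    id: int
    region5: Region
    region3: Region
    pairs: tuple[tuple[int, int], ...]  # (pos5, pos3), outermost first
    bulges5: tuple[int, ...] = ()
    bulges3: tuple[int, ...] = ()
    energy_centi: int | None = None
    tier: StabilityTier | None = None
    n_gc: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def energy(self) -> float | None:
        return None if self.energy_centi is None else self.energy_centi / 100.0

    @property
    def outer_pair(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner_pair(self) -> tuple[int, int]:
        return self.pairs[-1]

    def encloses(self, other: "HelixCandidate") -> bool:
        return (
            self.region5.end < other.region5.start
            and other.region3.end < self.region3.start
        )

    def precedes(self, other: "HelixCandidate") -> bool:
        return self.region3.end < other.region5.start


@dataclass
class FinderConfig:
    """Search parameters for the candidate finder."""

    min_bp: int = 2
    min_hairpin_loop: int = 3
    max_bulges_per_backbone: int = 1
    max_end_trim: int = 1  # sub-helix trims probed per helix end

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 0:
            raise InputError("min_hairpin_loop must be >= 0")
        if self.min_bp < 1:
            raise InputError("min_bp must be >= 1")


_VALID = set("ACGU")


def _clean_sequence(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s, start=1):
        if ch not in _VALID:
            raise InputError(f"invalid nucleotide {ch!r} at position {pos}")
    return s


def _extend_inward(s: str, i: int, j: int, cfg: FinderConfig):
    """All maximal inward extensions of a helix starting at outer pair (i, j).

    Yields pair tuples.  A contiguous stack step is always preferred; bulge
    steps (skip one nt on the 5' or 3' backbone, or one on each) are only
    taken where no stack is possible and the per-backbone budget allows.
    """
    results: list[tuple[tuple[int, int], ...]] = []

    def gap_ok(a: int, b: int) -> bool:
        return b - a - 1 >= cfg.min_hairpin_loop

    def walk(a: int, b: int, used5: int, used3: int, acc: list[tuple[int, int]]):
        acc = acc + [(a, b)]
        moves = []
        if gap_ok(a + 1, b - 1) and _is_canonical(s[a], s[b - 2]):
            moves.append((a + 1, b - 1, used5, used3))
        else:
            # no contiguous stack: the run so far is a maximal perfect
            # extension and a candidate in its own right, whether or not a
            # bulged continuation exists (the continuation is recorded too)
            results.append(tuple(acc))
            if (
                used5 < cfg.max_bulges_per_backbone
                and gap_ok(a + 2, b - 1)
                and _is_canonical(s[a + 1], s[b - 2])
            ):
                moves.append((a + 2, b - 1, used5 + 1, used3))
            if (
                used3 < cfg.max_bulges_per_backbone
                and gap_ok(a + 1, b - 2)
                and _is_canonical(s[a], s[b - 3])
            ):
                moves.append((a + 1, b - 2, used5, used3 + 1))
            if (
                used5 < cfg.max_bulges_per_backbone
                and used3 < cfg.max_bulges_per_backbone
                and gap_ok(a + 2, b - 2)
                and _is_canonical(s[a + 1], s[b - 3])
            ):
                moves.append((a + 2, b - 2, used5 + 1, used3 + 1))
        if not moves:
            results.append(tuple(acc))
            return
        for na, nb, nu5, nu3 in moves:
            walk(na, nb, nu5, nu3, acc)

    walk(i, j, 0, 0, [])
    return results


def _make_candidate(cid: int, pairs: tuple[tuple[int, int], ...], s: str, ecfg: EnergyConfig):
    region5 = Region(pairs[0][0], pairs[-1][0])
    region3 = Region(pairs[-1][1], pairs[0][1])
    p5 = {p for p, _ in pairs}
    p3 = {q for _, q in pairs}
    bulges5 = tuple(p for p in range(region5.start, region5.end + 1) if p not in p5)
    bulges3 = tuple(p for p in range(region3.start, region3.end + 1) if p not in p3)
    n_gc = sum(1 for a, b in pairs if {s[a - 1], s[b - 1]} == {"G", "C"})
    cand = HelixCandidate(
        id=cid,
        region5=region5,
        region3=region3,
        pairs=pairs,
        bulges5=bulges5,
        bulges3=bulges3,
        n_gc=n_gc,
    )
    cand.energy_centi = helix_free_energy_centi(cand, s, ecfg)
    cand.tier = classify_tier(cand.energy_centi, cand.n_pairs, n_gc, ecfg)
    return cand


def find_helix_candidates(
    seq: str,
    cfg: FinderConfig | None = None,
    ecfg: EnergyConfig | None = None,
) -> list[HelixCandidate]:
    """All helix candidates of the sequence whose stability tier is not NONE.

    Deterministic: output sorted by (region5.start, region3.end, pairs).
    A too-short sequence yields an empty list; an invalid alphabet raises
    InputError naming the offending position.
    """
    cfg = cfg or FinderConfig()
    ecfg = ecfg or EnergyConfig()
    s = _clean_sequence(seq)
    n = len(s)
    if n < 2 * cfg.min_bp + cfg.min_hairpin_loop:
        return []

    seen: set[tuple[tuple[int, int], ...]] = set()
    all_pairs: list[tuple[tuple[int, int], ...]] = []

    def consider(pairs: tuple[tuple[int, int], ...]) -> None:
        if len(pairs) >= cfg.min_bp and pairs not in seen:
            seen.add(pairs)
            all_pairs.append(pairs)

    # outer starts: canonical (i, j) not extendable outward by a stack
    for i in range(1, n + 1):
        for j in range(i + cfg.min_hairpin_loop + 1, n + 1):
            if not _is_canonical(s[i - 1], s[j - 1]):
                continue
            if i > 1 and j < n and _is_canonical(s[i - 2], s[j]):
                continue  # outward stack exists; covered by the larger start
            for pairs in _extend_inward(s, i, j, cfg):
                consider(pairs)
                # end-trimmed sub-helices reaching a different tier
                base = _make_candidate(-1, pairs, s, ecfg)
                for t_out in range(cfg.max_end_trim + 1):
                    for t_in in range(cfg.max_end_trim + 1):
                        if t_out == t_in == 0:
                            continue
                        sub = pairs[t_out : len(pairs) - t_in]
                        if len(sub) < cfg.min_bp:
                            continue
                        c = _make_candidate(-1, tuple(sub), s, ecfg)
                        if c.tier != base.tier and c.tier != StabilityTier.NONE:
                            consider(tuple(sub))

    cands = [_make_candidate(0, p, s, ecfg) for p in sorted(all_pairs)]
    cands = [c for c in cands if c.tier != StabilityTier.NONE]
    cands.sort(key=lambda c: (c.region5.start, c.region3.end, c.pairs))
    for k, c in enumerate(cands):
        c.id = k
    return cands


@dataclass
class _RegionEntry:
    rid: int
    region: Region
    cand_id: int
    side: str  # "5" (L region) or "3" (H region)


class CandidateIndex:
    """SPO/EPO orderings over candidate regions with the DP's order queries.

    Regions are per-candidate objects: each candidate contributes exactly one
    L region and one H region, even when spans coincide with another
    candidate's.  Ties on identical spans are broken by (candidate id, side),
    consistently in both orders.
    """

    def __init__(self, candidates: list[HelixCandidate]):
        self.candidates = list(candidates)
        self.by_id = {c.id: c for c in candidates}
        entries: list[_RegionEntry] = []
        for c in candidates:
            entries.append(_RegionEntry(-1, c.region5, c.id, "5"))
            entries.append(_RegionEntry(-1, c.region3, c.id, "3"))
        for rid, e in enumerate(entries):
            e.rid = rid
        self.entries = entries
        self.spo = sorted(
            range(len(entries)),
            key=lambda r: (
                entries[r].region.start,
                entries[r].region.end,
                entries[r].cand_id,
                entries[r].side,
            ),
        )
        self.epo = sorted(
            range(len(entries)),
            key=lambda r: (
                entries[r].region.end,
                entries[r].region.start,
                entries[r].cand_id,
                entries[r].side,
            ),
        )
        self.spo_index = {rid: k for k, rid in enumerate(self.spo)}
        self.epo_index = {rid: k for k, rid in enumerate(self.epo)}
        self._spo_starts = [entries[r].region.start for r in self.spo]
        self._epo_ends = [entries[r].region.end for r in self.epo]
        # pairing map A: (spo index of L, epo index of H) -> candidate id;
        # entries were appended L then H per candidate, so rids are 2k, 2k+1
        self.pair_map: dict[tuple[int, int], int] = {}
        for k, c in enumerate(self.candidates):
            l_rid, h_rid = 2 * k, 2 * k + 1
            self.pair_map[(self.spo_index[l_rid], self.epo_index[h_rid])] = c.id

    # -- basic accessors -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.entries)

    def region_at_spo(self, i: int) -> Region:
        return self.entries[self.spo[i]].region

    def region_at_epo(self, j: int) -> Region:
        return self.entries[self.epo[j]].region

    def entry_at_spo(self, i: int) -> _RegionEntry:
        return self.entries[self.spo[i]]

    def entry_at_epo(self, j: int) -> _RegionEntry:
        return self.entries[self.epo[j]]

    def candidate_at(self, i: int, j: int) -> HelixCandidate | None:
        """The candidate whose (L, H) regions are (SPO i, EPO j), if any."""
        cid = self.pair_map.get((i, j))
        return None if cid is None else self.by_id[cid]

    # -- order queries ---------------------------------------------------
    # The coordinate-anchored variants (…_end / …_start) serve the DP's
    # bifurcation splits, where the anchor is a region reached through the
    # *other* order; the index-anchored ones implement s>=x / p>=y / s'<=2 /
    # p'<=2 directly.
    def s_geq_end(self, end: int, x: int) -> int | None:
        """First SPO index whose region starts at distance >= x after ``end``."""
        k = bisect.bisect_left(self._spo_starts, end + x)
        return k if k < len(self.spo) else None

    def p_geq_start(self, start: int, y: int) -> int | None:
        """Last EPO index whose region ends at distance >= y before ``start``."""
        k = bisect.bisect_right(self._epo_ends, start - y) - 1
        return k if k >= 0 else None

    def s_leq2_end(self, end: int) -> list[int]:
        """All SPO indices at distance 1 or 2 after ``end``."""
        lo = bisect.bisect_left(self._spo_starts, end + 1)
        hi = bisect.bisect_right(self._spo_starts, end + 2)
        return list(range(lo, hi))

    def p_leq2_start(self, start: int) -> list[int]:
        """All EPO indices at distance 1 or 2 before ``start``."""
        lo = bisect.bisect_left(self._epo_ends, start - 2)
        hi = bisect.bisect_right(self._epo_ends, start - 1)
        return list(range(lo, hi))

    def s_geq(self, i: int, x: int) -> int | None:
        """First non-overlapping SPO successor of SPO index i at distance >= x."""
        return self.s_geq_end(self.region_at_spo(i).end, x)

    def p_geq(self, j: int, y: int) -> int | None:
        """First non-overlapping EPO predecessor of EPO index j at distance >= y."""
        return self.p_geq_start(self.region_at_epo(j).start, y)

    def s_leq2(self, i: int) -> list[int]:
        """All SPO successors of i at distance 1 or 2."""
        return self.s_leq2_end(self.region_at_spo(i).end)

    def p_leq2(self, j: int) -> list[int]:
        """All EPO predecessors of j at distance 1 or 2."""
        return self.p_leq2_start(self.region_at_epo(j).start)

    # distance helpers working on order indices
    def d_spo(self, i: int, i2: int) -> int:
        """d(region at SPO i, region at SPO i2)."""
        return distance(self.region_at_spo(i), self.region_at_spo(i2))

    def d_to_epo(self, r: Region, j: int) -> int:
        return distance(r, self.region_at_epo(j))


def build_orderings(candidates: list[HelixCandidate]) -> CandidateIndex:
    """Build the SPO/EPO index over the candidates' regions."""
    return CandidateIndex(candidates)


def order_query(
    index: CandidateIndex,
    anchor: int,
    mode: str,
    bound: int = 1,
):
    """Order-structure query on a region id (entry id, not order index).

    Modes: ``succ_geq`` / ``pred_geq`` return one region id or None;
    ``succ_leq2`` / ``pred_leq2`` return a list of region ids.
    """
    if anchor not in index.spo_index:
        raise InputError(f"unknown region id {anchor}")
    if mode == "succ_geq":
        if bound < 1:
            raise InputError("bound must be >= 1")
        k = index.s_geq(index.spo_index[anchor], bound)
        return None if k is None else index.spo[k]
    if mode == "pred_geq":
        if bound < 1:
            raise InputError("bound must be >= 1")
        k = index.p_geq(index.epo_index[anchor], bound)
        return None if k is None else index.epo[k]
    if mode == "succ_leq2":
        return [index.spo[k] for k in index.s_leq2(index.spo_index[anchor])]
    if mode == "pred_leq2":
        return [index.epo[k] for k in index.p_leq2(index.epo_index[anchor])]
    raise InputError(f"unknown query mode {mode!r}")


def candidates_to_tsv(candidates: list[HelixCandidate]) -> str:
    """Candidate dump: id, start5, end5, start3, end3, n_pairs, energy_kcal, tier."""
    lines = ["id\tstart5\tend5\tstart3\tend3\tn_pairs\tenergy_kcal\ttier"]
    for c in candidates:
        lines.append(
            f"{c.id}\t{c.region5.start}\t{c.region5.end}\t{c.region3.start}\t"
            f"{c.region3.end}\t{c.n_pairs}\t{c.energy:.2f}\t{c.tier.name}"
        )
    return "\n".join(lines) + "\n"
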