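"""Synthetic planted-structure sequences and an exhaustive optimization oracle.

The generator emits sequences whose true structure is known by
construction: helices are planted as exact reverse complements arranged in
a user-given topology tree, loops are filled with an inert alphabet
(alternating A/C, or all-C in the designed all-AU stem mode), and the
joining gaps encode the wanted coaxial-stack k values.  Decoy
complementarity between segments that do not belong to one planted helix
is eliminated by a repair pass where feasible; whatever survives is
reported in the truth object.

The brute-force optimizer enumerates *every* admissible structure
(helix subset + coax-stack assignment) on a small instance and is the
correctness oracle for the dynamic program.  It deliberately shares no
recurrence decomposition with the DP: structures are enumerated as subsets
and validated against the structural rules directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .candidates import (
    CandidateIndex,
    FinderConfig,
    HelixCandidate,
    Region,
    find_helix_candidates,
)
from .dp import DPConfig, combined_tier_centi
from .energy import EnergyConfig, StabilityTier
from .errors import InputError
from .geometry import CoaxPair, StackKind

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class HelixPlan:
    """One planted helix: base-pair count, G+C content, optional 1-nt bulge."""

    n_bp: int
    gc_fraction: float = 1.0
    bulge: bool = False


@dataclass
class PlantNode:
    """A helix with its enclosed children and the loop gaps between them.

    ``gaps`` has ``len(children) + 1`` entries: unpaired nucleotides before
    the first child, between consecutive children, and after the last
    child.  For a leaf, ``gaps`` is a single entry — the hairpin loop
    length (>= 3).
    """

    helix: HelixPlan
    children: list = field(default_factory=list)
    gaps: list = field(default_factory=lambda: [4])


@dataclass
class PlantSpec:
    """A full planted instance: top-level nodes, outer gaps, RNG seed."""

    roots: list
    outer_gaps: list  # len(roots) + 1
    seed: int = 0


@dataclass(frozen=True)
class PlantedHelix:
    region5: Region
    region3: Region
    pairs: tuple


@dataclass(frozen=True)
class PlantedStack:
    x: int  # index into truth.helices
    y: int
    kind: StackKind
    k: int


@dataclass
class PlantedTruth:
    """Ground truth of a generated sequence."""

    pairs: frozenset
    helices: tuple  # PlantedHelix, preorder
    coax: tuple  # PlantedStack
    decoys: tuple = ()  # candidate pair-tuples not contained in any planted helix


def _helix_strands(plan: HelixPlan, rng) -> tuple[str, str, list]:
    """5' strand, 3' strand and within-helix pair offsets for one plan.

    Letters are drawn G/C with probability gc_fraction, A/U otherwise,
    with at least one strong pair forced; the generator's repair loop
    later re-orients pairs to remove accidental complementarity.

    ``gc_fraction == 0`` selects the designed all-AU mode: an alternating
    A/U stem with one same-letter doublet at a random phase.  Alternating
    AU/UA stacks are strong enough to reach the ultra-stable tier at
    >= 6 bp, while a G-free sequence cannot host semi-stable or stable
    decoys at all (both tiers require a G-C pair), and the doublet
    desynchronizes stems so no >= 6 bp cross-stem run survives.
    """
    letters: list[str] = []
    if plan.gc_fraction == 0:
        first = rng.choice("AU")
        letters = [("AU" if first == "A" else "UA")[i % 2] for i in range(plan.n_bp)]
        if plan.n_bp >= 4:
            d = rng.randrange(1, plan.n_bp)
            letters[d] = letters[d - 1]
    else:
        for idx in range(plan.n_bp):
            if rng.random() < plan.gc_fraction:
                letters.append(rng.choice("GC"))
            else:
                letters.append(rng.choice("AU"))
        if not any(c in "GC" for c in letters):
            letters[rng.randrange(len(letters))] = rng.choice("GC")
    s5 = list(letters)
    offsets5 = list(range(plan.n_bp))
    if plan.bulge and plan.n_bp >= 3:
        at = plan.n_bp // 2
        s5.insert(at, "C" if plan.gc_fraction == 0 else "A")  # bulged nt, never paired
        offsets5 = [o + (1 if o >= at else 0) for o in offsets5]
    s3 = [_COMPLEMENT[c] for c in reversed(letters)]
    return "".join(s5), "".join(s3), offsets5


def _loop_fill(n: int, au_mode: bool = False) -> str:
    # all-C loops are fully inert in a G-free (all-AU-stem) sequence;
    # otherwise alternate A/C, which cannot pair with itself
    if au_mode:
        return "C" * n
    return "".join("AC"[i % 2] for i in range(n))


def generate_planted_sequence(
    spec: PlantSpec, max_attempts: int = 3, repair_rounds: int = 40
):
    """Build (sequence, truth) for a planted topology; deterministic per seed.

    Each attempt draws fresh helix letters and then repairs accidental
    complementarity: while the candidate finder discovers a decoy helix,
    one position involved in it is re-oriented (a planted pair flips
    GC<->CG or AU<->UA, a loop letter flips A<->C), which preserves the
    planted structure and composition while breaking the decoy.  The
    first decoy-free draw is returned; otherwise the best draw, with the
    surviving decoys reported in ``truth.decoys``.
    """
    import random

    rng = random.Random(spec.seed)
    best = None
    for _ in range(max_attempts):
        seq, truth = _assemble(spec, rng)
        seq, truth = _repair(seq, truth, rng, repair_rounds)
        if not truth.decoys:
            return seq, truth
        if best is None or len(truth.decoys) < len(best[1].decoys):
            best = (seq, truth)
    return best


_FLIP = {"G": "C", "C": "G", "A": "U", "U": "A"}
_CANON = {"AU", "UA", "GC", "CG", "GU", "UG"}
_STRONG = {"GC", "CG"}


def _proxy_decoys(chars: list, boxes: list) -> int:
    """Cheap decoy objective: canonical 3-stacks with a strong pair whose
    positions do not all sit in one planted helix's L x H region box."""
    n = len(chars)
    cnt = 0
    for i in range(1, n - 1):
        for j in range(i + 8, n + 1):
            run = ((i, j), (i + 1, j - 1), (i + 2, j - 2))
            ok = True
            strong = False
            for a, b in run:
                p = chars[a - 1] + chars[b - 1]
                if p not in _CANON:
                    ok = False
                    break
                strong = strong or p in _STRONG
            if not (ok and strong):
                continue
            benign = any(
                all(l0 <= a <= l1 and h0 <= b <= h1 for a, b in run)
                for l0, l1, h0, h1 in boxes
            )
            if not benign:
                cnt += 1
    return cnt


def _repair(seq: str, truth: PlantedTruth, rng, rounds: int):
    """Greedy letter re-orientation until no decoy complementarity remains.

    Flips preserve the planted structure: a planted pair changes
    orientation (GC<->CG, AU<->UA), a loop letter swaps within the inert
    {A, C} alphabet.  Hill-climbs the proxy objective, then verifies with
    the real candidate finder.
    """
    chars = list(seq)
    partner = {}
    for h in truth.helices:
        for a, b in h.pairs:
            partner[a] = b
            partner[b] = a

    def flip(p: int):
        if p in partner:
            q = partner[p]
            chars[p - 1], chars[q - 1] = _FLIP[chars[p - 1]], _FLIP[chars[q - 1]]
        else:
            chars[p - 1] = "C" if chars[p - 1] == "A" else "A"

    flippable = sorted(
        {min(p, partner.get(p, p)) for p in range(1, len(chars) + 1)}
    )
    boxes = [
        (h.region5.start, h.region5.end, h.region3.start, h.region3.end)
        for h in truth.helices
    ]
    cur = _proxy_decoys(chars, boxes)
    for _ in range(rounds):
        if cur == 0:
            break
        order = list(flippable)
        rng.shuffle(order)
        improved = False
        for p in order:
            flip(p)
            new = _proxy_decoys(chars, boxes)
            if new < cur:
                cur = new
                improved = True
                break
            flip(p)  # revert
        if not improved:
            flip(order[0])  # random perturbation to escape a plateau
            cur = _proxy_decoys(chars, boxes)

    # phase 2: greedy descent on the true decoy count (catches bulged and
    # wobble-free decoys the trigram proxy cannot see), flipping only
    # planted pairs and never letting a planted helix drop in tier
    def tiers():
        from .energy import classify_tier, helix_free_energy_centi

        out = []
        s = "".join(chars)
        for h in truth.helices:
            cand = HelixCandidate(
                id=-1, region5=h.region5, region3=h.region3, pairs=h.pairs,
                n_gc=sum(1 for a, b in h.pairs if {s[a - 1], s[b - 1]} == {"G", "C"}),
            )
            ecfg = EnergyConfig()
            dg = helix_free_energy_centi(cand, s, ecfg)
            out.append(classify_tier(dg, len(h.pairs), cand.n_gc, ecfg))
        return out

    floor = tiers()
    decoys = find_decoys("".join(chars), truth)
    for _ in range(rounds):
        if not decoys:
            break
        positions = sorted(
            {p for d in decoys for ab in d for p in ab if p in partner}
        )
        rng.shuffle(positions)
        improved = False
        for p in positions:
            flip(p)
            if any(t < f for t, f in zip(tiers(), floor)):
                flip(p)
                continue
            nd = find_decoys("".join(chars), truth)
            if len(nd) < len(decoys):
                decoys = nd
                improved = True
                break
            flip(p)
        if not improved:
            break
    return "".join(chars), _with_decoys(truth, tuple(decoys))


def _with_decoys(truth: PlantedTruth, decoys: tuple) -> PlantedTruth:
    return PlantedTruth(
        pairs=truth.pairs, helices=truth.helices, coax=truth.coax, decoys=decoys
    )


def _all_plans(node: PlantNode):
    yield node.helix
    for c in node.children:
        yield from _all_plans(c)


def _assemble(spec: PlantSpec, rng):
    au_mode = all(
        p.gc_fraction == 0 for r in spec.roots for p in _all_plans(r)
    )
    helices: list[PlantedHelix] = []
    stacks: list[PlantedStack] = []
    chunks: list[str] = []
    pos = 0  # 0-based running length

    def emit(text: str):
        nonlocal pos
        chunks.append(text)
        pos += len(text)

    def build(node: PlantNode) -> int:
        """Emit one node; returns its index in ``helices``."""
        plan = node.helix
        s5, s3, off5 = _helix_strands(plan, rng)
        my_index = len(helices)
        helices.append(None)  # reserve preorder slot
        start5 = pos + 1
        emit(s5)
        child_idx: list[int] = []
        gaps = node.gaps
        if not node.children:
            if gaps[0] < 3:
                raise InputError("hairpin loop must be >= 3 nt")
            emit(_loop_fill(gaps[0], au_mode))
        else:
            if len(gaps) != len(node.children) + 1:
                raise InputError("need len(children)+1 gaps")
            for g, child in zip(gaps, node.children):
                emit(_loop_fill(g, au_mode))
                child_idx.append(build(child))
            emit(_loop_fill(gaps[-1], au_mode))
        start3 = pos + 1
        emit(s3)
        end3 = pos
        pairs = tuple(
            (start5 + o, end3 - i) for i, o in enumerate(off5)
        )
        helices[my_index] = PlantedHelix(
            region5=Region(start5, start5 + len(s5) - 1),
            region3=Region(start3, end3),
            pairs=pairs,
        )
        # planted coax joins: respect the one-stack-per-interface rule
        if node.children:
            inner_used = False
            if len(node.children) == 1:
                g5, g3 = gaps[0], gaps[-1]
                if g5 <= 1 and g3 <= 1 and not (g5 == 0 and g3 == 0):
                    stacks.append(
                        PlantedStack(my_index, child_idx[0], StackKind.NESTED, min(g5, g3))
                    )
                    inner_used = True
            else:
                outward_used = set()
                if gaps[0] <= 1:
                    stacks.append(
                        PlantedStack(my_index, child_idx[0], StackKind.NESTED, gaps[0])
                    )
                    inner_used = True
                    outward_used.add(child_idx[0])
                elif gaps[-1] <= 1:
                    stacks.append(
                        PlantedStack(my_index, child_idx[-1], StackKind.NESTED, gaps[-1])
                    )
                    inner_used = True
                    outward_used.add(child_idx[-1])
                for a, b, g in zip(child_idx, child_idx[1:], gaps[1:-1]):
                    if g <= 1 and a not in outward_used and b not in outward_used:
                        stacks.append(PlantedStack(a, b, StackKind.PARALLEL, g))
                        outward_used.update((a, b))
        return my_index

    if len(spec.outer_gaps) != len(spec.roots) + 1:
        raise InputError("need len(roots)+1 outer gaps")
    for g, root in zip(spec.outer_gaps, spec.roots):
        emit(_loop_fill(g, au_mode))
        build(root)
    emit(_loop_fill(spec.outer_gaps[-1], au_mode))
    seq = "".join(chunks)
    all_pairs = frozenset(p for h in helices for p in h.pairs)
    truth = PlantedTruth(
        pairs=all_pairs,
        helices=tuple(helices),
        coax=tuple(stacks),
    )
    return seq, truth


def find_decoys(
    seq: str,
    truth: PlantedTruth,
    fcfg: FinderConfig | None = None,
    ecfg: EnergyConfig | None = None,
) -> tuple:
    """Unintended helix candidates of ``seq``.

    A candidate is benign when every one of its pairs connects the two
    backbone regions of a single planted helix — that covers the planted
    helix itself, its sub-helices, and alternative registrations of the
    same two strands (shifted or bulged re-alignments), which are inherent
    to planting a strong helix and cannot be designed away.  Everything
    else — pairings that recruit loop nucleotides or bridge different
    planted helices — is a decoy the generator tries to eliminate.
    """
    boxes = [
        (h.region5.start, h.region5.end, h.region3.start, h.region3.end)
        for h in truth.helices
    ]
    out = []
    for cand in find_helix_candidates(seq, fcfg, ecfg):
        benign = any(
            all(l0 <= a <= l1 and h0 <= b <= h1 for a, b in cand.pairs)
            for l0, l1, h0, h1 in boxes
        )
        if not benign:
            out.append(cand.pairs)
    return tuple(out)


# ---------------------------------------------------------------------------
# structural-rule validator (shared by the oracle and the prediction auditor)
# ---------------------------------------------------------------------------


def _compatible(x: HelixCandidate, y: HelixCandidate) -> bool:
    return x.encloses(y) or y.encloses(x) or x.precedes(y) or y.precedes(x)


def _forest(selected: list[HelixCandidate]):
    """Parent map by tightest enclosure + ordered children lists."""
    parent: dict[int, int | None] = {}
    for c in selected:
        enclosers = [o for o in selected if o.encloses(c)]
        if enclosers:
            tight = min(enclosers, key=lambda o: o.region3.end - o.region5.start)
            parent[c.id] = tight.id
        else:
            parent[c.id] = None
    children: dict[int | None, list[HelixCandidate]] = {}
    for c in selected:
        children.setdefault(parent[c.id], []).append(c)
    for v in children.values():
        v.sort(key=lambda c: c.region5.start)
    return parent, children


def structure_violations(
    selected: list[HelixCandidate],
    stacks: set,
    nested: dict,
    parallel: dict,
    dcfg: DPConfig | None = None,
    ecfg: EnergyConfig | None = None,
) -> list[str]:
    """All rule violations of a structure; empty list means admissible.

    ``stacks`` holds keys (x_id, y_id, "N"|"P"); ``nested``/``parallel``
    map (x_id, y_id) to the enumerated CoaxPair.
    """
    dcfg = dcfg or DPConfig()
    ecfg = ecfg or EnergyConfig()
    v: list[str] = []
    by_id = {c.id: c for c in selected}
    for x, y in itertools.combinations(selected, 2):
        if not _compatible(x, y):
            v.append(f"helices {x.id},{y.id} overlap or cross")
    if v:
        return v
    parent, children = _forest(selected)

    def kids(cid) -> list[HelixCandidate]:
        return children.get(cid, [])

    def cs_of(x_id: int, y_id: int, kind: str) -> int:
        pair = (nested if kind == "N" else parallel).get((x_id, y_id))
        return pair.reward_centi if pair else 0

    # stack applicability + interface (port) usage
    inner_port: dict[int, int] = {}
    outer_port: dict[int, int] = {}
    for x_id, y_id, kind in stacks:
        if x_id not in by_id or y_id not in by_id:
            v.append(f"stack ({x_id},{y_id}) involves an unselected helix")
            continue
        if kind == "N":
            pair = nested.get((x_id, y_id))
            if pair is None:
                v.append(f"nested stack ({x_id},{y_id}) was never enumerated")
                continue
            if parent.get(y_id) != x_id:
                v.append(f"nested stack ({x_id},{y_id}): X is not Y's parent")
                continue
            sibs = kids(x_id)
            if len(sibs) == 1:
                if not (pair.d_left <= 2 and pair.d_right <= 2):
                    v.append(f"2-way stack ({x_id},{y_id}) with a join > 2")
            else:
                if by_id[y_id] is sibs[0] and pair.d_left <= 2:
                    pass
                elif by_id[y_id] is sibs[-1] and pair.d_right <= 2:
                    pass
                else:
                    v.append(
                        f"m-way nested stack ({x_id},{y_id}): Y not an outermost "
                        "child with join <= 2"
                    )
            inner_port[x_id] = inner_port.get(x_id, 0) + 1
            outer_port[y_id] = outer_port.get(y_id, 0) + 1
        else:
            pair = parallel.get((x_id, y_id))
            if pair is None or pair.d_join > 2:
                v.append(f"parallel stack ({x_id},{y_id}) not admissible")
                continue
            p = parent.get(x_id)
            if p is None or parent.get(y_id) != p:
                v.append(f"parallel stack ({x_id},{y_id}): not siblings under a helix")
                continue
            sibs = kids(p)
            ix_, iy_ = sibs.index(by_id[x_id]), sibs.index(by_id[y_id])
            if iy_ != ix_ + 1:
                v.append(f"parallel stack ({x_id},{y_id}): not adjacent siblings")
            outer_port[x_id] = outer_port.get(x_id, 0) + 1
            outer_port[y_id] = outer_port.get(y_id, 0) + 1
    for cid, n in inner_port.items():
        if n > 1:
            v.append(f"helix {cid}: loop-side interface used {n} times")
    for cid, n in outer_port.items():
        if n > 1:
            v.append(f"helix {cid}: outward interface used {n} times")
    if v:
        return v

    stacked = {(x, y) for x, y, _ in stacks}

    # per-junction rules
    for p in selected:
        cs_list = kids(p.id)
        if not cs_list:
            continue
        if len(cs_list) == 1:
            c = cs_list[0]
            d5 = c.region5.start - p.region5.end
            d3 = p.region3.start - c.region3.end
            if d5 > dcfg.internal_loop_side_max or d3 > dcfg.internal_loop_side_max:
                v.append(f"2-way {p.id}->{c.id}: side distance > {dcfg.internal_loop_side_max}")
            if abs(d5 - d3) > dcfg.internal_loop_asymmetry_max:
                v.append(f"2-way {p.id}->{c.id}: asymmetry > {dcfg.internal_loop_asymmetry_max}")
            if dcfg.forbid_both_zero and d5 == 1 and d3 == 1:
                v.append(f"2-way {p.id}->{c.id}: both strands free of unpaired nt")
            cs = cs_of(p.id, c.id, "N") if (p.id, c.id) in stacked else 0
            if combined_tier_centi(p, c, cs, ecfg) < StabilityTier.STABLE:
                v.append(f"2-way {p.id}->{c.id}: combined pair below stable")
        else:
            ultra_ok = p.tier == StabilityTier.ULTRA_STABLE
            gp = parent.get(p.id)
            if not ultra_ok and gp is not None and len(kids(gp)) == 1:
                cs = cs_of(gp, p.id, "N") if (gp, p.id) in stacked else 0
                ultra_ok = (
                    combined_tier_centi(by_id[gp], p, cs, ecfg)
                    >= StabilityTier.ULTRA_STABLE
                )
            if not ultra_ok:
                v.append(f"m-way junction under {p.id}: encloser not ultra-acting")
            d_left = cs_list[0].region5.start - p.region5.end
            d_right = p.region3.start - cs_list[-1].region3.end
            if (p.id, cs_list[0].id) in stacked:
                if d_left > 2:
                    v.append(f"left join {p.id}->{cs_list[0].id} > 2")
            elif d_left < 2:
                v.append(f"m-way under {p.id}: unstacked left boundary at distance 1")
            if (p.id, cs_list[-1].id) in stacked:
                if d_right > 2:
                    v.append(f"right join {p.id}->{cs_list[-1].id} > 2")
            elif d_right < 2:
                v.append(f"m-way under {p.id}: unstacked right boundary at distance 1")

    # root rules: top-level junctions carry no constraint between roots, but
    # a bare top-level helix must be stable and a top-level m-way encloser
    # must itself be ultra-stable (no combined exception without a parent)
    for r in kids(None):
        n = len(kids(r.id))
        if n == 0 and r.tier < StabilityTier.STABLE:
            v.append(f"bare top-level helix {r.id} below stable")
        if n >= 2 and r.tier != StabilityTier.ULTRA_STABLE:
            v.append(f"top-level m-way encloser {r.id} not ultra-stable")

    # semi-stable usage
    for c in selected:
        if c.tier != StabilityTier.SEMI_STABLE:
            continue
        if len(kids(c.id)) == 1:
            continue  # 2-way parent; combined condition checked at the link
        par = parent.get(c.id)
        if par is not None and len(kids(par)) == 1:
            continue  # only child of a 2-way junction
        if kids(c.id):
            continue  # >= 2 children: the m-way rule already rejected it
        partners = [
            (y if x == c.id else x)
            for x, y, _ in stacks
            if c.id in (x, y)
        ]
        if not any(by_id[p].tier >= StabilityTier.STABLE for p in partners):
            v.append(f"semi-stable helix {c.id} without a stable stack partner")
    return v


@dataclass
class BruteResult:
    score_centi: int
    optima: list  # (frozenset helix ids, frozenset stack keys)

    @property
    def score(self) -> float:
        return self.score_centi / 100.0


def brute_force_optimum(
    index: CandidateIndex,
    coax: list[CoaxPair],
    dcfg: DPConfig | None = None,
    ecfg: EnergyConfig | None = None,
    max_regions: int = 12,
) -> BruteResult:
    """Exhaustive optimum over all admissible structures of a small instance.

    Enumerates every nucleotide-disjoint, non-crossing helix subset and
    every coax-stack assignment passing the structural rules; returns the
    maximum total score (helix weights + CS rewards, centi-kcal/mol) with
    all optimal witnesses.  Empty structure scores 0.
    """
    if index.n_regions > max_regions:
        raise InputError(
            f"instance has {index.n_regions} regions; brute force is limited "
            f"to {max_regions}"
        )
    dcfg = dcfg or DPConfig()
    ecfg = ecfg or EnergyConfig()
    nested = {(p.x_id, p.y_id): p for p in coax if p.kind == StackKind.NESTED}
    parallel = {(p.x_id, p.y_id): p for p in coax if p.kind == StackKind.PARALLEL}
    cands = index.candidates
    best = 0
    optima: list = [(frozenset(), frozenset())]
    for r in range(1, len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            sel = list(combo)
            if any(
                not _compatible(a, b) for a, b in itertools.combinations(sel, 2)
            ):
                continue
            ids = {c.id for c in sel}
            instances = [
                key
                for key in (
                    [(x, y, "N") for (x, y) in nested if x in ids and y in ids]
                    + [(x, y, "P") for (x, y) in parallel if x in ids and y in ids]
                )
            ]
            base = sum(-c.energy_centi for c in sel)
            for m in range(len(instances) + 1):
                for stks in itertools.combinations(instances, m):
                    sset = set(stks)
                    if structure_violations(sel, sset, nested, parallel, dcfg, ecfg):
                        continue
                    score = base + sum(
                        (nested if k == "N" else parallel)[(x, y)].reward_centi
                        for x, y, k in sset
                    )
                    if score > best:
                        best = score
                        optima = [(frozenset(ids), frozenset(sset))]
                    elif score == best:
                        optima.append((frozenset(ids), frozenset(sset)))
    return BruteResult(score_centi=best, optima=optima)


def audit_prediction(
    pred,
    index: CandidateIndex,
    coax: list[CoaxPair],
    dcfg: DPConfig | None = None,
    ecfg: EnergyConfig | None = None,
) -> list[str]:
    """Independent rule audit of a Prediction; returns violations (empty = ok)."""
    nested = {(p.x_id, p.y_id): p for p in coax if p.kind == StackKind.NESTED}
    parallel = {(p.x_id, p.y_id): p for p in coax if p.kind == StackKind.PARALLEL}
    selected = [index.by_id[cid] for cid in pred.helices]
    stacks = {
        (p.x_id, p.y_id, "N" if p.kind == StackKind.NESTED else "P")
        for p in pred.coax_stacks
    }
    v = structure_violations(selected, stacks, nested, parallel, dcfg, ecfg)
    # score must decompose exactly into weights + rewards
    total = sum(-c.energy_centi for c in selected) + sum(
        (nested if k == "N" else parallel)[(x, y)].reward_centi
        for x, y, k in stacks
    )
    if total != pred.score_centi:
        v.append(f"score {pred.score_centi} != decomposition {total}")
    seen_nt: set[int] = set()
    for c in selected:
        for a, b in c.pairs:
            if a in seen_nt or b in seen_nt:
                v.append(f"nucleotide reused by helix {c.id}")
            seen_nt.update((a, b))
    return v


def random_plant_spec(rng) -> PlantSpec:
    """A small random planted topology for oracle cross-checks.

    Most instances use the designed all-AU stem mode, which keeps the
    candidate set close to the planted helices so that multi-helix
    topologies (where coaxial stacks arise) stay within the exhaustive
    oracle's size limit; the rest draw mixed-composition stems to cover
    the G-C-dependent tier rules.
    """
    au = rng.random() < 0.6

    def plan(lo: int = 3, hi: int = 7) -> HelixPlan:
        if au:
            return HelixPlan(rng.randint(6, 8), 0.0)
        return HelixPlan(rng.randint(lo, hi), rng.choice([0.5, 0.8, 1.0]))

    def leaf() -> PlantNode:
        return PlantNode(plan(), gaps=[rng.randint(3, 6)])

    def gap() -> int:
        return rng.choice([0, 0, 1, 1, 2, 3, 5])

    shape = rng.randrange(6)
    if shape == 0:  # single hairpin
        roots = [leaf()]
    elif shape == 1:  # two top-level hairpins
        roots = [leaf(), leaf()]
    elif shape == 2:  # 2-way chain
        roots = [PlantNode(plan(3, 6), [leaf()], [gap(), gap()])]
    elif shape == 3:  # 3-way junction
        roots = [PlantNode(plan(6, 8), [leaf(), leaf()], [gap(), gap(), gap()])]
    elif shape == 4:  # 4-way junction (cloverleaf-like)
        roots = [
            PlantNode(
                plan(6, 8),
                [leaf(), leaf(), leaf()],
                [gap(), gap(), gap(), gap()],
            )
        ]
    else:  # chain of three
        inner = PlantNode(plan(3, 5), [leaf()], [gap(), gap()])
        roots = [PlantNode(plan(3, 6), [inner], [gap(), gap()])]
    outer = [rng.choice([0, 1, 2]) for _ in range(len(roots) + 1)]
    return PlantSpec(roots=roots, outer_gaps=outer, seed=rng.randrange(2**31))
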