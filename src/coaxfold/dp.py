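"""Helix-level dynamic program for simultaneous structure and coax prediction.

The optimizer works on candidate *regions* ordered two ways (SPO by start,
EPO by end).  A cell (i, j) covers the subsequence from the start of the
region with SPO index i to the end of the region with EPO index j, and the
twelve mutually recursive scoring functions fill one table each:

``M``          top level, not enclosed by any helix (score 0 allowed);
``ST``         regions i and j form the enclosing helix of the cell;
``M2W``/``M2WB``   interior of a 2-way junction chain (B: the helix
               immediately encloses an m-way junction, m > 2, legitimized
               by a combined-ultra 2-way pair);
``Mee``/``MeeB``   junction interior with no coax obligation crossing the
               cell boundary (B: immediate bifurcation);
``MateB``/``MetaB``  junction interior whose left-most (right-most) helix
               stacks with the enclosing helix (left/right nested coax);
``Mep``/``MepB``   the right-most helix has a pending parallel stack with a
               helix right of the cell;
``Mpe``/``MpeB``   mirror, pending to the left.

The pending-parallel functions are refined into an "ok" and a "weak"
channel: the weak channel carries a bare semi-stable leaf as the pending
helix, which is admissible only when the discharging partner's own tier is
at least STABLE (the semi-stable usage rule).  Likewise MatB/MetB carry a
flag telling whether the enclosing helix is strong enough to legitimize a
bare semi-stable leaf as the stacked child.

Scores are integers (centi-kcal/mol of stabilization): the weight of a
helix is its negated free energy, a coaxial stack adds its CS reward.
Structural rules enforced by construction:

* a bare helix with no junction role must be STABLE or better;
* every 2-way junction link obeys the internal-loop geometry bounds
  (per-side distance <= 11, asymmetry <= 4, connecting strands not both
  free of unpaired nucleotides) and the combined pair must act as a
  stable helix (ultra-stable to enclose a further m-way junction);
* an m-way junction (m > 2) is enclosed only by an ultra-stable helix or
  a combined-ultra 2-way pair; its boundary strands keep distance >= 2
  from the enclosing helix except on a side carrying a nested coax join
  (distance <= 2, i.e. k <= 1);
* parallel stacks occur only between adjacent helices inside an enclosed
  m-way junction; top-level junctions carry no coax;
* every coaxial stack consumes one interface of each partner (loop-side
  for stacking with an enclosed helix, outward otherwise), one stack per
  interface.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

from .candidates import CandidateIndex, HelixCandidate
from .energy import EnergyConfig, StabilityTier, classify_tier
from .errors import InputError, InternalConsistencyError
from .geometry import CoaxPair, StackKind

NEG = -(10**12)  # -infinity sentinel for integer scores


def _fin(v: int) -> bool:
    """True for a real score; sums involving the -inf sentinel fail this."""
    return v > NEG // 2


@dataclass
class DPConfig:
    """Geometry bounds of the prediction-phase recurrences."""

    internal_loop_side_max: int = 11
    internal_loop_asymmetry_max: int = 4
    forbid_both_zero: bool = True

    def __post_init__(self) -> None:
        if self.internal_loop_side_max < 1 or self.internal_loop_asymmetry_max < 0:
            raise InputError("internal-loop bounds must be positive")


@dataclass
class Prediction:
    """A predicted structure: base pairs, helices, coax stacks, total score."""

    pairs: frozenset
    helices: tuple
    coax_stacks: tuple
    score_centi: int

    @property
    def score(self) -> float:
        return self.score_centi / 100.0


def helix_weight(
    index: CandidateIndex, i: int, j: int, filter: str = "ANY"
) -> float:
    """Weight of the helix formed by SPO region i and EPO region j.

    Returns the negated free energy (kcal/mol, positive for stabilizing
    helices) when such a candidate exists and its tier meets the filter
    (ANY / STABLE / ULTRA), else -inf.
    """
    cand = index.candidate_at(i, j)
    if cand is None:
        return float("-inf")
    floor = {
        "ANY": StabilityTier.SEMI_STABLE,
        "STABLE": StabilityTier.STABLE,
        "ULTRA": StabilityTier.ULTRA_STABLE,
    }[filter]
    if cand.tier < floor:
        return float("-inf")
    return -cand.energy_centi / 100.0


def combined_tier_centi(
    outer: HelixCandidate, inner: HelixCandidate, cs_centi: int, ecfg: EnergyConfig
) -> StabilityTier:
    """Tier of a 2-way pair treated as one virtual helix (integer energies)."""
    dg = outer.energy_centi + inner.energy_centi - cs_centi
    return classify_tier(dg, outer.n_pairs + inner.n_pairs, outer.n_gc + inner.n_gc, ecfg)


def combined_strength(
    outer: HelixCandidate, inner: HelixCandidate, cs: float = 0.0,
    ecfg: EnergyConfig | None = None,
) -> StabilityTier:
    """Stability tier of outer+inner acting together across a 2-way junction.

    ``cs`` is the coaxial-stack reward magnitude in kcal/mol (0 when the
    pair does not stack); it deepens the combined free energy.
    """
    if not outer.encloses(inner):
        raise InputError("combined strength requires outer to enclose inner")
    return combined_tier_centi(outer, inner, round(cs * 100), ecfg or EnergyConfig())


@dataclass
class DPTables:
    """Filled score tables + backpointers, keyed by (function, i, j[, flag])."""

    cells: dict
    index: CandidateIndex
    top: tuple | None  # key of the optimum cell ("M", 0, N-1), None if empty


class _Solver:
    def __init__(
        self,
        index: CandidateIndex,
        coax: list[CoaxPair],
        cfg: DPConfig,
        ecfg: EnergyConfig,
    ):
        self.ix = index
        self.cfg = cfg
        self.ecfg = ecfg
        self.N = index.n_regions
        self.b_s = [index.region_at_spo(i).start for i in range(self.N)]
        self.e_s = [index.region_at_spo(i).end for i in range(self.N)]
        self.b_e = [index.region_at_epo(j).start for j in range(self.N)]
        self.e_e = [index.region_at_epo(j).end for j in range(self.N)]
        self.nested = {
            (p.x_id, p.y_id): p for p in coax if p.kind == StackKind.NESTED
        }
        self.parallel = {
            (p.x_id, p.y_id): p for p in coax if p.kind == StackKind.PARALLEL
        }
        # candidate owning an order position as its L (resp. H) region
        self.cand_L_at_spo: dict[int, HelixCandidate] = {}
        self.cand_H_at_epo: dict[int, HelixCandidate] = {}
        for k, c in enumerate(index.candidates):
            self.cand_L_at_spo[index.spo_index[2 * k]] = c
            self.cand_H_at_epo[index.epo_index[2 * k + 1]] = c
        # inner-candidate iteration order for the 2-way cases
        self.cand_cells = sorted(
            ((i, j, index.by_id[cid]) for (i, j), cid in index.pair_map.items()),
            key=lambda t: (t[0], t[1]),
        )
        self.memo: dict = {}

    # -- helpers ---------------------------------------------------------
    def w(self, cand: HelixCandidate) -> int:
        return -cand.energy_centi

    def A(self, i: int, j: int) -> HelixCandidate | None:
        return self.ix.candidate_at(i, j)

    def _best(self, cases):
        """Max over (value, bp) case terms; first-listed wins ties."""
        best_v, best_bp = NEG, None
        for v, bp in cases:
            if v > best_v:
                best_v, best_bp = v, bp
        return best_v, best_bp

    def _geometry_ok(self, d5: int, d3: int) -> bool:
        c = self.cfg
        if d5 > c.internal_loop_side_max or d3 > c.internal_loop_side_max:
            return False
        if abs(d5 - d3) > c.internal_loop_asymmetry_max:
            return False
        if c.forbid_both_zero and d5 == 1 and d3 == 1:
            return False
        return True

    def _inner_cells(self, i: int, j: int):
        """Inner candidates strictly inside cell (i, j) with their distances."""
        for i2, j2, cand in self.cand_cells:
            d5 = cand.region5.start - self.e_s[i]
            d3 = self.b_e[j] - cand.region3.end
            if d5 >= 1 and d3 >= 1:
                yield i2, j2, cand, d5, d3

    def _split_ks(self, start_b: int, j: int):
        """EPO split points k inside a cell starting at coordinate start_b."""
        for k in range(j):
            if self.b_e[k] >= start_b:
                yield k

    # -- memoized evaluation ---------------------------------------------
    def val(self, key) -> int:
        return self.cell(key)[0]

    def cell(self, key):
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        self.memo[key] = (NEG, None)  # cycle guard; never legitimately read
        fn = key[0]
        res = getattr(self, "_" + fn)(*key[1:])
        self.memo[key] = res
        return res

    def _dead(self, i: int, j: int) -> bool:
        return i >= self.N or j < 0 or self.b_s[i] > self.e_e[j]

    def _maxB_ee(self, i: int, j: int):
        """max{Mee, MeeB}(i, j) with its backpointer child key."""
        a = self.val(("Mee", i, j))
        b = self.val(("MeeB", i, j))
        if a >= b:
            return a, ("Mee", i, j)
        return b, ("MeeB", i, j)

    # -- M ----------------------------------------------------------------
    def _M(self, i: int, j: int):
        if self._dead(i, j):
            return 0, ("empty", (), (), ())
        cases = []
        cand = self.A(i, j)
        if cand is not None and cand.tier >= StabilityTier.STABLE:
            cases.append((self.w(cand), ("S", (cand.id,), (), ())))
        cases.append((self.val(("M", i + 1, j)), ("skip_i", (), (), (("M", i + 1, j),))))
        cases.append((self.val(("M", i, j - 1)), ("skip_j", (), (), (("M", i, j - 1),))))
        for k in self._split_ks(self.b_s[i], j):
            s1 = self.ix.s_geq_end(self.e_e[k], 1)
            if s1 is None:
                continue
            v = self.val(("M", i, k)) + self.val(("M", s1, j))
            cases.append((v, ("bifurcate", (), (), (("M", i, k), ("M", s1, j)))))
        cases.append((self.val(("ST", i, j)), ("ST", (), (), (("ST", i, j),))))
        return self._best(cases)

    # -- shared case families ---------------------------------------------
    def _twoway_cases(self, i, j, X):
        """ST cases 1-4 / M2W cases 2-5: X encloses a 2-way junction chain."""
        ST_, UL = StabilityTier.STABLE, StabilityTier.ULTRA_STABLE
        wX = self.w(X)
        inner = list(self._inner_cells(i, j))
        cases = []
        for i2, j2, Y, d5, d3 in inner:  # case: 2W, no coax, combined stable
            if self._geometry_ok(d5, d3) and combined_tier_centi(X, Y, 0, self.ecfg) >= ST_:
                v = self.val(("M2W", i2, j2))
                if _fin(v):
                    cases.append(
                        (wX + v, ("2w", (X.id,), (), (("M2W", i2, j2),)))
                    )
        for i2, j2, Y, d5, d3 in inner:  # case: 2WB, no coax, combined ultra
            if self._geometry_ok(d5, d3) and combined_tier_centi(X, Y, 0, self.ecfg) >= UL:
                v = self.val(("M2WB", i2, j2))
                if _fin(v):
                    cases.append(
                        (wX + v, ("2wb", (X.id,), (), (("M2WB", i2, j2),)))
                    )
        for with_b, tier_floor, tag in ((False, ST_, "2w_cs"), (True, UL, "2wb_cs")):
            for i2, j2, Y, d5, d3 in inner:  # cases: 2W/2WB with coax
                if d5 > 2 or d3 > 2 or not self._geometry_ok(d5, d3):
                    continue
                pair = self.nested.get((X.id, Y.id))
                if pair is None:
                    continue
                cs = pair.reward_centi
                if combined_tier_centi(X, Y, cs, self.ecfg) < tier_floor:
                    continue
                child = ("M2WB", i2, j2) if with_b else ("M2W", i2, j2)
                v = self.val(child)
                if _fin(v):
                    cases.append(
                        (wX + v + cs,
                         (tag, (X.id,), ((X.id, Y.id, "N"),), (child,)))
                    )
        return cases

    def _multiway_cases(self, i, j, X):
        """ST cases 5-8 / M2WB cases 1-4: X encloses an m-way junction, m > 2."""
        wX = self.w(X)
        allow_semi = X.tier >= StabilityTier.STABLE
        cases = []
        s2 = self.ix.s_geq(i, 2)
        p2 = self.ix.p_geq(j, 2)
        # left nested coax: stacked child starts at distance <= 2 from i
        if p2 is not None:
            for s in self.ix.s_leq2(i):
                Y = self.cand_L_at_spo.get(s)
                if Y is None:
                    continue
                pair = self.nested.get((X.id, Y.id))
                if pair is None or pair.d_left > 2:
                    continue
                key = ("MatB", s, p2, allow_semi)
                v = self.val(key)
                if _fin(v):
                    cases.append(
                        (wX + v + pair.reward_centi,
                         ("left_cs", (X.id,), ((X.id, Y.id, "N"),), (key,)))
                    )
        # right nested coax
        if s2 is not None:
            for p in self.ix.p_leq2(j):
                Y = self.cand_H_at_epo.get(p)
                if Y is None:
                    continue
                pair = self.nested.get((X.id, Y.id))
                if pair is None or pair.d_right > 2:
                    continue
                key = ("MetB", s2, p, allow_semi)
                v = self.val(key)
                if _fin(v):
                    cases.append(
                        (wX + v + pair.reward_centi,
                         ("right_cs", (X.id,), ((X.id, Y.id, "N"),), (key,)))
                    )
        if s2 is not None and p2 is not None:
            # plain m-way bifurcation
            for k in self._split_ks(self.b_s[s2], p2):
                s1 = self.ix.s_geq_end(self.e_e[k], 1)
                if s1 is None:
                    continue
                lv, lk = self._maxB_ee(s2, k)
                rv, rk = self._maxB_ee(s1, p2)
                if _fin(lv) and _fin(rv):
                    cases.append(
                        (wX + lv + rv, ("mway", (X.id,), (), (lk, rk)))
                    )
            # m-way with an internal parallel stack at the split
            for k in self._split_ks(self.b_s[s2], p2):
                XL = self.cand_H_at_epo.get(k)
                if XL is None:
                    continue
                for s in self.ix.s_leq2_end(self.e_e[k]):
                    YR = self.cand_L_at_spo.get(s)
                    if YR is None:
                        continue
                    ppair = self.parallel.get((XL.id, YR.id))
                    if ppair is None:
                        continue
                    for v, bp in self._parallel_split(
                        ("Mep", "MepB", s2, k), ("Mpe", "MpeB", s, p2), XL, YR
                    ):
                        cases.append(
                            (wX + v + ppair.reward_centi,
                             ("mway_cs", (X.id,),
                              ((XL.id, YR.id, "P"),), bp))
                        )
        return cases

    def _parallel_split(self, left, right, XL, YR):
        """Channel-checked combinations of a pending-parallel discharge.

        left/right = (fn, fnB, a, b); the weak channel (bare semi-stable
        pending leaf) is admitted only when the partner tier is >= STABLE.
        """
        lf, lfB, la, lb = left
        rf, rfB, ra, rb = right
        out = []
        combos = [("ok", "ok")]
        if YR.tier >= StabilityTier.STABLE:
            combos.append(("weak", "ok"))
        if XL.tier >= StabilityTier.STABLE:
            combos.append(("ok", "weak"))
        for lch, rch in combos:
            lv, lk = self._max_pair((lf, la, lb, lch), (lfB, la, lb, lch))
            rv, rk = self._max_pair((rf, ra, rb, rch), (rfB, ra, rb, rch))
            if not (_fin(lv) and _fin(rv)):
                continue
            out.append((lv + rv, (lk, rk)))
        return out

    def _max_pair(self, key_a, key_b):
        a, b = self.val(key_a), self.val(key_b)
        if a >= b:
            return a, key_a
        return b, key_b

    # -- ST ----------------------------------------------------------------
    def _ST(self, i: int, j: int):
        X = self.A(i, j)
        if X is None:
            return NEG, None
        cases = self._twoway_cases(i, j, X)
        if X.tier == StabilityTier.ULTRA_STABLE:
            cases.extend(self._multiway_cases(i, j, X))
        return self._best(cases)

    # -- M2W / M2WB --------------------------------------------------------
    def _M2W(self, i: int, j: int):
        X = self.A(i, j)
        if X is None:
            return NEG, None
        cases = [(self.w(X), ("bare", (X.id,), (), ()))]
        cases.extend(self._twoway_cases(i, j, X))
        return self._best(cases)

    def _M2WB(self, i: int, j: int):
        X = self.A(i, j)
        if X is None:
            return NEG, None
        return self._best(self._multiway_cases(i, j, X))

    # -- Mee / MeeB ---------------------------------------------------------
    def _Mee(self, i: int, j: int):
        if self._dead(i, j):
            return NEG, None
        cases = []
        cand = self.A(i, j)
        if cand is not None and cand.tier >= StabilityTier.STABLE:
            cases.append((self.w(cand), ("S", (cand.id,), (), ())))
        cases.append((self.val(("Mee", i + 1, j)), ("skip_i", (), (), (("Mee", i + 1, j),))))
        cases.append((self.val(("Mee", i, j - 1)), ("skip_j", (), (), (("Mee", i, j - 1),))))
        cases.append((self.val(("ST", i, j)), ("ST", (), (), (("ST", i, j),))))
        return self._best(cases)

    def _MeeB(self, i: int, j: int):
        if self._dead(i, j):
            return NEG, None
        cases = []
        for k in self._split_ks(self.b_s[i], j):
            s1 = self.ix.s_geq_end(self.e_e[k], 1)
            if s1 is None:
                continue
            lv, lk = self._maxB_ee(i, k)
            rv, rk = self._maxB_ee(s1, j)
            if _fin(lv) and _fin(rv):
                cases.append((lv + rv, ("bif", (), (), (lk, rk))))
        for k in self._split_ks(self.b_s[i], j):
            XL = self.cand_H_at_epo.get(k)
            if XL is None:
                continue
            for s in self.ix.s_leq2_end(self.e_e[k]):
                YR = self.cand_L_at_spo.get(s)
                if YR is None:
                    continue
                ppair = self.parallel.get((XL.id, YR.id))
                if ppair is None:
                    continue
                for v, bp in self._parallel_split(
                    ("Mep", "MepB", i, k), ("Mpe", "MpeB", s, j), XL, YR
                ):
                    cases.append(
                        (v + ppair.reward_centi,
                         ("bif_cs", (), ((XL.id, YR.id, "P"),), bp))
                    )
        return self._best(cases)

    # -- left/right nested junction interiors --------------------------------
    def _MatB(self, i: int, j: int, allow_semi: bool):
        """Junction interior whose first helix starts exactly at region i and
        stacks with the enclosing helix (left nested); >= 2 helices."""
        if self._dead(i, j):
            return NEG, None
        cases = []
        for k in range(j + 1):
            first = []
            Z = self.A(i, k)
            if Z is not None and (allow_semi or Z.tier >= StabilityTier.STABLE):
                first.append((self.w(Z), ("leaf", (Z.id,), (), ())))
            stv = self.val(("ST", i, k))
            first.append((stv, ("st", (), (), (("ST", i, k),))))
            fv, fbp = self._best(first)
            if not _fin(fv):
                continue
            s1 = self.ix.s_geq_end(self.e_e[k], 1)
            if s1 is None:
                continue
            rv, rk = self._maxB_ee(s1, j)
            if _fin(rv):
                cases.append(
                    (fv + rv,
                     ("at", fbp[1], (), tuple(fbp[3]) + (rk,)))
                )
        return self._best(cases)

    def _MetB(self, i: int, j: int, allow_semi: bool):
        """Mirror of MatB: last helix ends exactly at region j and stacks
        with the enclosing helix (right nested)."""
        if self._dead(i, j):
            return NEG, None
        cases = []
        for k in range(i, self.N):
            last = []
            Z = self.A(k, j)
            if Z is not None and (allow_semi or Z.tier >= StabilityTier.STABLE):
                last.append((self.w(Z), ("leaf", (Z.id,), (), ())))
            last.append((self.val(("ST", k, j)), ("st", (), (), (("ST", k, j),))))
            lv2, lbp = self._best(last)
            if not _fin(lv2):
                continue
            p1 = self.ix.p_geq_start(self.b_s[k], 1)
            if p1 is None:
                continue
            lv, lk = self._maxB_ee(i, p1)
            if _fin(lv):
                cases.append(
                    (lv + lv2,
                     ("et", lbp[1], (), (lk,) + tuple(lbp[3])))
                )
        return self._best(cases)

    # -- pending-parallel functions -------------------------------------------
    def _Mep(self, i: int, j: int, ch: str):
        if self._dead(i, j):
            return NEG, None
        cases = []
        cand = self.A(i, j)
        if cand is not None:
            if (ch == "ok" and cand.tier >= StabilityTier.STABLE) or (
                ch == "weak" and cand.tier == StabilityTier.SEMI_STABLE
            ):
                cases.append((self.w(cand), ("A", (cand.id,), (), ())))
        cases.append(
            (self.val(("Mep", i + 1, j, ch)), ("skip_i", (), (), (("Mep", i + 1, j, ch),)))
        )
        if ch == "ok":
            cases.append((self.val(("ST", i, j)), ("ST", (), (), (("ST", i, j),))))
        return self._best(cases)

    def _Mpe(self, i: int, j: int, ch: str):
        if self._dead(i, j):
            return NEG, None
        cases = []
        cand = self.A(i, j)
        if cand is not None:
            if (ch == "ok" and cand.tier >= StabilityTier.STABLE) or (
                ch == "weak" and cand.tier == StabilityTier.SEMI_STABLE
            ):
                cases.append((self.w(cand), ("A", (cand.id,), (), ())))
        cases.append(
            (self.val(("Mpe", i, j - 1, ch)), ("skip_j", (), (), (("Mpe", i, j - 1, ch),)))
        )
        if ch == "ok":
            cases.append((self.val(("ST", i, j)), ("ST", (), (), (("ST", i, j),))))
        return self._best(cases)

    def _MepB(self, i: int, j: int, ch: str):
        if self._dead(i, j):
            return NEG, None
        cases = [
            (self.val(("MepB", i + 1, j, ch)), ("skip_i", (), (), (("MepB", i + 1, j, ch),)))
        ]
        for k in self._split_ks(self.b_s[i], j):
            s1 = self.ix.s_geq_end(self.e_e[k], 1)
            if s1 is None:
                continue
            lv, lk = self._maxB_ee(i, k)
            rv, rk = self._max_pair(("Mep", s1, j, ch), ("MepB", s1, j, ch))
            if _fin(lv) and _fin(rv):
                cases.append((lv + rv, ("bif", (), (), (lk, rk))))
        return self._best(cases)

    def _MpeB(self, i: int, j: int, ch: str):
        if self._dead(i, j):
            return NEG, None
        cases = [
            (self.val(("MpeB", i, j - 1, ch)), ("skip_j", (), (), (("MpeB", i, j - 1, ch),)))
        ]
        for k in self._split_ks(self.b_s[i], j):
            s1 = self.ix.s_geq_end(self.e_e[k], 1)
            if s1 is None:
                continue
            lv, lk = self._max_pair(("Mpe", i, k, ch), ("MpeB", i, k, ch))
            rv, rk = self._maxB_ee(s1, j)
            if _fin(lv) and _fin(rv):
                cases.append((lv + rv, ("bif", (), (), (lk, rk))))
        return self._best(cases)


def fill_tables(
    index: CandidateIndex,
    coax: list[CoaxPair],
    cfg: DPConfig | None = None,
    ecfg: EnergyConfig | None = None,
) -> DPTables:
    """Fill the twelve recurrence tables; the optimum sits in M(1, N)."""
    cfg = cfg or DPConfig()
    ecfg = ecfg or EnergyConfig()
    solver = _Solver(index, coax, cfg, ecfg)
    if solver.N == 0:
        return DPTables(cells={}, index=index, top=None)
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000 + 40 * solver.N * solver.N))
    try:
        top = ("M", 0, solver.N - 1)
        solver.cell(top)
    finally:
        sys.setrecursionlimit(old)
    tables = DPTables(cells=solver.memo, index=index, top=top)
    tables._solver = solver  # kept for traceback expansion
    return tables


def traceback(
    tables: DPTables, index: CandidateIndex, coax: list[CoaxPair]
) -> Prediction:
    """Expand backpointers from the optimal top cell into a Prediction."""
    if tables.top is None:
        return Prediction(frozenset(), (), (), 0)
    nested = {(p.x_id, p.y_id): p for p in coax if p.kind == StackKind.NESTED}
    parallel = {(p.x_id, p.y_id): p for p in coax if p.kind == StackKind.PARALLEL}
    helices: list[int] = []
    stacks: list[CoaxPair] = []

    def expand(key) -> int:
        value, bp = tables.cells[key]
        if value <= NEG:
            raise InternalConsistencyError(f"traceback reached -inf cell {key}")
        if bp is None:
            raise InternalConsistencyError(f"finite cell {key} has no backpointer")
        tag, hel, stk, children = bp
        total = 0
        for cid in hel:
            helices.append(cid)
            total += -index.by_id[cid].energy_centi
        for x_id, y_id, kind in stk:
            pair = nested[(x_id, y_id)] if kind == "N" else parallel[(x_id, y_id)]
            stacks.append(pair)
            total += pair.reward_centi
        for child in children:
            total += expand(child)
        if total != value:
            raise InternalConsistencyError(
                f"cell {key}: backpointer expansion {total} != score {value}"
            )
        return total

    score = expand(tables.top)
    pairs = frozenset(
        p for cid in helices for p in index.by_id[cid].pairs
    )
    helices_t = tuple(sorted(set(helices)))
    if len(helices_t) != len(helices):
        raise InternalConsistencyError("a helix was selected twice")
    return Prediction(
        pairs=pairs,
        helices=helices_t,
        coax_stacks=tuple(sorted(stacks, key=lambda p: (p.x_id, p.y_id))),
        score_centi=score,
    )


def predict(
    seq: str,
    fcfg=None,
    ecfg: EnergyConfig | None = None,
    dcfg: DPConfig | None = None,
) -> Prediction:
    """End-to-end prediction for one sequence.

    Composes candidate search, order construction, coax enumeration, the
    DP fill and the traceback; a pure function of (sequence, configs).
    """
    from .candidates import FinderConfig, build_orderings, find_helix_candidates
    from .geometry import enumerate_coax_pairs

    ecfg = ecfg or EnergyConfig()
    cands = find_helix_candidates(seq, fcfg or FinderConfig(), ecfg)
    if not cands:
        return Prediction(frozenset(), (), (), 0)
    index = build_orderings(cands)
    coax = enumerate_coax_pairs(index, seq)
    tables = fill_tables(index, coax, dcfg or DPConfig(), ecfg)
    return traceback(tables, index, coax)
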