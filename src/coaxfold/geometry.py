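"""Coaxial-stack geometry: admissible pairs, nested/parallel kinds, compound rules.

Two helices may coaxially stack only when they share a contiguous
single-strand backbone with at most one unpaired nucleotide (join distance
d <= 2 under the convention d = b.start - a.end).  A stack (X, Y) is

* nested   if max L(X) < min L(Y) and max H(Y) < min H(X)  (X encloses Y);
* parallel if max H(X) < min L(Y)                          (X precedes Y).

For a nested pair either connecting strand may carry the join; the stacked
interface (X's loop-side pair on Y's outermost pair) is the same on both
sides, so one CoaxPair records both join distances and a single reward.

When one helix takes part in two stacks, exactly one of three compound
layouts is geometrically possible; equivalently, each helix has a loop-side
interface (used when it stacks with an enclosed helix) and an outward
interface (used when it stacks with its encloser or with a parallel
neighbor), and each interface supports at most one stack.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .candidates import CandidateIndex, HelixCandidate
from .energy import coax_reward_centi
from .errors import InputError


class StackKind(enum.Enum):
    NESTED = "nested"
    PARALLEL = "parallel"
    NONE = "none"


@dataclass(frozen=True)
class CoaxPair:
    """An admissible coaxial stack (X, Y) with its reward.

    ``k`` is the number of unpaired nucleotides at the (closest) join.
    For nested pairs ``d_left``/``d_right`` hold the two connecting-strand
    distances (None when the regions overlap the wrong way, which cannot
    happen for a valid nested pair); for parallel pairs ``d_join`` holds the
    single join distance.  A join is usable by the prediction only where its
    distance is <= 2.
    """

    x_id: int
    y_id: int
    kind: StackKind
    k: int
    reward_centi: int
    d_left: int | None = None
    d_right: int | None = None
    d_join: int | None = None

    @property
    def reward(self) -> float:
        return self.reward_centi / 100.0


def classify_stack(x: HelixCandidate, y: HelixCandidate) -> StackKind:
    """Nested / parallel / none classification of the ordered pair (X, Y)."""
    if x.region5.end < y.region5.start and y.region3.end < x.region3.start:
        return StackKind.NESTED
    if x.region3.end < y.region5.start:
        return StackKind.PARALLEL
    return StackKind.NONE


def enumerate_coax_pairs(index: CandidateIndex, seq: str) -> list[CoaxPair]:
    """Every ordered candidate pair admissible as a coaxial stack (k <= 1).

    Nested pairs are emitted when either connecting strand has distance
    <= 2; parallel pairs when the single joining strand does.  Rewards are
    computed from the interface terminal pairs as if contiguous, clipped at
    zero (so a pair may carry reward 0).
    """
    s = seq.upper().replace("T", "U")
    out: list[CoaxPair] = []
    cands = index.candidates
    for x in cands:
        for y in cands:
            if x.id == y.id:
                continue
            kind = classify_stack(x, y)
            if kind == StackKind.NONE:
                continue
            if kind == StackKind.NESTED:
                d_left = y.region5.start - x.region5.end
                d_right = x.region3.start - y.region3.end
                if min(d_left, d_right) > 2:
                    continue
                pa = (s[x.region5.end - 1], s[x.region3.start - 1])
                pb = (s[y.region5.start - 1], s[y.region3.end - 1])
                out.append(
                    CoaxPair(
                        x_id=x.id,
                        y_id=y.id,
                        kind=kind,
                        k=min(d_left, d_right) - 1,
                        reward_centi=coax_reward_centi(pa, pb),
                        d_left=d_left,
                        d_right=d_right,
                    )
                )
            else:
                d = y.region5.start - x.region3.end
                if d > 2:
                    continue
                pa = (s[x.region3.end - 1], s[x.region5.start - 1])
                pb = (s[y.region5.start - 1], s[y.region3.end - 1])
                out.append(
                    CoaxPair(
                        x_id=x.id,
                        y_id=y.id,
                        kind=kind,
                        k=d - 1,
                        reward_centi=coax_reward_centi(pa, pb),
                        d_join=d,
                    )
                )
    out.sort(key=lambda p: (p.x_id, p.y_id, p.kind.value))
    return out


def validate_compound(stacks: list[CoaxPair] | set[CoaxPair], x_id: int | None = None) -> bool:
    """Check the compound-stack rules for the stacks incident to one helix.

    Valid iff the set is empty, a singleton, or one of the three two-stack
    layouts: (1) (X,Y) and (Z,X) nested; (2) (X,Y) nested plus a parallel
    stack involving X; (3) a parallel stack involving X plus (X,Z) nested.
    Any helix in three or more stacks is invalid.
    """
    stacks = list(stacks)
    if not stacks:
        return True
    if x_id is None:
        common = set.intersection(*({s.x_id, s.y_id} for s in stacks))
        if len(common) != 1:
            raise InputError("stacks do not all share one helix")
        x_id = common.pop()
    for st in stacks:
        if x_id not in (st.x_id, st.y_id):
            raise InputError(f"stack ({st.x_id},{st.y_id}) does not involve helix {x_id}")
    if len(stacks) == 1:
        return True
    if len(stacks) > 2:
        return False
    a, b = stacks

    def role(st: CoaxPair) -> str:
        if st.kind == StackKind.PARALLEL:
            return "parallel"
        return "encloses" if st.x_id == x_id else "enclosed_by"

    roles = {role(a), role(b)}
    # case 1: (X,Y) nested and (Z,X) nested
    if roles == {"encloses", "enclosed_by"}:
        return True
    # cases 2 and 3: one nested stack in which X is the encloser, one parallel
    if roles == {"encloses", "parallel"}:
        return True
    return False
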