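"""Structure formats (dot-bracket, WUSS, Stockholm consensus) and evaluation.

Evaluation follows the usual base-pair sensitivity and, for coaxial
stacks, PPV and sensitivity over stack annotations:

    sensitivity = TP / (TP + FN) * 100 %
    PPV         = TP / (TP + FP) * 100 %

Base-pair PPV is computed as well but flagged: predicted pairs falling in
inserted regions of a consensus can be valid, so counting them as false
positives biases against sequences longer than the consensus.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

from .errors import InputError
from .geometry import StackKind

_OPEN = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}
_UNPAIRED = set(".,:_-~")


@dataclass(frozen=True)
class CoaxRef:
    """A reference coaxial-stack annotation (helices by outer coordinates)."""

    x_start5: int
    x_end3: int
    y_start5: int
    y_end3: int
    kind: StackKind
    k: int = 0


@dataclass
class ReferenceStructure:
    """A reference secondary structure: pair set and derived helices."""

    pairs: frozenset
    length: int
    coax: tuple = ()

    @property
    def helices(self) -> list:
        """Maximal stacked runs (1-nt bulges bridged) as (pairs tuple) lists."""
        return derive_helices(self.pairs)


def derive_helices(pairs) -> list:
    """Group a pair set into maximal helices, bridging single-nt bulges."""
    rest = sorted(pairs)
    taken = set()
    out = []
    pair_set = set(rest)
    for p in rest:
        if p in taken:
            continue
        run = [p]
        taken.add(p)
        while True:
            a, b = run[-1]
            nxt = None
            for da, db in ((1, 1), (2, 1), (1, 2), (2, 2)):
                q = (a + da, b - db)
                if q in pair_set and q not in taken and q[0] < q[1]:
                    nxt = q
                    break
            if nxt is None:
                break
            run.append(nxt)
            taken.add(nxt)
        out.append(tuple(run))
    return out


def parse_structure(text: str, dialect: str = "dot-bracket") -> ReferenceStructure:
    """Parse a dot-bracket / WUSS line into a pair set.

    Nested bracket families (), <>, [], {} are matched independently;
    pseudoknot letter annotations (Aa, Bb, ...) are dropped with a warning.
    Unbalanced brackets raise InputError naming the position.
    """
    if dialect == "stockholm-consensus":
        from Bio import AlignIO

        aln = AlignIO.read(io.StringIO(text), "stockholm")
        ss = aln.column_annotations.get("secondary_structure")
        if ss is None:
            raise InputError("Stockholm alignment has no #=GC SS_cons line")
        return parse_structure(ss, "wuss")
    if dialect not in ("dot-bracket", "wuss"):
        raise InputError(f"unknown dialect {dialect!r}")
    line = text.strip()
    stacks: dict[str, list[int]] = {k: [] for k in _OPEN}
    pairs = set()
    dropped_pk = False
    for pos, ch in enumerate(line, start=1):
        if ch in _OPEN:
            stacks[ch].append(pos)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise InputError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((stacks[opener].pop(), pos))
        elif ch in _UNPAIRED:
            continue
        elif ch.isalpha():
            dropped_pk = True
        else:
            raise InputError(f"unexpected character {ch!r} at position {pos}")
    for opener, st in stacks.items():
        if st:
            raise InputError(f"unbalanced {opener!r} at position {st[-1]}")
    if dropped_pk:
        warnings.warn("pseudoknot letter annotations dropped", stacklevel=2)
    return ReferenceStructure(pairs=frozenset(pairs), length=len(line))


def parse_stockholm(text: str) -> dict:
    """Per-record reference structures from a Stockholm alignment.

    Reads the ``#=GC SS_cons`` consensus line with Bio.AlignIO and maps it
    onto each ungapped member sequence through its alignment row.  Returns
    {record id: (ungapped sequence, ReferenceStructure)}.
    """
    from Bio import AlignIO

    aln = AlignIO.read(io.StringIO(text), "stockholm")
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise InputError("Stockholm alignment has no #=GC SS_cons line")
    cons = parse_structure(ss, "wuss")
    out = {}
    for rec in aln:
        row = str(rec.seq)
        col_to_pos = {}
        pos = 0
        for col, ch in enumerate(row, start=1):
            if ch not in ".-":
                pos += 1
                col_to_pos[col] = pos
        pairs = set()
        for a, b in cons.pairs:
            if a in col_to_pos and b in col_to_pos:
                pairs.add((col_to_pos[a], col_to_pos[b]))
        out[rec.id] = (
            row.replace(".", "").replace("-", "").upper().replace("T", "U"),
            ReferenceStructure(pairs=frozenset(pairs), length=pos),
        )
    return out


def write_dot_bracket(pairs, length: int) -> str:
    """Render a non-crossing pair set as a dot-bracket line."""
    chars = ["."] * length
    sorted_pairs = sorted(pairs)
    for (a, b), (c, d) in zip(sorted_pairs, sorted_pairs[1:]):
        if a < c < b < d:
            raise InputError(f"crossing pairs ({a},{b}) and ({c},{d})")
    for a, b in sorted_pairs:
        if not (1 <= a < b <= length):
            raise InputError(f"pair ({a},{b}) outside 1..{length}")
        chars[a - 1], chars[b - 1] = "(", ")"
    return "".join(chars)


def coax_tsv(stacks, index) -> str:
    """Coax annotation TSV: x_start5 x_end3 y_start5 y_end3 kind k reward_kcal."""
    lines = ["x_start5\tx_end3\ty_start5\ty_end3\tkind\tk\treward_kcal"]
    for p in stacks:
        x = index.by_id[p.x_id]
        y = index.by_id[p.y_id]
        lines.append(
            f"{x.region5.start}\t{x.region3.end}\t{y.region5.start}\t{y.region3.end}\t"
            f"{p.kind.value}\t{p.k}\t{p.reward:.2f}"
        )
    return "\n".join(lines) + "\n"


def parse_coax_tsv(text: str) -> tuple:
    """Reference coax annotations from the TSV format above."""
    out = []
    lines = [l for l in text.splitlines() if l.strip()]
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) < 6:
            raise InputError(f"bad coax TSV line: {line!r}")
        out.append(
            CoaxRef(
                x_start5=int(f[0]),
                x_end3=int(f[1]),
                y_start5=int(f[2]),
                y_end3=int(f[3]),
                kind=StackKind(f[4]),
                k=int(f[5]),
            )
        )
    return tuple(out)


def write_prediction(pred, seq: str, index) -> tuple[str, str]:
    """(dot-bracket text, coax TSV text) for a Prediction."""
    db = write_dot_bracket(pred.pairs, len(seq))
    return db + "\n", coax_tsv(pred.coax_stacks, index)


@dataclass
class EvalReport:
    """TP/FP/FN counts with percentage metrics."""

    tp: int
    fp: int
    fn: int
    topology_match: bool | None = None

    @property
    def sensitivity(self) -> float | None:
        return None if self.tp + self.fn == 0 else 100.0 * self.tp / (self.tp + self.fn)

    @property
    def ppv(self) -> float | None:
        return None if self.tp + self.fp == 0 else 100.0 * self.tp / (self.tp + self.fp)


def metrics_from_counts(tp: int, fp: int, fn: int) -> EvalReport:
    """An EvalReport from raw counts (e.g. published totals)."""
    return EvalReport(tp=tp, fp=fp, fn=fn)


def _helix_overlap_ge_half(ref_helix, pred_helices) -> tuple | None:
    """The predicted helix sharing >= 50% of a reference helix's pairs."""
    ref_set = set(ref_helix)
    best = None
    best_n = 0
    for ph in pred_helices:
        n = len(ref_set & set(ph))
        if n > best_n:
            best_n, best = n, ph
    if best is not None and best_n * 2 >= len(ref_set):
        return best
    return None


def _topology_match(pred_pairs, ref: ReferenceStructure) -> bool:
    """Overall-topology criterion.

    Every reference helix must be captured by a predicted helix sharing at
    least half of its pairs; the nesting relation among the capturing
    helices must match the reference; extra predicted helices are allowed
    only inside reference loop regions (they must not cross any reference
    pair).
    """
    ref_helices = derive_helices(ref.pairs)
    pred_helices = derive_helices(pred_pairs)
    capture = {}
    for rh in ref_helices:
        ph = _helix_overlap_ge_half(rh, pred_helices)
        if ph is None:
            return False
        capture[rh] = ph

    def encloses(h1, h2) -> bool:
        (a1, b1) = h1[0]
        (a2, b2) = h2[0]
        return a1 < a2 and b2 < b1

    for r1 in ref_helices:
        for r2 in ref_helices:
            if r1 is r2:
                continue
            if encloses(r1, r2) != encloses(capture[r1], capture[r2]):
                return False
    captured = set(capture.values())
    for ph in pred_helices:
        if ph in captured:
            continue
        for a, b in ph:
            for c, d in ref.pairs:
                if (c < a < d < b) or (a < c < b < d):
                    return False  # crosses the reference: not loop-internal
    return True


def _match_coax(pred_stacks, pred_index, ref_coax) -> tuple[int, int, int]:
    """(tp, fp, fn) matching predicted stacks to reference annotations.

    A predicted stack is a true positive iff some reference stack pairs the
    same two helices; helix identity is outer-coordinate agreement within
    half the helix length (>= 50% shared pairs for exact-register helices).
    """
    def helix_matches(cand, start5: int, end3: int) -> bool:
        n = cand.n_pairs
        return (
            abs(cand.region5.start - start5) * 2 < n
            and abs(cand.region3.end - end3) * 2 < n
        )

    used = set()
    tp = 0
    for p in pred_stacks:
        x = pred_index.by_id[p.x_id]
        y = pred_index.by_id[p.y_id]
        hit = None
        for ri, r in enumerate(ref_coax):
            if ri in used:
                continue
            if (
                helix_matches(x, r.x_start5, r.x_end3)
                and helix_matches(y, r.y_start5, r.y_end3)
            ) or (
                helix_matches(x, r.y_start5, r.y_end3)
                and helix_matches(y, r.x_start5, r.x_end3)
            ):
                hit = ri
                break
        if hit is not None:
            used.add(hit)
            tp += 1
    fp = len(list(pred_stacks)) - tp
    fn = len(list(ref_coax)) - tp
    return tp, fp, fn


def evaluate_prediction(
    pred,
    ref: ReferenceStructure,
    index=None,
    seq_length: int | None = None,
) -> tuple[EvalReport, EvalReport]:
    """(base-pair report, coax report) for a prediction against a reference.

    Base-pair level: TP = correctly predicted pairs, FN = missed reference
    pairs; sensitivity is the headline metric.  PPV is filled in but, for
    base pairs, should be read with the inserted-region caveat (see module
    docstring).  Coax level: reference stacks matched by helix identity.
    """
    if seq_length is not None and ref.length and seq_length != ref.length:
        raise InputError(
            f"sequence length {seq_length} != reference length {ref.length}"
        )
    pred_pairs = set(pred.pairs)
    ref_pairs = set(ref.pairs)
    tp = len(pred_pairs & ref_pairs)
    fn = len(ref_pairs - pred_pairs)
    fp = len(pred_pairs - ref_pairs)
    bp_report = EvalReport(
        tp=tp, fp=fp, fn=fn, topology_match=_topology_match(pred_pairs, ref)
    )
    if index is not None:
        ctp, cfp, cfn = _match_coax(pred.coax_stacks, index, ref.coax)
    else:
        ctp, cfp, cfn = 0, len(list(getattr(pred, "coax_stacks", ()))), len(ref.coax)
    coax_report = EvalReport(tp=ctp, fp=cfp, fn=cfn)
    return bp_report, coax_report
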