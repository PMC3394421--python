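# Methods

## Model

A secondary structure is modelled as a nucleotide-disjoint, non-crossing
set of helices (canonical Watson-Crick and G-U wobble pairs) plus a set of
coaxial stacks between helices that share a contiguous backbone strand with
at most one unpaired nucleotide (k ≤ 1). The objective maximized is

    score = Σ_helices (−ΔG_helix)  +  Σ_stacks CS

in kcal/mol of stabilization. The model deliberately scores helices from
base-pair stacking only: hairpin, internal and multibranch loop free
energies are excluded. This is the main systematic difference from full
nearest-neighbor folding and the main known limitation — structures with
large loops are over-rewarded relative to a complete Turner model.

### Helix energy

ΔG of a helix is the sum of nearest-neighbor stacking increments over
consecutive pairs (Turner-2004 values as distributed with the Vienna RNA
package, embedded as integer centi-kcal constants), plus a flat +3.8
kcal/mol per single-nucleotide bulge (the flanking pairs still stack), plus
+0.5 per helix end closed by A-U or G-U (configurable, default on; the
stability thresholds below were calibrated against energies that include
this penalty). Dangling ends, coaxial mismatch terms and special hairpin
corrections are out of scope.

### Stability tiers

* **semi-stable**: ΔG < −2.5 kcal/mol, ≥ 3 bp, ≥ 1 G-C pair;
* **stable**: ΔG < −3.7 kcal/mol, same side conditions;
* **ultra-stable**: ΔG < −4.6 kcal/mol and more than 5 bp (no G-C
  condition — an ultra-stable helix may in principle be G-C-free, which the
  synthetic fixtures exploit).

Classification is a cascade (ultra first), monotone in ΔG at fixed counts.

### Coaxial stacks

A stack (X, Y) is *nested* when X encloses Y (max L(X) < min L(Y) and
max H(Y) < min H(X)) and *parallel* when X wholly precedes Y
(max H(X) < min L(Y)). Its reward CS is the negated stacking increment of
the two interface terminal pairs treated as contiguous — X's loop-side pair
against Y's outermost pair for nested stacks, the two outermost pairs for
parallel stacks — clipped at zero for the few destabilizing wobble
combinations. Over Watson-Crick terminals CS spans 0.9 … 3.4 kcal/mol. For
a nested pair the interface is the same whichever connecting strand carries
the join, and the table's strand-flip symmetry makes the two lookups equal,
so one CoaxPair records both join distances and a single reward.

Stacks compose under three compound layouts (both nested; nested + a
parallel; a parallel + nested). Equivalently: each helix has a loop-side
interface (stacking with an enclosed helix) and an outward interface
(stacking with its encloser or a parallel neighbor), and each interface
carries at most one stack.

## Prediction

Candidates are found by exhaustive inward extension from every
non-extendable outer pair: a contiguous stack step is always taken when
possible; where it is not, the accumulated perfect run is recorded as a
candidate *and* bulge continuations (≤ 1 unpaired nt per backbone) are
explored. End-trimmed sub-helices (≤ 1 pair per end) are kept when trimming
changes the stability tier. Minimum hairpin loop: 3 nt.

The dynamic program works at helix level. Candidate regions are ordered by
start (SPO) and by end (EPO); a cell (i, j) spans from the start of SPO
region i to the end of EPO region j, and twelve mutually recursive
functions fill one table each (top level; enclosed helix; 2-way junction
chains and their bifurcating variants; junction interiors with no, left
nested, right nested, or pending-parallel coax obligations). Structural
rules enforced by the recurrences:

* a bare, unstacked helix must be stable or better;
* every 2-way junction link obeys internal-loop geometry (each connecting
  strand distance ≤ 11, asymmetry ≤ 4, the two strands not both free of
  unpaired nucleotides) and the pair must *combined* act as a stable helix
  (ΔG summed, minus CS if stacked; base pairs summed; a G-C pair in either
  helix), ultra-stable if the inner helix is to enclose an m-way junction;
* an m-way junction (m > 2) requires an ultra-stable or combined-ultra
  encloser; its boundary strands keep distance ≥ 2 from the encloser
  except on a side carrying a nested coax join (distance ≤ 2, i.e. k ≤ 1)
  — so a stack at a tight join is structurally load-bearing, not merely a
  bonus, and removing coax pairs can cost more than their rewards;
* parallel stacks arise only between adjacent helices inside an enclosed
  multibranch junction; top-level junctions carry no coax;
* a semi-stable helix enters only as (a) a leaf whose stack partner is
  itself stable or better, or (b) a member of a 2-way junction whose
  combined strength is stable. Rule (a) is enforced at the CS-discharging
  case by refining the pending-parallel functions into an "ok" and a
  "weak" (bare semi-stable leaf) channel and, for nested stacks under a
  combined-ultra encloser, by a context flag on the junction functions.

All scores are integers (centi-kcal/mol), so optima and ties are exact.
Ties in the traceback resolve by case order, then smaller split point, then
smaller inner index — predictions are bit-reproducible. Complexity is
O(cells × split points) with cells ≈ (2·candidates)²; sequences in the
hundred-nucleotide range with tens of candidates run in seconds in pure
Python, which is the intended scale.

## Synthetic data and the oracle

The generator plants an exact topology tree (helices as perfect reverse
complements; loop gaps encode the intended k values) and returns the truth:
all pairs, all planted stacks with kinds, and any *decoys*. A decoy is a
finder candidate whose pairs do not all connect the two backbone regions of
one planted helix; shifted or bulged re-registrations of a planted stem are
*not* decoys — they are unavoidable for any strong stem and are instead
covered by the recovery checks. Two alphabets are used:

* **mixed mode** (gc_fraction > 0): stem letters drawn G/C vs A/U; loops
  alternate A/C (which cannot pair with itself). Accidental cross-helix
  complementarity is then reduced by a greedy repair that re-orients
  planted pairs (GC↔CG, AU↔UA) and flips loop letters, guided first by a
  fast complementary-trigram proxy and then by the true candidate count,
  never lowering a planted helix's tier.
* **designed all-AU mode** (gc_fraction = 0): alternating A/U stems with
  one desynchronizing same-letter doublet, all-C loops. A G-free sequence
  cannot host semi-stable or stable decoys at all (both need a G-C pair),
  and ultra-stable decoys would need an accidental ≥ 6 bp run, which the
  repair removes. This is how decoy-free multibranch fixtures (e.g. the
  tRNA-like cloverleaf) are built deterministically.

What passing on these fixtures shows — and does not show: recovery on
decoy-free plants demonstrates that the optimizer and its stacking rules
behave exactly as specified when the energy signal is clean; it does not
demonstrate accuracy on natural sequences, where loop energies (excluded
here), non-canonical pairs and near-isoenergetic alternatives matter.

The correctness oracle enumerates *every* helix subset and stack
assignment on instances of ≤ 12 candidate regions and validates them
against the structural rules directly — it shares no recurrence
decomposition with the DP, so the two can disagree; exact score agreement
on hundreds of seeded random instances is the core correctness test. The
same validator audits every emitted prediction independently of the DP.

## Evaluation

Base-pair level: sensitivity = TP/(TP+FN)·100%. PPV is computed but
reported with a caveat — predicted pairs in regions inserted relative to a
consensus may be genuine, so counting them as false positives biases
against long sequences. Stack level: a predicted stack is a true positive
when a reference stack pairs the same two helices (helix identity by
outer-coordinate agreement within half the helix length, i.e. ≥ 50% shared
pairs for exact-register helices). Topology match: every reference helix is
captured by a predicted helix sharing ≥ 50% of its pairs, the nesting
relations among the capturing helices match the reference, and extra
predicted helices must not cross any reference pair (loop-internal
insertions are tolerated). Published stack-count percentages are truncated
rather than rounded, so comparisons are made at the printed precision.

## Defaults

| parameter | default | meaning |
|---|---|---|
| semi/stable/ultra thresholds | −2.5 / −3.7 / −4.6 kcal/mol | strict upper bounds on helix ΔG |
| min bp (semi/stable, ultra) | 3, 6 | side conditions on tier membership |
| bulge penalty | +3.8 kcal/mol | per single-nucleotide bulge |
| terminal A-U/G-U penalty | +0.5 kcal/mol, on | per closing helix end |
| coax join | d ≤ 2 (k ≤ 1) | unpaired nt at a stackable join |
| internal-loop bounds | 11 per side, asymmetry 4 | 2-way junction geometry |
| forbid_both_zero | on | 2-way strands cannot both lack unpaired nt |
| min hairpin loop | 3 nt | steric minimum |

Degenerate inputs: sequences without candidates predict the empty structure
at score 0; T is accepted and read as U; non-ACGU letters are rejected with
their position. Pseudoknots, suboptimal enumeration, partition functions
and tertiary contacts are out of scope.
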