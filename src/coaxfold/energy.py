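"""Nearest-neighbor stacking energetics, helix free energy and stability tiers.

All thermodynamic quantities are free-energy increments at 37 degC in
kcal/mol (negative = stabilizing).  Internally every energy is an integer in
centi-kcal/mol (1 unit = 0.01 kcal/mol) so that downstream optimization can
compare scores exactly; the public functions return floats in kcal/mol.

The model deliberately scores helices from base-pair stacking only: hairpin,
internal and multibranch loop terms are excluded.  A single-nucleotide bulge
inside a helix costs a flat penalty and the pairs flanking it still stack.
Helix ends closed by A-U or G-U get a terminal penalty (configurable).

Helices are classed into stability tiers (semi-stable / stable /
ultra-stable) by free-energy thresholds with base-pair and G-C side
conditions; the tiers gate where a helix may appear in a predicted
structure.  A coaxial stack between two helices is rewarded with the negated
stacking increment of the two interface terminal pairs, treated as if they
were contiguous, clipped at zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .errors import InputError, NonCanonicalPairError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .candidates import HelixCandidate

PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")

# Stacking free-energy increments, centi-kcal/mol at 37 degC.
# Transcribed from the Turner-2004 parameter set distributed with the Vienna
# RNA package (rna_turner2004.par, "# stack" block, dekacal units x10).
# _STACK[p][q] is the increment for the 2x2 motif
#     5'-p[0] . q'[0]-3'
#     3'-p[1] . q'[1]-5'
# where the row key p is the outer pair (top-strand nt first) and the column
# key q is the *reversed* inner pair, matching the Vienna convention.  The
# matrix is symmetric, which encodes the strand-flip identity
# dG(5'WX/3'ZY) = dG(5'YZ/3'XW).
_STACK: dict[str, dict[str, int]] = {
    #        CG    GC    GU    UG    AU    UA
    "CG": {"CG": -240, "GC": -330, "GU": -210, "UG": -140, "AU": -210, "UA": -210},
    "GC": {"CG": -330, "GC": -340, "GU": -250, "UG": -150, "AU": -220, "UA": -240},
    "GU": {"CG": -210, "GC": -250, "GU": +130, "UG": -50, "AU": -140, "UA": -130},
    "UG": {"CG": -140, "GC": -150, "GU": -50, "UG": +30, "AU": -60, "UA": -100},
    "AU": {"CG": -210, "GC": -220, "GU": -140, "UG": -60, "AU": -110, "UA": -90},
    "UA": {"CG": -210, "GC": -240, "GU": -130, "UG": -100, "AU": -90, "UA": -130},
}

#: Terminal A-U / G-U closing penalty per helix end (Turner 2004 "TerminalAU").
TERMINAL_AU_CENTI = 50
#: Single-nucleotide bulge penalty (Turner 2004 bulge-of-1).
BULGE1_CENTI = 380

WATSON_CRICK = ("AU", "UA", "CG", "GC")
WOBBLE = ("GU", "UG")


def _pair_str(pair) -> str:
    """Normalize a base pair given as a 2-string or (x, y) tuple."""
    if isinstance(pair, str):
        p = pair.upper().replace("T", "U")
    else:
        x, y = pair
        p = (str(x) + str(y)).upper().replace("T", "U")
    if p not in PAIR_TYPES:
        raise NonCanonicalPairError(f"non-canonical pair {p!r}")
    return p


def stack_energy_centi(pair_a, pair_b) -> int:
    """Stacking increment (centi-kcal/mol) for pair_b stacked 3' of pair_a.

    pair_a and pair_b are (top-strand nt, bottom-strand nt) with the top
    strand read 5'->3'; pair_b follows pair_a on the top strand.
    """
    a = _pair_str(pair_a)
    b = _pair_str(pair_b)
    return _STACK[a][b[::-1]]


def stack_energy(pair_a, pair_b) -> float:
    """Stacking increment in kcal/mol for pair_b stacked 3' of pair_a."""
    return stack_energy_centi(pair_a, pair_b) / 100.0


class StabilityTier(enum.IntEnum):
    """Helix stability classes, ordered; gates structural usage in the DP."""

    NONE = 0
    SEMI_STABLE = 1
    STABLE = 2
    ULTRA_STABLE = 3


@dataclass
class EnergyConfig:
    """Thresholds and penalties of the helix energy model.

    Thresholds are strict upper bounds in kcal/mol (a helix qualifies when
    its free energy is *below* the threshold).  ``min_bp_ultra`` encodes the
    "more than 5 base pairs" rule for ultra-stable helices.
    """

    semi_stable_max: float = -2.5
    stable_max: float = -3.7
    ultra_stable_max: float = -4.6
    min_bp_semi_stable: int = 3
    min_gc_semi_stable: int = 1
    min_bp_ultra: int = 6
    bulge1_penalty: float = BULGE1_CENTI / 100.0
    terminal_au_penalty: float = TERMINAL_AU_CENTI / 100.0
    include_terminal_penalty: bool = True

    def __post_init__(self) -> None:
        if not (self.ultra_stable_max < self.stable_max < self.semi_stable_max < 0):
            raise InputError(
                "stability thresholds must satisfy "
                "ultra_stable_max < stable_max < semi_stable_max < 0; got "
                f"{self.ultra_stable_max} / {self.stable_max} / {self.semi_stable_max}"
            )

    # centi-kcal views used by the integer-scoring core
    @property
    def semi_stable_max_centi(self) -> int:
        return round(self.semi_stable_max * 100)

    @property
    def stable_max_centi(self) -> int:
        return round(self.stable_max * 100)

    @property
    def ultra_stable_max_centi(self) -> int:
        return round(self.ultra_stable_max * 100)

    @property
    def bulge1_penalty_centi(self) -> int:
        return round(self.bulge1_penalty * 100)

    @property
    def terminal_au_penalty_centi(self) -> int:
        return round(self.terminal_au_penalty * 100)


def _is_canonical(x: str, y: str) -> bool:
    return (x + y) in PAIR_TYPES


def helix_free_energy_centi(candidate: "HelixCandidate", seq: str, cfg: EnergyConfig) -> int:
    """Free energy of a helix candidate in centi-kcal/mol.

    Sum of nearest-neighbor stacks over consecutive base pairs (pairs
    flanking a bulge still stack), plus the 1-nt bulge penalty per bulged
    nucleotide, plus the terminal A-U/G-U penalty per closing end when
    enabled.  Loop energies of enclosed loops are not included.
    """
    pairs = candidate.pairs
    if not pairs:
        raise InputError("empty helix candidate")
    s = seq.upper().replace("T", "U")
    total = 0
    for (i5, i3), (k5, k3) in zip(pairs, pairs[1:]):
        pa = (s[i5 - 1], s[i3 - 1])
        pb = (s[k5 - 1], s[k3 - 1])
        total += stack_energy_centi(pa, pb)
        # each skipped nucleotide on either backbone is a 1-nt bulge
        n_bulged = (k5 - i5 - 1) + (i3 - k3 - 1)
        total += n_bulged * cfg.bulge1_penalty_centi
    # validate single-pair helices too
    for i5, i3 in (pairs[0], pairs[-1]):
        if not _is_canonical(s[i5 - 1], s[i3 - 1]):
            raise NonCanonicalPairError(
                f"pair ({i5},{i3}) = {s[i5-1]}-{s[i3-1]} is not canonical"
            )
    if cfg.include_terminal_penalty:
        for i5, i3 in (pairs[0], pairs[-1]):
            if s[i5 - 1] + s[i3 - 1] in ("AU", "UA", "GU", "UG"):
                total += cfg.terminal_au_penalty_centi
    return total


def helix_free_energy(candidate: "HelixCandidate", seq: str, cfg: EnergyConfig | None = None) -> float:
    """Free energy of a helix candidate, kcal/mol."""
    return helix_free_energy_centi(candidate, seq, cfg or EnergyConfig()) / 100.0


def classify_tier(dg_centi: int, n_bp: int, n_gc: int, cfg: EnergyConfig) -> StabilityTier:
    """Stability tier from free energy (centi-kcal/mol), bp and G-C counts."""
    if dg_centi < cfg.ultra_stable_max_centi and n_bp >= cfg.min_bp_ultra:
        return StabilityTier.ULTRA_STABLE
    if (
        dg_centi < cfg.stable_max_centi
        and n_bp >= cfg.min_bp_semi_stable
        and n_gc >= cfg.min_gc_semi_stable
    ):
        return StabilityTier.STABLE
    if (
        dg_centi < cfg.semi_stable_max_centi
        and n_bp >= cfg.min_bp_semi_stable
        and n_gc >= cfg.min_gc_semi_stable
    ):
        return StabilityTier.SEMI_STABLE
    return StabilityTier.NONE


def classify_stability(candidate: "HelixCandidate", cfg: EnergyConfig) -> StabilityTier:
    """Stability tier of a candidate with computed energy."""
    if candidate.energy_centi is None:
        raise InputError("candidate has no computed free energy")
    return classify_tier(candidate.energy_centi, candidate.n_pairs, candidate.n_gc, cfg)


def coax_reward_centi(pair_a, pair_b) -> int:
    """Coaxial-stack reward for two interface terminal pairs, centi-kcal/mol.

    The two pairs are oriented as if contiguous across the join; the reward
    is the negated stacking increment, clipped at zero (a destabilizing
    wobble stack contributes nothing rather than a penalty).
    """
    return max(0, -stack_energy_centi(pair_a, pair_b))


def coax_reward(helix_x: "HelixCandidate", helix_y: "HelixCandidate", seq: str) -> float:
    """Coaxial-stack reward CS for an admissible join of two helices, kcal/mol.

    For a parallel arrangement (X entirely 5' of Y) the interface is X's
    outermost pair against Y's outermost pair; for a nested arrangement
    (X enclosing Y) it is X's loop-side pair against Y's outermost pair.
    The two helices must share a contiguous backbone with at most one
    unpaired nucleotide (join distance <= 2).
    """
    s = seq.upper().replace("T", "U")
    x5, x3 = helix_x.region5, helix_x.region3
    y5, y3 = helix_y.region5, helix_y.region3
    if x3.end < y5.start:  # parallel: X before Y
        if y5.start - x3.end > 2:
            raise InputError("helices do not share a contiguous backbone (join > 2)")
        pa = (s[x3.end - 1], s[x5.start - 1])  # X outer pair, 3' strand on top
        pb = (s[y5.start - 1], s[y3.end - 1])  # Y outer pair
    elif x5.end < y5.start and y3.end < x3.start:  # nested: X encloses Y
        d_left = y5.start - x5.end
        d_right = x3.start - y3.end
        if d_left > 2 and d_right > 2:
            raise InputError("helices do not share a contiguous backbone (join > 2)")
        pa = (s[x5.end - 1], s[x3.start - 1])  # X loop-side pair
        pb = (s[y5.start - 1], s[y3.end - 1])  # Y outer pair
    else:
        raise InputError("helices share no contiguous backbone in a stackable layout")
    return coax_reward_centi(pa, pb) / 100.0
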