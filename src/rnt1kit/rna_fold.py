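"""Minimum-free-energy RNA secondary structure with wobble and A-C pairs.

Rnt1p reacts with short stem-loops whose stems may contain G-U wobble and
non-canonical A-C pairs, so the folding engine here admits the pair set
{AU, UA, GC, CG, GU, UG, AC, CA}, with each A-C pair carrying a
destabilising surcharge. The energy model is a deliberately simplified
nearest-neighbour scheme: stacking energies for directly stacked pairs plus
a hairpin-loop length penalty; bulges, internal loops and multiloop closures
carry no extra term. This keeps the model exhaustively enumerable on short
sequences, which is how the dynamic programme is validated.

Energy of a structure (a non-crossing set of pairs, hairpins >= 3 nt):

    E = sum(stack energies over adjacent nested pairs)
      + sum(hairpin penalty over hairpin loops)
      + surcharge * (# A-C pairs)

The MFE is found by a Zuker-style O(n^3) dynamic programme; dG <= 0 always
(the open chain scores 0 and is admissible).
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

INF = float("inf")

ALLOWED_PAIRS = frozenset(
    ["AU", "UA", "GC", "CG", "GU", "UG", "AC", "CA"]
)
AC_SURCHARGE = 1.0  # kcal/mol per A-C pair
MIN_LOOP = 3  # minimum hairpin loop length, nt

# Watson-Crick / wobble stack free energies, kcal/mol at 37 C.
# Key "XY/WZ": pair X-Y stacked on pair W-Z reading 5'->3' on the top strand,
# i.e. pair (i,j) followed by pair (i+1,j-1). Values follow the standard
# nearest-neighbour ordering (GC-on-GC strongest, AU/GU weakest).
_STACK: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("AU", "GC"): -2.1,
    ("AU", "CG"): -2.2, ("AU", "GU"): -0.6, ("AU", "UG"): -1.4,
    ("UA", "AU"): -1.3, ("UA", "UA"): -0.9, ("UA", "GC"): -2.4,
    ("UA", "CG"): -2.1, ("UA", "GU"): -1.0, ("UA", "UG"): -1.3,
    ("GC", "AU"): -2.4, ("GC", "UA"): -2.2, ("GC", "GC"): -3.3,
    ("GC", "CG"): -3.4, ("GC", "GU"): -1.5, ("GC", "UG"): -2.5,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("CG", "GC"): -2.4,
    ("CG", "CG"): -3.3, ("CG", "GU"): -1.4, ("CG", "UG"): -2.1,
    ("GU", "AU"): -1.3, ("GU", "UA"): -1.4, ("GU", "GC"): -2.1,
    ("GU", "CG"): -2.5, ("GU", "GU"): -0.5, ("GU", "UG"): -1.3,
    ("UG", "AU"): -1.0, ("UG", "UA"): -0.6, ("UG", "GC"): -1.4,
    ("UG", "CG"): -1.5, ("UG", "GU"): -0.3, ("UG", "UG"): -0.5,
}
_AC_STACK = -0.5  # generic weak stack when either pair is A-C

# hairpin loop initiation penalties by loop length (kcal/mol); lengths past
# the table extrapolate with the Jacobson-Stockmayer log term.
_HAIRPIN: dict[int, float] = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_RT = 0.616  # kcal/mol at 37 C


def _norm(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid nucleotide(s): {sorted(bad)}")
    return seq


def pairable(a: str, b: str) -> bool:
    return a + b in ALLOWED_PAIRS


def stack_energy(pair_out: str, pair_in: str) -> float:
    """Energy of stacking pair_in directly inside pair_out."""
    if pair_out in ("AC", "CA") or pair_in in ("AC", "CA"):
        return _AC_STACK
    return _STACK[(pair_out, pair_in)]


def hairpin_penalty(loop_len: int) -> float:
    if loop_len < MIN_LOOP:
        return INF
    if loop_len in _HAIRPIN:
        return _HAIRPIN[loop_len]
    return _HAIRPIN[9] + 1.75 * _RT * math.log(loop_len / 9)


def structure_energy(seq: str, pairs: set[tuple[int, int]]) -> float:
    """Energy of an explicit structure under the bundled model.

    ``pairs`` are (i, j) with i < j; the structure must be non-crossing with
    hairpin loops >= MIN_LOOP (not re-checked here beyond the hairpin term).
    """
    seq = _norm(seq)
    energy = 0.0
    pairset = set(pairs)
    partner = {}
    for i, j in pairset:
        partner[i] = j
        partner[j] = i
    for i, j in pairset:
        pij = seq[i] + seq[j]
        if pij in ("AC", "CA"):
            energy += AC_SURCHARGE
        if (i + 1, j - 1) in pairset:
            energy += stack_energy(pij, seq[i + 1] + seq[j - 1])
        # hairpin: no paired position strictly inside
        if all(k not in partner for k in range(i + 1, j)):
            energy += hairpin_penalty(j - i - 1)
    return energy


@dataclasses.dataclass
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    dG: float
    pairs: list[tuple[int, int]]

    @property
    def terminal_loops(self) -> list[tuple[int, int, str]]:
        """Hairpin loops as (loop_start, loop_end, loop_sequence), 0-based
        half-open over the loop nucleotides."""
        partner = set()
        for i, j in self.pairs:
            partner.add(i)
            partner.add(j)
        loops = []
        for i, j in sorted(self.pairs):
            if all(k not in partner for k in range(i + 1, j)):
                loops.append((i + 1, j, self.sequence[i + 1 : j]))
        return loops

    @property
    def is_unfolded(self) -> bool:
        return not self.pairs


def fold(sequence: str) -> FoldResult:
    """MFE fold by dynamic programming; deterministic traceback."""
    seq = _norm(sequence)
    n = len(seq)
    if n < 8:
        raise ValueError("sequence must be at least 8 nt")

    # V[i][j]: MFE given (i,j) paired; W[i][j]: MFE on [i..j] (empty allowed);
    # W1[i][j]: MFE on [i..j] with at least one pair.
    V = [[INF] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]
    W1 = [[INF] * n for _ in range(n)]

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable(seq[i], seq[j]):
                pij = seq[i] + seq[j]
                best = hairpin_penalty(j - i - 1)
                if j - i - 2 > MIN_LOOP and pairable(seq[i + 1], seq[j - 1]):
                    cand = stack_energy(pij, seq[i + 1] + seq[j - 1]) + V[i + 1][j - 1]
                    best = min(best, cand)
                if i + 1 <= j - 1:
                    best = min(best, W1[i + 1][j - 1])
                surcharge = AC_SURCHARGE if pij in ("AC", "CA") else 0.0
                V[i][j] = surcharge + best
            # W / W1
            w = W[i + 1][j] if i + 1 <= j else 0.0
            w1 = W1[i + 1][j] if i + 1 <= j else INF
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i][k] < INF:
                    rest = W[k + 1][j] if k + 1 <= j else 0.0
                    cand = V[i][k] + rest
                    w = min(w, cand)
                    w1 = min(w1, cand)
            W[i][j] = min(0.0, w)
            W1[i][j] = w1

    dg = W[0][n - 1] if n else 0.0
    pairs: list[tuple[int, int]] = []
    _traceback_w(seq, V, W, W1, 0, n - 1, pairs, require_pair=False)
    struct = ["."] * n
    for i, j in pairs:
        struct[i] = "("
        struct[j] = ")"
    return FoldResult(sequence=seq, structure="".join(struct), dG=dg, pairs=sorted(pairs))


def _traceback_w(seq, V, W, W1, i, j, pairs, require_pair):
    if i >= j:
        return
    target = W1[i][j] if require_pair else W[i][j]
    if not require_pair and target == 0.0 and W1[i][j] > 0.0:
        return  # open chain is optimal
    # prefer pairing i (leftmost differing position paired), outermost partner first
    for k in range(j, i + MIN_LOOP, -1):
        if V[i][k] < INF:
            rest = W[k + 1][j] if k + 1 <= j else 0.0
            if V[i][k] + rest == target:
                _traceback_v(seq, V, W, W1, i, k, pairs)
                _traceback_w(seq, V, W, W1, k + 1, j, pairs, require_pair=False)
                return
    _traceback_w(seq, V, W, W1, i + 1, j, pairs, require_pair)


def _traceback_v(seq, V, W, W1, i, j, pairs):
    pairs.append((i, j))
    pij = seq[i] + seq[j]
    surcharge = AC_SURCHARGE if pij in ("AC", "CA") else 0.0
    inner = V[i][j] - surcharge
    if hairpin_penalty(j - i - 1) == inner:
        return
    if j - i - 2 > MIN_LOOP and pairable(seq[i + 1], seq[j - 1]):
        cand = stack_energy(pij, seq[i + 1] + seq[j - 1]) + V[i + 1][j - 1]
        if cand == inner:
            _traceback_v(seq, V, W, W1, i + 1, j - 1, pairs)
            return
    _traceback_w(seq, V, W, W1, i + 1, j - 1, pairs, require_pair=True)


# --------------------------------------------------------------------------
# loop classification
# --------------------------------------------------------------------------

LOOP_CLASSES = ("G2_NGNN", "AHNN", "BHNN", "TRILOOP", "PENTALOOP", "HEXALOOP", "OTHER")


def classify_tetraloop(loop: str) -> str:
    """Partition a 4-nt loop: G at position 2 -> G2_NGNN; else A at position 1
    -> AHNN; else BHNN. Total and mutually exclusive over all 256 tetraloops."""
    loop = _norm(loop)
    if len(loop) != 4:
        raise ValueError("tetraloop must be 4 nt")
    if loop[1] == "G":
        return "G2_NGNN"
    if loop[0] == "A":
        return "AHNN"
    return "BHNN"


def classify_loop(result: FoldResult) -> str:
    """Class label of the terminal loop capping the longest stem."""
    if result.is_unfolded:
        return "OTHER"
    pairset = set(result.pairs)
    best = None  # (helix_len, -loop_start, loop_seq)
    for start, end, loop_seq in result.terminal_loops:
        i, j = start - 1, end  # closing pair
        helix = 0
        while (i - helix, j + helix) in pairset:
            helix += 1
        key = (helix, -(start))
        if best is None or key > best[0]:
            best = (key, loop_seq)
    loop = best[1]
    size = len(loop)
    if size == 3:
        return "TRILOOP"
    if size == 4:
        return classify_tetraloop(loop)
    if size == 5:
        return "PENTALOOP"
    if size == 6:
        return "HEXALOOP"
    return "OTHER"


def classify_products(sequences: list[str]) -> dict[str, float]:
    """Fold each representative cleavage-product sequence, classify its
    terminal loop and tabulate class fractions. Empty input -> empty table."""
    if not sequences:
        return {}
    counts: dict[str, int] = {}
    for seq in sequences:
        label = classify_loop(fold(seq))
        counts[label] = counts.get(label, 0) + 1
    total = len(sequences)
    return {label: counts.get(label, 0) / total for label in LOOP_CLASSES if label in counts}


# --------------------------------------------------------------------------
# exhaustive oracle (used by the test suite; kept here so the CLI can expose
# it for debugging, but it is NOT called by fold())
# --------------------------------------------------------------------------

def enumerate_structures(seq: str) -> list[set[tuple[int, int]]]:
    """All non-crossing structures with hairpins >= MIN_LOOP (exponential;
    intended for sequences <= ~18 nt)."""
    seq = _norm(seq)
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[frozenset, ...]:
        if i >= j:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if pairable(seq[i], seq[k]):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(frozenset({(i, k)}) | inner | rest)
        return tuple(out)

    result = [set(s) for s in rec(0, n - 1)]
    rec.cache_clear()
    return result
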