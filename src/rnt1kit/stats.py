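"""Position-wise sequence and pairing statistics over substrate groups.

Substrates are laid on a fixed 1-based 52-position frame: 24 stem positions
per arm around the 4-nt loop at positions 25-28. The scissile phosphates
fall at frame positions 9, 10 (5' arm) and 43, 44 (3' arm) and the middle
stem at 15, 16. Shorter substrates are centre-anchored at the loop and
padded. Per position, nucleotide enrichment is tested with Fisher's exact
test against background frequencies and pairing with a chi-squared test
against a background pairing rate, both Bonferroni-corrected at 0.05.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from . import rna_fold
from .motif import candidate_from_hairpin, LoopCandidate

FRAME_LEN = 52
ARM_SPAN = 24          # stem positions per arm in the frame
LOOP_POSITIONS = (25, 26, 27, 28)  # 1-based
BASES = "ACGU"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("GU"): "K", frozenset("AC"): "M",
    frozenset("CG"): "S", frozenset("AU"): "W",
    frozenset("CGU"): "B", frozenset("AGU"): "D", frozenset("ACU"): "H", frozenset("ACG"): "V",
    frozenset("ACGU"): "N",
}


def frame_candidate(sequence: str, loop_start: int) -> LoopCandidate:
    """Lay a substrate on the 52-position frame (24-position arms)."""
    return candidate_from_hairpin(sequence, loop_start, stem_span=ARM_SPAN)


def _frame_arrays(group: Sequence[LoopCandidate]) -> tuple[np.ndarray, np.ndarray]:
    """(n, 52) base characters ('N' where padded) and paired flags."""
    seqs = np.full((len(group), FRAME_LEN), "N", dtype="U1")
    paired = np.zeros((len(group), FRAME_LEN), dtype=bool)
    for r, cand in enumerate(group):
        for off in range(ARM_SPAN):
            pos_up = ARM_SPAN - 1 - off      # frame index of up-arm offset `off`
            pos_dn = ARM_SPAN + 4 + off
            seqs[r, pos_up] = cand.up_arm[off]
            paired[r, pos_up] = cand.pairing_up[off]
            seqs[r, pos_dn] = cand.down_arm[off]
            paired[r, pos_dn] = cand.pairing_down[off]
        for k, base in enumerate(cand.loop_seq):
            seqs[r, ARM_SPAN + k] = base
    return seqs, paired


@dataclasses.dataclass
class PositionStats:
    position: int                      # 1-based frame position
    base_counts: dict[str, int]
    paired: int
    unpaired: int
    fisher_p: dict[str, float]
    chi2_p: float
    significant_bases: list[str]       # after Bonferroni at 0.05
    pairing_significant: bool


def position_tests(
    group: Sequence[LoopCandidate],
    background_freqs: Mapping[str, float] | None = None,
    background_pair_rate: float = 0.5,
    alpha: float = 0.05,
) -> list[PositionStats]:
    """Per-position Fisher (base enrichment vs background-expected counts)
    and chi-squared (pairing vs background rate) tests with Bonferroni
    correction over positions x tests."""
    if len(group) < 5:
        raise ValueError("need a group of at least 5 substrates")
    bg = {b: (background_freqs.get(b, 0.25) if background_freqs else 0.25) for b in BASES}
    total_bg = sum(bg.values())
    bg = {b: v / total_bg for b, v in bg.items()}

    seqs, paired = _frame_arrays(group)
    n_tests = FRAME_LEN * (len(BASES) + 1)
    out = []
    for pos in range(FRAME_LEN):
        col = seqs[:, pos]
        informative = col != "N"
        n = int(informative.sum())
        counts = {b: int(np.sum(col == b)) for b in BASES}
        fisher_p: dict[str, float] = {}
        sig_bases: list[str] = []
        for b in BASES:
            if n == 0:
                fisher_p[b] = 1.0
                continue
            obs = counts[b]
            exp = int(round(bg[b] * n))
            table = [[obs, n - obs], [exp, n - exp]]
            fisher_p[b] = float(sps.fisher_exact(table, alternative="two-sided")[1])
            if fisher_p[b] * n_tests < alpha:
                sig_bases.append(b)
        p_obs = int(paired[informative, pos].sum()) if n else 0
        if n:
            expected = np.array([background_pair_rate, 1 - background_pair_rate]) * n
            chi2_p = float(sps.chisquare([p_obs, n - p_obs], expected).pvalue)
        else:
            chi2_p = 1.0
        out.append(
            PositionStats(
                position=pos + 1,
                base_counts=counts,
                paired=p_obs,
                unpaired=n - p_obs,
                fisher_p=fisher_p,
                chi2_p=chi2_p,
                significant_bases=sig_bases,
                pairing_significant=chi2_p * n_tests < alpha,
            )
        )
    return out


def consensus(
    group: Sequence[LoopCandidate],
    threshold: float = 0.2,
    significance_gate: bool = False,
    background_freqs: Mapping[str, float] | None = None,
) -> str:
    """Minimal IUPAC consensus of the loop: per loop position, the code
    covering all bases with frequency >= threshold. With the significance
    gate enabled, positions with no Bonferroni-significant base fall back
    to N."""
    stats = position_tests(group, background_freqs) if significance_gate else None
    seqs, _ = _frame_arrays(group)
    loop_len = max(len(c.loop_seq) for c in group)
    out = []
    for k in range(loop_len):
        pos = ARM_SPAN + k
        col = seqs[:, pos]
        informative = col != "N"
        n = max(int(informative.sum()), 1)
        chosen = {b for b in BASES if np.sum(col == b) / n >= threshold}
        if not chosen:
            chosen = set(BASES)
        if significance_gate and not stats[pos].significant_bases:
            chosen = set(BASES)
        out.append(_IUPAC[frozenset(chosen)])
    return "".join(out)


def percent_paired_profile(
    groups: Mapping[str, Sequence[LoopCandidate]]
) -> dict[str, np.ndarray]:
    """Per-group fraction of substrates paired at each frame position."""
    out = {}
    for name, group in groups.items():
        seqs, paired = _frame_arrays(group)
        informative = seqs != "N"
        denom = np.maximum(informative.sum(axis=0), 1)
        out[name] = paired.sum(axis=0) / denom
    return out


def group_dG(groups: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Median folding free energy (kcal/mol) per named substrate group."""
    out = {}
    for name, seqs in groups.items():
        if len(seqs) == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = float(np.median([rna_fold.fold(s).dG for s in seqs]))
    return out
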