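"""Genome-wide enumeration and scoring of Rnt1p G2 stem-loop cleavage motifs.

The canonical Rnt1p cleavage signal is a stem capped by an NGNN tetraloop
(G at loop position 2). Candidates are enumerated at every NGNN loop whose
flanks form at least ``min_stem`` consecutive stable pairs (Watson-Crick or
G-U) closing the loop; each candidate is then scored in [0, 1] as a convex
combination of three components:

* sequence — positional log-odds over the loop and the stem boxes (IBPB,
  BSB, MB, CEB at fixed offsets from the loop), min-max normalised;
* structure — agreement between the candidate's pairing profile and the
  per-position pairing frequencies of the training substrates, blended with
  a stability term mapping the hairpin ΔG through a logistic centred at
  -10 kcal/mol;
* similarity — best global-alignment score (+1/-1/-2) against the training
  substrates, normalised by the maximum attainable score.

Candidates not forming at least three stable base pairs immediately
downstream of the tetraloop receive no score (hard disqualifier), and G-U
wobble in the first two positions downstream of the loop is flagged
(``wobble_proximal``) but does not zero the score.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import Feature, GenomicInterval
from .rna_fold import hairpin_penalty, stack_energy

BASES = "ACGU"
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# stable stem pairs for enumeration/pairing (no A-C here; A-C is permitted
# only by the folding engine)
_STEM_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}
_WOBBLE = {"GU", "UG"}

DEFAULT_STEM_SPAN = 16
DEFAULT_MIN_STEM = 3
DEFAULT_MAX_BULGE = 2
MIN_DOWNSTREAM_BP = 3

# stem boxes as arm offsets from the loop (offset 1 = adjacent to the loop),
# following the ladder of functional boxes from the loop down the stem:
# initial binding and positioning box, binding stability box, middle box,
# cleavage efficiency box (the scissile phosphates sit at offsets 14-15).
BOX_OFFSETS: dict[str, tuple[int, ...]] = {
    "IBPB": (1, 2, 3, 4),
    "BSB": (5, 6, 7, 8),
    "MB": (9, 10, 11, 12),
    "CEB": (13, 14, 15, 16),
}
CLEAVAGE_OFFSETS = (14, 15)  # arm offsets of the scissile phosphates


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
    return seq.translate(comp)[::-1]


def _stem_pair(a: str, b: str) -> bool:
    return a + b in _STEM_PAIRS


# --------------------------------------------------------------------------
# candidates
# --------------------------------------------------------------------------

@dataclasses.dataclass
class LoopCandidate:
    """An enumerated stem-loop candidate in genome coordinates."""

    interval: GenomicInterval       # full stem-loop span (clipped at contig ends)
    loop_interval: GenomicInterval  # the 4-nt loop
    loop_seq: str
    frame_seq: str                  # up arm + loop + down arm, N-padded
    up_arm: str                     # 5' arm, position 0 adjacent to the loop
    down_arm: str                   # 3' arm, position 0 adjacent to the loop
    pairing_up: np.ndarray          # bool per arm offset
    pairing_down: np.ndarray
    downstream_bp: int              # consecutive stable pairs closing the loop
    wobble_proximal: bool
    dG: float
    components: tuple[float, float, float] | None = None
    score: float | None = None


def _pair_arms(
    up: str, down: str, max_bulge: int = DEFAULT_MAX_BULGE
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Greedy bulge-aware pairing walk from the loop outward.

    Returns per-offset paired flags for each arm and the list of paired
    (up_offset, down_offset) steps. A single-position lookahead spends the
    per-arm bulge budget only when skipping restores pairing.
    """
    nu, nd = len(up), len(down)
    pu = np.zeros(nu, dtype=bool)
    pd = np.zeros(nd, dtype=bool)
    steps: list[tuple[int, int]] = []
    a = b = 0
    bu = bd = 0  # bulges spent per arm
    while a < nu and b < nd:
        if _stem_pair(up[a], down[b]):
            pu[a] = pd[b] = True
            steps.append((a, b))
            a += 1
            b += 1
        elif bd < max_bulge and b + 1 < nd and _stem_pair(up[a], down[b + 1]):
            b += 1
            bd += 1
        elif bu < max_bulge and a + 1 < nu and _stem_pair(up[a + 1], down[b]):
            a += 1
            bu += 1
        else:
            a += 1
            b += 1
    return pu, pd, steps


def _hairpin_dG(loop_seq: str, up: str, down: str, steps: list[tuple[int, int]]) -> float:
    """Hairpin-constrained free energy of the candidate's own stem-loop:
    loop penalty plus stack terms over directly adjacent paired steps."""
    if not steps:
        return 0.0
    dg = hairpin_penalty(len(loop_seq))
    for (a1, b1), (a2, b2) in zip(steps, steps[1:]):
        if a2 == a1 + 1 and b2 == b1 + 1:
            # outer pair is the one farther from the loop
            outer = up[a2] + down[b2]
            inner = up[a1] + down[b1]
            dg += stack_energy(outer, inner)
    return min(dg, 0.0) if dg < 0 else dg


def enumerate_candidates(
    sequence: str,
    contig: str = "seq",
    strand: str = "both",
    min_stem: int = DEFAULT_MIN_STEM,
    stem_span: int = DEFAULT_STEM_SPAN,
    max_bulge: int = DEFAULT_MAX_BULGE,
) -> list[LoopCandidate]:
    """Enumerate NGNN stem-loop candidates on one or both strands.

    A position yields a candidate when its 4-nt loop window has G at loop
    position 2 and the flanks form >= ``min_stem`` consecutive stable pairs
    (Watson-Crick or G-U) closing the loop. Arms are then evaluated over
    ``stem_span`` positions each side with up to ``max_bulge`` unpaired
    positions per arm.
    """
    seq = sequence.upper().replace("T", "U")
    out: list[LoopCandidate] = []
    strands = ["+", "-"] if strand == "both" else [strand]
    n = len(seq)
    for st in strands:
        s = seq if st == "+" else revcomp(seq)
        for i in _loop_positions(s, min_stem):
            cand = _build_candidate(s, i, contig, st, n, stem_span, max_bulge)
            out.append(cand)
    out.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.strand))
    return out


def _loop_positions(s: str, min_stem: int) -> np.ndarray:
    """Vectorised scan: loop start positions i with G at i+1 and min_stem
    consecutive closing stable pairs seq[i-k] : seq[i+3+k], k = 1..min_stem."""
    n = len(s)
    if n < 4 + 2 * min_stem:
        return np.array([], dtype=int)
    code = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, v in _CODE.items():
        lut[ord(b)] = v
    c = lut[code]
    pairmat = np.zeros((5, 5), dtype=bool)
    for p in _STEM_PAIRS:
        pairmat[_CODE[p[0]], _CODE[p[1]]] = True
    ok = np.zeros(n, dtype=bool)
    lo, hi = min_stem, n - 3 - min_stem  # valid loop starts
    if hi <= lo:
        return np.array([], dtype=int)
    idx = np.arange(lo, hi)
    good = c[idx + 1] == _CODE["G"]
    for k in range(1, min_stem + 1):
        good &= pairmat[c[idx - k], c[idx + 3 + k]]
    ok[idx[good]] = True
    return np.flatnonzero(ok)


def _build_candidate(
    s: str, i: int, contig: str, st: str, n: int, stem_span: int, max_bulge: int
) -> LoopCandidate:
    loop_seq = s[i : i + 4]
    up = s[max(0, i - stem_span) : i][::-1]  # position 0 adjacent to the loop
    up = up + "N" * (stem_span - len(up))
    down = s[i + 4 : i + 4 + stem_span]
    down = down + "N" * (stem_span - len(down))
    pu, pd, steps = _pair_arms(up, down, max_bulge)

    # consecutive stable closing pairs, strictly positional
    k = 0
    while k < stem_span and _stem_pair(up[k], down[k]):
        k += 1
    wobble = any(up[j] + down[j] in _WOBBLE for j in (0, 1) if j < stem_span)
    dg = _hairpin_dG(loop_seq, up, down, steps)

    span_lo = max(0, i - stem_span)
    span_hi = min(len(s), i + 4 + stem_span)
    if st == "+":
        interval = GenomicInterval(contig, span_lo, span_hi, "+")
        loop_iv = GenomicInterval(contig, i, i + 4, "+")
    else:
        interval = GenomicInterval(contig, n - span_hi, n - span_lo, "-")
        loop_iv = GenomicInterval(contig, n - (i + 4), n - i, "-")
    frame = up[::-1] + loop_seq + down
    return LoopCandidate(
        interval=interval,
        loop_interval=loop_iv,
        loop_seq=loop_seq,
        frame_seq=frame,
        up_arm=up,
        down_arm=down,
        pairing_up=pu,
        pairing_down=pd,
        downstream_bp=k,
        wobble_proximal=wobble,
        dG=dg,
    )


def candidate_from_hairpin(
    sequence: str,
    loop_start: int,
    contig: str = "seq",
    strand: str = "+",
    stem_span: int = DEFAULT_STEM_SPAN,
    max_bulge: int = DEFAULT_MAX_BULGE,
) -> LoopCandidate:
    """Build a candidate at a known loop position (used for training
    substrates and planted loops), without the enumeration stem filter."""
    seq = sequence.upper().replace("T", "U")
    return _build_candidate(seq, loop_start, contig, strand, len(seq), stem_span, max_bulge)


# --------------------------------------------------------------------------
# scoring model
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ScoringModel:
    """Trained positional weights and component weights for the 0-1 score."""

    loop_weights: np.ndarray            # (4 positions, 4 bases) log2-odds
    box_weights: np.ndarray             # (stem_span, 4 bases) log2-odds, 3' arm
    pairing_weights: np.ndarray         # (stem_span,) pairing fraction
    component_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    cutoff: float = 0.85
    stem_span: int = DEFAULT_STEM_SPAN
    conservation_enabled: bool = False
    cleavage_offsets: tuple[int, ...] = CLEAVAGE_OFFSETS
    similarity_refs: list[str] = dataclasses.field(default_factory=list)
    # per-component min-max normalisation bounds; the sequence bounds default
    # to the achievable PWM range at training, and all three are typically
    # re-anchored to the empirical background distribution at calibration so
    # the score spreads over [0, 1] the way the published score does
    seq_lo: float = 0.0
    seq_hi: float = 1.0
    struct_lo: float = 0.0
    struct_hi: float = 1.0
    sim_lo: float = 0.0
    sim_hi: float = 1.0
    stability_center: float = -10.0     # kcal/mol, logistic midpoint
    stability_scale: float = 3.0
    struct_mix: float = 0.5             # weight of stability inside c_structure

    def __post_init__(self) -> None:
        w = np.asarray(self.component_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("component_weights must be nonnegative and sum to 1")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "loop_weights": self.loop_weights.tolist(),
            "box_weights": self.box_weights.tolist(),
            "pairing_weights": self.pairing_weights.tolist(),
            "component_weights": list(self.component_weights),
            "cutoff": self.cutoff,
            "stem_span": self.stem_span,
            "conservation_enabled": self.conservation_enabled,
            "cleavage_offsets": list(self.cleavage_offsets),
            "similarity_refs": self.similarity_refs,
            "seq_lo": self.seq_lo,
            "seq_hi": self.seq_hi,
            "struct_lo": self.struct_lo,
            "struct_hi": self.struct_hi,
            "sim_lo": self.sim_lo,
            "sim_hi": self.sim_hi,
            "stability_center": self.stability_center,
            "stability_scale": self.stability_scale,
            "struct_mix": self.struct_mix,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoringModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            loop_weights=np.array(d["loop_weights"]),
            box_weights=np.array(d["box_weights"]),
            pairing_weights=np.array(d["pairing_weights"]),
            component_weights=tuple(d["component_weights"]),
            cutoff=d["cutoff"],
            stem_span=d["stem_span"],
            conservation_enabled=d["conservation_enabled"],
            cleavage_offsets=tuple(d["cleavage_offsets"]),
            similarity_refs=d["similarity_refs"],
            seq_lo=d["seq_lo"],
            seq_hi=d["seq_hi"],
            struct_lo=d.get("struct_lo", 0.0),
            struct_hi=d.get("struct_hi", 1.0),
            sim_lo=d.get("sim_lo", 0.0),
            sim_hi=d.get("sim_hi", 1.0),
            stability_center=d["stability_center"],
            stability_scale=d["stability_scale"],
            struct_mix=d["struct_mix"],
        )


def train_model(
    substrates: Sequence[tuple[str, str, int]],
    background_freqs: Mapping[str, float] | None = None,
    conservation: Mapping[str, Sequence[float]] | None = None,
    stem_span: int = DEFAULT_STEM_SPAN,
    pseudocount: float = 0.5,
) -> ScoringModel:
    """Train positional log-odds and pairing weights from curated substrates.

    ``substrates`` are (name, sequence, loop_start) with the loop anchored at
    ``loop_start``. With no conservation alignments the conservation
    component is disabled and its weight mass is redistributed to the
    remaining components (handled via component_weights staying a 3-simplex).
    """
    if len(substrates) < 10:
        raise ValueError(
            "need at least 10 substrates with aligned loop anchors; "
            "see the packaged synthetic fixture set"
        )
    bg = np.array(
        [background_freqs.get(b, 0.25) if background_freqs else 0.25 for b in BASES]
    )
    bg = bg / bg.sum()

    loop_counts = np.zeros((4, 4))
    box_counts = np.zeros((stem_span, 4))
    pair_counts = np.zeros(stem_span)
    pair_total = np.zeros(stem_span)
    refs = []
    for _, seq, loop_start in substrates:
        cand = candidate_from_hairpin(seq, loop_start, stem_span=stem_span)
        refs.append(cand.frame_seq)
        for pos, base in enumerate(cand.loop_seq):
            if base in BASES:
                loop_counts[pos, _CODE[base]] += 1
        for off in range(stem_span):
            base = cand.down_arm[off]
            if base in BASES:
                box_counts[off, _CODE[base]] += 1
            if cand.down_arm[off] != "N" or cand.up_arm[off] != "N":
                pair_total[off] += 1
                pair_counts[off] += float(
                    cand.pairing_down[off] or cand.pairing_up[off]
                )

    def log_odds(counts: np.ndarray) -> np.ndarray:
        freq = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        return np.log2(freq / bg)

    lw = log_odds(loop_counts)
    bw = log_odds(box_counts)
    pw = np.divide(pair_counts, np.maximum(pair_total, 1))

    box_mask = np.zeros(stem_span, dtype=bool)
    for offsets in BOX_OFFSETS.values():
        for off in offsets:
            if off - 1 < stem_span:
                box_mask[off - 1] = True
    lo = lw.min(axis=1).sum() + bw[box_mask].min(axis=1).sum()
    hi = lw.max(axis=1).sum() + bw[box_mask].max(axis=1).sum()

    return ScoringModel(
        loop_weights=lw,
        box_weights=bw,
        pairing_weights=pw,
        conservation_enabled=conservation is not None,
        similarity_refs=refs,
        seq_lo=float(lo),
        seq_hi=float(hi),
        stem_span=stem_span,
    )


# --------------------------------------------------------------------------
# component computation (batch, vectorised)
# --------------------------------------------------------------------------

def _encode(frames: Sequence[str]) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for b, v in _CODE.items():
        lut[ord(b)] = v
    return np.vstack([lut[np.frombuffer(f.encode(), dtype=np.uint8)] for f in frames])


def _batch_similarity(
    frames: Sequence[str], refs: Sequence[str], band: int = 4, batch: int = 4096
) -> np.ndarray:
    """Best banded global-alignment score (+1 match / -1 mismatch / -2 gap)
    of each frame against any reference, normalised by the frame length."""
    if not refs:
        return np.zeros(len(frames))
    L = len(frames[0])
    R = _encode(refs)
    out = np.empty(len(frames))
    for start in range(0, len(frames), batch):
        chunk = frames[start : start + batch]
        C = _encode(chunk)
        ncand, nref = len(chunk), len(refs)
        P = ncand * nref
        candc = np.repeat(C, nref, axis=0)
        refc = np.tile(R, (ncand, 1))
        W = 2 * band + 1
        NEG = -1e9
        prev = np.full((W, P), NEG)
        for d in range(band, W):  # row 0: j = d - band
            j = d - band
            prev[d] = -2.0 * j
        for i in range(1, L + 1):
            cur = np.full((W, P), NEG)
            ci = candc[:, i - 1]
            for d in range(W):
                j = i + d - band
                if j < 0 or j > L:
                    continue
                best = np.full(P, NEG)
                if j >= 1:
                    sub = np.where((ci == refc[:, j - 1]) & (ci < 4), 1.0, -1.0)
                    best = prev[d] + sub  # diagonal: (i-1, j-1) is same d
                if d + 1 < W:
                    best = np.maximum(best, prev[d + 1] - 2.0)  # gap in ref
                if d >= 1:
                    best = np.maximum(best, cur[d - 1] - 2.0)  # gap in frame
                if j == 0:
                    best = np.maximum(best, -2.0 * i)
                cur[d] = best
            prev = cur
        final = prev[band].reshape(ncand, nref)  # j == L at row L
        out[start : start + batch] = final.max(axis=1) / L
    return np.clip(out, 0.0, 1.0)


def raw_components(
    candidates: Sequence[LoopCandidate], model: ScoringModel
) -> np.ndarray:
    """(n, 3) array of pre-normalisation component values: the PWM log-odds
    sum, the pairing-agreement/stability blend, and the best normalised
    alignment score."""
    if not candidates:
        return np.zeros((0, 3))
    span = model.stem_span
    for c in candidates:
        if len(c.up_arm) != span:
            raise ValueError("candidate/model stem_span frame mismatch")

    box_mask = np.zeros(span, dtype=bool)
    for offsets in BOX_OFFSETS.values():
        for off in offsets:
            if off - 1 < span:
                box_mask[off - 1] = True

    n = len(candidates)
    c_seq = np.zeros(n)
    c_struct = np.zeros(n)
    pw = model.pairing_weights
    for k, cand in enumerate(candidates):
        s = 0.0
        for pos, base in enumerate(cand.loop_seq):
            if base in BASES:
                s += model.loop_weights[pos, _CODE[base]]
        for off in np.flatnonzero(box_mask):
            base = cand.down_arm[off]
            if base in BASES:
                s += model.box_weights[off, _CODE[base]]
        c_seq[k] = s
        obs = 0.5 * (cand.pairing_up.astype(float) + cand.pairing_down.astype(float))
        agreement = 1.0 - float(np.mean(np.abs(obs - pw)))
        stability = 1.0 / (
            1.0 + math.exp((cand.dG - model.stability_center) / model.stability_scale)
        )
        c_struct[k] = (1 - model.struct_mix) * agreement + model.struct_mix * stability

    c_sim = _batch_similarity([c.frame_seq for c in candidates], model.similarity_refs)
    return np.column_stack([c_seq, c_struct, c_sim])


def compute_components(
    candidates: Sequence[LoopCandidate], model: ScoringModel
) -> np.ndarray:
    """(n, 3) array of (c_sequence, c_structure, c_similarity), each min-max
    normalised through the model's per-component bounds and clipped to [0, 1]."""
    raw = raw_components(candidates, model)
    if raw.size == 0:
        return raw
    bounds = [
        (model.seq_lo, model.seq_hi),
        (model.struct_lo, model.struct_hi),
        (model.sim_lo, model.sim_hi),
    ]
    out = np.empty_like(raw)
    for k, (lo, hi) in enumerate(bounds):
        out[:, k] = np.clip((raw[:, k] - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
    return out


def fit_background_normalization(
    model: ScoringModel,
    background_candidates: Sequence[LoopCandidate],
    q_lo: float = 0.001,
    q_hi: float = 0.98,
) -> ScoringModel:
    """Anchor each component's min-max bounds to the empirical quantiles of
    the background candidate distribution, so component values (and hence
    scores) spread over [0, 1] on genomic background rather than clustering."""
    raw = raw_components(background_candidates, model)
    if len(raw) < 100:
        raise ValueError("need >= 100 background candidates to fit normalisation")
    lo = np.quantile(raw, q_lo, axis=0)
    hi = np.quantile(raw, q_hi, axis=0)
    return dataclasses.replace(
        model,
        seq_lo=float(lo[0]), seq_hi=float(hi[0]),
        struct_lo=float(lo[1]), struct_hi=float(hi[1]),
        sim_lo=float(lo[2]), sim_hi=float(hi[2]),
    )


def score_candidate(candidate: LoopCandidate, model: ScoringModel) -> LoopCandidate:
    """Score one candidate in place (returns it for chaining). Candidates
    with fewer than three stable pairs closing the loop get no score."""
    comp = compute_components([candidate], model)[0]
    candidate.components = tuple(float(x) for x in comp)
    if candidate.downstream_bp < MIN_DOWNSTREAM_BP:
        candidate.score = None
        return candidate
    w = np.asarray(model.component_weights)
    candidate.score = float(np.clip(w @ comp, 0.0, 1.0))
    return candidate


def score_candidates(
    candidates: Sequence[LoopCandidate], model: ScoringModel
) -> list[LoopCandidate]:
    comps = compute_components(candidates, model)
    w = np.asarray(model.component_weights)
    scores = np.clip(comps @ w, 0.0, 1.0)
    for cand, comp, sc in zip(candidates, comps, scores):
        cand.components = tuple(float(x) for x in comp)
        cand.score = float(sc) if cand.downstream_bp >= MIN_DOWNSTREAM_BP else None
    return list(candidates)


# --------------------------------------------------------------------------
# genome scan
# --------------------------------------------------------------------------

def scan_genome(
    genome: Mapping[str, str],
    model: ScoringModel,
    cutoff: float | None = None,
    min_stem: int = DEFAULT_MIN_STEM,
) -> tuple[list[LoopCandidate], dict]:
    """Scan both strands of every contig; return hits (score >= cutoff,
    coordinate-sorted) and a summary with candidate/hit counts and density."""
    cutoff = model.cutoff if cutoff is None else cutoff
    hits: list[LoopCandidate] = []
    total_candidates = 0
    scanned_nt = 0
    for contig, seq in genome.items():
        scanned_nt += 2 * len(seq)
        cands = enumerate_candidates(
            seq, contig=contig, strand="both", min_stem=min_stem,
            stem_span=model.stem_span,
        )
        total_candidates += len(cands)
        score_candidates(cands, model)
        hits.extend(c for c in cands if c.score is not None and c.score >= cutoff)
    hits.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.strand))
    summary = {
        "total_candidates": total_candidates,
        "hits": len(hits),
        "scanned_nt": scanned_nt,
        "spacing_kb": density(hits, scanned_nt),
    }
    return hits, summary


def density(hits: Sequence, scanned_nt: int) -> float:
    """Mean spacing in kb per hit over the both-strand scanned length;
    infinite when there are no hits."""
    if scanned_nt <= 0:
        raise ValueError("scanned_nt must be positive")
    if len(hits) == 0:
        return math.inf
    return scanned_nt / len(hits) / 1000.0


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

_NCRNA_TYPES = {"ncRNA", "snoRNA", "snRNA", "rRNA", "tRNA", "ncRNA_gene"}
_PCG_TYPES = {"gene", "mRNA", "CDS", "protein_coding_gene"}
_LTR_TYPES = {"LTR", "long_terminal_repeat", "LTR_retrotransposon"}

CATEGORIES = ("ncRNA", "PCG-sense", "LTR", "antisense", "intergenic")


def annotate_hits(
    hits: Sequence[LoopCandidate], features: Sequence[Feature]
) -> list[str]:
    """Category per hit with precedence ncRNA > PCG-sense > LTR > antisense
    > intergenic. Sense categories require strand agreement; LTR overlap is
    strand-blind; antisense is an opposite-strand gene/ncRNA overlap."""
    out = []
    for hit in hits:
        iv = hit.interval
        same_nc = same_pcg = ltr = anti = False
        for f in features:
            if not iv.overlaps(f.interval):
                continue
            same = f.interval.strand == iv.strand
            if f.ftype in _NCRNA_TYPES:
                same_nc |= same
                anti |= not same
            elif f.ftype in _PCG_TYPES:
                same_pcg |= same
                anti |= not same
            elif f.ftype in _LTR_TYPES:
                ltr = True
        if same_nc:
            out.append("ncRNA")
        elif same_pcg:
            out.append("PCG-sense")
        elif ltr:
            out.append("LTR")
        elif anti:
            out.append("antisense")
        else:
            out.append("intergenic")
    return out


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationReport:
    weights: tuple[float, float, float]
    fixture_fraction: float
    background_spacing_kb: float
    feasible: bool
    grid: list[dict]


def calibrate_model(
    model: ScoringModel,
    fixture_candidates: Sequence[LoopCandidate],
    background_candidates: Sequence[LoopCandidate],
    scanned_nt: int,
    min_fixture_fraction: float = 0.8,
    spacing_band_kb: tuple[float, float] = (1.5, 6.0),
    grid_step: float = 0.025,
) -> tuple[ScoringModel, CalibrationReport]:
    """Grid search over component weights on the simplex so that at least
    ``min_fixture_fraction`` of the fixture substrates score >= cutoff and
    the background hit spacing falls inside ``spacing_band_kb``.

    Among feasible weights the fixture fraction is maximised, with spacing
    closest to the band centre as tie-break. Raises with the best achieved
    values when no grid point is feasible.
    """
    fix_c = compute_components(fixture_candidates, model)
    bg_c = compute_components(background_candidates, model)
    bg_eligible = np.array(
        [c.downstream_bp >= MIN_DOWNSTREAM_BP for c in background_candidates]
    )
    fix_eligible = np.array(
        [c.downstream_bp >= MIN_DOWNSTREAM_BP for c in fixture_candidates]
    )
    lo_kb, hi_kb = spacing_band_kb
    mid = (lo_kb + hi_kb) / 2

    def evaluate(w: np.ndarray) -> tuple[float, float]:
        fs = np.clip(fix_c @ w, 0, 1)
        frac = float(np.mean((fs >= model.cutoff) & fix_eligible))
        bs = np.clip(bg_c @ w, 0, 1)
        nhits = int(np.sum((bs >= model.cutoff) & bg_eligible))
        spacing = scanned_nt / nhits / 1000.0 if nhits else math.inf
        return frac, spacing

    # fixed point: keep the current model when it already satisfies both
    w0 = np.asarray(model.component_weights)
    frac0, spacing0 = evaluate(w0)
    if frac0 >= min_fixture_fraction and lo_kb <= spacing0 <= hi_kb:
        report = CalibrationReport(
            tuple(w0), frac0, spacing0, True,
            [{"weights": tuple(w0), "fixture_fraction": frac0, "spacing_kb": spacing0}],
        )
        return model, report

    best = None
    best_any = None
    grid = []
    steps = int(round(1.0 / grid_step))
    for a in range(steps + 1):
        for b in range(steps + 1 - a):
            w = np.array([a * grid_step, b * grid_step, 1.0 - (a + b) * grid_step])
            frac, spacing = evaluate(w)
            grid.append({"weights": tuple(w), "fixture_fraction": frac, "spacing_kb": spacing})
            feasible = frac >= min_fixture_fraction and lo_kb <= spacing <= hi_kb
            key = (
                frac,
                -round(abs(spacing - mid), 1) if math.isfinite(spacing) else -math.inf,
                -float(w.max()),  # prefer balanced weights among near-ties
            )
            if feasible and (best is None or key > best[0]):
                best = (key, w, frac, spacing)
            band_dist = (
                abs(spacing - mid) if math.isfinite(spacing) else 1e9
            )
            any_key = (min(frac, min_fixture_fraction), -band_dist)
            if best_any is None or any_key > best_any[0]:
                best_any = (any_key, w, frac, spacing)
    if best is None:
        _, w, frac, spacing = best_any
        raise ValueError(
            "calibration infeasible: best achieved fixture fraction "
            f"{frac:.3f} at spacing {spacing:.2f} kb with weights {tuple(w)}"
        )
    _, w, frac, spacing = best
    calibrated = dataclasses.replace(model, component_weights=tuple(float(x) for x in w))
    return calibrated, CalibrationReport(tuple(float(x) for x in w), frac, spacing, True, grid)


# --------------------------------------------------------------------------
# packaged defaults
# --------------------------------------------------------------------------

def default_substrates() -> list[tuple[str, str, int]]:
    """The packaged synthetic stand-in for a curated substrate table:
    (name, sequence, loop_start) triples."""
    text = resources.files("rnt1kit.data").joinpath(
        "known_substrates_synthetic.tsv"
    ).read_text()
    out = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, seq, loop_start = line.split("\t")
        out.append((name, seq, int(loop_start)))
    return out


def default_model() -> ScoringModel:
    """The shipped calibrated scoring model."""
    text = resources.files("rnt1kit.data").joinpath("default_model.json").read_text()
    return ScoringModel.from_json(text)
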