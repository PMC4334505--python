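"""Tiling-array probe correction, normalisation and changepoint segmentation.

The expression and Cut-and-Chip callers share three steps implemented here:

1. probe-level hybridisation-energy correction — probes with the strongest
   predicted duplex ΔG (G/C-rich, prone to saturation) are dropped and the
   residual log-intensity ~ ΔG trend is regressed out per sample;
2. one of four normalisation variants producing per-probe log2 ratios
   between two samples (mutant vs wild type, or treated vs untreated);
3. an exact least-squares piecewise-constant segmentation with the number
   of segments selected by BIC.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .core_io import Feature, GenomicInterval, ProbeRecord

# SantaLucia-style DNA nearest-neighbour duplex free energies, kcal/mol,
# 37 C, 1 M NaCl. Keyed by the top-strand dinucleotide 5'->3'.
NN_DG: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}
_INIT_DG = 1.96  # duplex initiation


def probe_dG(sequence: str) -> float:
    """Nearest-neighbour hybridisation free energy of a probe duplex.

    More G/C-rich sequences give more negative values; the value is strand
    symmetric (a probe and its reverse complement hybridise with the same
    ΔG). U is treated as T.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotide(s) in probe sequence: {sorted(bad)}")
    if len(seq) < 2:
        raise ValueError("probe sequence must be at least 2 nt")
    return _INIT_DG + sum(NN_DG[seq[i : i + 2]] for i in range(len(seq) - 1))


# --------------------------------------------------------------------------
# probe correction
# --------------------------------------------------------------------------

def correct_probes(
    probes: Sequence[ProbeRecord],
    tail_fraction: float = 0.05,
    strongest_negative: bool = True,
) -> list[ProbeRecord]:
    """Drop the ``tail_fraction`` of probes with the strongest predicted
    hybridisation (most negative ΔG by default) and residualise the per-sample
    OLS of log2 intensity on ΔG so the post-fit slope is zero and the mean
    adjustment is zero. Returns new records with corrected intensities.
    """
    if len(probes) < 20:
        raise ValueError("need at least 20 probes for the 5% tail removal")
    dgs = np.array(
        [p.hyb_dG if p.hyb_dG is not None else probe_dG(p.sequence) for p in probes]
    )
    order = np.argsort(dgs) if strongest_negative else np.argsort(-dgs)
    n_drop = int(round(tail_fraction * len(probes)))
    dropped = set(order[:n_drop].tolist())
    kept = [i for i in range(len(probes)) if i not in dropped]

    samples = list(probes[0].intensity)
    dg_kept = dgs[kept]
    dg_centered = dg_kept - dg_kept.mean()
    corrected = []
    log2 = {}
    for s in samples:
        y = np.log2(np.maximum([probes[i].intensity[s] for i in kept], 1e-12))
        slope = float(dg_centered @ (y - y.mean()) / (dg_centered @ dg_centered))
        log2[s] = y - slope * dg_centered  # mean-zero adjustment, null slope
    for rank, i in enumerate(kept):
        p = probes[i]
        corrected.append(
            ProbeRecord(
                probe_id=p.probe_id,
                interval=p.interval,
                sequence=p.sequence,
                unique=p.unique,
                intensity={s: float(2.0 ** log2[s][rank]) for s in samples},
                hyb_dG=float(dgs[i]),
            )
        )
    return corrected


# --------------------------------------------------------------------------
# normalisation
# --------------------------------------------------------------------------

def _probe_in_features(
    probe: ProbeRecord, features: Iterable[Feature], same_strand: bool = True
) -> bool:
    for f in features:
        if probe.interval.overlaps(f.interval) and (
            not same_strand or probe.interval.strand == f.interval.strand
        ):
            return True
    return False


def _intergenic_mask(probes: Sequence[ProbeRecord], features: Sequence[Feature]) -> np.ndarray:
    gene_like = [f for f in features if f.ftype not in ("intergenic",)]
    return np.array(
        [not _probe_in_features(p, gene_like, same_strand=False) for p in probes]
    )


def normalize(
    probes: Sequence[ProbeRecord],
    sample_a: str,
    sample_b: str,
    method: str = "reference_genes",
    reference_genes: Sequence[str] | None = None,
    features: Sequence[Feature] | None = None,
    floor_genes: Sequence[str] | None = None,
    lts_quantile: float = 0.5,
    exclude_changed_fraction: float = 0.05,
) -> np.ndarray:
    """Per-probe log2 ratio of ``sample_a`` over ``sample_b`` under one of
    four normalisation variants.

    reference_genes
        subtract the median log2 ratio over probes inside the listed genes
        (constitutive references such as ACT1 and the Pol III transcripts).
    intergenic
        subtract the median log2 ratio over intergenic probes, after
        excluding the ``exclude_changed_fraction`` most changed ones.
    combined
        reference set is the union of the two above.
    vsn_robust
        affine + generalised-log (asinh) calibration of sample_a onto
        sample_b fitted by least-trimmed squares at ``lts_quantile``.

    ``floor_genes`` (absent auxotrophic deletions) optionally anchor the
    scale so their probes take the minimum ratio.
    """
    a = np.array([p.intensity[sample_a] for p in probes], dtype=float)
    b = np.array([p.intensity[sample_b] for p in probes], dtype=float)
    la = np.log2(np.maximum(a, 1e-12))
    lb = np.log2(np.maximum(b, 1e-12))
    ratio = la - lb

    def _ref_gene_mask() -> np.ndarray:
        if not reference_genes or features is None:
            raise ValueError("reference_genes method needs gene list and annotation")
        refs = [f for f in features if f.name in set(reference_genes)]
        return np.array([_probe_in_features(p, refs) for p in probes])

    def _intergenic_ref_mask() -> np.ndarray:
        if features is None:
            raise ValueError("intergenic method needs annotation")
        mask = _intergenic_mask(probes, features)
        if mask.sum() == 0:
            raise ValueError("no intergenic probes after exclusions")
        # drop the most changed intergenic probes
        idx = np.flatnonzero(mask)
        changed = np.abs(ratio[idx] - np.median(ratio[idx]))
        n_drop = int(round(exclude_changed_fraction * len(idx)))
        if n_drop:
            drop = idx[np.argsort(-changed)[:n_drop]]
            mask = mask.copy()
            mask[drop] = False
        return mask

    if method == "reference_genes":
        mask = _ref_gene_mask()
    elif method == "intergenic":
        mask = _intergenic_ref_mask()
    elif method == "combined":
        mask = _ref_gene_mask() | _intergenic_ref_mask()
    elif method == "vsn_robust":
        out = _vsn_robust(a, b, lts_quantile)
        return _apply_floor(out, probes, floor_genes, features)
    else:
        raise ValueError(f"unknown normalisation method: {method!r}")

    if mask.sum() == 0:
        raise ValueError("empty reference set after exclusions")
    out = ratio - np.median(ratio[mask])
    return _apply_floor(out, probes, floor_genes, features)


def _vsn_robust(a: np.ndarray, b: np.ndarray, lts_quantile: float) -> np.ndarray:
    """Least-trimmed-squares fit of a gain/offset for sample a against b on
    the asinh (generalised log) scale, iterated to convergence."""
    from scipy.optimize import minimize

    scale = max(np.median(b), 1e-9)
    hb = np.arcsinh(b / scale)

    def trimmed_loss(params: np.ndarray) -> float:
        gain, offset = params
        ha = np.arcsinh((a * np.exp(gain) + offset) / scale)
        resid = (ha - hb) ** 2
        k = max(3, int(lts_quantile * len(resid)))
        return float(np.sort(resid)[:k].sum())

    res = minimize(trimmed_loss, x0=np.array([0.0, 0.0]), method="Nelder-Mead")
    gain, offset = res.x
    ha = np.arcsinh((a * np.exp(gain) + offset) / scale)
    return (ha - hb) / np.log(2)


def _apply_floor(ratio, probes, floor_genes, features):
    if not floor_genes or features is None:
        return ratio
    floors = [f for f in features if f.name in set(floor_genes)]
    mask = np.array([_probe_in_features(p, floors) for p in probes])
    if mask.any():
        shift = ratio[mask].max() - ratio.min()
        ratio = ratio.copy()
        ratio[mask] -= shift
    return ratio


# --------------------------------------------------------------------------
# changepoint segmentation
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SegmentCall:
    """A piecewise-constant segment of the per-probe statistic.

    ``level`` is the median of the member-probe values (the reported level),
    distinct from the least-squares mean used in the fitting objective.
    """

    interval: GenomicInterval
    level: float
    probe_ids: list[str]
    n_probes_unique: int


def segment_values(
    values: Sequence[float], max_segments: int = 10
) -> tuple[list[int], list[tuple[int, int]]]:
    """Exact least-squares changepoint segmentation with BIC model selection.

    For each S <= max_segments the boundaries minimising the residual sum
    of squares of the piecewise-constant (segment-mean) fit are found by
    dynamic programming; S* minimises BIC = n*ln(RSS/n) + p*ln(n) with
    p = 2S - 1. Returns (changepoint indices, segment (start, end) spans),
    half-open over value indices.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values")
    max_segments = max(1, min(max_segments, n))

    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # RSS of fitting one mean over y[i:j] (vectorised over i)
        cnt = j - i
        s = c1[j] - c1[i]
        ss = c2[j] - c2[i]
        return ss - s * s / cnt

    # D[s][j]: best RSS splitting y[0:j] into s segments
    D = np.full((max_segments + 1, n + 1), np.inf)
    back = np.zeros((max_segments + 1, n + 1), dtype=int)
    idx = np.arange(n)
    D[1][1:] = [seg_cost(np.array([0]), j)[0] for j in range(1, n + 1)]
    for s in range(2, max_segments + 1):
        for j in range(s, n + 1):
            i = np.arange(s - 1, j)
            cand = D[s - 1][i] + seg_cost(i, j)
            k = int(np.argmin(cand))
            D[s][j] = cand[k]
            back[s][j] = i[k]

    best_bic, best_s = np.inf, 1
    for s in range(1, max_segments + 1):
        rss = max(D[s][n], 1e-12)
        bic = n * np.log(rss / n) + (2 * s - 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_s = bic, s
    # traceback
    bounds = [n]
    j, s = n, best_s
    while s > 1:
        j = int(back[s][j])
        bounds.append(j)
        s -= 1
    bounds.append(0)
    bounds = sorted(bounds)
    segments = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    changepoints = bounds[1:-1]
    return changepoints, segments


def best_rss(values: Sequence[float], n_segments: int) -> float:
    """Optimal piecewise-constant RSS at exactly ``n_segments`` segments
    (exposed for oracle comparison)."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(i, j):
        cnt = j - i
        s = c1[j] - c1[i]
        ss = c2[j] - c2[i]
        return ss - s * s / cnt

    D = np.full((n_segments + 1, n + 1), np.inf)
    D[0][0] = 0.0
    for s in range(1, n_segments + 1):
        for j in range(s, n + 1):
            i = np.arange(s - 1, j)
            D[s][j] = np.min(D[s - 1][i] + seg_cost(i, j))
    return float(D[n_segments][n])


def segment_probes(
    probes: Sequence[ProbeRecord],
    values: Sequence[float],
    max_segments: int = 10,
) -> list[SegmentCall]:
    """Segment per-probe statistics along one ordered strand track.

    Probes are grouped by (contig, strand) and ordered by start; each track
    is segmented independently and segment levels are probe medians.
    """
    if len(probes) != len(values):
        raise ValueError("probes and values length mismatch")
    tracks: dict[tuple[str, str], list[int]] = {}
    for i, p in enumerate(probes):
        tracks.setdefault((p.interval.contig, p.interval.strand), []).append(i)
    calls: list[SegmentCall] = []
    values = np.asarray(values, dtype=float)
    for (contig, strand), idxs in sorted(tracks.items()):
        idxs = sorted(idxs, key=lambda i: probes[i].interval.start)
        track_vals = values[idxs]
        if len(idxs) < 2:
            continue
        _, spans = segment_values(track_vals, max_segments=max_segments)
        for a, b in spans:
            members = [probes[idxs[k]] for k in range(a, b)]
            calls.append(
                SegmentCall(
                    interval=GenomicInterval(
                        contig,
                        members[0].interval.start,
                        members[-1].interval.end,
                        strand,
                    ),
                    level=float(np.median(track_vals[a:b])),
                    probe_ids=[m.probe_id for m in members],
                    n_probes_unique=sum(m.unique for m in members),
                )
            )
    return calls
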