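"""Cross-method comparison and validation statistics.

Covers the proportion estimate for in vitro validation of predicted loops
(with exact binomial confidence intervals), array-vs-qPCR concordance, the
ΔΔCt upregulation caller (> 1.2-fold and one-tailed t-test p < 0.01), 5'-P
end matching against in vivo RACE sites, and the method-overlap layer
(detection rates, Venn cardinalities, per-method score distributions).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import GenomicInterval, QpcrRecord


# --------------------------------------------------------------------------
# proportions
# --------------------------------------------------------------------------

def proportion_estimate(
    successes: int,
    n: int,
    ci_method: str = "clopper-pearson",
    level: float = 0.95,
    digits: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Percent point estimate with a binomial confidence interval.

    Returns (percent rounded to ``digits``, (lo_percent, hi_percent)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    from statsmodels.stats.proportion import proportion_confint

    method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=method)
    point = round(100.0 * successes / n, digits)
    if digits == 0:
        point = float(int(point))
    return point, (100.0 * float(lo), 100.0 * float(hi))


# --------------------------------------------------------------------------
# array vs qPCR concordance
# --------------------------------------------------------------------------

def concordance(
    array_log2: Sequence[float],
    qpcr_log2: Sequence[float],
    fold_threshold: float = 2.0,
) -> dict:
    """Spearman rank correlation (average-rank ties) plus directional
    concordance: among pairs with array log2 above log2(fold_threshold),
    the fraction whose qPCR fold also exceeds the threshold."""
    a = np.asarray(array_log2, dtype=float)
    q = np.asarray(qpcr_log2, dtype=float)
    if len(a) != len(q) or len(a) < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite values")
    rho, pval = sps.spearmanr(a, q)
    thr = np.log2(fold_threshold)
    up = a > thr
    concordant = float(np.mean(q[up] > thr)) if up.any() else float("nan")
    return {
        "rho": float(rho),
        "p": float(pval),
        "n": int(len(a)),
        "n_array_up": int(up.sum()),
        "directional_concordance": concordant,
    }


# --------------------------------------------------------------------------
# qPCR upregulation caller
# --------------------------------------------------------------------------

@dataclasses.dataclass
class UpregulationCall:
    gene: str
    condition: str
    fold: float
    p_value: float
    upregulated: bool


def call_upregulated(
    records: Sequence[QpcrRecord],
    fold_threshold: float = 1.2,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> tuple[list[UpregulationCall], dict[str, bool]]:
    """Per-gene, per-condition ΔΔCt caller.

    fold = 2^(mean ΔCt_wt - mean ΔCt_mut); a gene is upregulated in a
    condition iff fold > fold_threshold and the one-tailed two-sample t-test
    of mutant ΔCt < wild-type ΔCt gives p < alpha. Returns the per-condition
    calls and the any-condition union per gene.
    """
    groups: dict[tuple[str, str], dict[str, list[float]]] = {}
    for rec in records:
        key = (rec.gene, rec.condition)
        groups.setdefault(key, {"wild-type": [], "mutant": []})[rec.genotype].append(
            rec.delta_ct
        )
    calls = []
    union: dict[str, bool] = {}
    for (gene, condition), by_geno in sorted(groups.items()):
        wt = np.array(by_geno["wild-type"])
        mut = np.array(by_geno["mutant"])
        if len(wt) < 3 or len(mut) < 3:
            raise ValueError(
                f"{gene}/{condition}: need >= 3 replicates per genotype"
            )
        fold = float(2.0 ** (wt.mean() - mut.mean()))
        # one-tailed: mutant ΔCt smaller than wild type (higher expression)
        res = sps.ttest_ind(wt, mut, equal_var=equal_var, alternative="greater")
        up = fold > fold_threshold and res.pvalue < alpha
        calls.append(UpregulationCall(gene, condition, fold, float(res.pvalue), up))
        union[gene] = union.get(gene, False) or up
    return calls, union


# --------------------------------------------------------------------------
# in vivo 5'-P end matching
# --------------------------------------------------------------------------

def match_race_ends(
    product_3p_starts: Sequence[GenomicInterval],
    in_vivo_5pP_sites: Sequence[tuple[str, int, str]],
    window: int = 5,
) -> tuple[float, list[bool]]:
    """Fraction of 3' cleavage products whose 5' end has a RACE-detected
    5'-phosphate within its first ``window`` nucleotides (same strand).

    ``product_3p_starts`` intervals mark each product's 5'-most nucleotide
    span; sites are (contig, position, strand) with position 0-based.
    """
    matched = []
    for iv in product_3p_starts:
        start = iv.start if iv.strand == "+" else iv.end - 1
        hit = False
        for contig, pos, strand in in_vivo_5pP_sites:
            if contig != iv.contig or strand != iv.strand:
                continue
            offset = pos - start if iv.strand == "+" else start - pos
            if 0 <= offset < window:
                hit = True
                break
        matched.append(hit)
    frac = float(np.mean(matched)) if matched else 0.0
    return frac, matched


# --------------------------------------------------------------------------
# method comparison
# --------------------------------------------------------------------------

def compare_methods(
    call_sets: Mapping[str, set[str]],
    known_substrates: set[str],
    scores: Mapping[str, float] | None = None,
) -> dict:
    """Detection rates, all subset overlap cardinalities and per-method loop
    score distribution summaries.

    ``call_sets`` maps method name to the set of gene identifiers it called;
    ``scores`` optionally maps gene to its best loop score.
    """
    methods = list(call_sets)
    detection = {
        m: (
            len(call_sets[m] & known_substrates) / len(known_substrates)
            if known_substrates
            else float("nan")
        )
        for m in methods
    }
    universe = set().union(*call_sets.values()) if call_sets else set()
    overlaps = {}
    for r in range(1, len(methods) + 1):
        for combo in itertools.combinations(methods, r):
            inside = set(universe)
            for m in combo:
                inside &= call_sets[m]
            for m in methods:
                if m not in combo:
                    inside -= call_sets[m]
            overlaps["&".join(combo)] = len(inside)
    score_summary = {}
    if scores is not None:
        for m in methods:
            vals = sorted(scores[g] for g in call_sets[m] if g in scores)
            if vals:
                q = np.quantile(vals, [0.25, 0.5, 0.75])
                score_summary[m] = {
                    "n": len(vals),
                    "q25": float(q[0]),
                    "median": float(q[1]),
                    "q75": float(q[2]),
                }
    return {
        "detection_rates": detection,
        "overlaps": overlaps,
        "union_size": len(universe),
        "score_distributions": score_summary,
    }
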