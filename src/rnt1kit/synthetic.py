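"""Synthetic-data generators with ground-truth manifests.

Every pipeline in this package is validated by recovery tests on data whose
truth is known by construction: a first-order Markov genome with planted
stem-loops, two-genotype tiling-probe intensities with a hybridisation-ΔG
bias and lognormal noise, Cut-and-Chip treated/untreated pairs in which the
signal downstream of a cleavage site is attenuated, SALI read sets carrying
identical-copy internal cleavage fragments over a small-RNA background, and
ΔΔCt qPCR tables. Identical seeds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, ProbeRecord, QpcrRecord
from .motif import revcomp
from .segmentation import probe_dG

BASES = "ACGT"

# Yeast-like dinucleotide frequency table (GC ~ 0.38, mild AA/TT enrichment).
# This is a synthetic approximation of the S. cerevisiae composition, not a
# measured table; it exists so random backgrounds have realistic GC content.
def yeast_dinucleotide_freqs() -> np.ndarray:
    mono = np.array([0.31, 0.19, 0.19, 0.31])  # A C G T
    joint = np.outer(mono, mono)
    boost = np.ones((4, 4))
    boost[0, 0] = boost[3, 3] = 1.20  # AA / TT
    boost[0, 3] = boost[3, 0] = 1.08  # AT / TA
    joint = joint * boost
    return joint / joint.sum()


@dataclasses.dataclass
class PlantedLoop:
    interval: GenomicInterval       # full planted stem-loop span
    loop_interval: GenomicInterval  # the loop nucleotides
    loop_class: str
    loop_seq: str
    score_tier: str = "high"


@dataclasses.dataclass
class CleavageSite:
    """A planted double-cleavage event: the scissile span is the internal
    fragment released by cleavage on both sides of the loop."""

    interval: GenomicInterval  # internal-fragment span (between scissile positions)
    efficiency: float
    fragment_3p_len: int       # length of the 3' cleavage product, nt
    transcript: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")


@dataclasses.dataclass
class Transcript:
    name: str
    interval: GenomicInterval
    abundance: dict[str, float]  # sample -> linear abundance


@dataclasses.dataclass
class TruthManifest:
    seed: int
    planted_loops: list[PlantedLoop] = dataclasses.field(default_factory=list)
    planted_fold_changes: dict[str, float] = dataclasses.field(default_factory=dict)
    planted_cleavage_sites: list[CleavageSite] = dataclasses.field(default_factory=list)

    def validate(self, genome: Mapping[str, str]) -> None:
        for fold in self.planted_fold_changes.values():
            if fold <= 0:
                raise ValueError("fold changes must be positive")
        for loop in self.planted_loops:
            if loop.interval.end > len(genome[loop.interval.contig]):
                raise ValueError(f"planted loop {loop} outside genome")
        for site in self.planted_cleavage_sites:
            if site.interval.end > len(genome[site.interval.contig]):
                raise ValueError(f"planted site {site} outside genome")

    def to_json(self, path: str | Path | None = None) -> str:
        def iv(x: GenomicInterval):
            return [x.contig, x.start, x.end, x.strand]

        payload = {
            "seed": self.seed,
            "planted_loops": [
                {
                    "interval": iv(p.interval),
                    "loop_interval": iv(p.loop_interval),
                    "loop_class": p.loop_class,
                    "loop_seq": p.loop_seq,
                    "score_tier": p.score_tier,
                }
                for p in self.planted_loops
            ],
            "planted_fold_changes": self.planted_fold_changes,
            "planted_cleavage_sites": [
                {
                    "interval": iv(s.interval),
                    "efficiency": s.efficiency,
                    "fragment_3p_len": s.fragment_3p_len,
                    "transcript": s.transcript,
                }
                for s in self.planted_cleavage_sites
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------

def gen_genome(
    length: int,
    dinucleotide_freqs: np.ndarray | Mapping[str, float] | None = None,
    seed: int = 0,
    contig: str = "chrS",
) -> tuple[dict[str, str], TruthManifest]:
    """First-order Markov genome whose empirical dinucleotide frequencies
    converge to the requested 16-entry simplex as length grows."""
    if dinucleotide_freqs is None:
        joint = yeast_dinucleotide_freqs()
    elif isinstance(dinucleotide_freqs, Mapping):
        joint = np.zeros((4, 4))
        for key, value in dinucleotide_freqs.items():
            joint[BASES.index(key[0]), BASES.index(key[1])] = value
    else:
        joint = np.asarray(dinucleotide_freqs, dtype=float).reshape(4, 4)
    if np.any(joint < 0):
        raise ValueError("dinucleotide frequencies must be nonnegative")
    if abs(joint.sum() - 1.0) > 1e-9:
        raise ValueError("dinucleotide frequencies must sum to 1")

    rng = np.random.default_rng(seed)
    marginal = joint.sum(axis=1)
    marginal = marginal / marginal.sum()
    conditional = joint / np.maximum(joint.sum(axis=1, keepdims=True), 1e-300)

    out = np.empty(length, dtype=np.int64)
    out[0] = rng.choice(4, p=marginal)
    # draw transitions in vectorised blocks via inverse-CDF per current state
    cum = np.cumsum(conditional, axis=1)
    u = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    seq = "".join(BASES[b] for b in out)
    return {contig: seq}, TruthManifest(seed=seed)


# --------------------------------------------------------------------------
# planted stem-loops
# --------------------------------------------------------------------------

def substrate_like_arm(stem_len: int, rng: np.random.Generator) -> str:
    """Draw a 3' stem arm from the biased per-offset base distribution the
    fixture substrates use, so planted high-tier loops carry the learnable
    box signature."""
    arm = []
    for off in range(stem_len):
        pref = _ARM_PREF[off % len(_ARM_PREF)]
        if rng.random() < _ARM_PREF_P:
            arm.append(pref)
        else:
            arm.append("ACGT"[int(rng.integers(4))])
    return "".join(arm)


def build_hairpin(
    loop_seq: str,
    stem_len: int = 16,
    mismatches: Sequence[int] = (),
    seed: int = 0,
    down_arm: str | None = None,
    clamp: bool = True,
    substrate_like: bool = True,
) -> tuple[str, int]:
    """Construct a stem-loop insert: ``stem_len`` bp stem capped by
    ``loop_seq`` and closed by a 3-bp G-C clamp at the stem base, with the
    5' arm generated as the reverse complement of the 3' arm. ``mismatches``
    are 1-based stem positions (counted from the loop) where pairing is
    broken. Returns (sequence, loop_start within the sequence)."""
    if not 3 <= len(loop_seq) <= 6:
        raise ValueError("loop_seq length must be 3-6 nt")
    rng = np.random.default_rng(seed)
    if down_arm is None:
        if substrate_like:
            down_arm = substrate_like_arm(stem_len, rng)
        else:
            down_arm = "".join(rng.choice(list("ACGT"), size=stem_len))
    if len(down_arm) != stem_len:
        raise ValueError("down_arm length must equal stem_len")
    up_arm = revcomp(down_arm)
    down = list(down_arm)
    for pos in mismatches:
        if not 1 <= pos <= stem_len:
            raise ValueError(f"mismatch position {pos} outside stem")
        up_base = up_arm[::-1][pos - 1]  # up-arm base at this stem position
        choices = [b for b in "ACGT" if not _pairs_dna(up_base, b)]
        down[pos - 1] = choices[int(rng.integers(len(choices)))]
    down_arm = "".join(down)
    core = up_arm + loop_seq.replace("U", "T") + down_arm
    if clamp:
        core = "GGC" + core + "GCC"
        loop_start = 3 + stem_len
    else:
        loop_start = stem_len
    return core, loop_start


def _pairs_dna(a: str, b: str) -> bool:
    return a + b in {"AT", "TA", "GC", "CG", "GT", "TG"}


def plant_loop(
    genome: dict[str, str],
    manifest: TruthManifest,
    position: int,
    loop_seq: str,
    loop_class: str = "G2_NGNN",
    stem_len: int = 16,
    mismatches: Sequence[int] = (),
    seed: int = 0,
    contig: str | None = None,
    score_tier: str = "high",
) -> dict[str, str]:
    """Plant a stem-loop at ``position`` (replacing the resident sequence so
    genome length is preserved) and record it in the manifest."""
    contig = contig or next(iter(genome))
    insert, loop_start = build_hairpin(
        loop_seq, stem_len, mismatches, seed,
        substrate_like=(score_tier == "high"),
    )
    seq = genome[contig]
    if position < 0 or position + len(insert) > len(seq):
        raise ValueError("planted loop does not fit in genome")
    genome = dict(genome)
    genome[contig] = seq[:position] + insert + seq[position + len(insert):]
    manifest.planted_loops.append(
        PlantedLoop(
            interval=GenomicInterval(contig, position, position + len(insert), "+"),
            loop_interval=GenomicInterval(
                contig, position + loop_start, position + loop_start + len(loop_seq), "+"
            ),
            loop_class=loop_class,
            loop_seq=loop_seq.replace("T", "U"),
            score_tier=score_tier,
        )
    )
    return genome


# --------------------------------------------------------------------------
# tiling probes
# --------------------------------------------------------------------------

def sim_probes(
    genome: Mapping[str, str],
    transcripts: Sequence[Transcript],
    samples: Sequence[str],
    step: int = 25,
    probe_len: int = 25,
    dG_bias_coeff: float = 0.0,
    noise_sd: float = 0.0,
    background: float = 50.0,
    seed: int = 0,
) -> list[ProbeRecord]:
    """One probe per ``step`` per strand.

    intensity = abundance x 2^(dG_bias_coeff * hyb_dG) x 2^N(0, noise_sd);
    probes outside any same-strand transcript get ``background`` abundance.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    rng = np.random.default_rng(seed)
    probes: list[ProbeRecord] = []
    for contig, seq in genome.items():
        if probe_len > len(seq):
            raise ValueError("probe_len exceeds contig length")
        for strand in ("+", "-"):
            for start in range(0, len(seq) - probe_len + 1, step):
                iv = GenomicInterval(contig, start, start + probe_len, strand)
                psequence = seq[start : start + probe_len]
                if strand == "-":
                    psequence = revcomp(psequence)
                dg = probe_dG(psequence)
                intensity = {}
                for s in samples:
                    abundance = background
                    for t in transcripts:
                        if t.interval.strand == strand and iv.overlaps(t.interval):
                            abundance = t.abundance.get(s, background)
                            break
                    noise = 2.0 ** rng.normal(0.0, noise_sd) if noise_sd > 0 else 1.0
                    intensity[s] = abundance * (2.0 ** (dG_bias_coeff * dg)) * noise
                probes.append(
                    ProbeRecord(
                        probe_id=f"{contig}_{strand}_{start}",
                        interval=iv,
                        sequence=psequence,
                        unique=True,
                        intensity=intensity,
                        hyb_dG=dg,
                    )
                )
    return probes


def sim_cutchip(
    probes: Sequence[ProbeRecord],
    transcripts: Sequence[Transcript],
    sites: Sequence[CleavageSite],
    treated: str = "treated",
    untreated: str = "untreated",
) -> list[ProbeRecord]:
    """Derive a treated sample from an untreated one: probes downstream
    (toward the transcript 3' end) of each cleavage site are attenuated by
    (1 - efficiency), emulating Xrn1p degradation of the 3' product."""
    by_name = {t.name: t for t in transcripts}
    for site in sites:
        host = None
        if site.transcript and site.transcript in by_name:
            t = by_name[site.transcript]
            if t.interval.overlaps(site.interval):
                host = t
        else:
            for t in transcripts:
                if t.interval.overlaps(site.interval) and (
                    t.interval.strand == site.interval.strand
                ):
                    host = t
                    break
        if host is None:
            raise ValueError(f"cleavage site {site.interval} outside any transcript")
        site.transcript = host.name

    out = []
    for p in probes:
        factor = 1.0
        for site in sites:
            host = by_name[site.transcript]
            if p.interval.contig != host.interval.contig:
                continue
            if p.interval.strand != host.interval.strand:
                continue
            if not p.interval.overlaps(host.interval):
                continue
            downstream = (
                p.interval.start >= site.interval.end
                if host.interval.strand == "+"
                else p.interval.end <= site.interval.start
            )
            if downstream:
                factor *= 1.0 - site.efficiency
        base = p.intensity[untreated] if untreated in p.intensity else list(p.intensity.values())[0]
        intensity = dict(p.intensity)
        intensity[untreated] = base
        intensity[treated] = base * factor
        out.append(dataclasses.replace(p, intensity=intensity))
    return out


# --------------------------------------------------------------------------
# SALI reads
# --------------------------------------------------------------------------

DEFAULT_ADAPTER = "TGGAATTCTCGG"  # fixed 12-mer 5' adapter


def sim_sali(
    genome: Mapping[str, str],
    sites: Sequence[tuple[CleavageSite, int]],
    adapter: str = DEFAULT_ADAPTER,
    n_background: int = 200,
    background_len_range: tuple[int, int] = (16, 70),
    background_copy_max: int = 3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """SALI treated/control read sets.

    ``sites`` pairs each planted cleavage site with its fragment copy number.
    The treated file holds N identical copies of each internal fragment
    (5' adapter prepended) plus a small-RNA background present in BOTH
    files; the control holds the background only.
    """
    rng = np.random.default_rng(seed)
    treated: list[str] = []
    control: list[str] = []
    for site, copies in sites:
        seq = genome[site.interval.contig][site.interval.start : site.interval.end]
        if site.interval.strand == "-":
            seq = revcomp(seq)
        treated.extend([adapter + seq] * copies)
    contigs = list(genome)
    for _ in range(n_background):
        contig = contigs[int(rng.integers(len(contigs)))]
        seq = genome[contig]
        length = int(rng.integers(background_len_range[0], background_len_range[1] + 1))
        start = int(rng.integers(0, max(1, len(seq) - length)))
        frag = seq[start : start + length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        copies = int(rng.integers(1, background_copy_max + 1))
        read = adapter + frag
        treated.extend([read] * copies)
        control.extend([read] * copies)
    rng.shuffle(treated)
    rng.shuffle(control)
    return treated, control


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

def sim_qpcr(
    genes: Sequence[str],
    true_folds: Mapping[str, float],
    replicate_sd: float = 0.1,
    n_reps: int = 3,
    condition: str = "2% Dex",
    seed: int = 0,
    base_ct_reference: float = 15.0,
    base_delta_ct: float = 5.0,
) -> list[QpcrRecord]:
    """ΔΔCt tables: Ct values are generated so that
    2^(mean ΔCt_wt - mean ΔCt_mut) has expectation true_fold."""
    if n_reps < 3:
        raise ValueError("need at least 3 replicates per genotype")
    rng = np.random.default_rng(seed)
    records: list[QpcrRecord] = []
    for gene in genes:
        fold = float(true_folds.get(gene, 1.0))
        for genotype in ("wild-type", "mutant"):
            for rep in range(1, n_reps + 1):
                ct_ref = base_ct_reference + rng.normal(0.0, replicate_sd)
                delta = base_delta_ct
                if genotype == "mutant":
                    delta -= np.log2(fold)
                ct_target = ct_ref + delta + rng.normal(0.0, replicate_sd)
                records.append(
                    QpcrRecord(
                        gene=gene,
                        condition=condition,
                        genotype=genotype,
                        replicate=rep,
                        ct_target=float(ct_target),
                        ct_reference=float(ct_ref),
                    )
                )
    return records


# --------------------------------------------------------------------------
# fixture substrate set
# --------------------------------------------------------------------------

# per-offset preferred base of the 3' arm, from the loop outward; the box
# regions inherit their sequence preferences from this pattern
_ARM_PREF = "AATCTGATGCAATCGT"
_ARM_PREF_P = 0.6  # probability of the preferred base at each arm position


def make_substrate_table(
    n: int = 20, seed: int = 7, stem_len: int = 16
) -> list[tuple[str, str, int]]:
    """Synthetic stand-in for a curated table of known substrates.

    Loops follow the canonical G2 composition (position 1 A, position 2 G,
    position 3 split A/G/U, position 4 mostly U, i.e. consensus AGDU); the
    3' stem arm draws each base from a biased distribution so the stem boxes
    carry a learnable signature, and a minority of substrates have unpaired
    positions at the cleavage sites and middle stem, mirroring the pairing
    profile of natural substrates.
    """
    rng = np.random.default_rng(seed)
    pos3 = (["A"] * 7 + ["G"] * 7 + ["T"] * 6) * (n // 20 + 1)
    pos4 = (["T"] * 16 + ["A"] * 2 + ["C"] * 2) * (n // 20 + 1)
    out = []
    for i in range(n):
        loop = "AG" + pos3[i] + pos4[i]
        arm = []
        for off in range(stem_len):
            pref = _ARM_PREF[off % len(_ARM_PREF)]
            if rng.random() < _ARM_PREF_P:
                arm.append(pref)
            else:
                arm.append("ACGT"[int(rng.integers(4))])
        mismatches: list[int] = []
        if i % 4 == 0:
            mismatches = [9, 10]   # unpaired cleavage-site region
        elif i % 4 == 1:
            mismatches = [15]      # unpaired middle-stem position
        seq, loop_start = build_hairpin(
            loop, stem_len=stem_len, mismatches=mismatches,
            seed=int(rng.integers(2**31)), down_arm="".join(arm), clamp=False,
        )
        out.append((f"SYN{i+1:02d}", seq, loop_start))
    return out


def write_substrate_table(
    substrates: Sequence[tuple[str, str, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\tloop_start\n")
        for name, seq, loop_start in substrates:
            fh.write(f"{name}\t{seq}\t{loop_start}\n")
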