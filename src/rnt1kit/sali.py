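"""SALI read processing: adapter trimming, length filtering, unique exact
mapping, identical-read cluster enrichment and overlap merging.

The internal fragment released by double cleavage of a stem-loop is 32-38 nt
long; the pipeline keeps reads whose single exact genomic match falls in
that window, calls a cluster of identical reads enriched when it has at
least 14 copies in the cleaved sample and none in the control, and merges
enriched clusters overlapping by more than half of the shorter one.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

from .core_io import Feature, GenomicInterval
from .motif import revcomp

DEFAULT_MIN_COUNT = 14
DEFAULT_LEN_WINDOW = (32, 38)
DEFAULT_MIN_READ_LEN = 16


@dataclasses.dataclass
class ReadCluster:
    sequence: str
    interval: GenomicInterval
    count_treated: int
    count_control: int


@dataclasses.dataclass
class MergedCluster:
    interval: GenomicInterval
    members: list[ReadCluster]
    transcripts: list[str] = dataclasses.field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(m.count_treated for m in self.members)

    @property
    def representative(self) -> str:
        return max((m.sequence for m in self.members), key=len)


# --------------------------------------------------------------------------
# read processing
# --------------------------------------------------------------------------

def trim_adapter(
    reads: Sequence[str], adapter: str, max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> list[str]:
    """Remove the longest read prefix matching a suffix of the 5' adapter
    with mismatch rate <= max_error_rate; untouched reads pass through.
    Overlaps shorter than ``min_overlap`` never trim (spurious 1-2 nt
    coincidences would otherwise clip every read)."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper()
    out = []
    for read in reads:
        r = read.upper()
        best = 0
        for k in range(min(len(adapter), len(r)), min_overlap - 1, -1):
            mism = sum(a != b for a, b in zip(adapter[-k:], r[:k]))
            if mism <= max_error_rate * k:
                best = k
                break
        out.append(r[best:])
    return out


def filter_lengths(reads: Sequence[str], min_len: int = DEFAULT_MIN_READ_LEN) -> list[str]:
    return [r for r in reads if len(r) >= min_len]


# --------------------------------------------------------------------------
# mapping
# --------------------------------------------------------------------------

class GenomeIndex:
    """Seed-and-verify exact matcher over both strands of a genome."""

    def __init__(self, genome: Mapping[str, str], seed_len: int = 14):
        self.genome = {c: s.upper().replace("U", "T") for c, s in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append((contig, i))

    def matches(self, read: str) -> list[GenomicInterval]:
        """All exact genomic matches of the read on either strand."""
        read = read.upper().replace("U", "T")
        if len(read) < self.seed_len:
            raise ValueError("read shorter than seed length")
        found = []
        for strand, query in (("+", read), ("-", revcomp(read))):
            for contig, pos in self._index.get(query[: self.seed_len], []):
                if self.genome[contig][pos : pos + len(query)] == query:
                    found.append(GenomicInterval(contig, pos, pos + len(query), strand))
        return found


def map_unique(
    reads: Sequence[str],
    genome: Mapping[str, str] | GenomeIndex,
    len_window: tuple[int, int] = DEFAULT_LEN_WINDOW,
) -> tuple[list[tuple[str, GenomicInterval]], int, int]:
    """Place reads with exactly one exact match across both strands; after
    placement only reads inside ``len_window`` (32-38 nt) proceed.

    Returns (placed, n_multimapped_or_unmapped, n_outside_window).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    placed: list[tuple[str, GenomicInterval]] = []
    discarded = 0
    outside = 0
    lo, hi = len_window
    # identical reads map identically: resolve unique sequences once
    counts = Counter(reads)
    placements: dict[str, GenomicInterval | None] = {}
    for seq in counts:
        hits = index.matches(seq)
        placements[seq] = hits[0] if len(hits) == 1 else None
    for read in reads:
        iv = placements[read]
        if iv is None:
            discarded += 1
        elif not lo <= len(read) <= hi:
            outside += 1
        else:
            placed.append((read, iv))
    return placed, discarded, outside


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def enrich_clusters(
    placed_treated: Sequence[tuple[str, GenomicInterval]],
    placed_control: Sequence[tuple[str, GenomicInterval]],
    min_count: int = DEFAULT_MIN_COUNT,
    max_control_count: int = 0,
) -> list[ReadCluster]:
    """Identical-read clusters enriched in the cleaved sample: at least
    ``min_count`` treated copies and no more than ``max_control_count``
    (default 0 — found in the cleaved and not the control sample)."""
    treated = Counter(seq for seq, _ in placed_treated)
    control = Counter(seq for seq, _ in placed_control)
    interval_of = {seq: iv for seq, iv in placed_treated}
    clusters = []
    for seq, n in sorted(treated.items()):
        if n >= min_count and control.get(seq, 0) <= max_control_count:
            clusters.append(
                ReadCluster(
                    sequence=seq,
                    interval=interval_of[seq],
                    count_treated=n,
                    count_control=control.get(seq, 0),
                )
            )
    clusters.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return clusters


def merge_clusters(
    clusters: Sequence[ReadCluster],
    min_overlap_fraction: float = 0.5,
    features: Sequence[Feature] | None = None,
    strict: bool = True,
) -> list[MergedCluster]:
    """Merge clusters whose overlap exceeds ``min_overlap_fraction`` of the
    shorter member (strict '>' by default); merging is transitive. Merged
    clusters are assigned to overlapping same-strand transcripts when an
    annotation is supplied."""
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = clusters[i], clusters[j]
            if a.interval.strand != b.interval.strand:
                continue
            ov = a.interval.overlap_length(b.interval)
            shorter = min(len(a.interval), len(b.interval))
            frac = ov / shorter if shorter else 0.0
            merged = frac > min_overlap_fraction if strict else frac >= min_overlap_fraction
            if merged:
                union(i, j)

    groups: dict[int, list[ReadCluster]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(clusters[i])
    out = []
    for members in groups.values():
        contig = members[0].interval.contig
        strand = members[0].interval.strand
        iv = GenomicInterval(
            contig,
            min(m.interval.start for m in members),
            max(m.interval.end for m in members),
            strand,
        )
        merged = MergedCluster(interval=iv, members=sorted(members, key=lambda m: m.interval.start))
        if features is not None:
            merged.transcripts = sorted(
                {
                    f.name
                    for f in features
                    if f.interval.overlaps(iv) and f.interval.strand == strand
                }
            )
        out.append(merged)
    out.sort(key=lambda m: (m.interval.contig, m.interval.start))
    return out


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------

def run_pipeline(
    treated_reads: Sequence[str],
    control_reads: Sequence[str],
    genome: Mapping[str, str],
    adapter: str,
    features: Sequence[Feature] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    max_error_rate: float = 0.1,
) -> tuple[list[MergedCluster], dict]:
    """Full SALI pipeline: trim, length-filter, uniquely map, enrich, merge.
    Returns merged clusters and per-stage read counts."""
    index = GenomeIndex(genome)
    stats: dict[str, int] = {}

    def process(reads: Sequence[str], label: str):
        trimmed = trim_adapter(reads, adapter, max_error_rate)
        kept = filter_lengths(trimmed)
        placed, _, _ = map_unique(kept, index)
        stats[f"{label}_input"] = len(reads)
        stats[f"{label}_after_length"] = len(kept)
        stats[f"{label}_placed_32_38"] = len(placed)
        return placed

    placed_t = process(treated_reads, "treated")
    placed_c = process(control_reads, "control")
    clusters = enrich_clusters(placed_t, placed_c, min_count=min_count)
    stats["enriched_clusters"] = len(clusters)
    merged = merge_clusters(clusters, features=features)
    stats["merged_clusters"] = len(merged)
    return merged, stats
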