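"""Region callers on top of the segmentation engine.

Two call types:

* overexpressed regions (expression array, mutant vs wild type): segments
  above 2-fold (log2 level > 1), neighbours < 48 nt apart joined, joined
  regions with < 12 uniquely matching probes dropped;
* cleaved regions (Cut and Chip, treated vs untreated): a robust cutoff
  median - 1.96 * MAD over segment levels (unscaled MAD), neighbours < 48 nt
  apart grouped, grouped regions shorter than 125 nt dropped.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_io import GenomicInterval
from .motif import LoopCandidate
from .segmentation import SegmentCall


@dataclasses.dataclass
class RegionCall:
    interval: GenomicInterval
    level: float
    probe_ids: list[str]
    n_probes_unique: int


def _join_segments(
    segments: Sequence[SegmentCall],
    probe_values: dict[str, float] | None,
    max_gap: int = 48,
    strict: bool = True,
) -> list[RegionCall]:
    """Join same-strand neighbours separated by < max_gap nt (<= when
    ``strict`` is False); the joined level is recomputed as the median over
    member-probe values when those are supplied, else over segment levels."""
    by_track: dict[tuple[str, str], list[SegmentCall]] = {}
    for seg in segments:
        by_track.setdefault((seg.interval.contig, seg.interval.strand), []).append(seg)
    regions: list[RegionCall] = []
    for (contig, strand), segs in sorted(by_track.items()):
        segs = sorted(segs, key=lambda s: s.interval.start)
        group: list[SegmentCall] = []
        for seg in segs:
            if group:
                gap = seg.interval.start - group[-1].interval.end
                joined = gap < max_gap if strict else gap <= max_gap
            else:
                joined = False
            if joined:
                group.append(seg)
            else:
                if group:
                    regions.append(_make_region(group, contig, strand, probe_values))
                group = [seg]
        if group:
            regions.append(_make_region(group, contig, strand, probe_values))
    return regions


def _make_region(group, contig, strand, probe_values) -> RegionCall:
    probe_ids = [pid for seg in group for pid in seg.probe_ids]
    if probe_values is not None:
        level = float(np.median([probe_values[p] for p in probe_ids]))
    else:
        level = float(np.median([seg.level for seg in group]))
    return RegionCall(
        interval=GenomicInterval(
            contig, group[0].interval.start, group[-1].interval.end, strand
        ),
        level=level,
        probe_ids=probe_ids,
        n_probes_unique=sum(seg.n_probes_unique for seg in group),
    )


def call_overexpressed(
    segments: Sequence[SegmentCall],
    probe_values: dict[str, float] | None = None,
    min_log2: float = 1.0,
    max_gap: int = 48,
    min_unique_probes: int = 12,
    strict_gap: bool = True,
) -> list[RegionCall]:
    """Overexpressed regions: level > min_log2 (2-fold), join, drop joined
    regions with fewer than ``min_unique_probes`` uniquely matching probes."""
    kept = [s for s in segments if s.level > min_log2]
    regions = _join_segments(kept, probe_values, max_gap, strict_gap)
    return [r for r in regions if r.n_probes_unique >= min_unique_probes]


def call_cleaved(
    segments: Sequence[SegmentCall],
    probe_values: dict[str, float] | None = None,
    z: float = 1.96,
    max_gap: int = 48,
    min_region_nt: int = 125,
    min_unique_probes: int = 12,
    scaled_mad: bool = False,
    strict_gap: bool = True,
) -> tuple[list[RegionCall], float]:
    """Cleaved regions on log2(treated/untreated) segments.

    Segments with < ``min_unique_probes`` unique probes are removed first;
    the cutoff is median - z * MAD over the remaining segment levels (MAD
    unscaled unless ``scaled_mad``); segments strictly below the cutoff are
    grouped (< max_gap) and grouped regions shorter than ``min_region_nt``
    dropped. Returns (regions, cutoff).
    """
    reliable = [s for s in segments if s.n_probes_unique >= min_unique_probes]
    if len(reliable) < 3:
        raise ValueError("need at least 3 reliable segments for a MAD cutoff")
    levels = np.array([s.level for s in reliable])
    med = float(np.median(levels))
    mad = float(np.median(np.abs(levels - med)))
    if scaled_mad:
        mad *= 1.4826
    cutoff = med - z * mad
    kept = [s for s in reliable if s.level < cutoff]
    regions = _join_segments(kept, probe_values, max_gap, strict_gap)
    regions = [r for r in regions if len(r.interval) >= min_region_nt]
    return regions, cutoff


def associate_loops(
    regions: Sequence[RegionCall],
    loop_hits: Sequence[LoopCandidate],
    window: int = 100,
    cutoff: float | None = None,
) -> tuple[float, list[bool]]:
    """Fraction of regions with a scoring stem-loop hit within ``window`` nt
    of either region boundary on the region's strand."""
    flags = []
    for region in regions:
        iv = region.interval
        associated = False
        for hit in loop_hits:
            if cutoff is not None and (hit.score is None or hit.score < cutoff):
                continue
            h = hit.interval
            if h.contig != iv.contig or h.strand != iv.strand:
                continue
            near_5p = h.start <= iv.start + window and h.end >= iv.start - window
            near_3p = h.start <= iv.end + window and h.end >= iv.end - window
            if near_5p or near_3p:
                associated = True
                break
        flags.append(associated)
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags
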