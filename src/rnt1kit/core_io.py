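"""Readers/writers and coordinate conventions shared by every pipeline stage.

Internal coordinates are uniformly 0-based half-open on an explicit strand;
conversion to the 1-based inclusive GFF convention or the 0-based half-open
BED convention happens only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end (got {self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclasses.dataclass
class ProbeRecord:
    """A tiling-array probe: its genomic footprint, sequence, predicted
    hybridization free energy and per-sample intensities."""

    probe_id: str
    interval: GenomicInterval
    sequence: str
    unique: bool
    intensity: dict[str, float]
    hyb_dG: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"probe {self.probe_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )
        for sample, value in self.intensity.items():
            if value < 0:
                raise ValueError(
                    f"probe {self.probe_id}: negative intensity for {sample}"
                )


@dataclasses.dataclass(frozen=True)
class QpcrRecord:
    """One qPCR replicate measurement (reference gene = ACT1)."""

    gene: str
    condition: str
    genotype: str  # "wild-type" | "mutant"
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")
        if self.genotype not in ("wild-type", "mutant"):
            raise ValueError(f"genotype must be wild-type/mutant, got {self.genotype!r}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclasses.dataclass(frozen=True)
class Feature:
    """An annotated genomic feature (gene, ncRNA, LTR, ...)."""

    interval: GenomicInterval
    name: str
    ftype: str


# --------------------------------------------------------------------------
# FASTA / FASTQ
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping.

    Sequences are uppercased; T and U are both accepted and preserved.
    """
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as handle:
        # detect malformed leading junk that SeqIO would silently skip
        for lineno, line in enumerate(handle, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line!r}")
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> list[str]:
    """Read a FASTQ file (Sanger quality), returning the read sequences."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> None:
    """Write reads as FASTQ with uniform Sanger quality 'I' (Q40)."""
    with open(path, "w") as out:
        for i, seq in enumerate(reads):
            out.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------------
# probe tables
# --------------------------------------------------------------------------

_PROBE_FIXED_COLS = ["probe_id", "contig", "start", "end", "strand", "sequence", "unique"]


def read_probe_table(path: str | Path) -> list[ProbeRecord]:
    """Read a TSV probe table; sample columns are auto-discovered as every
    column after the fixed schema (an optional ``hyb_dG`` column is honoured).
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "probe_id": str})
    missing = [c for c in _PROBE_FIXED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"probe table missing column(s): {', '.join(missing)}")
    sample_cols = [c for c in df.columns if c not in _PROBE_FIXED_COLS and c != "hyb_dG"]
    records = []
    for row in df.itertuples(index=False):
        interval = GenomicInterval(row.contig, int(row.start), int(row.end), row.strand)
        rec = ProbeRecord(
            probe_id=str(row.probe_id),
            interval=interval,
            sequence=str(row.sequence).upper(),
            unique=bool(row.unique),
            intensity={s: float(getattr(row, s)) for s in sample_cols},
            hyb_dG=float(row.hyb_dG) if "hyb_dG" in df.columns else None,
        )
        records.append(rec)
    return records


def write_probe_table(records: Iterable[ProbeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "probe_id": rec.probe_id,
            "contig": rec.interval.contig,
            "start": rec.interval.start,
            "end": rec.interval.end,
            "strand": rec.interval.strand,
            "sequence": rec.sequence,
            "unique": int(rec.unique),
        }
        if rec.hyb_dG is not None:
            row["hyb_dG"] = rec.hyb_dG
        row.update(rec.intensity)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# qPCR tables
# --------------------------------------------------------------------------

def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "condition", "genotype", "replicate", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"qPCR table missing column(s): {', '.join(missing)}")
    return [
        QpcrRecord(
            gene=str(r.gene),
            condition=str(r.condition),
            genotype=str(r.genotype),
            replicate=int(r.replicate),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples(index=False)
    ]


def write_qpcr_table(records: Iterable[QpcrRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

def write_bed(
    records: Iterable[tuple[GenomicInterval, str, float]],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write (interval, name, score) triples as BED6.

    The BED score column carries round(1000 * score); coordinates stay
    0-based half-open. ``contig_lengths``, when given, bounds-checks output.
    """
    with open(path, "w") as out:
        for interval, name, score in records:
            if contig_lengths is not None:
                clen = contig_lengths.get(interval.contig)
                if clen is not None and interval.end > clen:
                    raise ValueError(
                        f"interval {interval} exceeds contig length {clen}"
                    )
            out.write(
                f"{interval.contig}\t{interval.start}\t{interval.end}\t{name}\t"
                f"{round(1000 * score)}\t{interval.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 fields")
            contig, start, end, name, score, strand = fields[:6]
            out.append(
                (
                    GenomicInterval(contig, int(start), int(end), strand),
                    name,
                    int(score) / 1000,
                )
            )
    return out


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[Feature]:
    """Parse GFF3 features (1-based inclusive on disk) into internal 0-based
    half-open :class:`Feature` records. The feature name is taken from the
    ``Name``, ``ID`` or ``gene`` attribute, in that order."""
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 fields")
            contig, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, _, value = item.partition("=")
                    attr_map[key.strip()] = value.strip()
            name = attr_map.get("Name") or attr_map.get("ID") or attr_map.get("gene") or ftype
            if strand not in ("+", "-"):
                continue  # unstranded features are not consumed by any caller
            features.append(
                Feature(
                    interval=GenomicInterval(contig, int(start) - 1, int(end), strand),
                    name=name,
                    ftype=ftype,
                )
            )
    return features


def write_gff(features: Iterable[Feature], path: str | Path, source: str = "rnt1kit") -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            out.write(
                f"{f.interval.contig}\t{source}\t{f.ftype}\t{f.interval.start + 1}\t"
                f"{f.interval.end}\t.\t{f.interval.strand}\t.\tID={f.name};Name={f.name}\n"
            )


# --------------------------------------------------------------------------
# dot-bracket
# --------------------------------------------------------------------------

def write_dot_bracket(
    entries: Iterable[tuple[str, str, str, float]], path: str | Path
) -> None:
    """Write (name, sequence, structure, dG) entries as dot-bracket records."""
    with open(path, "w") as out:
        for name, seq, struct, dg in entries:
            out.write(f">{name}\n{seq}\n{struct} ({dg:.2f})\n")
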