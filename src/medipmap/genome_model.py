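"""Reference sequence, gene models and the labelled genomic feature partition.

The partition labels a genome the way MeDIP-seq annotation studies do:
promoter (TSS +/- 2 kb), 5'/3' UTR, exon, intron, gene body (TSS..TES),
the 2 kb strictly upstream/downstream of the transcript span, and the
intergenic complement of merged gene bodies. Labels are deliberately NOT
forced disjoint (a promoter reaches 2 kb into the gene body); only
gene_body vs intergenic partition the genome exactly.

Coordinates are 0-based half-open internally. GTF (1-based inclusive) and
BED (0-based half-open) are converted at the file boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .intervals import (
    Interval,
    clip,
    complement_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)

PARTITION_LABELS = (
    "promoter",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "gene_body",
    "intergenic",
    "upstream2k",
    "downstream2k",
)


class ParseError(ValueError):
    """Raised for malformed annotation lines; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


@dataclass
class GenomeSequence:
    chrom: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if re.search(r"[^ACGTN]", self.sequence):
            bad = sorted(set(re.findall(r"[^ACGTN]", self.sequence)))
            raise ValueError(f"{self.chrom}: non-ACGTN characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_fasta(path) -> dict[str, GenomeSequence]:
    """Read a (multi-record) FASTA into GenomeSequence objects keyed by chrom."""
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {path}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    return genome


def chrom_sizes(genome: Mapping[str, GenomeSequence]) -> dict[str, int]:
    return {c: g.length for c, g in genome.items()}


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[Interval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.transcript_id}: tx_start >= tx_end")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"{self.transcript_id}: exon [{s},{e}) outside transcript "
                    f"span [{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: CDS must set both ends or neither")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript span")

    @property
    def tss(self) -> int:
        """Transcription start as a point coordinate (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def utr_intervals(self) -> tuple[list[Interval], list[Interval]]:
        """(utr5, utr3) exonic intervals; empty when no CDS is annotated."""
        if self.cds_start is None:
            return [], []
        left = subtract_intervals(self.exons, [(self.cds_start, self.tx_end)])
        right = subtract_intervals(self.exons, [(self.tx_start, self.cds_end)])
        return (left, right) if self.strand == "+" else (right, left)


# ---------------------------------------------------------------------------
# readers / writers

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path) -> list[TranscriptModel]:
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                s, e = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start!r}/{end!r}") from None
            if s >= e:
                raise ParseError(path, lineno, f"empty or inverted interval {start}-{end}")
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id", tid)
            if tid is None:
                raise ParseError(path, lineno, "missing transcript_id attribute")
            if tid not in meta:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            elif meta[tid][1] != chrom:
                raise ParseError(path, lineno, f"transcript {tid} spans multiple chromosomes")
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append((s, e))

    models = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        ex = merge_intervals(exons.get(tid, []))
        if not ex:
            continue
        c = cds.get(tid)
        cs, ce = (min(s for s, _ in c), max(e for _, e in c)) if c else (None, None)
        models.append(
            TranscriptModel(gid, tid, chrom, strand, ex[0][0], ex[-1][1], ex, cs, ce)
        )
    return models


def _parse_bed12(path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(path, lineno, f"expected 12 BED fields, got {len(f)}")
            try:
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(path, lineno, "malformed BED12 numeric field") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(path, lineno, "blockCount disagrees with block lists")
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            gid = name.split("|")[0] if "|" in name else name
            tid = name.split("|")[1] if "|" in name else name
            cds = (thick_s, thick_e) if thick_e > thick_s else (None, None)
            models.append(TranscriptModel(gid, tid, chrom, strand, start, end, exons, *cds))
    return models


def load_gene_models(path) -> list[TranscriptModel]:
    """Read transcript models from GTF or BED12, inferring the format.

    BED12 names of the form ``gene|transcript`` split into the two ids;
    otherwise the name serves as both.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _parse_gtf(path)
    if path.suffix.lower() == ".bed":
        return _parse_bed12(path)
    # sniff: GTF has 9 columns with an attribute field containing key "..."
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return _parse_gtf(path) if 'transcript_id "' in line else _parse_bed12(path)
    return []


def write_gene_models_bed12(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offs = ",".join(str(s - m.tx_start) for s, _ in m.exons)
            thick = (m.cds_start, m.cds_end) if m.cds_start is not None else (m.tx_start, m.tx_start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, m.tx_start, m.tx_end, f"{m.gene_id}|{m.transcript_id}",
                        0, m.strand, thick[0], thick[1], 0, len(m.exons), sizes, offs,
                    )
                )
                + "\n"
            )


@dataclass
class RepeatAnnotation:
    chrom: str
    start: int
    end: int
    family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"repeat {self.chrom}:{self.start}-{self.end}: start >= end")
        if not self.family:
            raise ValueError("repeat family label must be non-empty")


def load_repeats(path) -> list[RepeatAnnotation]:
    """BED with the family label (e.g. LINE/CR1) in the name column."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(path, lineno, "repeat BED needs chrom,start,end,family")
            out.append(RepeatAnnotation(f[0], int(f[1]), int(f[2]), f[3]))
    return out


# ---------------------------------------------------------------------------
# feature partition


@dataclass
class FeaturePartition:
    """Merged interval set per label per chromosome, plus per-label totals."""

    intervals: dict[str, dict[str, list[Interval]]]
    total_bp: dict[str, int] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total_bp:
            self.total_bp = {
                label: sum(total_length(ivs) for ivs in per_chrom.values())
                for label, per_chrom in self.intervals.items()
            }

    def label_intervals(self, label: str) -> dict[str, list[Interval]]:
        return self.intervals.get(label, {})

    def write_bed(self, label: str, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals.get(label, {})):
                for i, (s, e) in enumerate(self.intervals[label][chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}_{i}\t0\t.\n")

    def write_totals_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\ttotal_bp\n")
            for label in PARTITION_LABELS:
                fh.write(f"{label}\t{self.total_bp.get(label, 0)}\n")


def build_feature_partition(
    transcripts: list[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    promoter_flank: int = 2000,
) -> FeaturePartition:
    """Label the genome from transcript models.

    promoter = TSS +/- promoter_flank (strand-aware TSS, clipped to the
    chromosome); upstream2k/downstream2k = the flank strictly before/after
    the transcript span; introns = gene body minus exons; intergenic =
    complement of merged gene bodies. Per-label interval sets are merged
    across transcripts, so a base is counted once per label it carries.
    """
    if promoter_flank <= 0:
        raise ValueError("promoter_flank must be positive")
    for t in transcripts:
        if t.chrom not in chrom_sizes:
            raise KeyError(f"transcript {t.transcript_id} on unknown chromosome {t.chrom!r}")

    raw: dict[str, dict[str, list[Interval]]] = {
        label: {} for label in PARTITION_LABELS
    }

    def add(label: str, chrom: str, iv: Interval | None) -> None:
        if iv is not None:
            raw[label].setdefault(chrom, []).append(iv)

    for t in transcripts:
        L = chrom_sizes[t.chrom]
        add("gene_body", t.chrom, (t.tx_start, t.tx_end))
        add("promoter", t.chrom, clip(t.tss - promoter_flank, t.tss + promoter_flank, L))
        if t.strand == "+":
            up = clip(t.tx_start - promoter_flank, t.tx_start, L)
            down = clip(t.tx_end, t.tx_end + promoter_flank, L)
        else:
            up = clip(t.tx_end, t.tx_end + promoter_flank, L)
            down = clip(t.tx_start - promoter_flank, t.tx_start, L)
        add("upstream2k", t.chrom, up)
        add("downstream2k", t.chrom, down)
        for iv in t.exons:
            add("exon", t.chrom, iv)
        for iv in subtract_intervals([(t.tx_start, t.tx_end)], t.exons):
            add("intron", t.chrom, iv)
        utr5, utr3 = t.utr_intervals()
        for iv in utr5:
            add("utr5", t.chrom, iv)
        for iv in utr3:
            add("utr3", t.chrom, iv)

    merged = {
        label: {chrom: merge_intervals(ivs) for chrom, ivs in per_chrom.items()}
        for label, per_chrom in raw.items()
    }
    merged["intergenic"] = {
        chrom: complement_intervals(merged["gene_body"].get(chrom, []), size)
        for chrom, size in chrom_sizes.items()
    }
    return FeaturePartition(merged, chrom_sizes=dict(chrom_sizes))
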