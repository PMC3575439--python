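"""Methylation-enriched region ("peak") calling from uniquely aligned MeDIP reads.

A deliberately simple, fully specified Poisson caller with a MACS-flavoured
dynamic local background: reads are extended to the expected fragment
length from their 5' end, fragment coverage is counted in tiling windows,
and a window is a candidate when the Poisson upper tail
``P(X >= k | lambda_local)`` falls below the threshold, with
``lambda_local`` the maximum of the genome-wide rate and rates estimated
in larger windows centred on the candidate. Adjacent candidates merge;
merged peaks are re-scored over their final span. Deterministic: identical
reads and config give byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from scipy.stats import poisson

logger = logging.getLogger(__name__)


@dataclass
class AlignedRead:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    unique: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.chrom}:{self.start}-{self.end}: start >= end")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    read_count: int
    fold_enrichment: float
    pvalue: float
    lambda_local: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakCallConfig:
    """Parameters of the Poisson caller.

    fragment_extension: sonication fragment length the 5' read end is
    extended to (size-selected inserts here were a few hundred bp).
    window: scanning window width; defaults to fragment_extension.
    local_lambda_windows: widths of the centred windows the local rate is
    estimated in; the genome-wide rate is always included in the max.
    """

    fragment_extension: int = 200
    window: int | None = None
    pvalue_threshold: float = 1e-5
    local_lambda_windows: Sequence[int] = (5000, 10000)
    merge_gap: int | None = None

    def __post_init__(self) -> None:
        if self.window is None:
            self.window = self.fragment_extension
        if self.merge_gap is None:
            self.merge_gap = self.window
        if self.fragment_extension <= 0 or self.window <= 0 or self.merge_gap < 0:
            raise ValueError("sizes must be positive")
        if not 0 < self.pvalue_threshold < 1:
            raise ValueError("pvalue_threshold must be in (0, 1)")
        if any(w <= 0 for w in self.local_lambda_windows):
            raise ValueError("local lambda windows must be positive")


# ---------------------------------------------------------------------------
# input


def load_alignments(path, unique_only: bool = True) -> list[AlignedRead]:
    """Read aligned reads from BED6 or SAM/BAM.

    SAM/BAM uniqueness: mapped, primary, MAPQ > 0 and no XA multi-hit tag.
    """
    path = str(path)
    reads: list[AlignedRead] = []
    kept = dropped = 0
    if path.endswith((".sam", ".bam", ".cram")):
        mode = "r" if path.endswith(".sam") else "rb"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    dropped += 1
                    continue
                unique = aln.mapping_quality > 0 and not aln.has_tag("XA")
                if unique_only and not unique:
                    dropped += 1
                    continue
                reads.append(
                    AlignedRead(
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        "-" if aln.is_reverse else "+",
                        unique,
                    )
                )
                kept += 1
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line with < 3 fields")
                strand = f[5] if len(f) > 5 else "+"
                # BED convention here: score column 0 flags a multi-mapper
                unique = not (len(f) > 4 and f[4] == "multi")
                if unique_only and not unique:
                    dropped += 1
                    continue
                reads.append(AlignedRead(f[0], int(f[1]), int(f[2]), strand, unique))
                kept += 1
    logger.info("%s: retained %d reads, discarded %d", path, kept, dropped)
    return reads


def write_reads_bed(reads: Iterable[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# calling


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    return float(poisson.sf(k - 1, lam))


def _extend(read: AlignedRead, ext: int, chrom_len: int) -> tuple[int, int]:
    length = read.end - read.start
    if ext < length:
        ext = length
    if read.strand == "-":
        s, e = read.end - ext, read.end
    else:
        s, e = read.start, read.start + ext
    return max(0, s), min(chrom_len, e)


def call_peaks(
    reads: Sequence[AlignedRead],
    chrom_sizes: Mapping[str, int],
    config: PeakCallConfig | None = None,
) -> list[Peak]:
    if not reads:
        raise ValueError("no reads supplied to call_peaks")
    cfg = config or PeakCallConfig()
    ext = cfg.fragment_extension
    w = cfg.window
    genome_len = sum(chrom_sizes.values())
    n_total = len(reads)
    # genome-wide fragment-start rate per bp; expected overlap count in a
    # span of width s is rate * (s + ext)
    rate_bg = n_total / genome_len

    frags: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        if r.chrom not in chrom_sizes:
            raise KeyError(f"read on unknown chromosome {r.chrom!r}")
        frags.setdefault(r.chrom, []).append(_extend(r, ext, chrom_sizes[r.chrom]))

    peaks: list[Peak] = []
    for chrom in sorted(frags):
        fl = sorted(frags[chrom])
        starts = np.array([f[0] for f in fl], dtype=np.int64)
        ends_sorted = np.sort(np.array([f[1] for f in fl], dtype=np.int64))
        L = chrom_sizes[chrom]

        def count_overlapping(s: int, e: int) -> int:
            # fragments with start < e and end > s
            return int(np.searchsorted(starts, e, "left") - np.searchsorted(ends_sorted, s, "right"))

        def lambda_local(center: int, span: int) -> float:
            lam = rate_bg * (span + ext)
            for lw in cfg.local_lambda_windows:
                ls, le = max(0, center - lw // 2), min(L, center + lw // 2)
                k_loc = count_overlapping(ls, le)
                # overlap counts over-count rate by (width + ext)
                lam = max(lam, k_loc / (le - ls + ext) * (span + ext))
            return lam

        win_starts = np.arange(0, max(1, L - w + 1), w)
        k_win = np.searchsorted(starts, win_starts + w, "left") - np.searchsorted(
            ends_sorted, win_starts, "right"
        )
        # cheap prefilter against the genome background before the local test
        k_min = int(poisson.isf(cfg.pvalue_threshold, rate_bg * (w + ext))) + 1
        cand_idx = np.where(k_win >= max(1, k_min))[0]
        cand: list[tuple[int, int]] = []
        for i in cand_idx:
            ws = int(win_starts[i])
            k = int(k_win[i])
            lam = lambda_local(ws + w // 2, w)
            if poisson_upper_tail(k, lam) < cfg.pvalue_threshold:
                cand.append((ws, min(L, ws + w)))
        if not cand:
            continue

        # merge candidates within merge_gap
        merged: list[list[int]] = [list(cand[0])]
        for s, e in cand[1:]:
            if s <= merged[-1][1] + cfg.merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])

        for ms, me in merged:
            k = count_overlapping(ms, me)
            lam = lambda_local((ms + me) // 2, me - ms)
            p = poisson_upper_tail(k, lam)
            if p >= cfg.pvalue_threshold:
                continue
            # summit: position of maximum fragment coverage within the peak
            lo = np.searchsorted(starts, me, "left")
            sel = [f for f in fl[:lo] if f[1] > ms]
            edges = np.zeros(me - ms + 1, dtype=np.int32)
            for fs, fe in sel:
                edges[max(0, fs - ms)] += 1
                edges[min(me - ms, fe - ms)] -= 1
            cov = np.cumsum(edges[:-1])
            summit = ms + int(np.argmax(cov))
            peaks.append(Peak(chrom, ms, me, summit, k, k / lam, p, lam))
    return peaks


# ---------------------------------------------------------------------------
# peak I/O


def write_peaks(peaks: Iterable[Peak], bed_path, tsv_path=None) -> None:
    """BED6 with score = -10*log10(p) capped at 1000, plus optional full TSV."""
    peaks = list(peaks)
    with open(bed_path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            score = 1000 if p.pvalue <= 0 else min(1000, int(round(-10 * np.log10(p.pvalue))))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("name\tchrom\tstart\tend\tsummit\tread_count\tfold_enrichment\tpvalue\n")
            for i, p in enumerate(peaks, 1):
                fh.write(
                    f"peak_{i}\t{p.chrom}\t{p.start}\t{p.end}\t{p.summit}"
                    f"\t{p.read_count}\t{p.fold_enrichment:.4f}\t{p.pvalue:.6g}\n"
                )


def load_peaks_bed(path) -> list[Peak]:
    """Accept externally called peaks (e.g. real MACS output) as plain BED."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            s, e = int(f[1]), int(f[2])
            out.append(Peak(f[0], s, e, (s + e) // 2, 1, float("nan"), float("nan")))
    return out
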