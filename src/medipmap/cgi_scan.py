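"""CpG-island detection by sliding-window scanning.

Every position is scored with the mean GC fraction and mean
observed/expected CpG ratio (Gardiner-Garden form, ``#CpG * L / (#C * #G)``)
of all 100 bp windows covering it — the moving-average convention of the
classical island plotters, which makes island boundaries track the dense
region from both sides. Maximal runs of positions whose averaged scores
clear both thresholds are trimmed to the first and last CpG they contain
and re-validated over their final span against all three criteria:
length >= 200 bp, GC > 0.5, O/E > 0.6. Windows containing any N score
zero, so no island spans an N run at least one window long.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_model import GenomeSequence

logger = logging.getLogger(__name__)


@dataclass
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    methylated: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def obs_exp_cpg(window_sequence: str) -> float:
    """Observed/expected CpG ratio of a sequence window.

    Returns ``#CpG * L / (#C * #G)``; 0 when the window has no C or no G.
    """
    if not window_sequence:
        raise ValueError("empty sequence")
    seq = window_sequence.upper()
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (n_c * n_g)


def gc_fraction(window_sequence: str) -> float:
    if not window_sequence:
        raise ValueError("empty sequence")
    seq = window_sequence.upper()
    return (seq.count("C") + seq.count("G")) / len(seq)


def _score_span(seq: str) -> tuple[float, float]:
    return gc_fraction(seq), obs_exp_cpg(seq)


def scan_cpg_islands(
    seq: GenomeSequence,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 100,
    step: int = 1,
) -> list[CpGIsland]:
    """Scan one chromosome for CpG islands.

    Every emitted island, re-scored over its exact final span, passes all
    three thresholds and has ``length >= min_length``. Islands are sorted
    and non-overlapping.
    """
    if not 0 < min_gc < 1:
        raise ValueError("min_gc must be in (0, 1)")
    if min_oe <= 0:
        raise ValueError("min_oe must be positive")
    if min_length <= 0 or window <= 0 or step <= 0:
        raise ValueError("min_length, window and step must be positive")
    s = seq.sequence
    L = len(s)
    if window > L:
        logger.info("sequence %s shorter than window (%d < %d); skipped", seq.chrom, L, window)
        return []

    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cpg_start = np.zeros(L, dtype=bool)
    is_cpg_start[:-1] = is_c[:-1] & is_g[1:]

    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_n = np.concatenate(([0], np.cumsum(is_n)))
    cum_cpg = np.concatenate(([0], np.cumsum(is_cpg_start)))

    starts = np.arange(0, L - window + 1, step)
    ends = starts + window
    n_c = cum_c[ends] - cum_c[starts]
    n_g = cum_g[ends] - cum_g[starts]
    n_n = cum_n[ends] - cum_n[starts]
    # CpG starts strictly inside the window (a CG straddling the window end
    # belongs to the next window)
    n_cpg = cum_cpg[ends - 1] - cum_cpg[starts]

    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * window / (n_c * n_g), 0.0)
    win_gc = (n_c + n_g) / window
    # windows containing N contribute zero, so no island spans a long N run
    has_n = n_n > 0
    win_gc = np.where(has_n, 0.0, win_gc)
    oe = np.where(has_n, 0.0, oe)

    # moving-average convention: each position is scored by the mean GC and
    # O/E of every window covering it; runs of passing positions become
    # island candidates (boundaries track the dense region from both sides)
    cum_wgc = np.concatenate(([0.0], np.cumsum(win_gc)))
    cum_woe = np.concatenate(([0.0], np.cumsum(oe)))
    pos = np.arange(L)
    # covering window start range [pos - window + 1, pos], clipped to the
    # computed grid, expressed in grid indices (grid step may exceed 1)
    lo = np.clip(pos - window + 1, 0, L - window)
    hi = np.clip(pos, 0, L - window)
    lo_i = (lo + step - 1) // step
    hi_i = hi // step
    n_win = np.maximum(hi_i - lo_i + 1, 1)
    avg_gc = (cum_wgc[hi_i + 1] - cum_wgc[lo_i]) / n_win
    avg_oe = (cum_woe[hi_i + 1] - cum_woe[lo_i]) / n_win
    covered = (avg_gc > min_gc) & (avg_oe > min_oe)

    islands: list[CpGIsland] = []
    diffs = np.diff(covered.astype(np.int8))
    run_starts = list(np.where(diffs == 1)[0] + 1)
    run_ends = list(np.where(diffs == -1)[0] + 1)
    if covered[0]:
        run_starts.insert(0, 0)
    if covered[-1]:
        run_ends.append(L)

    cpg_positions = np.where(is_cpg_start)[0]
    for rs, re_ in zip(run_starts, run_ends):
        inside = cpg_positions[(cpg_positions >= rs) & (cpg_positions + 2 <= re_)]
        if inside.size == 0:
            continue
        ts, te = int(inside[0]), int(inside[-1]) + 2  # trim to first/last CpG
        span = s[ts:te]
        gc, oe_final = _score_span(span)
        if te - ts >= min_length and gc > min_gc and oe_final > min_oe:
            islands.append(CpGIsland(seq.chrom, ts, te, gc, oe_final))
    return islands


def scan_genome(genome: dict[str, GenomeSequence], **kwargs) -> list[CpGIsland]:
    out: list[CpGIsland] = []
    for chrom in sorted(genome):
        out.extend(scan_cpg_islands(genome[chrom], **kwargs))
    return out


def write_cgi_bed(islands: list[CpGIsland], bed_path, tsv_path=None) -> None:
    """BED6 (score = round(1000 * O/E), capped at 1000) plus optional TSV."""
    with open(bed_path, "w") as fh:
        for i, isl in enumerate(islands, 1):
            score = min(1000, round(1000 * isl.obs_exp_cpg))
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\tCGI_{i}\t{score}\t.\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("name\tchrom\tstart\tend\tlength\tgc_fraction\tobs_exp_cpg\n")
            for i, isl in enumerate(islands, 1):
                fh.write(
                    f"CGI_{i}\t{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.length}"
                    f"\t{isl.gc_fraction:.4f}\t{isl.obs_exp_cpg:.4f}\n"
                )


def load_cgi_bed(path) -> list[CpGIsland]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(CpGIsland(f[0], int(f[1]), int(f[2]), float("nan"), float("nan")))
    return out
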