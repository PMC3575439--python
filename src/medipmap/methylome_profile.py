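"""Descriptive methylome statistics over peaks, reads, CGIs and repeats.

Counting conventions follow the study design this pipeline mirrors:

* reads are classified into exactly one of {cgi, gene_body, repeat, other}
  by a fixed precedence (CGI first — the rarest class would otherwise be
  absorbed by gene bodies);
* a peak overlapping k genomic components increments each of the k
  per-component counts but the whole-genome total counts it once;
* a CGI is "methylated" iff it shares >= 1 bp with a peak;
* methylation density is peaks per Mb of a component;
* a peak over several repeat families is split fractionally between them
  so family percentages sum to 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cgi_scan import CpGIsland
from .genome_model import FeaturePartition, RepeatAnnotation
from .intervals import GenomeIntervals
from .medip_peaks import AlignedRead, Peak

logger = logging.getLogger(__name__)

PEAK_COMPONENTS = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic", "cgi", "repeats")
CGI_COMPONENTS = ("utr5", "utr3", "exon", "intron", "intergenic")
SIZE_BIN_PRECEDENCE = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


@dataclass
class ReadClassification:
    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    def percent(self, cls: str, decimals: int = 2) -> float:
        return round(100.0 * self.counts[cls] / self.total, decimals)


@dataclass
class ComponentPeakCounts:
    counts: dict[str, int]
    total_peaks: int


@dataclass
class RegionDensity:
    component: str
    peak_count: int
    total_bp: int

    @property
    def density(self) -> float:
        """Peaks per Mb of the component."""
        return self.peak_count / (self.total_bp / 1e6)


@dataclass
class CGIMethylationSummary:
    component_counts: dict[str, int]  # methylated CGIs per component (multi-counted)
    methylated: int
    total: int

    @property
    def percent_methylated(self) -> float:
        return round(100.0 * self.methylated / self.total, 1) if self.total else 0.0


@dataclass
class RepeatPeakDistribution:
    percents: dict[str, float]
    overlapping_peaks: int


def _partition_trees(partition: FeaturePartition, labels) -> dict[str, GenomeIntervals]:
    return {
        label: GenomeIntervals.from_mapping(partition.label_intervals(label), label)
        for label in labels
    }


def _cgi_tree(cgis: list[CpGIsland]) -> GenomeIntervals:
    t = GenomeIntervals()
    for i, c in enumerate(cgis):
        t.add(c.chrom, c.start, c.end, i)
    return t


def _repeat_tree(repeats: list[RepeatAnnotation]) -> GenomeIntervals:
    t = GenomeIntervals()
    for r in repeats:
        t.add(r.chrom, r.start, r.end, r.family)
    return t


def classify_reads(
    reads: list[AlignedRead],
    partition: FeaturePartition,
    cgis: list[CpGIsland],
    repeats: list[RepeatAnnotation],
    precedence: tuple[str, ...] = ("cgi", "gene_body", "repeat", "other"),
) -> ReadClassification:
    """Assign each read to the first class in ``precedence`` it overlaps."""
    if not reads:
        raise ValueError("empty read set")
    trees = {
        "cgi": _cgi_tree(cgis),
        "gene_body": GenomeIntervals.from_mapping(partition.label_intervals("gene_body")),
        "repeat": _repeat_tree(repeats),
    }
    counts = {c: 0 for c in precedence}
    for r in reads:
        for cls in precedence:
            if cls == "other" or trees[cls].any_overlap(r.chrom, r.start, r.end):
                counts[cls] += 1
                break
    return ReadClassification(counts, len(reads))


def peak_component_counts(
    peaks: list[Peak],
    partition: FeaturePartition,
    cgis: list[CpGIsland],
    repeats: list[RepeatAnnotation],
) -> ComponentPeakCounts:
    """Per-component peak counts; a peak in k components counts once in each,
    and once in the deduplicated genome-wide total."""
    trees = _partition_trees(partition, ("promoter", "utr5", "exon", "intron", "utr3", "intergenic"))
    trees["cgi"] = _cgi_tree(cgis)
    trees["repeats"] = _repeat_tree(repeats)
    counts = {c: 0 for c in PEAK_COMPONENTS}
    for p in peaks:
        for comp in PEAK_COMPONENTS:
            if trees[comp].any_overlap(p.chrom, p.start, p.end):
                counts[comp] += 1
    return ComponentPeakCounts(counts, len(peaks))


def methylation_density(
    counts: ComponentPeakCounts, partition: FeaturePartition,
    extra_totals: dict[str, int] | None = None,
) -> list[RegionDensity]:
    """Peaks/Mb per component; components without area are omitted with a notice.

    ``extra_totals`` supplies base counts for components the partition does
    not carry (cgi, repeats).
    """
    totals = dict(partition.total_bp)
    if extra_totals:
        totals.update(extra_totals)
    out = []
    for comp, n in counts.counts.items():
        bp = totals.get(comp, 0)
        if bp <= 0:
            logger.info("component %s has zero total length; omitted from densities", comp)
            continue
        out.append(RegionDensity(comp, n, bp))
    return out


def classify_cgis(
    cgis: list[CpGIsland], peaks: list[Peak], partition: FeaturePartition | None = None
) -> CGIMethylationSummary:
    """Mark CGIs methylated iff they overlap >= 1 peak by >= 1 bp (in place),
    and summarise per-component methylated counts when a partition is given."""
    peak_tree = GenomeIntervals()
    for p in peaks:
        peak_tree.add(p.chrom, p.start, p.end)
    n_meth = 0
    for c in cgis:
        c.methylated = peak_tree.any_overlap(c.chrom, c.start, c.end)
        n_meth += c.methylated
    comp_counts = {c: 0 for c in CGI_COMPONENTS}
    if partition is not None:
        trees = _partition_trees(partition, CGI_COMPONENTS)
        for c in cgis:
            if not c.methylated:
                continue
            for comp in CGI_COMPONENTS:
                if trees[comp].any_overlap(c.chrom, c.start, c.end):
                    comp_counts[comp] += 1
    return CGIMethylationSummary(comp_counts, n_meth, len(cgis))


def methylated_percent(methylated: int, total: int) -> float:
    """Percent of CGIs methylated, to one decimal (reporting convention)."""
    return round(100.0 * methylated / total, 1)


def _assign_component(
    cgi: CpGIsland, trees: dict[str, GenomeIntervals], precedence=SIZE_BIN_PRECEDENCE
) -> str:
    for comp in precedence:
        if trees[comp].any_overlap(cgi.chrom, cgi.start, cgi.end):
            return comp
    return "intergenic"


def cgi_size_distribution(
    cgis: list[CpGIsland],
    partition: FeaturePartition,
    bin_width: int = 100,
    min_size: int = 200,
    max_bin_start: int = 1000,
) -> dict[bool, dict[tuple[int, int | None], dict[str, float]]]:
    """Per size-bin, per genomic component, the fraction of islands of that
    methylation status falling in the component, normalised within the bin.

    Keys: methylated status -> (bin_start, bin_end or None for the open top
    bin) -> component -> fraction. Component assignment uses the precedence
    promoter > utr5 > utr3 > exon > intron > intergenic.
    """
    trees = _partition_trees(partition, SIZE_BIN_PRECEDENCE)
    bins: list[tuple[int, int | None]] = [
        (b, b + bin_width) for b in range(min_size, max_bin_start, bin_width)
    ] + [(max_bin_start, None)]

    raw: dict[bool, dict[tuple[int, int | None], dict[str, int]]] = {
        st: {b: {c: 0 for c in SIZE_BIN_PRECEDENCE} for b in bins} for st in (True, False)
    }
    for c in cgis:
        if c.length < min_size:
            raise ValueError(f"island of length {c.length} below min_size {min_size}")
        status = bool(c.methylated)
        for bs, be in bins:
            if c.length >= bs and (be is None or c.length < be):
                raw[status][(bs, be)][_assign_component(c, trees)] += 1
                break
    out: dict[bool, dict[tuple[int, int | None], dict[str, float]]] = {True: {}, False: {}}
    for st in (True, False):
        for b, comps in raw[st].items():
            tot = sum(comps.values())
            out[st][b] = {c: (n / tot if tot else 0.0) for c, n in comps.items()}
    return out


def repeat_peak_distribution(
    peaks: list[Peak], repeats: list[RepeatAnnotation]
) -> RepeatPeakDistribution:
    """Family percentages among repeat-overlapping peaks; a peak over several
    families contributes 1/|families| to each."""
    tree = _repeat_tree(repeats)
    weights: dict[str, float] = {}
    n_overlapping = 0
    for p in peaks:
        fams = set(tree.query(p.chrom, p.start, p.end))
        if not fams:
            continue
        n_overlapping += 1
        for fam in fams:
            weights[fam] = weights.get(fam, 0.0) + 1.0 / len(fams)
    if n_overlapping == 0:
        logger.info("no repeat-overlapping peaks; empty repeat distribution")
        return RepeatPeakDistribution({}, 0)
    percents = {fam: round(100.0 * w / n_overlapping, 2) for fam, w in sorted(weights.items())}
    return RepeatPeakDistribution(percents, n_overlapping)
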