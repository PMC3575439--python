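"""Methylated-gene calling and per-gene-region differential methylation.

A gene is "methylated" in a sample when >= 1 enrichment peak overlaps its
promoter (TSS +/- 2 kb) or gene body. Differential methylation between two
samples is tested per gene x gene-region on unique-read counts: the 2x2
table (count, library_total - count) for the two samples goes through a
two-sided Fisher exact test, the fold change is computed on pseudocounted
counts-per-million, and a region is called when |fold| >= min_fold in
either direction AND p < max_p. Direction "up" means greater normalised
coverage in the SECOND sample of the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genome_model import FeaturePartition, TranscriptModel
from .intervals import GenomeIntervals, clip, merge_intervals, subtract_intervals
from .medip_peaks import AlignedRead, Peak

GENE_REGIONS = (
    "upstream2k", "utr5", "exon", "intron", "utr3", "downstream2k", "promoter", "gene_body",
)
#: the regions reported in per-region DMG tables
TABLE_REGIONS = ("upstream2k", "utr5", "exon", "intron", "utr3", "downstream2k")


@dataclass
class MethylatedGene:
    gene_id: str
    evidence: list[int]  # indices of the overlapping peaks

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError(f"{self.gene_id}: methylated gene requires evidence")


@dataclass
class GeneRegionCoverage:
    gene_id: str
    region: str
    count: int
    library_total: int

    @property
    def cpm(self) -> float:
        return 1e6 * self.count / self.library_total


@dataclass
class DifferentialCall:
    gene_id: str
    region: str
    contrast: tuple[str, str]
    count_a: int
    count_b: int
    cpm_a: float
    cpm_b: float
    fold_change: float  # pseudocounted cpm_b / cpm_a
    pvalue: float
    qvalue: float
    direction: str  # up = greater in the second sample


def _gene_regions(
    transcripts: Sequence[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    flank: int = 2000,
) -> dict[str, dict[str, list]]:
    """Per gene, merged interval lists per region label (chrom from any tx)."""
    per_gene: dict[str, dict] = {}
    for t in transcripts:
        g = per_gene.setdefault(
            t.gene_id, {"chrom": t.chrom, **{r: [] for r in GENE_REGIONS}}
        )
        L = chrom_sizes[t.chrom]
        g["gene_body"].append((t.tx_start, t.tx_end))
        prom = clip(t.tss - flank, t.tss + flank, L)
        if prom:
            g["promoter"].append(prom)
        if t.strand == "+":
            up = clip(t.tx_start - flank, t.tx_start, L)
            down = clip(t.tx_end, t.tx_end + flank, L)
        else:
            up = clip(t.tx_end, t.tx_end + flank, L)
            down = clip(t.tx_start - flank, t.tx_start, L)
        if up:
            g["upstream2k"].append(up)
        if down:
            g["downstream2k"].append(down)
        g["exon"].extend(t.exons)
        g["intron"].extend(subtract_intervals([(t.tx_start, t.tx_end)], t.exons))
        u5, u3 = t.utr_intervals()
        g["utr5"].extend(u5)
        g["utr3"].extend(u3)
    for g in per_gene.values():
        for r in GENE_REGIONS:
            g[r] = merge_intervals(g[r])
    return per_gene


def call_methylated_genes(
    peaks: Sequence[Peak],
    partition: FeaturePartition,
    transcripts: Sequence[TranscriptModel],
) -> list[MethylatedGene]:
    """Genes with >= 1 peak overlapping promoter or gene body by >= 1 bp."""
    regions = _gene_regions(transcripts, partition.chrom_sizes)
    tree = GenomeIntervals()
    for gid, g in regions.items():
        for iv in g["promoter"] + g["gene_body"]:
            tree.add(g["chrom"], iv[0], iv[1], gid)
    hits: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        for gid in set(tree.query(p.chrom, p.start, p.end)):
            hits.setdefault(gid, []).append(i)
    return [MethylatedGene(gid, sorted(idx)) for gid, idx in sorted(hits.items())]


def gene_region_counts(
    reads: Sequence[AlignedRead],
    transcripts: Sequence[TranscriptModel],
    partition: FeaturePartition,
    regions: Sequence[str] = GENE_REGIONS,
) -> dict[tuple[str, str], GeneRegionCoverage]:
    """Unique-read count per gene x region; a read overlapping two regions
    of a gene counts once in each region."""
    per_gene = _gene_regions(transcripts, partition.chrom_sizes)
    tree = GenomeIntervals()
    for gid, g in per_gene.items():
        for region in regions:
            for s, e in g[region]:
                tree.add(g["chrom"], s, e, (gid, region))
    counts = {
        (gid, region): 0 for gid in per_gene for region in regions
    }
    lib = len(reads)
    for r in reads:
        for key in set(tree.query(r.chrom, r.start, r.end)):
            counts[key] += 1
    return {
        key: GeneRegionCoverage(key[0], key[1], n, lib) for key, n in counts.items()
    }


def compare_contrast(
    cov_a: Mapping[tuple[str, str], GeneRegionCoverage],
    cov_b: Mapping[tuple[str, str], GeneRegionCoverage],
    contrast: tuple[str, str] = ("A", "B"),
    min_fold: float = 2.0,
    max_p: float = 0.01,
    pseudocount: float = 0.5,
) -> list[DifferentialCall]:
    """Differential calls over the shared gene x region universe.

    The raw Fisher p is thresholded (matching the study design); BH
    q-values are reported for transparency but not used for calling.
    """
    if set(cov_a) != set(cov_b):
        raise ValueError("samples cover different gene x region universes")
    keys = sorted(cov_a)
    pvals: list[float] = []
    rows = []
    for key in keys:
        a, b = cov_a[key], cov_b[key]
        ka, kb = a.count, b.count
        la, lb = a.library_total, b.library_total
        if ka == 0 and kb == 0:
            p = 1.0
        else:
            _, p = fisher_exact([[ka, la - ka], [kb, lb - kb]], alternative="two-sided")
        cpm_a = 1e6 * (ka + pseudocount) / la
        cpm_b = 1e6 * (kb + pseudocount) / lb
        rows.append((key, ka, kb, cpm_a, cpm_b, p))
        pvals.append(p)
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    calls = []
    for (key, ka, kb, cpm_a, cpm_b, p), q in zip(rows, qvals):
        fold = cpm_b / cpm_a
        if p < max_p and (fold >= min_fold or fold <= 1.0 / min_fold):
            calls.append(
                DifferentialCall(
                    key[0], key[1], contrast, ka, kb, cpm_a, cpm_b, fold, p, float(q),
                    "up" if cpm_b > cpm_a else "down",
                )
            )
    return calls


def intersect_contrasts(
    calls_per_contrast: Mapping[str, Sequence[DifferentialCall]],
    grouping: str = "gene",
) -> dict:
    """Venn-style intersection of differential calls across contrasts.

    grouping="gene" collapses regions and directions (gene-level overlap);
    grouping="gene_region_direction" keeps the fine key.
    """
    if len(calls_per_contrast) < 2:
        raise ValueError("need >= 2 contrasts to intersect")
    if grouping == "gene":
        key = lambda c: c.gene_id
    elif grouping == "gene_region_direction":
        key = lambda c: (c.gene_id, c.region, c.direction)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    sets = {name: {key(c) for c in calls} for name, calls in calls_per_contrast.items()}
    names = sorted(sets)
    out = {
        "per_contrast": {n: len(sets[n]) for n in names},
        "pairwise": {},
        "shared_all": sorted(set.intersection(*sets.values())),
    }
    for a, b in combinations(names, 2):
        out["pairwise"][(a, b)] = len(sets[a] & sets[b])
    return out


def write_calls_tsv(calls: Sequence[DifferentialCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tregion\tcountA\tcountB\tcpmA\tcpmB\tfold\tp\tq\tdirection\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.region}\t{c.count_a}\t{c.count_b}\t{c.cpm_a:.4f}"
                f"\t{c.cpm_b:.4f}\t{c.fold_change:.4f}\t{c.pvalue:.4g}\t{c.qvalue:.4g}"
                f"\t{c.direction}\n"
            )
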