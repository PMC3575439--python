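"""Synthetic genomes, annotations and MeDIP read sets with known truth.

Emulates the study design the pipeline targets: four sample groups
(WRR_h, WRR_l, XH_h, XH_l — the high/low body-weight tails of two broiler
breeds), a genome with planted CpG islands, methylated domains whose read
enrichment grows with methylated-CpG content, and planted differentially
methylated genes with known fold changes.

MeDIP enrichment model: a fragment is sampled with probability
proportional to ``alpha + beta * (sum of methylation levels over the CpG
sites it covers)``; alpha 1 and beta 5 give roughly background-vs-domain
density ratios in the range MeDIP libraries show. Fragments are 100-500 bp
(the sonication range of the emulated protocol) and the sequenced read is
the 50 bp 5' end of the fragment, single-end.

Everything is deterministic under the config seed; all planted truths are
written to truth files sufficient to score every downstream module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cgi_scan import gc_fraction, obs_exp_cpg
from .genome_model import GenomeSequence, RepeatAnnotation, TranscriptModel, write_gene_models_bed12
from .medip_peaks import AlignedRead, write_reads_bed

SAMPLE_GROUPS = ("WRR_h", "WRR_l", "XH_h", "XH_l")
CONTRASTS = (("WRR_h", "WRR_l"), ("XH_h", "XH_l"), ("WRR_h", "XH_h"), ("WRR_l", "XH_l"))


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 500_000, "chr2": 300_000})
    background_gc: float = 0.40
    background_cpg_depletion: float = 0.8
    # planted CpG islands
    n_cgi: int = 30
    cgi_length_range: tuple = (250, 800)
    # genes
    n_genes: int = 40
    gene_length_range: tuple = (2_000, 6_000)
    exons_per_gene: tuple = (2, 8)
    # repeats: family -> genome coverage fraction
    repeat_families: dict = field(
        default_factory=lambda: {
            "LINE/CR1": 0.08, "LTR/ERVL": 0.04, "Simple_repeat": 0.02, "SINE": 0.01, "DNA": 0.01,
        }
    )
    # methylation landscape / MeDIP sampling
    n_background_domains: int = 20
    domain_length: int = 2_000
    domain_level: float = 1.0
    alpha: float = 1.0
    beta: float = 5.0
    fragment_length_range: tuple = (100, 500)
    read_length: int = 50
    samples: tuple = SAMPLE_GROUPS
    library_size: int = 100_000
    # planted differential methylation
    n_dmg: int = 20
    dmg_fold: float = 4.0
    dmg_low_level: float = 0.2
    null_gene_level: float = 0.5
    # bisulfite
    n_amplicons: int = 5
    clones_per_region: int = 10
    conversion_failure_rate: float = 0.01
    inappropriate_conversion_rate: float = 0.01

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# genome


def _window_thresholds_hold(block: str, window: int = 100) -> bool:
    """Every window of the block passes the island GC and O/E thresholds,
    so the block is island-dense throughout, not only on average."""
    if len(block) < window:
        return gc_fraction(block) > 0.5 and obs_exp_cpg(block) > 0.6
    arr = np.frombuffer(block.encode("ascii"), dtype=np.uint8)
    is_c, is_g = arr == ord("C"), arr == ord("G")
    cpg = np.zeros(len(arr), dtype=bool)
    cpg[:-1] = is_c[:-1] & is_g[1:]
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    cc, cg_, ccpg = cum(is_c), cum(is_g), cum(cpg)
    s = np.arange(0, len(arr) - window + 1)
    n_c, n_g = cc[s + window] - cc[s], cg_[s + window] - cg_[s]
    n_cpg = ccpg[s + window - 1] - ccpg[s]
    if ((n_c + n_g) <= 0.5 * window).any():
        return False
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * window / (n_c * n_g), 0.0)
    return bool((oe > 0.6).all())


def _cgi_block(length: int, rng: np.random.Generator) -> str:
    """A CpG-dense block passing all three island criteria by construction,
    in every window as well as overall."""
    bases = np.array(list("ACGT"))
    for _ in range(200):
        parts: list[str] = []
        n = 0
        while n < length:
            if rng.random() < 0.18:
                parts.append("CG")
                n += 2
            else:
                parts.append(str(rng.choice(bases)))
                n += 1
        block = "".join(parts)[:length]
        if (
            gc_fraction(block) > 0.5
            and obs_exp_cpg(block) > 0.6
            and _window_thresholds_hold(block)
        ):
            return block
    raise RuntimeError("failed to draw a CpG-dense block passing the island criteria")


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_lengths: dict, n: int, lengths, min_gap: int,
    max_tries_factor: int = 50, exclude: dict | None = None,
) -> list[tuple[str, int, int]]:
    chroms = sorted(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if exclude:
        for c, ivs in exclude.items():
            placed.setdefault(c, []).extend(ivs)
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries_factor * n:
            raise RuntimeError(f"could not place {n} non-overlapping intervals")
        L = int(lengths[len(out)]) if hasattr(lengths, "__getitem__") else int(lengths)
        c = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        if chrom_lengths[c] <= L + 2 * min_gap:
            continue
        s = int(rng.integers(min_gap, chrom_lengths[c] - L - min_gap))
        e = s + L
        if any(s - min_gap < pe and ps < e + min_gap for ps, pe in placed[c]):
            continue
        placed[c].append((s, e))
        out.append((c, s, e))
    return out


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, GenomeSequence], list[tuple[str, int, int]]]:
    """Background sequence at the configured GC plus planted CGI blocks.

    Returns the genome and the truth list of planted island coordinates.
    """
    rng = rng or config.rng()
    for c, L in config.chrom_lengths.items():
        if L < 10_000:
            raise ValueError(f"chromosome {c} shorter than 10 kb")
    gc = config.background_gc
    bases = np.array(list("ACGT"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for c, L in sorted(config.chrom_lengths.items()):
        arr = rng.choice(bases, size=L, p=probs)
        # vertebrate-like CpG depletion: break ~80% of background CG
        # dinucleotides so islands stand out from the background
        cg = np.where((arr[:-1] == "C") & (arr[1:] == "G"))[0]
        broken = cg[rng.random(cg.size) < config.background_cpg_depletion]
        arr[broken + 1] = rng.choice(np.array(list("AT")), size=broken.size)
        seqs[c] = arr
    lengths = rng.integers(*config.cgi_length_range, size=config.n_cgi)
    sites = _place_nonoverlapping(rng, config.chrom_lengths, config.n_cgi, lengths, min_gap=300)
    truth = []
    for c, s, e in sites:
        block = _cgi_block(e - s, rng)
        seqs[c][s:e] = list(block)
        truth.append((c, s, e))
    genome = {c: GenomeSequence(c, "".join(arr)) for c, arr in seqs.items()}
    return genome, sorted(truth)


def generate_genes(
    config: SyntheticConfig,
    rng: np.random.Generator,
    cgi_truth: list[tuple[str, int, int]] = (),
) -> list[TranscriptModel]:
    """Non-overlapping gene models (one transcript per gene) with CDS,
    placed clear of planted islands (methylated gene bodies should not sit
    on hypomethylated CGIs)."""
    exclude: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in cgi_truth:
        exclude.setdefault(c, []).append((s, e))
    lengths = rng.integers(*config.gene_length_range, size=config.n_genes)
    sites = _place_nonoverlapping(
        rng, config.chrom_lengths, config.n_genes, lengths, min_gap=2_500, exclude=exclude,
    )
    models = []
    for i, (chrom, s, e) in enumerate(sites, 1):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        # 2*n_ex - 2 interior cuts delimit alternating exon/intron blocks
        cuts = np.sort(rng.choice(np.arange(s + 50, e - 50), size=2 * n_ex - 2, replace=False))
        bounds = [s, *cuts.tolist(), e]
        exons = [(bounds[j], bounds[j + 1]) for j in range(0, len(bounds) - 1, 2)]
        strand = "+" if rng.random() < 0.5 else "-"
        cds_s = exons[0][0] + min(30, exons[0][1] - exons[0][0] - 1)
        cds_e = exons[-1][1] - min(30, exons[-1][1] - exons[-1][0] - 1)
        models.append(
            TranscriptModel(f"g{i:03d}", f"g{i:03d}.t1", chrom, strand, s, e, exons, cds_s, cds_e)
        )
    return models


def generate_repeats(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[RepeatAnnotation]:
    genome_len = sum(config.chrom_lengths.values())
    chroms = sorted(config.chrom_lengths)
    sizes = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    out = []
    for family, frac in sorted(config.repeat_families.items()):
        target = frac * genome_len
        covered = 0
        while covered < target:
            L = int(rng.integers(200, 1_000))
            c = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
            s = int(rng.integers(0, config.chrom_lengths[c] - L))
            out.append(RepeatAnnotation(c, s, s + L, family))
            covered += L
    return out


def write_genome_fasta(genome: dict[str, GenomeSequence], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom].sequence
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gtf(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_start is not None:
                for s, e in m.exons:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\tsynthetic\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# methylation landscape and read simulation

MethylationDomain = tuple[str, int, int, float]  # chrom, start, end, level


def background_domains(
    config: SyntheticConfig,
    genes: list[TranscriptModel],
    rng: np.random.Generator,
    cgi_truth: list[tuple[str, int, int]] = (),
) -> list[MethylationDomain]:
    """Intergenic methylated domains, placed clear of gene bodies (plus the
    2 kb flanks) so they cannot masquerade as gene-level differences, and
    clear of planted CGIs (islands are predominantly hypomethylated)."""
    exclude: dict[str, list[tuple[int, int]]] = {}
    for m in genes:
        exclude.setdefault(m.chrom, []).append((m.tx_start - 2_500, m.tx_end + 2_500))
    for c, s, e in cgi_truth:
        exclude.setdefault(c, []).append((s - 500, e + 500))
    sites = _place_nonoverlapping(
        rng, config.chrom_lengths, config.n_background_domains, config.domain_length,
        min_gap=1_000, exclude=exclude,
    )
    return [(c, s, e, config.domain_level) for c, s, e in sites]


def base_landscape(
    config: SyntheticConfig,
    genes: list[TranscriptModel],
    shared_domains: list[MethylationDomain],
    gene_levels: dict[str, float] | None = None,
) -> list[MethylationDomain]:
    """Shared background domains plus per-gene-body levels for one sample."""
    domains = list(shared_domains)
    for m in genes:
        level = (gene_levels or {}).get(m.gene_id, config.null_gene_level)
        if level > 0:
            domains.append((m.chrom, m.tx_start, m.tx_end, level))
    return domains


def plant_differential(
    config: SyntheticConfig,
    genes: list[TranscriptModel],
    dmg_genes: list[str],
    fold: float | None = None,
) -> tuple[dict[str, float], dict[str, float], list[dict]]:
    """Gene-body methylation levels for a two-sample contrast plus truth.

    Sample A keeps the low level on planted genes, sample B gets
    ``low * fold`` (clipped to 1), so the expected coverage change follows
    the planted fold and the expected call direction is "up" (greater in
    the second sample). Returns (levels_A, levels_B, truth rows).
    """
    fold = config.dmg_fold if fold is None else fold
    if fold <= 0:
        raise ValueError("fold must be positive")
    known = {m.gene_id for m in genes}
    missing = set(dmg_genes) - known
    if missing:
        raise KeyError(f"unknown planted genes: {sorted(missing)}")
    levels_a = {g: config.null_gene_level for g in known}
    levels_b = dict(levels_a)
    truth = []
    for g in dmg_genes:
        if fold == 1.0:
            continue
        levels_a[g] = config.dmg_low_level
        levels_b[g] = min(1.0, config.dmg_low_level * fold)
        truth.append(
            {"gene_id": g, "region": "gene_body", "fold": fold, "direction": "up"}
        )
    return levels_a, levels_b, truth


def _methylation_weight_arrays(
    genome: dict[str, GenomeSequence], landscape: list[MethylationDomain]
) -> dict[str, np.ndarray]:
    """Per-chromosome per-bp methylation mass: level at each CpG cytosine."""
    arrays = {}
    for chrom, g in genome.items():
        arr = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8)
        is_cpg = np.zeros(len(arr), dtype=bool)
        is_cpg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        level = np.zeros(len(arr), dtype=np.float32)
        for c, s, e, lv in landscape:
            if c == chrom:
                level[s:e] = np.maximum(level[s:e], lv)
        arrays[chrom] = (is_cpg * level).astype(np.float64)
    return arrays


def simulate_medip_reads(
    config: SyntheticConfig,
    genome: dict[str, GenomeSequence],
    landscape: list[MethylationDomain],
    rng: np.random.Generator,
    n_reads: int | None = None,
) -> list[AlignedRead]:
    """Sample exactly ``n_reads`` single-end reads under the MeDIP model.

    Rejection sampling: candidate fragments are uniform (start, length);
    acceptance probability is the fragment weight
    ``alpha + beta * methylated-CpG mass`` over a global bound.
    """
    n_reads = config.library_size if n_reads is None else n_reads
    if n_reads < 10_000:
        raise ValueError("library size must be >= 10,000")
    for c, *_ in landscape:
        if c not in genome:
            raise KeyError(f"landscape chromosome {c!r} absent from genome")
    fmin, fmax = config.fragment_length_range
    weights = _methylation_weight_arrays(genome, landscape)
    chroms = sorted(genome)
    offsets = np.cumsum([0] + [genome[c].length for c in chroms])
    total = int(offsets[-1])
    cum = np.concatenate([[0.0], np.cumsum(np.concatenate([weights[c] for c in chroms]))])
    # global weight bound from the maximum methylation mass any fragment can cover
    span_mass = cum[fmax:] - cum[:-fmax]
    wmax = config.alpha + config.beta * float(span_mass.max(initial=0.0))

    reads: list[AlignedRead] = []
    while len(reads) < n_reads:
        m = max(20_000, 4 * (n_reads - len(reads)))
        starts = rng.integers(0, total - fmax, size=m)
        lengths = rng.integers(fmin, fmax + 1, size=m)
        strands = rng.random(size=m) < 0.5
        u = rng.random(size=m)
        ends = starts + lengths
        ci = np.searchsorted(offsets, starts, "right") - 1
        within = ends <= offsets[ci + 1]
        w = config.alpha + config.beta * (cum[ends] - cum[starts])
        accept = within & (u * wmax < w)
        for s, e, c_idx, fwd in zip(starts[accept], ends[accept], ci[accept], strands[accept]):
            chrom = chroms[c_idx]
            off = offsets[c_idx]
            fs, fe = int(s - off), int(e - off)
            if fwd:
                reads.append(AlignedRead(chrom, fs, fs + config.read_length, "+"))
            else:
                reads.append(AlignedRead(chrom, fe - config.read_length, fe, "-"))
            if len(reads) == n_reads:
                break
    return reads


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, GenomeSequence]
    cgi_truth: list[tuple[str, int, int]]
    transcripts: list[TranscriptModel]
    repeats: list[RepeatAnnotation]
    sample_levels: dict[str, dict[str, float]]  # sample -> gene -> level
    landscapes: dict[str, list[MethylationDomain]]
    reads: dict[str, list[AlignedRead]]
    dmg_truth: list[dict]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """The four-group dataset: each planted gene is high in exactly one
    group, so every contrast carries a known set of differential genes."""
    rng = config.rng()
    genome, cgi_truth = generate_genome(config, rng)
    genes = generate_genes(config, rng, cgi_truth)
    repeats = generate_repeats(config, rng)
    gene_ids = [m.gene_id for m in genes]
    dmg_genes = gene_ids[: config.n_dmg]
    high = min(1.0, config.dmg_low_level * config.dmg_fold)

    sample_levels: dict[str, dict[str, float]] = {
        s: {g: config.null_gene_level for g in gene_ids} for s in config.samples
    }
    truth = []
    for i, g in enumerate(dmg_genes):
        hot = config.samples[i % len(config.samples)]
        for s in config.samples:
            sample_levels[s][g] = high if s == hot else config.dmg_low_level
        for a, b in CONTRASTS:
            la, lb = sample_levels[a][g], sample_levels[b][g]
            if la != lb:
                truth.append(
                    {
                        "gene_id": g, "region": "gene_body", "contrast": f"{a}_vs_{b}",
                        "fold": lb / la, "direction": "up" if lb > la else "down",
                    }
                )

    shared = background_domains(config, genes, rng, cgi_truth)
    landscapes = {}
    reads = {}
    for i, s in enumerate(config.samples):
        landscapes[s] = base_landscape(config, genes, shared, sample_levels[s])
        reads[s] = simulate_medip_reads(
            config, genome, landscapes[s], np.random.default_rng([config.seed, 11, i])
        )
    return SyntheticDataset(
        config, genome, cgi_truth, genes, repeats, sample_levels, landscapes, reads, truth
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every input the pipeline consumes plus the truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_genome_fasta(ds.genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    write_gtf(ds.transcripts, outdir / "genes.gtf")
    paths["genes"] = str(outdir / "genes.gtf")
    write_gene_models_bed12(ds.transcripts, outdir / "genes.bed")
    with open(outdir / "repeats.bed", "w") as fh:
        for r in ds.repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\n")
    paths["repeats"] = str(outdir / "repeats.bed")
    with open(outdir / "truth_cgi.bed", "w") as fh:
        for c, s, e in ds.cgi_truth:
            fh.write(f"{c}\t{s}\t{e}\tplanted_cgi\n")
    paths["truth_cgi"] = str(outdir / "truth_cgi.bed")
    for s, rd in ds.reads.items():
        write_reads_bed(rd, outdir / f"reads_{s}.bed")
        paths[f"reads_{s}"] = str(outdir / f"reads_{s}.bed")
    with open(outdir / "truth_dmg.tsv", "w") as fh:
        fh.write("gene_id\tregion\tcontrast\tfold\tdirection\n")
        for row in ds.dmg_truth:
            fh.write(
                f"{row['gene_id']}\t{row['region']}\t{row['contrast']}\t"
                f"{row['fold']:.3f}\t{row['direction']}\n"
            )
    paths["truth_dmg"] = str(outdir / "truth_dmg.tsv")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(ds.config), fh, indent=1, default=str)
    paths["config"] = str(outdir / "config.json")
    return paths
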