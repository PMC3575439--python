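"""End-to-end orchestration: simulate (or ingest) -> CGIs -> peaks ->
profile -> differential -> enrichment -> bisulfite, with a run manifest.

Every table is written as TSV with a leading comment line naming what it
summarises. Re-running with an identical config reproduces an identical
output tree (checksums recorded in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .bisulfite_validation import (
    amplicon_from_coords,
    build_clone_matrix,
    concordance_report,
    simulate_clones,
)
from .cgi_scan import scan_genome, write_cgi_bed
from .differential_methylation import (
    call_methylated_genes,
    compare_contrast,
    gene_region_counts,
    intersect_contrasts,
    write_calls_tsv,
    TABLE_REGIONS,
)
from .enrichment import AnnotationMap, enrich_terms, write_enrichment_tsv
from .genome_model import build_feature_partition, chrom_sizes
from .medip_peaks import PeakCallConfig, call_peaks, write_peaks
from .methylome_profile import (
    classify_cgis,
    classify_reads,
    methylation_density,
    peak_component_counts,
    repeat_peak_distribution,
)
from .synthetic_data import CONTRASTS, SyntheticConfig, generate_dataset, write_dataset


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config: SyntheticConfig,
    outdir,
    peak_config: PeakCallConfig | None = None,
    write_inputs: bool = True,
) -> dict:
    """Run the whole synthetic pipeline; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config)
    if write_inputs:
        write_dataset(ds, outdir / "inputs")

    sizes = chrom_sizes(ds.genome)
    partition = build_feature_partition(ds.transcripts, sizes)
    cgis = scan_genome(ds.genome)
    write_cgi_bed(cgis, outdir / "cgi.bed", outdir / "cgi.tsv")

    pk_cfg = peak_config or PeakCallConfig()
    peaks = {}
    for s in config.samples:
        peaks[s] = call_peaks(ds.reads[s], sizes, pk_cfg)
        write_peaks(peaks[s], outdir / f"peaks_{s}.bed", outdir / f"peaks_{s}.tsv")

    # read statistics (one row per sample)
    with open(outdir / "table_read_stats.tsv", "w") as fh:
        fh.write("# per-sample unique-read classification (cgi / gene body / repeat / other)\n")
        fh.write("sample\ttotal_unique\tcgi\tgene_body\trepeat\tother"
                 "\tpct_cgi\tpct_gene_body\tpct_repeat\tpct_other\n")
        for s in config.samples:
            rc = classify_reads(ds.reads[s], partition, cgis, ds.repeats)
            fh.write(
                f"{s}\t{rc.total}\t" + "\t".join(str(rc.counts[c]) for c in rc.counts)
                + "\t" + "\t".join(f"{rc.percent(c):.2f}" for c in rc.counts) + "\n"
            )

    # peak distribution per genomic component + densities
    cgi_bp = sum(c.length for c in cgis)
    repeat_bp = sum(r.end - r.start for r in ds.repeats)
    with open(outdir / "table_component_counts.tsv", "w") as fh, open(
        outdir / "table_density.tsv", "w"
    ) as fh2:
        fh.write("# peak counts per genomic component (a peak counts once per "
                 "component it overlaps; total is deduplicated)\n")
        fh.write("sample\ttotal_peaks\tpromoter\tutr5\texon\tintron\tutr3"
                 "\tintergenic\tcgi\trepeats\n")
        fh2.write("# methylation density: peaks per Mb of each component\n")
        fh2.write("sample\tcomponent\tpeak_count\ttotal_bp\tdensity_per_mb\n")
        for s in config.samples:
            counts = peak_component_counts(peaks[s], partition, cgis, ds.repeats)
            fh.write(
                f"{s}\t{counts.total_peaks}\t"
                + "\t".join(str(counts.counts[c]) for c in counts.counts) + "\n"
            )
            for rd in methylation_density(
                counts, partition, {"cgi": cgi_bp, "repeats": repeat_bp}
            ):
                fh2.write(
                    f"{s}\t{rd.component}\t{rd.peak_count}\t{rd.total_bp}"
                    f"\t{rd.density:.3f}\n"
                )

    # repeat-family distribution
    with open(outdir / "table_repeat_distribution.tsv", "w") as fh:
        fh.write("# percent of repeat-overlapping peaks per repeat family\n")
        fh.write("sample\tfamily\tpercent\n")
        for s in config.samples:
            dist = repeat_peak_distribution(peaks[s], ds.repeats)
            for fam, pct in dist.percents.items():
                fh.write(f"{s}\t{fam}\t{pct:.2f}\n")

    # CGI methylation summary
    with open(outdir / "table_cgi_summary.tsv", "w") as fh:
        fh.write("# methylated-CGI counts per component and percent methylated\n")
        fh.write("sample\tutr5\tutr3\texon\tintron\tintergenic"
                 "\tmethylated\ttotal\tpercent\n")
        for s in config.samples:
            summ = classify_cgis(cgis, peaks[s], partition)
            fh.write(
                f"{s}\t" + "\t".join(str(summ.component_counts[c]) for c in summ.component_counts)
                + f"\t{summ.methylated}\t{summ.total}\t{summ.percent_methylated:.1f}\n"
            )

    # methylated genes and differential calls
    methylated = {
        s: {g.gene_id for g in call_methylated_genes(peaks[s], partition, ds.transcripts)}
        for s in config.samples
    }
    coverages = {
        s: gene_region_counts(ds.reads[s], ds.transcripts, partition)
        for s in config.samples
    }
    calls = {}
    for a, b in CONTRASTS:
        name = f"{a}_vs_{b}"
        calls[name] = compare_contrast(coverages[a], coverages[b], (a, b))
        write_calls_tsv(calls[name], outdir / f"dmg_{name}.tsv")
    with open(outdir / "table_dmg_counts.tsv", "w") as fh:
        fh.write("# differentially methylated gene counts per contrast, region and direction\n")
        fh.write("contrast\tdirection\t" + "\t".join(TABLE_REGIONS) + "\n")
        for name, cl in calls.items():
            for direction in ("up", "down"):
                row = [
                    str(sum(1 for c in cl if c.region == r and c.direction == direction))
                    for r in TABLE_REGIONS
                ]
                fh.write(f"{name}\t{direction}\t" + "\t".join(row) + "\n")
    venn = intersect_contrasts(calls, grouping="gene")
    with open(outdir / "table_dmg_overlap.tsv", "w") as fh:
        fh.write("# gene-level overlap of differential calls between contrasts\n")
        fh.write("contrast_a\tcontrast_b\tshared_genes\n")
        for (a, b), n in venn["pairwise"].items():
            fh.write(f"{a}\t{b}\t{n}\n")
        fh.write(f"ALL\tALL\t{len(venn['shared_all'])}\n")

    # enrichment on a synthetic annotation map: planted genes share a term
    rng = np.random.default_rng([config.seed, 23])
    gene_ids = [m.gene_id for m in ds.transcripts]
    planted = {t["gene_id"] for t in ds.dmg_truth}
    amap = AnnotationMap(
        {
            g: {"planted_pathway"} if g in planted else {f"pathway_{int(rng.integers(5))}"}
            for g in gene_ids
        },
        {"planted_pathway": ("planted differential pathway", "pathway")},
    )
    background = set().union(*methylated.values()) or set(gene_ids)
    first = f"{CONTRASTS[0][0]}_vs_{CONTRASTS[0][1]}"
    study = {c.gene_id for c in calls[first]} & background
    if study:
        results = enrich_terms(study, background | study, amap)
        write_enrichment_tsv(results, amap, outdir / "enrichment.tsv")
    else:
        (outdir / "enrichment.tsv").write_text("term\tlabel\tk\tn\tK\tN\tpvalue\tadjusted_p\n")

    # bisulfite validation at synthetic amplicons: low region in unmethylated
    # background, high regions inside methylated domains
    bs_rng = np.random.default_rng([config.seed, 29])
    sample = config.samples[0]
    domains = [d for d in ds.landscapes[sample] if d[3] >= 0.9]
    reports = []
    with open(outdir / "bisulfite_report.tsv", "w") as fh:
        fh.write("# bisulfite-clone validation vs MeDIP peaks per amplicon\n")
        fh.write("region\texpected_class\tmean_methylation\thas_peak\tconcordance\n")
        for i in range(min(config.n_amplicons, len(domains) + 1)):
            if i == 0:  # low-methylation amplicon in plain background
                chrom = sorted(ds.genome)[0]
                start, end = 1_000, 1_400
                level, expected = 0.05, "low"
            else:
                chrom, ds_, de_, _ = domains[i - 1]
                start, end = ds_ + 100, min(de_, ds_ + 500)
                level, expected = 0.8, "high"
            region = amplicon_from_coords(f"AMP{i + 1}", chrom, start + 1, end, expected)
            ref = ds.genome[chrom].sequence[start:end]
            clones = simulate_clones(
                ref, level, config.clones_per_region, bs_rng,
                config.conversion_failure_rate, config.inappropriate_conversion_rate,
            )
            matrix = build_clone_matrix(region, clones, ref)
            verdict = concordance_report(matrix, peaks[sample], region)
            has_peak = any(
                p.chrom == chrom and p.start < end and start < p.end for p in peaks[sample]
            )
            fh.write(
                f"{region.name}\t{expected}\t{matrix.mean_fraction:.3f}"
                f"\t{has_peak}\t{verdict}\n"
            )
            (outdir / f"bisulfite_{region.name}.txt").write_text(matrix.lollipop() + "\n")
            reports.append((region.name, verdict))

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed"))
        },
        "bisulfite_concordance": dict(reports),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
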