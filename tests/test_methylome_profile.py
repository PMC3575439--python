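import numpy as np
import pytest

from medipmap.cgi_scan import CpGIsland
from medipmap.genome_model import RepeatAnnotation, TranscriptModel, build_feature_partition
from medipmap.medip_peaks import AlignedRead, Peak
from medipmap.methylome_profile import (
    ComponentPeakCounts,
    classify_cgis,
    classify_reads,
    cgi_size_distribution,
    methylated_percent,
    methylation_density,
    peak_component_counts,
    repeat_peak_distribution,
)
from medipmap.study_tables import CGI_METHYLATION_COUNTS


def _peak(chrom, s, e):
    return Peak(chrom, s, e, (s + e) // 2, 1, 1.0, 1e-9)


@pytest.fixture(scope="module")
def toy():
    """One gene, one CGI inside its body, one repeat elsewhere."""
    t = TranscriptModel("g1", "t1", "chr1", "+", 5_000, 9_000, [(5_000, 6_000), (8_000, 9_000)])
    part = build_feature_partition([t], {"chr1": 50_000})
    cgis = [CpGIsland("chr1", 5_500, 5_900, 0.6, 1.0)]
    repeats = [RepeatAnnotation("chr1", 20_000, 21_000, "LINE/CR1")]
    return part, cgis, repeats


# ---------------------------------------------------------------------------
# read classification


def test_read_in_cgi_inside_gene_body_classified_cgi(toy):
    part, cgis, repeats = toy
    rc = classify_reads([AlignedRead("chr1", 5_600, 5_650)], part, cgis, repeats)
    assert rc.counts == {"cgi": 1, "gene_body": 0, "repeat": 0, "other": 0}


def test_unannotated_read_is_other(toy):
    part, cgis, repeats = toy
    rc = classify_reads([AlignedRead("chr1", 40_000, 40_050)], part, cgis, repeats)
    assert rc.counts["other"] == 1


def test_empty_read_set_rejected(toy):
    part, cgis, repeats = toy
    with pytest.raises(ValueError):
        classify_reads([], part, cgis, repeats)


def test_read_classes_match_brute_force(dataset, partition, islands):
    reads = dataset.reads["WRR_h"][:5_000]
    rc = classify_reads(reads, partition, islands, dataset.repeats)
    assert sum(rc.counts.values()) == rc.total == len(reads)
    assert sum(rc.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def hits(read, ivs):
        return any(s < read.end and read.start < e for s, e in ivs)

    gene_ivs = {
        c: ivs for c, ivs in partition.label_intervals("gene_body").items()
    }
    expected = {"cgi": 0, "gene_body": 0, "repeat": 0, "other": 0}
    for r in reads:
        if hits(r, [(i.start, i.end) for i in islands if i.chrom == r.chrom]):
            expected["cgi"] += 1
        elif hits(r, gene_ivs.get(r.chrom, [])):
            expected["gene_body"] += 1
        elif hits(r, [(p.start, p.end) for p in dataset.repeats if p.chrom == r.chrom]):
            expected["repeat"] += 1
        else:
            expected["other"] += 1
    assert rc.counts == expected


# ---------------------------------------------------------------------------
# peak component counts and density


def test_peak_across_junction_counts_in_both_components(toy):
    part, cgis, repeats = toy
    counts = peak_component_counts([_peak("chr1", 5_950, 8_050)], part, cgis, repeats)
    assert counts.counts["exon"] == 1
    assert counts.counts["intron"] == 1
    assert counts.total_peaks == 1


def test_zero_peaks_all_zero(toy):
    part, cgis, repeats = toy
    counts = peak_component_counts([], part, cgis, repeats)
    assert counts.total_peaks == 0
    assert set(counts.counts.values()) == {0}


def test_component_counts_match_brute_force(dataset, partition, islands):
    peaks = [_peak(c, s, s + 400) for c, s, _ in dataset.cgi_truth[:6]] + [
        _peak(m.chrom, m.tx_start + 10, m.tx_start + 500) for m in dataset.transcripts[:6]
    ]
    counts = peak_component_counts(peaks, partition, islands, dataset.repeats)
    assert counts.total_peaks == len(peaks)
    for comp in ("promoter", "exon", "intron", "intergenic"):
        ivs = partition.label_intervals(comp)
        expected = sum(
            1
            for p in peaks
            if any(s < p.end and p.start < e for s, e in ivs.get(p.chrom, []))
        )
        assert counts.counts[comp] == expected, comp
    assert counts.total_peaks <= sum(counts.counts.values())


def test_density_is_peaks_per_megabase(toy):
    part, cgis, repeats = toy
    counts = ComponentPeakCounts({"promoter": 10, "intron": 0}, 10)
    fake_part = type(part)(
        {"promoter": {"chr1": [(0, 2_000_000)]}, "intron": {"chr1": [(0, 5_000_000)]}},
        chrom_sizes={"chr1": 10_000_000},
    )
    dens = {d.component: d.density for d in methylation_density(counts, fake_part)}
    assert dens["promoter"] == pytest.approx(5.0)
    assert dens["intron"] == 0.0


def test_zero_length_component_omitted(toy):
    part, _, _ = toy
    counts = ComponentPeakCounts({"cgi": 3}, 3)
    assert methylation_density(counts, part, {"cgi": 0}) == []


# ---------------------------------------------------------------------------
# CGI methylation status


def test_single_bp_overlap_makes_cgi_methylated(toy):
    part, _, _ = toy
    cgis = [CpGIsland("chr1", 1_000, 1_200, 0.6, 1.0)]
    summ = classify_cgis(cgis, [_peak("chr1", 1_199, 1_500)])
    assert summ.methylated == 1 and cgis[0].methylated is True
    summ = classify_cgis(cgis, [_peak("chr1", 1_200, 1_500)])
    assert summ.methylated == 0 and cgis[0].methylated is False


def test_no_peaks_zero_percent():
    cgis = [CpGIsland("chr1", 0, 300, 0.6, 1.0)]
    summ = classify_cgis(cgis, [])
    assert (summ.methylated, summ.percent_methylated) == (0, 0.0)


def test_reported_cgi_percentages_from_counts():
    """The one-decimal percent convention reproduces the published summary."""
    expected = {"WRR_h": 13.0, "WRR_l": 11.9, "XH_h": 13.0, "XH_l": 15.0}
    for sample, (meth, total) in CGI_METHYLATION_COUNTS.items():
        assert methylated_percent(meth, total) == expected[sample]


def test_adding_peaks_never_unmethylates(dataset, partition, islands):
    peaks = [_peak(c, s, e) for c, s, e in dataset.cgi_truth[:5]]
    more = peaks + [_peak(c, s - 1_000, s) for c, s, e in dataset.cgi_truth[5:10]]
    n1 = classify_cgis(islands, peaks).methylated
    n2 = classify_cgis(islands, more).methylated
    assert n2 >= n1


# ---------------------------------------------------------------------------
# size bins


def test_size_bins_place_islands_and_normalise(toy):
    part, _, _ = toy
    cgis = [
        CpGIsland("chr1", 0, 250, 0.6, 1.0, methylated=True),     # intergenic, bin 200-300
        CpGIsland("chr1", 30_000, 30_350, 0.6, 1.0, methylated=True),  # intergenic 300-400
        CpGIsland("chr1", 5_500, 5_850, 0.6, 1.0, methylated=True),    # promoter-overlapping
    ]
    dist = cgi_size_distribution(cgis, part)
    assert dist[True][(200, 300)]["intergenic"] == 1.0
    # 300-400 bin holds two islands, split between promoter and intergenic
    assert dist[True][(300, 400)]["intergenic"] == pytest.approx(0.5)
    assert dist[True][(300, 400)]["promoter"] == pytest.approx(0.5)
    for b, comps in dist[True].items():
        total = sum(comps.values())
        assert total == 0 or total == pytest.approx(1.0, abs=1e-9)


def test_undersized_island_rejected(toy):
    part, _, _ = toy
    with pytest.raises(ValueError):
        cgi_size_distribution([CpGIsland("chr1", 0, 150, 0.6, 1.0)], part)


# ---------------------------------------------------------------------------
# repeat distribution


def test_single_family_gets_hundred_percent():
    reps = [RepeatAnnotation("chr1", 0, 1_000, "LINE/CR1")]
    dist = repeat_peak_distribution([_peak("chr1", 100, 300)], reps)
    assert dist.percents == {"LINE/CR1": 100.0}


def test_two_families_split_evenly():
    reps = [
        RepeatAnnotation("chr1", 0, 1_000, "LINE/CR1"),
        RepeatAnnotation("chr1", 5_000, 6_000, "SINE"),
    ]
    peaks = [_peak("chr1", 100, 300), _peak("chr1", 5_100, 5_300)]
    dist = repeat_peak_distribution(peaks, reps)
    assert dist.percents == {"LINE/CR1": 50.0, "SINE": 50.0}


def test_multi_family_peak_split_fractionally():
    reps = [
        RepeatAnnotation("chr1", 0, 200, "LINE/CR1"),
        RepeatAnnotation("chr1", 250, 400, "SINE"),
    ]
    dist = repeat_peak_distribution([_peak("chr1", 100, 300)], reps)
    assert dist.percents == {"LINE/CR1": 50.0, "SINE": 50.0}


def test_repeat_percentages_sum_to_hundred(dataset):
    rng = np.random.default_rng(3)
    peaks = [
        _peak(r.chrom, max(0, r.start - 50), r.end + 50)
        for r in dataset.repeats[:: max(1, len(dataset.repeats) // 40)]
    ]
    dist = repeat_peak_distribution(peaks, dataset.repeats)
    assert dist.overlapping_peaks > 0
    assert sum(dist.percents.values()) == pytest.approx(100.0, abs=0.05)


def test_no_overlapping_peaks_empty_distribution():
    reps = [RepeatAnnotation("chr1", 0, 100, "SINE")]
    dist = repeat_peak_distribution([_peak("chr1", 500, 600)], reps)
    assert dist.percents == {} and dist.overlapping_peaks == 0
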